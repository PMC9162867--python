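import numpy as np
import pytest

from leukoswarm import (
    ExpressionDataset,
    FilterParams,
    SyntheticConfig,
    cfs_merit,
    cfs_select,
    ewusc_select,
    f_test_scores,
    generate_dataset,
    mrmr_select,
    shortlist,
    snr_scores,
    snr_select,
)
from conftest import random_dataset

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops, no shared code paths)
# ---------------------------------------------------------------------------


def oracle_f(values, labels):
    v0 = [x for x, l in zip(values, labels) if l == 0]
    v1 = [x for x, l in zip(values, labels) if l == 1]
    n0, n1 = len(v0), len(v1)
    mu0, mu1 = sum(v0) / n0, sum(v1) / n1
    mu = sum(values) / len(values)
    var0 = sum((x - mu0) ** 2 for x in v0) / (n0 - 1)
    var1 = sum((x - mu1) ** 2 for x in v1) / (n1 - 1)
    pooled = ((n0 - 1) * var0 + (n1 - 1) * var1) / (n0 + n1 - 1)
    if pooled == 0:
        return 0.0
    return (n0 * (mu0 - mu) ** 2 + n1 * (mu1 - mu) ** 2) / pooled


def oracle_snr(values, labels):
    v0 = np.array([x for x, l in zip(values, labels) if l == 0])
    v1 = np.array([x for x, l in zip(values, labels) if l == 1])
    denom = v0.std(ddof=1) + v1.std(ddof=1)
    return 0.0 if denom == 0 else (v0.mean() - v1.mean()) / denom


def oracle_merit(matrix, labels, subset):
    def corr(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))

    s = len(subset)
    rcf = np.mean([abs(corr(matrix[g], labels)) for g in subset])
    if s == 1:
        return s * rcf / np.sqrt(s)
    pairs = [
        abs(corr(matrix[g], matrix[h]))
        for i, g in enumerate(subset)
        for h in subset[i + 1 :]
    ]
    rff = np.mean(pairs)
    return s * rcf / np.sqrt(s + s * (s - 1) * rff)


def oracle_mrmr_step(matrix, F, selected, scheme):
    best, best_val = None, -np.inf
    for j in range(len(matrix)):
        if j in selected:
            continue
        dists = [
            max(np.sqrt(((matrix[j] - matrix[q]) ** 2).sum()), 1e-12)
            for q in selected
        ]
        if scheme == "FDM":
            val = F[j] * np.mean(dists)
        else:
            val = F[j] / np.mean([1.0 / d for d in dists])
        if val > best_val:
            best, best_val = j, val
    return best


# ---------------------------------------------------------------------------
# F-test
# ---------------------------------------------------------------------------


def test_f_score_hand_example():
    ds = ExpressionDataset(
        matrix=[[1, 2, 3, 4, 5, 6]],
        gene_ids=["g"], sample_ids=list("abcdef"),
        labels=[0, 0, 0, 1, 1, 1],
    )
    assert f_test_scores(ds)[0] == pytest.approx(16.875, abs=1e-12)


def test_f_score_constant_gene_is_zero():
    ds = ExpressionDataset(
        matrix=[[2.0] * 6, [1, 2, 3, 4, 5, 6]],
        gene_ids=["c", "g"], sample_ids=list("abcdef"),
        labels=[0, 0, 0, 1, 1, 1],
    )
    with pytest.warns(RuntimeWarning):
        scores = f_test_scores(ds)
    assert scores[0] == 0.0


def test_f_scores_match_brute_force_oracle():
    for seed in range(10):
        ds = random_dataset(20, 7, 5, seed)
        scores = f_test_scores(ds)
        for g in range(ds.n_genes):
            assert scores[g] == pytest.approx(
                oracle_f(ds.matrix[g].tolist(), ds.labels.tolist()), abs=1e-10
            )


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------


def test_snr_hand_example_and_conventions():
    ds = ExpressionDataset(
        matrix=[[3, 5, 1, 1]], gene_ids=["g"], sample_ids=list("abcd"),
        labels=[0, 0, 1, 1],
    )
    expected = 3 / np.sqrt(2)  # sd1 = 0 so both conventions agree
    assert snr_scores(ds, "sum")[0] == pytest.approx(expected, abs=1e-12)
    assert snr_scores(ds, "as_printed")[0] == pytest.approx(expected, abs=1e-12)


def test_snr_zero_for_equal_means_and_sign_symmetry():
    ds = random_dataset(10, 6, 6, 1)
    ds.matrix[0] = np.where(ds.labels == 0, 1.0, 1.0) + [0.1, -0.1] * 6
    snr = snr_scores(ds)
    flipped = ExpressionDataset(
        matrix=-ds.matrix, gene_ids=ds.gene_ids,
        sample_ids=ds.sample_ids, labels=ds.labels,
    )
    np.testing.assert_allclose(snr_scores(flipped), -snr, atol=1e-12)
    order_a = snr_select(ds, 10).gene_indices
    order_b = snr_select(flipped, 10).gene_indices
    np.testing.assert_array_equal(order_a, order_b)


def test_snr_matches_oracle_and_ranking_is_sorted():
    for seed in range(10):
        ds = random_dataset(20, 7, 5, 100 + seed)
        scores = snr_scores(ds)
        for g in range(ds.n_genes):
            assert scores[g] == pytest.approx(
                oracle_snr(ds.matrix[g], ds.labels), abs=1e-10
            )
        ranking = snr_select(ds, 8)
        assert np.all(np.diff(ranking.scores) <= 1e-15)


# ---------------------------------------------------------------------------
# MRMR
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("scheme", ["FDM", "FSQ"])
def test_mrmr_first_pick_is_argmax_f(tiny_dataset, scheme):
    ranking = mrmr_select(tiny_dataset, 1, scheme)
    assert ranking.gene_indices[0] == int(np.argmax(f_test_scores(tiny_dataset)))


@pytest.mark.parametrize("scheme", ["FDM", "FSQ"])
def test_mrmr_matches_stepwise_brute_force(scheme):
    for seed in range(8):
        ds = random_dataset(6, 7, 5, 200 + seed)
        F = f_test_scores(ds)
        ranking = mrmr_select(ds, 3, scheme)
        selected = [int(ranking.gene_indices[0])]
        assert selected[0] == int(np.argmax(F))
        for step in (1, 2):
            expect = oracle_mrmr_step(ds.matrix, F, set(selected), scheme)
            assert int(ranking.gene_indices[step]) == expect
            selected.append(expect)


def test_mrmr_fsq_never_picks_duplicate_of_top_gene():
    ds = random_dataset(5, 7, 5, 3)
    ds.matrix[0] += np.where(ds.labels == 0, 2.0, -2.0)  # strong top gene
    ds.matrix[1] = ds.matrix[0].copy()  # exact duplicate
    ranking = mrmr_select(ds, 4, "FSQ")
    assert ranking.gene_indices[0] in (0, 1)
    assert ranking.gene_indices[1] not in (0, 1)


def test_mrmr_k_exceeding_p_errors(tiny_dataset):
    with pytest.raises(ValueError):
        mrmr_select(tiny_dataset, 99)


# ---------------------------------------------------------------------------
# EWUSC
# ---------------------------------------------------------------------------


def test_ewusc_usc_stage_removes_duplicated_gene():
    ds = random_dataset(20, 10, 8, 4)
    ds.matrix[2] += np.where(ds.labels == 0, 3.0, -3.0)
    ds.matrix[5] = ds.matrix[2].copy()
    ranking = ewusc_select(ds, 5, rho_threshold=0.9)
    chosen = set(ranking.gene_indices.tolist())
    assert len(chosen & {2, 5}) == 1


def test_ewusc_inert_stages_reduce_to_sc_ordering():
    # unit-variance rows, delta 0, rho threshold 1 -> pure SC score ordering
    ds = random_dataset(12, 10, 8, 5)
    ds.matrix[1] += np.where(ds.labels == 0, 2.0, -2.0)
    ds.matrix[7] += np.where(ds.labels == 0, -1.0, 1.0)
    ds.matrix /= ds.matrix.std(axis=1, ddof=0, keepdims=True)
    from leukoswarm.filters import _centroid_stats

    _, _, _, s, _, d = _centroid_stats(ds.matrix, ds.labels)
    sc = np.abs(d).sum(axis=0)
    expected = np.lexsort((np.arange(12), -sc))[:6]
    ranking = ewusc_select(ds, 6, delta_grid=(0.0,), rho_threshold=1.0)
    # EW reweighting by 1/(s^2+eps) is near-constant for (near) unit variances
    np.testing.assert_array_equal(np.sort(ranking.gene_indices),
                                  np.sort(expected))


def test_ewusc_prefers_originals_over_correlated_copies():
    hits_orig, hits_copy = [], []
    for seed in range(10):
        cfg = SyntheticConfig(
            p=60, n_informative=10, n_redundant_blocks=2, block_size=5,
            block_rho=0.95, effect_size=3.0, seed=seed,
        )
        ds, truth = generate_dataset(cfg)
        chosen = set(ewusc_select(ds, 10).gene_indices.tolist())
        planted = set(truth.informative_genes.tolist())
        copies = set(np.concatenate(truth.redundant_blocks).tolist())
        hits_orig.append(len(chosen & planted))
        hits_copy.append(len(chosen & copies))
    assert np.median(hits_orig) >= 8
    assert np.median(hits_copy) <= 2


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------


def test_cfs_merit_singleton_and_duplicate_pairs():
    ds = random_dataset(6, 8, 6, 6)
    ds.matrix[0] += np.where(ds.labels == 0, 1.0, -1.0)
    ds.matrix[1] = ds.matrix[0].copy()
    r = oracle_merit(ds.matrix, ds.labels, [0])
    assert cfs_merit(ds, [0]) == pytest.approx(r, abs=1e-10)
    # two identical genes: merit collapses to the single-gene correlation
    assert cfs_merit(ds, [0, 1]) == pytest.approx(r, abs=1e-10)


def test_cfs_merit_matches_oracle_on_random_subsets():
    rng = np.random.default_rng(0)
    for seed in range(6):
        ds = random_dataset(12, 7, 5, 300 + seed)
        subset = rng.choice(12, size=4, replace=False).tolist()
        assert cfs_merit(ds, subset) == pytest.approx(
            oracle_merit(ds.matrix, ds.labels, sorted(subset)), abs=1e-10
        )


@pytest.mark.parametrize("search", ["forward", "best_first"])
def test_cfs_search_beats_random_subsets(search):
    wins = 0
    for seed in range(10):
        cfg = SyntheticConfig(p=8, n_informative=3, n_redundant_blocks=0,
                              effect_size=3.0, seed=seed)
        ds, _ = generate_dataset(cfg)
        found = cfs_select(ds, 3, search=search).gene_indices[:3].tolist()
        found_merit = cfs_merit(ds, found)
        rng = np.random.default_rng(seed)
        rand_best = max(
            cfs_merit(ds, rng.choice(8, size=3, replace=False).tolist())
            for _ in range(200)
        )
        wins += found_merit >= rand_best - 1e-12
    assert wins == 10


def test_cfs_pads_to_exactly_k():
    ds = random_dataset(30, 8, 6, 9)
    ranking = cfs_select(ds, 20)
    assert ranking.pool_size == 20
    assert len(set(ranking.gene_indices.tolist())) == 20


# ---------------------------------------------------------------------------
# shortlist dispatcher + shared properties
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("method", ["snr", "mrmr_fdm", "mrmr_fsq", "ewusc", "cfs"])
def test_shortlist_returns_unique_pool(method, planted_dataset):
    ds, truth = planted_dataset
    ranking = shortlist(ds, method, FilterParams(pool_size=40))
    assert ranking.pool_size == 40
    assert len(set(ranking.gene_indices.tolist())) == 40


def test_shortlist_full_pool_is_permutation(tiny_dataset):
    ranking = shortlist(tiny_dataset, "snr", FilterParams(pool_size=6))
    assert sorted(ranking.gene_indices.tolist()) == list(range(6))


@pytest.mark.parametrize("method", ["snr", "mrmr_fdm", "ewusc", "cfs"])
def test_shortlist_captures_planted_genes(method):
    hits = []
    for seed in range(10):
        cfg = SyntheticConfig(p=120, n_informative=8, n_redundant_blocks=0,
                              effect_size=2.0, seed=40 + seed)
        ds, truth = generate_dataset(cfg)
        pool = set(shortlist(ds, method, FilterParams(pool_size=40)).gene_indices.tolist())
        hits.append(len(pool & set(truth.informative_genes.tolist())))
    assert np.median(hits) == 8


def test_selectors_deterministic_and_scale_equivariant(tiny_dataset):
    a = shortlist(tiny_dataset, "snr", FilterParams(pool_size=6))
    b = shortlist(tiny_dataset, "snr", FilterParams(pool_size=6))
    np.testing.assert_array_equal(a.gene_indices, b.gene_indices)
    scaled = ExpressionDataset(
        matrix=tiny_dataset.matrix * 7.5,
        gene_ids=tiny_dataset.gene_ids,
        sample_ids=tiny_dataset.sample_ids,
        labels=tiny_dataset.labels,
    )
    np.testing.assert_allclose(
        snr_scores(scaled), snr_scores(tiny_dataset), atol=1e-12
    )
    assert cfs_merit(scaled, [0, 3]) == pytest.approx(
        cfs_merit(tiny_dataset, [0, 3]), abs=1e-12
    )
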