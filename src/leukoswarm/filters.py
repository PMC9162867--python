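"""First-level gene selection: score all genes, shortlist a pool.

Four families are provided:

* **F-test / MRMR** — per-gene one-way F statistic with pooled
  ``(n - 1)`` variance, plus greedy minimum-redundancy-maximum-relevance
  selection in multiplicative (FDM) or quotient (FSQ) form, redundancy
  measured by Euclidean distance between gene expression vectors.
* **SNR** — signal-to-noise ratio (difference of class means over the
  class standard deviations), genes ranked by |SNR|.
* **EWUSC** — error-weighted uncorrelated shrunken centroid: soft-
  thresholded standardized centroid deviations (shrinkage chosen by
  internal cross-validation of the nearest-shrunken-centroid rule),
  correlated-gene removal, then down-weighting by within-class variance.
* **CFS** — correlation-based feature selection maximizing the subset
  merit s*rcf / sqrt(s + s(s-1)*rff) by best-first or forward search.

All selectors are deterministic given dataset + params; score ties break
by ascending gene index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from heapq import heappush, heappop

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datasets import ExpressionDataset, GeneRanking, rank_by_score, warn_once

__all__ = [
    "FilterParams",
    "f_test_scores",
    "mrmr_select",
    "snr_scores",
    "snr_select",
    "ewusc_select",
    "cfs_merit",
    "cfs_select",
    "shortlist",
]

_D_CLAMP = 1e-12  # zero-distance clamp so FSQ's 1/d stays finite

FILTER_METHODS = ("mrmr_fdm", "mrmr_fsq", "snr", "ewusc", "cfs")


@dataclass
class FilterParams:
    """Knobs shared by the shortlist dispatcher."""

    pool_size: int = 2000
    mrmr_scheme: str = "FDM"  # FDM | FSQ
    snr_convention: str = "sum"  # sum | as_printed
    ewusc_delta_grid: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    ewusc_rho_threshold: float = 0.9
    cfs_search: str = "best_first"  # best_first | forward
    cfs_stall_limit: int = 5
    seed: int = 0  # internal CV folds for EWUSC shrinkage choice


def _class_split(ds: ExpressionDataset):
    m0 = ds.matrix[:, ds.labels == 0]
    m1 = ds.matrix[:, ds.labels == 1]
    return m0, m1


def f_test_scores(ds: ExpressionDataset) -> np.ndarray:
    """Two-class one-way F score per gene.

    F(Y_j) = sum_k n_k (mu_jk - mu_j)^2 / [(m - 1) sigma^2] with the pooled
    variance sigma^2 = sum_k (n_k - 1) s_k^2 / (n - 1).  Constant genes
    (zero pooled variance) score 0.
    """
    m0, m1 = _class_split(ds)
    n0, n1 = m0.shape[1], m1.shape[1]
    n = n0 + n1
    mu0, mu1 = m0.mean(axis=1), m1.mean(axis=1)
    mu = ds.matrix.mean(axis=1)
    var0 = m0.var(axis=1, ddof=1)
    var1 = m1.var(axis=1, ddof=1)
    pooled = ((n0 - 1) * var0 + (n1 - 1) * var1) / (n - 1)
    num = n0 * (mu0 - mu) ** 2 + n1 * (mu1 - mu) ** 2
    out = np.zeros(ds.n_genes)
    ok = pooled > 0
    if not ok.all():
        warn_once("f_test_scores: zero pooled variance gene(s) scored 0")
    out[ok] = num[ok] / ((2 - 1) * pooled[ok])
    return out


def snr_scores(ds: ExpressionDataset, convention: str = "sum") -> np.ndarray:
    """Signed SNR per gene: (mean0 - mean1) / (sd0 + sd1).

    ``convention="as_printed"`` divides by (sd0 - sd1) instead; the sum is
    the default because the difference is sign-unstable for near-equal
    spreads.  Zero denominators score 0.
    """
    m0, m1 = _class_split(ds)
    mu0, mu1 = m0.mean(axis=1), m1.mean(axis=1)
    sd0 = m0.std(axis=1, ddof=1)
    sd1 = m1.std(axis=1, ddof=1)
    if convention == "sum":
        denom = sd0 + sd1
    elif convention == "as_printed":
        denom = sd0 - sd1
    else:
        raise ValueError(f"unknown SNR convention {convention!r}")
    out = np.zeros(ds.n_genes)
    ok = denom != 0
    if not ok.all():
        warn_once("snr_scores: zero denominator gene(s) scored 0")
    out[ok] = (mu0 - mu1)[ok] / denom[ok]
    return out


def snr_select(ds: ExpressionDataset, k: int, convention: str = "sum") -> GeneRanking:
    """Top-k genes by |SNR| (sign only marks the overexpressing class)."""
    if k > ds.n_genes:
        raise ValueError(f"k={k} exceeds p={ds.n_genes}")
    snr = snr_scores(ds, convention)
    order = rank_by_score(np.abs(snr), k)
    return GeneRanking(
        gene_indices=order,
        scores=np.abs(snr)[order],
        method="SNR",
        gene_ids=[ds.gene_ids[i] for i in order],
    )


def mrmr_select(
    ds: ExpressionDataset, k: int, scheme: str = "FDM"
) -> GeneRanking:
    """Greedy MRMR: F-relevance with Euclidean-distance redundancy.

    The first gene is argmax F.  Each later pick maximizes, over unselected
    genes j, F_j * mean_d(j, T) for FDM or F_j / mean(1/d(j, T)) for FSQ,
    where T is the selected set.  Distances clamp at 1e-12 so duplicated
    probes keep the quotient finite.
    """
    scheme = scheme.upper()
    if scheme not in ("FDM", "FSQ"):
        raise ValueError(f"unknown MRMR scheme {scheme!r}")
    p = ds.n_genes
    if k > p:
        raise ValueError(f"k={k} exceeds p={p}")
    F = f_test_scores(ds)
    X = ds.matrix
    selected: list[int] = []
    scores: list[float] = []
    first = int(rank_by_score(F, 1)[0])
    selected.append(first)
    scores.append(float(F[first]))
    sum_d = np.zeros(p)
    sum_invd = np.zeros(p)
    available = np.ones(p, dtype=bool)
    available[first] = False
    last = first
    while len(selected) < k:
        d = np.sqrt(((X - X[last]) ** 2).sum(axis=1))
        d = np.maximum(d, _D_CLAMP)
        sum_d += d
        sum_invd += 1.0 / d
        t = len(selected)
        if scheme == "FDM":
            crit = F * (sum_d / t)
        else:
            crit = F / (sum_invd / t)
        crit = np.where(available, crit, -np.inf)
        nxt = int(np.lexsort((np.arange(p), -crit))[0])
        selected.append(nxt)
        scores.append(float(crit[nxt]))
        available[nxt] = False
        last = nxt
    idx = np.array(selected, dtype=int)
    return GeneRanking(
        gene_indices=idx,
        scores=np.array(scores),
        method=f"MRMR_{scheme}",
        gene_ids=[ds.gene_ids[i] for i in idx],
    )


# ---------------------------------------------------------------------------
# EWUSC
# ---------------------------------------------------------------------------


def _centroid_stats(X: np.ndarray, y: np.ndarray):
    """Standardized centroid deviations for the shrunken-centroid rule."""
    n = X.shape[1]
    classes = (0, 1)
    mu = X.mean(axis=1)
    within_ss = np.zeros(X.shape[0])
    mus, mks = [], []
    for c in classes:
        Xi = X[:, y == c]
        nk = Xi.shape[1]
        mu_k = Xi.mean(axis=1)
        within_ss += ((Xi - mu_k[:, None]) ** 2).sum(axis=1)
        mus.append(mu_k)
        mks.append(np.sqrt(1.0 / nk - 1.0 / n))
    s = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(np.median(s))
    denom = s + s0
    denom = np.where(denom > 0, denom, 1.0)
    d = np.stack([(mus[i] - mu) / (mks[i] * denom) for i in range(2)])  # (2, p)
    return mu, mus, mks, s, s0, d


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _nsc_predict(X_train, y_train, X_test, delta: float) -> np.ndarray:
    """Nearest-shrunken-centroid prediction (used to pick the shrinkage)."""
    n = X_train.shape[1]
    mu, mus, mks, s, s0, d = _centroid_stats(X_train, y_train)
    dprime = _soft_threshold(d, delta)
    denom = s + s0
    denom = np.where(denom > 0, denom, 1.0)
    scores = np.empty((X_test.shape[1], 2))
    for c in range(2):
        centroid = mu + mks[c] * denom * dprime[c]
        prior = (y_train == c).sum() / n
        dist = ((X_test - centroid[:, None]) ** 2 / (denom**2)[:, None]).sum(axis=0)
        scores[:, c] = dist - 2.0 * np.log(prior)
    return scores.argmin(axis=1)


def _choose_delta(ds: ExpressionDataset, grid, folds: int, seed: int) -> float:
    """Pick the shrinkage level by internal CV accuracy (ties -> smaller)."""
    y = ds.labels
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        return float(grid[0])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = np.zeros(len(grid))
    for tr, te in skf.split(y.reshape(-1, 1), y):
        Xtr, Xte = ds.matrix[:, tr], ds.matrix[:, te]
        for gi, delta in enumerate(grid):
            pred = _nsc_predict(Xtr, y[tr], Xte, float(delta))
            acc[gi] += (pred == y[te]).sum()
    best = int(np.lexsort((np.asarray(grid, float), -acc))[0])
    return float(grid[best])


def ewusc_select(
    ds: ExpressionDataset,
    k: int,
    delta_grid=(0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
    rho_threshold: float = 0.9,
    cv_folds: int = 5,
    seed: int = 0,
) -> GeneRanking:
    """Error-weighted uncorrelated shrunken-centroid selection.

    Three stages: (SC) keep genes with nonzero soft-thresholded centroid
    deviation at a shrinkage level chosen by internal CV; (USC) scan
    survivors in descending score order dropping any gene whose |Pearson
    correlation| with an already-kept gene exceeds ``rho_threshold``;
    (EW) weight scores by 1/(pooled within-class variance + 1e-8).
    Returns the top-k weighted survivors, padding (with a warning) only if
    the stages leave fewer than k genes.
    """
    if not (0.0 < rho_threshold <= 1.0):
        raise ValueError("rho_threshold must be in (0, 1]")
    if k > ds.n_genes:
        raise ValueError(f"k={k} exceeds p={ds.n_genes}")
    grid = sorted(float(g) for g in delta_grid)
    delta = _choose_delta(ds, grid, cv_folds, seed)
    _, _, _, s, _, d = _centroid_stats(ds.matrix, ds.labels)

    def retained_scores(dl: float):
        dprime = _soft_threshold(d, dl)
        sc = np.abs(dprime).sum(axis=0)
        return sc, np.flatnonzero(sc > 0)

    sc_scores, retained = retained_scores(delta)
    if len(retained) < k:
        for dl in grid:  # smallest shrinkage retaining >= k genes
            sc_scores, retained = retained_scores(dl)
            if len(retained) >= k:
                warn_once(
                    f"ewusc_select: shrinkage {delta} kept too few genes; fell back to {dl}"
                )
                delta = dl
                break

    # USC: drop genes too correlated with an already-retained, higher-scoring gene
    order = retained[np.lexsort((retained, -sc_scores[retained]))]
    Xc = ds.matrix - ds.matrix.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    kept: list[int] = []
    removed: list[int] = []
    for g in order:
        if norms[g] == 0:
            removed.append(int(g))
            continue
        ok = True
        for h in kept:
            r = abs(float(Xc[g] @ Xc[h]) / (norms[g] * norms[h]))
            if r > rho_threshold:
                ok = False
                break
        (kept if ok else removed).append(int(g))

    weights = 1.0 / (s**2 + 1e-8)
    final = np.array(kept, dtype=int)
    final_scores = sc_scores[final] * weights[final]
    pick = final[np.lexsort((final, -final_scores))]
    pick_scores = sc_scores[pick] * weights[pick]
    if len(pick) < k:
        warn_once("ewusc_select: padding with USC-removed/unretained genes to reach k")
        fallback = np.abs(d).sum(axis=0) * weights
        rest = [g for g in rank_by_score(fallback) if g not in set(pick.tolist())]
        pad = np.array(rest[: k - len(pick)], dtype=int)
        pick = np.concatenate([pick, pad])
        pick_scores = np.concatenate([pick_scores, fallback[pad]])
    idx = pick[:k]
    return GeneRanking(
        gene_indices=idx,
        scores=pick_scores[:k],
        method="EWUSC",
        gene_ids=[ds.gene_ids[i] for i in idx],
    )


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------


def _abs_corr_with_label(ds: ExpressionDataset) -> np.ndarray:
    yc = ds.labels - ds.labels.mean()
    Xc = ds.matrix - ds.matrix.mean(axis=1, keepdims=True)
    num = Xc @ yc
    den = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    out = np.zeros(ds.n_genes)
    ok = den > 0
    out[ok] = np.abs(num[ok] / den[ok])
    return out


class _CorrCache:
    """Lazy |Pearson| rows of the gene-gene correlation matrix."""

    def __init__(self, ds: ExpressionDataset):
        self.Xc = ds.matrix - ds.matrix.mean(axis=1, keepdims=True)
        self.norms = np.sqrt((self.Xc**2).sum(axis=1))
        self._rows: dict[int, np.ndarray] = {}

    def row(self, g: int) -> np.ndarray:
        if g not in self._rows:
            den = self.norms * self.norms[g]
            num = self.Xc @ self.Xc[g]
            out = np.zeros(len(den))
            ok = den > 0
            out[ok] = np.abs(num[ok] / den[ok])
            self._rows[g] = out
        return self._rows[g]


def _merit(sum_cf: float, pair_sum: float, s: int) -> float:
    """CFS merit from the sum of |gene-class| corr and pairwise |corr| sum."""
    if s == 0:
        return 0.0
    return sum_cf / np.sqrt(s + 2.0 * pair_sum)


def cfs_merit(ds: ExpressionDataset, subset) -> float:
    """Heuristic merit s*rcf_bar / sqrt(s + s(s-1)*rff_bar) of a gene subset."""
    subset = sorted(int(g) for g in subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    rcf = _abs_corr_with_label(ds)
    cache = _CorrCache(ds)
    sum_cf = float(rcf[subset].sum())
    pair_sum = 0.0
    for i, g in enumerate(subset):
        row = cache.row(g)
        for h in subset[i + 1 :]:
            pair_sum += float(row[h])
    return float(_merit(sum_cf, pair_sum, len(subset)))


def cfs_select(
    ds: ExpressionDataset,
    k: int,
    search: str = "best_first",
    stall_limit: int = 5,
) -> GeneRanking:
    """Merit-maximizing subset search, padded to exactly k genes.

    ``best_first`` keeps a priority queue of partial subsets and stops after
    ``stall_limit`` expansions without improving the best merit (or on
    reaching size k); ``forward`` is plain greedy with the same stall rule.
    Genes beyond the search result are padded by class-correlation rank.
    """
    if k > ds.n_genes:
        raise ValueError(f"k={k} exceeds p={ds.n_genes}")
    if search not in ("best_first", "forward"):
        raise ValueError(f"unknown CFS search {search!r}")
    p = ds.n_genes
    rcf = _abs_corr_with_label(ds)
    cache = _CorrCache(ds)

    def children(sel: tuple, sum_cf: float, cand_ff: np.ndarray):
        s = len(sel) + 1
        merits = np.full(p, -np.inf)
        mask = np.ones(p, dtype=bool)
        mask[list(sel)] = False
        cand = np.flatnonzero(mask)
        merits[cand] = (sum_cf + rcf[cand]) / np.sqrt(s + 2.0 * cand_ff[cand])
        return merits

    best_sel: tuple = ()
    best_merit = -np.inf
    order_added: list[int] = []
    merit_at_add: list[float] = []

    if search == "forward":
        sel: tuple = ()
        sum_cf, cand_ff = 0.0, np.zeros(p)
        stall = 0
        while len(sel) < k and stall <= stall_limit:
            merits = children(sel, sum_cf, cand_ff)
            g = int(np.lexsort((np.arange(p), -merits))[0])
            m = float(merits[g])
            sel = sel + (g,)
            sum_cf += float(rcf[g])
            cand_ff = cand_ff + cache.row(g)
            order_added.append(g)
            merit_at_add.append(m)
            if m > best_merit:
                best_merit, best_sel, stall = m, sel, 0
            else:
                stall += 1
    else:
        # node: (-merit, counter, sel tuple, sum_cf, cand_ff)
        heap: list = []
        counter = 0
        heappush(heap, (0.0, counter, (), 0.0, np.zeros(p)))
        visited: set[frozenset] = set()
        stall = 0
        merit_of: dict[int, float] = {}
        while heap and stall <= stall_limit:
            _, _, sel, sum_cf, cand_ff = heappop(heap)
            if len(sel) >= k:
                continue
            key = frozenset(sel)
            if key in visited:
                continue
            visited.add(key)
            merits = children(sel, sum_cf, cand_ff)
            ranked = np.lexsort((np.arange(p), -merits))
            improved = False
            for g in ranked[: min(5, p)]:  # beam over the best few additions
                g = int(g)
                if not np.isfinite(merits[g]):
                    continue
                child = tuple(sorted(sel + (g,)))
                m = float(merits[g])
                counter += 1
                heappush(heap, (-m, counter, child, sum_cf + float(rcf[g]),
                                cand_ff + cache.row(g)))
                if m > best_merit:
                    best_merit, best_sel = m, child
                    improved = True
                for gg in child:
                    merit_of.setdefault(gg, m)
            stall = 0 if improved else stall + 1
            if len(best_sel) >= k:
                break
        order_added = list(best_sel)
        merit_at_add = [merit_of.get(g, best_merit) for g in order_added]

    chosen = list(dict.fromkeys(order_added if search == "forward" else list(best_sel)))
    chosen = chosen[:k]
    scores = list(merit_at_add[: len(chosen)])
    if len(chosen) < k:
        seen = set(chosen)
        for g in rank_by_score(rcf):
            if len(chosen) >= k:
                break
            if int(g) not in seen:
                chosen.append(int(g))
                scores.append(float(rcf[g]))
    idx = np.array(chosen, dtype=int)
    return GeneRanking(
        gene_indices=idx,
        scores=np.array(scores, dtype=float),
        method="CFS",
        gene_ids=[ds.gene_ids[i] for i in idx],
    )


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


def shortlist(
    ds: ExpressionDataset, method: str, params: FilterParams | None = None
) -> GeneRanking:
    """First-level shortlist: top ``params.pool_size`` genes by one method."""
    params = params or FilterParams()
    method = method.lower()
    k = min(params.pool_size, ds.n_genes) if params.pool_size else ds.n_genes
    if params.pool_size > ds.n_genes:
        raise ValueError(
            f"pool_size={params.pool_size} exceeds p={ds.n_genes}"
        )
    if method == "snr":
        return snr_select(ds, k, params.snr_convention)
    if method in ("mrmr_fdm", "mrmr_fsq"):
        return mrmr_select(ds, k, scheme=method.split("_")[1])
    if method == "mrmr":
        return mrmr_select(ds, k, scheme=params.mrmr_scheme)
    if method == "ewusc":
        return ewusc_select(
            ds,
            k,
            delta_grid=params.ewusc_delta_grid,
            rho_threshold=params.ewusc_rho_threshold,
            seed=params.seed,
        )
    if method == "cfs":
        return cfs_select(ds, k, search=params.cfs_search, stall_limit=params.cfs_stall_limit)
    raise ValueError(f"unknown filter method {method!r}; choose from {FILTER_METHODS}")
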