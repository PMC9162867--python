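"""Second-level ("dual level") gene selection.

A fixed-size gene subset drawn from the first-level shortlist is encoded
as a real-valued optimizer position: one coordinate per subset slot,
each in [0, pool_size).  Coordinates floor to pool ranks; colliding
ranks advance cyclically to the next unused rank, so every in-bounds
position decodes to exactly k unique genes and every k-subset of the
pool has a preimage.  The optimizers maximize the inner cross-validated
accuracy (on the percent scale of the evaluation metrics) of a fast classifier on
the decoded subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import classify
from .datasets import ExpressionDataset, GeneRanking
from .filters import FilterParams, shortlist
from .metrics import confusion_counts, metrics_from_counts, minority_class, stratified_kfold
from .optimizers import ObjectiveSpec, OptimizationResult, OptimizerConfig, optimize

__all__ = [
    "SubsetEncoding",
    "WrapperConfig",
    "decode_ranks",
    "decode_position",
    "subset_fitness",
    "dual_level_select",
]

_EDGE = 1e-9  # keeps the upper bound open so floor() stays below pool_size


@dataclass
class SubsetEncoding:
    """Rank-space encoding of k-subsets of a shortlist pool."""

    pool: GeneRanking
    k: int

    def __post_init__(self):
        if self.k > self.pool.pool_size:
            raise ValueError(f"k={self.k} exceeds pool_size={self.pool.pool_size}")

    @property
    def position_dim(self) -> int:
        return self.k

    @property
    def lower(self) -> np.ndarray:
        return np.zeros(self.k)

    @property
    def upper(self) -> np.ndarray:
        return np.full(self.k, self.pool.pool_size - _EDGE)


def decode_ranks(pos: np.ndarray, pool_size: int) -> np.ndarray:
    """Floor coordinates to pool ranks; duplicates advance cyclically."""
    ranks = np.floor(np.asarray(pos, dtype=float)).astype(int)
    ranks = np.clip(ranks, 0, pool_size - 1)
    used = np.zeros(pool_size, dtype=bool)
    out = np.empty(len(ranks), dtype=int)
    for i, r in enumerate(ranks):
        while used[r]:
            r = (r + 1) % pool_size
        used[r] = True
        out[i] = r
    return out


def decode_position(pos: np.ndarray, enc: SubsetEncoding) -> np.ndarray:
    """Gene indices (into the originating dataset) for an optimizer position."""
    ranks = decode_ranks(pos, enc.pool.pool_size)
    return enc.pool.gene_indices[ranks]


@dataclass
class WrapperConfig:
    """Wrapper-objective settings: inner surrogate CV and the optimizer."""

    inner_classifier: str = "PNN"
    inner_folds: int = 5
    optimizer_cfg: OptimizerConfig = field(default_factory=OptimizerConfig)
    leakage_mode: str = "nested"  # nested | paper_faithful (pipeline-level)
    seed: int = 0


def subset_fitness(ds: ExpressionDataset, subset, wcfg: WrapperConfig) -> float:
    """Inner cross-validated accuracy (percent, 0-100) of a gene subset.

    Pools PC/MC/FA over ``inner_folds`` stratified folds and returns the
    balanced (sensitivity+specificity)/2 accuracy.  Deterministic given
    ``wcfg.seed``.  Folds shrink automatically if a class is too small.
    """
    subset = np.asarray(list(subset), dtype=int)
    if len(subset) == 0:
        raise ValueError("subset must be nonempty")
    folds = min(wcfg.inner_folds, int(np.bincount(ds.labels).min()))
    plan = stratified_kfold(ds.labels, k=max(folds, 2), seed=wcfg.seed)
    X = ds.samples_x_genes(subset)
    y = ds.labels
    pos = minority_class(y)
    pc = mc = fa = 0
    for tr, te in plan.folds():
        model = classify.train(
            wcfg.inner_classifier, X[tr], y[tr], seed=wcfg.seed
        )
        a, b, c = confusion_counts(model.predict(X[te]), y[te], pos)
        pc, mc, fa = pc + a, mc + b, fa + c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(metrics_from_counts(pc, mc, fa).accuracy)


class _CachedFitness:
    """Memoizes subset fitness by gene-index set; subsets recur late in a run."""

    def __init__(self, ds, enc, wcfg):
        self.ds, self.enc, self.wcfg = ds, enc, wcfg
        self.cache: dict[frozenset, float] = {}

    def __call__(self, pos: np.ndarray) -> float:
        genes = decode_position(pos, self.enc)
        key = frozenset(genes.tolist())
        if key not in self.cache:
            self.cache[key] = subset_fitness(self.ds, genes, self.wcfg)
        return self.cache[key]


def dual_level_select(
    ds: ExpressionDataset,
    filter_method: str,
    fparams: FilterParams | None,
    wcfg: WrapperConfig,
    k: int,
    pool: GeneRanking | None = None,
) -> tuple[np.ndarray, OptimizationResult]:
    """Filter shortlist, then metaheuristic refinement to k genes.

    Returns the decoded best subset (dataset gene indices) and the
    optimizer trace.  ``pool`` short-circuits the first level when the
    shortlist was already computed.  With k >= pool_size the pool itself
    is returned and the optimizer is bypassed.
    """
    fparams = fparams or FilterParams()
    if pool is None:
        pool = shortlist(ds, filter_method, fparams)
    if k >= pool.pool_size:
        genes = pool.gene_indices.copy()
        fit = subset_fitness(ds, genes, wcfg)
        trivial = OptimizationResult(
            best_position=np.arange(len(genes), dtype=float),
            best_fitness=fit,
            history=np.array([fit]),
            evaluations=1,
            seed=wcfg.optimizer_cfg.seed,
        )
        return genes, trivial
    enc = SubsetEncoding(pool=pool, k=k)
    fitness = _CachedFitness(ds, enc, wcfg)
    obj = ObjectiveSpec(
        fitness=fitness, lower=enc.lower, upper=enc.upper, direction="maximize"
    )
    ocfg = replace(wcfg.optimizer_cfg)
    result = optimize(obj, ocfg)
    genes = decode_position(result.best_position, enc)
    return genes, result
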