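"""Synthetic two-class microarray generator with known ground truth.

Emulates the structure of a classic two-class leukemia expression matrix
(default 7129 genes, 47 vs 25 samples): a small planted set of
class-discriminative genes whose class means are shifted by
``effect_size`` within-class standard deviations, optional blocks of
mutually correlated genes derived from class-informative latent signals
(what redundancy-aware selectors should penalise), and pure-noise genes
everywhere else.  Every dataset comes with its :class:`GroundTruth` so
downstream selection stages have a parameter-recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset"]


@dataclass
class SyntheticConfig:
    """Generator parameters.

    ``effect_size`` is the between-class mean shift in units of the
    within-class standard deviation ``noise_sd`` (applied symmetrically,
    +/- effect_size/2, with a random overexpressing class per gene).
    Redundant blocks share a latent class-informative signal mixed so that
    within-block pairwise correlation is approximately ``block_rho``.
    """

    n_class0: int = 47
    n_class1: int = 25
    p: int = 7129
    n_informative: int = 50
    effect_size: float = 2.0
    n_redundant_blocks: int = 5
    block_size: int = 10
    block_rho: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0
    class_names: tuple[str, str] = ("ALL", "AML")

    def validate(self) -> None:
        if self.n_class0 < 2 or self.n_class1 < 2:
            raise ValueError("each class needs >= 2 samples")
        if self.n_informative + self.n_redundant_blocks * self.block_size > self.p:
            raise ValueError("planted + redundant genes exceed p")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError("block_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset (index sets are disjoint)."""

    informative_genes: np.ndarray
    redundant_blocks: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    @property
    def all_planted(self) -> np.ndarray:
        parts = [self.informative_genes] + list(self.redundant_blocks)
        return np.concatenate(parts) if parts else np.array([], dtype=int)


def generate_dataset(cfg: SyntheticConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset; identical config (incl. seed) gives identical output."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_class0 + cfg.n_class1
    labels = np.concatenate(
        [np.zeros(cfg.n_class0, dtype=int), np.ones(cfg.n_class1, dtype=int)]
    )
    # class-shift template: label 0 -> +1/2, label 1 -> -1/2 (sign flipped per gene)
    half_shift = np.where(labels == 0, 0.5, -0.5)

    matrix = rng.normal(0.0, cfg.noise_sd, size=(cfg.p, n))

    # disjoint random placement of planted structure
    n_block_genes = cfg.n_redundant_blocks * cfg.block_size
    planted = rng.permutation(cfg.p)[: cfg.n_informative + n_block_genes]
    informative = np.sort(planted[: cfg.n_informative])
    block_slices = planted[cfg.n_informative :]
    blocks = [
        np.sort(block_slices[b * cfg.block_size : (b + 1) * cfg.block_size])
        for b in range(cfg.n_redundant_blocks)
    ]

    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)
    matrix[informative] += (
        signs[:, None] * half_shift[None, :] * cfg.effect_size * cfg.noise_sd
    )

    for block in blocks:
        sign = rng.choice([-1.0, 1.0])
        latent = sign * half_shift * cfg.effect_size * cfg.noise_sd + rng.normal(
            0.0, cfg.noise_sd, size=n
        )
        u = (latent - latent.mean()) / latent.std()  # unit sample variance
        eps = rng.normal(0.0, 1.0, size=(len(block), n))
        matrix[block] = cfg.noise_sd * (
            np.sqrt(cfg.block_rho) * u[None, :] + np.sqrt(1.0 - cfg.block_rho) * eps
        )

    gene_ids = [f"G{i + 1:06d}" for i in range(cfg.p)]
    sample_ids = [
        f"{cfg.class_names[lab]}_{j + 1:03d}"
        for j, lab in enumerate(labels)
    ]
    ds = ExpressionDataset(
        matrix=matrix,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels,
        class_names=cfg.class_names,
    )
    truth = GroundTruth(
        informative_genes=informative, redundant_blocks=blocks, seed=cfg.seed
    )
    return ds, truth
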