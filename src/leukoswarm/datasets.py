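"""Expression-matrix containers and delimited-text I/O.

The central object is :class:`ExpressionDataset`: a gene-major matrix
(p genes x n samples) with two-class labels, mirroring the classic
microarray distribution layout (genes in rows, samples in columns).
Files are plain TSV/CSV: first row sample ids, second row class labels,
one row per gene after that; a ``transpose`` flag accepts the
sample-major dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneRanking",
    "load_expression_dataset",
    "write_expression_dataset",
    "read_gene_ranking",
    "write_gene_ranking",
]


@dataclass
class ExpressionDataset:
    """Two-class expression matrix with identifiers.

    Parameters
    ----------
    matrix : ndarray of shape (p, n)
        Expression values, genes in rows.
    gene_ids : list of str, length p
    sample_ids : list of str, length n
    labels : ndarray of int, length n, values in {0, 1}
    class_names : tuple of 2 str
        Display names; index 0 names label 0.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    class_names: tuple[str, str] = ("ALL", "AML")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (genes x samples)")
        p, n = self.matrix.shape
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} matrix rows")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels length must match matrix columns")
        uniq = set(self.labels.tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"labels must be in {{0, 1}}, got {sorted(uniq)}")
        counts = np.bincount(self.labels, minlength=2)
        if (counts < 2).any():
            raise ValueError(
                "each class needs >= 2 samples for per-class variances; "
                f"counts = {counts.tolist()}"
            )
        if not np.isfinite(self.matrix).all():
            raise ValueError("matrix contains missing/non-finite values")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        c = np.bincount(self.labels, minlength=2)
        return int(c[0]), int(c[1])

    def subset_genes(self, indices) -> "ExpressionDataset":
        """Dataset restricted to the given gene indices (order preserved)."""
        idx = np.asarray(list(indices), dtype=int)
        return replace(
            self,
            matrix=self.matrix[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
        )

    def samples_x_genes(self, gene_indices=None) -> np.ndarray:
        """Samples-in-rows view for classifier training."""
        m = self.matrix if gene_indices is None else self.matrix[np.asarray(gene_indices, int)]
        return m.T.copy()


@dataclass
class GeneRanking:
    """Ordered gene indices with scores from a selection method.

    ``gene_indices`` refer to rows of the originating dataset; ``scores``
    are parallel and method-specific (only |SNR| rankings are guaranteed
    nonincreasing).
    """

    gene_indices: np.ndarray
    scores: np.ndarray
    method: str
    gene_ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.gene_indices.shape != self.scores.shape:
            raise ValueError("gene_indices and scores must be parallel")
        if len(np.unique(self.gene_indices)) != len(self.gene_indices):
            raise ValueError("ranking contains duplicate gene indices")

    @property
    def pool_size(self) -> int:
        return len(self.gene_indices)


def rank_by_score(scores: np.ndarray, k: int | None = None) -> np.ndarray:
    """Indices ordered by descending score, ties broken by ascending index."""
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order if k is None else order[:k]


# ---------------------------------------------------------------------------
# expression matrix I/O
# ---------------------------------------------------------------------------

_GENE_COL = "gene_id"
_LABEL_ROW = "label"


def load_expression_dataset(
    path,
    *,
    delimiter: str = "\t",
    transpose: bool = False,
    class_names: tuple[str, str] | None = None,
    missing_policy: str = "reject",
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    Standard layout (``transpose=False``): row 1 = sample ids (first cell a
    corner tag), row 2 = class labels, then one row per gene with the gene id
    in column 1.  ``transpose=True`` reads the same table transposed
    (samples in rows).  Labels may be arbitrary strings; they map to {0, 1}
    in first-seen order unless ``class_names`` fixes the mapping.

    ``missing_policy``: ``"reject"`` (default) raises on any missing cell;
    ``"gene_mean"`` imputes per-gene means.
    """
    try:
        raw = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    except Exception as exc:  # pragma: no cover - I/O context
        raise OSError(f"could not read expression file {path!r}: {exc}") from exc
    if transpose:
        raw = raw.T.reset_index(drop=True)
    if raw.shape[0] < 3 or raw.shape[1] < 2:
        raise ValueError(f"{path!r}: expression table too small ({raw.shape})")

    sample_ids = [str(s) for s in raw.iloc[0, 1:]]
    label_strs = [str(s) for s in raw.iloc[1, 1:]]
    gene_ids = [str(g) for g in raw.iloc[2:, 0]]

    body = raw.iloc[2:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j in range(body.shape[1]):
        col = body.iloc[:, j]
        try:
            values[:, j] = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(col, errors="coerce")
            i = int(np.flatnonzero(bad.isna() & col.notna())[0])
            raise ValueError(
                f"{path!r}: malformed numeric cell at gene row {i} "
                f"({gene_ids[i]!r}), sample column {j} ({sample_ids[j]!r})"
            ) from None

    if np.isnan(values).any():
        if missing_policy == "reject":
            n_miss = int(np.isnan(values).sum())
            raise ValueError(f"{path!r}: {n_miss} missing values (policy 'reject')")
        elif missing_policy == "gene_mean":
            means = np.nanmean(values, axis=1, keepdims=True)
            values = np.where(np.isnan(values), means, values)
        else:
            raise ValueError(f"unknown missing_policy {missing_policy!r}")

    distinct = list(dict.fromkeys(label_strs))  # first-seen order
    if len(distinct) != 2:
        raise ValueError(
            f"{path!r}: expected exactly 2 classes, found {len(distinct)}: {distinct}"
        )
    if class_names is not None:
        if set(class_names) != set(distinct):
            raise ValueError(
                f"class_names {class_names} do not match file labels {distinct}"
            )
        distinct = list(class_names)
    labels = np.array([distinct.index(s) for s in label_strs], dtype=int)

    return ExpressionDataset(
        matrix=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        labels=labels,
        class_names=(distinct[0], distinct[1]),
    )


def write_expression_dataset(
    ds: ExpressionDataset, path, *, delimiter: str = "\t", transpose: bool = False
) -> None:
    """Write a dataset in the layout :func:`load_expression_dataset` reads."""
    header = [_GENE_COL] + list(ds.sample_ids)
    labels = [_LABEL_ROW] + [ds.class_names[v] for v in ds.labels]
    table = [header, labels]
    for i, gid in enumerate(ds.gene_ids):
        table.append([gid] + [repr(float(v)) for v in ds.matrix[i]])
    frame = pd.DataFrame(table)
    if transpose:
        frame = frame.T
    try:
        frame.to_csv(path, sep=delimiter, header=False, index=False)
    except Exception as exc:  # pragma: no cover - I/O context
        raise OSError(f"could not write expression file {path!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# gene-ranking I/O  (two-column TSV: gene_id, score)
# ---------------------------------------------------------------------------


def write_gene_ranking(ranking: GeneRanking, path, *, delimiter: str = "\t") -> None:
    """Write a ranking as two-column TSV (gene_id, score), ranking order.

    If the ranking has no ``gene_ids``, the integer indices themselves are
    written as ids so the file is self-contained.
    """
    ids = ranking.gene_ids
    if ids is None:
        ids = [str(int(i)) for i in ranking.gene_indices]
    with open(path, "w") as fh:
        fh.write(f"# method={ranking.method}\n")
        fh.write(f"gene_id{delimiter}score\n")
        for gid, sc in zip(ids, ranking.scores):
            fh.write(f"{gid}{delimiter}{float(sc)!r}\n")


def read_gene_ranking(
    path, *, delimiter: str = "\t", gene_ids: list[str] | None = None
) -> GeneRanking:
    """Read a two-column ranking file back into a :class:`GeneRanking`.

    ``gene_ids`` (the dataset's id list) maps ids to row indices; without
    it, ids must be integer strings (as written for id-less rankings).
    """
    method = "unknown"
    rows: list[tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "method=" in line:
                    method = line.split("method=", 1)[1].strip()
                continue
            gid, _, sc = line.partition(delimiter)
            if gid == "gene_id":
                continue
            rows.append((gid, float(sc)))
    if gene_ids is not None:
        lookup = {g: i for i, g in enumerate(gene_ids)}
        try:
            idx = np.array([lookup[g] for g, _ in rows], dtype=int)
        except KeyError as exc:
            raise ValueError(f"{path!r}: gene id {exc} not in provided gene_ids")
        out_ids: list[str] | None = [g for g, _ in rows]
    else:
        try:
            idx = np.array([int(g) for g, _ in rows], dtype=int)
        except ValueError:
            raise ValueError(
                f"{path!r}: non-integer gene ids need a gene_ids mapping to resolve"
            ) from None
        out_ids = None
    scores = np.array([s for _, s in rows], dtype=float)
    return GeneRanking(gene_indices=idx, scores=scores, method=method, gene_ids=out_ids)


def warn_once(message: str, _seen: set = set()) -> None:
    """Emit a runtime warning once per process per distinct message."""
    if message not in _seen:
        _seen.add(message)
        warnings.warn(message, RuntimeWarning, stacklevel=3)
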