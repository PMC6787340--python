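"""Core in-memory containers for the three coupled data modalities.

Gene expression (genes x cells), enhancer accessibility (enhancers x cells)
and enhancer-promoter loops (sparse gene x enhancer counts) are carried as
light dataclasses wrapping numpy arrays plus identifier lists, so that every
numerical routine can work on plain arrays while file I/O and annotation keep
track of genomic identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "AccessibilityMatrix",
    "LoopTable",
    "SingleCellLoopMatrix",
    "MotifTable",
    "GenomicInterval",
]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


def _check_matrix(values: np.ndarray, n_rows: int, n_cols: int, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape != (n_rows, n_cols):
        raise ValueError(
            f"{what}: values shape {values.shape} does not match id lists "
            f"({n_rows} x {n_cols})"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: non-finite entries")
    if np.any(values < 0):
        raise ValueError(f"{what}: negative entries")
    return values


@dataclass
class ExpressionMatrix:
    """Gene x cell non-negative expression matrix (counts, TPM or FPKM)."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    unit: str = "count"  # one of {"count", "TPM", "FPKM"}

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.values = _check_matrix(
            self.values, len(self.gene_ids), len(self.cell_ids), "ExpressionMatrix"
        )
        if self.unit not in {"count", "TPM", "FPKM"}:
            raise ValueError(f"unknown expression unit {self.unit!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AccessibilityMatrix:
    """Enhancer (peak) x cell non-negative accessibility matrix."""

    values: np.ndarray
    enhancer_ids: list[str]
    cell_ids: list[str]
    intervals: list[GenomicInterval] | None = None

    def __post_init__(self) -> None:
        self.enhancer_ids = _check_ids(self.enhancer_ids, "enhancer")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        self.values = _check_matrix(
            self.values, len(self.enhancer_ids), len(self.cell_ids), "AccessibilityMatrix"
        )
        if self.intervals is not None and len(self.intervals) != len(self.enhancer_ids):
            raise ValueError("intervals do not match enhancer_ids")

    @property
    def n_enhancers(self) -> int:
        return len(self.enhancer_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class LoopTable:
    """Sparse gene x enhancer loop counts with the 0/1 modeling indicator.

    ``gene_index``/``enhancer_index``/``count`` are parallel arrays over the
    stored pairs (one entry per pair). The indicator mask d selects pairs with
    count >= 1 for the coupling model.
    """

    gene_index: np.ndarray
    enhancer_index: np.ndarray
    count: np.ndarray
    gene_ids: list[str]
    enhancer_ids: list[str]
    indicator: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_index = np.asarray(self.gene_index, dtype=int)
        self.enhancer_index = np.asarray(self.enhancer_index, dtype=int)
        self.count = np.asarray(self.count, dtype=float)
        if not (len(self.gene_index) == len(self.enhancer_index) == len(self.count)):
            raise ValueError("entry arrays have unequal lengths")
        if np.any(self.count < 0):
            raise ValueError("negative loop counts")
        if len(self.gene_index) and (
            self.gene_index.min() < 0 or self.gene_index.max() >= len(self.gene_ids)
        ):
            raise ValueError("gene index out of range")
        if len(self.enhancer_index) and (
            self.enhancer_index.min() < 0
            or self.enhancer_index.max() >= len(self.enhancer_ids)
        ):
            raise ValueError("enhancer index out of range")
        pairs = set(zip(self.gene_index.tolist(), self.enhancer_index.tolist()))
        if len(pairs) != len(self.gene_index):
            raise ValueError("duplicate (gene, enhancer) entries")
        if self.indicator is None:
            self.indicator = (self.count >= 1).astype(float)
        else:
            self.indicator = np.asarray(self.indicator, dtype=float)

    @property
    def n_pairs(self) -> int:
        return len(self.count)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_enhancers(self) -> int:
        return len(self.enhancer_ids)

    def to_dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (C, D): counts and indicator, zero off the stored support."""
        C = np.zeros((self.n_genes, self.n_enhancers))
        D = np.zeros_like(C)
        C[self.gene_index, self.enhancer_index] = self.count
        D[self.gene_index, self.enhancer_index] = self.indicator
        return C, D

    def pair_ids(self) -> list[tuple[str, str]]:
        return [
            (self.gene_ids[g], self.enhancer_ids[e])
            for g, e in zip(self.gene_index, self.enhancer_index)
        ]


@dataclass
class SingleCellLoopMatrix:
    """Loop-pair x cell count matrix over the supported pair set."""

    values: np.ndarray
    pair_ids: list[tuple[str, str]]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if len(set(self.pair_ids)) != len(self.pair_ids):
            raise ValueError("duplicate loop pairs")
        self.values = _check_matrix(
            self.values, len(self.pair_ids), len(self.cell_ids), "SingleCellLoopMatrix"
        )

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


@dataclass
class MotifTable:
    """Per-subpopulation motif enrichment results from an external scanner."""

    tf_names: list[str]
    p_values: np.ndarray
    fold_changes: np.ndarray

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.fold_changes = np.asarray(self.fold_changes, dtype=float)
        if not (len(self.tf_names) == len(self.p_values) == len(self.fold_changes)):
            raise ValueError("motif table columns have unequal lengths")
        if np.any(self.p_values <= 0) or np.any(self.p_values > 1):
            raise ValueError("motif p-values must lie in (0, 1]")
        if np.any(self.fold_changes < 0):
            raise ValueError("negative fold changes")
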