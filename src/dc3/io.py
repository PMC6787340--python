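"""File readers/writers, preprocessing filters and loop annotation.

On-disk conventions
-------------------
* Matrices: dense TSV with a header row of cell ids and a first column of
  feature ids, or MatrixMarket (.mtx) with sibling ``<stem>.rows.txt`` /
  ``<stem>.cols.txt`` id files; picked by file extension.
* Loop tables: 3-column TSV ``gene_id  enhancer_id  count``.
* BED (peaks), BEDPE (loop anchors) and TSS tables are plain TSV; all
  coordinates are 0-based half-open, TSS is strand-aware.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .datatypes import (
    AccessibilityMatrix,
    ExpressionMatrix,
    GenomicInterval,
    LoopTable,
    MotifTable,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_expression",
    "read_accessibility",
    "read_loop_table",
    "write_loop_table",
    "read_bed",
    "read_bedpe",
    "read_tss_table",
    "read_motif_table",
    "build_indicator_mask",
    "filter_peaks_by_cell_support",
    "filter_loop_replicate",
    "annotate_loops",
]


# ---------------------------------------------------------------------------
# matrix I/O

def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a feature x cell matrix; returns (values, row_ids, col_ids)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = mmread(path)
        values = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        row_ids = _read_ids(path.parent / (path.stem + ".rows.txt"))
        col_ids = _read_ids(path.parent / (path.stem + ".cols.txt"))
        return values, row_ids, col_ids
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def _read_ids(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_matrix(path: str | Path, values: np.ndarray, row_ids, col_ids) -> None:
    """Write a matrix as TSV (``.tsv``) or MatrixMarket + id files (``.mtx``)."""
    path = Path(path)
    values = np.asarray(values)
    if path.suffix == ".mtx":
        mmwrite(str(path), coo_matrix(values))
        (path.parent / (path.stem + ".rows.txt")).write_text("\n".join(map(str, row_ids)) + "\n")
        (path.parent / (path.stem + ".cols.txt")).write_text("\n".join(map(str, col_ids)) + "\n")
        return
    pd.DataFrame(values, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_expression(path: str | Path, unit: str = "count") -> ExpressionMatrix:
    values, genes, cells = read_matrix(path)
    return ExpressionMatrix(values, genes, cells, unit=unit)


def read_accessibility(path: str | Path) -> AccessibilityMatrix:
    values, peaks, cells = read_matrix(path)
    intervals = None
    if all(_looks_like_interval(p) for p in peaks):
        intervals = [_parse_interval(p) for p in peaks]
    return AccessibilityMatrix(values, peaks, cells, intervals=intervals)


def _looks_like_interval(peak_id: str) -> bool:
    parts = peak_id.replace(":", "-").split("-")
    return len(parts) == 3 and parts[1].isdigit() and parts[2].isdigit()


def _parse_interval(peak_id: str) -> GenomicInterval:
    chrom, rest = peak_id.split(":")
    start, end = rest.split("-")
    return GenomicInterval(chrom, int(start), int(end))


# ---------------------------------------------------------------------------
# loop tables

def read_loop_table(path: str | Path) -> LoopTable:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "enhancer_id", "count"],
        dtype={"gene_id": str, "enhancer_id": str},
    )
    genes = list(dict.fromkeys(df["gene_id"]))
    enhancers = list(dict.fromkeys(df["enhancer_id"]))
    g_idx = {g: i for i, g in enumerate(genes)}
    e_idx = {e: i for i, e in enumerate(enhancers)}
    return LoopTable(
        gene_index=df["gene_id"].map(g_idx).to_numpy(),
        enhancer_index=df["enhancer_id"].map(e_idx).to_numpy(),
        count=df["count"].to_numpy(dtype=float),
        gene_ids=genes,
        enhancer_ids=enhancers,
    )


def write_loop_table(path: str | Path, loops: LoopTable) -> None:
    with open(path, "w") as fh:
        for g, e, c in zip(loops.gene_index, loops.enhancer_index, loops.count):
            fh.write(f"{loops.gene_ids[g]}\t{loops.enhancer_ids[e]}\t{c:.10g}\n")


def read_motif_table(path: str | Path) -> MotifTable:
    df = pd.read_csv(path, sep="\t")
    return MotifTable(
        tf_names=[str(t) for t in df.iloc[:, 0]],
        p_values=df.iloc[:, 1].to_numpy(dtype=float),
        fold_changes=df.iloc[:, 2].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# genomic record readers

def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """BED3+ peaks; returns [(peak_id, interval)]; id is chrom:start-end."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            out.append((f"{iv.chrom}:{iv.start}-{iv.end}", iv))
    return out


def read_bedpe(path: str | Path, count_column: int = 6):
    """BEDPE loop anchors; yields (anchor1, anchor2, count).

    ``count_column`` is the 0-based column holding the loop read count
    (default: the 7th column, immediately after the two anchor triplets).
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            a1 = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            a2 = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
            count = float(parts[count_column]) if len(parts) > count_column else 1.0
            out.append((a1, a2, count))
    return out


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """TSS table: gene_id, chrom, tss (0-based), strand."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "chrom", "tss", "strand"],
        dtype={"gene_id": str, "chrom": str, "tss": int, "strand": str},
    )


# ---------------------------------------------------------------------------
# preprocessing filters

def build_indicator_mask(loops: LoopTable) -> LoopTable:
    """Populate the 0/1 coupling indicator: d = 1 iff count >= 1."""
    loops.indicator = (loops.count >= 1).astype(float)
    return loops


def filter_peaks_by_cell_support(
    O: AccessibilityMatrix, min_cells: int = 10
) -> AccessibilityMatrix:
    """Drop peaks with nonzero signal in fewer than ``min_cells`` cells.

    Presence is read as count > 0; survivor order is preserved.
    """
    support = (O.values > 0).sum(axis=1)
    keep = np.flatnonzero(support >= min_cells)
    if keep.size == 0:
        raise ValueError("all peaks removed by the cell-support filter")
    return AccessibilityMatrix(
        O.values[keep],
        [O.enhancer_ids[i] for i in keep],
        list(O.cell_ids),
        intervals=None if O.intervals is None else [O.intervals[i] for i in keep],
    )


def filter_loop_replicate(
    loops: LoopTable, strong_min_count: float = 5, min_strong_loops: int = 500
) -> bool:
    """Replicate QC: pass iff #{pairs with count > strong_min_count} >= min_strong_loops."""
    return int((loops.count > strong_min_count).sum()) >= min_strong_loops


# ---------------------------------------------------------------------------
# loop annotation

def annotate_loops(
    anchors,
    peaks,
    tss,
    promoter_halfwidth: int = 2000,
) -> LoopTable:
    """Turn BEDPE loop anchors into a gene x enhancer loop table.

    A loop contributes ``count`` to pair (g, e) when one anchor overlaps the
    promoter window [TSS - halfwidth, TSS + halfwidth) of gene g and the other
    anchor overlaps peak e (counts for duplicate pairs are summed). The rule
    is applied to both anchor orders, so the result is symmetric in anchor
    order. TSS is strand-aware and supplied directly in the ``tss`` table.

    Parameters
    ----------
    anchors : list of (GenomicInterval, GenomicInterval, count)
    peaks : list of (peak_id, GenomicInterval)
    tss : DataFrame with columns gene_id, chrom, tss, strand
    """
    promoters = []
    for row in tss.itertuples(index=False):
        start = max(0, int(row.tss) - promoter_halfwidth)
        promoters.append((str(row.gene_id), GenomicInterval(str(row.chrom), start, int(row.tss) + promoter_halfwidth)))

    known_chroms = {iv.chrom for _, iv in peaks} | {iv.chrom for _, iv in promoters}
    counts: dict[tuple[str, str], float] = defaultdict(float)
    for a1, a2, count in anchors:
        if a1.chrom not in known_chroms and a2.chrom not in known_chroms:
            warnings.warn(
                f"loop on unknown chromosome {a1.chrom}/{a2.chrom}; record skipped"
            )
            continue
        for prom_anchor, peak_anchor in ((a1, a2), (a2, a1)):
            genes = [g for g, iv in promoters if iv.overlaps(prom_anchor)]
            if not genes:
                continue
            hit_peaks = [p for p, iv in peaks if iv.overlaps(peak_anchor)]
            for g in genes:
                for p in hit_peaks:
                    counts[(g, p)] += count

    gene_ids = [g for g, _ in promoters]
    enhancer_ids = [p for p, _ in peaks]
    g_idx = {g: i for i, g in enumerate(gene_ids)}
    e_idx = {e: i for i, e in enumerate(enhancer_ids)}
    gi, ei, cc = [], [], []
    for (g, e), c in counts.items():
        gi.append(g_idx[g])
        ei.append(e_idx[e])
        cc.append(c)
    return LoopTable(
        gene_index=np.array(gi, dtype=int),
        enhancer_index=np.array(ei, dtype=int),
        count=np.array(cc, dtype=float),
        gene_ids=gene_ids,
        enhancer_ids=enhancer_ids,
    )
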