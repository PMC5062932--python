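"""Partitioned supermatrix construction and informativeness statistics.

Trimmed per-locus alignments are concatenated into one matrix (absent
taxa filled with the missing symbol, one RAxML-style partition per
locus) and summarised the way capture datasets are reported: variable
and parsimony-informative site counts, percent missing characters,
per-locus parsimony-informative-character (PIC) counts with their
regression on locus length, and a positional PIC profile relative to
the anchor (probe-region) centre — anchors are conserved, so
informativeness rises into the flanks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqmodel import (GAP, MISSING, AlignedLocus, PartitionTable, SeqRecord)

__all__ = ["Supermatrix", "MatrixStats", "concatenate", "count_site_classes",
           "missingness", "per_locus_stats", "pic_by_position",
           "pic_length_regression", "matrix_stats", "runner_manifests"]

_BASES = (b"A", b"C", b"G", b"T")


@dataclass
class Supermatrix:
    """Concatenated alignment with per-locus partitions."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, total_cols) array of bytes ("S1")
    partitions: PartitionTable
    loci: list[AlignedLocus] = field(default_factory=list)

    @property
    def total_width(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        return [row.tobytes().decode() for row in self.matrix]


@dataclass
class MatrixStats:
    n_loci: int
    n_taxa: int
    total_bp: int
    n_variable_sites: int
    n_informative_sites: int
    pct_missing: float
    pct_absent_fill: float
    per_locus: pd.DataFrame  # locus_id, length, n_taxa, n_pic
    regression: dict[str, float]


def concatenate(loci: Sequence[AlignedLocus],
                taxon_universe: Sequence[str] | None = None) -> Supermatrix:
    """Concatenate loci in locus_id order, missing-filling absent taxa.

    Masked cells are written as the missing symbol. A duplicate taxon
    within one locus is an error (orthology guarantees at most one).
    """
    loci = sorted(loci, key=lambda m: m.locus_id)
    if taxon_universe is None:
        seen: dict[str, None] = {}
        for msa in loci:
            for t in msa.taxa:
                seen.setdefault(t)
        taxon_universe = sorted(seen)
    taxa = list(taxon_universe)
    index = {t: i for i, t in enumerate(taxa)}
    total = sum(m.n_cols for m in loci)
    matrix = np.full((len(taxa), total), MISSING.encode(), dtype="S1")
    pos = 0
    for msa in loci:
        counts: dict[str, int] = {}
        for t in msa.taxa:
            counts[t] = counts.get(t, 0) + 1
        dups = [t for t, c in counts.items() if c > 1]
        if dups:
            raise ValueError(f"locus {msa.locus_id!r}: duplicate taxa {dups}")
        for i, row in enumerate(msa.masked_rows()):
            if row.taxon not in index:
                raise ValueError(f"locus {msa.locus_id!r}: taxon {row.taxon!r} "
                                 "outside taxon universe")
            matrix[index[row.taxon], pos:pos + msa.n_cols] = \
                np.frombuffer(row.sequence.encode(), dtype="S1")
        pos += msa.n_cols
    parts = PartitionTable.from_widths([(m.locus_id, m.n_cols) for m in loci])
    return Supermatrix(taxa, matrix, parts, list(loci))


def _site_classes(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(variable, informative) boolean arrays per column.

    Only unambiguous bases count: a column is variable with >= 2 distinct
    bases, parsimony-informative with >= 2 distinct bases each occurring
    >= 2 times.
    """
    counts = np.stack([(matrix == b).sum(axis=0) for b in _BASES])
    present = (counts > 0).sum(axis=0)
    recurrent = (counts >= 2).sum(axis=0)
    return present >= 2, recurrent >= 2


def count_site_classes(matrix: np.ndarray | Supermatrix) -> tuple[int, int]:
    """(n_variable, n_informative) over the columns of a character matrix."""
    if isinstance(matrix, Supermatrix):
        matrix = matrix.matrix
    variable, informative = _site_classes(np.asarray(matrix, dtype="S1"))
    return int(variable.sum()), int(informative.sum())


def missingness(matrix: np.ndarray | Supermatrix) -> float:
    """Percent of cells that are gap, N or missing fill."""
    if isinstance(matrix, Supermatrix):
        matrix = matrix.matrix
    matrix = np.asarray(matrix, dtype="S1")
    missing = (matrix == GAP.encode()) | (matrix == MISSING.encode())
    return 100.0 * missing.mean()


def per_locus_stats(loci: Sequence[AlignedLocus]) -> pd.DataFrame:
    rows = []
    for msa in loci:
        mat = np.frombuffer(
            "".join(r.sequence for r in msa.masked_rows()).encode(),
            dtype="S1").reshape(msa.n_rows, msa.n_cols)
        variable, informative = _site_classes(mat)
        rows.append({
            "locus_id": msa.locus_id,
            "length": msa.n_cols,
            "n_taxa": msa.n_rows,
            "n_variable": int(variable.sum()),
            "n_pic": int(informative.sum()),
            "pct_missing": missingness(mat),
        })
    return pd.DataFrame(rows)


def pic_by_position(loci: Sequence[AlignedLocus],
                    anchor_centers: Mapping[str, int] | None = None
                    ) -> pd.DataFrame:
    """Counts of loci with >= 1 PIC, and loci with any character, at each
    offset from the anchor centre (offset 0 = centre column).

    The centre defaults to the locus's recorded anchor centre, falling
    back to the alignment midpoint.
    """
    per_offset_pic: dict[int, int] = {}
    per_offset_occ: dict[int, int] = {}
    for msa in loci:
        center = None
        if anchor_centers is not None:
            center = anchor_centers.get(msa.locus_id)
        if center is None:
            center = msa.anchor_center
        if center is None:
            center = msa.n_cols // 2
        mat = np.frombuffer(
            "".join(r.sequence for r in msa.masked_rows()).encode(),
            dtype="S1").reshape(msa.n_rows, msa.n_cols)
        _, informative = _site_classes(mat)
        occupied = ((mat != GAP.encode()) & (mat != MISSING.encode())).any(axis=0)
        for j in range(msa.n_cols):
            off = j - center
            if occupied[j]:
                per_offset_occ[off] = per_offset_occ.get(off, 0) + 1
            if informative[j]:
                per_offset_pic[off] = per_offset_pic.get(off, 0) + 1
        # occupancy: count a locus once per offset it spans, PIC once if any
    offsets = sorted(set(per_offset_occ) | set(per_offset_pic))
    return pd.DataFrame({
        "offset": offsets,
        "n_loci_with_pic": [per_offset_pic.get(o, 0) for o in offsets],
        "n_loci_present": [per_offset_occ.get(o, 0) for o in offsets],
    })


def pic_length_regression(per_locus: pd.DataFrame
                          ) -> dict[str, float]:
    """OLS of per-locus PIC count on locus length.

    Returns slope, intercept, adjusted R-squared
    (1 - (1-R^2)(n-1)/(n-2)) and the two-sided p-value of the slope.
    """
    if len(per_locus) < 3:
        raise ValueError("need >= 3 loci for the regression")
    x = per_locus["length"].to_numpy(dtype=float)
    y = per_locus["n_pic"].to_numpy(dtype=float)
    if np.allclose(x.var(), 0):
        raise ValueError("zero variance in locus length")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "adjusted_r2": float(adj), "p_value": float(res.pvalue)}


def matrix_stats(sm: Supermatrix) -> MatrixStats:
    variable, informative = count_site_classes(sm)
    per_locus = per_locus_stats(sm.loci) if sm.loci else pd.DataFrame()
    reg = (pic_length_regression(per_locus)
           if len(per_locus) >= 3 and per_locus["length"].var() > 0 else {})
    # fill introduced for absent taxa, as a separate figure
    absent_cells = 0
    for msa, entry in zip(sm.loci, sm.partitions.entries):
        absent_cells += (len(sm.taxa) - msa.n_rows) * msa.n_cols
    total_cells = sm.matrix.size
    return MatrixStats(
        n_loci=len(sm.partitions.entries),
        n_taxa=len(sm.taxa),
        total_bp=sm.total_width,
        n_variable_sites=variable,
        n_informative_sites=informative,
        pct_missing=missingness(sm),
        pct_absent_fill=100.0 * absent_cells / total_cells if total_cells else 0.0,
        per_locus=per_locus,
        regression=reg,
    )


def runner_manifests(sm: Supermatrix, base_path: str | Path,
                     model: str = "GTRGAMMA", n_ras: int = 1000,
                     n_bootstrap: int = 1000) -> Path:
    """Emit JSON manifests describing the external RAxML / ASTRAL
    invocations (tree inference is an external-tool contract; nothing is
    executed in-process)."""
    base_path = Path(base_path)
    base_path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "supermatrix": {
            "tool": "raxmlHPC",
            "args": ["-f", "a", "-m", model, "-p", "SEED", "-x", "SEED",
                     "-N", str(n_bootstrap), "-s", base_path.name + ".phy",
                     "-q", base_path.name + ".partitions", "-n", "supermatrix"],
            "random_addition_replicates": n_ras,
        },
        "gene_trees": [
            {"tool": "raxmlHPC",
             "args": ["-m", model, "-p", "SEED", "-s", f"{e.locus_id}.fasta",
                      "-n", e.locus_id]}
            for e in sm.partitions.entries
        ],
        "species_tree": {
            "tool": "astral",
            "args": ["-i", "gene_trees.nwk", "-o", "species_tree.nwk"],
        },
    }
    path = base_path.with_suffix(".runners.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
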