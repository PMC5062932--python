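"""Alignment trimming and masking.

Raw per-locus alignments are cleaned by a three-rule procedure:
columns where the modal non-gap base makes up more than 70% of the
non-gap characters are *good*; any 20-column sliding window containing
fewer than 10 good columns is masked in all rows; and columns left with
fewer than 10 unmasked bases are removed outright. Applied once the
procedure is idempotent, so re-trimming a trimmed alignment is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqmodel import GAP, MISSING, AlignedLocus

__all__ = ["ColumnQuality", "good_sites", "mask_low_quality",
           "drop_sparse_columns", "trim_alignment"]


@dataclass
class ColumnQuality:
    locus_id: str
    good: np.ndarray            # bool per column
    unmasked_count: np.ndarray  # int per column (non-gap, unmasked chars)


def good_sites(msa: AlignedLocus, min_similarity: float = 0.70) -> ColumnQuality:
    """Flag columns whose modal non-gap base fraction strictly exceeds
    *min_similarity*; all-gap and single-base columns are not good.

    Masked characters (and N) do not count toward the modal base or the
    denominator.
    """
    if msa.n_rows < 2:
        raise ValueError(f"locus {msa.locus_id!r}: need >= 2 rows")
    mat = msa.char_matrix()
    usable = (mat != GAP.encode()) & (mat != MISSING.encode()) & ~msa.mask
    good = np.zeros(msa.n_cols, dtype=bool)
    counts = usable.sum(axis=0)
    for j in range(msa.n_cols):
        n = counts[j]
        if n < 2:
            continue
        col = mat[usable[:, j], j]
        _, freq = np.unique(col, return_counts=True)
        good[j] = freq.max() / n > min_similarity
    return ColumnQuality(msa.locus_id, good, counts)


def mask_low_quality(msa: AlignedLocus, quality: ColumnQuality,
                     window: int = 20, min_good: int = 10) -> AlignedLocus:
    """Mask (all rows of) every column covered by a sliding *window*-column
    window containing fewer than *min_good* good columns.

    Windows slide with step 1; a column is masked if ANY covering window
    triggers. An alignment narrower than *window* is evaluated as a
    single window.
    """
    n = msa.n_cols
    good = quality.good.astype(int)
    w = min(window, n)
    csum = np.concatenate([[0], np.cumsum(good)])
    col_masked = np.zeros(n, dtype=bool)
    for s in range(0, n - w + 1):
        if csum[s + w] - csum[s] < min_good:
            col_masked[s:s + w] = True
    mask = msa.mask | col_masked[None, :]
    return AlignedLocus(msa.locus_id, msa.rows, mask,
                        anchor_center=msa.anchor_center)


def drop_sparse_columns(msa: AlignedLocus, min_unmasked: int = 10) -> AlignedLocus:
    """Remove columns with fewer than *min_unmasked* unmasked, non-gap,
    non-missing characters; remaining column order is preserved."""
    mat = msa.char_matrix()
    usable = (mat != GAP.encode()) & (mat != MISSING.encode()) & ~msa.mask
    keep = np.flatnonzero(usable.sum(axis=0) >= min_unmasked)
    if keep.size == 0:
        raise ValueError(f"locus {msa.locus_id!r}: no columns survive trimming")
    out = msa.take_columns(keep)
    if msa.anchor_center is not None:
        out.anchor_center = int(np.searchsorted(keep, msa.anchor_center))
    return out


def trim_alignment(msa: AlignedLocus, min_similarity: float = 0.70,
                   window: int = 20, min_good: int = 10,
                   min_unmasked: int = 10) -> AlignedLocus:
    """good_sites -> mask_low_quality -> drop_sparse_columns in one call."""
    quality = good_sites(msa, min_similarity)
    masked = mask_low_quality(msa, quality, window, min_good)
    return drop_sparse_columns(masked, min_unmasked)
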