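"""Target-locus selection and exon-boundary detection.

The design stage starts from per-locus ortholog alignments and keeps
loci that are conserved enough to anchor a capture probe: at least
``min_taxa`` species and one 120-column window whose mean pairwise
identity exceeds 50%. Candidate probe regions are then the maximal
alignment intervals that are >= 150 bp, free of indel gaps, and free of
exon boundaries (probes must not straddle an intron, or half the probe
would not hybridise to genomic DNA).

Exon boundaries are found two ways, matching the two data types a
design typically has in hand:

* from an assembled genome, by chaining exact 40-mer matches between
  transcript and genome into colinear blocks and reporting transcript
  positions where adjacent blocks are separated by intronic sequence in
  the genome;
* from raw genomic reads mapped to the transcript, by locating
  positions at which reads match well on one side and poorly on the
  other (a read crossing a splice junction agrees with the transcript
  only up to the junction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .seqmodel import GAP, AlignedLocus, SeqRecord, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "WindowScore", "ExonMap", "TargetRegion",
    "window_identity", "sliding_window_identity", "filter_ortholog_alignments",
    "map_exons_by_kmer", "map_exons_by_reads",
    "lift_boundaries_to_alignment", "select_preliminary_targets",
    "split_alignment_at_boundaries",
]


@dataclass(frozen=True)
class WindowScore:
    locus_id: str
    start: int
    width: int
    mean_pairwise_identity: float


@dataclass
class ExonMap:
    """Exon cut points of one transcript, in 0-based transcript coordinates."""

    transcript_id: str
    boundaries: list[int] = field(default_factory=list)
    evidence: Literal["genome_kmer", "read_discordance"] = "genome_kmer"

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.boundaries):
            raise ValueError("boundaries must be strictly positive cut points")
        if sorted(set(self.boundaries)) != self.boundaries:
            raise ValueError("boundaries must be strictly increasing")


@dataclass
class TargetRegion:
    """A candidate probe region: a gap- and boundary-free alignment interval."""

    locus_id: str
    start: int  # 0-based half-open alignment columns
    stop: int
    sequences: dict[str, str]  # taxon -> ungapped sequence over the interval
    mean_pairwise_identity: float = float("nan")

    @property
    def width(self) -> int:
        return self.stop - self.start

    def reference(self) -> tuple[str, str]:
        """(taxon, sequence) of the first row; rows are gap-free here."""
        taxon = next(iter(self.sequences))
        return taxon, self.sequences[taxon]


# ---------------------------------------------------------------------------
# pairwise identity windows

def _pair_arrays(msa: AlignedLocus) -> tuple[np.ndarray, np.ndarray]:
    """(match, comparable) arrays of shape (n_pairs, n_cols).

    comparable = both rows non-gap; match = comparable and equal.
    """
    mat = msa.char_matrix()
    nongap = mat != GAP.encode()
    n = msa.n_rows
    ii, jj = np.triu_indices(n, k=1)
    comp = nongap[ii] & nongap[jj]
    match = comp & (mat[ii] == mat[jj])
    return match, comp


def window_identity(msa: AlignedLocus, start: int, width: int = 120) -> WindowScore:
    """Mean pairwise identity of one alignment window.

    Identity of a pair is computed over positions where both rows are
    non-gap; pairs with no comparable position in the window are
    excluded from the mean.
    """
    if msa.n_rows < 2:
        raise ValueError(f"locus {msa.locus_id!r}: need >= 2 rows")
    if not (0 <= start and start + width <= msa.n_cols):
        raise ValueError(f"window [{start}, {start + width}) outside alignment "
                         f"of {msa.n_cols} columns")
    match, comp = _pair_arrays(msa)
    m = match[:, start:start + width].sum(axis=1)
    c = comp[:, start:start + width].sum(axis=1)
    ok = c > 0
    ident = float(np.mean(m[ok] / c[ok])) if ok.any() else 0.0
    return WindowScore(msa.locus_id, start, width, ident)


def sliding_window_identity(msa: AlignedLocus, width: int = 120) -> np.ndarray:
    """Mean pairwise identity of every step-1 window; empty if none fit."""
    if msa.n_rows < 2 or msa.n_cols < width:
        return np.empty(0)
    match, comp = _pair_arrays(msa)
    kernel = np.ones(width)
    m = np.apply_along_axis(lambda r: np.convolve(r, kernel, "valid"), 1,
                            match.astype(float))
    c = np.apply_along_axis(lambda r: np.convolve(r, kernel, "valid"), 1,
                            comp.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = m / c
    counts = (c > 0).sum(axis=0)
    sums = np.nansum(np.where(c > 0, ident, np.nan), axis=0)
    out = np.zeros(m.shape[1])
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def filter_ortholog_alignments(loci: Sequence[AlignedLocus], min_taxa: int = 6,
                               window: int = 120,
                               min_identity: float = 0.5) -> list[AlignedLocus]:
    """Keep loci with >= *min_taxa* rows and one window strictly above
    *min_identity* mean pairwise identity."""
    kept = []
    for msa in loci:
        if msa.n_rows < min_taxa:
            continue
        scores = sliding_window_identity(msa, width=window)
        if scores.size and scores.max() > min_identity:
            kept.append(msa)
    return kept


# ---------------------------------------------------------------------------
# exon boundaries from a genome (40-mer chaining)

@dataclass(frozen=True)
class _Block:
    t_start: int  # transcript, 0-based half-open base interval
    t_stop: int
    g_start: int  # genome, forward-strand coordinates of the block
    g_stop: int
    strand: int   # +1 / -1


def _kmer_hits(transcript: str, genome: str, k: int) -> list[tuple[int, int, int]]:
    """(t_pos, g_pos, strand) for every exact k-mer match; N never matches."""
    index: dict[str, list[int]] = {}
    for g in range(len(genome) - k + 1):
        kmer = genome[g:g + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(g)
    hits = []
    for t in range(len(transcript) - k + 1):
        kmer = transcript[t:t + k]
        if "N" in kmer:
            continue
        for g in index.get(kmer, ()):
            hits.append((t, g, +1))
        for g in index.get(revcomp(kmer), ()):
            hits.append((t, g, -1))
    return hits


def _blocks_from_hits(hits: list[tuple[int, int, int]], k: int) -> list[_Block]:
    """Merge diagonal runs of k-mer hits into maximal blocks."""
    by_diag: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for t, g, strand in hits:
        diag = g - t if strand > 0 else g + t
        by_diag.setdefault((strand, diag), []).append((t, g))
    blocks = []
    for (strand, _), tg in by_diag.items():
        tg.sort()
        run = [tg[0]]
        for t, g in tg[1:]:
            if t == run[-1][0] + 1:
                run.append((t, g))
            else:
                blocks.append(_run_to_block(run, k, strand))
                run = [(t, g)]
        blocks.append(_run_to_block(run, k, strand))
    return blocks


def _run_to_block(run: list[tuple[int, int]], k: int, strand: int) -> _Block:
    t0, g0 = run[0]
    t1, g1 = run[-1]
    if strand > 0:
        return _Block(t0, t1 + k, g0, g1 + k, strand)
    # reverse strand: genome interval runs opposite to transcript
    return _Block(t0, t1 + k, g1, g0 + k, strand)


def _chain_blocks(blocks: list[_Block], k: int) -> list[_Block]:
    """Best colinear chain (max transcript coverage) of blocks.

    Blocks may overlap by up to k-1 transcript bases (a junction base
    matching the intron flank extends a block past the true splice
    point); overlapping chains are allowed and the overlap is charged
    against the coverage gain.
    """
    if not blocks:
        return []
    best_chain: list[_Block] = []
    best_cov = -1
    for strand in (+1, -1):
        sub = sorted((b for b in blocks if b.strand == strand),
                     key=lambda b: (b.t_start, b.t_stop))
        n = len(sub)
        if not n:
            continue
        cov = [b.t_stop - b.t_start for b in sub]
        prev = [-1] * n
        for j in range(n):
            for i in range(j):
                a, b = sub[i], sub[j]
                o = max(0, a.t_stop - b.t_start)
                if o >= k or b.t_start < a.t_start:
                    continue
                g_ok = ((strand > 0 and b.g_start + o >= a.g_stop) or
                        (strand < 0 and b.g_stop - o <= a.g_start))
                gain = b.t_stop - b.t_start - o
                if g_ok and cov[i] + gain > cov[j]:
                    cov[j] = cov[i] + gain
                    prev[j] = i
        j = int(np.argmax(cov))
        if cov[j] > best_cov:
            best_cov = cov[j]
            chain = []
            while j != -1:
                chain.append(sub[j])
                j = prev[j]
            best_chain = chain[::-1]
    return best_chain


def map_exons_by_kmer(transcript: SeqRecord, genome: SeqRecord,
                      k: int = 40) -> ExonMap:
    """Exon boundaries of *transcript* against *genome* via exact k-mer chains.

    A boundary is reported at each transcript position where consecutive
    chained blocks are adjacent in the transcript but separated by > 0
    bases (an intron) in the genome.
    """
    if k > len(transcript.sequence):
        raise ValueError("k exceeds transcript length")
    hits = _kmer_hits(transcript.sequence, genome.sequence, k)
    chain = _chain_blocks(_blocks_from_hits(hits, k), k)
    if not chain:
        logger.warning("transcript %s: no %d-mer block found in genome %s",
                       transcript.id, k, genome.id)
        return ExonMap(transcript.id, [], "genome_kmer")
    boundaries = []
    for a, b in zip(chain, chain[1:]):
        o = max(0, a.t_stop - b.t_start)  # junction-flank coincidence
        t_gap = max(0, b.t_start - a.t_stop)
        g_gap = ((b.g_start + o - a.g_stop) if a.strand > 0
                 else (a.g_start - (b.g_stop - o)))
        if t_gap == 0 and g_gap > 0:
            boundaries.append(a.t_stop - o if o else a.t_stop)
    boundaries = sorted({b for b in boundaries
                         if 0 < b < len(transcript.sequence)})
    return ExonMap(transcript.id, boundaries, "genome_kmer")


# ---------------------------------------------------------------------------
# exon boundaries from raw reads (side-contrast of mapped reads)

def _align_read(read: str, transcript: str):
    """Best infix alignment of read (either strand) against transcript.

    Returns (t_start, t_stop, mismatch indicator per covered transcript
    position) or None when the read does not align.
    """
    import edlib

    best = None
    for seq in (read, revcomp(read)):
        res = edlib.align(seq, transcript, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]["editDistance"]:
            best = (res, seq)
    if best is None:
        return None
    res, _ = best
    t_start, t_end = res["locations"][0]
    t_stop = t_end + 1
    mism = np.zeros(len(transcript), dtype=bool)
    pos = t_start
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            pos += n
        elif ch == "X":
            mism[pos:pos + n] = True
            pos += n
        elif ch == "D":  # deleted from transcript
            mism[pos:pos + n] = True
            pos += n
        elif ch == "I":  # insertion in the read
            if pos < len(transcript):
                mism[pos] = True
    return t_start, t_stop, mism


def map_exons_by_reads(transcript: SeqRecord, reads: Sequence[SeqRecord],
                       flank: int = 30, mismatch_frac: float = 0.2,
                       min_reads: int = 5) -> ExonMap:
    """Exon boundaries from genomic reads mapped onto the transcript.

    A transcript position p is a candidate when >= *min_reads* reads
    spanning [p - flank, p + flank) match the transcript well
    (per-base mismatch rate <= *mismatch_frac*) on one side of p and
    poorly (> *mismatch_frac*) on the other. Runs of adjacent candidate
    positions are merged to the position with maximal side contrast.
    """
    L = len(transcript.sequence)
    n_discord = np.zeros(L)
    contrast = np.zeros(L)
    for read in reads:
        if len(read.sequence) < 2 * flank:
            continue
        aln = _align_read(read.sequence, transcript.sequence)
        if aln is None:
            continue
        t_start, t_stop, mism = aln
        lo, hi = t_start + flank, t_stop - flank
        if hi <= lo:
            continue
        csum = np.concatenate([[0], np.cumsum(mism[t_start:t_stop])])
        p = np.arange(lo, hi)
        rel = p - t_start
        left = (csum[rel] - csum[rel - flank]) / flank
        right = (csum[rel + flank] - csum[rel]) / flank
        disc = ((left <= mismatch_frac) & (right > mismatch_frac)) | \
               ((right <= mismatch_frac) & (left > mismatch_frac))
        n_discord[p] += disc
        contrast[p] += np.where(disc, np.abs(left - right), 0.0)

    cand = np.flatnonzero(n_discord >= min_reads)
    boundaries = []
    if cand.size:
        splits = np.flatnonzero(np.diff(cand) > 1) + 1
        for group in np.split(cand, splits):
            boundaries.append(int(group[np.argmax(contrast[group])]))
    boundaries = [b for b in sorted(set(boundaries)) if 0 < b < L]
    return ExonMap(transcript.id, boundaries, "read_discordance")


# ---------------------------------------------------------------------------
# target selection

def lift_boundaries_to_alignment(row: SeqRecord, boundaries: Sequence[int]) -> list[int]:
    """Lift ungapped-transcript cut points to alignment-column cut points."""
    cols = np.flatnonzero(np.frombuffer(row.sequence.encode(), dtype="S1")
                          != GAP.encode())
    out = []
    for b in boundaries:
        if not 0 < b <= cols.size:
            raise ValueError(f"boundary {b} outside ungapped length {cols.size}")
        # cut before the b-th ungapped base
        out.append(int(cols[b]) if b < cols.size else int(cols[-1]) + 1)
    return out


def _retained_rows(msa: AlignedLocus) -> list[int]:
    """Indices of rows that are not entirely gap/missing."""
    mat = msa.char_matrix()
    informative = (mat != b"-") & (mat != b"N")
    return [i for i in range(msa.n_rows) if informative[i].any()]


def select_preliminary_targets(msa: AlignedLocus,
                               boundary_cols: Sequence[int] = (),
                               min_len: int = 150) -> list[TargetRegion]:
    """Maximal alignment intervals >= *min_len* wide with no gap in any
    retained row and no exon boundary strictly inside."""
    keep = _retained_rows(msa)
    if not keep:
        return []
    mat = msa.char_matrix()[keep]
    gap_col = (mat == GAP.encode()).any(axis=0)
    cuts = sorted({c for c in boundary_cols if 0 < c < msa.n_cols})
    segment_edges = [0, *cuts, msa.n_cols]
    regions: list[TargetRegion] = []
    for s, e in zip(segment_edges, segment_edges[1:]):
        pos = s
        while pos < e:
            if gap_col[pos]:
                pos += 1
                continue
            run_start = pos
            while pos < e and not gap_col[pos]:
                pos += 1
            if pos - run_start >= min_len:
                seqs = {}
                for i in keep:
                    r = msa.rows[i]
                    key = r.taxon if r.taxon not in seqs else r.id
                    seqs[key] = r.sequence[run_start:pos]
                ident = window_identity(msa, run_start, pos - run_start) \
                    .mean_pairwise_identity if len(keep) >= 2 else float("nan")
                regions.append(TargetRegion(msa.locus_id, run_start, pos, seqs,
                                            mean_pairwise_identity=ident))
    return regions


def split_alignment_at_boundaries(msa: AlignedLocus,
                                  boundary_cols: Sequence[int]) -> list[AlignedLocus]:
    """Cut an alignment into exon alignments at the given column cut points."""
    cuts = sorted(set(boundary_cols))
    for c in cuts:
        if not 0 < c < msa.n_cols:
            raise ValueError(f"boundary {c} outside (0, {msa.n_cols})")
    edges = [0, *cuts, msa.n_cols]
    children = []
    for i, (s, e) in enumerate(zip(edges, edges[1:]), start=1):
        suffix = f"_e{i}" if cuts else ""
        children.append(msa.slice_columns(s, e, locus_id=msa.locus_id + suffix))
    return children
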