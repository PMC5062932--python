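"""High-copy repeat masking by 15-mer genome counting, and probe tiling.

Capture probes hybridising to microsatellites or transposable elements
pull down enormous amounts of off-target DNA, so before tiling probes
the candidate regions are screened against whole genomes: every 15-mer
observed in the trimmed probe-region alignments (plus all single-base
substitution neighbours, to tolerate light divergence) is recorded
against the alignment column it came from, the genome is scanned for
exact matches on both strands, and columns accumulating more than
100,000 hits in any genome are masked. Probes of 120 bp are then tiled
at 4.0x density (one start every 30 bases) over each reference row,
skipping masked positions, and the probe list is padded to the
synthesis capacity of the kit by replicating probes of short loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqmodel import GAP, AlignedLocus, revcomp

logger = logging.getLogger(__name__)

__all__ = ["KmerTally", "Probe", "build_kmer_db", "tally_genome",
           "mask_high_copy", "tile_probes", "replicate_to_capacity",
           "probes_for_locus"]

_BASES = "ACGT"


@dataclass
class KmerTally:
    """Per-column genome-occurrence counts for one locus against one genome."""

    locus_id: str
    genome_id: str
    counts: np.ndarray  # int64, length n_cols

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative tally")


@dataclass(frozen=True)
class Probe:
    """One 120-base capture probe tile."""

    probe_id: str
    locus_id: str
    reference_taxon: str
    start: int  # 0-based offset in the reference's ungapped target sequence
    sequence: str
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def hamming_neighbors(kmer: str) -> list[str]:
    """All 3k single-substitution variants of *kmer* (excludes the k-mer itself)."""
    out = []
    for i, base in enumerate(kmer):
        for alt in _BASES:
            if alt != base:
                out.append(kmer[:i] + alt + kmer[i + 1:])
    return out


def build_kmer_db(alignments: Sequence[AlignedLocus], k: int = 15,
                  neighbors: int = 1) -> dict[str, set[tuple[str, int]]]:
    """k-mer -> {(locus_id, column of the k-mer's first base)} multimap.

    Every ungapped k-mer of every row contributes itself and (when
    *neighbors* is 1) all Hamming-distance-1 substitution variants,
    mapped to the alignment column of its first base. k-mers containing
    N are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    db: dict[str, set[tuple[str, int]]] = {}
    for msa in alignments:
        for row in msa.rows:
            cols = np.flatnonzero(
                np.frombuffer(row.sequence.encode(), dtype="S1") != GAP.encode())
            seq = row.ungapped
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                key = (msa.locus_id, int(cols[i]))
                db.setdefault(kmer, set()).add(key)
                if neighbors >= 1:
                    for var in hamming_neighbors(kmer):
                        db.setdefault(var, set()).add(key)
    return db


def tally_genome(db: Mapping[str, set[tuple[str, int]]], genome,
                 k: int = 15) -> dict[str, KmerTally]:
    """Scan both strands of *genome* and tally exact db hits per column.

    Returns one :class:`KmerTally` per locus present in the db; windows
    containing N never hit. Tally arrays are sized lazily to the highest
    column seen plus k (callers with the locus in hand may re-size).
    """
    hits: dict[str, dict[int, int]] = {}
    seq = genome.sequence
    for strand_seq in (seq, revcomp(seq)):
        for i in range(len(strand_seq) - k + 1):
            kmer = strand_seq[i:i + k]
            if "N" in kmer:
                continue
            for locus_id, col in db.get(kmer, ()):
                hits.setdefault(locus_id, {})[col] = \
                    hits.get(locus_id, {}).get(col, 0) + 1
    loci = {locus_id for targets in db.values() for locus_id, _ in targets}
    out = {}
    for locus_id in loci:
        cols = hits.get(locus_id, {})
        width = (max(cols) + k) if cols else k
        counts = np.zeros(width, dtype=np.int64)
        for col, n in cols.items():
            counts[col] = n
        out[locus_id] = KmerTally(locus_id, genome.id, counts)
    return out


def mask_high_copy(msa: AlignedLocus, tallies: Iterable[KmerTally],
                   threshold: int = 100_000) -> AlignedLocus:
    """Mask every column whose count strictly exceeds *threshold* in ANY
    genome; a count of exactly *threshold* is left unmasked. Bases are
    preserved; only the mask state changes."""
    mask = msa.mask.copy()
    for tally in tallies:
        if tally.locus_id != msa.locus_id:
            continue
        counts = np.zeros(msa.n_cols, dtype=np.int64)
        n = min(msa.n_cols, tally.counts.size)
        counts[:n] = tally.counts[:n]
        mask[:, counts > threshold] = True
    return AlignedLocus(msa.locus_id, msa.rows, mask,
                        anchor_center=msa.anchor_center)


def tile_probes(sequence: str, mask: np.ndarray | None = None,
                locus_id: str = "", reference_taxon: str = "",
                probe_len: int = 120, density: float = 4.0) -> list[Probe]:
    """Tile 120-base probes over an ungapped reference sequence.

    Spacing = round(probe_len / density); starts run 0, 30, 60, ... and
    the final probe is shifted left to end flush with the sequence end.
    Probes overlapping any masked position are discarded; sequences
    shorter than *probe_len* yield no probes.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    L = len(sequence)
    if L < probe_len:
        return []
    if mask is None:
        mask = np.zeros(L, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    spacing = int(round(probe_len / density))
    starts = list(range(0, L - probe_len + 1, spacing))
    if starts[-1] + probe_len < L:
        starts.append(L - probe_len)
    probes = []
    for s in starts:
        if mask[s:s + probe_len].any():
            continue
        probes.append(Probe(
            probe_id=f"{locus_id}|{reference_taxon}|{s}",
            locus_id=locus_id, reference_taxon=reference_taxon,
            start=s, sequence=sequence[s:s + probe_len]))
    return probes


def probes_for_locus(msa: AlignedLocus, probe_len: int = 120,
                     density: float = 4.0) -> list[Probe]:
    """Tile every row of a (possibly masked) locus and deduplicate by
    exact probe sequence, keeping the first (row-order) occurrence."""
    seen: set[str] = set()
    probes = []
    for i, row in enumerate(msa.rows):
        cols = np.flatnonzero(
            np.frombuffer(row.sequence.encode(), dtype="S1") != GAP.encode())
        seq = row.ungapped
        rmask = msa.mask[i, cols] if cols.size else np.zeros(0, bool)
        # masked bases also present as N in the sequence are unusable
        nmask = np.frombuffer(seq.encode(), dtype="S1") == b"N"
        for p in tile_probes(seq, rmask | nmask, msa.locus_id, row.taxon,
                             probe_len, density):
            if p.sequence not in seen:
                seen.add(p.sequence)
                probes.append(p)
    return probes


def replicate_to_capacity(probes: Sequence[Probe], capacity: int = 57_700,
                          locus_lengths: Mapping[str, int] | None = None,
                          ) -> list[Probe]:
    """Pad the probe list to kit capacity by replicating short-locus probes.

    Extra replicate counts are assigned one at a time, cycling through
    probes ordered shortest-locus-first (then locus_id, then start),
    until the replicate total equals *capacity*. Output order is
    deterministic: (locus_id, start, sequence).
    """
    probes = list(probes)
    if len(probes) > capacity:
        raise ValueError(
            f"{len(probes)} distinct probes exceed kit capacity {capacity}; "
            "reduce the locus set")
    if locus_lengths is None:
        locus_lengths = {}
        for p in probes:
            locus_lengths[p.locus_id] = max(
                locus_lengths.get(p.locus_id, 0), p.start + len(p.sequence))
    order = sorted(range(len(probes)),
                   key=lambda i: (locus_lengths.get(probes[i].locus_id, 0),
                                  probes[i].locus_id, probes[i].start))
    extra = [0] * len(probes)
    remaining = capacity - len(probes)
    j = 0
    while remaining > 0 and order:
        extra[order[j % len(order)]] += 1
        remaining -= 1
        j += 1
    out = [replace(p, replicates=1 + e) for p, e in zip(probes, extra)]
    out.sort(key=lambda p: (p.locus_id, p.start, p.sequence))
    assert sum(p.replicates for p in out) == capacity or not out
    return out
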