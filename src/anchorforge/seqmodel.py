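"""Core sequence and alignment data model.

The toolkit works over a deliberately small alphabet: ``A C G T N -``.
``N`` doubles as the missing/masked symbol in every on-disk output;
IUPAC ambiguity codes are normalised to ``N`` on input (the source data
for probe design are consensus sequences whose ambiguity carries no
information the pipeline uses). Internal coordinates are 0-based
half-open; anything written to a report or partition file is 1-based
inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")
GAP = "-"
MISSING = "N"

_AMBIG = re.compile(r"[RYSWKMBDHVU]")


def normalize_sequence(seq: str, *, context: str = "") -> str:
    """Uppercase *seq* and collapse non-N ambiguity codes to ``N``.

    Raises ``ValueError`` for characters outside the IUPAC nucleotide set.
    """
    s = seq.upper()
    if _AMBIG.search(s):
        logger.warning("ambiguity codes normalised to N%s",
                       f" in {context}" if context else "")
        s = _AMBIG.sub("N", s)
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(
            f"invalid sequence characters {sorted(bad)}"
            + (f" in {context}" if context else ""))
    return s


def infer_taxon(seq_id: str) -> str:
    """Taxon label = id prefix up to the first underscore-delimited numeric token.

    Specimen ids like ``APH_0856`` encode specimen, not species; absent an
    explicit sample map this heuristic at least groups specimens sharing a
    prefix. ``Aptostichus_simus_12`` -> ``Aptostichus_simus``.
    """
    parts = seq_id.split("_")
    keep: list[str] = []
    for p in parts:
        if p.isdigit():
            break
        keep.append(p)
    return "_".join(keep) if keep else seq_id


@dataclass
class SeqRecord:
    """One sequence: a transcript, genome, consensus contig or alignment row.

    ``read_support`` carries the supporting-read count of an assembled
    consensus sequence (None when the provenance has no such notion).
    """

    id: str
    sequence: str
    taxon: str = ""
    sample: str = ""
    read_support: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = normalize_sequence(self.sequence, context=f"record {self.id!r}")
        if self.read_support is not None and self.read_support < 0:
            raise ValueError(f"record {self.id!r}: negative read_support")
        if not self.taxon:
            self.taxon = infer_taxon(self.id)
        if not self.sample:
            self.sample = self.id

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")

    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count(GAP)

    def reverse_complement(self) -> "SeqRecord":
        return replace(self, sequence=revcomp(self.sequence))


_RC = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class AlignedLocus:
    """A per-locus multiple sequence alignment with a row x column mask.

    ``mask[i, j]`` True means position j of row i is masked (high-copy or
    low-quality); bases are preserved in memory and written as ``N``.
    ``anchor_center`` optionally records the centre column of the probe
    (anchor) region for positional informativeness profiles.
    """

    def __init__(self, locus_id: str, rows: Sequence[SeqRecord],
                 mask: np.ndarray | None = None,
                 anchor_center: int | None = None) -> None:
        if not rows:
            raise ValueError(f"locus {locus_id!r}: no rows")
        widths = {len(r.sequence) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"locus {locus_id!r}: unequal row lengths {sorted(widths)}")
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError(f"locus {locus_id!r}: duplicate row ids")
        self.locus_id = locus_id
        self.rows = list(rows)
        self.n_cols = widths.pop()
        if mask is None:
            mask = np.zeros((len(rows), self.n_cols), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(rows), self.n_cols):
            raise ValueError(f"locus {locus_id!r}: mask shape {mask.shape} != "
                             f"({len(rows)}, {self.n_cols})")
        self.mask = mask
        self.anchor_center = anchor_center

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def taxa(self) -> list[str]:
        return [r.taxon for r in self.rows]

    def __iter__(self) -> Iterator[SeqRecord]:
        return iter(self.rows)

    def __repr__(self) -> str:
        return (f"AlignedLocus({self.locus_id!r}, {self.n_rows} rows x "
                f"{self.n_cols} cols)")

    def char_matrix(self) -> np.ndarray:
        """Rows as a (n_rows, n_cols) array of single characters."""
        return np.frombuffer("".join(r.sequence for r in self.rows).encode(),
                             dtype="S1").reshape(self.n_rows, self.n_cols)

    def masked_rows(self) -> list[SeqRecord]:
        """Rows with masked positions written as the missing symbol."""
        out = []
        for i, r in enumerate(self.rows):
            if self.mask[i].any():
                chars = np.frombuffer(r.sequence.encode(), dtype="S1").copy()
                chars[self.mask[i]] = MISSING.encode()
                out.append(replace(r, sequence=chars.tobytes().decode()))
            else:
                out.append(r)
        return out

    def take_columns(self, cols: np.ndarray) -> "AlignedLocus":
        """New locus restricted to the given column index array (order kept)."""
        cols = np.asarray(cols)
        mat = self.char_matrix()[:, cols]
        rows = [replace(r, sequence=mat[i].tobytes().decode())
                for i, r in enumerate(self.rows)]
        return AlignedLocus(self.locus_id, rows, self.mask[:, cols],
                            anchor_center=self.anchor_center)

    def slice_columns(self, start: int, stop: int,
                      locus_id: str | None = None) -> "AlignedLocus":
        sub = self.take_columns(np.arange(start, stop))
        if locus_id is not None:
            sub.locus_id = locus_id
        return sub


@dataclass(frozen=True)
class PartitionEntry:
    locus_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


@dataclass
class PartitionTable:
    """Contiguous per-locus blocks tiling [1, total width] in locus order."""

    entries: list[PartitionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        expect = 1
        for e in self.entries:
            if e.start != expect or e.end < e.start:
                raise ValueError(f"partition {e.locus_id}: {e.start}-{e.end} "
                                 f"not contiguous (expected start {expect})")
            expect = e.end + 1

    @classmethod
    def from_widths(cls, widths: Iterable[tuple[str, int]]) -> "PartitionTable":
        entries, pos = [], 1
        for locus_id, w in widths:
            entries.append(PartitionEntry(locus_id, pos, pos + w - 1))
            pos += w
        return cls(entries)

    @property
    def total_width(self) -> int:
        return self.entries[-1].end if self.entries else 0

    def raxml_lines(self) -> list[str]:
        return [f"DNA, {e.locus_id} = {e.start}-{e.end}" for e in self.entries]
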