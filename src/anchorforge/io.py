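"""Readers and writers for every on-disk format the toolkit touches.

FASTA is parsed by a small strict line parser rather than a library
reader because the toolkit's error contract requires naming the
offending line number, and because headers carry a ``reads=N`` token
(supporting-read count of a consensus sequence) that must round-trip.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

from .seqmodel import GAP, PartitionTable, SeqRecord

__all__ = [
    "FastaParseError", "read_fasta", "write_fasta",
    "read_sample_map", "write_phylip_and_partitions",
]

_READS_TOKEN = re.compile(r"\breads=(\d+)\b")


class FastaParseError(ValueError):
    def __init__(self, path: Path | str, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def read_fasta(path: str | Path,
               sample_map: dict[str, str] | None = None) -> list[SeqRecord]:
    """Read FASTA into SeqRecords.

    ``reads=N`` in a header becomes ``read_support``; *sample_map* maps
    record id (specimen) to taxon, overriding the prefix heuristic.
    Malformed input raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(path, header_line, f"record {header!r}: empty sequence")
        rid = header.split()[0]
        if rid in seen:
            raise FastaParseError(path, header_line, f"duplicate id {rid!r}")
        seen.add(rid)
        m = _READS_TOKEN.search(header)
        support = int(m.group(1)) if m else None
        taxon = sample_map.get(rid, "") if sample_map else ""
        records.append(SeqRecord(id=rid, sequence=seq, taxon=taxon,
                                 read_support=support))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(path, line_no, "empty header")
                header_line = line_no
            else:
                if header is None:
                    raise FastaParseError(path, line_no,
                                          "sequence data before first header")
                chunks.append(line)
        flush(line_no=header_line)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path,
                width: int = 80) -> None:
    """Write FASTA; ``read_support`` is emitted as a ``reads=N`` header token."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.read_support is not None:
                header += f" reads={rec.read_support}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_sample_map(path: str | Path) -> dict[str, str]:
    """TSV of ``sample<TAB>taxon`` (header line optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 tab-separated columns")
            if line_no == 1 and parts[0].lower() in {"sample", "specimen", "id"}:
                continue
            out[parts[0]] = parts[1]
    return out


def write_phylip_and_partitions(matrix, base_path: str | Path) -> tuple[Path, Path]:
    """Write a relaxed-PHYLIP supermatrix plus a RAxML partition file.

    *matrix* is a :class:`~anchorforge.supermatrix.Supermatrix`. Returns
    ``(phylip_path, partition_path)``; coordinates in the partition file
    are 1-based inclusive.
    """
    base_path = Path(base_path)
    base_path.parent.mkdir(parents=True, exist_ok=True)
    taxa = list(matrix.taxa)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels in supermatrix")
    phy = base_path.with_suffix(".phy")
    parts = base_path.with_suffix(".partitions")
    pad = max(len(t) for t in taxa) + 2
    with open(phy, "w") as fh:
        fh.write(f" {len(taxa)} {matrix.total_width}\n")
        for taxon, row in zip(taxa, matrix.sequences()):
            fh.write(f"{taxon.ljust(pad)}{row}\n")
    with open(parts, "w") as fh:
        for line in matrix.partitions.raxml_lines():
            fh.write(line + "\n")
    return phy, parts
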