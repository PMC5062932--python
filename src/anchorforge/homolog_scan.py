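"""Scan transcriptomes for homologs of candidate targets and apply the
lineage/representation filters that winnow candidate loci.

Matching uses a pluggable pairwise local aligner; the default is an
edlib infix alignment of the target's reference sequence against each
transcript on both strands, with match fraction = identity over the
aligned span. Loci must contain both configured anchor taxa (in the
original spider design, one representative each of the two deepest
mygalomorph lineages with genomic reads), and loci where too many of
the remaining species are represented only by short transcripts are
dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .io import write_fasta
from .seqmodel import AlignedLocus, SeqRecord, revcomp
from .target_design import TargetRegion

logger = logging.getLogger(__name__)

__all__ = ["HomologHit", "best_transcript_match", "assemble_locus_set",
           "representation_filter", "FilterDecision"]


@dataclass(frozen=True)
class HomologHit:
    locus_id: str
    taxon: str
    transcript_id: str
    match_fraction: float
    aligned_length: int
    strand: int = +1


def _edlib_identity(query: str, text: str) -> tuple[float, int]:
    """(identity over aligned span, span length) of the best infix alignment."""
    import edlib

    res = edlib.align(query, text, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return 0.0, 0
    t_start, t_end = res["locations"][0]
    span = max(t_end + 1 - t_start, len(query))
    return 1.0 - res["editDistance"] / span, span


def best_transcript_match(target: TargetRegion,
                          transcriptome: Sequence[SeqRecord],
                          min_match: float = 0.55,
                          aligner: Callable[[str, str], tuple[float, int]] | None = None,
                          ) -> HomologHit | None:
    """Best-matching transcript for a target region, or None below *min_match*.

    The threshold is inclusive: a best hit exactly at *min_match* is
    returned; only strictly lower ones are rejected.
    """
    aligner = aligner or _edlib_identity
    taxon, ref = target.reference()
    best: HomologHit | None = None
    for tr in transcriptome:
        for strand, seq in ((+1, ref), (-1, revcomp(ref))):
            ident, span = aligner(seq, tr.sequence)
            if span == 0:
                continue
            hit = HomologHit(target.locus_id, tr.taxon, tr.id, ident, span, strand)
            if best is None or hit.match_fraction > best.match_fraction:
                best = hit
    if best is None or best.match_fraction < min_match:
        return None
    return best


def assemble_locus_set(hits: Sequence[HomologHit],
                       sequences: dict[str, SeqRecord],
                       out_dir: str | Path,
                       aligner_cmd: str = "mafft",
                       aligner_flags: Sequence[str] = ("--genafpair", "--maxiterate", "1000"),
                       ) -> Path | None:
    """Write the unaligned per-locus FASTA plus a manifest describing the
    external aligner invocation; alignment itself is an external-tool
    contract whose output is read back as an :class:`AlignedLocus`.

    Returns the FASTA path, or None when the locus is skipped (< 2 hits).
    """
    if len(hits) < 2:
        logger.info("locus %s: %d hit(s), skipped",
                    hits[0].locus_id if hits else "?", len(hits))
        return None
    locus_id = hits[0].locus_id
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{locus_id}.fasta"
    write_fasta([sequences[h.transcript_id] for h in hits], fasta)
    manifest = {
        "locus_id": locus_id,
        "input": fasta.name,
        "output": f"{locus_id}.aligned.fasta",
        "tool": aligner_cmd,
        "args": list(aligner_flags),
    }
    with open(out_dir / f"{locus_id}.aligner.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return fasta


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str


def representation_filter(msa: AlignedLocus, required_taxa: Iterable[str],
                          len_fraction: float = 0.8,
                          max_short: int = 2) -> FilterDecision:
    """Drop a locus missing any required anchor taxon, or where more than
    *max_short* of the other species have transcripts shorter than
    *len_fraction* x the longest required-taxon transcript.

    Only ungapped lengths matter, so the decision is invariant to row
    order and to gap padding.
    """
    required = set(required_taxa)
    by_taxon = {r.taxon: r for r in msa.rows}
    missing = required - set(by_taxon)
    if missing:
        return FilterDecision(False, f"missing required taxon {sorted(missing)}")
    ref_len = max(by_taxon[t].ungapped_length() for t in required)
    threshold = len_fraction * ref_len
    n_short = sum(1 for r in msa.rows
                  if r.taxon not in required and r.ungapped_length() < threshold)
    if n_short > max_short:
        return FilterDecision(False,
                              f"{n_short} species below {len_fraction:.0%} of "
                              f"required-taxon length {ref_len}")
    return FilterDecision(True, "ok")
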