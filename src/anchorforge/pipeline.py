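"""End-to-end orchestration of the design and process pipelines.

Both pipelines are staged exactly as a kit designer would run them and
record a *funnel* — the count of surviving loci after every filter —
into a JSON run manifest along with the config digest, so a rerun with
the same config and inputs is hash-identical. External tools (the
multiple aligner, tree inference) are never executed in-process; their
invocations are emitted as manifests and, in the in-memory pipelines
used on simulated data, equal-length sequence sets are stacked
directly (the simulator plants no indels).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import homolog_scan, orthology, repeat_tiling, supermatrix, target_design, trim
from .config import PipelineConfig
from .seqmodel import GAP, AlignedLocus, SeqRecord
from .simulate import SimulatedClade

logger = logging.getLogger(__name__)

__all__ = ["DesignResult", "ProcessResult", "clade_alignments",
           "group_consensus_by_locus", "run_design", "run_process"]


@dataclass
class DesignResult:
    probes: list[repeat_tiling.Probe]
    regions: list[target_design.TargetRegion]
    masked_loci: list[AlignedLocus]
    funnel: dict[str, int]
    manifest: dict = field(default_factory=dict)


@dataclass
class ProcessResult:
    loci: list[AlignedLocus]
    matrix: supermatrix.Supermatrix | None
    stats: supermatrix.MatrixStats | None
    funnel: dict[str, int]
    manifest: dict = field(default_factory=dict)


def _stack(locus_id: str, records: list[SeqRecord],
           anchor_center: int | None = None) -> AlignedLocus:
    """Stack equal-length (or gap-padded) sequences into an alignment."""
    width = max(len(r.sequence) for r in records)
    rows = []
    for r in records:
        seq = r.sequence + GAP * (width - len(r.sequence))
        rows.append(SeqRecord(id=r.id, taxon=r.taxon, sample=r.sample,
                              sequence=seq, read_support=r.read_support))
    return AlignedLocus(locus_id, rows, anchor_center=anchor_center)


def clade_alignments(clade: SimulatedClade) -> list[AlignedLocus]:
    """Per-locus ortholog alignments of the simulated primary-copy
    transcripts (the simulator plants no indels, so stacking aligns)."""
    out = []
    for li in range(clade.spec.n_loci):
        recs = [r for r in clade.transcripts_for_locus(li)
                if clade.copy_of[r.id][1] == "c1"]
        if recs:
            out.append(_stack(f"L{li:03d}", recs))
    return out


def group_consensus_by_locus(records: list[SeqRecord],
                             clade: SimulatedClade) -> dict[str, list[SeqRecord]]:
    """Group consensus records by target locus using the truth table
    (stands in for the assembler's reference-locus bookkeeping)."""
    groups: dict[str, list[SeqRecord]] = {}
    for rec in records:
        li, _ = clade.copy_of[rec.id]
        groups.setdefault(f"L{li:03d}", []).append(rec)
    return groups


def _manifest(config: PipelineConfig, funnel: dict[str, int],
              payload_digest: str) -> dict:
    body = {"config_digest": config.digest(), "funnel": funnel,
            "output_digest": payload_digest}
    body["manifest_digest"] = hashlib.sha256(
        json.dumps(body, sort_keys=True).encode()).hexdigest()
    return body


def run_design(loci: list[AlignedLocus],
               transcriptomes: dict[str, list[SeqRecord]],
               genomes: dict[str, SeqRecord],
               config: PipelineConfig | None = None,
               exon_boundaries: dict[str, list[int]] | None = None,
               ) -> DesignResult:
    """Design pipeline: select -> exons -> scan -> mask -> tile -> replicate.

    *exon_boundaries* (alignment-column cut points per locus) may be
    supplied; otherwise boundaries are detected by 40-mer mapping of each
    locus's first row against every genome and unioned across species.
    """
    config = config or PipelineConfig()
    funnel = {"candidate_loci": len(loci)}

    kept = target_design.filter_ortholog_alignments(
        loci, config.min_taxa, config.window, config.min_identity)
    funnel["after_identity_filter"] = len(kept)

    regions: list[target_design.TargetRegion] = []
    region_loci: list[AlignedLocus] = []
    for msa in kept:
        if exon_boundaries is not None:
            cuts = exon_boundaries.get(msa.locus_id, [])
        else:
            cuts = set()
            ref = msa.rows[0]
            ungapped = SeqRecord(id=ref.id, taxon=ref.taxon,
                                 sequence=ref.ungapped)
            for genome in genomes.values():
                emap = target_design.map_exons_by_kmer(
                    ungapped, genome, k=config.kmer_exon)
                cuts.update(target_design.lift_boundaries_to_alignment(
                    ref, emap.boundaries))
            cuts = sorted(cuts)
        found = target_design.select_preliminary_targets(
            msa, cuts, min_len=config.min_target_len)
        for region in found:
            regions.append(region)
            sub = msa.slice_columns(
                region.start, region.stop,
                locus_id=f"{msa.locus_id}@{region.start}")
            sub.anchor_center = (region.stop - region.start) // 2
            region_loci.append(sub)
    funnel["preliminary_targets"] = len(regions)

    # homolog scan + representation filter
    scanned: list[AlignedLocus] = []
    for region, sub in zip(regions, region_loci):
        hits = []
        for taxon, transcripts in transcriptomes.items():
            hit = homolog_scan.best_transcript_match(
                region, transcripts, min_match=config.min_match)
            if hit is not None:
                hits.append(hit)
        if len(hits) < 2:
            continue
        present = {h.taxon for h in hits}
        keep_rows = [r for r in sub.rows if r.taxon in present]
        if len(keep_rows) < 2:
            continue
        cand = AlignedLocus(sub.locus_id, keep_rows,
                            anchor_center=sub.anchor_center)
        required = config.required_taxa or ()
        if required:
            decision = homolog_scan.representation_filter(
                cand, required, config.len_fraction, config.max_short)
            if not decision.keep:
                logger.info("locus %s dropped: %s", cand.locus_id, decision.reason)
                continue
        scanned.append(cand)
    funnel["after_homolog_scan"] = len(scanned)

    # repeat masking
    db = repeat_tiling.build_kmer_db(scanned, k=config.kmer_repeat)
    tallies_by_locus: dict[str, list[repeat_tiling.KmerTally]] = {}
    for genome in genomes.values():
        for locus_id, tally in repeat_tiling.tally_genome(
                db, genome, k=config.kmer_repeat).items():
            tallies_by_locus.setdefault(locus_id, []).append(tally)
    masked = [repeat_tiling.mask_high_copy(
                  msa, tallies_by_locus.get(msa.locus_id, []),
                  threshold=config.repeat_threshold)
              for msa in scanned]
    funnel["masked_loci"] = len(masked)

    probes: list[repeat_tiling.Probe] = []
    for msa in masked:
        probes.extend(repeat_tiling.probes_for_locus(
            msa, probe_len=config.probe_len, density=config.density))
    funnel["distinct_probes"] = len(probes)
    if probes:
        probes = repeat_tiling.replicate_to_capacity(
            probes, capacity=config.capacity)
    funnel["kit_probes"] = sum(p.replicates for p in probes)

    digest = hashlib.sha256("".join(
        f"{p.probe_id}:{p.sequence}:{p.replicates};" for p in probes
    ).encode()).hexdigest()
    return DesignResult(probes, regions, masked,
                        funnel, _manifest(config, funnel, digest))


def run_process(consensus_by_locus: dict[str, list[SeqRecord]],
                config: PipelineConfig | None = None,
                n_species_total: int | None = None,
                ) -> ProcessResult:
    """Process pipeline: filter -> cluster -> occupancy -> trim ->
    concatenate -> stats."""
    config = config or PipelineConfig()
    funnel = {"input_loci": len(consensus_by_locus),
              "input_consensus": sum(len(v) for v in consensus_by_locus.values())}

    filtered = {lid: orthology.filter_consensus(recs, config.min_reads)
                for lid, recs in consensus_by_locus.items()}
    funnel["consensus_after_read_filter"] = sum(len(v) for v in filtered.values())

    if n_species_total is None:
        n_species_total = len({r.taxon for recs in filtered.values()
                               for r in recs})
    clusters_by_locus: dict[str, list[orthology.OrthologCluster]] = {}
    for lid, recs in sorted(filtered.items()):
        if not recs:
            continue
        clusters = orthology.cluster_orthologs(
            recs, k=config.kmer_ortho, canonical=config.canonical_kmers)
        clusters_by_locus[lid] = orthology.filter_clusters(
            clusters, n_species_total, config.min_occupancy)
    funnel["clusters_after_occupancy"] = sum(
        len(v) for v in clusters_by_locus.values())

    loci: list[AlignedLocus] = []
    for lid, clusters in sorted(clusters_by_locus.items()):
        for ci, cluster in enumerate(clusters):
            locus_id = lid if len(clusters) == 1 else f"{lid}_c{ci + 1}"
            msa = _stack(locus_id, cluster.members)
            if msa.n_rows < 2:
                continue
            try:
                loci.append(trim.trim_alignment(
                    msa, config.min_similarity, config.trim_window,
                    config.min_good, config.min_unmasked))
            except ValueError:
                logger.info("locus %s fully trimmed away", locus_id)
    funnel["loci_after_trimming"] = len(loci)

    if not loci:
        logger.warning("no loci survive processing; empty result")
        return ProcessResult([], None, None, funnel,
                             _manifest(config, funnel, "empty"))
    matrix = supermatrix.concatenate(loci)
    stats = supermatrix.matrix_stats(matrix)
    digest = hashlib.sha256(matrix.matrix.tobytes()).hexdigest()
    return ProcessResult(loci, matrix, stats, funnel,
                         _manifest(config, funnel, digest))
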