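"""Synthetic clades with known ground truth.

Every stage of the toolkit is exercised against simulated data: a
birth--death (or user-supplied) species tree, per-locus genes built as
exons separated by introns, Jukes--Cantor-like substitution along
branches, optional gene duplications planted on named ancestral
branches, high-copy repeat elements planted in the genomes, uniform
shotgun reads, and per-sample consensus sequences with supporting-read
counts. Truth tables record exon boundaries, ortholog/paralog
assignments and repeat coordinates so recovery can be scored exactly.

All randomness flows from one top-level seed through named substreams
(one per stage), so identical specs reproduce byte-identical output and
stages can be re-run independently.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .seqmodel import SeqRecord, revcomp

__all__ = ["SimSpec", "Duplication", "SimulatedClade", "substream",
           "simulate_tree", "simulate_clade", "simulate_reads",
           "simulate_consensus_set", "jc_expected_difference"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one named stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),)))


def jc_expected_difference(distance: float) -> float:
    """Expected per-site difference between two sequences separated by
    *distance* expected substitutions (Jukes-Cantor)."""
    return 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))


@dataclass(frozen=True)
class Duplication:
    """A gene duplication planted on the branch subtending the MRCA of
    *tips*; the new copy starts *divergence* expected substitutions away."""

    locus: int
    tips: tuple[str, ...]
    divergence: float = 0.15


@dataclass
class SimSpec:
    seed: int = 0
    n_species: int = 8
    newick: str | None = None           # overrides the birth-death tree
    tree_height: float = 1.0
    n_loci: int = 20
    exon_count_range: tuple[int, int] = (1, 3)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (80, 300)
    subs_rate: float = 0.05             # expected subs/site per unit branch length
    intron_rate_factor: float = 3.0     # introns evolve faster than exons
    duplications: tuple[Duplication, ...] = ()
    repeat_motif: str = "CAG"
    repeat_copies: int = 0              # per genome; 0 disables planting
    repeat_in_locus: int | None = None  # locus index receiving an exonic repeat tract
    repeat_tract_len: int = 60
    intergenic_length: int = 200
    read_length: int = 150
    coverage: float = 20.0
    read_error: float = 0.005
    consensus_error: float = 0.002
    support_range: tuple[int, int] = (40, 400)

    def __post_init__(self) -> None:
        if self.subs_rate < 0 or self.coverage < 0 or self.repeat_copies < 0:
            raise ValueError("rates, coverage and copy numbers must be >= 0")


@dataclass
class SimulatedClade:
    spec: SimSpec
    tree: dendropy.Tree
    species: list[str]
    genomes: dict[str, SeqRecord]
    transcriptomes: dict[str, list[SeqRecord]]
    # truth tables -----------------------------------------------------
    exon_boundaries: dict[int, list[int]]              # locus -> transcript cut points
    gene_structures: dict[int, tuple[list[int], list[int]]]  # locus -> (exon, intron lens)
    copy_of: dict[str, tuple[int, str]]                # transcript id -> (locus, copy)
    locus_positions: dict[tuple[str, int, str], tuple[int, int]]
    repeat_regions: dict[str, list[tuple[int, int]]]   # genome id -> intervals

    def transcripts_for_locus(self, locus: int) -> list[SeqRecord]:
        out = []
        for recs in self.transcriptomes.values():
            out.extend(r for r in recs if self.copy_of[r.id][0] == locus)
        return out


def simulate_tree(spec: SimSpec) -> dendropy.Tree:
    """Species tree: fixed newick when given, else a birth-death tree
    rescaled to *tree_height* with tips sp01, sp02, ..."""
    if spec.newick is not None:
        tree = dendropy.Tree.get(data=spec.newick, schema="newick")
    else:
        from dendropy.simulate import treesim
        rng = random.Random(spec.seed ^ 0x5EED)
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0,
            num_extant_tips=spec.n_species, rng=rng)
        for i, leaf in enumerate(sorted(tree.leaf_node_iter(),
                                        key=lambda n: n.taxon.label), start=1):
            leaf.taxon.label = f"sp{i:02d}"
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= spec.tree_height / depth
    return tree


def _mutate(seq: np.ndarray, distance: float,
            rng: np.random.Generator) -> np.ndarray:
    """JC transition over *distance* expected substitutions: each site
    changes with probability 3/4(1 - exp(-4d/3)), uniformly to another base."""
    if distance <= 0:
        return seq.copy()
    p = jc_expected_difference(distance)
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p)
    if hit.size:
        cur = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _BASES[(cur + shift) % 4]
    return out


def _random_seq(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _other_base(base: np.bytes_) -> np.bytes_:
    return b"A" if base != b"A" else b"C"


def _disambiguate_junctions(root: np.ndarray, gene: "_Gene") -> None:
    """Make intron flank bases differ from the neighbouring exon bases.

    Real splice junctions carry intron-specific dinucleotides (GT...AG);
    without this the planted splice point is ambiguous by up to one base
    whenever an intron flank happens to match the adjacent exon, and no
    mapper could recover it exactly.
    """
    pos = 0
    for i, e in enumerate(gene.exon_lengths):
        pos += e
        if i < len(gene.intron_lengths):
            il = gene.intron_lengths[i]
            if root[pos] == root[pos + il]:           # intron[0] vs next exon
                root[pos] = _other_base(root[pos + il])
            if root[pos + il - 1] == root[pos - 1]:   # intron[-1] vs prev exon
                root[pos + il - 1] = _other_base(root[pos - 1])
            pos += il


@dataclass
class _Gene:
    exon_lengths: list[int]
    intron_lengths: list[int]

    def splice(self, seq: np.ndarray) -> np.ndarray:
        out, pos = [], 0
        for i, e in enumerate(self.exon_lengths):
            out.append(seq[pos:pos + e])
            pos += e
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return np.concatenate(out)

    @property
    def length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    def boundaries(self) -> list[int]:
        cuts, pos = [], 0
        for e in self.exon_lengths[:-1]:
            pos += e
            cuts.append(pos)
        return cuts

    def exon_sites(self) -> np.ndarray:
        flags, pos = np.zeros(self.length, dtype=bool), 0
        for i, e in enumerate(self.exon_lengths):
            flags[pos:pos + e] = True
            pos += e
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return flags


def _evolve(node, seqs: dict[str, np.ndarray], gene_rates: np.ndarray,
            spec: SimSpec, dup_nodes: dict, locus: int,
            rng: np.random.Generator, out: dict) -> None:
    """Recursively evolve all current copies of one locus down the tree."""
    for child in node.child_nodes():
        t = child.edge.length or 0.0
        child_seqs = {cid: _mutate_sites(s, t, gene_rates, rng)
                      for cid, s in seqs.items()}
        if child in dup_nodes:
            for dup in dup_nodes[child]:
                if dup.locus == locus and "c2" not in child_seqs:
                    child_seqs["c2"] = _mutate_sites(
                        child_seqs["c1"], dup.divergence,
                        np.ones_like(gene_rates), rng)
        if child.is_leaf():
            out[child.taxon.label] = child_seqs
        else:
            _evolve(child, child_seqs, gene_rates, spec, dup_nodes, locus,
                    rng, out)


def _mutate_sites(seq: np.ndarray, t: float, rates: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-site-rate JC mutation (rates = expected subs per unit t)."""
    if t <= 0:
        return seq.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * rates * t / 3.0))
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p)
    if hit.size:
        cur = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _BASES[(cur + shift) % 4]
    return out


def simulate_clade(spec: SimSpec) -> SimulatedClade:
    """Simulate genomes, transcriptomes and truth tables for one clade."""
    tree = simulate_tree(spec)
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    if len(set(species)) != len(species):
        raise ValueError("duplicate tip labels in tree")

    # resolve duplication branches to nodes
    dup_nodes: dict = {}
    for dup in spec.duplications:
        missing = set(dup.tips) - set(species)
        if missing:
            raise ValueError(f"duplication names absent tips {sorted(missing)}")
        taxa = [tree.taxon_namespace.get_taxon(t) for t in dup.tips]
        node = tree.mrca(taxa=taxa)
        if node is None:
            raise ValueError(f"no branch subtends tips {dup.tips}")
        dup_nodes.setdefault(node, []).append(dup)
        if not 0 <= dup.locus < spec.n_loci:
            raise ValueError(f"duplication on absent locus {dup.locus}")

    rng_struct = substream(spec.seed, "gene-structure")
    rng_root = substream(spec.seed, "root-sequences")
    rng_evo = substream(spec.seed, "evolution")

    genes: list[_Gene] = []
    for li in range(spec.n_loci):
        n_ex = int(rng_struct.integers(spec.exon_count_range[0],
                                       spec.exon_count_range[1] + 1))
        exons = [int(rng_struct.integers(spec.exon_length_range[0],
                                         spec.exon_length_range[1] + 1))
                 for _ in range(n_ex)]
        introns = [int(rng_struct.integers(spec.intron_length_range[0],
                                           spec.intron_length_range[1] + 1))
                   for _ in range(n_ex - 1)]
        genes.append(_Gene(exons, introns))

    # per-locus evolution
    tip_seqs: dict[int, dict[str, dict[str, np.ndarray]]] = {}
    exon_boundaries: dict[int, list[int]] = {}
    for li, gene in enumerate(genes):
        root = _random_seq(gene.length, rng_root)
        _disambiguate_junctions(root, gene)
        if spec.repeat_in_locus == li and spec.repeat_copies > 0:
            # plant a repeat tract inside the first exon
            motif = np.frombuffer(spec.repeat_motif.encode(), dtype="S1")
            tract = np.tile(motif, spec.repeat_tract_len // len(motif) + 1)
            tract = tract[:spec.repeat_tract_len]
            off = max(0, gene.exon_lengths[0] - spec.repeat_tract_len) // 2
            root[off:off + tract.size] = tract
        rates = np.where(gene.exon_sites(), spec.subs_rate,
                         spec.subs_rate * spec.intron_rate_factor)
        seqs = {"c1": root}
        # a duplication at the root (all tips named) predates the clade:
        # both copies descend in parallel through every species
        for dup in dup_nodes.get(tree.seed_node, []):
            if dup.locus == li:
                seqs["c2"] = _mutate_sites(root, dup.divergence,
                                           np.ones_like(rates), rng_evo)
        out: dict[str, dict[str, np.ndarray]] = {}
        _evolve(tree.seed_node, seqs, rates, spec, dup_nodes, li,
                rng_evo, out)
        tip_seqs[li] = out
        exon_boundaries[li] = gene.boundaries()

    # assemble genomes / transcriptomes
    rng_genome = substream(spec.seed, "genome-assembly")
    genomes: dict[str, SeqRecord] = {}
    transcriptomes: dict[str, list[SeqRecord]] = {sp: [] for sp in species}
    copy_of: dict[str, tuple[int, str]] = {}
    locus_positions: dict[tuple[str, int, str], tuple[int, int]] = {}
    repeat_regions: dict[str, list[tuple[int, int]]] = {}
    motif = spec.repeat_motif
    for sp in species:
        parts: list[np.ndarray] = []
        pos = 0
        repeat_regions[sp] = []

        def filler(n: int) -> None:
            nonlocal pos
            parts.append(_random_seq(n, rng_genome))
            pos += n

        filler(spec.intergenic_length)
        for li, gene in enumerate(genes):
            for cid in sorted(tip_seqs[li].get(sp, {})):
                seq = tip_seqs[li][sp][cid]
                locus_positions[(sp, li, cid)] = (pos, pos + seq.size)
                parts.append(seq)
                pos += seq.size
                tr_id = f"{sp}_L{li:03d}_{cid}"
                transcriptomes[sp].append(SeqRecord(
                    id=tr_id, taxon=sp, sample=sp,
                    sequence=gene.splice(seq).tobytes().decode()))
                copy_of[tr_id] = (li, cid)
                filler(spec.intergenic_length)
        if spec.repeat_copies > 0:
            tract = (motif * (spec.repeat_copies * len(motif)))[
                : spec.repeat_copies * len(motif)]
            start = pos
            parts.append(np.frombuffer(tract.encode(), dtype="S1"))
            pos += len(tract)
            repeat_regions[sp].append((start, pos))
            filler(spec.intergenic_length)
        genomes[sp] = SeqRecord(id=sp, taxon=sp, sample=sp,
                                sequence=np.concatenate(parts).tobytes().decode())
    return SimulatedClade(
        spec=spec, tree=tree, species=species, genomes=genomes,
        transcriptomes=transcriptomes, exon_boundaries=exon_boundaries,
        gene_structures={li: (g.exon_lengths, g.intron_lengths)
                         for li, g in enumerate(genes)},
        copy_of=copy_of, locus_positions=locus_positions,
        repeat_regions=repeat_regions)


def simulate_reads(genome: SeqRecord, length: int = 150, coverage: float = 20.0,
                   error: float = 0.005, seed: int = 0,
                   ) -> tuple[list[SeqRecord], list[tuple[int, int]]]:
    """Uniform-start shotgun reads from both strands with substitution errors.

    Returns (reads, truth) where truth[i] = (0-based start, strand).
    Read count = round(coverage x genome_length / length).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = substream(seed, f"reads:{genome.id}")
    L = len(genome.sequence)
    n_reads = int(round(coverage * L / length))
    reads: list[SeqRecord] = []
    truth: list[tuple[int, int]] = []
    starts = rng.integers(0, max(1, L - length + 1), size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    for i, (s, fwd) in enumerate(zip(starts, strands)):
        frag = genome.sequence[s:s + length]
        if len(frag) < length:
            continue
        arr = np.frombuffer(frag.encode(), dtype="S1").copy()
        if error > 0:
            arr = _mutate_err(arr, error, rng)
        seq = arr.tobytes().decode()
        if not fwd:
            seq = revcomp(seq)
        reads.append(SeqRecord(id=f"{genome.id}_r{i}", taxon=genome.taxon,
                               sample=genome.sample, sequence=seq))
        truth.append((int(s), 1 if fwd else -1))
    return reads, truth


def _mutate_err(arr: np.ndarray, rate: float,
                rng: np.random.Generator) -> np.ndarray:
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        cur = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(cur + shift) % 4]
    return arr


def simulate_consensus_set(clade: SimulatedClade,
                           support_range: tuple[int, int] | None = None,
                           ) -> list[SeqRecord]:
    """Per-sample consensus sequences with supporting-read counts.

    One record per (sample, locus, gene copy): paralog copies appear as
    separate records, mirroring an assembler that splits gene copies
    above its divergence threshold. Sequences are the spliced transcript
    with a light consensus error; read support is drawn uniformly from
    *support_range* (default: the spec's range).
    """
    spec = clade.spec
    lo, hi = support_range or spec.support_range
    rng = substream(spec.seed, "consensus")
    records: list[SeqRecord] = []
    for sp in clade.species:
        for tr in clade.transcriptomes[sp]:
            arr = np.frombuffer(tr.sequence.encode(), dtype="S1").copy()
            if spec.consensus_error > 0:
                arr = _mutate_err(arr, spec.consensus_error, rng)
            support = int(rng.integers(lo, hi + 1))
            records.append(SeqRecord(
                id=tr.id, taxon=sp, sample=sp,
                sequence=arr.tobytes().decode(), read_support=support))
    return records
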