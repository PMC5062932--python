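"""Post-capture orthology assessment.

Assembled consensus sequences are first filtered on supporting-read
count (weakly supported contigs are usually index-hopping artefacts),
then grouped into putative ortholog clusters per target locus by
agglomerative average-linkage clustering on a k-mer set distance:

* a sequence's profile is the set of its contiguous 20-mers plus all
  20-mers built from every third position (so that third-codon
  variation in exons does not swamp the measure);
* the distance between two sequences is one minus the fraction of
  20-mers observed in the two sequences that are found in both
  (Jaccard distance on the profile sets);
* clusters merge greedily by minimum average distance, but a merge is
  admissible only while the union keeps at most one sequence per
  species — a gene duplicated before the root separates into parallel
  clusters, one per copy, while a duplication inside the clade yields a
  full cluster plus a partial cluster of the descendant species.

Clusters occupying fewer than 75% of the sampled species are dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seqmodel import SeqRecord, revcomp

logger = logging.getLogger(__name__)

__all__ = ["KmerProfile", "OrthologCluster", "DistanceMatrix",
           "filter_consensus", "kmer_profile", "pair_distance",
           "distance_matrix", "cluster_orthologs", "filter_clusters"]


@dataclass
class KmerProfile:
    sequence_id: str
    k: int
    kmers: frozenset[str]


@dataclass
class OrthologCluster:
    cluster_id: str
    members: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        taxa = [m.taxon for m in self.members]
        if len(set(taxa)) != len(taxa):
            raise ValueError(f"cluster {self.cluster_id}: duplicate taxon")

    @property
    def species_set(self) -> set[str]:
        return {m.taxon for m in self.members}


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v


def filter_consensus(records: Sequence[SeqRecord],
                     min_reads: int = 35) -> list[SeqRecord]:
    """Keep consensus sequences derived from at least *min_reads* reads
    (the printed rule removes those from *fewer than* 35)."""
    for rec in records:
        if rec.read_support is None:
            raise ValueError(f"record {rec.id!r}: read_support missing")
    return [r for r in records if r.read_support >= min_reads]


def kmer_profile(seq: SeqRecord | str, k: int = 20,
                 canonical: bool = False) -> KmerProfile:
    """Contiguous k-mers plus every-third-position k-mers of a sequence.

    The strided part takes bases at positions p, p+3, ..., p+3(k-1) for
    every valid start p. k-mers containing N are excluded; a sequence
    shorter than k yields an empty profile. With *canonical* each k-mer
    is replaced by the lexicographic minimum of itself and its reverse
    complement (for unoriented input).
    """
    if isinstance(seq, SeqRecord):
        sid, s = seq.id, seq.ungapped
    else:
        sid, s = "", seq.replace("-", "")
    kmers: set[str] = set()
    for i in range(len(s) - k + 1):
        kmers.add(s[i:i + k])
    span = 3 * (k - 1) + 1
    for p in range(len(s) - span + 1):
        kmers.add(s[p:p + span:3])
    kmers = {m for m in kmers if "N" not in m}
    if canonical:
        kmers = {min(m, revcomp(m)) for m in kmers}
    return KmerProfile(sid, k, frozenset(kmers))


def pair_distance(a: KmerProfile, b: KmerProfile) -> float:
    """1 - |A ∩ B| / |A ∪ B| on the two k-mer sets; 1.0 when both empty."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")
    union = a.kmers | b.kmers
    if not union:
        logger.warning("pair_distance: both profiles empty (%s, %s)",
                       a.sequence_id, b.sequence_id)
        return 1.0
    return 1.0 - len(a.kmers & b.kmers) / len(union)


def distance_matrix(records: Sequence[SeqRecord], k: int = 20,
                    canonical: bool = False) -> DistanceMatrix:
    profiles = [kmer_profile(r, k, canonical) for r in records]
    n = len(records)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pair_distance(profiles[i], profiles[j])
    return DistanceMatrix([r.id for r in records], d)


def cluster_orthologs(homologs: Sequence[SeqRecord],
                      max_distance: float | None = None,
                      k: int = 20, canonical: bool = False,
                      dist: DistanceMatrix | None = None,
                      ) -> list[OrthologCluster]:
    """Species-constrained average-linkage clustering of homologs.

    At each step the pair of clusters with minimum average pairwise
    distance is merged, restricted to pairs whose union still holds at
    most one sequence per species; merging stops when no admissible
    pair remains or the best admissible distance exceeds *max_distance*
    (when set). Ties break on the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest member id),
    making the result order-independent.
    """
    if not homologs:
        return []
    if dist is None:
        dist = distance_matrix(homologs, k=k, canonical=canonical)
    d = dist.values
    clusters: list[list[int]] = [[i] for i in range(len(homologs))]

    def label(c: list[int]) -> str:
        return min(homologs[i].id for i in c)

    def taxa(c: list[int]) -> set[str]:
        return {homologs[i].taxon for i in c}

    while len(clusters) > 1:
        best = None  # (distance, label pair, index pair)
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            if taxa(ca) & taxa(cb):
                continue
            avg = float(np.mean([d[i, j] for i in ca for j in cb]))
            key = (avg, tuple(sorted((label(ca), label(cb)))))
            if best is None or key < best[0]:
                best = (key, (a, b))
        if best is None:
            break
        (avg, _), (a, b) = best
        if max_distance is not None and avg > max_distance:
            break
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]

    clusters.sort(key=label)
    return [OrthologCluster(f"c{i + 1}", [homologs[j] for j in c])
            for i, c in enumerate(clusters)]


def filter_clusters(clusters: Sequence[OrthologCluster], n_species_total: int,
                    min_fraction: float = 0.75) -> list[OrthologCluster]:
    """Keep clusters whose species occupancy is at least *min_fraction*
    of the sampled species (removal is strict-below, so a cluster at
    exactly the threshold is kept)."""
    if n_species_total < 1:
        raise ValueError("n_species_total must be >= 1")
    return [c for c in clusters
            if len(c.species_set) / n_species_total >= min_fraction]
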