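"""Pipeline configuration: every tunable threshold in one place.

Defaults are the operating point of the original spider kit design;
they are deliberately conservative and each is documented at its point
of use. The config serialises to YAML and hashes stably, so a run
manifest fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # target selection
    min_taxa: int = 6
    window: int = 120
    min_identity: float = 0.5
    min_target_len: int = 150
    # exon mapping
    kmer_exon: int = 40
    read_flank: int = 30
    read_mismatch_frac: float = 0.2
    read_min_reads: int = 5
    # homolog scan
    min_match: float = 0.55
    required_taxa: tuple[str, ...] = ()
    len_fraction: float = 0.8
    max_short: int = 2
    # repeat masking / tiling
    kmer_repeat: int = 15
    repeat_threshold: int = 100_000
    probe_len: int = 120
    density: float = 4.0
    capacity: int = 57_700
    # post-capture processing
    min_reads: int = 35
    kmer_ortho: int = 20
    canonical_kmers: bool = False
    min_occupancy: float = 0.75
    min_similarity: float = 0.70
    trim_window: int = 20
    min_good: int = 10
    min_unmasked: int = 10
    # misc
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.min_taxa >= 2, "min_taxa >= 2"),
            (0 <= self.min_identity <= 1, "min_identity in [0,1]"),
            (0 <= self.min_match <= 1, "min_match in [0,1]"),
            (0 <= self.min_occupancy <= 1, "min_occupancy in [0,1]"),
            (0 < self.density, "density > 0"),
            (self.capacity >= 1, "capacity >= 1"),
            (self.min_reads >= 0, "min_reads >= 0"),
        ]
        for ok, what in checks:
            if not ok:
                raise ValueError(f"config: {what} violated")
        self.required_taxa = tuple(self.required_taxa)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["required_taxa"] = list(d["required_taxa"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "required_taxa" in d:
            d["required_taxa"] = tuple(d["required_taxa"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
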