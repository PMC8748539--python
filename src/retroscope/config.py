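"""Pipeline-wide tunable constants.

The defaults encode the windows and thresholds used throughout the
analysis: 100-bp windows both for two-caller consensus and for pairing
tumor against normal calls, a 20-bp distance for filtering insertions
already segregating in the population, ±50-bp flanks for base
composition, ±500-bp TE TSS windows for methylation probes, recurrence at
3 or more patients, and the 100-insertion burden split for survival
stratification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    consensus_window_bp: int = 100
    polymorphic_distance_bp: int = 20
    somatic_window_bp: int = 100
    flank_bp: int = 50
    tss_flank_bp: int = 500
    recurrence_min_patients: int = 3
    burden_threshold: int = 100
    full_length_line1_min_bp: int = 5900
    alpha: float = 0.05
    rng_seed: int = 0
    #: normalize "chr" prefixes when matching chromosome names; off by
    #: default so mismatched annotation builds fail loudly
    strip_chr_prefix: bool = False

    def __post_init__(self) -> None:
        for f in (
            "consensus_window_bp",
            "polymorphic_distance_bp",
            "somatic_window_bp",
            "flank_bp",
            "tss_flank_bp",
            "recurrence_min_patients",
            "burden_threshold",
            "full_length_line1_min_bp",
        ):
            v = getattr(self, f)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{f} must be a strictly positive integer, got {v!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")

    def normalize_chrom(self, chrom: str) -> str:
        if self.strip_chr_prefix and chrom.startswith("chr"):
            return chrom[3:]
        return chrom

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
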