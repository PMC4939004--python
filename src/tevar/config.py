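"""Analysis configuration.

The defaults encode the analysis constants: 170 bp fragments matched by
170-mer mappability with up to 2 mismatches, 400 bp peak-calling feature
length, top/bottom 5% variable/common classification, a neutral
substitution rate of 4.5e-9 per site per year with a 40 Myr young/old TE
cutoff, differential-methylation thresholds (variance > 0.05, range >
0.75), motif selection rules (enrichment p < 0.01 and occurrence in > 10%
of targets), and +/-2500 bp boundary profiles.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml


@dataclass
class AnalysisConfig:
    kmer_length: int = 170                 # bp; mappability k-mer / fragment length
    max_mismatches: int = 2                # mappability mismatch budget
    feature_length: int = 400              # bp; peak-calling kernel feature length
    variable_fraction: float = 0.05        # top/bottom fraction for variable/common
    substitution_rate: float = 4.5e-9      # substitutions / site / year
    age_cutoff: float = 4.0e7              # years; young/old TE boundary
    dm_variance_threshold: float = 0.05    # cross-strain methylation variance
    dm_range_threshold: float = 0.75       # cross-strain methylation range
    motif_p_threshold: float = 0.01        # motif enrichment p cutoff
    motif_occurrence_fraction: float = 0.10  # min fraction of targets with motif
    flank: int = 2500                      # bp; TE boundary profile flank
    rng_seed: int = 0

    # exposed implementation knobs (documented in docs/methods.md)
    peak_threshold_sd: float = 7.0         # background mean + k*SD peak threshold
                                           # (controls the genome-wide maximum)
    idr_window: int = 20                   # reproducibility rolling window
    idr_discordance: float = 0.5           # rolling mean |rank diff| cutoff
    motif_score_fraction: float = 0.8      # PWM hit threshold as fraction of max
    gc_bin_width: float = 0.05             # GC-matching bin width
    gc_background_ratio: int = 2           # backgrounds sampled per target
    mappability_max_bp: int = 5_000_000    # exact-algorithm genome size cap

    def __post_init__(self):
        for name in ("kmer_length", "feature_length", "flank"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        for name in ("variable_fraction", "motif_occurrence_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v!r}")
        if self.variable_fraction >= 0.5:
            raise ValueError("variable_fraction must be < 0.5")
        if self.substitution_rate <= 0:
            raise ValueError("substitution_rate must be > 0")
        if not (0 < self.motif_p_threshold < 1):
            raise ValueError("motif_p_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
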