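"""Run configuration: one object bundling every stage's parameters.

The defaults ARE the study conditions of the default end-to-end simulation;
see docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .capture import CaptureParams
from .damage import DamageParams, SizeModel
from .genome import GenomeConfig, MethylationProfile

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    methylation: MethylationProfile = field(default_factory=MethylationProfile)
    damage: DamageParams = field(default_factory=DamageParams)
    capture: CaptureParams = field(default_factory=CaptureParams)
    n_fragments: int = 150_000
    endogenous_fraction: float = 0.35
    mito_copy_boost: float = 3.0
    n_reads: int = 60_000  # per fraction
    amp_dispersion: float = 0.3
    gc_bias_slope: float | None = None
    seed: int | None = None
    d_max: int = 25
    ms_window: int = 100
    ms_min_cov: int = 1  # desk-scale aggregation threshold; paper-scale uses 50/60

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for simulation runs")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        self.genome.validate()
        self.methylation.validate()
        self.damage.validate()
        self.capture.validate()

    # -- (de)serialisation -------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "genome" in d:
            d["genome"] = GenomeConfig(**d["genome"])
        if "methylation" in d:
            d["methylation"] = MethylationProfile(**d["methylation"])
        if "damage" in d:
            dmg = dict(d["damage"])
            if "size_model" in dmg and isinstance(dmg["size_model"], dict):
                dmg["size_model"] = SizeModel(**dmg["size_model"])
            d["damage"] = DamageParams(**dmg)
        if "capture" in d:
            d["capture"] = CaptureParams(**d["capture"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def small(self) -> "RunConfig":
        """A scaled-down variant for smoke tests (~50 kb genome)."""
        return RunConfig(
            genome=GenomeConfig(
                nuclear_length=50_000,
                n_cgi=4,
                cgi_length=800,
                n_te_families=2,
                te_copies=2,
                te_length=600,
                mito_length=3_000,
                n_microbial=2,
                microbial_length=10_000,
            ),
            methylation=self.methylation,
            damage=self.damage,
            capture=self.capture,
            n_fragments=5_000,
            endogenous_fraction=self.endogenous_fraction,
            mito_copy_boost=self.mito_copy_boost,
            n_reads=3_000,
            amp_dispersion=self.amp_dispersion,
            gc_bias_slope=self.gc_bias_slope,
            seed=self.seed,
            d_max=self.d_max,
            ms_window=self.ms_window,
            ms_min_cov=self.ms_min_cov,
        )
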