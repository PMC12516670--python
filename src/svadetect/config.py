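"""Pipeline configuration.

Every analysis threshold lives here with its study default: 5 % RHa and
2 vol-% VWC bins, a 20-observation bin minimum, 0.45/0.55 dominance bounds,
the 75 % RHa dew threshold, the 5 degC air-temperature floor and rain-day
exclusion, the 3 h SVA-day criterion and the >= 10 days annual inclusion
rule.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["SiteInput", "PipelineConfig"]


@dataclass
class SiteInput:
    """One site file plus its reader dialect and metadata."""

    path: str
    site_id: str | None = None
    column_map: dict = field(default_factory=dict)
    vpd_unit: str = "kPa"
    meta: dict = field(default_factory=dict)  # e.g. pft, aridity labels
    anchors_path: str | None = None  # laboratory retention anchors CSV


@dataclass
class PipelineConfig:
    """All knobs of the detection pipeline, defaults = study values."""

    sites: list[SiteInput] = field(default_factory=list)
    # filters
    qc_max: int = 0
    rain_day_mm: float = 0.0
    ta_min_c: float = 5.0
    vwc_min: float = 0.0
    vwc_max: float = 100.0
    # binning and dominance classification
    rha_bin_width: float = 5.0
    vwc_bin_width: float = 2.0
    min_obs_per_bin: int = 20
    dominance_lo: float = 0.45
    dominance_hi: float = 0.55
    # dew exclusion
    dew_rha_thresh: float = 75.0
    # template library (VWC_RH80 values, vol-%); None -> package default set
    template_values: list[float] | None = None
    # event statistics
    day_threshold_h: float = 3.0
    min_days_per_year: int = 10
    event_night_only: bool = False
    # bookkeeping
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if self.dominance_lo >= self.dominance_hi:
            raise ValueError("dominance thresholds require lo < hi")
        if self.rha_bin_width <= 0 or self.vwc_bin_width <= 0:
            raise ValueError("bin widths must be positive")
        if self.min_obs_per_bin < 1:
            raise ValueError("min_obs_per_bin must be >= 1")
        if not 0 <= self.dew_rha_thresh <= 100:
            raise ValueError("dew_rha_thresh must be in [0, 100] %")
        if self.day_threshold_h < 0 or self.min_days_per_year < 0:
            raise ValueError("event thresholds must be non-negative")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["sites"] = [
            s if isinstance(s, SiteInput) else SiteInput(**s)
            for s in d.get("sites", [])
        ]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
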