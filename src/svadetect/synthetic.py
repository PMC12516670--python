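"""Synthetic half-hourly tower data with known adsorption ground truth.

The generator emulates the statistical structure the detection pipeline
assumes: a diel air-temperature sinusoid with a vapor-pressure cycle lagged
so relative humidity peaks at night; rain pulses followed by exponential
soil-moisture drydown toward a dry residual; nocturnal latent-heat fluxes
whose sign follows the vapor-pressure gradient between air and soil pore
space under a known retention boundary, buried in symmetric zero-mean noise;
dew events that force condensation at very high humidity; and daytime
evaporative fluxes.  Every series carries a ground-truth sidecar of
adsorption and dew flags so parameter-recovery and consistency tests have an
exact oracle.

The defaults are the documented study conditions of this package's synthetic
experiments (180 days, night signal 8 W m^-2 against 10 W m^-2 noise); they
are a calibration of the simulator, not field truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core_physics import DEFAULT_CONSTANTS, esat
from .ec_io import SENTINEL, SiteSeries
from .eve_templates import EVEaTemplate, build_template

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_site",
    "generate_null_site",
    "generate_twin_towers",
    "write_fluxnet_csv",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic tower.

    Units: temperatures degC, vapor pressures kPa, fluxes W m^-2, water
    contents vol-%, precipitation mm per event, times days/hours.
    """

    n_days: int = 180
    seed: int = 0
    # diel meteorology: a repeatable nocturnal humidity trajectory so that
    # (RHa, VWC) bins accumulate enough observations for dominance calls
    ta_mean: float = 20.0
    ta_amp: float = 2.5
    ta_noise_sd: float = 0.1
    vapor_pressure_mean: float = 1.316
    vapor_pressure_amp: float = 0.020
    vapor_pressure_daily_sd: float = 0.01
    humid_night_prob: float = 0.001
    humid_offset: float = 0.62
    # rain and soil moisture: dryland-like rare rain with fast drydown
    rain_prob_per_day: float = 0.008
    rain_mm: float = 5.0
    vwc_wet: float = 25.0
    vwc_residual: float = 2.0
    drydown_efold_days: float = 0.25
    # retention / fluxes
    true_vwc_rh80: float = 8.08
    day_le_mean: float = 100.0
    day_noise_sd: float = 15.0
    night_signal: float = 8.0
    night_noise_sd: float = 10.0
    noise_family: str = "gaussian"  # or "laplace"
    dew_rha_thresh: float = 95.0
    dew_enabled: bool = True
    start: str = "2010-01-01"
    site_id: str = "SYN-001"

    def __post_init__(self) -> None:
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")
        if not (0 <= self.rain_prob_per_day <= 1):
            raise ValueError("rain_prob_per_day must be in [0, 1]")
        if self.vwc_residual <= 0 or self.vwc_residual >= self.vwc_wet:
            raise ValueError("require 0 < vwc_residual < vwc_wet")
        for name in ("ta_amp", "drydown_efold_days", "vapor_pressure_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_family not in ("gaussian", "laplace"):
            raise ValueError("noise_family must be 'gaussian' or 'laplace'")

    @property
    def template(self) -> EVEaTemplate:
        if self.true_vwc_rh80 == 0:
            return EVEaTemplate(0.0, label="null")
        return build_template(self.true_vwc_rh80, label="true")


@dataclass
class GroundTruth:
    """Per-record truth flags plus the generating template."""

    flags: pd.DataFrame  # columns: adsorption, dew
    template: EVEaTemplate


# night window: 10 h, 21:00-07:00 local
_NIGHT_START, _NIGHT_END = 21.0, 7.0


def _night_mask(hour: np.ndarray) -> np.ndarray:
    return (hour >= _NIGHT_START) | (hour < _NIGHT_END)


def _noise(rng: np.random.Generator, sd: float, n: int, family: str) -> np.ndarray:
    if family == "laplace":
        return rng.laplace(0.0, sd / np.sqrt(2.0), n)
    return rng.normal(0.0, sd, n)


def _generate(cfg: SynthConfig, signal_scale: float, null_night: bool):
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_days * 48
    i = np.arange(n)
    hour = (i % 48) / 2.0
    day_idx = i // 48
    timestamp = pd.date_range(cfg.start, periods=n, freq="30min")

    # air temperature: sinusoid peaking at 15:00 plus small noise
    ta = (
        cfg.ta_mean
        + cfg.ta_amp * np.sin(2 * np.pi * (hour - 9.0) / 24.0)
        + rng.normal(0.0, cfg.ta_noise_sd, n)
    )
    es = esat(ta)

    # air vapor pressure: diel cycle peaking at 03:00 (lagged vs Ta so RHa
    # peaks at night), a day-to-day synoptic offset, and rare humid spells
    # that push RHa toward saturation (dew conditions)
    daily_offset = rng.normal(0.0, cfg.vapor_pressure_daily_sd, cfg.n_days)
    humid = rng.random(cfg.n_days) < cfg.humid_night_prob
    daily_offset[humid] += cfg.humid_offset
    vp_offset = daily_offset[day_idx]
    e_air = (
        cfg.vapor_pressure_mean
        + cfg.vapor_pressure_amp * np.sin(2 * np.pi * (hour - 21.0) / 24.0)
        + vp_offset
    )
    e_air = np.clip(e_air, 0.05, es)
    vpd = es - e_air
    rha = np.clip(100.0 * e_air / es, 0.0, 100.0)

    # rain days and soil moisture drydown
    # rain in the morning: the shallow wetted layer dries through the rest of
    # the (excluded) rain day, so nights sample either wet or residual soil
    rain_day = rng.random(cfg.n_days) < cfg.rain_prob_per_day
    precip = np.zeros(n)
    morning = (hour == 8.0) | (hour == 8.5)
    precip[rain_day[day_idx] & morning] = cfg.rain_mm / 2.0

    decay = np.exp(-1.0 / (48.0 * cfg.drydown_efold_days))
    vwc = np.empty(n)
    v = cfg.vwc_residual + (cfg.vwc_wet - cfg.vwc_residual) * 0.5
    for k in range(n):
        if precip[k] > 0:
            v = cfg.vwc_wet
        else:
            v = cfg.vwc_residual + (v - cfg.vwc_residual) * decay
        vwc[k] = v

    template = cfg.template
    rhs = template.rhs_at_vwc(vwc)

    night = _night_mask(hour)
    night_noise = _noise(rng, cfg.night_noise_sd, n, cfg.noise_family)
    day_noise = rng.normal(0.0, cfg.day_noise_sd, n)

    # daytime: solar-shaped evaporation
    solar = np.where(~night, np.sin(np.pi * (hour - _NIGHT_END) / 14.0), 0.0)
    solar = np.clip(solar, 0.0, None)
    le = cfg.day_le_mean * solar + np.where(night, 0.0, day_noise)

    # nighttime: gradient-driven signal in symmetric noise
    if null_night:
        le_night = night_noise
    else:
        grad_sign = np.sign(rhs - rha)  # +1: soil wetter -> upward flux
        le_night = signal_scale * cfg.night_signal * grad_sign + night_noise
    le = np.where(night, le_night, le)

    # dew: very high humidity forces condensation at night (not in the null
    # mode, whose nocturnal flux is pure noise by construction)
    dew = np.zeros(n, dtype=bool)
    if cfg.dew_enabled and not null_night:
        dew = night & (rha > cfg.dew_rha_thresh)
        le = np.where(dew, -cfg.night_signal - np.abs(night_noise), le)

    adsorption = night & (rha > rhs) & template.is_sva_possible(rha, vwc)
    if null_night or signal_scale == 0.0:
        adsorption = np.zeros(n, dtype=bool)

    records = pd.DataFrame(
        {
            "timestamp": timestamp,
            "le": le,
            "le_qc": 0,
            "vpd": vpd,
            "ta": ta,
            "vwc": vwc,
            "precip": precip,
            "night": night,
            "rha": rha,
            "valid": True,
            "invalid_reason": "",
        }
    )
    series = SiteSeries(site_id=cfg.site_id, records=records, meta={"synthetic": True})
    truth = GroundTruth(
        flags=pd.DataFrame({"adsorption": adsorption, "dew": dew}),
        template=template,
    )
    return series, truth


def generate_site(cfg: SynthConfig) -> tuple[SiteSeries, GroundTruth]:
    """Generate one synthetic site; deterministic given ``cfg.seed``."""
    return _generate(cfg, signal_scale=1.0, null_night=False)


def generate_null_site(cfg: SynthConfig) -> SiteSeries:
    """Same meteorology and soil dynamics, but nocturnal flux is pure noise."""
    series, _ = _generate(cfg, signal_scale=1.0, null_night=True)
    return series


def generate_twin_towers(
    cfg: SynthConfig, decoupling: float
) -> tuple[SiteSeries, SiteSeries]:
    """A coupled "short tower" and a partially decoupled "tall tower".

    The tall tower sees the same meteorology and noise, with the nocturnal
    gradient signal attenuated by (1 - decoupling).
    """
    if not 0.0 <= decoupling <= 1.0:
        raise ValueError("decoupling must be in [0, 1]")
    short, _ = _generate(cfg, signal_scale=1.0, null_night=False)
    tall_cfg = replace(cfg, site_id=cfg.site_id + "-tall")
    tall, _ = _generate(tall_cfg, signal_scale=1.0 - decoupling, null_night=False)
    return short, tall


def write_fluxnet_csv(
    series: SiteSeries, path: str | Path, truth: GroundTruth | None = None
) -> None:
    """Write a series as a FLUXNET-style CSV (plus optional truth sidecar).

    Columns follow the default ONEFlux names; missing values become -9999.
    The sidecar (``<path stem>_truth.csv``) holds the adsorption/dew flags and
    the generating template's VWC_RH80.
    """
    path = Path(path)
    df = series.records
    out = pd.DataFrame(
        {
            "TIMESTAMP_START": df["timestamp"].dt.strftime("%Y%m%d%H%M"),
            "LE_F_MDS": df["le"],
            "LE_F_MDS_QC": df["le_qc"],
            "VPD_F": df["vpd"],
            "TA_F": df["ta"],
            "SWC_F_MDS_1": df["vwc"],
            "P_F": df["precip"],
            "NIGHT": df["night"].astype(int),
        }
    )
    out = out.fillna(SENTINEL)
    out.to_csv(path, index=False, float_format="%.4f")
    if truth is not None:
        side = truth.flags.copy()
        side.insert(0, "TIMESTAMP_START", out["TIMESTAMP_START"].to_numpy())
        side["true_vwc_rh80"] = truth.template.vwc_rh80
        side.to_csv(path.with_name(path.stem + "_truth.csv"), index=False)
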