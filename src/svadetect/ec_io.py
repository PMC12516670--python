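"""Reading FLUXNET-style half-hourly site files and the quality/meteorological filters.

The reader targets ONEFlux-processed half-hourly CSVs: 12-digit
``TIMESTAMP_START`` stamps, a ``-9999`` missing-value sentinel, and the usual
column names (``LE_F_MDS``, ``VPD_F``, ``SWC_F_MDS_1``, ...).  Site dialects
are handled through a column map.  Records are kept in a pandas DataFrame
wrapped in :class:`SiteSeries`; filtering never drops rows, it only sets a
validity flag and a first-failing-rule reason, so record counts are conserved
and filter reports are auditable.

Filters applied (in order): non-measured flux (QC != 0), any record on a
calendar day with summed precipitation > 0 mm, air temperature below 5 degC,
implausible soil moisture (<= 0 or > 100 vol-%), and missing required fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_physics import DEFAULT_CONSTANTS, PhysicalConstants, rha_from_vpd

__all__ = [
    "SiteSeries",
    "FilterSettings",
    "DEFAULT_COLUMN_MAP",
    "SENTINEL",
    "read_fluxnet_csv",
    "apply_filters",
    "select_night",
]

SENTINEL = -9999

#: Default FLUXNET/ONEFlux column names keyed by internal field name.
DEFAULT_COLUMN_MAP = {
    "le": "LE_F_MDS",
    "le_qc": "LE_F_MDS_QC",
    "vpd": "VPD_F",
    "ta": "TA_F",
    "vwc": "SWC_F_MDS_1",
    "precip": "P_F",
    "night": "NIGHT",
}

REQUIRED_FIELDS = ("le", "le_qc", "vpd", "ta", "vwc", "precip")

FILTER_RULES = ("qc", "rain_day", "ta", "vwc", "missing")


@dataclass
class FilterSettings:
    """Quality-filter thresholds (defaults are the study's values)."""

    qc_max: int = 0          # keep only measured data: QC == 0
    rain_day_mm: float = 0.0  # exclude whole days with summed precip > this
    ta_min_c: float = 5.0    # exclude half hours colder than this
    vwc_min: float = 0.0     # exclusive lower bound, vol-%
    vwc_max: float = 100.0


@dataclass
class SiteSeries:
    """Half-hourly records for one site.

    ``records`` columns: timestamp, le, le_qc, vpd, ta, vwc, precip, night,
    rha, valid, invalid_reason.
    """

    site_id: str
    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def valid(self) -> pd.DataFrame:
        return self.records[self.records["valid"]]


class DataError(ValueError):
    """Malformed input data (duplicate timestamps, broken cadence)."""


class ConfigurationError(ValueError):
    """Missing columns or inconsistent configuration."""


def _check_cadence(ts: pd.Series) -> None:
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise DataError(f"duplicate timestamp {dup}")
    if not ts.is_monotonic_increasing:
        raise DataError("timestamps must be strictly increasing")
    deltas = ts.diff().dropna()
    if len(deltas) and (deltas % pd.Timedelta(minutes=30) != pd.Timedelta(0)).any():
        raise DataError("timestamps must fall on a half-hourly grid")


def read_fluxnet_csv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    site_id: str | None = None,
    vpd_unit: str = "kPa",
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    meta: dict | None = None,
) -> SiteSeries:
    """Read one half-hourly FLUXNET-style CSV into a :class:`SiteSeries`.

    Parameters
    ----------
    column_map
        Overrides for :data:`DEFAULT_COLUMN_MAP` (internal name -> file column).
    vpd_unit
        ``"kPa"`` (default) or ``"hPa"`` for releases that report VPD in hPa.
    """
    path = Path(path)
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    raw = pd.read_csv(path)
    if "TIMESTAMP_START" not in raw.columns:
        raise ConfigurationError("missing required column 'TIMESTAMP_START'")
    for name in REQUIRED_FIELDS:
        if cmap[name] not in raw.columns:
            raise ConfigurationError(
                f"mapped column {cmap[name]!r} for field {name!r} not in file"
            )

    df = pd.DataFrame()
    df["timestamp"] = pd.to_datetime(
        raw["TIMESTAMP_START"].astype("int64").astype(str), format="%Y%m%d%H%M"
    )
    _check_cadence(df["timestamp"])

    for name in REQUIRED_FIELDS:
        col = pd.to_numeric(raw[cmap[name]], errors="coerce")
        df[name] = col.mask(col == SENTINEL)
    if cmap["night"] in raw.columns:
        night = pd.to_numeric(raw[cmap["night"]], errors="coerce").mask(
            lambda s: s == SENTINEL
        )
        df["night"] = night > 0
    else:
        df["night"] = pd.NA

    if vpd_unit.lower() == "hpa":
        df["vpd"] = df["vpd"] / 10.0
    elif vpd_unit.lower() != "kpa":
        raise ConfigurationError(f"unknown vpd_unit {vpd_unit!r}")

    # soil moisture in vol-% throughout; fractional (m3/m3) columns detected
    # by their scale and converted
    vwc = df["vwc"]
    if vwc.notna().any() and vwc.dropna().max() <= 1.0:
        df["vwc"] = vwc * 100.0

    ok = df["vpd"].notna() & df["ta"].notna()
    rha = np.full(len(df), np.nan)
    if ok.any():
        rha[ok.to_numpy()] = rha_from_vpd(
            df.loc[ok, "vpd"].to_numpy(), df.loc[ok, "ta"].to_numpy(), constants
        )
    df["rha"] = rha
    df["valid"] = True
    df["invalid_reason"] = ""
    return SiteSeries(
        site_id=site_id or path.stem, records=df, meta=dict(meta or {})
    )


def apply_filters(
    series: SiteSeries, cfg: FilterSettings | None = None
) -> tuple[SiteSeries, pd.DataFrame]:
    """Flag records failing the quality and meteorological filters.

    Returns the flagged series (same length, values untouched) and a filter
    report with one row per rule.  Each invalid record is attributed to the
    first failing rule in the order QC -> rain day -> Ta -> VWC -> missing.
    """
    cfg = cfg or FilterSettings()
    df = series.records.copy()

    qc_bad = df["le_qc"].isna() | (df["le_qc"] > cfg.qc_max)

    day = df["timestamp"].dt.normalize()
    day_precip = df["precip"].fillna(0.0).groupby(day).transform("sum")
    rain_bad = day_precip > cfg.rain_day_mm

    ta_bad = df["ta"].notna() & (df["ta"] < cfg.ta_min_c)
    vwc_bad = df["vwc"].notna() & (
        (df["vwc"] <= cfg.vwc_min) | (df["vwc"] > cfg.vwc_max)
    )
    missing = df[list(REQUIRED_FIELDS)].isna().any(axis=1) | df["rha"].isna()

    reason = pd.Series("", index=df.index, dtype=object)
    for rule, mask in [
        ("qc", qc_bad),
        ("rain_day", rain_bad),
        ("ta", ta_bad),
        ("vwc", vwc_bad),
        ("missing", missing),
    ]:
        reason = reason.mask((reason == "") & mask, rule)

    df["valid"] = reason == ""
    df["invalid_reason"] = reason

    report = pd.DataFrame(
        {
            "rule": FILTER_RULES,
            "records_removed": [int((reason == r).sum()) for r in FILTER_RULES],
        }
    )
    return SiteSeries(series.site_id, df, dict(series.meta)), report


def select_night(series: SiteSeries) -> SiteSeries:
    """Return only the valid nighttime records (flag taken as provided)."""
    df = series.records
    if df["night"].isna().all():
        raise ConfigurationError(
            f"site {series.site_id}: no NIGHT flag present and none derivable"
        )
    keep = df["valid"] & df["night"].fillna(False).astype(bool)
    return SiteSeries(series.site_id, df[keep].reset_index(drop=True), dict(series.meta))
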