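"""SVA event labeling and occurrence statistics.

Once a site's best-fitting EVEa template is known, every quality-filtered
half hour (day and night alike) is labeled a true-positive adsorption record
when the latent heat flux is negative under conditions where the template
says adsorption is physically possible (VWC below the boundary at the
observed RHa).  Labels are aggregated to daily adsorption hours, SVA days
(>= 3 h by default), annual day counts, and a site-level report using the
inclusion rule that at least one year must show >= 10 SVA days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ec_io import SiteSeries
from .eve_templates import EVEaTemplate

__all__ = [
    "label_tp",
    "summarize_days",
    "summarize_years",
    "summarize_site",
    "SiteEventReport",
]

#: Years with fewer valid days than this are flagged partial (still summarized).
PARTIAL_YEAR_DAYS = 300


def label_tp(
    series: SiteSeries, template: EVEaTemplate, night_only: bool = False
) -> pd.Series:
    """Boolean per-record adsorption label, aligned to ``series.records``.

    True iff the record is valid, le < 0 strictly, and adsorption is possible
    at its (rha, vwc).  The null template labels nothing.  By default the full
    24 h of records is eligible; ``night_only`` restricts to the night flag.
    """
    df = series.records
    use = df["valid"] & df[["le", "rha", "vwc"]].notna().all(axis=1)
    if night_only:
        use = use & df["night"].fillna(False).astype(bool)
    out = pd.Series(False, index=df.index)
    if template.is_null or not use.any():
        return out
    rha = df.loc[use, "rha"].to_numpy(float)
    vwc = df.loc[use, "vwc"].to_numpy(float)
    le = df.loc[use, "le"].to_numpy(float)
    out.loc[use] = (le < 0) & template.is_sva_possible(rha, vwc)
    return out


def summarize_days(
    labels: pd.Series, series: SiteSeries, day_threshold_h: float = 3.0
) -> pd.DataFrame:
    """Aggregate labels to local calendar days.

    Columns: date, tp_halfhours, hours (= tp_halfhours / 2), is_sva_day
    (hours >= ``day_threshold_h``).  Every day with at least one valid record
    appears, so zero-adsorption days are represented explicitly.
    """
    df = series.records
    day = df["timestamp"].dt.normalize()
    present = day[df["valid"]].unique()
    tp = labels.groupby(day).sum().reindex(present, fill_value=0)
    out = pd.DataFrame(
        {"date": tp.index, "tp_halfhours": tp.to_numpy(int)}
    ).sort_values("date", ignore_index=True)
    out["hours"] = out["tp_halfhours"] / 2.0
    out["is_sva_day"] = out["hours"] >= day_threshold_h
    return out


def summarize_years(dailies: pd.DataFrame) -> pd.DataFrame:
    """Per calendar year: SVA-day count, raw adsorption-day count, durations.

    ``sva_days`` applies the >= 3 h floor (via ``is_sva_day``); ``raw_days``
    counts any day with at least one labeled half hour.  The median duration
    is over SVA days only.
    """
    cols = [
        "year",
        "sva_days",
        "raw_days",
        "median_hours_per_sva_day",
        "days_observed",
        "partial",
    ]
    if dailies.empty:
        return pd.DataFrame(columns=cols)
    year = dailies["date"].dt.year
    rows = []
    for y, g in dailies.groupby(year):
        sva = g[g["is_sva_day"]]
        rows.append(
            {
                "year": int(y),
                "sva_days": int(sva.shape[0]),
                "raw_days": int((g["tp_halfhours"] > 0).sum()),
                "median_hours_per_sva_day": float(sva["hours"].median())
                if len(sva)
                else 0.0,
                "days_observed": int(g.shape[0]),
                "partial": bool(g.shape[0] < PARTIAL_YEAR_DAYS),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SiteEventReport:
    """Site-level SVA occurrence summary."""

    site_id: str
    included: bool
    median_days_per_year: float
    median_hours_per_day: float
    pct_years_with_sva: float
    annual: pd.DataFrame

    def to_row(self) -> dict:
        return {
            "site": self.site_id,
            "included": self.included,
            "median_days_per_year": self.median_days_per_year,
            "median_hours_per_day": self.median_hours_per_day,
            "pct_years_with_sva": self.pct_years_with_sva,
        }


def summarize_site(
    dailies: pd.DataFrame, min_days: int = 10, site_id: str = ""
) -> SiteEventReport:
    """Site report with the >= ``min_days``-days-in-some-year inclusion rule.

    Medians are taken over observed years (days per year) and over SVA days
    (hours per day); the percentage of years counts years with at least one
    SVA day.
    """
    if dailies.empty:
        return SiteEventReport(site_id, False, 0.0, 0.0, 0.0, summarize_years(dailies))
    annual = summarize_years(dailies)
    annual["qualifies"] = annual["sva_days"] >= min_days
    included = bool(annual["qualifies"].any())
    sva_days_med = float(annual["sva_days"].median())
    sva_day_hours = dailies.loc[dailies["is_sva_day"], "hours"]
    hours_med = float(sva_day_hours.median()) if len(sva_day_hours) else 0.0
    pct_years = float(100.0 * np.mean(annual["sva_days"] > 0))
    return SiteEventReport(site_id, included, sva_days_med, hours_med, pct_years, annual)
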