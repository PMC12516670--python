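"""Binned flux-direction classification and EVEa template scoring.

Nighttime half hours are binned in (RHa, VWC) space (5 % x 2 vol-% cells),
the relative frequency of negative latent-heat fluxes is computed per cell,
and each sufficiently populated cell is labeled by its dominant flux
direction: toward the atmosphere (fraction < 0.45), toward the soil
(fraction > 0.55), or random noise in between.  A template then predicts
"soil" wherever adsorption is physically possible (VWC below its boundary at
the cell center), yielding a per-cell confusion table, accuracy and the
true/false positive fractions.  High-humidity cells (lower RHa edge >= 75 %)
whose soil is too wet for adsorption are excluded from scoring, since
negative fluxes there are plausibly dew or fog rather than adsorption.  The
best-fitting template per site maximizes accuracy; the null template
(VWC_RH80 = 0, "flux always upward") provides the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ec_io import SiteSeries
from .eve_templates import EVEaTemplate, TemplateLibrary

__all__ = [
    "BinGrid",
    "ConfusionSummary",
    "SiteFit",
    "assign_bins",
    "classify_bins",
    "dew_exclusion",
    "score_template",
    "fit_site",
]

# direction codes
ATMOSPHERE, SOIL, NOISE, INSUFFICIENT, EMPTY = range(5)
DIRECTION_NAMES = {
    ATMOSPHERE: "atmosphere",
    SOIL: "soil",
    NOISE: "noise",
    INSUFFICIENT: "insufficient",
    EMPTY: "empty",
}


@dataclass
class BinGrid:
    """2-D histogram of flux direction over (RHa, VWC) bins.

    Cells tile [0, 100] % x [0, vwc_max] with half-open intervals [lo, hi);
    the top RHa cell additionally absorbs RHa = 100 exactly.  Arrays are
    indexed [vwc_bin, rha_bin].
    """

    rha_edges: np.ndarray
    vwc_edges: np.ndarray
    n_total: np.ndarray
    n_negative: np.ndarray
    site_id: str = ""
    n_records: int = 0
    direction: np.ndarray | None = field(default=None)

    @property
    def fraction_negative(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_total > 0, self.n_negative / self.n_total, np.nan)

    @property
    def rha_centers(self) -> np.ndarray:
        return 0.5 * (self.rha_edges[:-1] + self.rha_edges[1:])

    @property
    def vwc_centers(self) -> np.ndarray:
        return 0.5 * (self.vwc_edges[:-1] + self.vwc_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        """Matrix of fraction_negative: rows = VWC bins, columns = RHa bins."""
        return pd.DataFrame(
            self.fraction_negative,
            index=pd.Index(self.vwc_edges[:-1], name="vwc_lo"),
            columns=pd.Index(self.rha_edges[:-1], name="rha_lo"),
        )


def assign_bins(
    series: SiteSeries, rha_width: float = 5.0, vwc_width: float = 2.0
) -> BinGrid:
    """Bin valid records by (RHa, VWC) with half-open [lo, hi) intervals.

    Every record with finite rha, vwc and le lands in exactly one cell; the
    count over cells equals the number of binned records.
    """
    df = series.records
    use = df["valid"] & df[["rha", "vwc", "le"]].notna().all(axis=1)
    rha = df.loc[use, "rha"].to_numpy(float)
    vwc = df.loc[use, "vwc"].to_numpy(float)
    le = df.loc[use, "le"].to_numpy(float)

    n_rha = int(np.ceil(100.0 / rha_width))
    rha_edges = np.arange(n_rha + 1) * rha_width
    vwc_top = max(vwc.max() if len(vwc) else 0.0, vwc_width)
    n_vwc = int(np.floor(vwc_top / vwc_width)) + 1
    vwc_edges = np.arange(n_vwc + 1) * vwc_width

    i_rha = np.minimum((rha // rha_width).astype(int), n_rha - 1)  # fold rha=100
    i_vwc = (vwc // vwc_width).astype(int)

    flat = i_vwc * n_rha + i_rha
    n_total = np.bincount(flat, minlength=n_vwc * n_rha).reshape(n_vwc, n_rha)
    n_negative = np.bincount(
        flat, weights=(le < 0).astype(float), minlength=n_vwc * n_rha
    ).reshape(n_vwc, n_rha).astype(int)

    return BinGrid(
        rha_edges=rha_edges,
        vwc_edges=vwc_edges,
        n_total=n_total,
        n_negative=n_negative,
        site_id=series.site_id,
        n_records=int(len(rha)),
    )


def classify_bins(
    grid: BinGrid, min_n: int = 20, lo: float = 0.45, hi: float = 0.55
) -> BinGrid:
    """Label each cell by its dominant flux direction.

    fraction < ``lo`` -> atmosphere; fraction > ``hi`` -> soil; the closed
    band [lo, hi] -> noise; fewer than ``min_n`` observations -> insufficient.
    """
    if lo >= hi:
        raise ValueError("dominance thresholds require lo < hi")
    frac = grid.fraction_negative
    direction = np.full(grid.n_total.shape, EMPTY, dtype=int)
    occupied = grid.n_total > 0
    enough = grid.n_total >= min_n
    direction[occupied & ~enough] = INSUFFICIENT
    direction[enough & (frac < lo)] = ATMOSPHERE
    direction[enough & (frac > hi)] = SOIL
    direction[enough & (frac >= lo) & (frac <= hi)] = NOISE
    grid.direction = direction
    return grid


def dew_exclusion(
    grid: BinGrid, template: EVEaTemplate, rha_thresh: float = 75.0
) -> np.ndarray:
    """Mask of cells excluded as likely dew/fog rather than adsorption.

    A cell is excluded iff its whole RHa range lies at or above ``rha_thresh``
    (lower edge >= threshold) and the soil at its center is too wet for
    adsorption under ``template``.
    """
    rha_c, vwc_c = np.meshgrid(grid.rha_centers, grid.vwc_centers)
    high_rh = grid.rha_edges[:-1][np.newaxis, :] >= rha_thresh
    high_rh = np.broadcast_to(high_rh, rha_c.shape)
    possible = template.is_sva_possible(rha_c, vwc_c)
    return high_rh & ~possible


@dataclass
class ConfusionSummary:
    """Per-cell confusion counts and fractions for one template.

    Positive class = flux dominantly toward the soil.  Fractions are ``None``
    when their denominator is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded_dew: int
    n_noise: int
    n_insufficient: int

    @property
    def n_scorable(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def scorable(self) -> bool:
        return self.n_scorable > 0

    @property
    def acc(self) -> float | None:
        n = self.n_scorable
        return (self.tp + self.tn) / n if n else None

    @property
    def tpf(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def fpf(self) -> float | None:
        d = self.fp + self.tn
        return self.fp / d if d else None

    @property
    def tnf(self) -> float | None:
        f = self.fpf
        return None if f is None else 1.0 - f


def score_template(
    grid: BinGrid, template: EVEaTemplate, rha_thresh: float = 75.0
) -> ConfusionSummary:
    """Score one template against a classified grid.

    Only cells with a dominant direction (atmosphere or soil) that survive the
    dew exclusion enter the confusion table; noise and insufficient cells are
    counted separately.
    """
    if grid.direction is None:
        raise ValueError("grid must be classified first (classify_bins)")
    direction = grid.direction
    excluded = dew_exclusion(grid, template, rha_thresh)

    rha_c, vwc_c = np.meshgrid(grid.rha_centers, grid.vwc_centers)
    pred_pos = template.is_sva_possible(rha_c, vwc_c)

    dominant = np.isin(direction, (ATMOSPHERE, SOIL))
    scorable = dominant & ~excluded
    obs_pos = direction == SOIL

    return ConfusionSummary(
        tp=int(np.sum(scorable & pred_pos & obs_pos)),
        fp=int(np.sum(scorable & pred_pos & ~obs_pos)),
        tn=int(np.sum(scorable & ~pred_pos & ~obs_pos)),
        fn=int(np.sum(scorable & ~pred_pos & obs_pos)),
        n_excluded_dew=int(np.sum(dominant & excluded)),
        n_noise=int(np.sum(direction == NOISE)),
        n_insufficient=int(np.sum(direction == INSUFFICIENT)),
    )


@dataclass
class SiteFit:
    """Template-selection result for one site."""

    site_id: str
    per_template: list[tuple[EVEaTemplate, ConfusionSummary]]
    best_template: EVEaTemplate
    acc_baseline: float | None
    acc_best: float | None
    scorable: bool

    @property
    def improvement(self) -> float:
        if self.acc_best is None or self.acc_baseline is None:
            return 0.0
        return self.acc_best - self.acc_baseline

    @property
    def best_summary(self) -> ConfusionSummary:
        return next(s for t, s in self.per_template if t is self.best_template)

    def to_row(self) -> dict:
        """One row in the per-site fit table (ancillary-table schema)."""
        return {
            "site": self.site_id,
            "acc_at_0": self.acc_baseline,
            "max_acc": self.acc_best,
            "vwc_rh80": self.best_template.vwc_rh80,
            "tp": self.best_summary.tp,
        }


def fit_site(
    grid: BinGrid, library: TemplateLibrary, rha_thresh: float = 75.0
) -> SiteFit:
    """Score every template in the library and select the best by accuracy.

    Ties are broken toward the smaller VWC_RH80 (the more conservative
    template); an unscorable grid falls back to the null template.
    """
    scored = [(t, score_template(grid, t, rha_thresh)) for t in library]
    null_summary = next(s for t, s in scored if t.is_null)
    acc_baseline = null_summary.acc

    best_t, best_s = None, None
    for t, s in scored:  # library is sorted ascending: first max wins ties
        if s.acc is not None and (best_s is None or s.acc > best_s.acc):
            best_t, best_s = t, s

    if best_s is None:
        return SiteFit(grid.site_id, scored, library.null, None, None, False)
    return SiteFit(grid.site_id, scored, best_t, acc_baseline, best_s.acc, True)
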