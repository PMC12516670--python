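"""Apparent Ecosystem Vapor Equilibrium (EVEa) boundary templates.

An EVEa template is the zero-vapor-gradient curve in (RHa, VWC) space that
separates conditions where the latent heat flux should point toward the
atmosphere (wet soil relative to the air) from conditions where vapor
adsorption into the soil is possible (soil drier than the air).  Each template
is indexed by a single parameter, VWC_RH80: the volumetric water content in
equilibrium with air at 80 % relative humidity (a water potential of roughly
-300,000 hPa).

The parametric family is log-linear in potential (Campbell-Shiozawa form):
water content falls linearly with pF = log10(|psi| in hPa) from the 80 %-RH
anchor down to zero at an oven-dry potential (default pF 6.8).  Templates may
instead carry laboratory anchors, in which case the curve is piecewise-linear
in (ln RH, VWC) through those points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_physics import DEFAULT_CONSTANTS, PhysicalConstants, psi_from_rh

__all__ = [
    "EVEaTemplate",
    "TemplateLibrary",
    "build_template",
    "vwc_eq",
    "is_sva_possible",
    "default_library",
    "TABLE_VALUES",
    "TEXTURE_GRID",
    "T_REF",
]

#: Reference temperature (K) for converting RH to potential inside templates.
#: Temperature effects on the Kelvin relation are second order compared with
#: the effect of water potential, so a fixed 20 degC reference is used.
T_REF = 293.15

#: VWC_RH80 values (vol-%) of site-fitted templates reported for example sites,
#: including the pure-clay end member 11.03.
TABLE_VALUES = (2.31, 4.20, 8.08, 11.0, 11.03)

#: Configurable 11-point stand-in grid spanning sand-like to clay-like behavior
#: (the per-texture laboratory averages themselves are not published).
TEXTURE_GRID = tuple(np.round(np.linspace(1.0, 11.0, 11), 2))

# RH clamp for curve evaluation: keeps pF finite at saturation and bounds the
# dry end; 0.999 corresponds to about pF 3.1 where capillary water takes over.
_RH_LO, _RH_HI = 1e-6, 0.999


def _pf(rh: np.ndarray, c: PhysicalConstants) -> np.ndarray:
    """pF = log10 of suction magnitude in hPa at relative humidity ``rh``."""
    psi_hpa = np.abs(psi_from_rh(rh, T_REF, c)) / 100.0
    return np.log10(psi_hpa)


@dataclass(frozen=True)
class EVEaTemplate:
    """A zero-gradient boundary curve in (RHa, VWC) space.

    Attributes
    ----------
    vwc_rh80 : float
        Volumetric water content (vol-%) in equilibrium with 80 % RH; the
        template's name/index.  0 denotes the null template (no adsorption
        region anywhere).
    psi_dry : float
        Oven-dry anchor potential in hPa (negative); water content is zero at
        this suction.
    label : str
        Free-text label (e.g. a USDA texture name).
    anchors : tuple of (rh fraction, vwc vol-%) pairs, optional
        Laboratory retention anchors; when present the curve interpolates
        these instead of the parametric form.
    """

    vwc_rh80: float
    psi_dry: float = -(10.0 ** 6.8)
    label: str = ""
    anchors: tuple[tuple[float, float], ...] | None = None
    constants: PhysicalConstants = field(default=DEFAULT_CONSTANTS, compare=False)

    def __post_init__(self) -> None:
        if self.vwc_rh80 < 0:
            raise ValueError("vwc_rh80 must be >= 0")
        if self.psi_dry >= 0:
            raise ValueError("psi_dry must be negative (suction)")
        if self.anchors is not None:
            a = tuple(sorted((float(r), float(v)) for r, v in self.anchors))
            if any(r <= 0 or r > 1 for r, _ in a):
                raise ValueError("anchor RH values must be fractions in (0, 1]")
            object.__setattr__(self, "anchors", a)

    @property
    def is_null(self) -> bool:
        return self.vwc_rh80 == 0 and self.anchors is None

    # -- boundary curve ----------------------------------------------------

    def vwc_eq(self, rha):
        """Equilibrium water content (vol-%) at atmospheric humidity ``rha`` (%)."""
        rha = np.asarray(rha, dtype=float)
        scalar = rha.ndim == 0
        if np.any((rha < 0) | (rha > 100)):
            raise ValueError("rha must lie in [0, 100] %")
        rh = np.clip(rha / 100.0, _RH_LO, _RH_HI)
        if self.anchors is not None:
            xs = np.log([r for r, _ in self.anchors])
            ys = np.array([v for _, v in self.anchors])
            out = np.interp(np.log(rh), xs, ys)
        elif self.vwc_rh80 == 0:
            out = np.zeros_like(rh)
        else:
            c = self.constants
            pf_dry = np.log10(abs(self.psi_dry))
            pf80 = _pf(np.asarray(0.80), c)
            out = self.vwc_rh80 * (pf_dry - _pf(rh, c)) / (pf_dry - pf80)
            out = np.maximum(out, 0.0)
        return float(out) if scalar else out

    def rhs_at_vwc(self, vwc):
        """Invert the boundary: pore-air humidity (%) of soil at water content ``vwc``.

        Values above the curve's saturated end return 100 %; only meaningful
        for the parametric (anchor-free) form.
        """
        vwc = np.asarray(vwc, dtype=float)
        scalar = vwc.ndim == 0
        if self.vwc_rh80 == 0:
            out = np.full_like(vwc, 100.0)
        else:
            c = self.constants
            pf_dry = np.log10(abs(self.psi_dry))
            pf80 = _pf(np.asarray(0.80), c)
            pf = pf_dry - (vwc / self.vwc_rh80) * (pf_dry - pf80)
            pf = np.minimum(pf, pf_dry)
            psi_pa = -(10.0 ** pf) * 100.0
            rhs = np.exp(c.mw * psi_pa / (c.rho_w * c.r * T_REF)) * 100.0
            # wetter than the clamped saturated end of the curve -> pore air saturated
            out = np.where(vwc >= self.vwc_eq(100.0), 100.0, rhs)
        return float(out) if scalar else out

    def is_sva_possible(self, rha, vwc):
        """True where adsorption is physically possible: VWC strictly below the curve.

        Points exactly on the boundary count as not SVA-possible (conservative
        tie rule); the null template returns False everywhere.
        """
        vwc = np.asarray(vwc, dtype=float)
        if np.any(vwc < 0):
            raise ValueError("vwc must be >= 0")
        out = vwc < self.vwc_eq(rha)
        return bool(out) if out.ndim == 0 else out


def build_template(
    vwc_rh80: float,
    psi_dry: float = -(10.0 ** 6.8),
    label: str = "",
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> EVEaTemplate:
    """Construct a parametric EVEa template anchored at (80 % RH, ``vwc_rh80``)."""
    t = EVEaTemplate(vwc_rh80=vwc_rh80, psi_dry=psi_dry, label=label, constants=constants)
    if abs(t.psi_dry) * 100.0 <= abs(psi_from_rh(0.80, T_REF, constants)):
        raise ValueError("psi_dry must be drier than the potential at 80 % RH")
    return t


def template_from_anchors(
    anchors: Sequence[tuple[float, float]], label: str = ""
) -> EVEaTemplate:
    """Build a data-driven template from laboratory (RH fraction, VWC) anchors.

    vwc_rh80 is read off the interpolated curve at 80 % RH so that
    anchor-based templates sort consistently with parametric ones.
    """
    t = EVEaTemplate(vwc_rh80=0.0, label=label, anchors=tuple(anchors))
    v80 = t.vwc_eq(80.0)
    return EVEaTemplate(vwc_rh80=float(v80), label=label, anchors=t.anchors)


# module-level functional aliases mirroring the operation names
def vwc_eq(template: EVEaTemplate, rha):
    return template.vwc_eq(rha)


def is_sva_possible(template: EVEaTemplate, rha, vwc):
    return template.is_sva_possible(rha, vwc)


@dataclass(frozen=True)
class TemplateLibrary:
    """Ordered collection of templates containing exactly one null template."""

    templates: tuple[EVEaTemplate, ...]

    def __post_init__(self) -> None:
        values = [t.vwc_rh80 for t in self.templates]
        if len(set(values)) != len(values):
            raise ValueError("vwc_rh80 values must be unique")
        if sorted(values) != values:
            raise ValueError("templates must be sorted ascending by vwc_rh80")
        if sum(t.is_null for t in self.templates) != 1:
            raise ValueError("library must contain exactly one null template")

    def __iter__(self):
        return iter(self.templates)

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def null(self) -> EVEaTemplate:
        return next(t for t in self.templates if t.is_null)

    def values(self) -> list[float]:
        return [t.vwc_rh80 for t in self.templates]

    def step_distance(self, a: float, b: float) -> int:
        """Number of library steps between two member vwc_rh80 values."""
        vals = self.values()
        return abs(vals.index(a) - vals.index(b))


def default_library(values: Sequence[float] | None = None) -> TemplateLibrary:
    """Library of the null template plus one parametric template per value.

    With no argument, uses the published site-fit values united with the
    11-point texture grid.  Duplicates are dropped with a warning.
    """
    if values is None:
        values = sorted(set(TABLE_VALUES) | set(TEXTURE_GRID))
    values = [float(v) for v in values]
    if any(v < 0 for v in values):
        raise ValueError("vwc_rh80 values must be non-negative")
    uniq = sorted(set(values) - {0.0})
    if len(uniq) != len([v for v in values if v != 0.0]):
        warnings.warn("duplicate vwc_rh80 values deduplicated", stacklevel=2)
    templates = [EVEaTemplate(0.0, label="null")]
    templates += [build_template(v) for v in uniq]
    return TemplateLibrary(tuple(templates))
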