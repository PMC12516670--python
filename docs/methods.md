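# Methods

## The physical picture

Vapor exchange across the soil–atmosphere interface follows the water
potential gradient: F ∝ −(Ψa − Ψs). Only the *sign* of this gradient is used
here; the effective transport coefficient cancels and is never parameterized.
Potentials are mapped to relative humidities through the Kelvin equation
RH = exp(Mw·Ψ/(ρw·R·T)) with Mw = 0.018 kg mol⁻¹, R = 8.31 J K⁻¹ mol⁻¹,
ρw = 1000 kg m⁻³. Potentials are stored as Pa ≤ 0 (suction negative);
pF-style magnitudes are derived views. Atmospheric humidity comes from VPD
via a Magnus saturation curve with Sonntag water-surface coefficients
(a = 6.112 hPa, b = 17.62, c = 243.12 °C), clipped to [0, 100] % to absorb
sensor-level VPD slightly above saturation. The temperature dependence of the
Kelvin relation is second order next to the potential dependence (< 0.03 RH
across 278–308 K down to −30 MPa), so template curves use a fixed 293.15 K
reference.

Note on printed round numbers: 95 % RH evaluates to −6.94 MPa at 20 °C under
these constants; the commonly quoted −6.8 MPa is a rounding, and agreement is
only asserted to 3 %.

## EVEa templates

The boundary separating "flux toward atmosphere" from "adsorption possible"
conditions is indexed by a single number, VWC_RH80 — the volumetric water
content in equilibrium with 80 % RH (≈ −300,000 hPa). The curve family is
log-linear in pF (Campbell–Shiozawa): water content falls linearly from the
80 %-RH anchor to zero at an oven-dry potential, default pF 6.8, and is
truncated at zero. This preserves the one property the classifier consumes —
a monotone boundary, totally ordered in VWC_RH80 (larger values ⇒ strictly
larger adsorption-possible regions) — without fitting a multi-branch
retention model. Users with laboratory retention measurements can instead
supply (RH, VWC) anchors per template; the curve is then piecewise-linear in
(ln RH, VWC). For numerical sanity the RH argument is clamped to
[10⁻⁶, 0.999] inside curve evaluation: at the 0.999 end (≈ pF 3.1) capillary
water dominates and the adsorptive branch is no longer meaningful, so the
boundary stays finite at saturation. Points exactly on the curve count as
*not* SVA-possible (conservative tie rule).

## Filters and classification

Filters (defaults, in first-failing-rule order): QC ≠ 0 (only measured flux
is used), any record on a local calendar day with summed precipitation
> 0 mm, air temperature < 5 °C, VWC ≤ 0 or > 100 vol-%, and missing required
fields. Filtering flags records rather than dropping them, so counts are
conserved and the per-rule report sums to the number of invalidated records.
The dataset's own nighttime flag is used as provided. Soil moisture is
handled in vol-% throughout; fractional (m³ m⁻³) inputs are detected by scale
(max ≤ 1) and converted.

Nighttime observations are binned into half-open 5 % RHa × 2 vol-% VWC cells
(RHa = 100 folds into the top cell). Cells with ≥ 20 observations are
labeled by the fraction of negative λE: atmosphere (< 0.45), soil (> 0.55),
or noise (the closed band between, consistent with symmetric random flux
error). Confusion metrics are computed **per cell**, not per observation;
noise and under-populated cells are excluded from the table but counted.
Templates are evaluated at cell centers — an unambiguous, resolution-
consistent choice. Consequence worth knowing: when the ambient soil rests
within one bin of a template boundary, neighbouring templates can become
indistinguishable at the cell-center resolution; the tie rule (smallest
VWC_RH80 wins) then picks the more conservative one.

Dew exclusion: cells whose whole RHa range is at or above 75 % *and* whose
center is too wet for adsorption under the evaluated template are dropped
from that template's score, because negative λE there plausibly reflects
condensation. The mask is recomputed per template (for the null template
this removes every high-RH cell, consistent with its "no adsorption
anywhere" hypothesis). Best-template selection maximizes accuracy over the
library including the null template, so the reported improvement over the
null baseline is never negative.

Event statistics use the full 24 h of quality-filtered records (a
night-only switch exists): a TP half hour has λE < 0 strictly (λE = 0 counts
as upward) with VWC below the boundary. Days with ≥ 3 h of TP are SVA days;
annual counts apply this 3 h floor (raw day counts are also exported); a
site's report is flagged `included` when some calendar year reaches ≥ 10 SVA
days. Median duration is computed over SVA days only; years with fewer than
300 observed days are flagged partial but still summarized.

## Synthetic data: what it emulates, and what it does not

The generator produces half-hourly series with the statistical structure the
detector assumes: a diel air-temperature sinusoid; an air vapor-pressure
cycle lagged so RHa peaks pre-dawn; rain pulses (recorded, so the rain-day
filter removes them) followed by exponential drydown to a dry residual;
nocturnal λE whose sign follows sign(RHs − RHa) under a known template, with
symmetric zero-mean noise (Gaussian by default, Laplace optional); dew
forcing λE negative above 95 % RHa on rare humid nights; and a solar-shaped
positive daytime flux. The ground-truth sidecar flags adsorption half hours
(night, RHa above the soil's pore-air humidity, VWC below the boundary) and
dew records. A "null" variant replaces the nocturnal flux by pure noise
(including no dew forcing), and a twin-tower variant attenuates the
nocturnal gradient signal by a decoupling factor.

**Calibration.** The defaults are the package's documented study conditions
for its synthetic experiments, and they are a *calibration of the
simulator*, not field climatology. A 180-day record yields ≈ 3,500 night
observations; with a 20-observation bin floor and a ±0.05 dominance band,
any bin holding 20–500 pure-noise observations is likely to be classified as
spuriously "dominant" (binomial sd at n = 100 is 0.05), and maximizing
accuracy over a template library then manufactures improvement where none
exists. The defaults therefore concentrate occupancy into a few large
cells: a tight, repeatable nocturnal RHa trajectory (≈ 56 → 67 → 61 %, diel
amplitude 2.5 °C, small synoptic variability) whose turning points sit at
bin centers; rare morning rain (p = 0.008 d⁻¹, 5 mm) with a fast drydown
(e-folding 0.25 d) so transitional moisture states pass in excluded or
daytime hours; residual moisture 2 vol-% against wet 25 vol-%; night signal
8 W m⁻² inside noise of sd 10 W m⁻² (signal below noise, as for real
nocturnal EC records); humid dew nights at p = 0.001 per night. Under these
conditions the full pipeline recovers the generating template (within one
library step) in 20/20 seeded runs with mean accuracy improvement ≈ 1.0,
while 20/20 null sites select the null template with mean improvement below
0.01.

What the generator does **not** emulate — and hence what passing tests do
not show about field data: synoptic weather variability and seasonality
(real sites spread observations over many more bins, with proportionally
longer records), vertical soil-moisture structure and sensor-depth mismatch,
heteroscedastic and gap-ridden flux records, advection, fog, storage terms
and energy-balance non-closure. Results on synthetic data demonstrate the
*correctness of the machinery*, not the field detectability of adsorption at
any particular site.

## Numerical and design choices

- Bin assignment uses flat `bincount` indexing; conservation (records in =
  counts out) is asserted in tests against a brute-force recount.
- Undefined metric denominators (e.g. TPF with no observed-soil cells) are
  reported as missing, never as 0 or NaN arithmetic.
- Accuracy ties break toward the smaller VWC_RH80; an unscorable grid (no
  dominant cells) falls back to the null template and is flagged.
- The pipeline's run log records the full configuration, a config hash and
  the seed, sufficient to reproduce a run byte-for-byte.
- Laboratory-anchor templates are named by their interpolated water content
  at 80 % RH so parametric and data-driven templates sort consistently.

## Known limitations

- The 11-point default texture grid is a stand-in spanning sand-like to
  clay-like behavior; per-texture laboratory averages are not reproduced.
- Only the shallowest soil-moisture sensor is used; no multi-depth logic.
- Flux magnitudes (mm of adsorbed water) are out of scope by design; only
  directions are interpreted.
- Multivariate soil-moisture consistency checks beyond the plausibility
  bounds are a hook, not implemented.
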