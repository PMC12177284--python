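# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `rhizoflux`. It is written for someone who wants to
judge what the package computes and what its validation does and does not
demonstrate.

## The inference chain

The package turns multi-depth soil-moisture logger series into layer-wise
root water uptake and, from there, into effective root hydraulic
parameters:

1. **Diel mass balance.** The 1-D soil-water balance at a sensor depth is
   ∂Θ/∂t = −∂q/∂z − s, with Θ volumetric water content, q vertical flux
   (cm d⁻¹) and s the root sink (d⁻¹). Integrating separately over the
   preceding night (t₀→t₁), the daytime (t₁→t₂) and the following night
   (t₂→t₃), and assuming roots are quiescent at night, the mean daytime
   uptake rate is

       s′ = (Θ₁−Θ₂)/(t₂−t₁) + ½[(Θ₁−Θ₀)/(t₁−t₀) + (Θ₃−Θ₂)/(t₃−t₂)]

   The second term is the night-flux correction: the average nocturnal
   storage-change rate stands in for the daytime flow across soil
   sections. The finer and less conductive the soil, the smaller and the
   more accurate this correction.

2. **Transpiration and relative uptake.** s′(z) through the three sensor
   depths (15/30/45 cm) is interpolated piecewise-linearly with constant
   extension to 0 and 50 cm and integrated; each sensor's band (split at
   sensor midpoints: 0–22.5, 22.5–37.5, 37.5–50 cm) divided by the total
   gives the relative uptake fractions.

3. **Water release curve.** The van Genuchten form with m = 1−1/n maps Θ
   to matric potential ψ. Parameters are fitted to (ψ, Θ) pairs from
   tension/pressure-plate style measurements by nonlinear least squares.

4. **Permeability inversion.** The volume-averaged uptake law per soil
   volume is s = 2π k_r L (ψ−ψ₀), with L root length density (cm cm⁻³),
   k_r the effective radial root water permeability (cm² d⁻¹ MPa⁻¹,
   absorbing the per-segment ln(R/r) geometry) and ψ₀ the effective root
   water potential (MPa). After fitting s(ψ) to candidate forms (linear,
   power, exponential), a local linearization over a small step Δψ gives

       2π k_r L = [s(ψ+Δψ) − s(ψ)]/Δψ
       ψ₀       = ψ − s(ψ)·Δψ/[s(ψ+Δψ) − s(ψ)]

   exact whenever s is linear in ψ. For subsoil layers, ψ₀ is transferred
   from the topsoil ψ₀(ψ) relation under the assumption that this
   relation is independent of depth, and k_r follows from one point:
   k_r = s/(2π L (ψ−ψ₀)). The surface-area-based conductivity is
   k_R = k_r/R (R the representative root radius; 1 cm d⁻¹ =
   1.1574×10⁻⁷ m s⁻¹).

5. **Root length.** Core-break counts (three rotations, both faces
   summed) convert to root length density as N/(π(d/2)²) with N half the
   both-faces sum, assuming roots parallel to the core axis. Backward
   extrapolation L(t) = L_m(α(t_m−t)+1) brackets root growth between
   α = 0 and α = 0.002 d⁻¹; the two cases envelope intermediate growth
   rates. The printed extrapolation form makes L larger before the
   measurement date; the package also offers the opposite "growth"
   convention (L_m(1−α(t_m−t)), floored at 0.05 L_m) because the two
   readings of the extrapolation disagree in sign; the default follows
   the literal form, loudly.

## Key parameter choices

| parameter | default | why |
|---|---|---|
| day window | 06:00–20:00 local | wide fixed window for April–June mid-latitude daylight; configurable |
| boundary window | ±4 h | see "Boundary estimation" below |
| gap fill | ≤ 2 missing 15-min steps | longer gaps invalidate the day rather than guess |
| rain threshold | ΔΘ ≥ 0.01 within 6 h at the shallowest sensor | merges consecutive detections; series smoothed over 5 samples first |
| rain policy | flag the day and both neighbours; exclude from inversion fits, keep in tables | infiltration violates the quiescent-night assumption |
| Δψ | 5% of local \|ψ\| | small enough for local linearity, large enough to be robust to curve noise |
| growth cases | α ∈ {0, 0.002} d⁻¹ | bracketing envelope |
| form selection | highest R² among forms whose shape coefficient has p < 0.05 | R² on the original y scale so forms are comparable |

## Boundary estimation

Θ at each diel boundary is estimated from the samples within ±4 h by
fitting a straight line to each side separately, evaluating both at the
boundary, and averaging (clamped to the window's observed range). A
symmetric window *mean* was rejected: θ(t) has a kink at dawn and dusk,
and averaging across the kink biases the daytime and night storage rates
by roughly −10% for a ±60-min window under 15-min logging. The two-sided
edge fit is unbiased for piecewise-linear θ(t) and, at ±4 h, has the same
noise (s′ standard deviation ≈ 0.0028 d⁻¹ at sensor noise σ = 0.002) as
the biased mean. A zero window gives exact point reads (used when
comparing against simulator truth).

Daily matric potential is computed by converting each 15-min Θ sample
through the retention curve and then averaging over the diurnal window.
Converting the daily-mean Θ instead adds the retention curve's Jensen gap
— a spurious convexity at the dry end of the s(ψ) relation that can flip
the selected candidate form.

## The synthetic soil-water simulator

The ground-truth generator solves the 1-D vertical Richards equation on a
60 cm, 1 cm finite-volume grid (cell-centred, z positive downward, matric
head in cm internally) with van Genuchten–Mualem hydraulics (tortuosity
0.5), a rainfall-flux top boundary with a ponded-infiltration limiter
(excess is runoff), free drainage (unit gradient) or no-flux at the
bottom, and the radial uptake law as sink, active in the diurnal window
and scaled by a daily multiplier λ_d that tracks a transpiration demand,
capped at λ_max. A capped multiplier makes the plant supply-limited:
uptake then follows the hydraulic law exactly, which is what the
parameter-recovery scenarios need (and is also the premise of inverting
k_r from uptake data); demand-tracking with jitter is exercised in the
rainfall scenario.

Time stepping is backward Euler with modified-Picard iteration
(tolerance 10⁻⁹ on the θ increment), adaptive step halving, upstream
interface conductivities (arithmetic means chatter at sharp wetting
fronts), adaptive under-relaxation, and positive pore pressure allowed in
saturated blocks (the block then solves a Laplace problem for pressure so
infiltration can route through it). After each converged step the water
contents are updated from the converged interface fluxes and sink, so the
discrete water budget closes to machine precision by construction; the
per-interval residual series is recorded and asserted (≤10⁻⁶ of storage,
observed ~10⁻¹⁴). Tiny saturation overshoots at wetting fronts are pushed
conservatively to the next cell down (the front advancing); a Picard
iterate that stalls in a sub-10⁻⁵ limit cycle at a saturation front is
accepted at its best iterate — the budget stays exact either way.

### Reference scenarios

Soil: Carsel & Parrish silty clay loam (θr 0.089, θs 0.43, α 0.01 cm⁻¹,
n 1.23, K_s 1.68 cm d⁻¹) — the soil class of the field system this
package models; roots L(z) = 6·exp(−z/25) cm cm⁻³ (≈2.9 at 15 cm, 0.99 at
45 cm, typical winter wheat); sensors at 15/30/45 cm, 15-min logging,
i.i.d. Gaussian noise σ = 0.002.

* `no-flow` — K_s = 0; the diel estimator is exact (machine precision).
* `baseline-drying` — 30-day rain-free dry-down; k_r = 0.0015
  cm² d⁻¹ MPa⁻¹, ψ₀ = −0.8 MPa, constant potential demand 0.65 cm d⁻¹ so
  uptake is supply-limited from day one (λ = 1 throughout). Topsoil dries
  from −8 to ≈ −800 kPa; realized transpiration falls from ≈5.9 to
  ≈1 mm d⁻¹.
* `two-rains` — 90 days, demand-tracking uptake with 15% daily jitter,
  2 cm rain pulses on days 5 and 65; used for rain detection,
  before/after grouping and conservation under infiltration.
* `depth-invariant-psi0` — ψ₀ = −0.5 + 0.1·ψ (MPa) prescribed as the same
  function of local ψ at every depth, for validating the subsoil
  transfer.

## What the validation shows — and what it does not

The recovery harness (`rhizoflux.validation`) runs the full chain —
noisy virtual sensors → segmentation → diel estimator → retention →
candidate fit → inversion — against prescribed truth. On the baseline
dry-down at the default seed it recovers k_r within ≈7% (topsoil, both
growth cases) and ψ₀ within ≈0.05 MPa; subsoil k_r via the ψ₀ transfer
lands within ≈15%. Across other noise realizations roughly one in eight
produces a case where the exponential candidate narrowly beats the linear
one on R² for data whose noiseless relation is linear to R² = 0.99999;
the local-linearization inversion then misreports k_r at the edges of the
ψ range. This is selection noise inherent in the best-R² rule at n ≈ 28
days, not an implementation defect; longer records (the field design uses
~90 days) suppress it.

The generator emulates the structure of real logger data (diel cycles,
drying punctuated by rain, sensor noise) but not: sensor calibration
drift, soil heterogeneity and hysteresis, root growth feedback on the
flow field, soil temperature effects, macropore flow, or nighttime
transpiration. Passing recovery here therefore demonstrates the
*estimator chain* is correct and well-conditioned under the stated noise,
not that field estimates carry these error bars.

## Numerical details and degenerate inputs

* Retention fits require ≥5 pairs spanning a decade of |ψ|; constant Θ is
  rejected as degenerate. θ above saturation clamps to ψ = 0 with a
  warning path; θ ≤ θr is an error (ψ unbounded).
* With an 8-potential lab design and Θ noise σ = 0.005, θs and n recover
  to <1–4% (median), while θr and a_vg individually carry 6–10% — the
  usual van Genuchten identifiability limits; the pooled median parameter
  error is ≈2.7%.
* Zero-length diel segments raise; invalid windows propagate as invalid
  rows rather than silently dropping days; negative s′ is retained and
  flagged (clipping would bias the inversion).
* A locally constant s(ψ) makes the inversion singular (raised, not
  NaN); a negative-slope k_r is floored at 0 and flagged.
* The ANCOVA equal-slopes test calibrates to a 4–5% type-I rate at
  α = 0.05 over 200 null replicates and has power ≈1.0 for a slope ratio
  of 2 at n = 20 per group with small noise.

## Unit conventions

θ: fraction; ψ: kPa ≤ 0 everywhere inside the package, MPa only at the
hydraulics boundary (1 MPa = 1000 kPa); depths cm positive downward;
rates d⁻¹; fluxes cm d⁻¹; k_r cm² d⁻¹ MPa⁻¹; k_R cm d⁻¹ MPa⁻¹ and
m s⁻¹ MPa⁻¹. The printed conversion of the wheat topsoil permeability
range (0.001 and 0.007 cm² MPa⁻¹ d⁻¹ to 7.7×10⁻⁹ and 5.4×10⁻⁸
m s⁻¹ MPa⁻¹) corresponds to an effective radius R = 0.015 cm; the
commonly cited mean root diameter of 0.6 mm gives R = 0.03 cm and
values a factor 2 lower. The package reproduces the printed numbers with
R = 0.015 cm and documents the inconsistency rather than resolving it.
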