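# Methods

## Model

`somic` simulates soil organic carbon (SOC) as five interacting pools, all in
t C ha⁻¹ over a fixed topsoil horizon: readily soluble plant matter (SPM, C₁),
insoluble plant matter (IPM, C₂), dissolved organic carbon (DOC, C₃),
mineral-associated carbon (MAC, C₄) and living microbial biomass (MB, C₅).
Litter input L splits between SPM and IPM by the soluble fraction f_s.  Every
pool's decomposition products pass through DOC — the only substrate microbes
can take up, because substrates must be in solution to cross a cell membrane.
DOC removal is partitioned between mineral sorption (fraction f_sorb, linear
in clay content) and microbial uptake; uptake splits into growth and respired
CO₂ by the carbon-use efficiency CUE(T):

    dC1/dt = f_s dL/dt            − k′₁C₁
    dC2/dt = (1−f_s) dL/dt        − k′₂C₂
    dC3/dt = k′₁C₁ + k′₂C₂ + k′₄C₄ + k′₅C₅ − k′₃C₃
    dC4/dt = f_sorb k′₃C₃          − k′₄C₄
    dC5/dt = CUE (1−f_sorb) k′₃C₃  − k′₅C₅
    dCO₂/dt = (1−CUE)(1−f_sorb) k′₃C₃

Effective rates are k′ᵢ = kᵢ·f_T(T)·f_w(w)·f_mb(MB) for i = 1…4, with the
reverse Michaelis–Menten factor f_mb = MB/(K_m+MB); microbial turnover
(k′₅ = k₅·f_T·f_w) is first-order and carries no f_mb.  The system is therefore
not first-order: scarce substrate shrinks the microbial pool, which slows all
decomposition (persistence without an intrinsically stable pool), and a fresh
litter pulse grows it, which accelerates decomposition of pre-existing SOC
(positive priming).  No pool here has a base mean residence time (MRT) beyond
decades; long apparent ages emerge from the microbial feedback and, at depth,
from slow DOC advection.

### Assumptions

- Microbes take up DOC only; sorption competes with uptake for the same
  removal flux, with a clay-only partition f_sorb = clamp(s₀+s₁·clay, 0, 1).
- CUE is linear in temperature, clamped to [0, 1] (clamps are logged).
- Drivers supply a ready-made moisture scalar w ∈ [0, 1]; the model does not
  compute a water balance.
- No nutrient stoichiometry, dormancy, density-dependent mortality, pH or
  mineralogy effects.

## Parameters

Rates are month⁻¹; stocks and K_m are t C ha⁻¹.  The temperature modifier is
a pluggable strategy: a Q10 exponential normalized to 1 at 15 °C (default)
and a RothC-style sigmoid (also normalized at 15 °C) are shipped.

The released set pins everything the calibration constrains publicly:

| symbol | value | why |
|---|---|---|
| q10 | 17/5.5 ≈ 3.09 | ratio of the MAC base MRTs at 10 vs 20 °C (17 y / 5.5 y) |
| k4 | 1/(66·√q10) ≈ 0.00862 | makes base MRT(20 °C) exactly 5.5 y, MRT(10 °C) 17 y |
| cue_ref, cue_slope | 0.28, −0.0081 °C⁻¹ | reported calibrated CUE at 15 °C and its slope |
| K_m | 0.45 | places the microbial MRT multiplier 1/f_mb near 1.4 at nominal temperate-cropland equilibrium, the reported mean |
| k1, k2 | 0.83, 0.025 | litter-pool MRTs of ~1 month (soluble) and ~3 y (structural), the classic decomposable/resistant plant-matter split |
| k3 | 2.0 | DOC residence of days–weeks |
| k5 | 0.2 | microbial biomass turnover of months |
| f_s | 0.5 | even litter solubility split for mixed residues |
| s0, s1 | 0.05, 1.5 | f_sorb ≈ 0.4–0.5 on loamy soils; weak sorption in sand |
| w_min | 0.2 | dry-soil floor of the moisture modifier (RothC convention) |

The RothC sigmoid cannot reproduce the printed MRT pair (its 10→20 °C ratio
is ≈2.57, not 3.09), which is why the released set uses the Q10 form.

## Numerics

Explicit Euler on the monthly driver cadence with automatic sub-stepping so
no k′ᵢ·dt exceeds 0.5 (the f_mb ≤ 1 bound makes the sub-step count
forcing-only).  The discrete update conserves mass identically: per step,
Δ(ΣCᵢ) = inputs − CO₂ to float rounding (≤10⁻¹⁰ relative is asserted over
10⁴ randomized steps).  Pools are clipped at zero with the deficit logged;
with the released parameters and the default threshold no clipping occurs.
Spin-up (`equilibrate`) iterates an annual forcing cycle until the per-cycle
change is below tolerance, warm-started from an analytic mean-forcing fixed
point (closed form given f_mb, iterated with damping against the reverse-MM
feedback).  Degenerate inputs: f_sorb = 1 short-circuits uptake and
respiration; CUE = 1 produces zero CO₂; MB = 0 freezes all fluxes except
microbial decay, so a zero-input system converges to a frozen, not empty,
state.

## Site initialization and calibration

Field sites: spin-up under the first year of drivers scaled by the site's
pre-experiment input regime, then all pools rescaled proportionally so the
modeled stock at the first observation time matches that observation (initial
pool fractionation is unobservable).  Synthetic sites generated by this
package carry a fully known initial state, so they skip the rescale —
rescaling divides out the absolute stock level, which is the main signal
separating cue_ref from K_m; keeping it makes the recovery experiment
well-posed.

The loss is unweighted SSE on total SOC pooled over sites (per-site weights
optional).  The optimizer is `scipy.optimize.differential_evolution` (Sobol
init, seeded, bounded) with an L-BFGS-B polish; model failures inside the
search return a large finite penalty.  The calibration/validation split is a
seeded uniform half/half permutation, and validation statistics are always
computed from parameters fitted on calibration sites only.

Goodness of fit is the squared Pearson correlation and RMSE; the RMSE
uncertainty is a Monte-Carlo bootstrap (10⁴ iterations, 50 pairs resampled
with replacement, seeded).

## Radiocarbon and tracers

Each pool carries a fraction modern F; Δ¹⁴C = (F−1)·1000 ‰.  Isotope
bookkeeping mirrors the carbon fluxes of each Euler sub-step exactly:
outflows carry the source pool's F, litter carries the atmospheric signature,
then all ¹⁴C decays with the true mean life 8267 y.  The Libby mean life
8033 y appears only in the conventional-age formula −8033·ln F.  Setting the
decay rate to zero turns the machinery into a conserved two-source tracer;
the priming experiment tags all pre-existing C with F = 1, feeds litter with
F = 0, and reads cumulative ¹⁴CO₂ as mineralized old carbon.

The layered profile moves DOC (and its ¹⁴C) downward by first-order upwind
advection with per-interface velocities (m month⁻¹), internal CFL
sub-stepping, and a free-outflow bottom boundary; particulate pools do not
move.  `make_profile` initializes each layer at the analytic steady state
implied by the DOC flux advected from the layer above, so profile runs start
near the column attractor; ~1500 simulated years are still needed for deep
ages to converge, because deep-layer effective MRTs are multi-century (small
MB → small f_mb — the persistence mechanism itself).

## Synthetic data

`ClimateSpec` emulates a cool temperate cropland record: sinusoidal soil
temperature (9 ± 7 °C, warmest in July, 1 °C monthly noise), moist winters
(w = 0.75 ∓ 0.15), 3 t C ha⁻¹ y⁻¹ litter concentrated in autumn with 10%
interannual CV, optional spring manure, clay 0.25, 150 years.  Records start
at a land-use change: pre-experiment inputs default to twice the experimental
rate, giving the classic multi-decadal SOC decline that long-term
agricultural experiments show — without such a transient an SOC series is
nearly flat and calibration is structurally unidentifiable.  Observations are
total SOC plus seeded Gaussian noise (default sd 2% of the mean stock), one
baseline sample at month 0 and one per year thereafter.  The synthetic
atmosphere curve is a slightly depleted pre-bomb baseline with an optional
1963-style spike (+700 ‰ peak, 16-y e-folding relaxation) — shaped like the
Northern-Hemisphere record but not a transcription of any compilation.

What passing on these fixtures does not show: skill against real weather
autocorrelation, management changes mid-record, measurement-method drift,
depth-varying clay/temperature, or the original 22-experiment data, none of
which are distributed with this package.

## Problem sizes

The test and acceptance runs use a single 150-y monthly site (1800 steps)
for recovery, five noise seeds, a 22-site ensemble for summary statistics,
and a 4-layer × 1500-y column for the age–depth property; these sizes keep
every result stable while remaining desk-scale.

## Known limitations

- Monthly Euler with sub-stepping is first-order accurate; stiff parameter
  corners are handled by stability, not error control.
- The calibration recovery of cue_ref relies on absolute stock information;
  for field sites (rescaled initialization) cue_ref and K_m are nearly
  collinear and should not be freed together without additional constraints.
- Upward (capillary) DOC transport and bioturbation are unsupported.
- The gridded runner treats cells independently; no lateral transport.
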