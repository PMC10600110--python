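# Methods

This note documents the models implemented in `n2ofix`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Dissolved-gas physics (`n2ofix.gases`)

Solubility is evaluated from the standard freshwater-limit functions,
with coefficients and provenance in `src/n2ofix/constants.yaml`:
Hamme–Emerson polynomials for N₂ and Ar (µmol kg⁻¹ at equilibrium with
water-saturated air at 1 atm), the García–Gordon (Benson–Krause) fit for
O₂, and the Weiss–Price `F` function for N₂O (mol L⁻¹ atm⁻¹, moist air).
Salinity is hard-wired to 0: the ponds are rain-fed freshwater, and
saline corrections are out of scope. µmol kg⁻¹ values are converted to
µM with the Kell density polynomial.

Every gas is reduced internally to a dimensionless Ostwald-style
coefficient `K(T)` — the aqueous/gas-phase concentration ratio at
equilibrium, computed as the published equilibrium concentration divided
by the ideal-gas concentration of the gas in water-saturated air. This
makes the headspace mole balance

    C_hs·V_hs + C_hs·K_lab·V_aq = C_field·K_field·V_aq

read directly, and the partition inverse is closed-form:
`C_hs = total/(V_hs + K_lab·V_aq)`. Mole conservation holds to 1 × 10⁻⁹
relative (property-tested over random geometries).

Equilibrium concentrations scale linearly with mole fraction and total
pressure, with the 1-atm moist-air vapour correction folded into the
published functions (the Weiss convention). This is exact at 1 atm and a
mild approximation far from it; the ponds are at sea-level pressure.

Atmospheric composition defaults: N₂ 0.7808, Ar 0.00934, O₂ 0.2095,
N₂O 332 ppb (ambient; the 359.73 ppb NOAA value used for GC calibration
is carried separately in the constants file). All are configurable on
`GasSpec`.

The air–water flux model is deliberately minimal: `F = k·(C − C_eq)`
(µmol m⁻² d⁻¹, into-water negative), with the gas transfer velocity `k`
a **required** parameter — lake-physics parameterisations of `k` are out
of scope, and `k` is the main free parameter when comparing areal
budgets against flux estimates. The simulator's pond scenario carries
`k = 0.7 m d⁻¹`, a typical value for small sheltered ponds and the value
under which the default saturation climatology yields a mean N₂O influx
of order −1 to −2 µmol m⁻² d⁻¹.

## Saturation pipeline (`n2ofix.saturation`)

**Drift correction.** Air standards interspersed through an IRMS run
(every 10 positions in the simulated runs) anchor a piecewise-linear
interpolation of each channel's standard signal over run order; every
reading is scaled by nominal/interpolated. Standards therefore map
exactly onto their nominal value, identical standards reduce to a
constant rescale, and samples outside the bracketing standards fall back
to nearest-standard scaling with a warning. The interpolation rule is a
design choice (the run protocol fixes only the standard spacing).

**GC calibration.** Default response model is linear through the origin
on the standard range, with an optional quadratic term for µECD
nonlinearity over wide ranges; the fitted curve must be strictly
increasing and its inverse is exact on the calibrated range
(round-trip-tested). Below-blank responses are clipped to zero and
flagged; out-of-range responses are flagged as extrapolation, never
dropped.

**N₂ saturation** uses the N₂:Ar double ratio: argon is biologically
inert and near-saturated, so the measured/expected N₂/Ar ratio of a
sample, normalised by the same quantity for laboratory-equilibrated
reference water, cancels detector gain exactly (property-tested under
random common gains). Expected ratios come from the per-vial two-gas
mole balance at the vial's own field/lab temperatures. Reference basis
defaults to lab-equilibrated pond water; a deionized-water reference is
the supported alternative.

**N₂O saturation** is concentration relative to atmospheric equilibrium
at field temperature. At 332 ppb the equilibrium is ≈ 9.3 nM at 20 °C —
the "atmospheric equilibration" scale of the kinetics range.

## ¹⁵N bookkeeping (`n2ofix.tracer`)

The labelling fraction of a pool after adding `A` µM of tracer at ¹⁵N
atom fraction `p` to `B` µM ambient gas is `F = p·A/(A + B)` — the
*excess* (tracer-derived) ¹⁵N fraction. The ambient pool's natural
abundance (0.00366) can be added with `include_natural_abundance=True`,
and a `table_literal` mode drops the purity factor; the default is the
excess form, which is the quantity that converts ¹⁵N-based rates to
gross rates. With the default scheme (9 µM at 0.98 into 487 µM N₂ /
0.01 µM N₂O) the fractions are 0.018 and 0.98, and the indirect scenario
(≤ 0.63 µM ¹⁵N₂ produced into 487 µM N₂) gives F′ ≤ 0.0013.

Rates are reported ¹⁵N-based (as measured), with an F-corrected gross
variant emitted alongside and clearly labelled. Negative rates are
retained and flagged, never truncated; cohort summaries include the
2.5–97.5 percentile-trimmed mean and s.e. alongside the plain mean,
matching the convention of reporting 95% of a heavily skewed dataset.

Δ¹⁵N₂ (= Δ²⁹ + 2·Δ³⁰) is censored at the 0.14 µM detection limit;
below-LOD values enter the fixation partition as 0 by default
(conservative for fixation — any undetected N₂ production would only
lower the fixation estimate), with LOD/2 and keep-as-measured options.

The fate partition enforces the two budget identities exactly and
reports, rather than absorbs, the closure residual when an independent
NOₓ measurement is present. ¹⁵NOₓ⁻ enters as a delivered concentration
(the assay chemistry is upstream of this package).

## Kinetics, budget, energetics (`n2ofix.kinetics`, `n2ofix.energetics`)

Michaelis–Menten fits use Hanes–Woolf starting values followed by
bounded nonlinear least squares, with a log-spaced Km restart grid on
non-convergence. Fits require ≥ 4 distinct concentrations spanning an
order of magnitude; noise-free self-generated data are recovered to
1 × 10⁻⁶ relative. In-situ evaluation warns below the lowest measured
concentration (the fit is used at ~10 nM, near the bottom anchor of the
9.2–20 000 nM design).

Areal upscaling multiplies the per-gram in-situ rate by benthic biomass
areal density — a required input, 340 g dw m⁻² in the simulator's
default scenario — and compares magnitudes with the air–water flux.
GPP equivalence converts an N₂ flux to carbon at Redfield 106:16 with
two N atoms per N₂ (3934 µmol N₂ m⁻² d⁻¹ ↔ 52 126 µmol C m⁻² d⁻¹).

ΔG values per mol NH₃ are computed from the bundled formation table
(CODATA water and nitrate; aqueous dissolved-gas values derived from
gas-phase values plus Henry's-law transfer energies), adjusted to
temperature by Gibbs–Helmholtz under constant reaction enthalpy, and
corrected by RT ln Q over a documented freshwater activity set: NH₃ at
the 0.2 µM analytical detection limit, O₂ at 10 °C air saturation
(353 µM), N₂ at the 487 µM ambient pool, N₂O at the 9 µM incubation
level, NO₃⁻ at 0.5 µM, pH 7, electrons at the standard hydrogen
electrode. Under these conventions N₂O fixation costs ≈ +248 and N₂
fixation ≈ +292 kJ per NH₃ at 10 °C. The NO₃⁻-assimilation half-reaction
is convention-sensitive (it consumes free electrons, and its published
cost depends on the electron donor assumed); under the SHE convention
used here it computes to ≈ +193 kJ, well below literature values near
+241 — the package documents this sensitivity rather than hiding it, and
the percentage-saving comparisons are therefore anchored on explicitly
supplied ΔG values. Savings are defined relative to the *cheaper*
pathway, `100·(ΔG_ref − ΔG_alt)/ΔG_alt` — the only convention under
which 247-vs-291 gives ~18% while 241-vs-291 gives ~21%.

## Temperature response (`n2ofix.temperature`)

Biomass-normalised rates are heavy-tailed, so central tendency uses
median (τ = 0.5) quantile regression: a linear fit (slope in
nmol g⁻¹ d⁻¹ per °C) and an exponential median fit `a·e^{bT}` by least
absolute deviations, with `Q₁₀ = e^{10b}`. Confidence intervals are
seeded nonparametric bootstrap (rank-inversion intervals are unreliable
under this heteroscedastic noise at these sizes).

Three Q₁₀ estimators are reported because they answer subtly different
questions under a measurement-noise floor:

* `q10` (default of the median fits) — exponential LAD fit retaining
  non-positive rates. A log-linear fit must discard them, which censors
  the cold cohorts hardest and flattens the response.
* `q10_log_linear` — the log-scale median regression, for comparison
  with quantile-regression analyses.
* `q10_trimmed_mean` — least squares through the log of per-temperature
  2.5–97.5%-trimmed cell means. Conditional *medians* of noisy rates are
  inflated where the symmetric noise floor is large relative to the
  rate (the cold, slow cohorts), so median-based Q₁₀ estimates are
  attenuated by a few percent even at infinite n; cell means are immune
  to symmetric noise, and the trim factor cancels in the slope because
  the rate-distribution shape is shared across temperatures. Recovery
  tests and the acceptance script use this estimator.

The N₂O share of total fixation is `r_N₂O/(r_N₂O + r_N₂)`, with relative
change between temperatures `100·(share(T₁)/share(T₂) − 1)`.

## Synthetic-data generator (`n2ofix.simulate`)

The generator is first-class, tested code that produces every input the
pipeline consumes, sharing the package's own forward physics so that
zero-noise simulations round-trip exactly (tested, not assumed). Fixed
seeds reproduce byte-identical tables.

**Truth block defaults** encode the study conditions: grand-mean N₂O
saturation 79.1% with a 15-point single-harmonic seasonal cycle
bottoming in December; N₂ at 98.5% with a 1.5-point cycle peaking in
winter; trimmed cohort-mean assimilation 11.5 (¹⁵N₂) and 5.3 (¹⁵N₂O)
nmol N g⁻¹ d⁻¹ with log-normal heterogeneity (CV 1.35, back-computed
from reported cohort s.e. at n ≈ 300); winter/summer total reduction
507/237 nmol N g⁻¹ d⁻¹ (CV 1.2); median NOₓ share 0.117; detectable
¹⁵N₂ production in 30% of benthic (0% of floating) vials at 5–30% of
reduction; Michaelis–Menten Vmax 450 nmol N g⁻¹ d⁻¹, Km 2000 nM (these
reproduce the −0.75 µmol m⁻² d⁻¹ areal scale at ~10 nM with 340 g m⁻²
biomass); Q₁₀ 1.38 for the N₂ pathway and 1.0 for N₂O, referenced to
15 °C. Because campaign months are not calendar-balanced, the harmonic
offset is solved so that the *design mean* equals the configured mean;
because cohort statistics are reported on the trimmed sample, the
log-normal scale is adjusted by the analytic trim factor
`[Φ(z₀.₉₇₅−σ) − Φ(z₀.₀₂₅−σ)]/0.95` so configured cohort means are
trimmed means.

**Noise block defaults**: GC 2% CV (the stated instrument precision) as
mean-one multiplicative log-normal; IRMS channels 0.1% with linear +
sinusoidal drift over run order (corrected by the pipeline's air
standards); isotopologue concentrations 2% CV; EA ¹⁵N atom% noise
1 × 10⁻⁴ atom% per measurement — chosen so that, at the configured rate
scales, ~87% of tracer vials show positive enrichment, the observed
detection prevalence; Δ¹⁵N₂ noise floor 0.119 µM — the value at which a
true-zero signal falls below the 0.14 µM LOD in ~76% of vials; pond
effects 8 (N₂O) and 0.5 (N₂) saturation points.

**Vial geometry**: 12 mL vials, 2 mL helium headspace (weighed, i.e.
recorded exactly, with 0.05 mL scatter), lab equilibration at 22 °C.
Incubation vials carry 2 g wet biomass (displacing 2 mL, leaving 10 mL
water) with dry weight 0.04 g — a loading chosen so that even the upper
tail of winter reduction rates consumes < 90% of the 17.6 µM-¹⁵N tracer
pool in 24 h, keeping the finite-pool truth self-consistent. PON is
1.43 × 10⁶ nmol g⁻¹ dw (≈ 2% N by mass).

**What the generator does not emulate**: real chromatogram peak shapes
(inputs are integrated responses), O₂ dynamics and diel cycles within
incubations, inter-month correlation of pond effects, nutrient feedback
on rates, or community composition. Passing recovery tests therefore
demonstrates that the *inference chain* is unbiased under realistic
noise, drift and skew — not that the field protocol itself is free of
systematic effects the simulator does not model.

**Simulation scales.** The recovery tests and acceptance script use the
full 20-pond × 11-month campaign (440 N₂O + 660 N₂ vials) and incubation
batches of 300 Tf vials per tracer treatment (≈ paper-scale cohorts),
averaging a handful of replicate campaigns for the stochastic targets;
these sizes put Monte-Carlo error well below the quantities' reported
precision while keeping a full run under two minutes.

## Numerical conventions

CSV everywhere, UTF-8, unit-suffixed column names (`conc_nM`,
`rate_nmolN_per_g_d`); simulator outputs carry `true_*` columns the
pipeline never reads. Bootstrap CIs at 95%, seeded. Temperatures in °C
(0–35 valid for solubility, 0–40 for vials), volumes mL, amounts nmol,
concentrations µM (nM for dissolved N₂O), rates nmol N g⁻¹ d⁻¹, fluxes
µmol m⁻² d⁻¹ with into-water negative.

## Known limitations

* The flux model is two-layer with user-supplied `k`; no wind/buoyancy
  parameterisation.
* The NO₃⁻-assimilation ΔG depends on the electron-donor convention
  (documented above); absolute ΔG values generally carry table- and
  activity-set sensitivity of a few kJ.
* The N₂O share's temperature contrast depends on both pathways'
  fitted intercepts; with the default truth block (flat N₂O pathway,
  N₂ Q₁₀ 1.38, cohort means 5.3/11.5) the 6-vs-25 °C share contrast is
  ≈ +50%, and the module reports whatever the data imply.
* Quantile-regression bootstrap CIs are approximate under heavy tails;
  rank-inversion is not used.
* ¹⁵NH₄⁺ is not measurable in this design (assay interference); DIN
  production is inferred by budget closure and the NOₓ⁻ assay only.
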