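# Methods

## Thermodynamic model

The package treats a cotransporter cycle as a single reversible reaction
moving `n_Na` Na⁺ ions, `n_Cl` Cl⁻ ions and one neutral substrate molecule
across the membrane, with net charge `z_T = n_Na − n_Cl`. At membrane
potential V the electrochemical driving force vanishes at

    E_T = (2.3 R T / (z_T F)) · log10( [Na]o^n_Na [Cl]o^n_Cl [S]o /
                                       ([Na]i^n_Na [Cl]i^n_Cl [S]i) )

This is purely thermodynamic: no rate constants, no alternating-access
kinetics, no voltage dependence of individual steps. Consequences used
throughout:

* E_T is affine in log10 of any single concentration with the others fixed;
  the Na⁺ slope is `2.3 R T n_Na / (z_T F)` mV per decade.
* Swapping all external and internal concentrations flips the sign of E_T.
* A measured slope, with z_T fixed independently (from the charge-to-flux
  ratio), inverts to `n_Na = slope · z_T · F / (2.3 R T)`.

An electroneutral cycle (z_T = 0) carries no current and has no reversal
potential; all slope/E_T operations raise an explicit error for it.

### Constants and units

`R = 8.314 J mol⁻¹ K⁻¹`, `F = 96485 C mol⁻¹`, and the log₁₀ conversion
prefactor `2.3` (the conventional rounded value; `ln 10 ≈ 2.3026` may be
substituted via `PhysicalConstants`). With the defaults the 18 °C slope
predictions are 86.55 mV/decade (3Na:1Cl, z_T = 2) and 115.41 mV/decade
(2Na:1Cl, z_T = 1); the exact values depend on constant rounding at the
0.05 % level, which is why the constants are configurable rather than
hard-coded. Interfaces use mM for concentrations (only ratios enter, so the
unit cancels), mV for potentials, °C for temperature (kelvin internally),
nA for currents, and coulombs for charge.

### Default conditions

Oocyte analyses default to 18 °C (the bath temperature of two-electrode
voltage-clamp recordings); cell-uptake contexts use 37 °C explicitly.
Internal concentrations in oocytes are not directly measurable, so
`IonConditions` fills them with documented assumptions — `na_i = 10 mM`,
`cl_i = 40 mM`, `gly_i = 10 mM` — flagged as such in the docstrings. The
chloride and substrate terms are retained in the model even in experiments
that hold them constant, where they contribute only to the intercept of the
E_rev–log[Na⁺]ₒ line, never to its slope.

## Slope fitting and Na⁺ counting

`fit_reversal_series` is ordinary least squares of E_rev on log10[Na⁺]ₒ
(scipy's linregress), reporting slope, intercept, slope standard error, n
and R². The pipeline fits each oocyte separately and averages the
per-oocyte slopes (SE = SD/√n across oocytes), also reporting the pooled
fit; with ≥2 distinct Na⁺ levels per oocyte the two agree in expectation.

## Charge-to-flux

Charge is the trapezoidal integral of (current − baseline) over the
application window, converted nA·s → C. The baseline is the mean current
over the 5 s preceding the application window — a choice made here, since
bath-application recordings have no canonical baseline rule — and is tied
to the application window (not the integration sub-window) so that charge
is additive over sub-windows. Moles of substrate come from scintillation
counts: net dpm over the non-injected-oocyte background, divided by
2.22 × 10¹² dpm/Ci and the tracer specific activity in Ci/mmol (0.4 Ci/mmol
by default, the standard ³H-glycine dilution for 1-min uptake at 30 µM).
The ratio (|Q|/F)/moles estimates z_T. Ratios are reported as measured,
without leak- or noise-bias correction: real measurements scatter around
(and above) the integer z_T, and the package does not attempt to attribute
the excess.

## I/V analysis

* **Reversal potential** from a discrete I/V curve: linear interpolation
  between the unique sign-change bracket. Curves that do not reverse within
  the tested range (the wild-type phenotype under physiological gradients)
  raise a distinct `NonReversingError`; multiple crossings are ambiguous
  and also raise. Interpolation is exact when the true reversal falls on a
  grid point and is otherwise biased by curve curvature; with the 20 mV
  step protocol and the generator's rectification defaults the error stays
  under ~2 mV.
* **Rectification degree**: OLS slope through the k = 3 most hyperpolarized
  points divided by the slope through the k = 3 most depolarized ones.
  Equal to 1 for any affine I/V, invariant under current scaling, `inf`
  (with the sign convention preserved) when the depolarized limb is flat.
* **Normalization** divides by the magnitude of the current at a reference
  potential (−150 mV by default), so inward currents normalize to −1 there;
  the operation is idempotent.

## Uptake kinetics

Hill fits `v = Vmax·Cⁿ/(EC50ⁿ + Cⁿ)` and Michaelis–Menten fits (n ≡ 1) use
unweighted nonlinear least squares on individual replicate rates
(scipy `curve_fit`, trust-region reflective with positivity bounds,
n ≤ 10). Initialisation is deterministic: Vmax from the maximal observed
rate, EC50/Km from the concentration nearest half-max, and a multi-start
over n ∈ {0.5, 1, 2, 3} keeping the lowest-SSE solution — no randomness
enters fitting. At least 4 distinct concentrations are required; datasets
whose maximal rate is below twice the lowest-concentration rate are fitted
but flagged (`saturation_warning`) because the plateau is unconstrained.
Mock-transfected background is subtracted per concentration (mean over mock
replicates) before fitting; rates driven negative are clipped to zero and
counted rather than dropped, keeping concentration grids intact.

Vmax/Km ("transport efficiency") is computed as the ratio of the fitted
parameters with a first-order (delta-method) SE that neglects the
Vmax–Km covariance. When efficiencies are instead averaged over per-
experiment ratios the two summaries differ; the report labels the quantity
it computes and makes no attempt to reproduce any particular averaging
convention.

## Synthetic experiments

The generator exists to give every analysis stage an input with known
ground truth, at the scales typical of oocyte recordings: currents of tens
of nA at −150 mV, external Na⁺ grids up to 150 mM, the −150…+30 mV / 20 mV
step protocol, 1 kHz sampling, 1-min tracer applications at 0.4 Ci/mmol.

* **I/V curves**: `I(V) = g·z_T·(V − E_T)·σ(V)` with
  `σ(V) = 1/(1 + exp((V − V₀)/k))` (defaults V₀ = −40 mV, k = 30 mV;
  `None` disables rectification). This is the simplest functional form with
  an exact thermodynamic reversal and tunable inward rectification — a
  phenomenological stand-in, not a kinetic model. Default conductance
  g = 0.5 nA/mV yields ≈ −70 nA at −150 mV for z_T = 2 with the default
  rectification.
* **Reversal series**: per-oocyte E_T plus i.i.d. Gaussian noise
  (SD `noise_sd_erev`, 5 mV in the standard scenario of 8 oocytes × 5 Na⁺
  levels {20, 40, 60, 80, 100} mM).
* **Charge-flux experiments**: a rectangular evoked current of amplitude
  `z_T·F·N/duration` (N = rate × duration moles) with optional Gaussian
  sample noise, plus tracer counts `N[mmol]·SA·2.22e12 + background`. The
  application window is snapped onto the sampling grid and its endpoints
  are derived from the same index arithmetic as the time axis, so the
  noiseless chain returns z_T to ~1e-12 relative error for any duration.
* **Uptake datasets**: `model(C)·(1 + ε)`, ε ~ N(0, CV), with optional
  constant-mean mock rows added to the sample and returned separately so
  background subtraction can be exercised.

Seeding is hierarchical: each experiment spawns independent child streams
per oocyte/replicate from `numpy.random.SeedSequence(seed)`, so enlarging
an experiment never changes the replicates already drawn, and identical
spec + seed give bit-identical output.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real recordings: capacitive transients and membrane
RC dynamics, series-resistance and leak currents, drifting baselines,
oocyte-to-oocyte conductance heterogeneity, correlated (non-Gaussian,
non-i.i.d.) noise, and any uncoupled/channel-mode flux. Recovery results on
synthetic data demonstrate correctness of the analysis chain, not accuracy
on arbitrary experimental traces.

## Pipeline and determinism

`run_pipeline` takes one YAML/JSON config (constants, seed, per-construct
stoichiometry, temperature, and either CSV paths or a simulation block),
runs subtraction → fits → slope/rectification/charge-flux in order, and
writes `report.json`/`report.txt` with provenance (seed, config hash,
constants). The report is byte-identical across reruns of the same config
and seed; warnings (clipped rates, non-reversing curves) are logged per
stage and recorded in the report rather than raised.

## Problem sizes

The standard test and acceptance scenarios use 8 oocytes × 5 sodium levels
for reversal assays, 8–12 concentrations × 3 replicates for saturation
fits, 60 s traces at 1 kHz for charge integration, and 50–100 Monte-Carlo
repeats for noisy-recovery checks — sizes chosen to match the scale of the
emulated experiments while keeping the full suite fast.

## Known limitations

* The thermodynamic model assumes fixed integer-like stoichiometry and
  tight coupling; partially coupled or channel-mode transport violates the
  slope and charge-flux identities it relies on.
* Hill-fit standard errors are asymptotic (from the curve_fit covariance)
  and optimistic for small, noisy datasets.
* `estimate_erev` assumes a single monotone crossing; strongly rectifying
  curves sampled coarsely can bias the interpolated reversal by a few mV.
* The CLI's `simulate` commands cover the four standard protocols only;
  bespoke protocols should use the library API directly.
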