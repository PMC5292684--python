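# Methods

This note documents the models implemented in decorakin, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## SPR kinetics (`decorakin.spr`)

### Model

The two-compartment, steady-state mass-transport-limited 1:1 model:

    dR/dt = [k_on C (R_max − R) − k_off R] / [1 + k_on (R_max − R)/k_t]

with C the bulk analyte concentration during association and C = 0
during dissociation. This is the standard form fitted by commercial
biosensor evaluation software; it reduces to ideal Langmuir kinetics as
k_t → ∞ and, at finite k_t, slows both apparent association and —
through rebinding of freshly released analyte to free sites — apparent
dissociation. Transport changes kinetics only: the equilibrium response
is R_max·C/(C + K_D) for every k_t, with K_D = k_off/k_on (an invariant
held exactly by every fit object).

### Exact solution

The ODE is separable in both phases. Integrating t(R) and inverting
gives, during association (a = k_on·C + k_off, R_eq = k_on·C·R_max/a,
κ = k_on/k_t, c₁ = 1 + κ(R_max − R_eq), β = κ/c₁, u = R_eq − R):

    βu·e^{βu} = βR_eq·e^{βR_eq}·e^{−at/c₁}   ⇒   u = W₀(·)/β

and during dissociation (c₂ = 1 + κR_max, γ = κ/c₂):

    −γR·e^{−γR} = −γR₀·e^{−γR₀}·e^{−k_off t/c₂}   ⇒   R = −W₀(·)/γ

with W₀ the principal Lambert W branch (the dissociation argument is
always in (−1/e, 0), where W₀ is the physical branch). Small-argument
(W(x) ≈ x) and large-argument (w = m − ln w fixed point) expansions
guard against under/overflow. `simulate_sensorgram(method="ode")`
integrates the same equation with LSODA at rtol 1e-8 / atol 1e-6; the
test suite verifies the two paths agree to the integrator tolerance.
The analytic path is the default because it is exact and fast enough to
make multi-start global fitting and 50-experiment recovery studies
routine on one CPU.

### Fitting

* `fit_dissociation_koff`: per-curve single-exponential fits of the
  (optionally drift-corrected) dissociation phases; the estimate is the
  mean over curves, the error the scatter across curves. Non-decaying
  phases warn and contribute the lower bound 0.
* `fit_global` / `TransportLimitedBindingModel`: one shared
  (k_on, R_max, k_t) — k_off fixed by default at 2 × 10⁻⁴ s⁻¹,
  overridable or free — minimising unweighted least squares over all
  phases of all curves. Parameters are fitted in log₁₀ space (they are
  positive scale parameters; k_t in particular spans decades). Ten
  seeded multi-starts by default (one heuristic + nine log-uniform)
  guard against local minima. Standard errors come from the
  Gauss–Newton covariance at the optimum, mapped back by the delta
  method. When the fitted transport influence k_on·R_max/k_t falls
  below 10⁻³ the data carry no transport information and k_t is
  reported as unbounded above rather than as a spurious number.
  Fewer than two distinct positive concentrations is rejected as
  unidentifiable. When k_off is fixed, K_D carries no error, the usual
  convention for forced parameters.
* `double_reference` subtracts the reference-surface and buffer-blank
  traces (interpolated onto the raw grid) and re-zeroes to the baseline
  mean; `correct_capture_drift` divides the dissociation phase by
  e^(−k_capture·t) and warns when the correction amplifies the late
  signal more than 10×.

### Study conditions emulated by the generator

k_on = 1.8 × 10⁸ M⁻¹s⁻¹, k_off = 2 × 10⁻⁴ s⁻¹, seven concentrations
0.312–20 nM, 60 s baseline / 200 s association / 600 s dissociation at
1 Hz, additive i.i.d. Gaussian noise of 0.5 RU. R_max = 100 RU: a
captured-capsid surface of ~10³ RU gains ~8% of its mass at full
decoration, so ~10² RU of ligand signal. k_t = 6.5 × 10⁸ RU M⁻¹ s⁻¹:
the value at which the closed-form dissociation relation
k_off·t = c₂·ln(R₀/R) − κ(R₀ − R) gives a ~7% signal loss over 700 s —
the experimentally observed near-irreversibility — instead of the 13.1%
(1 − e^{−0.14}) of the ideal exponential. Rebinding depends on *free*
sites, so dissociation from saturation starts at the ideal rate and
slows as sites open; matching the integrated loss therefore requires a
strongly transport-limited regime.

## Model-free relaxation (`decorakin.relax`)

### Rates

¹⁵N R1, R2 and {¹H-¹⁵N} NOE from the standard dipolar + CSA
expressions evaluated at the five canonical frequencies of J(ω), with
the Lipari–Szabo spectral density (two-timescale extension for M5) and
Rex added to R2 only. Constants: r(N–H) = 1.02 Å, Δσ(¹⁵N) = −160 ppm,
γ_H = 2.6752218744 × 10⁸, γ_N = −2.7126 × 10⁷ rad s⁻¹ T⁻¹ — the
conventional model-free defaults, configurable through `NMRConstants`.
An independent literal transcription of the same expressions lives in
the test suite and must agree to 10⁻¹⁰ relative.

### Tumbling

Tumbling is isotropic per domain: the physical picture is a two-domain
protein whose domains move semi-independently on a flexible linker, so
each domain carries its own τm; diffusion-tensor anisotropy is out of
scope. `estimate_tm_from_ratio` excludes residues with NOE < 0.6 at any
field (fast internal motion contaminates the ratio), trims the top and
bottom 10% of T1/T2 = R2/R1 (exchange and residual-flexibility
outliers), and inverts the rigid-limit R2/R1(τm) relation by Brent's
method per field, averaging τm over fields. The inversion is exact for
rigid residues; with S² = 0.85 and τe = 20 ps the residual bias is ~1%,
inside the 2% round-trip tolerance asserted in the tests.

### Per-residue fits and model selection

Models M1 (S²), M2 (S², τe), M3 (S², Rex), M4 (S², τe, Rex) and M5
(Sf², Ss², τs; S² = Sf²Ss²) are fitted by bounded least squares from
three fixed starts each; χ² uses the measured errors, falling back to
unit weights where an error is zero (noise-free round trips). Selection
is by AICc on χ²; when the sample size makes the AICc correction
undefined (n − k − 1 ≤ 0, e.g. single-field data) plain AIC is used,
and saturated models are not selectable. The AICc ladder replaces the
historical stepwise F-test protocol because it is simpler and fully
reproducible. Rex is quoted at the lowest field present and scaled by
B² across fields. Fits failing a χ² goodness-of-fit cut (0.995
quantile) are flagged "unmodelled" but still returned; a NOE error
spanning the physical range flags "uninformative".

Monte-Carlo errors resample the observables within their measured
Gaussian errors (≥ 100 draws), refit the selected model and report
percentile intervals; zero measurement errors collapse the intervals to
points with a warning. `flag_exchange` uses a closed threshold
(Rex = min_rex is included) and can additionally require the
Monte-Carlo Rex interval to exclude zero.

### Generator presets

`two_domain_calibration_protein()`: all-rigid two-domain protein whose
mean T1/T2 is calibrated (by the exact ratio inversion) to 12.0 and
17.2 at 600 MHz — the configuration used for tumbling diagnostics,
where including exchange or flexible residues would confound the
average. `pb10_like_protein()`: a 164-residue two-domain protein with
rigid cores (S² 0.85, τe 20 ps), a flexible low-NOE poly-proline linker
(residues 63–71; S² 0.4, τe 1.2 ns) and exactly 16 exchange-broadened
residues (a C-terminal NTD helix plus two CTD loops, Rex 4 s⁻¹) — the
configuration for model-selection and exchange-flagging round trips.
Which residues enter published domain averages is generally not
reported; keeping the two presets separate makes the calibration
assumption explicit instead of hiding it in a residue-exclusion rule.

Noise: `NoiseSpec.sd` acts as a fractional error on R1 and R2 and an
absolute error on the (dimensionless, O(1)) NOE; the default 0.02
matches duplicate-level experimental precision. Reported errors are
standard errors of the replicate mean, hence shrink as 1/√replicates.

## SAXS forward model (`decorakin.saxs`)

Beads are point scatterers with unit default weight — no atomic form
factors, no hydration layer. Consequently χ against a *real*
experimental curve is not comparable to full-atom forward models; the
χ machinery is exercised against synthetic curves with known noise,
where χ ≈ 1 under matched errors is the calibration check.

* `debye_curve`: vectorised Debye sum with the q → 0 limit handled
  analytically (I(0) = (Σw)²); verified against a literal O(N²) double
  loop to 10⁻¹⁰.
* `pr_from_beads`: weighted pair-distance histogram (default 1 Å bins);
  Dmax is the exact maximum pairwise distance, no smoothing or
  extrapolation. Rg uses the finite-sum identity
  Rg² = Σ_{i<j} wᵢwⱼdᵢⱼ²/(Σw)² — the continuum formula
  ∫r²P/(2∫P) with the zero-distance self-pairs kept in the
  normalisation. The continuum form is biased by O(1/N) for finite bead
  counts and gives d/√2 instead of the correct d/2 for two beads.
* `guinier_rg`: self-consistent fit range q·Rg < 1.3 by default with a
  curvature flag. For strongly elongated particles the textbook 1.3
  limit biases Rg low (~7% for the default two-lobe model); the
  cross-method agreement test therefore uses the conservative
  q·Rg < 1.0 range (~4%).
* `chi_score`: exactly χ = sqrt(1/N Σ((I_exp−I_calc)/σ)²) on the
  experimental grid; scale fitting (a single multiplicative factor on
  I_calc, closed form) defaults to on, mirroring standard practice.
  Any σ = 0 point is rejected with its q value.

### Two-lobe bead generator

A globular sphere (r = 14.5 Å) and an elongated, Ig-like prolate
ellipsoid (semi-axes 39 × 10 × 10 Å) 52 Å apart along x, 75
pseudo-residues per lobe plus 3 linker beads on the axis. The first
bead of each lobe anchors the lobe centre and the second the outer pole
(the chain termini), making the model's maximum extension
deterministic. Lobe interiors are sampled uniformly (rejection) and the
sampled cloud is standardised per axis to the exact first and second
moments of the continuous uniform ellipsoid (mean 0, E[x²] = a²/5) —
a variance-reduction step that pins the model Rg for every seed. The
geometry is calibrated once so the model sits at Rg ≈ 30.4 Å and
Dmax ≈ 106 Å, inside the 30 ± 1 / 110 ± 5 Å windows of the reference
two-lobe particle. With 150 beads the same Rg/Dmax cannot sit at the
exact centre of both windows simultaneously (a 110 Å end-to-end
two-lobe body of this mass distribution has Rg > 31 Å); the calibration
favours Rg.

## Melting analysis (`decorakin.melt`)

The synthetic curve is baseline(T)·(1 − f(T)) + amplitude·f(T) with a
linearly declining probe baseline (the dye's intrinsic temperature
dependence; default slope 0.4%/°C of the initial value, baseline 20% of
amplitude) and a logistic released fraction f whose 10–90% rise spans
`release_width` (default 6 °C); the analytic maximum of the release
derivative sits exactly at `tex_true`. Grid: 4–99 °C at 0.5 °C; noise:
additive Gaussian, default 2% of amplitude.

Extraction: Savitzky–Golay smoothing (degree 2, default window 7,
endpoint handling by polynomial extension; a window-3 quadratic filter
reproduces quadratics exactly), dF/dT by central differences, global
maximum of +dF/dT restricted to T > 30 °C (excludes low-temperature
probe-equilibration artefacts; configurable), then sub-grid refinement
by a quadratic fit over ±5 points around the discrete peak — averaging
over roughly the release-peak width, which is far more noise-robust
than a 3-point parabola. A release is reported only when the peak
derivative exceeds `min_prominence` (default 0.05) of the total signal
range per characteristic 10 °C — i.e. the release must climb at least
5% of the range over ~10 °C; otherwise "no release detected"
(amplitude-0 curves are monotonically decreasing and never trigger).
T_ex is invariant under affine transforms of the fluorescence, and a
linear baseline contributes a constant, not a peak, to the derivative.

Instrument software conventions differ on the derivative sign (some
plot the *opposite* first derivative of the globally decreasing raw
signal); both are available through `sign=±1`, and no claim is made
about which convention any particular instrument reports.

`compare_tex` averages replicates per (phage, condition), reports
standard errors of the mean, differences wild-type minus variant with
errors in quadrature, and lists unmatched conditions explicitly instead
of dropping them.

## Cooperative lattice decoration (`decorakin.lattice`)

Energy E = ΔG_bind·N_bound + ε_coop·(occupied adjacent pairs), kT
units. Metropolis exchange moves between a shared finite pool (total
ligand = ratio × 120 × n_capsids, conserved exactly — checked every
sweep inside the kernel) and individual sites; a bind is proposed only
while the pool is non-empty, which preserves detailed balance on the
constrained state space. At ε = 0 with an ample pool the stationary
occupancy is the independent-site isotherm p = 1/(1 + e^{ΔG}), checked
against the exact Binomial(120, p).

The nearest-neighbour pairwise coupling is this package's *model* of
the experimentally observed cooperativity (which experiments establish
only at the population-pattern level — a conformational-transmission
mechanism is one proposed interpretation); conclusions are drawn only
at the level of qualitative pattern reproduction. Kinetic cooperativity
(spreading in time) is not modelled; only equilibrium populations.

Lattices: a seeded random 6-regular graph (default; hexamer adjacency
on a real quasi-equivalent lattice is non-uniform near the pentamers,
so 6-regular is an explicit approximation), or the deterministic
"icosa-net" — 120 quasi-uniform Fibonacci-lattice points on a sphere
triangulated by their convex hull: connected, mean degree
6 − 12/120 = 5.9, with the 12 five-fold defects any closed triangulated
shell must carry. The seed is ignored in icosa-net mode.

Study conditions: ΔG_bind = 0, ε_coop = −2.0 kT. These make single
bound ligands marginal but clusters deeply bound (interior site:
−12 kT), so sub-stoichiometric populations condense into saturated
capsids while cluster-edge detachment (~4 kT) remains frequent enough
for the single-site dynamics to equilibrate. Defaults: 200 capsids,
10 000 sweeps (one sweep = one attempted move per site of every
capsid; the numba kernel performs ~10⁸ moves in a few seconds). Burn-in
is the first half; the reported distribution is the final-sweep state.

Equilibration is diagnosed by comparing mean occupancy between the
third and fourth quarters of the run (2% tolerance). Note its blind
spot: once the pool is exhausted, mean occupancy is conserved while the
*shape* of the population distribution may still be coarsening — the
reason the default sweep count is set an order of magnitude above where
the all-or-none pattern stops changing, rather than where the mean
flattens.

`bimodality_score` = 1 − (mass in the middle occupancy tercile) when
both outer terciles are populated, else 0 (so all-empty or all-full
alone scores 0 by convention); `gel_pattern` maps occupancy < 10% /
10–90% / > 90% to the bare / intermediate / decorated band classes.
Electrophoretic mobility physics is not modelled — band classes are
occupancy thresholds only.

## Problem sizes

The recovery studies run at: 50 seeded SPR experiments (7
concentrations × 861 points each, 6 fit starts); 40-residue model-free
recovery at duplicate noise plus a 163-residue noise-free
exchange-flagging round trip; 153-bead SAXS models; 100 melting ramps
of 191 points; Monte-Carlo populations of 150–400 capsids at 300–8000
sweeps. These sizes give stable medians and population fractions on a
single CPU in about a minute for the full acceptance script.

## Known limitations

* The SPR model is strictly 1:1: no bivalent or heterogeneous-ligand
  schemes, no surface-regeneration or bulk refractive-index modelling
  beyond double referencing; avidity effects on a polyvalent surface
  enter only through the transport/rebinding term.
* Relaxation analysis has no reduced spectral-density mapping, no ¹³C,
  no CPMG dispersion — Rex magnitude is estimated, its timescale is not.
* The SAXS direction is forward-only: no indirect Fourier transform of
  experimental I(q), no ab-initio reconstruction, no rigid-body
  refinement. Synthetic generators emulate the statistical structure of
  instrument output, not vendor file formats or systematic artefacts
  (buffer mismatch, radiation damage, capillary fouling), so passing
  tests demonstrate correctness of the analysis logic, not robustness
  to every pathology of real data.
* The melting model is phenomenological (logistic release); no
  two-state thermodynamic fitting (ΔH, ΔS) and no modelling of the
  structural failure mode that opens the DNA gate.
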