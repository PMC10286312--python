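# Methods

## The model

`tkreceptor` implements a two-compartment toxicokinetic model for
contaminants that bind their molecular target irreversibly, developed
for the neonicotinoid thiacloprid in the amphipod *Gammarus pulex*.
The organism is split into

* a **structure compartment** — the bulk tissue pool, exchanging ligand
  reversibly with the surrounding water through an uptake rate
  `k_u` (L kg_structure⁻¹ d⁻¹) and a first-order elimination rate
  `k_e` (d⁻¹); and
* a **membrane-protein (MP) compartment** — the protein fraction
  containing the nicotinic acetylcholine receptors (nAChRs), a mass
  fraction `fms` of the structure compartment (default 0.01, the
  measured 1 % MP content).  Ligand in the structure compartment binds
  free receptors by second-order mass action with rate `k_on`
  (kg_structure µmol⁻¹ d⁻¹) up to the maximal binding capacity
  `B_max` (µmol kg_MP⁻¹).

With `C_structure` (µmol/kg) and `C_MP` (µmol/kg_MP) as states and
`C_W(t)` (µM) the piecewise-constant water concentration:

    dC_MP/dt        = k_on · C_structure · (B_max − C_MP) − k_off · C_MP
    dC_structure/dt = k_u · C_W − k_e · C_structure − fms · dC_MP/dt
    C_total         = C_structure + fms · C_MP

The dissociation rate `k_off` is fixed at 0: on experimental timescales
(days) no depletion of the receptor-bound pool is observed, so binding
is treated as irreversible.  Constructing a parameter set with
`k_off > 0` is allowed but emits a warning, because the steady-state
formulas below then no longer apply.  Under constant exposure the
irreversible system tends to `C_structure → (k_u/k_e)·C_W` and
`C_MP → B_max` — the receptor pool always fills completely; only the
time to saturation depends on the exposure level.

Key consequences implemented here:

* **Elimination resistance.**  After depuration the body burden
  plateaus at `fms · B_max` (0.25 µmol/kg for the default parameters)
  regardless of exposure concentration, duration, or pulsing.
* **Concentration-dependent BCF.**  The asymptotic whole-body
  bioconcentration factor is `k_u/k_e + fms·B_max/C_W`, which grows
  without bound as `C_W` falls; it crosses the regulatory
  B criterion (2000 L/kg) near 31 ng/L and the vB criterion
  (5000 L/kg) near 13 ng/L for the default parameter set.  The
  crossing concentration is computed analytically as
  `C_W = fms·B_max/(threshold − k_u/k_e)`.

Three BCF estimators mirror how uptake–elimination experiments are
analysed: whole-body `C_tissue,u/C_water` at the end of uptake;
structure-only `(C_tissue,u − C_tissue,e)/C_water`, which subtracts the
elimination-resistant residue measured after depuration; and the kinetic
ratio `k_u/k_e`.  First-order error propagation for ratios
(`propagate_ratio_sd`) accompanies them.

## Numerical treatment of the ODE system

With `k_on` at its default 200 the MP equation is stiff relative to
`k_e` (the fast eigenvalue is ≈ `fms·k_on·B_max + k_on·C_structure`,
two orders of magnitude above `k_e`), so trajectories are integrated
with the stiffness-switching LSODA method (via `scipy`'s `odeint`,
with an analytic Jacobian) at `rtol = 1e-8`, `atol = 1e-10`.  The water
forcing is discontinuous at scenario breakpoints; instead of stepping
across the discontinuity the integrator is restarted at every interval
boundary.  Solver output may overshoot the saturation bound
`C_MP ≤ B_max` by amounts within tolerance; these are clipped, and
violations beyond ~10× tolerance raise an error rather than being
hidden.  An independent fixed-step explicit-Euler implementation (step
10⁻⁵ d) lives in the test suite as an oracle; the adaptive solver
matches it to < 10⁻³ relative error, and matches the closed-form
one-compartment solution to < 10⁻⁶ when the receptor pool is removed.

**Units.**  All internal computation uses µM, µmol/kg wet weight and
days.  Mass concentrations (µg/L, ng/L) are converted at the boundary
with a configurable molar mass whose default, 250 g/mol, follows from
the 50 µg/L ≡ 200 nM equivalence used in the exposure designs.  The
wet→dry conversion factor 5.4 is exposed as a constant but never
applied implicitly.  Exposure media during depuration are treated as
exactly ligand-free (measured values fall below quantification limits),
and within-interval water concentrations as constant at nominal values
(measurements stayed within 20 % of nominal; medium renewals are not
modelled).  In `C_total` the structure compartment's mass fraction is
taken as 1 (the MP mass is not subtracted) — the additive approximation
appropriate to the `fms ≪ 1` regime.

## Saturation-binding assay

The in vitro assay incubates an MP extract with ligand at free
concentrations `C_free` and measures specifically bound ligand.  The
one-site isotherm `C_bound = B_max·C_free/(K_d + C_free)`, optionally
extended with a linear unspecific term `NS·C_free`, is fitted by
ordinary least squares on the natural scale (the standard choice for
saturation binding; per-point weights are accepted for variance
weighting).  Specific-only fits are restricted to `C_free ≤ 25 nM` by
default because unspecific membrane binding is no longer negligible at
the 50 nM assay level; the window is a configurable default, not
hard-coded.  The 0 nM level enters as a (0, 0) anchor; blank-corrected
bound values below zero are clamped to zero with a warning.  95 %
confidence intervals are asymptotic (covariance-based, ±1.96 SE),
matching what standard curve-fitting tools report.  A Scatchard
transform (`C_bound` vs `C_bound/C_free`; slope −1/K_d, x-intercept
B_max) is provided as a design diagnostic — for the default assay
levels it makes visible that the isotherm is sampled far above `K_d`,
which is why `K_d` carries much more uncertainty than `B_max`.

The fitted capacity is scaled to a whole-organism receptor density as
`C_Bmax = B_max · fms / recovery`, with `recovery` the MP recovery
fraction of the assay work-up (0.24 for the in vitro route; 1 for a
model-calibrated capacity, which already refers to intact organisms).

## Likelihood, calibration and confidence intervals

Observed whole-body concentrations span four orders of magnitude across
treatments, so the default error model is Gaussian on log-transformed
concentrations — equivalent to multiplicative lognormal measurement
error — with a natural-scale option.  The original analysis does not
state its residual model; this is the package's largest assumption and
is therefore switch-selectable.  The residual SD is a nuisance
parameter profiled out analytically (`σ̂² = SSR/n`), reducing the NLL
to `n/2·(log 2πσ̂² + 1)`; a floor on σ̂ (default 10⁻⁶) keeps the
perfect-fit NLL finite, and a concentration floor (10⁻⁹ µmol/kg)
guards the log transform against zero observations.

Calibration minimizes the NLL by multi-start bounded trust-region least
squares in log₁₀-parameter space (≥ 16 Latin-hypercube starts, seeded;
equivalent to NLL minimization because the concentrated NLL is monotone
in SSR).  Finite-difference steps are set to 10⁻⁴ — well above the
integrator's relative tolerance — because Jacobians differenced at the
default ~10⁻⁸ step would measure solver noise; the winning start is
polished with tightened stopping tolerances for the same reason.
Default bounds are `k_u ∈ [0.1, 1000]`, `k_e ∈ [0.01, 100]`,
`k_on ∈ [0.01, 200]`, `B_max ∈ [0.1, 1000]`.  The upper bound on
`k_on` is deliberate: binding faster than ~200 kg µmol⁻¹ d⁻¹ is
observationally indistinguishable from instantaneous in these designs.
Among starts with tied NLL the lowest `k_on` wins (parsimony toward
slower kinetics).  Fit quality is additionally summarized by R² on the
natural scale across all calibration observations.

A parameter is reported as **boundary-limited** when its optimum is
statistically indistinguishable from a search bound: it either lands on
the bound, or stalls near one (within 10 % of the log-span) while the
profile NLL at the bound — other parameters re-optimized — stays within
the 95 % cut-off of the minimum.  This catches the characteristic
flat-likelihood plateau of `k_on` even when the optimizer happens to
stop at an interior value.

Profile-likelihood intervals step one parameter over a multiplicative
grid (factor 1.2), re-optimize the remaining free parameters warm-
started from the neighbouring solution, and define the 95 % interval by
`ΔNLL ≤ χ²(0.95, 1)/2 = 1.92`.  Interval end points are sharpened by
root-finding (Brent) on the NLL rise inside the bracketing step, and
the interval is anchored on the minimum actually seen during the scan
(warm-started re-optimizations can undercut the incoming optimum
slightly).  End points that reach a bound before crossing the cut-off
are reported at the bound and flagged one-sided — the expected outcome
for `k_on`.  Failed re-optimizations at individual grid points are
recorded as infinite NLL rather than aborting the scan.

Validation is strictly forward: held-out scenarios are simulated with
the best-fit parameters (no refitting) and compared with observations
via overall and per-treatment R² and log-residual summaries.

## Synthetic data

The generators reproduce the statistical structure of the study's
experimental designs so that every estimator in the package can be
exercised without measured data:

| design | exposure | depuration | levels (µg/L) | sampling | replicates |
|---|---|---|---|---|---|
| I   | 2 d | 8 d | 50 | regular grid | 2 |
| II  | 20/20/4 d | 5/5/4 d | 0.05, 0.5, 5 | every 5 d (long arms) | 3 |
| III | 2 d | 2 d | 5–5000 | phase ends | 3 |
| IV  | 3 × 2 d | 3 × 3 d | 5, 50 | days 1, 2, 3, 5 per pulse | 3 |

Calibration uses the five constant-exposure treatments (0.05, 0.5, 5,
50, 1500 µg/L) drawn from designs I–III; validation uses the remaining
constant treatments (design III) plus the pulsed design IV.  The exact
sampling days of the kinetic experiment are not published ("regular
time intervals"); the default grid (daily during short uptake phases,
every 5 days during long ones, a geometric-like set of offsets during
depuration, plus all phase boundaries) is a reasonable stand-in, not a
reproduction.

Measurement error is multiplicative lognormal with configurable CV —
concentrations are strictly positive and heteroscedastic across
decades, consistent with the log-scale likelihood.  The noise is
median-preserving (`exp(σZ)` with `σ² = ln(1+CV²)`), so geometric means
of replicates converge to the model value.  An additive-Gaussian option
exists for sensitivity checks.  Seeds are mandatory whenever CV > 0 and
every generator is deterministic given its inputs.  Mortality/dropout
is not simulated, and neither is the in vivo fractionation assay
(supernatant/debris/MP partitioning), whose fractions are measured
rather than modelled.

What passing tests on these data do **not** show: the generator assumes
the model is true, noise is exactly lognormal and independent, exposure
follows nominal concentrations exactly, and organisms are exchangeable.
Real experiments add model error (biotransformation, temperature
dependence, physiological variability between sampling seasons), none
of which the recovery studies here can detect.

## Problem sizes and defaults in the shipped studies

The shipped calibration study uses the five-treatment design above
(109 observations), CV = 0.05, 16 optimization starts; the binding
recovery study uses the assay levels 0–25 nM, 4 replicates, CV = 0.10.
The profile-coverage study in the test suite runs 20 replicates of a
reduced three-treatment design (2 replicates per time point, 4 starts)
— enough observations to identify `k_u`, `k_e`, `B_max` while keeping a
full calibrate-and-profile cycle to seconds.  With a single in-silico
assay, `K_d` recovery inherits the design's weak identifiability: its
sampling distribution (SD ≈ 0.23 nM around 0.41 nM) is wide for the
same reason the published interval (0.15–0.85 nM) is.

## Known limitations

* No toxicodynamics: the model predicts internal concentrations, not
  effects; coupling to survival/effect models is out of scope.
* No biotransformation and no temperature dependence — both documented
  extensions rather than features.
* `steady_state` supports only the irreversible configuration
  (`k_off = 0`); with reversible binding the MP steady state depends on
  the exposure history.
* Covariance-based CIs for the binding fit understate the asymmetry of
  `K_d`'s uncertainty; the profile machinery is available where that
  matters.
* The boundary-limited check evaluates the profile only at the bounds,
  not everywhere, so a pathological multi-modal likelihood could in
  principle evade it.
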