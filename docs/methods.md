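# Methods

## Model structure and assumptions

The package couples a fast mechanotransduction module to a slow circadian
module under a separation-of-timescales assumption: nuclear translocation of
YAP/TAZ and MRTF equilibrates within tens of minutes, while clock protein
levels change over hours to days, so the clock only ever sees the
*steady-state* nuclear concentrations of its two mechanical inputs.  All
species are treated as well mixed within their compartment (ODE/DDE
description, no spatial gradients), and the coupling is one-way: the clock
does not feed back on the cytoskeleton.

### Mechanotransduction network

The network is a feed-forward cascade solved algebraically stage by stage
(the steady state is therefore unique and deterministic):

- **FAK**: phosphorylation rate rises with substrate stiffness through a
  saturating law in E^0.5 (half-activation 10 kPa on the square-root scale),
  spreading sensitivity over the 0.1 kPa–glass range; contact area scales
  FAK activation through a saturating area law normalized to the control
  area A₀, and high cell density reduces it by a fixed factor.
- **RhoA → ROCK/mDia → LIMK ⊣ cofilin, ROCK → myosin**: saturating
  activation kinetics; Y-27632 inhibits ROCK and blebbistatin inhibits
  active myosin through Hill terms.
- **Actin**: dF/dt = k_a[G] − k_d[F] with mass conservation
  [F] + [G] = Actin_tot; k_a grows with mDia, k_d with active cofilin.
  Closed forms replace this balance under cytochalasin D (capping + C·G
  dimerization; the dimer pool no longer sequesters MRTF), latrunculin
  (G sequestration; the *total* G pool sequesters MRTF) and jasplakinolide
  (k_a up / k_d down with a shared saturation constant).
- **Nucleus**: cytosolic stiffness E_cyto is a saturating function of F;
  lamin A dephosphorylation (lamina incorporation) follows E_cyto; NPC
  opening requires lamin A *and* cytoskeletal tension (F·myosin).
- **YAP/TAZ**: three pools (phosphorylated cytosolic, active cytosolic,
  nuclear).  Stress fibers (F·myosin) drive dephosphorylation; import has a
  basal component plus an NPC-dependent one.  The YAP-5SA mutation adds a
  second, phosphorylation-dead species with total equal to the wild-type
  pool (doubling overall YAP/TAZ); the LMNA mutation sets lamin A
  phosphorylation to zero and doubles the NPC opening rate.
- **MRTF**: G-actin binds MRTF with a squared saturating law; only free
  MRTF shuttles, with basal plus NPC-dependent import.

Concentrations are normalized (protein totals 1–2 model units); stiffness
is in kPa with glass encoded as 1.0e7 kPa; drug concentrations in uM.
Because cytochalasin D lowers both F-actin (→ less nuclear YAP/TAZ) and
free G-actin (→ *more* free MRTF), it is the unique treatment moving the
two nuclear inputs in opposite directions — a structural signature the
tests pin down.

### Clock

Three DDEs for nuclear BMAL1 (B), PER/CRY (P) and REV-ERBα (R):
REV-ERBα represses BMAL1 expression with delay τ_B = 12 h; BMAL1 activates
and PER/CRY self-represses E-box expression with delay τ_P = 9 h; REV-ERBα
expression is the same E-box drive at delay τ_R = 4 h scaled by ζ = 0.5.
All Hill exponents are 2.  Mechano-coupling adds activating Hill terms in
the steady-state nuclear YAP/TAZ and MRTF to each expression rate.  The
history before t = 0 is the constant initial condition
(B₀, P₀, R₀) = (5B*, 0.2P*, R*) built from the condition's fixed point — a
perturbed start from which oscillations develop, mirroring common DDE
solver defaults.  Luciferase integrates the PER/CRY expression rate with
decay K_dL and L(0) = 0.

The delayed PER/CRY self-repression loop (supported by the longer B–R
loop) makes the fixed point unstable over a range of coupling inputs:
oscillation period ≈ 23.5–24 h at the packaged point estimates.  The
additive mechano input raises P* and R*, lowering the effective loop gain;
past a supercritical Hopf bifurcation the limit cycle disappears and
oscillations decay.  This is the mechanism behind every population-level
effect in the package: soft substrates (low input) → robust, slightly
longer-period, higher-amplitude rhythms; stiff substrates and mutants
(high input) → weaker or decaying rhythms.

## Numerics

- **DDE integration**: method of steps on a uniform grid, classical RK4
  with cubic-Hermite interpolation of the stored solution for delayed
  lookups (interpolation matches the stepper's fourth order).  Default step
  0.025 h for single trajectories, 0.05 h for cohorts, 0.2–0.25 h inside
  the walker-vectorized likelihood; halving the step changes period
  estimates by <0.1% (tested).  Zero delays degenerate to the instantaneous
  state, reducing the system to an ODE (validated against LSODA at 1e-6).
  The integrator is vectorized over a batch axis (cells or MCMC walkers),
  which is what makes 200-cell cohorts (~4 s) and ensemble calibration
  tractable on one core.
- **Fixed points**: the equilibrium reduces to a scalar monotone equation
  in P*, solved by vectorized bisection to ~1e-14; clock right-hand-side
  residuals at the returned point are below 1e-10.
- **Luciferase**: exponential time differencing, exact for piecewise-linear
  expression inputs on the output grid.
- **Characteristic roots**: Newton iterations on
  det(λI − A₀ − Σ A_j e^{−λτ_j}) from a grid of complex starting points,
  residual-checked, deduplicated, conjugates completed.  The Hopf locus is
  traced by bisection along the YAP axis per MRTF grid value — robust at
  desk scale, no continuation needed.
- **Power fraction**: noise → 15-min sampling → zero-phase FIR
  (b = 0.2·[1,1,1,1], a = 1, applied forward–backward) → standardization →
  periodogram.  SNR is a linear power ratio (default 5, per-cell).  The
  window is f_C ± 0.1 day⁻¹ (half-width configurable; the denominator is
  total power to Nyquist, 48 day⁻¹); f_C maximizes the population-average
  power in 0.7–1.3 day⁻¹.
- **Calibration**: reference curves are Monte Carlo means/s.d. of
  A·cos(2πt/T) over normally distributed (T, A) draws on an hourly grid
  (dephasing makes the mean envelope decay, as in averaged population
  recordings); non-positive period draws are rejected and logged.  Model
  traces are shifted to their second peak, normalized to the control
  amplitude and mean-centered.  The objective adds −η(T_model − T_exp)²
  (hours², η = 100) to the Gaussian log-likelihood; non-oscillatory
  parameter sets get −∞ (the comparison is undefined without a second
  peak).  A 5% amplitude floor on σ(t) prevents the near-node hours from
  dominating.  MCMC uses emcee's affine-invariant ensemble (60 walkers ×
  1000 steps by default, 500 burn-in); convergence is assessed with the
  integrated autocorrelation time.
- **Sobol' indices**: scrambled Sobol' sequences (scipy.stats.qmc) for the
  Saltelli A/B/AB_i design and Jansen's total-order estimator, with
  pairwise exclusion of failed (NaN) evaluations.

## Parameters and calibration status

Baseline parameter values (the "point estimates" packaged in
`data/parameters.csv`) were set by a development-time numerical search so
that the model reproduces the qualitative phenotypes the package is built
around: monotone stiffness responses; a ~24 h rhythm for the representative
cell; sustained oscillations for untreated cells from 0.1–30 kPa;
decaying oscillations under jasplakinolide and for both mutants at 30 kPa;
and wild-type-like power fractions when the LMNA mutant is moved to 3 kPa
or the YAP-5SA mutant to 0.3 kPa.  The glass point estimate lies *just
above* the Hopf bifurcation (rightmost eigenvalue ≈ −5e-4 1/h at the
baseline, per-cycle amplitude ratio ≈ 0.97): effectively critical, so
single glass cells oscillate for many days with a slow amplitude drift
while glass *cohorts* — whose per-cell coupling spreads widely — show a
clearly reduced power fraction.  Fitting ranges in the parameter table
bound the calibration's uniform priors.  The packaged calibration summary
table (`data/calibration_targets.csv`) is synthetic-but-plausible: no raw
luminescence dataset ships with the package, so the table encodes the
published qualitative trends (softer/less contractile → longer period,
larger normalized amplitude) with realistic dispersions; it exists to
exercise the full calibration machinery end to end.

## Population model

Cell-to-cell variability multiplies every non-exponent mechano parameter by
exp(σ·r), r ~ N(0,1), σ = 0.2.  Calibrated (clock + MRTF) parameters are
drawn jointly from posterior chain rows when a chain is supplied —
preserving posterior correlations — and otherwise log-normally with
σ = 0.05, a stand-in for posterior width: period-setting parameters are far
better constrained by rhythmic data than generic rate constants, and a 0.2
spread on delays would scatter single-cell frequencies far outside the
observed circadian band.  Per-cell seeds derive from the master seed via
`numpy` SeedSequence spawning, so cohorts are bit-reproducible from
(parameter table, condition, seed).  Cohorts default to 200 cells; metrics
use a 6-day window after a 1-day transient (96 samples/day); kymographs
show the first 3 days.  REV-ERBα is the metric species (matching
fluorescent REV-ERB reporters); PER/CRY is used for single-cell displays.

## What the synthetic data do and do not show

The generator varies kinetics and measurement noise but not: intercellular
coupling (cells are independent), transcriptional bursting or other
intrinsic stochasticity (each cell is deterministic between noise
injection), entrainment cues, 3D culture effects, or clock→mechanics
feedback.  Passing population tests therefore demonstrate that the coupled
model plus parameter dispersion reproduces the *direction and rough size*
of mechanical effects on rhythm quality — not that real fibroblast
populations share the model's variance structure.

## Known limitations

- The mechano cascade is feed-forward; real networks contain feedback
  (e.g. tension-dependent focal adhesion reinforcement) that could make
  steady states multistable.
- The glass condition sits essentially on the Hopf bifurcation, so
  quantities there are sensitive to small parameter changes; conclusions
  in the package rely on comparisons between conditions, not on the exact
  glass values.
- Calibration against the packaged synthetic summary table recovers
  well-identified parameters (delays, decay rates) but leaves
  production/scale parameters sloppy — expected, since period and
  normalized amplitude constrain mostly ratios.
- The period shift between soft and stiff substrates at the packaged
  estimates (~0.3–0.5 h in cohort medians) is smaller than the amplitude
  and power-fraction effects; the direction is robust but the magnitude
  depends on how deeply the soft condition sits in the oscillatory regime.
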