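# Methods

## Scope and model structure

`mitoclock` implements four nested ODE models of mitotic control and the
dynamical-systems machinery needed to analyse them. All state variables are
dimensionless activities/concentrations; time is in minutes (one time unit
of the source models ≈ 1 min). The models share a cyclin-B synthesis term
(k_sy) and an APC/C-driven degradation factor; they differ in how APC/C
activation is delayed and how MPF activity is gated.

State layouts:

| model | states |
|---|---|
| model1 | MPF, KinP, APCP |
| model2/3 | MPF, GwlP, ENSAP, APCP, APCPC20 |
| model4 | CycBT, MPF, GwlP, ENSAP, APCP, APCPC20 |
| size model | model4 states + V |

Conservation is closed algebraically (free form = total − modified form),
so the conservation laws hold identically along trajectories; tests verify
the closure consistency (B55_free + ENSA_P:B55 = B55_tot to 1e-9 relative)
and that every stored state respects the bounds. One ordering constraint,
APCPC20 ≤ APCP, holds for admissible initial states but not along
trajectories: the equations dephosphorylate the whole phospho-APC pool
while Cdc20 unbinds only slowly, so the bound form transiently overshoots
during mitotic exit (by ≈0.03 at reference parameters). This is a property
of the model equations, and `validate_state` exposes a flag to skip that
check when validating trajectory output.

## Algebraic closures

Four closures carry the model's ultrasensitivity and are implemented as
ratios of geometric sums rather than the textbook rational forms:

- ubiquitinated fraction f(r) = r⁴ / (1+r+r²+r³+r⁴) — the top-state
  occupancy of a five-state ordered-distributive ubiquitination chain
  (degradation requires four ubiquitins; the depth is a module constant,
  not a tunable);
- Wee1 active fraction (1+…+s⁴)/(1+…+s⁸) and Cdc25 active fraction
  (s⁵+…+s⁸)/(1+…+s⁸) — nine-state multisite-phosphorylation occupancies
  with states P0–P4 (Wee1) and P5–P8 (Cdc25) active; their sum is exactly 1;
- the tQSSA complex, the smaller root of C² − ΣC + E·B = 0 written in the
  cancellation-free form 2EB/(Σ + √(Σ² − 4EB)).

The geometric-sum forms are singularity-free at ratio 1 (where the rational
forms are 0/0) and are evaluated in powers of 1/x above 1, so no guard
interval is needed and overflow is impossible. The typeset source of the
tQSSA omits the radical sign; the standard smaller-root formula is the only
reading consistent with the tQSSA literature and dimensional analysis, and
the implementation is verified against a generic polynomial-root oracle.

Strict domain errors (negative activities) are raised by the public closure
functions. Inside the right-hand sides the closure inputs are clamped at
zero instead: Newton correctors and continuation predictors legitimately
probe slightly outside the physical box, while integrated trajectories
never leave it. Invariant checking (non-negativity, totals, APCPC20 ≤ APCP,
MPF ≤ CycBT) is provided by `validate_state` rather than by raises in the
integration hot path.

## Parameters

The reference parameter sets ship as structured-text fixtures
(`mitoclock/data/parameters.yaml`) with one provenance label per value.
Global totals: PP = Gwl_tot = APC_tot = Cdc20_tot = B55_tot = Wee1_tot =
Cdc25_tot = 1, ENSA_tot = 4. Model-specific constants of note:
K_m = 0.0008 / deUb = 0.75 (model 2), K_m = 0.0026 / deUb = 0.5
(models 3–4), CAP = 0.3 (model 4). The model-1 column parameterises the
intermediary-kinase equation with the Greatwall rate-constant names; no
separate Greatwall species exists there.

The source table is typeset in a way that concatenates columns ambiguously
in plain text. The shipped transcription is the unique digit-split giving
each row one value per model that uses the parameter, and it independently
reproduces the printed dynamical anchors (oscillator period ≈ 46 min;
hysteresis thresholds ≈ 1.2 / 0.5).

## Checkpoints

All three checkpoints are parameter overrides of model 4, so clearing an
override restores the base dynamics exactly:

- G2 (unreplicated DNA): Cdc25_tot 1 → 0.4;
- SAC (unaligned chromosomes): Cdc20_tot 1 → 0.1 (a documented alternate
  config uses 0.2; both arrest);
- G1 (DNA damage): the degradation factor gains k_de3·(APC_tot − APC_P)
  with k_de3 = 0.2, representing Cdh1-loaded APC/C acting on cyclin B. The
  extended factor is applied to both the CycBT and the MPF equations, so
  the two cyclin-pool species degrade consistently; k_de3 defaults to 0,
  which reduces bit-for-bit to the base model.

## Numerics

- **Integration**: LSODA (stiff-capable) at rtol 1e-8 / atol 1e-10; models
  3–4 are relaxation oscillators with abrupt mitotic jumps and the small
  tQSSA Michaelis constant makes the ENSA equation stiff. Output is dense
  interpolation on a user grid; everything is seed-free deterministic.
- **Limit cycles**: the period is the mean spacing of ≥5 successive maxima
  of MPF (the reference observable throughout), each refined by bounded
  scalar maximisation on the dense solution; the convergence flag requires
  a coefficient of variation of spacings < 1e-3. Transient discard: the
  larger of 500 min and three rough periods. Amplitude below 1e-4 is
  reported as "no cycle", never raised.
- **Arrest detection**: steady state declared when max |dx/dt| < 1e-8 and
  state drift < 1e-6 over the trailing 10% of the horizon; otherwise the
  trajectory is handed to the limit-cycle detector, and an inconclusive
  outcome is flagged as such.
- **Steady states**: damped Newton (backtracking line search) from ≥27
  seeded uniform starts in the admissible box (bounded by totals and the
  synthesis ceiling k_sy/k_de1); roots kept at residual < 1e-10, merged at
  distance 1e-6, classified by finite-difference Jacobian eigenvalues
  (central differences, relative step 1e-6, step-halving consistency
  check).
- **Continuation**: native pseudo-arclength with secant predictor and
  Newton corrector (no external continuation binary). Folds are flagged by
  a sign change of the parameter component of the unit tangent and refined
  by arclength bisection to 1e-6 in the parameter; Hopf points by the real
  part of the complex pair nearest the axis changing sign, refined the same
  way. Both are exact to 1e-6 on the saddle-node and Hopf normal forms.
- **Pseudo-nullclines**: one state variable's ODE is removed and that
  variable continued as a parameter; the starting root is found by settling
  the reduced dynamics at the low end of the range. With two folds the
  curve is classified S (response increasing) or Z (decreasing); note that
  an S-shaped branch appears N-shaped when a figure puts the response on
  the abscissa.
- **SNIC classification**: a fold is a saddle-node on an invariant circle
  when stable oscillations exist just beyond it on the side where the
  steady state vanished and the measured period grows monotonically to
  more than 5× the far-field period as the fold is approached (the 5×
  factor is this package's operational criterion). Unstable limit cycles
  cannot be traced by forward integration and are out of scope; only Hopf
  point locations are reported.

## Size-controlled division

Cell size V enters model 4 through Cdc25_tot = V(t) (bigger cells
accumulate more of the activating phosphatase); dV/dt = μV with μ = 0.005
min⁻¹ by default. A division fires on the downward crossing of MPF through
the mitotic-exit threshold (0.2), armed only after MPF has exceeded the
mitotic-entry threshold since the last division; the entry threshold is not
fixed by the source material and defaults to 0.5 — comfortably above the
interphase MPF plateau and below every mitotic peak, so its exact value is
immaterial. At division V halves instantaneously; all protein
concentrations are intensive quantities and stay continuous. Crossings are
located by the integrator's event root-finding (well below 1e-8 min).
Interdivision statistics discard the first two completed cycles.

## What the computations show — and a parameter-table discrepancy

With the shipped parameter table the package reproduces, from scratch: the
model-1 period (45.7 min vs the quoted ≈46), the monotone → S-shaped
transition of the APC/C pseudo-nullcline between models 2 and 3, the
cyclin hysteresis thresholds of model 4 (activation fold at CycBT = 1.158,
inactivation at 0.519, vs the quoted ≈1.2 and ≈0.5), all three checkpoint
arrests with the documented high/low signatures and their release into
oscillation, and size homeostasis (interdivision time 138.6 min = ln 2/μ,
independent of μ and of the initial size over [0.3, 2]).

Two size-control quantities do not reproduce under the same table: the
arrested-branch fold of the clamped-V diagram computes to V = 0.544 (quoted
≈0.85) and the asymptotic division size to 0.64 (quoted ≈1). These are
internally consistent with each other — the division-size/fold ratio
(1.17) matches the quoted ratio (≈1.18), and the fold does classify as a
SNIC by period divergence — indicating the same dynamics at a shifted
scale. The fold location depends only on parameters that are unambiguous
in the table (cyclin synthesis/degradation, the four Cdk
phosphorylation/dephosphorylation rates, CAP); reproducing 0.85 requires
k_dp1,cdk ≈ 0.1 instead of the tabulated 0.2, but that value moves the
cyclin activation threshold to 1.84, contradicting the quoted 1.2. No
single parameter set satisfies both figure families, so the table is
shipped as printed and the discrepancy documented rather than patched.
Additionally, no Hopf bifurcation exists on any physical steady-state
branch of the clamped-V system over V ∈ [0.02, 1.3] under the shipped
table (verified by a global census: the relevant complex pair keeps real
part ≈1.5–1.8 throughout), so the acceptance script omits a Hopf location
when none is found.

The clamped-CycBT branch also carries a small interior fold-loop (three
coexisting stable states around CycBT ≈ 0.9 — an intermediate state of the
kind reported for interlinked mitotic switches), so the raw fold count is
six; the hysteresis thresholds reported are the two folds terminating the
stable low-MPF and high-MPF branches.

## What the tests do and do not show

All inputs are the fixed parameter tables above — there is no synthetic
data generator with distributional choices, and no noise model. Passing
tests therefore certify the deterministic dynamics of these ODE systems
(oracle-checked algebra, integrator-independent extrema, normal-form-exact
bifurcation detection), not any fit to experimental measurements: real
mitotic cycles have stochastic period variability, unequal division, and
checkpoint signalling far richer than a single parameter override.

## Known limitations

- Unstable limit cycles (subcritical Hopf branches) are not traced.
- Two-parameter bifurcation diagrams and limit-cycle continuation by
  collocation are out of scope.
- The SAC is modelled purely as a reduction of available Cdc20; mitotic
  checkpoint complex assembly kinetics are not represented.
- DNA-replication (S-phase promoting factor) dynamics are not modelled.
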