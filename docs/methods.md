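# Methods

This note records the model, the numerical choices, and what the synthetic
study does and does not establish.  It is the package's own account; all
empirical numbers quoted here are computed by the test suite or the
acceptance script.

## Muscle–tendon model

Each MTU is a Hill-type muscle belly in series with an elastic tendon,
reduced to a force along the line of action.  States and outputs follow the
implicit formulation in which activation `a` and normalised tendon force
`F̃ = F_T/F_max` are the states and normalised fibre length `ℓ* = ℓ/ℓₒ` is an
output of the geometry: the tendon length follows from the inverse tendon
curve, the fibre spans the remaining path, and pennation obeys the
constant-thickness rule `ℓ sin α = ℓₒ sin αₒ`.

Characteristic curves (all C¹, defined on open domains):

* **Active force–length** — a three-Gaussian sum, renormalised so the value
  at `ℓ* = 1` is exactly 1 (the literature constants give ≈ 0.9994).
* **Passive force–length** — exactly zero at and below `ℓ* = 1` (value and
  slope both vanish at the junction), rising as a shifted exponential with
  strain scale 0.6 and unit value at `ℓ* = 1.6`.  Making the curve exactly
  zero below optimum (rather than slightly negative, as in some published
  parameterizations) keeps "no passive force below optimal length" an exact
  statement that downstream filters and penalties rely on.
* **Force–velocity** — arcsinh (logarithmic) form, re-anchored so
  `f_v(0) = 1` exactly; ≈ 0.01 at maximal shortening (`v* = −1`).
* **Tendon force–strain** — `f_T(x) = c·(e^{k̂(x−1)} − 1)` with `c = 0.2`
  and `k̂ = k_T/(1+c)`.  The two anchors are exact for *every* stiffness:
  `f_T(1) = 0`, and the slope where the tendon carries `F_max` equals `k_T`.
  The default `k_T = 100` reflects measured tendon dimensions of small
  terrestrial birds; the curve constants are re-solved per `k_T` rather than
  fixed at a human-model default.

Numerical choices: a damping term `β v*` with `β = 0.01` regularises the
equilibrium inversion; fibre length is floored at `ℓₒ sin αₒ + 1 µm`; curve
evaluation outside `ℓ* ∈ [0.2, 1.8]` is permitted (extreme static postures
reach it) but logged.  Static equilibrium is solved by safeguarded Brent
iteration on `F̃` with an analytic bracket; a vectorised 90-step bisection
solves pose batteries in bulk.  Both report infeasible geometry (path at or
below tendon slack length, or fibre crushed to the thickness floor)
distinctly from numerical non-convergence.

Activation dynamics are first order with a tanh blend (width 0.1) between
the activation and deactivation time constants.  Defaults are the human
values (0.015/0.060 s) scaled by body mass^(1/6) to a 0.545 kg animal:
0.007/0.027 s.

## Limb geometry

MTU path geometry is functional: `l_MT` is a multivariate polynomial of the
joint angles the MTU crosses, and moment arms are defined by tendon
excursion, `r = −∂l_MT/∂q`, so lengths and arms are consistent to machine
precision and every derivative the collocation needs is exact.  This is the
standard surrogate for wrapping-surface geometry; anything that can compute
`l_MT(q)` tables can be imported, since trial files may carry explicit
per-sample length/arm columns that override model evaluation.

## Inverse (redundancy) solver

Direct collocation with two-stage Radau IIA points (third order) on evenly
spaced mesh intervals (default 100; configurable down to 10 for desk-scale
problems).  Controls are the excitation and the scaled tendon-force rate;
`ℓ*` is lifted to an algebraic variable per collocation node, which keeps the
objective's passive-force term local and the constraint Jacobian sparse.
Constraints per node: Radau defects for both states, the geometric `ℓ*`
consistency equation, the damped Hill equilibrium (fibre velocity derived
from the tendon-force rate through the tendon compliance), and moment
balance per DOF with reserve actuators scaled by per-DOF caps.  The NLP is
solved with SciPy's `trust-constr`, with an analytic objective gradient and
grouped finite-difference constraint Jacobians on the exact sparsity
pattern.  The interior point starts from a small barrier parameter (1e−4):
activations and excitations sit at or near their lower bounds over most of a
stride, and the default barrier first pushes the iterate deep into
co-contraction from which large problems recover only slowly.
Tendon-curve inverses are evaluated through a softplus-smoothed
force offset so that arbitrary NLP iterates (which can transiently leave the
physical region) remain finite and differentiable; the smoothing changes
tendon length by < 1e−8 m in the physical region.

Objective weights are `w1..w6 = 2, 500, 1, 100, 2, 1`.  The two rate
penalties are non-dimensionalised with the conventional control scalings of
this problem class (activation rate × 0.01 s, normalised tendon-force rate
× 0.1 s); with a coarser activation-rate scale the smoothing term visibly
flattens recovered bursts.  Reserve caps default to 10% of each DOF's peak
external moment.  Tuning factors are bounded to [0.5, 2.0] (reported tunings
in comparable studies stay well inside).  The static-optimization seed
solves, per instant, minimum squared activation under rigid-tendon moment
balance by an active-set KKT iteration, falling back to a reserve-saturated
least-squares point (logged) where the instant cannot be balanced.

Feasibility at the solution is checked by re-evaluating all constraints
(tolerance 1e−6 on the scaled residuals); moment rows are scaled by each
DOF's peak external moment.  When tuning is frozen the trials decouple and
are solved as independent NLPs; this is algebraically identical to the
joint problem and faster.

## Synthetic data: what it emulates, and what it does not

`make_toy_limb` samples architectures over the spreads of the packaged
36-MTU hindlimb table: pennation 0–35°, `L_S/ℓₒ` 0.05–8 (log-uniform),
`F_max` 0.6–30 N, fibre lengths 12–55 mm.  Three structural regularities of
real limbs are imposed rather than left to chance:

* **Excursion scales with relative tendon length.**  Primary moment arms are
  sized so the MTU's excursion over the full range-of-motion box is at least
  `max(0.5, 0.14·L_S/ℓₒ)·ℓₒ`.  In real limbs, long-tendoned distal muscles
  cross large-excursion joints; without this, a long compliant tendon's
  stretch across activation states can exceed the whole MTU excursion and
  the fibre range would (correctly but unrealistically) exceed the MTU
  range.
* **Antagonist capacities are matched.**  Within each antagonist pair the
  moment capacities `F_max·r` agree to within a few-fold jitter.  With
  independently sampled strengths, a weak-lever muscle facing a strong
  antagonist has its force transients absorbed by cheap co-contraction in
  the optimum, and activation recovery is then limited by the redundancy
  itself rather than by the solver.
* **Long relative tendons belong to multi-joint muscles.**  Monoarticular
  pair muscles sample `L_S/ℓₒ` in 0.05–3; the 3–8 band is reserved for the
  biarticular extras, as in the reference architecture, where the extreme
  ratios are all multi-joint digit flexors.

Gait trials are forward-generated: smooth two-harmonic periodic kinematics
inside the joint ranges (walk 0.39 m/s at duty factor 0.71, grounded run
1.39 m/s at 0.57; stride times 0.70/0.55 s chosen for a ~0.5 kg biped),
smoothed-boxcar ground-truth activations (stance bursts for positive-arm
muscles, weaker swing bursts for their antagonists, amplitudes ≤ 0.8), each
MTU's contraction dynamics integrated along its path by an implicit adaptive
scheme (Radau, rtol 1e−8) with one warm-up stride, and external moments
*defined* as the summed tendon-force moments (plus optional Gaussian noise).
Burst transition widths satisfy `w·T ≥ ~2 τ_deact` so the implied
excitations stay in [0, 1] and are no sharper than ~0.14 stride, and bursts
sit ~2 widths inside the stride so activations and their rates vanish at the
boundaries.  Both choices exist because the inverse problem is regularised:
it imposes no initial/final conditions (truth edge transients would not be
recoverable even in principle), and its rate-smoothing term makes sharing
sharp force transients between antagonists genuinely optimal, so a recovery
experiment about solver correctness must keep the truth's transients gentle
enough that this regularisation bias stays well below the recovery
tolerance.  Walking uses activation amplitudes of 0.25–0.45 and running
0.35–0.55 (antagonist swing bursts at 60% of that).

What passing recovery tests shows: the transcription, dynamics, equilibrium
and moment balance are mutually consistent, and the optimizer finds the
generating solution when the problem is identifiable.  What it does not
show: robustness to measurement noise, soft-tissue artefact, model-form
error in geometry or curves, or redundancy of real 36-muscle limbs — real
data have all of these, and there the reserve actuators and the tuning
penalties do real work rather than remaining at zero.

### Identifiability of the tuning factors

Fibre-length tuning is only informative when the data visit parts of the
force–length curve whose shape depends on `ℓₒ`.  If every muscle fires near
`ℓ* = 1`, the same moments are reproducible at `p_ℓ = 1` with *lower*
activation cost, and the penalty `w5 (p_ℓ−1)²` then correctly parks the
factor near 1.  Two further confounds matter: slack-length tuning can mimic
fibre-length tuning for muscles with `L_S ~ ℓₒ` (and is cheaper under
`w6 < w5`), and the penalties always bias the recovered factor toward 1 by a
margin set by the strength of the identifying signal.  The recovery
experiment therefore tunes the *short-tendon* muscle (`L_S ≪ ℓₒ`, so the
slack channel is bound-limited) and poses it slightly stretched
(`ℓ*` ≈ 1.15 at the neutral pose via `make_toy_limb(ln_mid=...)`), so its
passive force participates in the joint moments during the stride:
underestimating `ℓₒ` then produces excess passive force that cannot be
cancelled (activations are non-negative), and overestimating it demands
costly active substitution.  This is experiment design, not tolerance
tuning; with the default near-optimum posing the recovered `p_ℓ` is ≈ 1.01
for a generating value of 1.1, and that outcome is itself the scientifically
correct answer to an unidentifiable question.

## Static posture battery

Poses are sampled uniformly and independently per actuated DOF (the
reference protocol says only "random"); overridden DOFs are held fixed.
Four simulations per pose; gravity and inertia are excluded throughout, so
the whole-limb constraint is zero net muscle moment.  Within each pose the
monotone activation→force map of each muscle is tabulated on a 13-point
activation grid by vectorised bisection and replaced by a cubic polynomial
surrogate inside the per-pose SLSQP problems (the map is near-linear for
stiff tendons; surrogate error is far below the optimizer's tolerance).
Final states of viable poses are re-solved exactly, so reported equilibria
satisfy the residual to < 1e−6 independent of the surrogate.  Feasibility
(filter rule i) is declared failed only after a least-squares moment
residual stays above tolerance from 3 seeded starts; maximisation
(simulation 2) likewise uses 3 seeded multistarts.  Filters are applied in
order — (i) whole-limb equilibrium impossible, (ii) `l_MT < L_S` per MTU in
the isolated simulations, (iii) per-MTU `l_MT` cap (e.g. 80 mm for a muscle
whose geometry model misbehaves at extremes) — and the first failure is the
recorded reason.

## Range analysis

Hyperplane fits use the Moore–Penrose pseudoinverse of the ones-augmented
angle matrix (minimum-norm least squares; exact for rank-deficient designs),
reporting r², RMSE and the maximum absolute error; r² is flagged undefined
when the observations have zero variance rather than reported as 0 or 1.
Force–length regions default to steep ascending < 0.80 ≤ shallow ascending
< 0.95 ≤ plateau ≤ 1.05 < descending — conventional, approximate divisions,
fully configurable because no exact boundaries are canonical.  Histograms
bin `ℓ*` at 0.02 widths.  Decoupling regressions (fibre range / normalised
MTU range against pennation and against `L_S/ℓₒ`) use ordinary least
squares; a zero-variance predictor is reported as degenerate, and the whole
regression errors only if every predictor is degenerate.

## Problem sizes

The shipped study runs at desk scale: 4-MTU/2-DOF limbs, 101-sample strides,
50 collocation intervals per trial for activation recovery (20 for the
tuning-recovery experiment), 250–400 NLP iterations, and 5,000-pose
batteries.  These sizes give stable recovery statistics while keeping a full
test run in minutes; they are configuration, not limits — mesh, pose counts
and limb sizes all scale through the public interfaces.

## Known limitations

* No fibre-type heterogeneity, history dependence, or aponeurosis model.
* Geometry is rotation-only and polynomial; no joint translations.
* The NLP uses finite-difference constraint Jacobians (grouped on the exact
  sparsity); an algorithmically differentiated implementation would converge
  in fewer iterations on large problems.
* `trust-constr` reports slow tail convergence on these problems; runs are
  iteration-capped and feasibility-checked rather than run to strict
  first-order optimality, which is adequate for recovery but would need
  revisiting for publication-grade objective values.
* The battery's simulation-2 maximisation is non-convex; 3 multistarts are a
  heuristic, and distinct local optima are possible at some poses.
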