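# Methods

## Model

The package analyzes modulation within a two-state (resting ⇌ active)
cyclic co-agonist scheme. Every ligand — transmitter, anesthetic, or
allosteric modulator — is a co-agonist characterized by its resting-state
dissociation constant K_R and its gating efficacy c, the ratio of active-
to resting-state dissociation constants. Each of N equivalent, independent
sites multiplies the equilibrium by the occupancy bracket, so the state
function in a background of open probability p is

    P_A(L) = 1 / (1 + ((1−p)/p) · [(1 + L/K_R)/(1 + L/(K_R·c))]^N).

Assumptions worth making explicit:

* **Binary gating.** All functional states collapse onto resting/active;
  desensitization, sub-conductances and kinetics are outside the model.
* **Saturation.** Efficacy estimation uses the L → ∞ limit (bracket → c).
  Operationally a concentration ≥ 1000·K_R is treated as saturating; the
  occupancy bracket converges to c at rate ~|1−c|/1000, so the limit form
  is accurate to ≲1e-3 relative for potentiator efficacies at that
  concentration. Callers assert saturation on the `ActivationPair`; the
  package does not infer it. In mutants the same concentration may no
  longer saturate, in which case the estimated c is an effective value
  (affinity and efficacy changes are confounded).
* **Site-count conventions.** N is imposed, not fitted: 2 by default (the
  convention for the α7-PAMs, etomidate and the neurosteroid), 4 for
  propofol. c depends on N; ΔG = N·RT·ln(c) does not, which is why group
  comparisons are made on ΔG.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| RT | kcal/mol | 0.5925 | R = 1.987e-3 kcal/(mol·K) at T = 298.15 K; configurable, echoed in run manifests |
| N (site count) | — | 2 (propofol 4) | field convention; per-compound override map |
| z quantile | — | 1.96 | normal-approximation 95% intervals for ΔΔG (see below) |
| clamp ε | probability | 1e-12 | guards log/ratio arithmetic at exact 0/1 without altering any measurable value |
| constitutive thresholds | probability | 0.01 / 0.02 | below 0.01 the low-agonist background needs no constitutive correction; above 0.02 the cell is measured by direct activation |
| measurement CV | relative | 0.05 | multiplicative probability noise in the simulator |

The recording temperature behind RT is recorded as configurable metadata
rather than asserted; published energies are consistent with ~298 K.

## Normalization and protocols

Per cell, currents are anchored between a picrotoxin reference (P_A = 0)
and a GABA + propofol reference (P_A = 1); the mapping is linear and
affine-invariant (offset and gain in the recording chain cancel), and both
current polarities are accepted. Protocol selection depends only on the
cell's constitutive activity: strictly above 0.02 the modulator is applied
alone and the constitutive activity is the background; at or below 0.02
the background is the low-agonist steady state. In the 0.01–0.02 band no
published correction rule exists; the background is used unchanged and the
record carries an audit flag (`correction_flag`), surfaced in CLI output,
so the affected cells are identifiable. Per-cell estimation always precedes
aggregation: c and ΔG are computed cell by cell and then summarized as
group mean ± SD, never recomputed from group-mean probabilities (the
inversion is nonlinear, so the order matters).

## Coupling energies and additivity

ΔΔG = mean ΔG_mut − mean ΔG_wt with se² = sd²_wt/n_wt + sd²_mut/n_mut and
a z = 1.96 normal interval. A t-quantile would be defensible at these group
sizes (n = 5–25); the z convention is adopted because it exactly reproduces
the published intervals, and the difference is documented rather than
hidden. When summing ΔΔG values across interfaces, component variances are
added as if independent even though each ΔΔG contains the same wild-type
term; this is the default reporting convention (again matching the
published sums), and a covariance-aware mode
(`additivity_sum(..., wildtype=...)`, k shared terms contributing k²·var_wt)
is available for methodological comparison — it widens the interval, so the
default is the anti-conservative choice for the additivity test. The
verdict is boundary-inclusive: additive iff −ΔG_wt ∈ [ci_low, ci_high] of
the sum.

## Synthetic data

`simulate_cells` draws per-cell constitutive and background activities from
truncated normals (rejection sampling within (0.005, 0.95), 10,000-draw
cap), computes the modulated probability through the saturating state
function with the group's true efficacy, and applies multiplicative
Normal(1, CV) noise to the observed probabilities. Multiplicative noise was
chosen because it reproduces the pattern that group SDs of c scale with c.
Protocol assignment then follows the same constitutive-activity rule as
real data, so high-constitutive mutants are automatically analyzed by
direct activation. `simulate_amplitudes` maps probabilities back to
currents between explicit anchors (inverse of the normalization) with
optional additive amplitude noise. All randomness flows from a single seed;
identical seeds give bit-identical tables.

What the generator emulates: per-oocyte scatter in background activity,
measurement noise on probabilities, group sizes, and the protocol split.
What it does not: trace-level kinetics (wash-in/wash-out, desensitization),
concentration–response structure (everything is at saturation), and any
correlation between a cell's background activity and its noise level.
Passing recovery tests therefore shows the estimation chain is unbiased
under the assumed noise model, not that real recordings meet that model.

Simulation presets mirror the published group statistics (wild-type
background 0.05 ± 0.03 at n = 25, mutant constitutive activities and group
sizes as reported). For the one cycle receptor without a published
background (α1(Y293C)) the wild-type low-agonist background 0.06 ± 0.03 is
assumed.

## Numerical notes

* Probabilities are validated against [0, 1] and clamped to
  [1e-12, 1 − 1e-12] before ratio arithmetic. The efficacy inversion
  computes (1 − p)/p (exact subtraction for p ≥ 0.5) rather than 1/p − 1.
* The inversion is an exact right-inverse of the saturating state function
  to 1e-9 relative wherever the modulated probability lies in
  [1e-7, 1 − 1e-7]. Closer to saturation the spacing of double-precision
  floats near 1 quantizes 1 − p in steps of ~1.1e-16, capping the
  recoverable efficacy precision at ~1.1e-16/(N·(1−p)); at the most extreme
  admissible corner (background 0.999, c = 0.01, N = 4, modulated
  probability within ~1e-11 of 1) this is ~1e-5 relative regardless of
  implementation. The test suite asserts the 1e-9 contract in the
  representable regime and a 1e-4 bound in that corner.
* Fold-potentiation curves reject grid points at exactly 0 or 1; the fold
  tends to 1 as the background approaches saturation (ceiling effect) and
  is strictly decreasing in background for c < 1.
* Degenerate normalization anchors (zero span relative to machine
  tolerance) raise rather than return infinities.
* Monte-Carlo checks of the analytic ΔΔG intervals draw group means from
  Normal(mean, sd/√n) and compare 2.5/97.5 percentiles at 100,000 draws;
  agreement within 0.02 kcal/mol on every published group.

## Problem sizes used in the test suite

Recovery checks use 200 simulated cells per group at 5% CV; power checks
use 200 replicate four-group studies at the published group sizes
(25/5/5/5); the Monte-Carlo CI oracle uses 100,000 draws per group; the
protection null-calibration uses 1,000 replicate two-group draws. The whole
suite runs in well under a minute on one core.

## Known limitations

* K_R is never fitted; all analyses assume a single near-saturating
  concentration, so affinity changes in mutants masquerade as efficacy
  changes.
* The additivity test inherits the normal approximation and the
  independence convention for the summed variance; with n = 5 groups the
  intervals are approximate.
* SCAMP quantification provides pairwise Welch comparisons; omnibus ANOVA
  across protectant groups is delegated to standard statistical packages.
* The 0.01–0.02 constitutive band is flagged, not corrected — there is no
  principled correction without a model of how constitutive and
  agonist-driven activity combine in the measured background.
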