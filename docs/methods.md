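# Methods

`wormstates` segments single-animal centroid tracks into locomotive
behavioral states with a hidden Markov model, then analyzes the geometry
of the discovered state space and the behavioral similarity between
recordings. This note describes the model, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Motion reduction

Three consecutive centroid positions carry six degrees of freedom, three
of which describe the dish, not the animal. The invariant description is
a reversal bit `r`, a speed `s`, and an acceleration two-vector
`a = (a_t, a_r)` in a frame aligned with the direction of motion. With
velocities `v1 = (p2-p1)/dt`, `v2 = (p3-p2)/dt`, `u = v1+v2`,
`w = v2-v1`:

* `r = 1` iff `|w| > |u|`, equivalently iff the heading changes by more
  than 90° (`v1·v2 < 0`). Ties break to `r = 0`.
* The direction vector `D` is `u` for a non-reversal and `v1 - v2` for a
  reversal; `s = |D|/2` (the mean-velocity magnitude in the non-reversal
  branch). The laboratory acceleration is the conventional `w/dt` for a
  non-reversal and the unconventional `u/dt` for a reversal, rotated into
  the frame whose x-axis is `D/|D|`, with the first row of the rotation
  negated in the reversal branch.

Two properties pin this construction down: both components of `a` are
continuous across the branch switch (verified by a boundary-perturbation
test), and the map positions → `(r, s, a)` is exactly invertible up to
rigid motion (verified to 1e-9 on 10⁴ random frames). An animal that
exactly reverses and ends where it started one step earlier is measured
as having zero acceleration. A triple of three identical points is the
degenerate zero frame, kept (flagged) rather than rejected because
quiescent recordings contain such frames.

Frames are computed only over consecutive valid triples whose spacing is
within 10% of the nominal `dt` (1 s); frames touching gaps are
invalidated and later bridged by transition-only steps in the HMM.

Speed and acceleration magnitude are strongly right-skewed; both are
deskewed with `asinh(x/x0)`, linear below `x0` (where measurement noise
dominates) and logarithmic above. The offsets are fixed at
`s0 = 1 µm/s`, `a0 = 1 µm/s²` — the scale of the position measurement
error — rather than estimated from data, so different datasets remain
comparable.

## States and emissions

A state is seven numbers: reversal probability `p_rev`; means `mu_s`,
`mu_a` of deskewed speed and deskewed acceleration magnitude; variances
`var_s`, `var_a`, `var_ar` (deskewed radial acceleration has mean fixed
at zero — dorsal/ventral orientation is unknown and assumed random); and
the speed/acceleration covariance `cov_sa`.

The emission density is a Bernoulli term for `r` times a
three-dimensional fat-tailed kernel over `(s_hat, a_hat, ar_hat)`:

    f(x) ∝ (1 + d²/ν)^(-(ν+1)/2),   d² = (x-µ)ᵀ Σ⁻¹ (x-µ)

normalized by `Γ((ν+1)/2) / (Γ((ν-2)/2) (νπ)^{3/2} |Σ|^{1/2})` (checked
against 3-D numerical quadrature to 1e-3). `ν = 5` is the smallest
integer for which this density has a finite mean (ν > 3) and variance
(ν > 4) in three dimensions. The tail matters: with Gaussian emissions a
single outlier frame yields astronomically lopsided likelihood ratios
and forces spurious state switches; with the t kernel at unit scale the
ratio between states one unit apart never exceeds
`((11+√21)/10)³ = 3.784` (attained at `x = (3+√21)/2`), so isolated
outliers cannot overcome the transition penalty. Σ is the plug-in
matrix of weighted sample moments, used directly in the Mahalanobis
form; the kernel's true covariance is `ν/(ν-4) · Σ`, but the fitting
scheme is deliberately self-consistent in moment space rather than
moment-matched.

Numerical guards: a variance floor of 1e-6 (deskewed units²) keeps Σ
positive definite on immobile segments; `p_rev` is floored at 1e-12 away
from {0, 1} so Bernoulli log terms stay finite; `cov_sa` is clipped to
0.999·√(var_s·var_a).

## Transitions and decoding

Transitions are parameterized by a lifetime τ: stay probability
`exp(-dt/τ)`, with the remaining mass split evenly among the other
states (this preserves τ as the mean lifetime for any state count; the
documented two-state penalty of 86,400 per second at τ = 1 day becomes
2× larger per pairwise alternative at m = 3). τ is best understood as
the weight of evidence needed to recognize a switch — three consecutive
points each favoring another state 50-fold overcome the one-day penalty
— not as a constraint on observed lifetimes, which come out in the 1–2
minute range regardless. Defaults: τ = 86,400 s for steady-state
analyses, 300 s for time-resolved ones.

Decoding uses the scaled forward–backward recursion (per-row max-shift
plus normalization constants; the total log-likelihood is recovered from
the scaling factors and verified against a pure log-space recursion and
against exhaustive path enumeration at small N). Invalid frames emit
nothing and contribute transition factors only, which interpolates the
posterior across gaps. Log-likelihoods are kept in nats internally and
converted to bits only in excess-entropy and dissimilarity reporting.

Re-estimation is posterior-weighted moments with the `N/(N-1)` bias
correction for plug-in means (`var_ar` is the uncorrected weighted mean
square, since its mean is fixed at zero). These are not maximum
likelihood estimates; the closed loop can show tolerance-scale wiggle in
likelihood.

## Fitting protocols

*Open loop*: one decode under fixed states, one re-estimation.
*Closed loop*: iterate decode/re-estimate to a fixed point
(max |Δparameter| < 1e-4, max 200 iterations), with transitions held at
the lifetime form and the full second-moment block (variances *and*
covariance) pooled across states as an N-weighted average — pooling the
covariance too keeps the pooled block automatically positive definite,
and a weight-average of per-state PD blocks is PD. After convergence,
one relaxation pass re-estimates per-state variances freely and takes a
single Baum–Welch step on the transition matrix. *Unbiased fit*: the
one-state fit (global moments) is split by cloning the state and adding
0.1 deskewed-speed units to the clone's mean (≈10% of a typical dynamic
range); after the two-state closed loop converges its fastest state is
split the same way. The fit with the highest excess entropy wins, ties
to fewer states. A split is abandoned if any state's posterior mass
falls below 2 points.

The split-the-fastest seeding has a basin-geometry requirement worth
knowing: with three well-separated states it recovers all three reliably
when the middle state is closer (in pooled-σ units) to the fast state
than to the slow cluster, because the two-state stage first isolates the
slow cluster and the three-state split must then pull the middle state
off the fast one. The canonical synthetic triplet is placed accordingly
(see below); clouds violating this geometry can converge to a duplicated
fast state and select two states.

Excess entropy of a fit, `S = H(p̄) − (1/N) Σ_t H(p_t)` in bits per
point, is the model-selection criterion: it is 0 for time-constant
posteriors, at most log₂ m (1 bit for two states, 1.58 for three), and
measures how much time-resolved structure the fit extracts beyond
overall occupancy. The forecaster worked example (three equally accurate
weather forecasts of increasing sharpness: 0, 0.094, 0.59 bits/day) is
kept as an executable fixture.

*Scramble control*: permuting the valid frames of a series destroys
temporal structure while preserving marginals. Scrambles are re-fit with
the unbiased protocol; their excess entropy collapses because the pooled
variances of the discovery loop bound the emission ratios. Note that a
*fixed-states* fit with sharply separated standard states does not
collapse on scrambles — per-frame density ratios on caricature-grade
synthetic states can exceed the τ penalty for adjacent same-state pairs
— which is why the null distribution machinery defaults to the
discovery protocol on synthetic data.

*Standard states* pool, per pure-play condition, the most probable state
of each track's unbiased fit: means are N-weighted averages of per-track
means; second moments are taken about the common pooled means and so
include the between-track component (law of total variance — pooled
variance is never below the weighted mean of within-track variances).
*Typical segments* standardize top-state descriptions to unit SD, pick
the track closest to the pooled mean (ties to the lowest index), and
return the central 90 s of the longest run with top-state posterior
≥ 0.99.

## State-space geometry

Discovered states form a probability-weighted cloud of 7-vectors.
Parameters are standardized to weighted mean 0 / SD 1 (constant
parameters standardize to zero), PCA diagonalizes the weighted
correlation matrix, and triangularity of the first two components is
measured as `t = hull area / minimal-enclosing-triangle area` (1 for a
triangle, π/(3√3) ≈ 0.605 for a disc). Hull and triangle are
weight-free; weights enter only the PCA and the optional π > 0.1 filter.

The minimal enclosing triangle always has one side flush with a hull
edge. The search fixes each edge normal as one side direction and
optimizes the other two support-line angles with a vectorized zoom-grid
refinement (17-point grids, 4 levels, 24 refinement candidates across
all edges); corner optima with two or three flush sides are evaluated
exactly from all hull-edge-normal triples. The test suite retains an
independent Nelder–Mead flush-edge search as an oracle (agreement within
0.1% on random clouds).

Significance comes from permuting the second component only (the same
x's and y's re-paired at random, default 10⁴ permutations) with the
add-one p-value estimator `(1 + #{t* ≥ t}) / (1 + n_perm)`, which cannot
return zero.

## Dissimilarity and embedding

With `L(A|M)` the log-likelihood per valid point (bits) of record A
under model M, model dissimilarity is the symmetrized gap
`½[(L(A|M_A) − L(A|M_B)) + (L(B|M_B) − L(B|M_A))]`; the ½ makes it the
mean per-direction gap and the four-term form is forced by symmetry and
zero self-dissimilarity. The state-probability term is the N→∞
multinomial limit `Λ(A|B) = Σ q_i log₂(p_i/q_i) ≤ 0` (−KL; verified
against exact multinomial log-probabilities at N = 10³–10⁴), with zero
occupancies floored at 1e-12 rather than mapped to infinity. Fit
dissimilarity is the sum of both; state dissimilarity repeats the model
term with the fitted transition matrices replaced by the plain lifetime
form, so only state parameters inform the cross fit — with the
documented failure mode that a state absent from one record inflates it
even when the state definitions agree.

Fit dissimilarity is not a metric. A distance is derived by all-pairs
shortest paths on the complete graph with edge weights `D_ij + c`, with
`c` chosen to maximize the reflective correlation
`ΣAB/√(ΣA²ΣB²)` between graph distances and raw dissimilarities
(25-point grid bracketing plus bounded scalar polish; ρ(c) is smooth and
unimodal in practice). MDS starts from Torgerson double-centering (or
PCA scores for state clouds) and minimizes the spring potential
`Σ w_ij (|x_i−x_j| − D_ij)²` by L-BFGS with an analytic gradient
(pairwise weights `π_i π_j` for states, 1 for tracks); stress is the
unweighted `√(Σ(|x_i−x_j|−D_ij)²/ΣD_ij²)`.

The starvation-recovery trend test regresses mean dissimilarity per time
separation on the separation, weighting each group mean by its pair
count (the variance of a group mean scales as 1/count; the weighted
regression keeps the slope p-value calibrated under pair-level noise).
Pairs of adjacent 15-minute cuts are excluded by default, since a state
straddling the cut boundary makes contiguous cuts artificially similar.

## The synthetic-data generator

The generator emulates the recording conditions the analysis targets:
1 Hz centroid sampling in µm, recordings 30–240 min, Markov switching
with lifetimes of tens of seconds to minutes, and ~1 µm position noise
with a 3:1 anisotropy along a fixed body axis.

Characteristics are drawn from the heavy-tailed family *moment-matched*
to the state description — a multivariate t with ν−2 degrees of freedom
and scale `Σ(ν−4)/(ν−2)`, whose covariance is exactly Σ — so sample
moments of the draws reproduce the state parameters and parameter-
recovery tests compare like with like. (The plug-in emission density
used in fitting is intentionally *not* moment-matched; see above.)
Draws violating `a_hat ≥ |ar_hat|` — impossible for real frames, since
the acceleration magnitude bounds its radial part — are redrawn, with a
configuration error above 50% rejection. The redraw couples weakly to
the t mixing variable, so second moments of states whose `mu_a` is small
relative to √var_ar shift slightly; the canonical states keep var_ar
small enough that the effect is below Monte-Carlo noise. Deskewed speed
may be negative in a drawn series (the fitted density also puts mass
there); such frames are valid observations but not realizable positions.

Position tracks are synthesized by chaining canonical triples. Exact
realization of an independently drawn frame at *every* interior
timepoint is impossible — consecutive triples share a velocity whose
magnitude both frames would have to prescribe — so drawn frames are
realized exactly at alternating interior timepoints, rotated to continue
the previous heading; the intermediate frames are continuity byproducts.
Zero-noise round trips recover the drawn characteristics at the realized
timepoints to 1e-9. Frames not realizable as positions (negative speed,
or `a_mag·dt > 2s`) are redrawn for track synthesis only.

The canonical study triplet (`three_state_example`) is: roaming
(p_rev 0.02, mu_s 3.7 ≈ 20 µm/s, mu_a 1.5), dwelling (p_rev 0.30,
mu_s 2.6 ≈ 6.7 µm/s, mu_a 1.2, cov_sa 0.10), quiescence (p_rev 0.05,
mu_s 0.25 ≈ 0.25 µm/s, small variances), lifetimes 90/60/120 s. The
dwelling state sits closer to roaming than to quiescence in deskewed
speed — both a realistic picture (dwelling worms still progress at a few
µm/s while quiescent worms sit at the noise floor) and the geometry the
split-the-fastest discovery protocol requires (see above). End-to-end
tests use series of 3600 points (one hour at 1 Hz) and cohorts of 20
tracks of 1200 points; these sizes keep every check comfortably
repeatable while leaving clear statistical margins.

A note on the noise floor: with i.i.d. per-frame position noise of
standard deviation σ, the branch-selected speed of a pure-noise triple
averages ≈1.1σ (the reversal branch usually wins on noise). The
immobilized-worm calibration (mean 0.32 µm/s, 99.7% below 1 µm/s) is
reproduced at an effective σ ≈ 0.3 µm; real border-pixel noise is
evidently partly correlated between frames, so the single-frame position
error and the effective i.i.d. noise are not the same number. The
generator's default σ = 1 µm describes the position error; the
calibration test uses σ = 0.3 µm and documents the ≈1.1σ speed floor.

## Known limitations

* The discovery protocol explores at most three states and inherits the
  basin-geometry requirement described above.
* The emission density assigns mass to negative deskewed speed and
  ignores the `a_mag ≥ |a_r|` constraint; it is an approximation by
  construction.
* Model selection by excess entropy can prefer a duplicated-state fit by
  a noise-scale margin on data whose true state count is lower; ties
  break to fewer states only at exact equality.
* The synthetic generator draws frames independently given the state;
  real locomotion has within-state autocorrelation (body waves), so
  passing recovery tests demonstrates correctness of the machinery, not
  realism of worm behavior.
* Position-level simulation controls every second frame exactly; tests
  of full-rate per-frame statistics should use characteristic-level
  simulation.
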