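# Methods

## Generative model

Neural dynamics are one-state, deterministic and bilinear over four
regions in fixed order (IFG, Cau, GP, Thal):

    dx/dt = J(u) x + C u,
    J(u)[i,k] = A[i,k] + Σ_j u_j B_j[i,k]        (i ≠ k, in Hz)
    J(u)[i,i] = −0.5 · exp(A[i,i] + Σ_j u_j B_j[i,i])

The exponential self-connection parameterization guarantees strictly
negative effective self-connections for every admissible parameter
value, which is what keeps the prior predictive dynamics mostly stable.
Two condition inputs (Go, NoGo) act as both modulators (B) and drivers
(C).  Inputs are block-level boxcars built at microtime resolution and
mean-centered over the session, so A is the mean effective connectivity
across conditions; consequently the model's "rest" baseline carries a
small constant input offset that is absorbed by run-intercept confounds
at the observation level.

Each region's activity enters a balloon/Windkessel cascade
(vasodilatory signal s, inflow f, volume v, deoxyhemoglobin q):

    ds/dt = x − κs − γ(f−1);  df/dt = s;
    τ dv/dt = f − v^{1/α};    τ dq/dt = f·(1−(1−E0)^{1/f})/E0 − v^{1/α} q/v

with BOLD output y = 100·V0·(k1(1−q) + k2(1−q/v) + k3(1−v)) in percent
signal change, using the revised coefficients k1 = 4.3·ν0·E0·TE,
k2 = ε·r0·E0·TE, k3 = 1−ε.  Defaults: κ = 0.64 s⁻¹, γ = 0.32 s⁻¹,
τ = 2.0 s, α = 0.32, E0 = 0.4, V0 = 0.04, TE = 0.03 s, ν0 = 40.3 s⁻¹,
r0 = 25 s⁻¹, ε = 1 — canonical published values for 3T; all
configurable.  (s, f, v, q) = (0, 1, 1, 1) at x = 0 is an exact fixed
point, so a zero model produces an exactly flat signal.

### Integration

Fixed step at microtime dt = TR/16.  Inputs are piecewise constant per
microtime bin, so the neural subsystem is advanced *exactly* over each
bin with the augmented matrix exponential
exp(dt·[[J, Cu],[0, 0]]) — both the propagator and the affine drive
term in one well-conditioned operation, cached per unique input
combination (a session has only ~3: Go block, NoGo block, gap).  The
hemodynamic states advance by classical RK4 using the exact neural
activity at half- and full-step.  Halving dt changes sampled BOLD by
< 1e-4 (asserted in the tests).  Integration is batched over parameter
sets (a numba kernel advances all batch members simultaneously), which
is what makes finite-difference sensitivities affordable.  Simulations
whose activity exceeds |x| = 1000 or whose hemodynamic states leave the
physical domain fail loudly, naming the offending batch member.  Runs
restart from rest; there is no dynamic carry-over between runs.

## Synthetic cohorts

The paradigm generator reproduces the emulated design exactly: 2 runs ×
12 blocks (6 Go, 6 NoGo, order randomized per run by the paradigm
seed); Go blocks hold 18 Go trials, NoGo blocks 12 Go + 6 NoGo trials
(33.3% NoGo within block).  Trial SOA (2 s) and inter-block gap (10 s,
also the initial rest) are this package's own timing choices — the
emulated design does not fix them — yielding 562 s runs at TR = 2 s
(281 volumes).  Counts are deterministic; only ordering is random.

Ground-truth group connectivity encodes the reported sign pattern:
intrinsic IFG→Thal and IFG→Cau negative; Cau→IFG, Cau→GP, GP→Thal,
Thal→GP positive (±0.2–0.25 Hz); self log-scalings −0.1 (IFG, Cau,
Thal) and +0.1 (GP); NoGo modulation with IFG→Cau, IFG→Thal at −0.25
and GP→Cau at −0.15 (Go counterparts −0.05, −0.05, +0.10); NoGo drive
into all four regions, Go drive into IFG only.  Magnitudes are
configuration values chosen once for dynamical stability and realistic
1–2% BOLD amplitudes; they are not empirical estimates.

Between-subject structure: iid N(0, 0.05²) deviations on every A/B/C
entry; a sex difference (female − male) of −0.1 on A[GP,Thal] and +0.1
on the NoGo thalamic self-modulation; a slope of 0.003 Hz per
percentage point of mean-centered NoGo accuracy on B_NoGo[IFG,Thal].
Observation noise is set per region from the requested SNR
(std(signal)/std(noise), default 1 — a typical event-related regime).
Behavioral accuracies are truncated-normal draws (NoGo 70.34 ± 15.6%,
Go 98.47 ± 3.4%), trial correctness is Bernoulli, and reaction times
are a 150 ms shift plus a lognormal with mean tuned so correct-Go RT
averages 314.44 ms.  All randomness descends from one master seed via
per-subject substreams; a cohort is a pure function of its
specification.

What the generator does not emulate: physiological/scanner noise
autocorrelation and drift, motion, spatial hemodynamic variability,
emotional-valence manipulations, and session effects.  Passing tests
therefore demonstrate correctness of the machinery under idealized
noise, not performance on real data.

## Variational Laplace

Priors (configurable): N(0, 1/16) on A off-diagonal, B and C entries;
N(0, 1/256) on self-connection log-scalings and on log deviations of
the hemodynamic transit time and signal decay (per region); switched
off parameters have zero prior variance and never move.  Noise is iid
per region with log precision λ_i; the hyperprior is N(4, 16).  The
wide hyperprior variance is deliberate: at SNR 1 in percent-signal
units the true log precisions sit around −1…1.5, and a tight hyperprior
centered at 4 would pin the noise estimate an order of magnitude too
low, overfitting the data and corrupting the posterior.

Each iteration computes the Jacobian of the predicted (confound
filtered) signal by forward finite differences, all parameters in one
batched integration (step 1e-3 prior SD), then takes a Levenberg-damped
Gauss–Newton step; candidate noise precisions come from Newton
fixed-point updates of the λ-objective (concave in λ) and are discarded
if they lower F.  Damping halves on acceptance, doubles on rejection
(floor 1e-4).  Because the Laplace F depends on the linearization
point, candidates are judged against a reference free energy computed
under the *current* Jacobian; the recorded trace keeps accepted new
highs, so it is non-decreasing by construction.  Convergence: ΔF < 1e-4
for four consecutive accepted steps (cap 128 iterations); a stall whose
best candidate is within 0.5 nats of the optimum also counts as
converged, anything worse sets the convergence flag false with
diagnostics.  On linear problems the implementation reproduces the
exact Bayesian linear-regression posterior and log evidence (to 1e-6
and better), which the tests use as the closed-form oracle.

Confounds: per-run means are projected out of data and predictions
(run-intercept baseline); the synthetic data carry no drift, so no
further filtering is applied at the inversion stage.  Explained
variance is 100·(1 − SS_res/SS_tot) of the filtered data against the
posterior-mean prediction, pooled over regions and volumes; the
inclusion rule excludes subjects below 10% and reports Welch t-tests
comparing included vs excluded behavior as a selection-bias check.

## Group level (PEB / BMR / BMA)

Second-level model: θ_i = (x_i ⊗ I)β + ε_i with ε_i ~ N(0, Σ_b),
Σ_b = exp(−γ)·(first-level prior variance)/16, a single γ with
hyperprior N(0, 1/16) optimized by bounded scalar search on the exact
(given γ) marginal evidence; β then has an exact Gaussian posterior.
Design columns: intercept, sex (±0.5), mean-centered NoGo accuracy,
optionally mean-centered age; separate PEB runs per parameter block
(A, B or C).  The β prior replicates the first-level prior variance per
covariate.

Bayesian model reduction uses the closed-form Gaussian identity in
precision form (reduced precision P_r = P + P0r − P0); "off" means
prior variance 1e-8 rather than exactly zero, keeping every precision
finite — at that scale the approximation error is far below the 1e-8
agreement with explicit refits asserted in the tests.  The greedy
search sweeps all candidate β entries, permanently switching off any
whose removal does not decrease F (re-scored against the progressively
reduced model), then exhaustively evaluates the ≤ 8 least decisive
survivors (2^8 = 256 models when 8 remain; stronger survivors stay on)
and averages the reduced posteriors under softmax(F) model weights.
Presence of a parameter is reported as model-space posterior
probability Pp (pruned → 0, fixed-on → 1), thresholded at 0.95 for
"strong evidence"; *directional* condition comparisons instead use
Gaussian tail probabilities of BMA contrasts — two complementary
framings, kept deliberately distinct.  Savage–Dickey ratios
(prior/posterior density at zero) quantify evidence against point
nulls.

The group machinery is node-set agnostic: running the identical
pipeline on a left-hemisphere (or any other) region set is pure
configuration.

## First-level GLM stage

Condition regressors are built at microtime resolution from trial
onsets, convolved with the canonical double-gamma HRF, and sampled at
TR; each run gets an intercept and a discrete-cosine drift basis of
order floor(2·duration/cutoff)+1 (cutoff 128 s); motion confounds are
appended when supplied.  Contrasts are OLS t-tests (exact match to the
normal-equations oracle is asserted to 1e-10), with one- and two-sample
second-level tests over subject maps.  ROI handling runs on small
synthetic voxel grids: the individual peak is the statistic's argmax
within atlas-mask ∩ sphere around the group peak (radius default 2
voxels ≈ 6 mm; lexicographic tie-break; fallback to the group peak if
nothing clears an optional threshold), and the region's signal is the
first principal eigenvariate, scaled by s₁/√n_voxels and sign-aligned
to the ROI mean.  Whole-brain random-field correction is out of scope;
on toy grids Bonferroni is the stated simplification.

## Behavioral statistics

With a two-level within factor, the mixed ANOVA reduces exactly to
regressions on difference scores: the inhibition main effect is the
intercept test of (Go − NoGo accuracy) on [1, sex, age], giving
F(1, n−3) — F(1, 115) at n = 118 — and the interaction is the sex term;
the between-subject sex effect uses subject means.  Partial eta squared
is F·df1/(F·df1 + df2), identical to the sums-of-squares form (asserted
against a brute-force oracle).  Cohen's d uses the pooled-SD form
d = (m1 − m2)/√((s1² + s2²)/2) with s = SEM·√n, which reproduces the
reference value 2.48 from the printed summary statistics at n = 118;
other d conventions exist, so the formula is documented and isolated.

## Problem sizes and design choices in the validation suite

The parameter-recovery study inverts 20 subjects at SNR 1 under the
full two-run paradigm — the package's standard recovery benchmark.
Group-level calibration and power studies (null false-positive rate of
Pp > 0.95; NoGo − Go contrast power at n = 30 over 20 replications) run
on emulated first-level posteriors (`synthetic_posteriors`: truth plus
iid N(0, 0.05²) estimation error), which exercises the PEB/BMR/BMA
stack at scale while keeping the suite fast; the full
inversion-to-group path is covered by the recovery study.  GLM type-I
error uses 1000 null series in one vectorized fit.

## Known limitations

- Single-subject identifiability of this design is intrinsically
  limited: the Go and NoGo boxcars are complementary (a block is almost
  always on), so A, B_Go and B_NoGo are separated mainly by the short
  inter-block gaps, and the strong GP↔Thal coupling makes their
  outgoing influences nearly collinear.  Posterior uncertainty reports
  this honestly (the posterior is approximately calibrated), the
  B_NoGo − B_Go contrast and group-level averages are well identified,
  but individual A/B entries carry substantial posterior variance at
  SNR 1.
- One-state deterministic neural model only; no stochastic, two-state,
  or nonlinear (D-matrix) variants.
- White observation noise; no serial correlation model.
- The hemodynamic model estimates only transit-time and decay
  deviations; other balloon constants are fixed at their defaults.
- The free energy is linearization-dependent; reported F values are
  those of the final accepted iterate.
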