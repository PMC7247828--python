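# Methods

This note records the models, algorithms, numerical choices, and known
limitations of the package. It complements the API docstrings; nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Oscillator models

All dynamics are Kuramoto-family phase models,

    dθ_i/dt = ω_i [+ α_i sin θ_i] + coupling_i(θ),

with four coupling variants: a global constant K (all-to-all mean field),
per-oscillator strengths K_i, an optional excitable "firing" term
α_i sin θ_i, and a general network (K/N) Σ_j A_ij sin(θ_j − θ_i) with A a
Chung-Lu random graph. For all-to-all-type coupling the pairwise sum is
evaluated through the exact mean-field identity
(K_i/N) Σ_j sin(θ_j − θ_i) = K_i R sin(ψ − θ_i), where
R e^{iψ} = (1/N) Σ_j e^{iθ_j} is the complex order parameter; the O(N²)
pairwise form is retained as a test oracle only.

Natural frequencies are Cauchy with scale γ (density γ/π/(ω² + γ²))
unless a variant specifies a uniform range. The deterministic sampler
evaluates the Cauchy quantile function at N equally spaced quantiles on
[ε, 1 − ε] with ε = 2.5×10⁻⁴ by default; the cap bounds the fastest
rotator (the Cauchy has no moments) so that adaptive integration remains
practical, and the symmetric grid suppresses finite-sample noise in R.

Detailed simulations use adaptive RK45 (`scipy.integrate.solve_ivp`) with
absolute/relative tolerances 10⁻⁷/10⁻⁴. Complete synchronization is
declared when the largest rotating-frame phase speed, v_i − dψ/dt with
dψ/dt = Im(z̄ ż)/|z|², falls below 10⁻⁴; steady-state runs integrate in
chunks of 5 time units until that criterion is met (error at t_max = 200).

Conventions: phases wrap to the half-open interval [−π, π); ψ is reported
in (−π, π]; the rotating frame subtracts the instantaneous ψ(t) per
snapshot (no cumulative unwrapping — only R and relative phases are
consumed downstream). Chung-Lu weights read w_i = N p (1 − q(i−1)/N)^r
(exponent applied to the parenthesized factor; the alternative grouping
1 − q((i−1)/N)^r is available as a variant switch), edge probabilities
P_ij = min(w_i w_j / Σ_k w_k, 1), independent Bernoulli edges for i < j,
symmetrized, no self-loops (self-coupling is dynamically irrelevant since
sin 0 = 0, but the degree κ_i = Σ_j A_ij requires the choice).

## Diffusion maps and harmonic detection

The kernel is Gaussian, K_ij = exp(−‖x_i − x_j‖² / (2ε²)), with ε
defaulting to the median pairwise distance. Density normalization
K̃ = D^{−α} K D^{−α} uses α = 1 throughout the pipelines
(Laplace–Beltrami limit: the embedding is independent of the sampling
density). The row-stochastic operator A = D̃^{−1} K̃ is diagonalized via
its symmetric conjugate D̃^{−1/2} K̃ D̃^{−1/2} (real spectrum, stable
solvers: dense `eigh` below 1500 points, Lanczos above). Eigenfunctions
are scaled so the trivial pair is (1, 𝟙), every nontrivial φ_k has norm
√n, and signs are fixed against a reference observable (first data
coordinate, or R / θ_∞ in the pipelines) so results are deterministic.
Eleven eigenpairs (constant + 10) are computed by default.

Harmonics — eigenfunctions that re-parameterize an already-discovered
direction — are detected by leave-one-out local linear regression: φ_k is
locally regressed on (φ_1, …, φ_{k−1}) with Gaussian weights of scale one
third of the median pairwise distance among the predecessor rows, the
regressed point excluded from its own fit, a ridge term 10⁻¹⁰·tr(G), and
a tiny uniform weight floor so points isolated in predictor space fall
back to a global fit instead of a singular local system. The residual is
the normalized leave-one-out error r_k = √(Σ(φ_k − φ̂_k)² / Σφ_k²);
r_1 ≡ 1 by convention. Residuals above 0.5 flag significant
(new-direction) eigenfunctions; the threshold is configurable and the
full residual spectrum is always reported so the gap is auditable.

Significance is restricted to eigenfunctions the kernel has actually
resolved. At the bottom of the computed spectrum the eigenvectors are
dominated by discretization/sampling noise — they are not functions on
the manifold, so they regress poorly on their predecessors and would be
flagged spuriously. Three guards exclude them: eigenvalues below 10⁻³ of
the leading nontrivial eigenvalue; a trailing plateau of two or more
quasi-equal smallest eigenvalues (a resolved spectrum keeps decaying);
and everything past a more-than-twentyfold drop between consecutive
eigenvalues. The guards only suppress flags — low-residual harmonics are
unaffected — and the one situation in which they could hide a real
direction (extremely anisotropic data whose second direction sits behind
a spectral cliff) is documented under limitations.

Geometric harmonics extend a function F sampled at n points to new
points: diagonalize the symmetric kernel on the samples, retain the
leading d eigenpairs (eigenvalues below 10⁻⁸ of the largest are truncated
with a warning), and evaluate f = K_new Ψ Λ⁻¹ Ψᵀ F through the
cross-kernel. With the full spectrum retained and a well-conditioned
kernel this is exact at the training points.

## Coarse-variable discovery

Phase snapshots are featurized as 200-bin histograms of the
rotating-frame phases over [−π, π] — a permutation-invariant measure of
phase clustering — normalized to unit mass. Because the kernel bandwidth
uses the median-distance heuristic, any global rescaling of the density
(counts, mass, mass/bin-width) leaves the embedding invariant; a
reference bandwidth of ε ≈ 1.54 on the density-per-radian scale is noted
in the reproduction preset. The two training trajectories start from full
synchrony (all phases π) and from incoherence (equally spaced phases) at
N = 8000, K = 2, γ = 0.5, with deterministic quantile-sampled
frequencies; 400 equidistant snapshots per trajectory are taken on
per-branch windows — t ∈ [0.5, 4] for the synchronized start (it relaxes
to the steady coherence within a few time units; the first half unit
discards the fast off-manifold transient) and t ∈ [4, 20] for the
incoherent start (the structured equally-spaced initial condition grows
much more slowly than the continuum flow). A single shared window would
oversample the steady-state plateau, where snapshot ordering is pure
noise and the rank correlation between φ₁ and R degrades. One-to-one-ness
of φ₁ against R is quantified by the
Spearman rank correlation, the fraction of ordering violations after
sorting by R, and the extreme local slopes of a moving-average fit.

## Flow pairs and the RK4-templated network

The continuum (Ott–Antonsen) reduction of the all-to-all model with
Cauchy frequencies closes the order-parameter dynamics:

    dR/dt = −γR + (K/2) R (1 − R²),   dψ/dt = 0,

with stable fixed point R* = √(1 − 2γ/K) for K > 2γ. It is a Bernoulli
ODE; u = R⁻² linearizes it and the closed-form flow and its time
inversion are used throughout (analytic oracle, rollout reference,
scheduling).

Training data are pairs (R(t), R(t+Δt)) from 2,000 fresh ensembles per
horizon (Δt ∈ {0.01, 0.05}), each with its own stratified-quantile Cauchy
frequency draw and its own initial phases: half-branch "incoherent"
(uniform random phases, R₀ ~ N^{−1/2}) and "synchronized" (identical
phases, R₀ = 1), allocated in proportion to the R-span each branch can
reach. Stratified sampling (one uniform draw per equal-probability
stratum, no tail cap) makes the empirical frequency distribution an
unbiased, low-noise draw of the exact Cauchy law; a quantile cap would
leave a deterministic offset of order the removed tail mass in R(t) just
after the synchronized start, which at Δt = 0.01 would alias into a
percent-level bias of the learned right-hand side.

Pre-integration scheduling aims at a jittered uniform grid of target
coherences. Times are fixed in advance wherever the analytic flow
predicts the trajectory well: the synchronized branch (deterministic
decay) and low targets on the incoherent branch. Mid-range targets on
the growth branch cannot be hit by any fixed schedule — the growth onset
jitters between realizations, so the realized coherence at a fixed time
is bimodal (still low, or already saturated). Those rows instead arm a
crossing trigger on a backshifted level (the analytic flow run backward
by 1.5 time units from the target) and are snapshotted a fixed 1.5-unit
delay after first crossing it. Snapshotting at a crossing itself would
condition on the noise history (first-passage selection) and measurably
bias the sampled slopes near the fixed point; during the delay that
conditioning decays at the local contraction rate while the trajectory
drifts deterministically onto the target. The realized R(t) values cover
[0, 1] with a Kolmogorov–Smirnov distance to uniform of well under 0.08
at reference scale.

Batch integration of the ensembles uses a symmetric drift–kick–drift
splitting on unit phasors z_j = e^{iθ_j}: the free rotation by ω_j is an
exact precomputed complex multiplication (hence arbitrarily fast
rotators cost nothing in accuracy or step size), and the mean-field kick
θ' = K·Im(Z z̄_j) is a midpoint (RK2) substep applied as degree-5 Taylor
rotations (kick angles are bounded by K·h ≈ 0.02, so the rotation error
is O(10⁻¹³) per step). The scheme is second order; at the default step
h = 0.01 it matches tight-tolerance RK45 trajectories of R to ~3×10⁻⁵
and reproduces a single Δt reporting leg to better than 10⁻⁶, checked in
the test suite. The kernel is JIT-compiled (numba) and advances all
ensembles as one batch, retiring each pair as it completes.

The learner embeds a feedforward sub-network f̂ (three tanh hidden layers
of 24 units, Glorot-uniform kernels, zero biases) inside one classical
RK4 step; the prediction for a pair is rk4_step(f̂, R(t), Δt) and the
loss is the full-batch mean squared error on R(t+Δt), minimized by Adam
(lr 10⁻³, β = (0.9, 0.999), ε = 10⁻⁸) with a seeded 90/10
train/validation split and no early stopping; a cosine learning-rate
decay to 10⁻⁵ is available as an option for fits that need a finer
optimization floor. Gradients are obtained by backpropagating through
all four stages of the shared sub-network. The configuration default of
10,000 epochs matches the reference protocol; the reproduction runs
train with the cosine schedule for 60,000 (Δt = 0.01) and 30,000
(Δt = 0.05) epochs because this implementation's optimizer reaches its
loss plateau more slowly (the loss, and hence the gradient scale,
carries a factor Δt², and the sparsely sampled domain edges are the
last features to converge) — training is to convergence, judged by the
loss curve, not to an epoch budget. Even at convergence the learned
right-hand side at the extreme ends of [0, 1] retains a draw-dependent
uncertainty of order ±0.01: the loss is nearly flat there (the RK4 step
damps an f-hat perturbation by a factor Δt, and only a few percent of
the pairs live near the ends), so the endpoint values follow the local
sampling noise of the edge pairs, amplified slightly by extrapolation. At the scaled-down test profile the data are noisier (fewer and
smaller ensembles) and the appropriate stopping point is the validation
plateau (10–20k epochs); training far beyond it makes the network
memorize per-pair ensemble noise. Trained networks are evaluated
directly as f̂(R), and rolled out with fixed-step RK4.

The baseline estimator forms forward-Euler slopes (R(t+Δt) − R(t))/Δt and
smooths them with a 10-harmonic geometric-harmonics fit. Note the Euler
slope itself carries an O(Δt) discretization bias (Δt/2)·f·f′ — about
+0.027 near R = 0.98 at Δt = 0.05 — which the RK4-templated model does
not, being an exact-integrator template; comparisons between the two are
made on the baseline's own terms.

For the discovered-coordinate dynamics, all snapshots of both ends of
every retained pair are rotated (ψ removed), binned, and embedded in one
joint diffusion map, so φ₁(t) and φ₁(t+Δt) share a scale; the same
training procedure then learns dφ₁/dt (50,000-epoch default — the
nonuniform sampling in φ₁ makes the regression harder, mirroring the
lower fit quality expected for the discovered coordinate).

## Effective parameters

For completely synchronized ensembles the steady rotating-frame phase of
each oscillator is a function of its heterogeneities. The output-only
informed kernel applies the diffusion map to the steady phases alone,
embedded as unit complex numbers x_j = e^{iθ_j,∞} (Euclidean distance in
the complex plane), ignoring the heterogeneity table. A single
significant eigenfunction φ₁ means the steady state is intrinsically
one-dimensional: φ₁ is a data-driven effective parameter, a possibly
nonlinear combination of (ω, K), (ω, K, α), or (ω, κ). Case-study
defaults: N = 1500 with ω ~ U[−π, π] and K_i ~ U[10, 100] (plus
α_i ~ U[−2, 2] for the firing variant; bandwidths 0.5 and 0.9), and
N = 4000, ω ~ U[0, 1], scalar K = 20 on a Chung-Lu graph with
(p, q, r) = (0.5, 0.9, 0.5) (bandwidth 2.3×10⁻²). The analytic
cross-checks are the steady-state balances
θ_∞ = ψ + arcsin(ω/(RK)) and (RK/α − 1) sin θ = ω/α (ψ = 0 frame).

The firing variant needs special care. Its term α_i sin θ_i breaks
rotational symmetry and pins the ensemble to the stationary frame, so
(a) the steady state is detected on the absolute phase velocities, and
(b) the analytic balance carries the realized steady mean phase ψ∞
explicitly — (RK_i/α_i)·sin(θ−ψ∞) − sin θ = ω_i/α_i — since no frame
choice can zero ψ∞ while preserving the equation (the familiar ψ = 0
form is recovered exactly when ψ∞ = 0). Because the balance divides by
α_i, oscillators with small |α_i| amplify any residual drift; the sync
tolerance for this variant is therefore 3×10⁻⁷ with integration
tolerances 10⁻¹²/10⁻¹⁰. The variant also relaxes slowly (a weakly damped
collective mode, relaxation times of hundreds of time units), and some
heterogeneity draws never settle at all: their attractor is a
small-amplitude collective limit cycle, not a fixed point, and such
draws raise an incomplete-synchronization error rather than producing a
dataset. The reference runs use a convergent draw.

Level sets of φ₁ in parameter space are iso-phase sets. The scattered
per-oscillator φ₁ values are transferred to a regular grid by geometric
harmonics on standardized heterogeneity coordinates (parameters have
incommensurate units; standardization makes the isotropic kernel
meaningful), then contoured by marching squares (2-D) or marching cubes
(3-D, OBJ-style text export).

## Synthetic data: what it emulates and what it does not

All inputs are simulated. The generators reproduce the study conditions:
finite Kuramoto ensembles with heavy-tailed or uniform heterogeneities,
synchronizing coupling, and observation protocols (density snapshots,
flow pairs, steady states). They do not emulate measurement noise,
missing oscillators, non-sinusoidal coupling, time delays, or spatial
embedding; passing tests therefore demonstrate correctness of the
method on clean finite-ensemble data, not robustness to experimental
artifacts. Finite-N effects are deliberately present — flow-pair slopes
carry ensemble noise that the network must average out, and coherences
below ~N^{−1/2} are unreachable, so the learned right-hand side is least
constrained at the extreme ends of [0, 1].

## Problem sizes

Reproduction presets use the reference sizes (N = 8000 / 2000 pairs for
flow learning; N = 1500/4000 for the effective-parameter studies). The
test suite runs the flow-learning checks at a scaled-down profile
(N = 2000, 500 pairs) with a correspondingly relaxed accuracy bound
(0.02 instead of 0.01), and the Chung-Lu realization-invariance check at
N = 1000 over three network draws; all other pipelines run at reference
size. The scaled profiles were chosen so the full suite completes on a
single desktop core.

## Known limitations

- The splitting integrator is specific to all-to-all mean-field
  coupling; network variants integrate with RK45.
- Harmonic detection compares each eigenfunction only against its
  predecessors in eigenvalue order, as the residual definition requires;
  a fundamental appearing after many harmonics of φ₁ is still found, but
  the residual spectrum should be inspected when the gap is small.
- The marching-squares contour accuracy is limited by the grid and by
  the geometric-harmonics transfer; near the boundary of the sampled
  parameter region the extension is an extrapolation.
- `check_one_to_one` reports rank correlation and smoothed slopes; it
  cannot distinguish a genuinely non-monotone map from snapshot noise at
  very small sample sizes.
- The significance guards treat the bottom of the computed spectrum as
  unresolved; a true manifold direction hiding behind a twentyfold
  eigenvalue drop (aspect ratios far beyond the cases treated here)
  would require inspecting the residual spectrum by hand.
- The Euclidean metric on phase densities degenerates at full synchrony
  (all mass in one bin). At reduced sampling the few near-delta
  snapshots disconnect the kernel graph of the joint flow embedding, so
  the scaled discovered-coordinate runs cap coherence targets at 0.97;
  reference-scale runs do not need the cap.
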