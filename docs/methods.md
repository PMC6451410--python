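# Methods

## The channel

The object of study is the information channel from a binary EGF pulse
train to single-cell ERK activity. Inputs are sequences of L slots of
duration T minutes; slot *i* either contains a 5-min square EGF pulse of
100 pg/ml ("1") or is empty ("0"). The output read by the receiver is the
vector of integrated ERK responses

    R_i = ∫ ERK_pp(t) dt  over  [(i−1)·T, i·T]   (molecule·s),

i.e. slot *i*'s window starts at its own pulse. Because the pathway's
response is close to all-or-nothing, the channel is approximately a noisy
version of a deterministic *transcoding* map: a pulse elicits a response
only if more than the relaxation time τ has passed since the previous
response.

## Coding theory (`theory`)

For slot time T and relaxation time τ, the refractory index is
k = max{j ≥ 0 : jT < τ} (strict inequality; with τ = 51.5 min, T = 60, 30,
20, 15 min give k = 0, 1, 2, 3). Transcoding is greedy left-to-right: an
input 1 is emitted iff no output 1 occurred in the previous k slots. This
convention (refractory window counted from the last *emitted* response)
uniquely reproduces the worked examples, e.g. '111' → '101' at k = 1 and
'111' → '100' at k = 2. Preimages of outputs partition the 2^L inputs into
K groups; each group contains exactly one fixed point of the map (its
representative = the common output).

Fixed points are the sequences whose 1s are pairwise more than k apart;
their count satisfies n_{L+1} = n_L + n_{L−k} with n_L = L + 1 for
L ≤ k + 1. For the deterministic partition channel, MI = H(Y) = −Σ q_g
log₂ q_g with q_g the input mass of group g; uniform inputs give
MI = L − Σ (|g|/2^L) log₂|g| and any distribution with mass 1/K per group
attains the maximum log₂ K. Asymptotically n_L → a_{k,0}·a_k^L where a_k is
the dominant root of a^{k+1} = a^k + 1, and the capacity of a T = 60/(k+1)
min grid is C(k) = (k+1)·log₂(a_k) bit/h — monotone increasing in k, with
C(k)/log₂(k) → 1.

`dominant_root` brackets the root in (1, 2) with Brent's method
(tolerance 1e−12). `prefactor` computes lim n_L/a_k^L numerically from the
recurrence, judging convergence on the spread of a trailing window of
estimates because the subdominant roots' moduli approach a_k as k grows.
The computed prefactors are 1.1708 (= φ²/√5), 1.3134, 1.4397 and 2.1231 for
k = 1, 2, 3, 10; they are cross-checked in the tests against an
eigen-decomposition of the recurrence and against brute-force enumeration.
(Published two-decimal values for k ≥ 2 differ from these; the recurrence
with the stated initial conditions is unambiguous, so we report its true
limits.)

## The ODE model (`model`)

The reference implementation of the pathway (a rule-based model with its
full parameter table) is not bundled here; instead the package implements a
minimal surrogate with the same feedback topology, *calibrated to the same
observable contract*. Three states in fraction units:

    dS/dt = (k_in·u(EGF) + k_pf·S⁴/(S⁴+K_s⁴)) · (1−S) · 1/(1+(I/K_i)⁶) − k_off·S
    dE/dt = k_e·S⁴/(S⁴+K_se⁴)·(1−E) − k_de·E
    dI/dt = nf1_scale·k_nf·E·(1−I) − k_rec·I

with receptor drive u = EGF⁴/(EGF⁴ + K_egf⁴) and ERK_pp = E_tot·E. S is
active SOS/RAS (fast, excitable through the positive feedback PF1), I is
the slow ERK→SOS negative feedback NF1 whose recovery rate k_rec sets the
refractory clock, and the effective first-order ERK_pp shutdown k_de stands
in for the fast shaping feedbacks (NF2/NF3). Quartic Hill functions give
the threshold behaviour that makes responses all-or-nothing; the sextic
inhibition term makes the refractory boundary sharp.

Calibration targets and achieved values (defaults in `ModelParameters`):

| target | value |
| --- | --- |
| relaxation time τ (bisection of R₂/R₁ = 0.5 on [30, 90] min, tol 0.1) | 51.4 min |
| single-pulse R_max | 2.65 × 10⁹ molecule·s (E_tot sets the scale) |
| ERK_pp pulse half-maximum width | ≈ 21 min (≈ 88% of the integral within 30 min) |
| dose response | R₁(3 pg/ml) < 1% R_max; R₁(≥10 pg/ml) ≈ R_max |
| R₂/R₁ at T = 45 / 60 min | 0.12 / 0.64 |
| constant-EGF oscillations | sustained for ~4–5 pg/ml, absent at ≥ 8 pg/ml |

Known deviations of the surrogate: the ERK pulse is somewhat shorter than
the reference ~30 min, the recovery at T = 60 min (0.64) sits below the
reference 0.75, and the constant-EGF oscillation window is narrow. More
consequentially, because NF1 here both terminates the pulse and sets the
refractory period, weakening it (`nf1_scale` < 1) *lengthens* the measured
τ before oscillations vanish near scale ≈ 0.2, whereas in the reference
network — where separate fast feedbacks terminate the pulse — τ shrinks
with NF1 strength. `scan_feedback_strength` therefore reports the measured
table without asserting a direction; it uses a leakage-corrected second-
pulse response ('11' minus '10' trajectories) because at weak NF1 the pulse
outlasts the slot and the plain window ratio is contaminated by the first
pulse's tail.

Numerics: EGF is piecewise constant, so trajectories are integrated
segment by segment with LSODA (rtol 1e−7, atol 1e−12) and sampled on a 1-s
grid; R_i is a trapezoidal integral on that grid (error ≪ 0.1% at these
time scales). The resting state under EGF = 0 is the origin, verified by a
48-h pre-equilibration (relative drift < 1e−8 per hour). One four-pulse
simulation takes ~40 ms, so a full 16-sequence × 200-cell channel is ~2
minutes on one core.

## Noise (`population`)

Cell-specific noise: each flagged parameter (protein levels and
pseudo-first-order rates: k_in, k_pf, k_e, k_nf, k_off, k_de, k_rec, E_tot)
is drawn per cell as exp(Normal(ln default, σ²)) — median equal to the
default, σ interpreted as the log-scale standard deviation. (The source
convention is ambiguous between log-SD and log-variance; log-SD is adopted,
and the noise-free results are insensitive to the choice.) Additive noise:
each R_i receives an independent draw from exp(Normal(ln μ*, σ₀²)) with
median μ* = μ₀·R_max·T/60 min and σ₀ = 1, representing background ERK
activity from pathways outside the model (μ₀ = 0.03 ≈ 3% of per-slot
activity). Each cell draws from its own RNG stream seeded by (seed,
cell_id), so populations are reproducible under any execution order.

## The surrogate channel (`surrogate`)

The estimator/optimizer stack is exercised against an ODE-free generator
that emulates what the simulations produce: per cell, (1) a lognormal gain
g (log-SD `cell_cv`, mapped 1:1 from σ) shared across slots — the dominant,
strongly correlated amplitude component of extrinsic noise; (2) stochastic
transcoding with per-pulse miss probability logistic((τ − Δt)/miss_width),
Δt the time since the last emitted response — the soft refractory boundary
(miss_width → 0 recovers the deterministic map exactly); (3) R_i =
emitted_i·g·R_max + additive background. It reproduces the qualitative
features that matter to the estimator — bimodal marginals, within-cell
correlation, a sigmoidal fraction-responding curve — but does not claim
quantitative equivalence to the ODE population for σ > 0: the ODE's
parameter noise perturbs timing and pulse shape, not just amplitude, so
σ-grid results from the two backends agree in shape, not value. Passing
surrogate-based tests therefore validates the estimation machinery, not the
biology; the ODE-backend checks (τ, R_max, the T = 60 MI table) do that.

## MI estimation (`mi`)

Input X is discrete, output Y continuous in d = L dimensions, so the
Kraskov neighbour construction is adapted as in discrete/continuous MI
estimators: for sample j of category x, ε_j is the Chebyshev distance to
its k-th nearest neighbour *within the same category* (k = 15), and m_j
counts samples of all categories strictly inside ε_j. To support capacity
maximization without re-sampling, every sample of category x′ carries
weight w_{x′} = p(x′)·N_ref/M_{x′} (N_ref = total sample count, fixed), and

    MI(p) = ψ(N_ref) + ⟨ψ(k·w_x) − ψ(p_x·N_ref) − ψ(m̃_j)⟩   (nats → bits),

with m̃_j the weighted within-ε count (own weight included) and the outer
average weighted by p_x. At uniform p with equal M_x this reduces exactly
to the standard unweighted form ψ(N) + ψ(k) − ⟨ψ(M_x)⟩ − ⟨ψ(m_j)⟩. The
algebra of the weighting is a design choice, not a derivation, and is
validated against `mi_oracle_numeric`: deterministic grid integration of
H(Y) for Gaussian mixtures (absolute error < 0.005 bit, grid refined until
converged), with H(Y|X) analytic. On eight overlapping 3-D Gaussians at
unit-cube vertices (σ = 0.42, true MI 1.81 bits) the estimator is biased
high by ~2–4% at M = 1000 and ~1.5% at M = 5000; estimates are clipped
below at zero. Exact duplicate samples (noise-free channels) are broken by
a deterministic relative jitter of 1e−10 before neighbour searches.
N_ref is fixed at the total sample count under non-uniform p — a
convention, made so that the uniform case is recovered exactly.

## Capacity (`capacity`)

p = softmax(z) keeps the ascent unconstrained; the gradient of the weighted
estimate w.r.t. p is analytic (polygamma terms), chained through the
softmax, and fed to an Adam-style optimizer (step 0.05, ≤ 2000 iterations,
3 random restarts, convergence when MI moves < 1e−4 bit over 50
iterations; all defaults exposed in `OptimizerConfig` since the reference
hyperparameters are not published). The neighbour geometry (ε_j and
per-category within-ε counts) is computed once per dataset; each iteration
is a cheap re-weighting, O(total samples × categories). Zero-probability
categories (the equal-representatives scheme) contribute zero weight and
are dropped from the averaged term. On the noise-free L = 4, k = 1 channel
the optimizer recovers C = 2.99 bits with 1/8 ± 0.002 of the optimal mass
per group.

## Scales used by the default test-suite and acceptance runs

Surrogate-backend analyses use M = 250–1000 cells per sequence (sampling
error ~0.03–0.05 bit); the ODE-backend MI table uses L = 4, T = 60 min,
M = 200 cells per sequence. Full-scale runs (M = 1000, L = 6–8, complete
σ × T grids) are available through the same drivers and CLI but are not
part of the default suite.

## Limitations

- The ODE model is a calibrated surrogate: it honours the observable
  contract above but not the reference reaction network's full state space,
  so σ > 0 fraction-responding curves and the feedback-strength scan are
  qualitative (see deviations listed under the model section).
- The estimator inherits the kNN estimator's positive bias and its
  degradation with dimension; d ≤ 8 is the intended regime.
- Capacity is maximized over input distributions for a *fixed* sampled
  channel; sampling noise in the dataset propagates into C (±0.05 bit at
  M = 1000 in the regimes tested).
- The numerical-integration oracle supports ≤ 16 mixture components in
  ≤ 3 dimensions; it is a test fixture, not a general MI integrator.
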