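# Methods

This note documents the models, numerics and design decisions behind
`sigcap`, in the order a user meets them: the capacity framework, the
reference methods it is benchmarked against, the sensor benchmark, the
linear-noise-approximation (LNA) engine, and the interferon case study.

## 1. The asymptotic capacity framework

A signaling system is a channel `P(Y | X = x)` with input
`x = (x_1, …, x_k)` (ligand concentrations, in the model's concentration
units) and output `Y` (effector activity — a scalar count, or a stacked time
series). For `N` cells observing independently, the joint capacity obeys

```
C*_N − (k/2) log2 N  →  C*_A = log2( (2πe)^(−k/2) ∫_X √|FIM(x)| dx ),
```

the limit of reference-prior theory, with the optimal input distribution
converging to the Jeffreys prior `P*(x) ∝ √|FIM(x)|`. The package treats
`C*_A` as the primary object:

* it may be **negative** — it is the per-cell rate at which the number of
  resolvable inputs `2^{C*_A} N^{k/2}` grows, not a single-cell capacity.
  When `C*_A` (or the small-noise `C*_SN`) is used as an approximation of
  the single-cell capacity `C*_1 ≥ 0`, negatives are set to zero by the
  explicit, separate operation `clamp_for_single_cell`, which flags that it
  clamped. Raw values are never silently altered.
* the **Jeffreys integral** is evaluated by tensor trapezoid quadrature on
  the stored input grid (deterministic, reproducible), with a Richardson
  half-grid error estimate attached to every result; a seeded uniform
  Monte-Carlo rule (with linear interpolation of `√|FIM|`) is available for
  `k > 2`, where tensor grids become impractical. All study cases here have
  `k ≤ 2`. Grid resolution is a configuration knob; the convergence
  diagnostic (halved grid) is reported in every `CapacityResult`.
* **singular nodes** (`|FIM| = 0`) contribute zero to the integral — isolated
  zeros are integrable; only an all-singular field is an error (the capacity
  would be `−∞`), reported as a flagged failure rather than a number.

Derived quantities share the same field: estimator covariance
`(N·FIM)⁻¹` (raising, with the null direction named, when FIM is singular —
a non-identifiable input combination), the discrimination error
`ε(x₀,x₁,N) = exp(−N Δᵀ FIM(x₀) Δ)` clipped to `[0, 1]`, and isolines of the
discrimination quadratic form (ellipses with semi-axes `√(level/λ_i)`;
degenerate parallel-line descriptors when an eigenvalue falls below
`1e−12 × trace`).

All capacities are in bits; natural-log internals are converted once at the
boundary.

## 2. Fisher information: four routes

`FIM_ij(x) = E[∂_i log P(Y|x) · ∂_j log P(Y|x)]` is computed by:

1. **closed forms** for built-in families (binomial sensor, Gaussian
   location);
2. **exact discrete sums** over the output alphabet, with the score by
   central finite differences;
3. **Monte-Carlo** sample averages of score outer products, with per-entry
   standard errors (seeded, reproducible);
4. the **Gaussian moment formula**
   `FIM_ij = ∂_iμᵀ Σ⁻¹ ∂_jμ + ½ tr(Σ⁻¹∂_iΣ Σ⁻¹∂_jΣ)` for channels whose
   first two moments are available (the LNA route).

Finite differences use a *relative* step `max(|x_i|, 1) × 1e−4`: inputs are
concentrations spanning decades, and absolute steps fail at the extremes of
a log grid. Consequences worth knowing: at `x ≪ 1` the step is effectively
absolute (1e−4), so the FD error grows like `(1e−4/x)²`; closed-form
agreement at the 1e−6 level holds for `x ≳ 0.5` in the sensor benchmark.
Returned matrices are symmetrized, and eigenvalues driven slightly negative
by FD noise are clipped at zero before determinants are taken (otherwise
`√|FIM|` would be undefined). Zero-probability outcomes are dropped from
score sums (the standard `0·log 0` convention).

## 3. Reference methods

**Blahut–Arimoto.** Exact capacity of a discretized channel by the standard
alternating maximization, stopped by the classical certificate
`I(p) ≤ C ≤ max_i D(Q_i ‖ q)`: iteration ends when the bound gap is below
`tol_bits` (default 1e−6), so every converged result carries a proof of its
own accuracy. Two performance refinements preserve that certificate exactly:

* *over-relaxation*: the multiplicative update may use an exponent
  `γ ∈ [1, 3]` (default 1; the benchmark sweep uses 2), with a safeguard
  that falls back to the plain step whenever the accelerated step would
  decrease `I(p)`. Bounds are always evaluated at the current `p`, so
  acceleration affects only the iteration count.
* *active-set pruning*: inputs whose weight has collapsed below 1e−15 are
  dropped from the update (they shrink monotonically under the
  multiplicative iteration); the upper bound is still evaluated over **all**
  inputs every 50 iterations and at termination, so pruning can delay but
  never corrupt certification.

The monotone lower-bound trace (sampled every 100 iterations) is stored in
the diagnostics and asserted in the tests.

**Discretization.** Discrete channels pass their alphabet through; continuous
outputs are binned by CDF differences when a CDF is available, otherwise by
density × width; rows are renormalized and a pre-normalization row mass
below 0.999 is recorded as a truncated-support warning.

**Product channels** (`N` independent observations) are tabulated explicitly
with a guard `N log2|Y| ≤ 24`; they exist for validating the scaling law on
small fixtures, not for production use.

**Small-noise capacity.**
`C*_SN = log2((2πe)^(−1/2) ∫ |dμ/dx| / σ(x) dx)` for scalar input and a
scalar output summary — the classical analytic approximation valid when
output fluctuations around the mean dose–response are small. For discrete
outputs, `μ` and `σ` are the *exact* mixture moments (no Gaussian fit): the
approximation lives in the capacity formula, not in the moments. Only the
scalar-input form is provided; that is the form the benchmark uses.

## 4. The binomial sensor benchmark

The benchmark channel is a pool of `L` sensors, each active with probability
`h(S) = (S/H)/(1 + S/H)` where `S = X + X_F/λ`: `X` is the cognate ligand
(the input), `X_F` a random non-cognate ligand, `λ = H_F/H ≥ 1` the
selectivity, and `Y | X_F ~ Binomial(L, h)`. The marginal channel
`P(Y|X)` is a binomial mixture over `P(X_F)`, evaluated on Gauss-type
quadratures exact for each family's weight function (Gauss–Hermite in log
space for the lognormal; generalized Gauss–Laguerre for the gamma;
Gauss–Legendre against the density for the normal truncated at zero, whose
`(m_F, σ_XF)` are pre-truncation location/scale). `σ_XF = 0` degenerates to
a point mass. 32 nodes by default; a mass loss above 1e−6 triggers one
automatic doubling, then an error.

**The 27-scenario sweep** crosses `L ∈ {10, 100, 1000}`,
`λ ∈ {1, 10, 100}`, and the three `X_F` families, over a noise grid
`σ_XF ∈ {0, 0.25, 0.5, 1, 2}·H`, on `x ∈ [10⁻²H, 10²H]` with 101 log-spaced
nodes (covering the sensitive region of `h`; doubling the grid moves the
capacities by far less than the deviations being measured). In the sweep the
non-cognate law **scales with its own standard deviation**: `m_F = σ_XF`,
so each family keeps a fixed shape (lognormal and gamma with unit
coefficient of variation; mildly truncated normal) and `σ_XF = 0` is a
genuinely noise-free channel. The alternative — a fixed background mean
`m_F = H` across the noise grid (available via `scale_m_F=False`) — makes
the zero-noise column misleading: the constant shift `m_F/λ` destroys half
the sensor's dynamic range at `λ = 1` even with no variability at all, so
the deviation at `σ_XF = 0` is dominated by that floor (~24%, roughly flat
across the noise grid) rather than by what the sweep is meant to measure —
how the approximations degrade *as noise grows*. With the scaled law the
deviation of both approximations rises cleanly with `σ_XF` (≈14% → 27% for
`C*_A`), the two methods coincide at `σ_XF = 0` (for a binomial output the
small-noise information equals the exact Fisher information), and the
asymptotic route stays the more accurate one under strong noise.

Per cell the sweep computes: exact `C*_1` (certified BA, tol 1e−5 bits,
over-relaxation 2), clamped `C*_A` (FD Fisher field + trapezoid), and
clamped `C*_SN` (exact mixture moments). Rows with `C*_1 ≤ 0.05` bits or a
non-certified BA run are flagged and excluded from averages (none of the
default cells trigger this). Relative deviations `|C − C*_1|/C*_1` are
averaged over the 27 scenarios per noise level.

## 5. The LNA engine

For a network with stoichiometry `S` and macroscopic propensities
`f(φ, t; x)`:

```
mean         dφ/dt = S f(φ, t)
covariance   dΣ/dt = AΣ + ΣAᵀ + S diag(f) Sᵀ,   A = S ∂f/∂φ
cross-time   Cov(X(t_i), X(t_j)) = Σ(t_i) Φ(t_j, t_i)ᵀ,  dΦ/dt = A(t)Φ
```

The observed output `Y = (Y(t_1), …, Y(t_n))` (selected species at selected
times, stacked time-major) is then an explicit multivariate Gaussian — the
input to the Gaussian FIM route. Networks can be written directly in Python
(vectorized propensity functions, optionally with analytic Jacobians) or
declared in a YAML config with mass-action and Michaelis–Menten rate laws,
input-scaled propensities and a stimulus window
(`sigcap.config.network_from_config`). Cross-time blocks are assembled from
per-segment fundamental matrices; an independence switch (`cross_time=False`)
zeroes them for comparison, since treating time points as independent is a
common simplification whose cost can then be measured.

**Integration.** The macroscopic-only path (`mre_trajectory`) uses LSODA at
rtol 1e−8 / atol 1e−10, restarting at stimulus boundaries. The moment
equations use a fixed-step classical Runge–Kutta (RK4) scheme vectorized
over a batch axis, so hundreds of (input point × FD stencil × extrinsic
node) systems integrate in one pass; steps land exactly on observation
times and stimulus discontinuities. Two properties matter:

* *accuracy*: at the default `dt = 0.5` min the IFN moments agree with a
  10×-finer step to ~2×10⁻³ relative, and the step is shared by all batch
  elements, so the integration error is a smooth function of `x` and largely
  cancels in the FD stencils;
* *stability*: explicit RK4 requires the fastest local rate times `dt` to
  stay below ≈2.8. The IFN default rates are chosen so the fastest rate over
  the whole input grid × extrinsic envelope is ≈2/min (see §6); generic
  user networks should pick `dt` by the same criterion (the test suite's
  step-halving check is the template).

**Extrinsic variability.** Cell-to-cell variation of initial copy numbers is
modeled by independent lognormal marginals with a common coefficient of
variation `c_v` (positive support; the standard model for mammalian
expression noise — the family itself is a package choice). The mixture over
cells is handled by quadrature — unscented sigma points (2d+1 = 9 nodes for
the four varying species; default) or tensor Gauss–Hermite (3⁴ = 81 nodes;
high-accuracy switch) — and collapsed to a single Gaussian by the law of
total variance (moment matching). Node images are rescaled per dimension so
each marginal's **mean and variance are matched exactly** (the raw sigma-point
images of a lognormal underestimate its variance — by 8.5% already at
`c_v = 0.4`). Moment matching keeps the first two moments of the mixture
exact and drops higher cumulants; what that approximation does and does not
support is discussed under §6 and §8.

## 6. The interferon case study

Two receptor systems (type I bound by IFN-α, type III by IFN-λ1) converge on
shared effectors. Species (12): inactive/active receptor pools `R_I/R_I*`,
`R_III/R_III*`; free and phosphorylated STAT1/STAT2; cytoplasmic and nuclear
p-STAT1/1 and p-STAT1/2 dimers. Reactions: ligand-proportional receptor
activation `k₊ · x · R` during the 30-minute stimulus window only;
complex deactivation at `k_R̄I` (type I) and `δ·k_R̄I` (type III), with
`δ ∈ (0,1]` the **differential kinetics coefficient** — the *only* asymmetry
between the two receptor systems (both active complexes phosphorylate STAT1
and STAT2 at identical catalytic rates); mass-action dimerization; nuclear
import; nuclear dephosphorylation returning monomeric STATs to the
cytoplasmic pool. Stoichiometry conserves each receptor pool and each STAT
pool. The input is `x = (x_α, x_λ1)` in ng/ml; the output stacks nuclear
p-STAT1/2 and p-STAT1/1 at `t = 6, 12, …, 180` min (n = 30, a 60-dimensional
Gaussian output).

**Parameter defaults** (all in `IFNParams`, all overridable) are calibrated
to qualitative anchors rather than fitted to data: nuclear dimer response
peaking ≈30–60 min after stimulus onset; at `δ = 0.1` the IFN-λ response
decays much more slowly than the IFN-α response (half-decay ≈100 vs ≈60 min)
while at `δ = 0.9` the two are indistinguishable; capacity of the full
profile above 2 bits at `c_v = 0` for all `δ` and below 2 bits (negative)
at `c_v = 1.5, δ = 0.9`. Binding rates satisfy two structural constraints:
the dissociation constants `K_d = k₋/k₊` (1 ng/ml for type I, 25 ng/ml for
type III — the λ reference dose is correspondingly higher) define the
reference point `x₀` for FIM analysis, and the largest activation propensity
over the input grid `10^±2 × K_d`, times the `c_v = 1.5` copy-number
envelope, stays ≈2/min so the batched integrator is stable at `dt = 0.5`.

**Fisher route.** Capacity surfaces use the **mean-sensitivity Fisher
information** `∂μᵀ Σ⁻¹ ∂μ` (`cov_term=False`, the default in `sigcap.ifn`):
the temporal mean profile is the information carrier, and `Σ` — intrinsic
plus between-cell — is the noise it must be read through. The
covariance-sensitivity trace term of the full Gaussian formula is available
(`cov_term=True`) but excluded by default because, under extrinsic moment
matching, it converts the strong `x`-dependence of the low-rank
between-component spread into information that the true mixture likelihood
does not offer in that form: with the trace term included the capacity stops
decreasing — and eventually *rises* — with `c_v`, whereas more extrinsic
noise must mean less information. The mean-sensitivity route is monotone
nonincreasing in `c_v` and `δ` throughout (the surface the tests assert).
At `c_v = 0` the two routes differ only modestly (the intrinsic covariance's
input dependence is real but minor). The general `fim_gaussian` operation
retains the full formula.

**Problem sizes.** The spec-level default input grid is 21×21 (log-spaced,
`10^±2 × K_d` per axis) with a halved-grid convergence diagnostic; the
capacity surfaces and tests in this package use 11×11, where the capacity
values differ from 21×21 by far less than the bit-level contrasts being
asserted, and a full `(4 c_v) × (3 δ)` surface completes in ≈4 minutes on
one core. The `capacity_vs_time` curves reuse a single batched moments pass
per `δ` — truncating the output to `t ≤ t_n` is a sub-block extraction, so
thirty horizons cost one integration.

## 7. Jeffreys optimality at finite N: what the test measures

On a *fixed finite grid* the exact finite-`N` optimal input does not converge
to the Jeffreys prior (as `N → ∞` it approaches uniform over the grid,
since all nodes eventually become resolvable); the JP is optimal in the
continuum limit. On the benchmark fixture (L = 4, 9 nodes, N = 8) the
discretized JP sits ≈0.2 bits below the exact product-channel capacity —
a discretization gap, not an error. The optimality test therefore draws
perturbations at low Dirichlet concentration (`Dirichlet(3·w_JP)`):
genuinely different input strategies with mean JP. The JP transmits at least
as much information as ≈98% of such draws. At high concentration the
comparison would instead measure the discretization gap and is not a test of
the JP's shape.

## 8. What the synthetic studies do and do not show

All inputs are synthetic: the binomial sensor and the IFN network are
*models*, and passing tests certify the implementation and the internal
consistency of the framework (scaling law, Jeffreys optimality,
approximation-accuracy ordering), not biological ground truth. Specific
caveats:

* the LNA is exact for linear kinetics (birth–death, cascades — hence those
  oracles) and an approximation for bimolecular steps and receptor-mediated
  activation; it degrades at low copy numbers;
* the extrinsic mixture is summarized by two moments; strongly bimodal
  population responses would not be captured;
* sensor scenario parameters and IFN kinetic rates are calibrated defaults,
  so quantitative capacities (e.g. "6 bits at δ = 0.1") are
  parameter-dependent; the asserted results are directional and structural
  (monotonicities, orderings, sign changes, singularity patterns);
* the discrimination error formula is a large-`N` hypothesis-testing
  approximation; the tests check its exponential order against simulated
  likelihood-ratio tests within a factor of 2.

## 9. Numerical conventions

* capacities in bits; weights normalized to 1 within 1e−12; discrete channel
  rows sum to 1 within 1e−10;
* FIM symmetry enforced to 1e−8 relative; PSD tolerated to −1e−8 × trace,
  then eigen-clipped for determinant use;
* covariances receive a diagonal jitter `1e−8 × mean(diag)` only when the
  smallest eigenvalue drops below `1e−10 × trace`; failure after jitter is
  an error carrying the eigenvalues;
* CSV output prints floats at 12 significant digits so identical runs are
  byte-identical; JSON round-trips node positions and weights bit-exactly;
* every CLI run writes a manifest (command, config hash, seed, wall clock,
  package version, output list);
* all randomness flows through seeded `numpy` generators; Monte-Carlo
  results carry standard errors.
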