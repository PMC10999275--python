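# Methods

Models, parameter conventions, numerical design choices and limitations of
`macroresilience`. Everything quantitative stated here is computed by the test
suite or the acceptance script; no empirical field results are claimed.

## 1. Stochastic community dynamics (`community`)

### Birth–death chains and the master equation

`gillespie_simulate` runs an exact single-species birth–death chain with
arbitrary rate functions `b(n)`, `d(n)` (exponential waiting times, one event
per step). `solve_master_equation` integrates the corresponding probability
vector `p_n(t)` with a sparse generator and `scipy.sparse.linalg.expm_multiply`;
the top state is reflecting, and the solver raises if more than the configured
tolerance of probability mass reaches the top 1% of states (the truncation
`n_max` must then be increased). For the pure-birth (linear birth, no death)
chain the closed form `p_n(t) = e^{−βt}(1 − e^{−βt})^{n−1}` (`yule_pmf`) is the
oracle: the solver matches it to 1e−6 and the Monte-Carlo mean matches
`e^{βt}` within sampling error.

`diffusion_limit_check` verifies that a discrete rate family rescales to its
claimed drift/diffusion pair: it reports the sup-norm gap between `J·rate(n)`
and the rescaled rate at `x = n/J` across a ladder of community sizes, which
must shrink as `1/J`.

### The zero-sum neutral community

`simulate_neutral_community` implements a Moran-type local community of fixed
size `J`: at each event one uniformly chosen individual dies and is replaced
either by an immigrant from a uniform metacommunity of `S_meta` species (with
probability `m`) or by the offspring of a uniformly chosen local individual.
The implementation keeps an individual array and performs O(1) work per event
with block-drawn random numbers; event times are exponential with total rate
`J`, so one time unit is one generation. Defaults: `J = 500`, `m = 0.1`,
`S_meta = 25`, burn-in `20·J` events, one snapshot every `10·J` events
(about one immigration relaxation time `1/m` generations apart).

The diffusion limit of this process for a single species' proportional
abundance `x = n/J` has drift `m(p − x)` and diffusion `2x(1−x)/J` (with `p`
the metacommunity relative abundance), whose stationary density is the beta
law with shapes `(Jmp, Jm(1−p))`. The finite-volume solver reproduces this
density (sup-CDF distance < 0.01), and the simulator's pooled snapshot
abundances pass a parametric-bootstrap KS test against a beta baseline fitted
to a long calibration run (`stationary_abundance_test`; 200-observation
minimum, 95th-percentile critical distance from `n_boot` baseline samples).

## 2. Distributions and estimators (`distributions`)

* **Beta abundance density** `ρ(x) ∝ x^(α−1)(1−x)^(β−1)` on (0,1). Fitting
  delegates to `scipy.stats.beta` MLE with fixed support; standard errors come
  from the closed-form Fisher information (trigamma functions). The density is
  exactly log-linear in `log x` when `β = 1` and in `log(1−x)` when `α = 1` —
  the power-law special case.
* **Truncated Pareto** `f(m) = (λ+1) m^λ / (mmax^{λ+1} − m0^{λ+1})` on
  `[m0, mmax]`, with the `λ = −1` logarithmic limit handled analytically.
  Hand-written pdf/cdf/inverse-cdf sampler and a one-dimensional bounded MLE
  for `λ ∈ [−6, 2]` with plug-in endpoints `m0 = min(m)`, `mmax = max(m)`;
  confidence intervals by percentile bootstrap. The exponent convention is the
  *density* exponent, so the steady-state size spectrum has `λ ≈ −2`.
  A consequence of plug-in endpoints worth knowing: deleting **every**
  individual below a cutoff re-truncates the Pareto self-similarly and leaves
  the fitted exponent unchanged; only *partial* removal of small individuals
  shallows it.
* **Density–mass scaling** `N = a M^(−b)` by OLS on logs (`b` reported
  positive).

## 3. Forward Kolmogorov solver (`diffusion`)

`fokker_planck_solve` integrates `∂P/∂t = −∂(AP)/∂x + ½∂²(BP)/∂x²` with a
conservative cell-centred finite-volume scheme: first-order upwind advection
(sub-stepped to the CFL limit), backward-Euler diffusion of the **full**
`∂²(BP)/∂x²` operator (correct for state-dependent `B`) solved as a
tridiagonal system, optional per-cell source (recruitment) and exponential
sink (mortality) terms, and reflecting or absorbing edges. Boundary cells are
half-width so discrete mass equals the trapezoidal integral exactly;
reflecting boundaries conserve mass to 1e−6 over thousands of steps.
`stationary_density` computes the zero-flux stationary law
`P ∝ exp(∫2A/B)/B` by quadrature and raises a descriptive error when the
result is non-normalizable at an edge.

Known accuracy limits: the upwind advection is first order, so sharp
stationary densities need fine grids (the Ornstein–Uhlenbeck KS check uses
801 nodes); the L1 error against closed forms halves when the grid spacing
halves, as the convergence test asserts.

## 4. Size structure (`size_structure`)

### The demographic balance and the −2 slope

At steady state the number density `N(D)` satisfies
`½ d²/dD²[V N] − d/dD[G N] − M N = 0`. With deterministic growth (`V = 0`)
this integrates to `d ln N/d ln D = −D·M/G − d ln G/d ln D`. Growth follows
metabolic scaling, `G = g0 D^θ` with `θ = 1/3` by default. The mortality
schedule `M(D) = G(D)(2 − D·d ln G/dD)/D = g0(2−θ)D^{θ−1}`
(`steady_state_mortality`) balances growth so that the slope is exactly −2
for every `θ < 2` (at `θ ≥ 2` the balance would demand negative mortality and
the constructor raises).

`solve_steady_state_size_distribution` integrates the first-order balance in
`ln D` (the integrand `D·M/G` is constant for power-law families, so the
quadrature is exact and the acceptance slope is −2 to machine precision).
With `V > 0` it instead relaxes the full second-order balance in time using
the shared solver, with a recruitment source in the smallest cell and an
absorbing upper edge; the outer step keeps per-step mortality near 10% and
the run stops early once stationary.

### The individual-based forest

`IbmForest` tracks every individual's diameter. Per step of length `dt`
(default `0.01 / max M`, keeping per-step death probabilities near 1%): deaths
are drawn first with probability `1 − e^{−M(D)dt}`, survivors grow by `G(D)dt`
(optionally with Gaussian noise of variance `σ²G(D)D·dt`), and recruits enter
at `D_min`. Under `zero-sum` recruitment every death is replaced one-for-one —
all freed space is immediately recolonized — so the population size is
invariant; `closed` recruitment lets the population decline. Initialization
warm-starts from the analytic steady state (truncated Pareto, exponent −2, on
`[D_min, D_max]`) and then relaxes under the simulator's own dynamics, so the
fitted exponent reflects the dynamics rather than the initializer. With
stochastic growth the IBM's stationary size distribution matches the
second-order continuity solution (KS < 0.05 at n = 5000).

### Slope estimation

`fit_loglog_slope` offers the truncated-Pareto MLE (preferred; the density
exponent equals the log-log pdf slope) and log-binned OLS (12 logarithmic
bins, bins with fewer than 5 individuals dropped) as a cross-check; the two
agree within 0.1 at n = 10⁵.

## 5. Disturbance and recovery (`resilience`)

Perturbations (`PerturbationSpec`): pulse removal of individuals below
(`remove_small`) or above (`remove_large`) a size threshold or of everyone
(`proportional_thinning`), each independently with probability `intensity`;
or a press `rate_shift` that multiplies the mortality schedule (below a size
threshold, if given) for a bounded interval. A pulse that would remove the
whole population raises — total mortality is not a recoverable disturbance.
Under zero-sum recruitment the space a pulse frees is refilled immediately
with recruits at `D_min`, so the population size — and therefore the sampling
noise of all subsequent fits — stays at its baseline level.

Deviation metrics: KS distance between current sizes and the fitted baseline
distribution (default), Hellinger distance between refitted densities, and
standardized parameter distance; Bray–Curtis for abundance vectors.

Recovery is declared at the first time the deviation stays below a tolerance
for `persistence = 3` consecutive samples. The tolerance is not a free knob:
`calibrate_tolerance` runs an unperturbed null panel (5 seeds by default in
the experiment driver) and takes the 95th percentile of its own deviation
fluctuation. The end state of an experiment is summarized over the last three
sampling times — mean fitted exponent, with a confidence band formed as the
envelope of the per-sample bootstrap intervals — because a single-snapshot
bootstrap understates the slow wander of the realized exponent in a finite
population.

The scenario contract (checked on a fixed 10-seed panel): removal of the
largest individuals recovers to the −2 baseline (survivors grow, recruits
refill), while a press doubling of small-tree mortality equilibrates near a
fitted exponent of about −3.3 — a steeper, different attractor — and never
returns.

## 6. Random-matrix stability (`networks`)

Community matrices: off-diagonal entries are nonzero independently with
probability `C`, drawn from a zero-mean normal with standard deviation
`alpha_strength`; the diagonal is `self_regulation = −1`. Stability means all
eigenvalues have negative real part. `stability_probability` reports the
Monte-Carlo stable fraction with a Wilson binomial interval. The transition
sits at complexity `α√(SC) = 1`: at 0.5 the stable fraction is ≥ 0.95 and at
1.5 it is ≤ 0.05 (S = 100, 200 replicates). `sparse_scaling_scan` shows the
corollary: with `C = c0/S` complexity is size-independent and the stable
fraction is statistically constant across `S`, whereas a fixed dense `C`
destabilizes growing networks.

## 7. IO, reproducibility, CLI (`io`, `cli`)

Tables are TSV/CSV with validated schemas (`site_id, individual_id, size`;
`site_id, species, count`); errors name the offending 1-based data row.
Results JSON carries a `spec_version` field. Every CLI subcommand takes
`--seed`, derives all randomness from it through named
`numpy.random.SeedSequence` streams, and writes a resolved `config.json`
snapshot, making runs bit-reproducible. `make_fixtures` generates seeded
synthetic tables (neutral-community abundances, truncated-Pareto sizes,
perturbed sizes) with JSON sidecars recording the generating — and for
perturbed fixtures, the pre/post fitted — parameters.

## Limitations

* The neutral community uses a uniform metacommunity and a single immigration
  parameter; no speciation, no spatial structure.
* The forest IBM has no competition beyond zero-sum space filling, no species
  identity, and recruits enter exactly at `D_min`.
* The advection discretization is first order; very peaked densities require
  fine grids, and the stationary-quadrature path requires strictly positive
  diffusion in the interior.
* Truncated-Pareto endpoints are plug-in estimates; inference on `λ` ignores
  their sampling variability (the bootstrap partially compensates).
* Stability analysis is local (sign of the leading eigenvalue of a random
  linearization); no dynamics on the network are simulated.
* Runtime envelopes assume the default parameter scales; mortality diverges
  as `D_min^{θ−1}` at small `D_min`, shrinking the stable time step.
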