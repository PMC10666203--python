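# Methods

`cellabc` estimates parameters of stochastic multicellular lattice models by
approximate Bayesian computation. This note records the models, the
inference procedure, the numerical choices, and what the bundled synthetic
problems do and do not establish.

## Problem formulation

A model `M` maps a parameter vector θ (and random input ξ) to simulated data
`y = M(θ, ξ)`. The likelihood of such simulators is intractable, so the
posterior π(θ | y_obs) is approximated by the ABC posterior

    π_ε(θ | y_obs) ∝ π(θ) · P[ d(s(M(θ)), s(y_obs)) ≤ ε ],

where `s` is a vector of summary statistics, `d` a weighted distance, and ε
an acceptance threshold driven toward zero across generations.

Problems are defined on disk as a yaml index referencing an XML model
document plus four tab-separated tables (parameters, conditions,
measurements, summary statistics), a deliberately small dialect in the PEtab
lineage. Parameters and condition overrides address locations in the model
document through a restricted XPath-like grammar (child steps, `[@name='…']`
predicates, a final `/@attr` or `/text()` selector). Sampling and
perturbation happen on each parameter's declared scale (`lin` or `log10`);
values are back-transformed only when written into the document.

## Simulators

### Two-route viral spread

A rectangular grid of cells (SUSCEPTIBLE / INFECTED / DEAD) is coupled to a
virion concentration field V(x, t). Infection spreads by two routes: a
cell-free hazard `β_cf · V(x)` from local virions and a cell-to-cell hazard
`β_cc · n_inf(x)` from the infected von Neumann neighbors. Per step of
length dt (all hazards evaluated on the pre-step configuration, so one step
is a product of independent Bernoulli draws):

* susceptible sites become infected with `1 − exp(−(β_cf V + β_cc n_inf) dt)`;
* infected sites die with `1 − exp(−δ_death dt)`;
* the field obeys `∂V/∂t = D ∇²V + p_prod · 1[infected] − c_decay · V`,
  integrated by a forward-Euler 5-point stencil with zero-flux boundaries
  (a bounded tissue patch).

Defaults (the reference synthetic-truth setting, per tissue-patch reading of
a plaque-growth experiment): β_cf = 0.05, β_cc = 0.2, p_prod = 1, c_decay =
0.1, D = 0.5, δ_death = 0.05, dt = 0.1, t_end = 10 on a 50×50 grid with one
center-infected cell. Rates are per unit model time; the lattice spacing is
1, so D is in sites²/time.

Numerical constraints: the explicit scheme needs `D·dt ≤ 1/4`; the update is
a convex combination (hence provably non-negative) when
`4·D·dt + c_decay·dt ≤ 1`, and is clipped at zero only outside that regime.
With zero source and decay the stencil conserves mass to machine precision.
A run terminates early once no infected cell remains and the field is
identically zero — nothing observable can change afterwards — which makes
the work a simulation consumes parameter-dependent (exploited by early
rejection). The step size is part of the model definition: halving dt with
doubled hazards defines a *different* model and is not expected to match.

### Cellular Potts kernel

Cells are spin domains on a lattice with the standard adhesion +
volume-constraint energy `H = Σ_<x,x'> J(τ(s(x)), τ(s(x'))) · 1[s≠s'] +
λ_v Σ_k (v_k − V_T,k)²` over 4-neighbor pairs without wraparound. Dynamics
are elementary copy attempts accepted with `min(1, exp(−ΔH/T))`; one sweep
is width·height attempts; proposals pointing off-lattice are discarded (but
count as attempts). ΔH is computed locally and volumes (including the
medium's) are tracked incrementally; a full-recompute Hamiltonian serves as
the test oracle. The CPM is a library kernel exercised by tests; the
inference fixtures use the viral model, which is far cheaper per simulation.

## Summary statistics and distances

A registry provides `count_timeseries`, `patch_radius_timeseries`
(√(area/π) of the infected+dead patch), `radial_profile` (mean of an
indicator or field in n concentric equal-width bins around the grid center),
and `final_fraction`. The same statistic table maps observed measurement
rows into a vector with identical component names, so simulated and
observed data are always compared per component. Replicate simulations are
averaged on the summary level before the distance.

Distances are weighted p-norms `(Σ_i w_i |s_i − o_i|^p)^(1/p)`, p ∈ {1, 2},
default p = 2. Weights default to MAD-based scale normalization
(`w_i = 1/scale_i`), refit each generation from the previous generation's
accepted summaries; generation 1 uses weights from a pilot of 100 prior
simulations. A statistic with zero scale in a generation gets weight 0 (it
is uninformative there) with a logged warning.

Because refitting changes the distance scale, the refit weight vector is
rescaled so that the α-quantile of the previous generation's accepted
distances is unchanged; that quantile is then the next ε. This keeps the ε
trajectory monotone and the acceptance rate near α while the *relative*
weighting adapts. Without the rescaling the threshold lands in the tail of
the new distance distribution and the acceptance rate collapses (observed:
below 1% by generation 3 on the viral fixture).

Optionally, statistic vectors are projected through a linear
inverse-regression map `s ↦ b0 + B·s` (one least-squares fit of θ on s per
parameter, ridge fallback with λ = 1e-8 on rank-deficient designs), fitted
on the pilot sample and then frozen: refitting per generation would change
the acceptance target mid-run. The projected summary is the predicted
parameter vector, so the distance then operates in parameter space.

## ABC-SMC engine

* Generation 1 accepts prior draws as-is (ε₁ = ∞, uniform weights 1/N),
  redrawing on failed or budget-exceeded simulations.
* Each later generation: ε_t = the type-1 α-quantile (default α = 0.5) of
  the previous accepted distances, never above the previous ε; proposals
  resample the previous population by weight and perturb with a Gaussian
  kernel whose covariance is 2× the weighted empirical covariance
  (unbiased weighted normalization, 1e-12·trace jitter on the Cholesky);
  out-of-support draws trigger resample-and-retry, up to 10⁴ times.
* Importance weights `w ∝ π(θ') / Σ_j w_j K(θ' − θ_j)` are computed in log
  space and normalized per population.
* Stopping: ε ≤ min_epsilon (checked on the threshold the generation ran
  at), max_generations, or a wall-time limit that always finishes the
  running generation.

Early rejection: each particle carries a work budget counted in simulation
work units (lattice update steps; the Gaussian toy charges one). A
simulation that exhausts the budget is discarded at that point with
distance +∞. Work units rather than wall seconds keep the mechanism
deterministic and portable; a wall-seconds budget would tie results to the
executing hardware.

## Parallel sampling contract

Evaluation is scheduled by pluggable samplers. Static mode assigns balanced
per-worker acceptance quotas (sum N, pairwise difference ≤ 1; minimizes
total CPU time). Dynamic mode issues tasks on demand from a central counter
(minimizes wall time). Every task owns the random substream
`SeedSequence([seed, generation, task_index])`; substreams are
non-overlapping, never reused (checked), and make results independent of
worker count and scheduling.

Dynamic mode accepts by *issue order*: the population is the accepted
particles with the N smallest task indices; acceptances issued later are
discarded regardless of completion time. Accepting by completion order
instead favors parameter regions that simulate fast; the bias equals the
in-flight deficit at stop time, so it grows with the number of concurrent
tasks relative to N — the test suite demonstrates it with 500 simulated
workers and θ-correlated latencies, where issue-order selection is provably
latency-invariant (it returns byte-identical populations). Workers are
simulated in-process by a discrete-event loop; the contract, not a broker
deployment, is the deliverable. Parallel efficiency is reported as
`PE = t_single / (t_multi · i)`.

## Result store and diagnostics

All generations (ε, proposal counts, wall seconds, full particle tables)
persist in one sqlite file; REAL columns round-trip floats losslessly.
Wall seconds are inherently non-reproducible, so `save(include_timing=False)`
writes a canonical file that is byte-identical across reruns of a
deterministic run. Diagnostics: ESS = 1/Σw²; weighted credible intervals by
type-1 weighted quantiles (the same no-interpolation convention as the ε
schedule); ε and samples-per-generation trajectories; weighted
Gaussian-product 2-D KDEs with per-dimension bandwidth
`ESS^(−1/6) ×` weighted sd (Silverman's rule for d = 2). A KDE over a
dimension with zero weighted variance is refused (a rug plot is the honest
display there). The report exporter writes plain tsv/npy files.

## Synthetic problems, and what the tests show

* **Gaussian conjugate toy** (y = θ + N(0,1), θ ~ N(0,1), y_obs = 1):
  posterior N(0.5, 0.5) in closed form. This is the engine's calibration
  oracle; it validates weighting, perturbation, and the ε schedule, but
  exercises neither spatial structure nor multi-statistic distances.
* **Viral recovery fixture**: observed data are one stochastic simulation
  at the reference truth — the realistic well-specified case — with 11
  infected-count records (t = 0…10) and a 5-bin radial profile at t = 10;
  β_cf and β_cc are estimated with log10-uniform priors spanning one decade
  either side of truth. The two routes trade off along a posterior ridge
  (both produce infections; only the spatial pattern separates them), so
  marginal intervals are wide in the β_cf direction. The recovery test runs
  ten full studies, each with a fresh dataset, and requires the 95%
  intervals to cover both true rates in at least nine; note that the joint
  coverage of two 95% marginals is ≈90% even for perfectly calibrated
  posteriors, and datasets from the small-epidemic tail legitimately pull
  the posterior away from the truth.
* **Early-rejection fixture**: pure cell-to-cell spread with brisk death on
  a 21×21 grid, where extinction time — and hence simulation work — depends
  strongly on β_cc; the budget is the median work of a pilot run.

None of these fixtures contain measurement noise beyond the simulator's
own stochasticity, misspecification, or image-derived observables, so
passing tests demonstrate correctness of the machinery on well-specified
desk-scale problems, not robustness to the artifacts of real microscopy
data.

## Problem sizes used by the test suite

Chosen as the smallest sizes at which each statistical check is sharp: the
conjugate recovery runs N = 1000 to ε ≤ 0.1; the rejection-ABC equivalence
uses N = 2000 at ε = 0.4; the recovery experiment runs N = 500 for 3
generations per study (well under the 15-generation cap; fewer generations
also keep interval widths honest relative to the information actually
extracted); scheduler checks use 500–2000 toy tasks. The acceptance script
repeats the recovery with 3 studies.

## Known limitations

Square 4-neighbor lattices only; no hexagonal/3-D geometry; no intracellular
ODE/SDE sub-models; CPM is single-threaded and not coupled to the field; the
problem dialect covers exactly the column set documented here; dynamic
scheduling is validated in a simulated-worker harness, not across machines;
normal priors on log10 scale are supported but uniform-kind priors are the
tested path.
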