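# cellabc

Likelihood-free parameter estimation for stochastic multicellular lattice
models: a tsv/yaml problem-specification dialect, desk-scale simulators (a
two-route viral-spread cellular automaton coupled to a diffusing virion
field, and a cellular Potts kernel), an ABC-SMC inference engine with
adaptive distances and early rejection, a static/dynamic particle-sampling
contract, and a shareable sqlite result store with posterior diagnostics.

**Who it is for.** Modelers of tissue-scale stochastic processes — viral
plaque growth, spheroid expansion, regeneration fronts — whose simulators
have no tractable likelihood. Given observed summary data and a prior, the
package samples the approximate posterior of the simulator's parameters and
reports credible intervals and run diagnostics, end to end from one problem
bundle.

## The method

For a stochastic model `y = M(θ, ξ)` with prior π(θ), ABC-SMC approximates
the posterior by the distribution

    π_ε(θ | y_obs) ∝ π(θ) · P[ d(s(M(θ)), s(y_obs)) ≤ ε ],

propagating a weighted particle population through a decreasing sequence of
thresholds ε₁ = ∞ > ε₂ > …, where each ε is the α-quantile (default: the
median) of the previous generation's accepted distances. Proposals resample
the previous population and perturb with a Gaussian kernel (covariance 2×
the weighted empirical covariance); importance weights
`w ∝ π(θ′) / Σⱼ wⱼ K(θ′ − θⱼ)` correct for the proposal mixture. Distances
are weighted p-norms over summary statistics with MAD-based per-statistic
weights refit each generation, and an optional inverse-regression projection
`s ↦ b0 + B·s` (predicted parameters as summaries). Simulations that exceed
a work budget are rejected early, without being finished. See
`docs/methods.md` for the full account.

## Worked example

Generate the bundled conjugate toy problem (model `y = θ + N(0,1)`, prior
`θ ~ N(0,1)`, observed `y = 1`; exact posterior `N(0.5, 0.5)`), fit it, and
export diagnostics:

```
$ fmc fixtures --name gaussian --out toy
toy/problem.yaml

$ fmc fit toy/problem.yaml --pop-size 1000 --max-gens 40 --min-eps 0.1 \
      --alpha 0.5 --adapt none --seed 7 --out toy_store.db
finished 6 generations; final epsilon 0.0671769
  theta: posterior mean 0.4701 (sampling scale)
store written to toy_store.db

$ fmc report toy_store.db --out toy_report
toy_report/epsilon_trajectory.tsv
toy_report/ess.tsv
toy_report/samples_per_generation.tsv
toy_report/ci_0.95.tsv
```

The fit stops once the acceptance threshold drops below 0.1: six
generations here, with the threshold shrinking roughly geometrically
(1.16 → 0.52 → 0.27 → 0.13 → 0.067). The weighted posterior mean 0.470 and
variance 0.525 sit within Monte-Carlo error of the closed-form values 0.5
and 0.5 — the closer ε gets to zero, the closer the ABC posterior is to the
exact one. `ci_0.95.tsv` holds the weighted 95% credible interval for θ,
and `epsilon_trajectory.tsv` / `ess.tsv` are the standard run-health plots
(threshold per generation; effective sample size 1/Σw², which should stay
well above 1).

The same workflow drives the spatial model: `fmc fixtures --name viral`
creates a 50×50 lattice problem whose observed data (an infected-count time
course and a radial infection profile) were simulated at known transmission
rates β_cf = 0.05 (cell-free, per virion concentration) and β_cc = 0.2
(cell-to-cell, per infected neighbor), and `fmc fit` recovers both rates
with log10-uniform priors. `fmc validate` checks any bundle against the
format's invariants, and `fmc simulate` runs the simulator stand-alone.

## Layout

```
src/cellabc/
  problem.py    problem bundles: parse, validate, write, parameter mapping
  lattice.py    viral-spread automaton + reaction-diffusion field
  cpm.py        cellular Potts kernel (Metropolis copy attempts)
  summaries.py  statistic registry, weighted distances, inverse regression
  smc.py        ABC-SMC engine (priors, kernels, epsilon schedule, budgets)
  parallel.py   static/dynamic scheduling contract, issue-order acceptance
  store.py      sqlite result store, ESS / CI / KDE diagnostics, report export
  fixtures.py   generated test problems (toy, viral, budget, invalid corpus)
  cli.py        the `fmc` command-line front end
```
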