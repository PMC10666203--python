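"""Self-contained test problems with known answers.

Three families:

* the **Gaussian conjugate toy** — model ``y = theta + N(0, 1)``, prior
  ``theta ~ N(0, 1)``, observed ``y = 1``; its exact posterior is
  ``N(0.5, 0.5)``, the engine's closed-form oracle;
* the **viral-spread fixture** — the two-route lattice model at a fixed
  reference setting, with synthetic observed data drawn from one simulator
  run at known parameters (the realistic well-specified case); the recovery
  target is (beta_cf, beta_cc) with log10-uniform priors spanning two
  decades around the truth;
* the **invalid corpus** — bundles each violating exactly one validation
  rule, used to pin the validator's error codes.

Everything is regenerated from seeds at call time; no data files ship with
the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .lattice import LatticeState, ViralParams, run_viral_model
from .summaries import _radial_bin_index

__all__ = [
    "FixtureBundle",
    "REFERENCE_VIRAL_PARAMS",
    "VIRAL_TRUTH",
    "make_gaussian_toy",
    "make_viral_fixture",
    "make_invalid_corpus",
]

#: reference synthetic-truth setting of the viral model (50x50 grid)
REFERENCE_VIRAL_PARAMS = ViralParams(
    beta_cf=0.05, beta_cc=0.2, p_prod=1.0, c_decay=0.1, D=0.5,
    delta_death=0.05, dt=0.1, t_end=10.0,
)
VIRAL_TRUTH = {"beta_cf": 0.05, "beta_cc": 0.2}
VIRAL_GRID = (50, 50)  # (width, height)


@dataclass
class FixtureBundle:
    name: str
    index_path: Path
    ground_truth: dict = field(default_factory=dict)
    seed: int = 0
    expected_error_code: Optional[str] = None


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def _write_bundle(base: Path, model_xml: str, parameters: str, conditions: str,
                  measurements: str, statistics: str) -> Path:
    _write(base / "model.xml", model_xml)
    _write(base / "parameters.tsv", parameters)
    _write(base / "conditions.tsv", conditions)
    _write(base / "measurements.tsv", measurements)
    _write(base / "statistics.tsv", statistics)
    index = base / "problem.yaml"
    _write(
        index,
        "model_file: model.xml\n"
        "parameter_file: parameters.tsv\n"
        "condition_file: conditions.tsv\n"
        "measurement_file: measurements.tsv\n"
        "statistic_file: statistics.tsv\n",
    )
    return index


_PARAM_HEADER = (
    "parameter_id\tprior_kind\tprior_arg1\tprior_arg2\tscale\testimate\tnominal_value\ttarget_path\n"
)


def make_gaussian_toy(out_dir, seed: int = 0) -> FixtureBundle:
    """Conjugate Gaussian toy; posterior is N(0.5, 0.5) in closed form."""
    base = Path(out_dir)
    model = (
        '<Model kind="gaussian">'
        '<Param name="theta" value="0.0"/>'
        '<Param name="noise_sd" value="1.0"/>'
        "</Model>"
    )
    parameters = _PARAM_HEADER + (
        "theta\tnormal\t0\t1\tlin\ttrue\t\tModel/Param[@name='theta']/@value\n"
    )
    conditions = "condition_id\nc0\n"
    # single observed datum y = 1 at t = 0
    measurements = (
        "observable_id\tcondition_id\ttime\tvalue\tdata_ref\treplicate_id\n"
        "y\tc0\t0\t1.0\t\t\n"
    )
    statistics = (
        "statistic_id\tfunction_id\targs\tobservable_ids\n"
        "y_stat\tcount_timeseries\t" + json.dumps({"observable": "y", "times": [0.0]}) + "\ty\n"
    )
    index = _write_bundle(base, model, parameters, conditions, measurements, statistics)
    return FixtureBundle(
        name="gaussian",
        index_path=index,
        ground_truth={
            "posterior_mean": 0.5,   # (tau^-2 mu0 + sigma^-2 y) / (tau^-2 + sigma^-2)
            "posterior_variance": 0.5,  # 1 / (tau^-2 + sigma^-2)
            "observed_y": 1.0,
        },
        seed=seed,
    )


def _viral_model_xml(params: ViralParams, width: int, height: int) -> str:
    pars = "".join(
        f'<Param name="{k}" value="{getattr(params, k)}"/>'
        for k in ("beta_cf", "beta_cc", "p_prod", "c_decay", "D", "delta_death", "dt", "t_end")
    )
    return (
        f'<Model kind="viral">{pars}'
        f'<Lattice width="{width}" height="{height}" init_infected="center"/></Model>'
    )


def make_viral_fixture(out_dir, seed: int = 1) -> FixtureBundle:
    """Viral-spread recovery problem with synthetic observed data.

    Observed data are one stochastic simulation at the reference setting:
    the infected-cell count at t = 0..10 (11 rows) and a 5-bin radial
    profile of the infected-or-dead indicator at t = 10 (5 rows). The two
    transmission rates are estimated with log10-uniform priors spanning one
    decade either side of the truth.
    """
    base = Path(out_dir)
    params = REFERENCE_VIRAL_PARAMS
    width, height = VIRAL_GRID
    times = [float(t) for t in range(11)]
    n_bins = 5

    init = LatticeState.center_infected(width, height)
    traj = run_viral_model(params, init, seed, record_times=times, snapshot_times=[10.0])
    counts = [traj.at("infected_count", t) for t in times]
    grid = traj.snapshots[10.0]["infected_or_dead"]
    idx = _radial_bin_index(grid.shape, n_bins)
    sums = np.bincount(idx.ravel(), weights=grid.ravel(), minlength=n_bins)
    per_bin = np.bincount(idx.ravel(), minlength=n_bins)
    profile = sums / per_bin

    model = _viral_model_xml(params, width, height)
    parameters = _PARAM_HEADER + (
        "beta_cf\tlog10-uniform\t0.005\t0.5\tlog10\ttrue\t\t"
        "Model/Param[@name='beta_cf']/@value\n"
        "beta_cc\tlog10-uniform\t0.02\t2.0\tlog10\ttrue\t\t"
        "Model/Param[@name='beta_cc']/@value\n"
    )
    conditions = "condition_id\nc0\n"
    rows = ["observable_id\tcondition_id\ttime\tvalue\tdata_ref\treplicate_id"]
    for t, v in zip(times, counts):
        rows.append(f"infected_count\tc0\t{t:g}\t{v:g}\t\t")
    for v in profile:
        rows.append(f"occupied_radial\tc0\t10\t{float(v)!r}\t\t")
    measurements = "\n".join(rows) + "\n"
    statistics = (
        "statistic_id\tfunction_id\targs\tobservable_ids\n"
        "s_counts\tcount_timeseries\t"
        + json.dumps({"observable": "infected_count", "times": times})
        + "\tinfected_count\n"
        "s_radial\tradial_profile\t"
        + json.dumps({"observable": "infected_or_dead", "time": 10.0, "n_bins": n_bins})
        + "\toccupied_radial\n"
    )
    index = _write_bundle(base, model, parameters, conditions, measurements, statistics)
    return FixtureBundle(
        name="viral",
        index_path=index,
        ground_truth=dict(VIRAL_TRUTH),
        seed=seed,
    )


def make_budget_fixture(out_dir, seed: int = 1) -> FixtureBundle:
    """Early-rejection testbed: pure cell-to-cell spread with brisk cell death.

    With no virion route (beta_cf = p_prod = D = 0) a run ends as soon as
    the infection goes extinct, so the work a simulation consumes depends
    strongly on beta_cc: small rates burn a handful of steps, large rates
    the full hundred. Thresholding a pilot run's median work yields a budget
    that roughly half of all prior draws exceed.
    """
    base = Path(out_dir)
    params = ViralParams(
        beta_cf=0.0, beta_cc=0.2, p_prod=0.0, c_decay=0.0, D=0.0,
        delta_death=0.6, dt=0.1, t_end=10.0,
    )
    width = height = 21
    times = [float(t) for t in range(11)]
    init = LatticeState.center_infected(width, height)
    traj = run_viral_model(params, init, seed, record_times=times)

    model = _viral_model_xml(params, width, height)
    parameters = _PARAM_HEADER + (
        "beta_cc\tlog10-uniform\t0.02\t2.0\tlog10\ttrue\t\t"
        "Model/Param[@name='beta_cc']/@value\n"
    )
    conditions = "condition_id\nc0\n"
    rows = ["observable_id\tcondition_id\ttime\tvalue\tdata_ref\treplicate_id"]
    for t in times:
        rows.append(f"dead_count\tc0\t{t:g}\t{traj.at('dead_count', t):g}\t\t")
    measurements = "\n".join(rows) + "\n"
    statistics = (
        "statistic_id\tfunction_id\targs\tobservable_ids\n"
        "s_dead\tcount_timeseries\t"
        + json.dumps({"observable": "dead_count", "times": times})
        + "\tdead_count\n"
    )
    index = _write_bundle(base, model, parameters, conditions, measurements, statistics)
    return FixtureBundle(
        name="budget", index_path=index, ground_truth={"beta_cc": 0.2}, seed=seed
    )


def make_invalid_corpus(out_dir) -> list[FixtureBundle]:
    """Bundles each violating exactly one validation rule (>= 6 of them)."""
    out = Path(out_dir)
    gauss_model = (
        '<Model kind="gaussian">'
        '<Param name="theta" value="0.0"/>'
        '<Param name="noise_sd" value="1.0"/>'
        "</Model>"
    )
    conditions = "condition_id\nc0\n"
    measurements = (
        "observable_id\tcondition_id\ttime\tvalue\tdata_ref\treplicate_id\n"
        "y\tc0\t0\t1.0\t\t\n"
    )
    statistics = (
        "statistic_id\tfunction_id\targs\tobservable_ids\n"
        "y_stat\tcount_timeseries\t" + json.dumps({"observable": "y", "times": [0.0]}) + "\ty\n"
    )
    ok_param = "theta\tnormal\t0\t1\tlin\ttrue\t\tModel/Param[@name='theta']/@value\n"

    bundles = []

    def add(name, code, parameters=None, meas=None, stats=None):
        idx = _write_bundle(
            out / name,
            gauss_model,
            parameters if parameters is not None else _PARAM_HEADER + ok_param,
            conditions,
            meas if meas is not None else measurements,
            stats if stats is not None else statistics,
        )
        bundles.append(FixtureBundle(name=name, index_path=idx, expected_error_code=code))

    # 1. missing required column prior_kind
    add(
        "missing_column",
        "SCHEMA_MISSING_COLUMN",
        parameters=(
            "parameter_id\tprior_arg1\tprior_arg2\tscale\testimate\tnominal_value\ttarget_path\n"
            "theta\t0\t1\tlin\ttrue\t\tModel/Param[@name='theta']/@value\n"
        ),
    )
    # 2. measurement references an unknown condition
    add(
        "dangling_condition",
        "LINK_UNKNOWN_CONDITION",
        meas=(
            "observable_id\tcondition_id\ttime\tvalue\tdata_ref\treplicate_id\n"
            "y\tc99\t0\t1.0\t\t\n"
        ),
    )
    # 3. inverted uniform prior bounds
    add(
        "inverted_bounds",
        "PRIOR_BOUNDS",
        parameters=_PARAM_HEADER
        + "theta\tuniform\t2\t1\tlin\ttrue\t\tModel/Param[@name='theta']/@value\n",
    )
    # 4. non-positive log10-uniform lower bound
    add(
        "nonpositive_log_bound",
        "PRIOR_POSITIVITY",
        parameters=_PARAM_HEADER
        + "theta\tlog10-uniform\t0\t10\tlog10\ttrue\t\tModel/Param[@name='theta']/@value\n",
    )
    # 5. unresolvable target path
    add(
        "bad_path",
        "PATH_UNRESOLVABLE",
        parameters=_PARAM_HEADER
        + "theta\tnormal\t0\t1\tlin\ttrue\t\tModel/Param[@name='no_such']/@value\n",
    )
    # 6. unknown summary-statistic function
    add(
        "unknown_statistic",
        "STAT_UNKNOWN_FUNCTION",
        stats=(
            "statistic_id\tfunction_id\targs\tobservable_ids\n"
            "y_stat\tno_such_function\t{}\ty\n"
        ),
    )
    return bundles
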