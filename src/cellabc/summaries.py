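"""Summary statistics and weighted distances for likelihood-free inference.

Raw simulator output (a :class:`~cellabc.lattice.Trajectory`) is reduced to
a fixed-order vector of summary statistics by registry functions named in
the problem's statistic table; the same table maps the observed measurement
rows into a vector with identical names, so simulated and observed data are
always compared component by component.

Distances are weighted p-norms. Weights can be adapted per generation from
the spread of each statistic across the accepted population (MAD or SD
scale normalization — statistics measured in different units then
contribute comparably), and statistic vectors can optionally be projected
through a linear inverse-regression map ``s -> b0 + B s`` fitted on pilot
simulations, in which case the distance operates on predicted parameters
(the Fearnhead–Prangle construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .lattice import Trajectory
from .problem import ProblemSpec, SummaryStatisticSpec

logger = logging.getLogger(__name__)

__all__ = [
    "StatisticVector",
    "DistanceSpec",
    "RegressionMap",
    "STATISTIC_REGISTRY",
    "statistic_arg_errors",
    "compute_summaries",
    "observed_summaries",
    "distance",
    "adapt_weights",
    "fit_regression_statistics",
]


@dataclass
class StatisticVector:
    values: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")


@dataclass
class RegressionMap:
    """Affine map s -> b0 + B s used as a projected summary."""

    b0: np.ndarray
    B: np.ndarray

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return self.b0 + self.B @ np.asarray(s, dtype=float)


@dataclass
class DistanceSpec:
    p: int = 2
    weights: Optional[np.ndarray] = None  # None = all ones
    adapt: str = "mad"  # none | mad | sd
    regression_map: Optional[RegressionMap] = None

    def __post_init__(self):
        if self.p not in (1, 2):
            raise ValueError("norm order p must be 1 or 2")
        if self.adapt not in ("none", "mad", "sd"):
            raise ValueError(f"unknown adaptation scheme {self.adapt!r}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            if not np.any(self.weights > 0):
                raise ValueError("at least one weight must be positive")


# ---------------------------------------------------------------------------
# statistic registry


def _radial_bin_index(shape: tuple[int, int], n_bins: int) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    r_max = r.max()
    edges = np.linspace(0.0, r_max, n_bins + 1)
    idx = np.clip(np.digitize(r, edges[1:-1], right=True), 0, n_bins - 1)
    return idx


def _stat_count_timeseries(traj: Trajectory, args: dict) -> np.ndarray:
    obs = args["observable"]
    return np.array([traj.at(obs, t) for t in args["times"]])


def _stat_patch_radius(traj: Trajectory, args: dict) -> np.ndarray:
    # equivalent-circle radius sqrt(area/pi) of the infected+dead patch
    out = []
    for t in args["times"]:
        area = traj.at("infected_count", t) + traj.at("dead_count", t)
        out.append(np.sqrt(area / np.pi))
    return np.array(out)


def _stat_radial_profile(traj: Trajectory, args: dict) -> np.ndarray:
    t = float(args["time"])
    n_bins = int(args["n_bins"])
    key = args.get("observable", "infected_or_dead")
    match = [ts for ts in traj.snapshots if abs(ts - t) < 1e-9]
    if not match:
        raise KeyError(f"no snapshot recorded at time {t}")
    grid = traj.snapshots[match[0]][key]
    idx = _radial_bin_index(grid.shape, n_bins)
    sums = np.bincount(idx.ravel(), weights=grid.ravel(), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    return sums / counts


def _stat_final_fraction(traj: Trajectory, args: dict) -> np.ndarray:
    obs = args.get("observable", "infected_count")
    return np.array([traj.series[obs][-1] / traj.n_sites])


STATISTIC_REGISTRY = {
    "count_timeseries": _stat_count_timeseries,
    "patch_radius_timeseries": _stat_patch_radius,
    "radial_profile": _stat_radial_profile,
    "final_fraction": _stat_final_fraction,
}

_REQUIRED_ARGS = {
    "count_timeseries": ("observable", "times"),
    "patch_radius_timeseries": ("times",),
    "radial_profile": ("time", "n_bins"),
    "final_fraction": (),
}


def statistic_arg_errors(function_id: str, args: dict) -> list[str]:
    """Schema check of one statistic's args; returns human-readable problems."""
    errors = []
    for key in _REQUIRED_ARGS.get(function_id, ()):
        if key not in args:
            errors.append(f"missing required arg {key!r} for {function_id}")
    if function_id == "radial_profile" and "n_bins" in args:
        if not (isinstance(args["n_bins"], int) and args["n_bins"] >= 1):
            errors.append("n_bins must be a positive integer")
    return errors


def _component_names(spec: SummaryStatisticSpec, n: int) -> list[str]:
    if n == 1:
        return [spec.statistic_id]
    return [f"{spec.statistic_id}[{i}]" for i in range(n)]


def compute_summaries(traj: Trajectory, specs: Sequence[SummaryStatisticSpec]) -> StatisticVector:
    """Evaluate every statistic on a trajectory; components concatenate in table order."""
    values, names = [], []
    for spec in specs:
        fn = STATISTIC_REGISTRY.get(spec.function_id)
        if fn is None:
            raise KeyError(f"unknown statistic function {spec.function_id!r}")
        v = np.asarray(fn(traj, spec.args), dtype=float)
        values.append(v)
        names.extend(_component_names(spec, v.size))
    return StatisticVector(np.concatenate(values) if values else np.empty(0), names)


def observed_summaries(problem: ProblemSpec, condition_id: str) -> StatisticVector:
    """Assemble the observed statistic vector from the measurement table.

    For time-series statistics the observed components are the measurement
    values of the statistic's observable at the requested times (averaged
    over replicates); for ``radial_profile`` the table must carry exactly
    ``n_bins`` rows for (observable, time), taken as bins in table order.
    """
    from .problem import load_gridded_array  # noqa: F401  (data_ref support)

    rows = [m for m in problem.measurement_table if m.condition_id == condition_id]
    values, names = [], []
    for spec in problem.statistic_table:
        obs_id = spec.observable_ids[0] if spec.observable_ids else spec.args.get("observable")
        if spec.function_id in ("count_timeseries", "patch_radius_timeseries"):
            v = []
            for t in spec.args["times"]:
                matches = [
                    m.value
                    for m in rows
                    if m.observable_id == obs_id and abs(m.time - float(t)) < 1e-9
                ]
                if not matches:
                    raise KeyError(
                        f"no measurement of {obs_id!r} at time {t} for condition {condition_id!r}"
                    )
                v.append(float(np.mean(matches)))
            v = np.asarray(v)
        elif spec.function_id == "radial_profile":
            t = float(spec.args["time"])
            n_bins = int(spec.args["n_bins"])
            matches = [m.value for m in rows if m.observable_id == obs_id and abs(m.time - t) < 1e-9]
            if len(matches) != n_bins:
                raise ValueError(
                    f"radial_profile {spec.statistic_id!r} expects {n_bins} rows of "
                    f"{obs_id!r} at t={t}, found {len(matches)}"
                )
            v = np.asarray(matches, dtype=float)
        elif spec.function_id == "final_fraction":
            matches = [m.value for m in rows if m.observable_id == obs_id]
            v = np.asarray([float(np.mean(matches))])
        else:
            raise KeyError(f"unknown statistic function {spec.function_id!r}")
        values.append(v)
        names.extend(_component_names(spec, v.size))
    return StatisticVector(np.concatenate(values) if values else np.empty(0), names)


# ---------------------------------------------------------------------------
# distances


def distance(sim: StatisticVector, obs: StatisticVector, d: DistanceSpec) -> float:
    """Weighted p-norm (sum_i w_i |sim_i - obs_i|^p)^(1/p), optionally projected."""
    if sim.names != obs.names:
        raise ValueError(f"statistic name mismatch: {sim.names} vs {obs.names}")
    x, y = sim.values, obs.values
    if d.regression_map is not None:
        x, y = d.regression_map(x), d.regression_map(y)
        w = np.ones(x.size) if d.weights is None or d.weights.size != x.size else d.weights
    else:
        w = np.ones(x.size) if d.weights is None else d.weights
        if w.size != x.size:
            raise ValueError(f"{w.size} weights for {x.size} statistics")
    diff = np.abs(x - y)
    return float(np.sum(w * diff**d.p) ** (1.0 / d.p))


def adapt_weights(
    summaries_of_population: Sequence[StatisticVector], scheme: str, normalize: bool = False
) -> np.ndarray:
    """Per-statistic weights 1/scale from a population of statistic vectors.

    scale is the median absolute deviation (``mad``) or the sample standard
    deviation (``sd``, ddof=1) of each component across the population. A
    zero scale (statistic constant this generation) yields weight 0 with a
    logged warning: the statistic is uninformative for this generation.
    """
    if len(summaries_of_population) < 2:
        raise ValueError("need at least 2 statistic vectors to adapt weights")
    mat = np.stack([s.values for s in summaries_of_population])
    if scheme == "mad":
        scale = np.median(np.abs(mat - np.median(mat, axis=0)), axis=0)
    elif scheme == "sd":
        scale = np.std(mat, axis=0, ddof=1)
    else:
        raise ValueError(f"unknown adaptation scheme {scheme!r}")
    weights = np.zeros_like(scale)
    nonzero = scale > 0
    weights[nonzero] = 1.0 / scale[nonzero]
    if np.any(~nonzero):
        names = summaries_of_population[0].names
        flat = [names[i] for i in np.flatnonzero(~nonzero)]
        logger.warning("zero %s scale for statistics %s: weight set to 0", scheme, flat)
    if normalize and np.any(nonzero):
        # standardize the vector (mean positive weight = 1) so distances --
        # and hence acceptance thresholds -- stay comparable across
        # generations as the population concentrates and scales shrink
        weights = weights / weights[nonzero].mean()
    return weights


def fit_regression_statistics(
    thetas: Sequence[np.ndarray], summaries: Sequence[StatisticVector]
) -> RegressionMap:
    """Least-squares fit of theta on s: one linear model per parameter.

    Returns the affine map s -> b0 + B s whose output (the predicted
    parameters) serves as the projected summary statistic. On a
    rank-deficient design the fit falls back to ridge regression with fixed
    regularization 1e-8 and logs a notice.
    """
    TH = np.stack([np.asarray(t, dtype=float).ravel() for t in thetas])
    S = np.stack([s.values for s in summaries])
    n, k = S.shape
    if n < TH.shape[1] + k + 1:
        raise ValueError(
            f"need at least dim(theta)+dim(s)+1 = {TH.shape[1] + k + 1} samples, got {n}"
        )
    X = np.column_stack([np.ones(n), S])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("rank-deficient regression design: using ridge fallback (1e-8)")
        lam = 1e-8
        A = X.T @ X + lam * np.eye(X.shape[1])
        coef = np.linalg.solve(A, X.T @ TH)
    else:
        coef, *_ = np.linalg.lstsq(X, TH, rcond=None)
    return RegressionMap(b0=coef[0].copy(), B=coef[1:].T.copy())
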