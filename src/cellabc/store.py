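"""Result persistence and posterior diagnostics.

A :class:`ResultStore` records every generation of a run — threshold,
proposal counts, wall time, and the full particle table (parameters,
weights, distances, summaries) — and round-trips losslessly through a
single sqlite database file, the shareable artifact of a fit. The
diagnostics here (effective sample size, weighted credible intervals,
epsilon/sample trajectories, weighted 2-D kernel density estimates) are the
data behind the usual ABC monitoring plots; they are emitted as plain
tsv/npy files so any plotting tool can render them.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .weighted import ess, weighted_quantile

__all__ = [
    "GenerationRecord",
    "ResultStore",
    "ess",
    "credible_interval",
    "epsilon_trajectory",
    "samples_per_generation",
    "kde2d",
    "export_report",
]


@dataclass
class GenerationRecord:
    t: int
    epsilon: float
    total_proposals: int
    wall_seconds: float
    thetas: np.ndarray  # (N, dim)
    weights: np.ndarray  # (N,)
    distances: np.ndarray  # (N,)
    summaries: np.ndarray  # (N, n_stats); empty second axis if absent


@dataclass
class ResultStore:
    problem_fingerprint: str = ""
    config: dict = field(default_factory=dict)
    parameter_names: list[str] = field(default_factory=list)
    statistic_names: list[str] = field(default_factory=list)
    generations: list[GenerationRecord] = field(default_factory=list)

    def append_generation(self, population, wall_seconds: float = 0.0) -> None:
        summaries = [pt.summaries for pt in population.particles]
        if all(s is not None for s in summaries):
            smat = np.stack([s.values for s in summaries])
            if not self.statistic_names and summaries:
                self.statistic_names = list(summaries[0].names)
        else:
            smat = np.empty((len(summaries), 0))
        self.generations.append(
            GenerationRecord(
                t=population.generation_index,
                epsilon=float(population.epsilon),
                total_proposals=int(population.total_proposals),
                wall_seconds=float(wall_seconds),
                thetas=population.thetas.astype(float),
                weights=population.weights.astype(float),
                distances=population.distances.astype(float),
                summaries=smat.astype(float),
            )
        )

    @property
    def final(self) -> GenerationRecord:
        if not self.generations:
            raise ValueError("empty result store")
        return self.generations[-1]

    # -- persistence --------------------------------------------------------

    def save(self, path, include_timing: bool = True) -> None:
        """Write the store to a single sqlite file (REAL = 8-byte IEEE, lossless).

        ``include_timing=False`` zeroes the wall-second column, yielding a
        canonical file that is byte-identical across reruns of a
        deterministic run.
        """
        path = Path(path)
        if path.exists():
            path.unlink()
        con = sqlite3.connect(path)
        try:
            cur = con.cursor()
            cur.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
            cur.execute(
                "CREATE TABLE generations (t INTEGER PRIMARY KEY, epsilon REAL,"
                " total_proposals INTEGER, wall_seconds REAL)"
            )
            cur.execute(
                "CREATE TABLE particles (generation INTEGER, idx INTEGER,"
                " weight REAL, distance REAL, PRIMARY KEY (generation, idx))"
            )
            cur.execute(
                "CREATE TABLE thetas (generation INTEGER, idx INTEGER,"
                " param INTEGER, value REAL, PRIMARY KEY (generation, idx, param))"
            )
            cur.execute(
                "CREATE TABLE summaries (generation INTEGER, idx INTEGER,"
                " stat INTEGER, value REAL, PRIMARY KEY (generation, idx, stat))"
            )
            meta = {
                "problem_fingerprint": self.problem_fingerprint,
                "config": json.dumps(self.config, sort_keys=True),
                "parameter_names": json.dumps(self.parameter_names),
                "statistic_names": json.dumps(self.statistic_names),
            }
            cur.executemany("INSERT INTO meta VALUES (?, ?)", sorted(meta.items()))
            for g in self.generations:
                wall = g.wall_seconds if include_timing else 0.0
                cur.execute(
                    "INSERT INTO generations VALUES (?, ?, ?, ?)",
                    (g.t, g.epsilon, g.total_proposals, wall),
                )
                cur.executemany(
                    "INSERT INTO particles VALUES (?, ?, ?, ?)",
                    [
                        (g.t, i, float(g.weights[i]), float(g.distances[i]))
                        for i in range(len(g.weights))
                    ],
                )
                cur.executemany(
                    "INSERT INTO thetas VALUES (?, ?, ?, ?)",
                    [
                        (g.t, i, j, float(g.thetas[i, j]))
                        for i in range(g.thetas.shape[0])
                        for j in range(g.thetas.shape[1])
                    ],
                )
                cur.executemany(
                    "INSERT INTO summaries VALUES (?, ?, ?, ?)",
                    [
                        (g.t, i, j, float(g.summaries[i, j]))
                        for i in range(g.summaries.shape[0])
                        for j in range(g.summaries.shape[1])
                    ],
                )
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path) -> "ResultStore":
        con = sqlite3.connect(Path(path))
        try:
            meta = dict(con.execute("SELECT key, value FROM meta"))
            store = cls(
                problem_fingerprint=meta["problem_fingerprint"],
                config=json.loads(meta["config"]),
                parameter_names=json.loads(meta["parameter_names"]),
                statistic_names=json.loads(meta["statistic_names"]),
            )
            gens = con.execute(
                "SELECT t, epsilon, total_proposals, wall_seconds FROM generations ORDER BY t"
            ).fetchall()
            for t, eps, total, wall in gens:
                pw = con.execute(
                    "SELECT weight, distance FROM particles WHERE generation=? ORDER BY idx",
                    (t,),
                ).fetchall()
                n = len(pw)
                th = con.execute(
                    "SELECT idx, param, value FROM thetas WHERE generation=? ORDER BY idx, param",
                    (t,),
                ).fetchall()
                dim = (max(r[1] for r in th) + 1) if th else 0
                thetas = np.zeros((n, dim))
                for i, j, v in th:
                    thetas[i, j] = v
                sm = con.execute(
                    "SELECT idx, stat, value FROM summaries WHERE generation=? ORDER BY idx, stat",
                    (t,),
                ).fetchall()
                sdim = (max(r[1] for r in sm) + 1) if sm else 0
                summaries = np.zeros((n, sdim))
                for i, j, v in sm:
                    summaries[i, j] = v
                store.generations.append(
                    GenerationRecord(
                        t=int(t),
                        epsilon=float(eps),
                        total_proposals=int(total),
                        wall_seconds=float(wall),
                        thetas=thetas,
                        weights=np.array([r[0] for r in pw]),
                        distances=np.array([r[1] for r in pw]),
                        summaries=summaries,
                    )
                )
            return store
        finally:
            con.close()

    def equals(self, other: "ResultStore", include_timing: bool = True) -> bool:
        if (
            self.problem_fingerprint != other.problem_fingerprint
            or self.config != other.config
            or self.parameter_names != other.parameter_names
            or self.statistic_names != other.statistic_names
            or len(self.generations) != len(other.generations)
        ):
            return False
        for a, b in zip(self.generations, other.generations):
            if a.t != b.t or a.total_proposals != b.total_proposals:
                return False
            if not (a.epsilon == b.epsilon or (np.isinf(a.epsilon) and np.isinf(b.epsilon))):
                return False
            if include_timing and a.wall_seconds != b.wall_seconds:
                return False
            for x, y in ((a.thetas, b.thetas), (a.weights, b.weights), (a.summaries, b.summaries)):
                if not np.array_equal(x, y):
                    return False
            if not np.array_equal(
                np.nan_to_num(a.distances, posinf=np.finfo(float).max),
                np.nan_to_num(b.distances, posinf=np.finfo(float).max),
            ):
                return False
        return True


# ---------------------------------------------------------------------------
# diagnostics


def credible_interval(theta_samples, weights, level: float = 0.95):
    """Weighted credible interval(s) at the given level, per parameter.

    The endpoints are weighted type-1 quantiles at ``(1-level)/2`` and
    ``1-(1-level)/2``; with equal weights they coincide with the ordinary
    empirical quantiles.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    th = np.atleast_2d(np.asarray(theta_samples, dtype=float))
    if th.shape[0] == 1 and np.asarray(theta_samples).ndim == 1:
        th = th.T
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    out = []
    for j in range(th.shape[1]):
        out.append(
            (
                weighted_quantile(th[:, j], weights, lo_q),
                weighted_quantile(th[:, j], weights, hi_q),
            )
        )
    return out if th.shape[1] > 1 else out[0]


def epsilon_trajectory(store: ResultStore) -> list[tuple[int, float]]:
    return [(g.t, g.epsilon) for g in store.generations]


def samples_per_generation(store: ResultStore) -> list[tuple[int, int, int]]:
    return [(g.t, g.total_proposals, len(g.weights)) for g in store.generations]


def kde2d(x_samples, y_samples, weights, grid):
    """Weighted Gaussian-product KDE evaluated on a rectangular grid.

    ``grid`` is ``(x_grid, y_grid)``; the returned matrix has shape
    ``(len(x_grid), len(y_grid))``. The per-dimension bandwidth is the
    Silverman factor ``n_eff**(-1/6)`` (2-D rule) times the weighted
    standard deviation, with the effective sample size standing in for n.
    """
    x = np.asarray(x_samples, dtype=float)
    y = np.asarray(y_samples, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y, weights must have equal length")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be normalized")
    n_eff = ess(w)
    bw = []
    for v in (x, y):
        mu = w @ v
        var = w @ (v - mu) ** 2
        if var <= 0:
            raise ValueError(
                "zero weighted variance in one dimension: density is degenerate, use a rug plot"
            )
        bw.append(np.sqrt(var) * n_eff ** (-1.0 / 6.0))
    gx, gy = (np.asarray(g, dtype=float) for g in grid)
    kx = np.exp(-0.5 * ((gx[:, None] - x[None, :]) / bw[0]) ** 2) / (bw[0] * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - y[None, :]) / bw[1]) ** 2) / (bw[1] * np.sqrt(2 * np.pi))
    return (kx * w[None, :]) @ ky.T


def export_report(
    store: ResultStore,
    out_dir,
    levels: Sequence[float] = (0.95,),
    kde_grid_size: int = 64,
    kde_pairs: Optional[Sequence[tuple[int, int]]] = None,
) -> list[Path]:
    """Write the diagnostic tables a run report is plotted from.

    Emits epsilon_trajectory.tsv, ess.tsv, samples_per_generation.tsv, one
    ci_<level>.tsv per level (final generation), and one kde_<p1>_<p2>.npy
    per parameter pair of the final generation.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    df = pd.DataFrame(epsilon_trajectory(store), columns=["t", "epsilon"])
    written.append(out / "epsilon_trajectory.tsv")
    df.to_csv(written[-1], sep="\t", index=False)

    df = pd.DataFrame(
        [(g.t, ess(g.weights)) for g in store.generations], columns=["t", "ess"]
    )
    written.append(out / "ess.tsv")
    df.to_csv(written[-1], sep="\t", index=False)

    df = pd.DataFrame(
        samples_per_generation(store), columns=["t", "total_proposals", "n_accepted"]
    )
    written.append(out / "samples_per_generation.tsv")
    df.to_csv(written[-1], sep="\t", index=False)

    g = store.final
    names = store.parameter_names or [f"p{j}" for j in range(g.thetas.shape[1])]
    for level in levels:
        rows = []
        for j, name in enumerate(names):
            lo, hi = (
                weighted_quantile(g.thetas[:, j], g.weights, (1 - level) / 2),
                weighted_quantile(g.thetas[:, j], g.weights, 1 - (1 - level) / 2),
            )
            rows.append({"parameter": name, "lower": lo, "upper": hi})
        written.append(out / f"ci_{level:g}.tsv")
        pd.DataFrame(rows).to_csv(written[-1], sep="\t", index=False)

    dim = g.thetas.shape[1]
    pairs = kde_pairs if kde_pairs is not None else [
        (i, j) for i in range(dim) for j in range(i + 1, dim)
    ]
    for i, j in pairs:
        xi, yj, w = g.thetas[:, i], g.thetas[:, j], g.weights
        span = lambda v: (v.min() - 0.1 * (np.ptp(v) + 1e-9), v.max() + 0.1 * (np.ptp(v) + 1e-9))
        gx = np.linspace(*span(xi), kde_grid_size)
        gy = np.linspace(*span(yj), kde_grid_size)
        try:
            dens = kde2d(xi, yj, w, (gx, gy))
        except ValueError:
            continue  # degenerate dimension: nothing to plot
        written.append(out / f"kde_{names[i]}_{names[j]}.npy")
        np.save(written[-1], dens)
    return written
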