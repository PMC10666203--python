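"""Stochastic lattice simulation of viral spread through a tissue patch.

The model is a synchronous cellular automaton on a rectangular grid coupled
to an explicit reaction-diffusion field. Each lattice site holds one cell in
state SUSCEPTIBLE, INFECTED or DEAD; a continuous virion concentration field
V(x, t) lives on the same grid. Infection spreads through two routes:

* **cell-free**: a susceptible cell is infected by local virions with hazard
  ``beta_cf * V``;
* **cell-to-cell**: direct contact with each infected von Neumann neighbor
  contributes hazard ``beta_cc``.

Within one step of length ``dt`` a susceptible site becomes infected with
probability ``1 - exp(-(beta_cf * V + beta_cc * n_inf) * dt)``; an infected
site dies with probability ``1 - exp(-delta_death * dt)``; infected cells
produce virions at rate ``p_prod`` which diffuse (forward-Euler 5-point
stencil, zero-flux boundaries) and decay at rate ``c_decay``. All hazards are
evaluated on the pre-step configuration, so a single update is an exact
product of independent Bernoulli draws — which is what makes the simulator
testable against closed-form binomial oracles.

The explicit scheme requires ``D * dt <= 1/4`` (lattice spacing 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SUSCEPTIBLE",
    "INFECTED",
    "DEAD",
    "LatticeState",
    "ViralParams",
    "Trajectory",
    "BudgetExceeded",
    "diffusion_step",
    "infection_probability",
    "viral_step",
    "run_viral_model",
    "simulate_model",
    "write_trajectory",
]

SUSCEPTIBLE, INFECTED, DEAD = 0, 1, 2


class BudgetExceeded(Exception):
    """A simulation hit its early-rejection work budget before finishing."""

    def __init__(self, work_done: int):
        self.work_done = work_done
        super().__init__(f"simulation budget exhausted after {work_done} work units")


@dataclass
class ViralParams:
    """Rates of the two-route infection model; lattice spacing is 1.

    beta_cf
        cell-free infection rate per unit virion concentration per unit time
    beta_cc
        cell-to-cell rate per infected neighbor per unit time
    p_prod
        virion production per infected cell per unit time
    c_decay
        virion decay rate
    D
        virion diffusion coefficient
    delta_death
        infected-cell death rate
    """

    beta_cf: float = 0.05
    beta_cc: float = 0.2
    p_prod: float = 1.0
    c_decay: float = 0.1
    D: float = 0.5
    delta_death: float = 0.05
    dt: float = 0.1
    t_end: float = 10.0

    def validate(self) -> None:
        for name in ("beta_cf", "beta_cc", "p_prod", "c_decay", "D", "delta_death"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt <= 0 or self.t_end < 0:
            raise ValueError("dt must be > 0 and t_end >= 0")
        if self.D * self.dt > 0.25 + 1e-12:
            raise ValueError(
                f"explicit scheme unstable: D*dt = {self.D * self.dt:.4g} > 1/4 (dx=1)"
            )


@dataclass
class LatticeState:
    cell_state: np.ndarray  # uint8 grid
    virion_field: np.ndarray  # float grid, same shape
    time: float = 0.0

    def __post_init__(self):
        self.cell_state = np.asarray(self.cell_state, dtype=np.uint8)
        self.virion_field = np.asarray(self.virion_field, dtype=float)
        if self.cell_state.shape != self.virion_field.shape:
            raise ValueError("cell_state and virion_field must share a shape")

    @classmethod
    def center_infected(cls, width: int, height: int) -> "LatticeState":
        grid = np.zeros((height, width), dtype=np.uint8)
        grid[height // 2, width // 2] = INFECTED
        return cls(grid, np.zeros((height, width)))

    def counts(self) -> tuple[int, int, int]:
        return (
            int(np.count_nonzero(self.cell_state == SUSCEPTIBLE)),
            int(np.count_nonzero(self.cell_state == INFECTED)),
            int(np.count_nonzero(self.cell_state == DEAD)),
        )

    def copy(self) -> "LatticeState":
        return LatticeState(self.cell_state.copy(), self.virion_field.copy(), self.time)


@dataclass
class Trajectory:
    """Recorded output of one simulation run.

    ``series`` maps an observable name (infected_count, dead_count,
    susceptible_count, virion_total, or a model-specific scalar) to values at
    ``times``. ``snapshots`` maps a recording time to named 2-D grids
    (``infected``, ``dead``, ``infected_or_dead`` indicators and ``virion``).
    """

    times: np.ndarray
    series: dict[str, np.ndarray]
    snapshots: dict[float, dict[str, np.ndarray]] = field(default_factory=dict)
    n_sites: int = 0
    work: int = 0  # work units consumed (early-rejection accounting)

    def at(self, observable: str, time: float) -> float:
        index = self.__dict__.get("_time_index")
        if index is None:
            index = {round(float(t), 9): i for i, t in enumerate(self.times)}
            self.__dict__["_time_index"] = index
        i = index.get(round(float(time), 9))
        if i is None:
            raise KeyError(f"time {time} not recorded in trajectory")
        return float(self.series[observable][i])


def diffusion_step(field, D, decay, source, dt):
    """One forward-Euler step of du/dt = D lap(u) + source - decay*u.

    Zero-flux (reflecting) boundaries via edge replication; with zero source
    and decay the stencil conserves total mass exactly. Every site's update
    is a convex combination of non-negative inputs when
    ``4*D*dt + decay*dt <= 1``, so the result is then provably non-negative
    and is returned untouched; outside that regime (large decay per step) it
    is clipped at zero.
    """
    field = np.asarray(field, dtype=float)
    if D * dt > 0.25 + 1e-12:
        raise ValueError(f"stability bound violated: D*dt = {D * dt:.4g} > 1/4")
    # neighbor sum with edge replication (ghost cell = boundary value <=> zero flux)
    lap = field * -4.0
    lap[1:, :] += field[:-1, :]
    lap[0, :] += field[0, :]
    lap[:-1, :] += field[1:, :]
    lap[-1, :] += field[-1, :]
    lap[:, 1:] += field[:, :-1]
    lap[:, 0] += field[:, 0]
    lap[:, :-1] += field[:, 1:]
    lap[:, -1] += field[:, -1]
    lap *= D
    lap += np.asarray(source, dtype=float)
    lap -= decay * field
    lap *= dt
    out = lap
    out += field
    if 4.0 * D * dt + decay * dt > 1.0:
        np.clip(out, 0.0, None, out=out)
    return out


def infection_probability(V_local, n_infected_neighbors, params: ViralParams):
    """P(infection within dt) = 1 - exp(-(beta_cf*V + beta_cc*n) * dt)."""
    hazard = params.beta_cf * np.asarray(V_local, dtype=float) + params.beta_cc * np.asarray(
        n_infected_neighbors, dtype=float
    )
    return -np.expm1(-hazard * params.dt)


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    """Number of von Neumann neighbors where mask is true (no wraparound)."""
    m = mask.view(np.uint8) if mask.dtype == bool else mask.astype(np.uint8)
    out = np.zeros(m.shape, dtype=np.uint8)
    out[1:, :] += m[:-1, :]
    out[:-1, :] += m[1:, :]
    out[:, 1:] += m[:, :-1]
    out[:, :-1] += m[:, 1:]
    return out


def viral_step(state: LatticeState, params: ViralParams, rng: np.random.Generator) -> LatticeState:
    """One synchronous update of duration dt: diffuse, infect, die.

    All hazards use the pre-step configuration: the infected-neighbor counts,
    the virion concentrations entering the infection probability, and the set
    of cells at risk of death are those *before* this step's changes.
    """
    cells = state.cell_state
    infected = cells == INFECTED
    source = params.p_prod * infected
    new_field = diffusion_step(state.virion_field, params.D, params.c_decay, source, params.dt)

    # fused infection_probability: hazard = beta_cf*V + beta_cc*n_neighbors
    hazard = state.virion_field * (params.beta_cf * params.dt)
    if params.beta_cc != 0.0:
        hazard += _neighbor_count(infected) * (params.beta_cc * params.dt)
    np.negative(hazard, out=hazard)
    np.expm1(hazard, out=hazard)
    np.negative(hazard, out=hazard)  # hazard now holds p_inf

    draws = rng.random((2,) + cells.shape)
    newly_infected = (cells == SUSCEPTIBLE) & (draws[0] < hazard)
    p_death = -np.expm1(-params.delta_death * params.dt)
    newly_dead = infected & (draws[1] < p_death)

    new_cells = cells.copy()
    new_cells[newly_infected] = INFECTED
    new_cells[newly_dead] = DEAD
    return LatticeState(new_cells, new_field, state.time + params.dt)


def run_viral_model(
    params: ViralParams,
    init: LatticeState,
    seed,
    record_times: Optional[Sequence[float]] = None,
    snapshot_times: Sequence[float] = (),
    budget: Optional[int] = None,
) -> Trajectory:
    """Simulate the viral model and record counts/snapshots at given times.

    A deterministic function of (params, init, seed). ``seed`` may be an int
    or a ``numpy.random.SeedSequence``. ``budget`` caps the number of lattice
    update steps (work units); exceeding it raises :class:`BudgetExceeded`.

    The run stops early once no infected cell remains *and* the virion field
    is identically zero — from then on the recorded observables are frozen,
    so remaining record times are filled without further stepping. This
    makes the work consumed depend on the parameters (fast-extinguishing
    epidemics are cheap), which is what the early-rejection budget exploits.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n_steps = int(round(params.t_end / params.dt))
    if record_times is None:
        record_times = np.arange(n_steps + 1) * params.dt
    record_times = np.asarray(sorted(set(float(t) for t in record_times)))
    snapshot_times = sorted(set(float(t) for t in snapshot_times))
    for t in list(record_times) + snapshot_times:
        k = t / params.dt
        if abs(k - round(k)) > 1e-6 or t > params.t_end + 1e-9:
            raise ValueError(f"requested time {t} is not a multiple of dt within t_end")

    state = init.copy()
    n_sites = state.cell_state.size
    times, inf_c, dead_c, susc_c, vtot = [], [], [], [], []
    snapshots: dict[float, dict[str, np.ndarray]] = {}
    work = 0

    def record(st: LatticeState):
        s, i, d = st.counts()
        times.append(st.time)
        susc_c.append(s)
        inf_c.append(i)
        dead_c.append(d)
        vtot.append(float(st.virion_field.sum()))

    def snapshot(st: LatticeState):
        t = round(st.time / params.dt) * params.dt
        snapshots[float(t)] = {
            "infected": (st.cell_state == INFECTED).astype(float),
            "dead": (st.cell_state == DEAD).astype(float),
            "infected_or_dead": (st.cell_state != SUSCEPTIBLE).astype(float),
            "virion": st.virion_field.copy(),
        }

    record_steps = {int(round(t / params.dt)) for t in record_times}
    snapshot_steps = {int(round(t / params.dt)) for t in snapshot_times}

    def maybe_record(st: LatticeState, step_index: int):
        if step_index in record_steps:
            record(st)
        if step_index in snapshot_steps:
            snapshot(st)

    maybe_record(state, 0)
    for k in range(1, n_steps + 1):
        extinct = not (state.cell_state == INFECTED).any() and state.virion_field.sum() == 0.0
        if extinct:
            # nothing can change any more: freeze remaining records
            for t in record_times[record_times > state.time + 1e-9]:
                frozen = replace(state.copy(), time=float(t))
                record(frozen)
            for ts in snapshot_times:
                if ts > state.time + 1e-9:
                    frozen = replace(state.copy(), time=float(ts))
                    snapshot(frozen)
            break
        if budget is not None and work + 1 > budget:
            raise BudgetExceeded(work)
        state = viral_step(state, params, rng)
        work += 1
        maybe_record(state, k)

    return Trajectory(
        times=np.asarray(times),
        series={
            "infected_count": np.asarray(inf_c, dtype=float),
            "dead_count": np.asarray(dead_c, dtype=float),
            "susceptible_count": np.asarray(susc_c, dtype=float),
            "virion_total": np.asarray(vtot, dtype=float),
        },
        snapshots=snapshots,
        n_sites=n_sites,
        work=work,
    )


# ---------------------------------------------------------------------------
# model-document dispatcher


def _param_map(doc) -> dict[str, float]:
    return {
        el.get("name"): float(el.get("value"))
        for el in doc.iter("Param")
        if el.get("name") is not None
    }


def simulate_model(
    doc,
    seed,
    record_times: Optional[Sequence[float]] = None,
    snapshot_times: Sequence[float] = (),
    budget: Optional[int] = None,
) -> Trajectory:
    """Run the simulator a model document describes.

    Dispatches on the ``kind`` attribute of the root element:

    * ``viral`` — the two-route lattice model; ``<Lattice width height
      init_infected="center"/>`` fixes the geometry, ``<Param name value/>``
      elements the rates (beta_cf, beta_cc, p_prod, c_decay, D, delta_death,
      dt, t_end).
    * ``gaussian`` — the conjugate toy: one draw y = theta + N(0, noise_sd^2),
      reported as observable ``y`` at every requested time (the model is
      static); charges one work unit.
    """
    kind = doc.get("kind")
    pars = _param_map(doc)
    if kind == "viral":
        lat = doc.find("Lattice")
        if lat is None:
            raise ValueError("viral model document lacks a <Lattice> element")
        width, height = int(lat.get("width")), int(lat.get("height"))
        if lat.get("init_infected", "center") != "center":
            raise ValueError("only init_infected='center' is supported")
        params = ViralParams(
            beta_cf=pars.get("beta_cf", 0.0),
            beta_cc=pars.get("beta_cc", 0.0),
            p_prod=pars.get("p_prod", 0.0),
            c_decay=pars.get("c_decay", 0.0),
            D=pars.get("D", 0.0),
            delta_death=pars.get("delta_death", 0.0),
            dt=pars.get("dt", 0.1),
            t_end=pars.get("t_end", 10.0),
        )
        init = LatticeState.center_infected(width, height)
        return run_viral_model(
            params, init, seed, record_times, snapshot_times=snapshot_times, budget=budget
        )
    if kind == "gaussian":
        if budget is not None and budget < 1:
            raise BudgetExceeded(0)
        rng = np.random.default_rng(seed)
        y = pars["theta"] + pars.get("noise_sd", 1.0) * rng.standard_normal()
        times = np.asarray(record_times if record_times is not None else [0.0], dtype=float)
        return Trajectory(
            times=times,
            series={"y": np.full(times.shape, y)},
            n_sites=1,
            work=1,
        )
    raise ValueError(f"unknown model kind {kind!r}")


def write_trajectory(traj: Trajectory, out_dir) -> None:
    """Write counts as tsv and field snapshots as CSV matrices."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {"time": traj.times}
    cols.update({k: v for k, v in traj.series.items()})
    pd.DataFrame(cols).to_csv(out / "trajectory.tsv", sep="\t", index=False)
    for t, grids in traj.snapshots.items():
        np.savetxt(out / f"snapshot_t{t:g}.csv", grids["virion"], delimiter=",")
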