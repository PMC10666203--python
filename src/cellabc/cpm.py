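"""Cellular Potts model: Metropolis kinetics on a spin lattice.

Cells are connected domains of equal spin (cell id); spin 0 is medium. The
energy is the standard adhesion + volume-constraint Hamiltonian

    H = sum_{<x,x'>: s(x) != s(x')} J(type(s(x)), type(s(x')))
        + lambda_v * sum_{cells k} (volume_k - V_T_k)^2

over 4-neighbor site pairs, with no wraparound (a bounded tissue patch).
Dynamics are boundary copy attempts: pick a random site and a random
neighbor, propose copying the neighbor's spin, accept with probability
min(1, exp(-dH / T)). One Monte Carlo sweep makes width*height attempts.

The kernel tracks cell volumes incrementally; `cpm_hamiltonian` recomputes
the energy from scratch and is the test oracle for the incremental dH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CPMState", "cpm_hamiltonian", "cpm_step"]


@dataclass
class CPMState:
    spin: np.ndarray  # int grid; 0 = medium, k > 0 = cell id
    cell_type: np.ndarray  # type index per cell id (index 0 = medium)
    adhesion: np.ndarray  # symmetric J matrix over type pairs
    target_volume: np.ndarray  # per cell id; entry 0 ignored
    lambda_v: float = 1.0
    temperature: float = 1.0
    volume: np.ndarray = field(default=None)  # per cell id, tracked incrementally

    def __post_init__(self):
        self.spin = np.asarray(self.spin, dtype=np.int64)
        self.cell_type = np.asarray(self.cell_type, dtype=np.int64)
        self.adhesion = np.asarray(self.adhesion, dtype=float)
        self.target_volume = np.asarray(self.target_volume, dtype=np.int64)
        if not np.allclose(self.adhesion, self.adhesion.T):
            raise ValueError("adhesion matrix J must be symmetric")
        if self.volume is None:
            self.volume = np.bincount(self.spin.ravel(), minlength=len(self.target_volume))
        else:
            self.volume = np.asarray(self.volume, dtype=np.int64)

    def recount_volumes(self) -> np.ndarray:
        return np.bincount(self.spin.ravel(), minlength=len(self.target_volume))

    def copy(self) -> "CPMState":
        return CPMState(
            self.spin.copy(),
            self.cell_type.copy(),
            self.adhesion.copy(),
            self.target_volume.copy(),
            self.lambda_v,
            self.temperature,
            self.volume.copy(),
        )


def cpm_hamiltonian(state: CPMState) -> float:
    """Full-recompute energy: adhesion over heterotypic interfaces + volume term."""
    s = state.spin
    t = state.cell_type
    J = state.adhesion
    e = 0.0
    # horizontal and vertical neighbor pairs, each counted once
    for a, b in ((s[:, :-1], s[:, 1:]), (s[:-1, :], s[1:, :])):
        diff = a != b
        e += float(J[t[a[diff]], t[b[diff]]].sum())
    vols = state.recount_volumes()
    cells = np.arange(1, len(state.target_volume))
    e += state.lambda_v * float(((vols[cells] - state.target_volume[cells]) ** 2).sum())
    return e


_DIRS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _delta_h(state: CPMState, i: int, j: int, s_new: int) -> float:
    """Local energy change of writing spin s_new at site (i, j)."""
    s = state.spin
    t = state.cell_type
    J = state.adhesion
    s_old = s[i, j]
    h, w = s.shape
    d_adh = 0.0
    for di, dj in _DIRS:
        ni, nj = i + di, j + dj
        if 0 <= ni < h and 0 <= nj < w:
            sn = s[ni, nj]
            if sn != s_old:
                d_adh -= J[t[s_old], t[sn]]
            if sn != s_new:
                d_adh += J[t[s_new], t[sn]]
    d_vol = 0.0
    lam = state.lambda_v
    if s_old > 0:
        v, vt = state.volume[s_old], state.target_volume[s_old]
        d_vol += lam * ((v - 1 - vt) ** 2 - (v - vt) ** 2)
    if s_new > 0:
        v, vt = state.volume[s_new], state.target_volume[s_new]
        d_vol += lam * ((v + 1 - vt) ** 2 - (v - vt) ** 2)
    return float(d_adh + d_vol)


def cpm_step(
    state: CPMState,
    temperature: float | None = None,
    rng: np.random.Generator | None = None,
    audit=None,
) -> CPMState:
    """One Monte Carlo sweep (width*height elementary copy attempts).

    Each attempt picks a uniform random site and a uniform random 4-neighbor
    direction; proposals pointing off-lattice are discarded (still counting
    as an attempt — no wraparound). dH is computed locally and the copy is
    accepted with probability min(1, exp(-dH/T)); volumes are updated
    incrementally.

    ``audit``, if given, is called as ``audit(state_before_write, i, j,
    s_new, dH, accepted)`` before each accepted write; tests use it to check
    the incremental dH against a full Hamiltonian recompute.
    """
    if rng is None:
        rng = np.random.default_rng()
    T = state.temperature if temperature is None else float(temperature)
    if T <= 0:
        raise ValueError("temperature must be > 0")
    out = state.copy()
    h, w = out.spin.shape
    n_attempts = h * w
    sites = rng.integers(0, h * w, size=n_attempts)
    dirs = rng.integers(0, 4, size=n_attempts)
    accept_draws = rng.random(n_attempts)
    for k in range(n_attempts):
        i, j = divmod(int(sites[k]), w)
        di, dj = _DIRS[dirs[k]]
        ni, nj = i + di, j + dj
        if not (0 <= ni < h and 0 <= nj < w):
            continue
        s_new = out.spin[ni, nj]
        s_old = out.spin[i, j]
        if s_new == s_old:
            continue
        dh = _delta_h(out, i, j, s_new)
        accepted = dh <= 0 or accept_draws[k] < np.exp(-dh / T)
        if audit is not None:
            audit(out, i, j, int(s_new), dh, accepted)
        if accepted:
            out.spin[i, j] = s_new
            out.volume[s_old] -= 1  # index 0 tracks the medium, kept consistent too
            out.volume[s_new] += 1
    return out
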