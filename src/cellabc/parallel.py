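"""Particle-sampling schedulers: static quotas and dynamic on-demand issue.

A *sampler* turns "evaluate proposals until N are accepted" into a schedule
over workers. Two strategies are provided, mirroring the trade-off between
total CPU time and wall time:

* **static** — each worker receives a fixed acceptance quota up front and
  samples until it is met; no worker ever idles waiting for coordination,
  which minimizes total CPU time.
* **dynamic** — tasks are issued on demand from a central counter until
  enough acceptances exist; idle time at the end of a generation shrinks,
  which minimizes wall time.

Dynamic mode must not bias the sampled population: simulations whose
parameters make them fast would otherwise be overrepresented, because their
acceptances *complete* earlier. The rule here is therefore to accept by
task-*issue* order: the population consists of the accepted particles with
the N smallest task indices, discarding acceptances issued later, no matter
when they completed. A completion-order variant is kept only to demonstrate
the bias it introduces.

Every task owns a dedicated, non-overlapping random substream derived from
``(seed, generation, task_index)``, so results are independent of worker
count and scheduling — and byte-identical across reruns for a fixed seed.

Workers are simulated in-process by a discrete-event loop with an optional
per-task latency model; the contract is the deliverable, not a specific
message broker.
"""

from __future__ import annotations

import bisect
import heapq
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Task",
    "TaskResult",
    "SchedulerConfig",
    "static_quotas",
    "StaticSampler",
    "DynamicSampler",
    "SequentialSampler",
    "parallel_efficiency",
]


@dataclass(frozen=True)
class Task:
    index: int
    generation: int
    seed: int

    @property
    def seed_seq(self) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.seed, self.generation, self.index])

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed_seq)

    @property
    def substream_id(self) -> tuple[int, int, int]:
        return (self.seed, self.generation, self.index)


@dataclass
class TaskResult:
    task: Task
    accepted: bool
    payload: object  # engine-defined (a particle record)
    cost: float = 1.0


@dataclass
class SchedulerConfig:
    mode: str = "dynamic"  # static | dynamic
    n_workers: int = 1

    def __post_init__(self):
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"unknown scheduling mode {self.mode!r}")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")

    def make_sampler(self):
        if self.mode == "static":
            return StaticSampler(self.n_workers)
        return DynamicSampler(self.n_workers)


def static_quotas(N: int, n_workers: int) -> tuple[int, ...]:
    """Balanced per-worker acceptance quotas: sum to N, pairwise differ by <= 1."""
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if N < n_workers:
        raise ValueError(f"population size {N} smaller than worker count {n_workers}")
    base, rem = divmod(N, n_workers)
    return tuple(base + 1 if w < rem else base for w in range(n_workers))


def parallel_efficiency(t_single: float, t_multi: float, i: int) -> float:
    """PE = t_single / (t_multi * i): wall time on one node over i-node wall time times i."""
    if t_single <= 0 or t_multi <= 0 or i < 1:
        raise ValueError("wall times must be positive and i >= 1")
    return t_single / (t_multi * i)


EvaluateFn = Callable[[Task], TaskResult]


class StaticSampler:
    """Fixed per-worker quotas; each worker owns an interleaved task-index stream."""

    mode = "static"

    def __init__(self, n_workers: int = 1):
        if n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        self.n_workers = n_workers
        self.used_substreams: set[tuple[int, int, int]] = set()

    def sample_until_n_accepted(self, n: int, evaluate: EvaluateFn, generation: int, seed: int):
        quotas = static_quotas(n, self.n_workers)
        accepted: list[TaskResult] = []
        total = 0
        for w, quota in enumerate(quotas):
            got, k = 0, 0
            while got < quota:
                task = Task(index=k * self.n_workers + w, generation=generation, seed=seed)
                self._claim(task)
                res = evaluate(task)
                total += 1
                if res.accepted:
                    accepted.append(res)
                    got += 1
                k += 1
        accepted.sort(key=lambda r: r.task.index)
        return accepted, total

    def _claim(self, task: Task):
        sid = task.substream_id
        if sid in self.used_substreams:
            raise RuntimeError(f"rng substream {sid} consumed twice")
        self.used_substreams.add(sid)


class DynamicSampler:
    """On-demand task issue with issue-order acceptance.

    ``latency_fn(result) -> float`` models per-task evaluation time for the
    in-process discrete-event worker simulation (default: unit latency).
    ``acceptance_rule`` is ``"issue_order"`` (unbiased, default) or
    ``"completion_order"`` (biased; kept for the demonstration tests).
    """

    mode = "dynamic"

    def __init__(
        self,
        n_workers: int = 1,
        latency_fn: Optional[Callable[[TaskResult], float]] = None,
        acceptance_rule: str = "issue_order",
    ):
        if n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if acceptance_rule not in ("issue_order", "completion_order"):
            raise ValueError(f"unknown acceptance rule {acceptance_rule!r}")
        self.n_workers = n_workers
        self.latency_fn = latency_fn or (lambda _res: 1.0)
        self.acceptance_rule = acceptance_rule
        self.used_substreams: set[tuple[int, int, int]] = set()

    def sample_until_n_accepted(self, n: int, evaluate: EvaluateFn, generation: int, seed: int):
        next_index = 0
        clock = 0.0
        # event heap entries: (finish_time, task_index, result)
        events: list[tuple[float, int, TaskResult]] = []
        completed: dict[int, TaskResult] = {}
        pending: set[int] = set()

        def issue(now: float):
            nonlocal next_index
            task = Task(index=next_index, generation=generation, seed=seed)
            sid = task.substream_id
            if sid in self.used_substreams:
                raise RuntimeError(f"rng substream {sid} consumed twice")
            self.used_substreams.add(sid)
            next_index += 1
            res = evaluate(task)
            pending.add(task.index)
            heapq.heappush(events, (now + float(self.latency_fn(res)), task.index, res))

        for _ in range(self.n_workers):
            issue(clock)

        completion_accepted: list[TaskResult] = []
        accepted_sorted: list[int] = []  # accepted task indices, kept ordered
        while True:
            finish, idx, res = heapq.heappop(events)
            clock = finish
            pending.discard(idx)
            completed[idx] = res
            if res.accepted:
                completion_accepted.append(res)
                bisect.insort(accepted_sorted, idx)

            if self.acceptance_rule == "completion_order":
                if len(completion_accepted) >= n:
                    return completion_accepted[:n], len(completed)
                issue(clock)
                continue

            if len(accepted_sorted) >= n:
                cutoff = accepted_sorted[n - 1]
                # pending never exceeds the worker count, so this scan is cheap
                if not any(i < cutoff for i in pending):
                    population = [completed[i] for i in accepted_sorted[:n]]
                    # indices are issued contiguously, so exactly cutoff+1
                    # tasks have index <= cutoff, and all of them completed
                    return population, cutoff + 1
                # enough acceptances may exist; let low-index tasks drain
                continue
            issue(clock)


def SequentialSampler() -> DynamicSampler:
    """Single-worker sampler; the reproducibility reference."""
    return DynamicSampler(n_workers=1)
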