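"""Fault-tolerant FIFO task queue with an in-process worker pool.

The protocol mirrors a single-daemon distributed work queue: the queue is
initialized with every task ID; an idle worker requests a task and receives
the queue head (or NO_TASK when the queue is drained); finished results are
uploaded before the next request; when a worker dies its in-flight tasks are
reloaded into the queue (at the tail). Dispatch is therefore at-least-once and
result collection is idempotent, which yields exactly-once results under any
failure schedule.

``run_pool`` drives the protocol with a deterministic seeded simulation of
worker interleaving, mid-run joins and injected crashes.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Optional, Sequence

__all__ = ["NO_TASK", "TaskQueue", "ProtocolError", "run_pool"]

NO_TASK = "NO_TASK"


class ProtocolError(RuntimeError):
    """A worker violated the queue protocol (e.g. completed a foreign task)."""


@dataclass
class TaskQueue:
    """FIFO queue with in-flight tracking and idempotent result collection.

    Invariant: pending, in-flight and completed task sets are pairwise
    disjoint and their union is the initial task set.
    """

    tasks: Sequence[Hashable]
    pending: deque = field(init=False)
    in_flight: dict = field(init=False)  # task id -> worker id
    completed: set = field(init=False)
    results: dict = field(init=False)  # task id -> result reference

    def __post_init__(self) -> None:
        task_list = list(self.tasks)
        if len(set(task_list)) != len(task_list):
            raise ValueError("task IDs must be unique")
        self.pending = deque(task_list)
        self.in_flight = {}
        self.completed = set()
        self.results = {}
        self._all = set(task_list)

    # -- protocol operations -------------------------------------------------

    def request_task(self, worker_id: Hashable):
        """Assign the queue head to the worker; NO_TASK when pending is empty."""
        if not self.pending:
            return NO_TASK
        task = self.pending.popleft()
        self.in_flight[task] = worker_id
        return task

    def complete_task(self, worker_id: Hashable, task_id: Hashable, result_ref) -> None:
        """Record a result and retire the task; duplicate completions are ignored."""
        if task_id in self.completed:
            return  # idempotent collect after a failure/reload race
        if self.in_flight.get(task_id) != worker_id:
            raise ProtocolError(
                f"worker {worker_id!r} completed task {task_id!r} not assigned to it")
        del self.in_flight[task_id]
        self.completed.add(task_id)
        self.results[task_id] = result_ref

    def handle_worker_failure(self, worker_id: Hashable) -> list:
        """Reload the failed worker's in-flight tasks at the queue tail."""
        reloaded = [t for t, w in self.in_flight.items() if w == worker_id]
        for task in reloaded:
            del self.in_flight[task]
            self.pending.append(task)
        return reloaded

    # -- bookkeeping ---------------------------------------------------------

    @property
    def done(self) -> bool:
        return not self.pending and not self.in_flight

    def check_conservation(self) -> None:
        pending = set(self.pending)
        in_flight = set(self.in_flight)
        if pending & in_flight or pending & self.completed or in_flight & self.completed:
            raise AssertionError("pending/in-flight/completed sets overlap")
        if pending | in_flight | self.completed != self._all:
            raise AssertionError("task set not conserved")


FailureInjector = Callable[[random.Random, Hashable, Hashable], bool]


def run_pool(tasks: Sequence[Hashable], worker_fn: Callable,
             n_workers: int = 4,
             failure_injector: Optional[FailureInjector] = None,
             seed: int = 0,
             max_attempts: int = 3,
             join_schedule: Optional[dict[int, int]] = None) -> dict:
    """Run every task to completion through the queue protocol.

    Workers are simulated deterministically: at each step a seeded RNG picks an
    idle worker, which requests a task, may crash (``failure_injector(rng,
    worker_id, task_id)`` returning True), and otherwise executes ``worker_fn``
    and uploads the result before its next request. Crashed workers are
    replaced by fresh ones so the pool size is maintained; ``join_schedule``
    maps step number → number of extra workers joining mid-run. A task whose
    ``worker_fn`` raises ``max_attempts`` times consecutively is marked failed
    and the run continues.

    Returns task id → {"status": "ok"|"failed", "result"|"error": ...}.
    """
    rng = random.Random(seed)
    queue = TaskQueue(tasks)
    workers = [f"w{i}" for i in range(n_workers)]
    next_worker = n_workers
    attempts: dict[Hashable, int] = {}
    failed: dict[Hashable, str] = {}
    step = 0

    while not queue.done:
        step += 1
        for _ in range((join_schedule or {}).get(step, 0)):
            workers.append(f"w{next_worker}")
            next_worker += 1
        if not workers:  # every worker crashed: replace the pool
            workers.append(f"w{next_worker}")
            next_worker += 1
        worker = rng.choice(workers)
        task = queue.request_task(worker)
        if task is NO_TASK:
            # nothing pending but tasks still in flight elsewhere; this worker
            # would exit in the live system — try another one next step
            continue
        if failure_injector is not None and failure_injector(rng, worker, task):
            queue.handle_worker_failure(worker)
            workers.remove(worker)
            continue
        try:
            result = worker_fn(task)
        except Exception as exc:
            attempts[task] = attempts.get(task, 0) + 1
            if attempts[task] >= max_attempts:
                failed[task] = str(exc)
                queue.complete_task(worker, task, None)
            else:
                queue.handle_worker_failure(worker)
                workers.remove(worker)
                workers.append(f"w{next_worker}")
                next_worker += 1
            continue
        attempts[task] = 0
        queue.complete_task(worker, task, result)
        queue.check_conservation()

    out = {}
    for task in queue.completed:
        if task in failed:
            out[task] = {"status": "failed", "error": failed[task]}
        else:
            out[task] = {"status": "ok", "result": queue.results[task]}
    return out
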