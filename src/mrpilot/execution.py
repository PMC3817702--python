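"""Executor contract: deterministic parallel map with job pooling.

Jobs are pure functions of their inputs, so results are independent of
scheduling: ``parallel_map`` returns identical results for any worker
count. Fast jobs are pooled into batches so that per-process overhead
does not dominate cheap calculations; pooling changes batching only,
never results. A failing job yields a recorded per-job error rather
than aborting the run.
"""

from __future__ import annotations

import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from typing import Any, Callable, Sequence


@dataclass(frozen=True)
class JobSpec:
    job_id: str
    kind: str
    fn: Callable
    args: tuple = ()
    cost_hint: str = "slow"        # "fast" jobs are pooled into batches
    priority: tuple = ()


@dataclass
class JobResult:
    job_id: str
    ok: bool
    value: Any = None
    error: str | None = None


@dataclass
class ExecReport:
    results: dict                   # job_id -> JobResult
    n_batches: int                  # batch executions actually performed

    def in_canonical_order(self, jobs: Sequence[JobSpec]) -> list:
        ordered = sorted(jobs, key=lambda j: (j.priority, j.job_id))
        return [self.results[j.job_id] for j in ordered]


def _run_one(fn, args) -> JobResult:
    try:
        return JobResult("", True, fn(*args))
    except Exception:                                     # noqa: BLE001
        return JobResult("", False, None, traceback.format_exc(limit=5))


def _run_batch(batch):
    """Execute a pooled batch of (job_id, fn, args) as one unit."""
    out = []
    for job_id, fn, args in batch:
        r = _run_one(fn, args)
        r.job_id = job_id
        out.append(r)
    return out


def parallel_map(jobs: Sequence[JobSpec], workers: int = 1,
                 pool_threshold: int = 20) -> ExecReport:
    """Run jobs, pooling fast ones, and key results by job identity."""
    if workers < 1:
        raise ValueError("workers must be >= 1")
    fast = [j for j in jobs if j.cost_hint == "fast"]
    slow = [j for j in jobs if j.cost_hint != "fast"]
    batches = []
    for lo in range(0, len(fast), pool_threshold):
        chunk = fast[lo:lo + pool_threshold]
        batches.append([(j.job_id, j.fn, j.args) for j in chunk])
    for j in slow:
        batches.append([(j.job_id, j.fn, j.args)])

    results: dict = {}
    if workers == 1 or len(batches) <= 1:
        outs = [_run_batch(b) for b in batches]
    else:
        with ProcessPoolExecutor(max_workers=workers) as ex:
            outs = list(ex.map(_run_batch, batches))
    for out in outs:
        for r in out:
            results[r.job_id] = r
    return ExecReport(results=results, n_batches=len(batches))
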