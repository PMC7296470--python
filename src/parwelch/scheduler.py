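"""Master-worker parallel execution of the Welch estimator.

The pipeline has five stages: input, split, map, reduce, output.  The
master splits the channel into segments, assigns them round-robin to
workers (segment j goes to rank j mod size, so loads differ by at most
one), every worker — including rank 0 — computes the periodograms of its
segments, and the master gathers the tagged results and averages them.

Reduction is centralised on the master and the gathered periodograms are
re-sorted into ascending segment-index order before accumulation, so the
final PSD is bitwise identical to the serial estimator for every worker
count, backend, and message-arrival order.  This deliberately trades a
possible tree-reduction speedup for exact reproducibility.

Backends
--------
``"serial"``
    In-process sequential emulation of the master-worker loop.  Always
    available; the reference for determinism tests and the Ts baseline.
``"process"``
    Local process pool (joblib/loky); one job per worker rank.
``"message-passing"``
    Adapter for an MPI runtime via mpi4py, for cluster deployment.  It is
    only importable where mpi4py is installed and is not used by the
    default test suite.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ConfigError, IntegrityError, ParwelchError
from .types import (
    Periodogram,
    PSDResult,
    SegmentPlan,
    SignalChannel,
    WelchConfig,
    WindowVector,
)
from .welch import (
    average_periodograms,
    frequency_axis,
    make_window,
    plan_segments,
    segment_periodogram,
    welch_psd,
)

__all__ = [
    "TaskAssignment",
    "WorkerResult",
    "allocate_tasks",
    "worker_compute",
    "reduce_psd",
    "parallel_welch",
    "benchmark_speedup",
    "format_speedup_table",
    "BACKENDS",
]


@dataclass(frozen=True)
class TaskAssignment:
    """Round-robin segment-to-rank mapping: ``mapping[j] == j % n_workers``."""

    n_workers: int
    mapping: tuple  # mapping[j] = rank of segment j

    def segments_for(self, rank: int) -> list[int]:
        """Ascending list of segment indices assigned to ``rank``."""
        return [j for j, r in enumerate(self.mapping) if r == rank]


@dataclass(frozen=True)
class WorkerResult:
    """Periodograms computed by one worker, tagged with segment indices."""

    rank: int
    periodograms: tuple  # of Periodogram, ascending segment index


def allocate_tasks(n_segments: int, n_workers: int) -> TaskAssignment:
    """Assign segment j to worker rank j mod n_workers.

    For 7 segments over 4 workers this reproduces the canonical allocation
    (ranks 0 1 2 3 0 1 2); every segment is assigned exactly once and
    worker loads differ by at most one.
    """
    if n_workers < 1:
        raise ConfigError(f"worker count must be >= 1, got {n_workers}")
    if n_segments < 1:
        raise ConfigError(f"segment count must be >= 1, got {n_segments}")
    return TaskAssignment(
        n_workers=n_workers,
        mapping=tuple(j % n_workers for j in range(n_segments)),
    )


def worker_compute(
    channel: SignalChannel,
    plan: SegmentPlan,
    window: WindowVector,
    config: WelchConfig,
    assigned: Sequence[int],
    rank: int = 0,
) -> WorkerResult:
    """Map stage for one worker: periodograms of its assigned segments.

    Results are ordered by ascending segment index.  An empty assignment
    (idle worker when n_workers > Ns) yields an empty result.
    """
    try:
        periodograms = tuple(
            segment_periodogram(channel, plan, i, window, config)
            for i in sorted(assigned)
        )
    except ParwelchError as exc:
        raise type(exc)(f"worker rank {rank}: {exc}") from exc
    return WorkerResult(rank=rank, periodograms=periodograms)


def reduce_psd(
    results: Iterable[WorkerResult],
    plan: SegmentPlan,
    config: WelchConfig,
    label: str,
    fs: float,
) -> PSDResult:
    """Reduce stage: merge worker periodograms into the final PSD.

    Validates that the union of received segment indices is exactly
    {0, ..., Ns-1} (a missing or duplicated index signals a lost or
    repeated worker message), re-sorts into ascending segment order, and
    averages.  The output is bitwise equal to the serial estimator.
    """
    collected: list[Periodogram] = []
    for result in results:
        collected.extend(result.periodograms)
    seen: set[int] = set()
    for p in collected:
        if p.segment_index in seen:
            raise IntegrityError(
                f"segment index {p.segment_index} received more than once"
            )
        seen.add(p.segment_index)
    expected = set(range(plan.n_segments))
    missing = expected - seen
    if missing:
        raise IntegrityError(f"segment indices missing from reduce: {sorted(missing)}")
    extra = seen - expected
    if extra:
        raise IntegrityError(f"unexpected segment indices in reduce: {sorted(extra)}")
    psd = average_periodograms(collected, plan.n_segments)
    return PSDResult(
        label=label,
        freqs=frequency_axis(config.seg_len, fs, config.sided),
        psd=psd,
        n_segments_used=plan.n_segments,
        config=config,
    )


# ---------------------------------------------------------------------------
# Backends
#
# A backend maps `worker_compute` over all ranks and returns the list of
# WorkerResult objects (in any order; the reduce stage re-sorts).


class SerialBackend:
    """Sequential in-process emulation of the master-worker loop."""

    name = "serial"

    def run(self, channel, plan, window, config, assignment) -> list[WorkerResult]:
        return [
            worker_compute(
                channel, plan, window, config, assignment.segments_for(rank), rank
            )
            for rank in range(assignment.n_workers)
        ]


class ProcessBackend:
    """Local process pool; one job per worker rank."""

    name = "process"

    def run(self, channel, plan, window, config, assignment) -> list[WorkerResult]:
        from joblib import Parallel, delayed

        try:
            return Parallel(n_jobs=assignment.n_workers)(
                delayed(worker_compute)(
                    channel, plan, window, config, assignment.segments_for(rank), rank
                )
                for rank in range(assignment.n_workers)
            )
        except ParwelchError:
            raise
        except Exception as exc:  # pool launch/communication failure
            raise ParwelchError(f"process backend failure: {exc}") from exc


class MPIBackend:
    """Adapter for a distributed message-passing runtime (mpi4py).

    The master (rank 0) broadcasts the task description, every rank
    computes its own share, and the results are gathered back to rank 0.
    Requires an MPI launcher (e.g. ``mpiexec -n 4 parwelch psd ...``);
    intended for cluster deployment and exercised only in optional
    integration environments.
    """

    name = "message-passing"

    def run(self, channel, plan, window, config, assignment) -> list[WorkerResult]:
        try:
            from mpi4py import MPI
        except ImportError as exc:
            raise ParwelchError(
                "the message-passing backend requires mpi4py, which is not "
                "installed; use backend='serial' or 'process' instead"
            ) from exc
        comm = MPI.COMM_WORLD
        rank = comm.Get_rank()
        payload = comm.bcast(
            (channel, plan, window, config, assignment) if rank == 0 else None, root=0
        )
        channel, plan, window, config, assignment = payload
        mine = worker_compute(
            channel, plan, window, config, assignment.segments_for(rank), rank
        )
        gathered = comm.gather(mine, root=0)
        if rank != 0:
            return []
        return list(gathered)


BACKENDS = {
    "serial": SerialBackend,
    "process": ProcessBackend,
    "message-passing": MPIBackend,
}


def _resolve_backend(backend):
    if isinstance(backend, str):
        try:
            return BACKENDS[backend]()
        except KeyError:
            raise ConfigError(
                f"unknown backend {backend!r}; expected one of {sorted(BACKENDS)}"
            ) from None
    return backend


def parallel_welch(
    channel: SignalChannel,
    config: WelchConfig | None = None,
    backend="serial",
    n_workers: int = 1,
) -> PSDResult:
    """Parallel Welch estimate: split, round-robin map, ordered reduce.

    For every worker count and backend the output is bitwise identical to
    :func:`parwelch.welch.welch_psd` on the same inputs.
    """
    if config is None:
        config = WelchConfig()
    if n_workers < 1:
        raise ConfigError(f"worker count must be >= 1, got {n_workers}")
    backend = _resolve_backend(backend)
    plan = plan_segments(channel.n_samples, config)
    window = make_window(config.window_kind, config.window_convention, config.seg_len)
    assignment = allocate_tasks(plan.n_segments, n_workers)
    results = backend.run(channel, plan, window, config, assignment)
    return reduce_psd(results, plan, config, channel.label, channel.fs)


# ---------------------------------------------------------------------------
# Speedup benchmarking


@dataclass(frozen=True)
class SpeedupRow:
    n_workers: int
    time_s: float
    speedup: float


def benchmark_speedup(
    workload: Callable[[str, int], None],
    worker_counts: Sequence[int],
    repetitions: int = 3,
) -> list[SpeedupRow]:
    """Measure speedup = Ts/Tp of a workload over worker counts.

    ``workload(backend_name, n_workers)`` runs the computation once.  The
    serial baseline Ts is measured first with the sequential emulation
    backend and reported as the first row with speedup exactly 1.0; each
    parallel time Tp is the minimum wall time over ``repetitions`` runs on
    a monotonic clock.  Wall times are reported, never asserted.
    """
    if repetitions < 1:
        raise ConfigError(f"repetitions must be >= 1, got {repetitions}")

    def _time(backend_name: str, n_workers: int) -> float:
        best = float("inf")
        for _ in range(repetitions):
            t0 = time.perf_counter()
            workload(backend_name, n_workers)
            best = min(best, time.perf_counter() - t0)
        return best

    ts = _time("serial", 1)
    rows = [SpeedupRow(n_workers=1, time_s=ts, speedup=1.0)]
    for n in worker_counts:
        if n == 1:
            continue
        tp = _time("process", n)
        rows.append(SpeedupRow(n_workers=n, time_s=tp, speedup=ts / tp))
    return rows


def format_speedup_table(rows: Sequence[SpeedupRow]) -> str:
    """Render benchmark rows as a tab-separated table with a header."""
    lines = ["n_workers\ttime_s\tspeedup"]
    for row in rows:
        lines.append(f"{row.n_workers}\t{row.time_s:.6f}\t{row.speedup:.4f}")
    return "\n".join(lines) + "\n"
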