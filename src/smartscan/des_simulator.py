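"""Discrete-event simulation of the imaging and computation threads.

The simulator schedules two resources — the microscope (imaging thread) and
the support computer (computation thread) — under three policies and emits a
timestamped event log.  Makespans from the log are used to validate the
closed-form runtimes in :mod:`smartscan.runtime_model`: the serial policy
reproduces the serial equation exactly, while the globally-pipelined policy
can exceed the parallel equation (which is a lower bound) whenever the
computation thread idles at a section boundary and later backlogs.

Policies
--------
``serial``
    One thread of control: per tile, transition, fast scan, compute, rescan.
``parallel_global``
    The imaging thread performs every transition and fast scan in section/
    tile order; the computation thread consumes finished tiles FIFO.  After
    the last compute, a second full pass performs transitions and rescans.
``parallel_per_section``
    The same producer/consumer structure, but section ``s`` is rescanned as
    soon as its masks are ready, and the imaging thread does not start
    section ``s + 1`` until those rescans finish (a single physical beam
    serves both passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import ValidationError
from .runtime_model import (
    AcquisitionParams,
    RescanPlan,
    parallel_smart_runtime,
    serial_smart_runtime,
)

SERIAL = "serial"
PARALLEL_GLOBAL = "parallel_global"
PARALLEL_PER_SECTION = "parallel_per_section"
POLICIES = (SERIAL, PARALLEL_GLOBAL, PARALLEL_PER_SECTION)

IMAGING = "imaging"
COMPUTATION = "computation"
_THREAD_ORDER = {IMAGING: 0, COMPUTATION: 1}

SECTION_TRANSITION = "section_transition"
TILE_TRANSITION = "tile_transition"
FAST_SCAN = "fast_scan"
COMPUTE = "compute"
RESCAN = "rescan"


@dataclass(frozen=True)
class SimEvent:
    """One scheduled interval on a thread.

    ``tile_index`` is -1 for section transitions, which belong to the
    section as a whole.
    """

    thread: str
    kind: str
    section_index: int
    tile_index: int
    start_s: float
    end_s: float


@dataclass
class EventLog:
    """Ordered schedule produced by :func:`simulate_acquisition`.

    Events are sorted by start time, imaging before computation at equal
    timestamps (stable within each thread's generation order).
    """

    params: AcquisitionParams
    policy: str
    alpha: float
    events: list[SimEvent] = field(default_factory=list)


def makespan(log: EventLog) -> float:
    """Latest event end time in the log; errors on an empty log."""
    if not log.events:
        raise ValidationError("cannot take the makespan of an empty event log")
    return max(e.end_s for e in log.events)


class _Recorder:
    def __init__(self) -> None:
        self.events: list[SimEvent] = []

    def add(self, thread, kind, section, tile, start, duration) -> float:
        end = start + duration
        self.events.append(SimEvent(thread, kind, section, tile, start, end))
        return end

    def sorted_events(self) -> list[SimEvent]:
        return sorted(self.events, key=lambda e: (e.start_s, _THREAD_ORDER[e.thread]))


def simulate_acquisition(
    p: AcquisitionParams,
    plan: RescanPlan,
    policy: str = PARALLEL_GLOBAL,
    queue_capacity: Optional[int] = None,
) -> EventLog:
    """Simulate one acquisition and return the full event log.

    Parameters
    ----------
    p, plan
        Workflow parameters and the rescan fraction.
    policy
        One of :data:`POLICIES`.
    queue_capacity
        Size of the buffer between the imaging and computation threads in the
        parallel policies.  ``None`` (the default) means unbounded.  When
        bounded, the imaging thread blocks before a tile's transition until a
        buffer slot is free, i.e. until the compute of the tile scanned
        ``queue_capacity`` tiles earlier has started.

    Notes
    -----
    Rescan duration is the deterministic ``alpha * t_slow_s`` for every tile;
    zero-duration rescan and transition events are still logged.  When a scan
    ends exactly as the computation thread becomes free, the compute starts
    at that same instant.
    """
    if policy not in POLICIES:
        raise ValidationError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    if queue_capacity is not None and (
        not isinstance(queue_capacity, int) or queue_capacity < 1
    ):
        raise ValidationError(
            f"queue_capacity must be a positive integer or None, got {queue_capacity!r}"
        )
    rec = _Recorder()
    rescan_len = plan.alpha * p.t_slow_s

    if policy == SERIAL:
        t = 0.0
        for s in range(p.n_sections):
            t = rec.add(IMAGING, SECTION_TRANSITION, s, -1, t, p.t_section_s)
            for j in range(p.n_tiles):
                t = rec.add(IMAGING, TILE_TRANSITION, s, j, t, p.t_tile_s)
                t = rec.add(IMAGING, FAST_SCAN, s, j, t, p.t_fast_s)
                t = rec.add(COMPUTATION, COMPUTE, s, j, t, p.t_compute_s)
                t = rec.add(IMAGING, RESCAN, s, j, t, rescan_len)

    elif policy == PARALLEL_GLOBAL:
        compute_starts: list[float] = []
        comp_free = 0.0
        t = 0.0
        idx = 0
        for s in range(p.n_sections):
            t = rec.add(IMAGING, SECTION_TRANSITION, s, -1, t, p.t_section_s)
            for j in range(p.n_tiles):
                if queue_capacity is not None and idx >= queue_capacity:
                    t = max(t, compute_starts[idx - queue_capacity])
                t = rec.add(IMAGING, TILE_TRANSITION, s, j, t, p.t_tile_s)
                t = rec.add(IMAGING, FAST_SCAN, s, j, t, p.t_fast_s)
                start = max(comp_free, t)
                comp_free = rec.add(COMPUTATION, COMPUTE, s, j, start, p.t_compute_s)
                compute_starts.append(start)
                idx += 1
        t = comp_free  # rescan pass begins after the last mask is ready
        for s in range(p.n_sections):
            t = rec.add(IMAGING, SECTION_TRANSITION, s, -1, t, p.t_section_s)
            for j in range(p.n_tiles):
                t = rec.add(IMAGING, TILE_TRANSITION, s, j, t, p.t_tile_s)
                t = rec.add(IMAGING, RESCAN, s, j, t, rescan_len)

    else:  # PARALLEL_PER_SECTION
        compute_starts = []
        comp_free = 0.0
        t = 0.0
        idx = 0
        for s in range(p.n_sections):
            t = rec.add(IMAGING, SECTION_TRANSITION, s, -1, t, p.t_section_s)
            section_masks_ready = t
            for j in range(p.n_tiles):
                if queue_capacity is not None and idx >= queue_capacity:
                    t = max(t, compute_starts[idx - queue_capacity])
                t = rec.add(IMAGING, TILE_TRANSITION, s, j, t, p.t_tile_s)
                t = rec.add(IMAGING, FAST_SCAN, s, j, t, p.t_fast_s)
                start = max(comp_free, t)
                comp_free = rec.add(COMPUTATION, COMPUTE, s, j, start, p.t_compute_s)
                compute_starts.append(start)
                section_masks_ready = comp_free
                idx += 1
            t = max(t, section_masks_ready)
            t = rec.add(IMAGING, SECTION_TRANSITION, s, -1, t, p.t_section_s)
            for j in range(p.n_tiles):
                t = rec.add(IMAGING, TILE_TRANSITION, s, j, t, p.t_tile_s)
                t = rec.add(IMAGING, RESCAN, s, j, t, rescan_len)

    return EventLog(params=p, policy=policy, alpha=plan.alpha, events=rec.sorted_events())


@dataclass(frozen=True)
class AnalyticComparison:
    """Simulated vs closed-form runtimes for one parameter set."""

    des_serial: float
    eq_serial: float
    des_parallel_global: float
    eq_parallel: float
    gap: float  # des_parallel_global - eq_parallel, >= 0 up to tolerance


def validate_against_analytic(
    p: AcquisitionParams, plan: RescanPlan, tol: float = 1e-9
) -> AnalyticComparison:
    """Run the serial and globally-pipelined simulations and compare them to
    the closed-form runtimes.

    The serial makespan must match the serial equation to relative tolerance
    ``tol``; the pipelined makespan must be at least the parallel equation
    (the equation is a lower bound, tight except when the computation thread
    idles at a section boundary and then backlogs).
    """
    des_serial = makespan(simulate_acquisition(p, plan, SERIAL))
    eq2 = serial_smart_runtime(p, plan)
    des_par = makespan(simulate_acquisition(p, plan, PARALLEL_GLOBAL))
    eq3 = parallel_smart_runtime(p, plan)
    scale = max(1.0, abs(eq2))
    if abs(des_serial - eq2) > tol * scale:
        raise ValidationError(
            f"serial simulation ({des_serial!r}) disagrees with the serial "
            f"equation ({eq2!r})"
        )
    gap = des_par - eq3
    if gap < -tol * max(1.0, abs(eq3)):
        raise ValidationError(
            f"pipelined simulation ({des_par!r}) fell below the parallel "
            f"lower bound ({eq3!r})"
        )
    return AnalyticComparison(des_serial, eq2, des_par, eq3, gap)


def event_log_to_frame(log: EventLog) -> pd.DataFrame:
    """Event log as a DataFrame with columns
    (thread, kind, section, tile, start_s, end_s)."""
    return pd.DataFrame(
        {
            "thread": [e.thread for e in log.events],
            "kind": [e.kind for e in log.events],
            "section": [e.section_index for e in log.events],
            "tile": [e.tile_index for e in log.events],
            "start_s": [e.start_s for e in log.events],
            "end_s": [e.end_s for e in log.events],
        }
    )


def write_event_log(log: EventLog, path) -> None:
    """Write the event log CSV (see :func:`event_log_to_frame`)."""
    event_log_to_frame(log).to_csv(path, index=False)


def plot_gantt(log: EventLog, path=None, ax=None):
    """Gantt-style plot of the schedule, one row per thread.

    Saves to ``path`` if given, otherwise returns the axes.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        SECTION_TRANSITION: "tab:gray",
        TILE_TRANSITION: "lightgray",
        FAST_SCAN: "tab:blue",
        COMPUTE: "tab:orange",
        RESCAN: "tab:green",
    }
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    rows = {IMAGING: 10, COMPUTATION: 0}
    for e in log.events:
        if e.end_s > e.start_s:
            ax.broken_barh(
                [(e.start_s, e.end_s - e.start_s)],
                (rows[e.thread], 8),
                facecolors=colors[e.kind],
            )
    ax.set_yticks([14, 4])
    ax.set_yticklabels([IMAGING, COMPUTATION])
    ax.set_xlabel("time (s)")
    ax.set_title(f"{log.policy}, alpha={log.alpha:g}")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        return None
    return ax
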