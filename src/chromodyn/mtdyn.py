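"""Astral-microtubule dynamic-instability statistics.

Length-time traces (sampled nominally every 15 s) are segmented into
growth / shrink / pause phases, and the four canonical dynamic-instability
statistics are computed from the segmentation:

* catastrophe frequency - number of growth-to-shrink transitions divided by
  the total time spent growing;
* rescue frequency - number of shrink-to-growth transitions divided by the
  total time spent shrinking;
* polymerization rate - net length change over duration, per growth event;
* depolymerization rate - the same per shrinkage event.

A phase cut short by the end of the trace is not a completed event: it is
kept in the segmentation (and contributes a per-event velocity) but is
excluded from the frequency denominators, and no transition is ever counted
at a trace boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MTTrace",
    "Phase",
    "TransitionEvent",
    "PhaseSegmentation",
    "DynamicsSummary",
    "segment_phases",
    "dynamics_summary",
    "batch_dynamics",
]

GROWTH, SHRINK, PAUSE = "growth", "shrink", "pause"


@dataclass
class MTTrace:
    """One microtubule's length-time series."""

    times: np.ndarray  # s
    lengths: np.ndarray  # um
    cell_id: str = ""
    mt_id: str = ""
    bud_directed: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if len(self.times) != len(self.lengths):
            raise ValueError("times and lengths must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.lengths < 0):
            raise ValueError("lengths must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Phase:
    kind: str  # growth | shrink | pause
    start_time: float
    end_time: float
    start_length: float
    end_length: float

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def net_change(self) -> float:
        return self.end_length - self.start_length

    @property
    def rate_um_per_min(self) -> float:
        """Net length change over duration, in um/min."""
        return self.net_change / self.duration * 60.0


@dataclass(frozen=True)
class TransitionEvent:
    kind: str  # catastrophe | rescue
    time: float
    length: float


@dataclass
class PhaseSegmentation:
    phases: list[Phase]
    events: list[TransitionEvent]
    trace: MTTrace


@dataclass
class DynamicsSummary:
    n_cat: int
    n_res: int
    f_cat: float  # events per min of growth
    f_res: float  # events per min of shrinkage
    v_poly: float  # mean over growth events, um/min
    v_depoly: float  # mean over shrink events, um/min (positive)
    v_poly_events: list[float]
    v_depoly_events: list[float]
    growth_durations: list[float]  # s
    shrink_durations: list[float]  # s
    growth_time_s: float  # denominator actually used for f_cat
    shrink_time_s: float
    lengths_at_catastrophe: list[float]
    lengths_at_rescue: list[float]


def segment_phases(trace: MTTrace, min_delta: float = 0.2, min_points: int = 2) -> PhaseSegmentation:
    """Decompose a length trace into growth / shrink / pause phases.

    Consecutive sampling intervals with the same sign of length change are
    merged; a merged run whose net length change is below ``min_delta`` (um)
    is classified as a pause, as is any run with fewer than ``min_points``
    sample points. Transitions between growth and shrink phases become
    catastrophe / rescue events; a pause between opposite-sign phases is
    transparent, with the event placed at the pause end. Setting
    ``min_delta = 0`` disables the pause category for noiseless traces.
    """
    if len(trace) < 4:
        raise ValueError("need at least 4 time points to segment")
    t, L = trace.times, trace.lengths
    signs = np.sign(np.diff(L))

    # merge equal-sign steps into runs of point indices [i0, i1]
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(signs)):
        if signs[i] != signs[start]:
            runs.append((start, i))
            start = i
    runs.append((start, len(signs)))

    phases: list[Phase] = []
    for i0, i1 in runs:  # run covers points i0..i1 inclusive
        net = L[i1] - L[i0]
        n_pts = i1 - i0 + 1
        if abs(net) < min_delta or n_pts < min_points or net == 0:
            kind = PAUSE
        else:
            kind = GROWTH if net > 0 else SHRINK
        phases.append(Phase(kind, t[i0], t[i1], L[i0], L[i1]))

    # merge adjacent phases of the same kind
    merged: list[Phase] = []
    for p in phases:
        if merged and merged[-1].kind == p.kind:
            q = merged.pop()
            merged.append(Phase(p.kind, q.start_time, p.end_time, q.start_length, p.end_length))
        else:
            merged.append(p)

    # transitions: pause-transparent, event at the start of the later phase
    events: list[TransitionEvent] = []
    prev_active: Phase | None = None
    for p in merged:
        if p.kind == PAUSE:
            continue
        if prev_active is not None and prev_active.kind != p.kind:
            kind = "catastrophe" if prev_active.kind == GROWTH else "rescue"
            events.append(TransitionEvent(kind, p.start_time, p.start_length))
        prev_active = p
    return PhaseSegmentation(phases=merged, events=events, trace=trace)


def dynamics_summary(seg: PhaseSegmentation) -> DynamicsSummary:
    """Compute the four dynamic-instability statistics from a segmentation."""
    if not seg.phases:
        raise ValueError("empty segmentation")
    growth = [p for p in seg.phases if p.kind == GROWTH]
    shrink = [p for p in seg.phases if p.kind == SHRINK]
    final = seg.phases[-1]  # truncated by the end of the trace

    n_cat = sum(1 for e in seg.events if e.kind == "catastrophe")
    n_res = sum(1 for e in seg.events if e.kind == "rescue")
    growth_time = sum(p.duration for p in growth if p is not final)
    shrink_time = sum(p.duration for p in shrink if p is not final)
    if growth_time == 0 and n_cat > 0:  # impossible: every catastrophe follows growth
        raise AssertionError("catastrophes without growth time")
    if shrink_time == 0 and n_res > 0:
        raise AssertionError("rescues without shrink time")

    v_poly_events = [p.rate_um_per_min for p in growth]
    v_depoly_events = [-p.rate_um_per_min for p in shrink]
    return DynamicsSummary(
        n_cat=n_cat,
        n_res=n_res,
        f_cat=(n_cat / (growth_time / 60.0)) if growth_time > 0 else 0.0,
        f_res=(n_res / (shrink_time / 60.0)) if shrink_time > 0 else 0.0,
        v_poly=float(np.mean(v_poly_events)) if v_poly_events else float("nan"),
        v_depoly=float(np.mean(v_depoly_events)) if v_depoly_events else float("nan"),
        v_poly_events=v_poly_events,
        v_depoly_events=v_depoly_events,
        growth_durations=[p.duration for p in growth],
        shrink_durations=[p.duration for p in shrink],
        growth_time_s=growth_time,
        shrink_time_s=shrink_time,
        lengths_at_catastrophe=[e.length for e in seg.events if e.kind == "catastrophe"],
        lengths_at_rescue=[e.length for e in seg.events if e.kind == "rescue"],
    )


def batch_dynamics(
    traces: list[MTTrace],
    filter_bud_directed: bool = True,
    min_delta: float = 0.2,
    min_points: int = 2,
) -> tuple[pd.DataFrame, DynamicsSummary]:
    """Per-trace summaries plus pooled statistics.

    Pooled frequencies are event-count over pooled phase time (not a mean of
    per-trace frequencies). Non-bud-directed traces are excluded when the
    filter is on, matching the convention that dynamics are scored only on
    bud-directed astral microtubules.
    """
    kept = [tr for tr in traces if tr.bud_directed] if filter_bud_directed else list(traces)
    if not kept:
        raise ValueError("no traces left after bud-directed filtering")

    summaries = [dynamics_summary(segment_phases(tr, min_delta, min_points)) for tr in kept]
    table = pd.DataFrame(
        {
            "cell_id": [tr.cell_id for tr in kept],
            "mt_id": [tr.mt_id for tr in kept],
            "n_cat": [s.n_cat for s in summaries],
            "n_res": [s.n_res for s in summaries],
            "f_cat_per_min": [s.f_cat for s in summaries],
            "f_res_per_min": [s.f_res for s in summaries],
            "v_poly_um_min": [s.v_poly for s in summaries],
            "v_depoly_um_min": [s.v_depoly for s in summaries],
            "growth_time_s": [s.growth_time_s for s in summaries],
            "shrink_time_s": [s.shrink_time_s for s in summaries],
        }
    )
    n_cat = int(sum(s.n_cat for s in summaries))
    n_res = int(sum(s.n_res for s in summaries))
    g_time = float(sum(s.growth_time_s for s in summaries))
    s_time = float(sum(s.shrink_time_s for s in summaries))
    v_poly_all = [v for s in summaries for v in s.v_poly_events]
    v_depoly_all = [v for s in summaries for v in s.v_depoly_events]
    pooled = DynamicsSummary(
        n_cat=n_cat,
        n_res=n_res,
        f_cat=(n_cat / (g_time / 60.0)) if g_time > 0 else 0.0,
        f_res=(n_res / (s_time / 60.0)) if s_time > 0 else 0.0,
        v_poly=float(np.mean(v_poly_all)) if v_poly_all else float("nan"),
        v_depoly=float(np.mean(v_depoly_all)) if v_depoly_all else float("nan"),
        v_poly_events=v_poly_all,
        v_depoly_events=v_depoly_all,
        growth_durations=[d for s in summaries for d in s.growth_durations],
        shrink_durations=[d for s in summaries for d in s.shrink_durations],
        growth_time_s=g_time,
        shrink_time_s=s_time,
        lengths_at_catastrophe=[x for s in summaries for x in s.lengths_at_catastrophe],
        lengths_at_rescue=[x for s in summaries for x in s.lengths_at_rescue],
    )
    return table, pooled


def read_traces_csv(path) -> list[MTTrace]:
    """Read traces from CSV with columns cell_id, mt_id, time_s, length_um, bud_directed."""
    df = pd.read_csv(path)
    traces = []
    for (cell, mt), grp in df.groupby(["cell_id", "mt_id"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(
            MTTrace(
                times=grp["time_s"].to_numpy(),
                lengths=grp["length_um"].to_numpy(),
                cell_id=str(cell),
                mt_id=str(mt),
                bud_directed=bool(grp["bud_directed"].iloc[0]) if "bud_directed" in grp else True,
            )
        )
    return traces
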