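"""Step segmentation, gait start-up discard and step-level sliding windows.

A "step" is one foot-contact event of either foot, counted across both feet
in onset order; a window of L steps spans L consecutive contacts and keeps
both feet's signals over that time span (symmetry features need both feet).
A walk of S steps is augmented into ``N = floor((S - L) / s) + 1`` windows
advanced by a stride of ``s`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    EmptyGaitError,
    InsufficientDataError,
    Recording,
    StepEvent,
    StepIndex,
    ValidationError,
    WindowingPlan,
)


def contact_threshold(rec: Recording, eps_frac: float = 0.02) -> float:
    """Contact threshold: ``eps_frac`` of the 95th-percentile total force.

    Real sensors never read exactly zero during swing, so "the zero value of
    foot plantar pressure" is detected against a small data-driven floor.
    """
    total = np.concatenate([rec.left.sum(axis=1), rec.right.sum(axis=1)])
    return float(eps_frac * np.percentile(total, 95))


def _foot_contacts(total: np.ndarray, eps: float, min_gap: int) -> list[tuple[int, int]]:
    """Contiguous above-threshold runs; sub-``min_gap`` dropouts are bridged."""
    above = total > eps
    if not above.any():
        return []
    # close short gaps: a contact only ends once force stays <= eps for min_gap
    idx = np.flatnonzero(above)
    runs: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 >= max(min_gap, 1):
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))
    # a real contact must itself persist at least min_gap frames
    return [(a, b) for a, b in runs if b - a >= max(min_gap, 1)]


def segment_steps(rec: Recording, eps: float | None = None, min_dur_ms: float = 50.0,
                  eps_frac: float = 0.02) -> StepIndex:
    """Detect per-foot contact intervals and merge them into an ordered step list.

    For each foot a contact starts when the per-foot total pressure rises
    above ``eps`` and ends when it returns to <= ``eps`` for at least
    ``min_dur_ms``.  Events from both feet are merged and sorted by onset;
    each event is one step.
    """
    if rec.n_frames == 0:
        raise EmptyGaitError("recording has no frames")
    if eps is None:
        eps = contact_threshold(rec, eps_frac)
    min_gap = max(int(round(min_dur_ms / 1000.0 * rec.rate)), 1)
    events: list[StepEvent] = []
    for side in ("left", "right"):
        total = rec.foot(side).sum(axis=1)
        for a, b in _foot_contacts(total, eps, min_gap):
            events.append(StepEvent(onset=a, end=b, side=side))
    if not events:
        raise EmptyGaitError(f"no contact above eps={eps:g} in {rec.subject_id}")
    events.sort(key=lambda e: (e.onset, e.side))
    return StepIndex(events=events, startup_discarded=0)


def discard_startup(idx: StepIndex, k: int = 2) -> StepIndex:
    """Drop the first ``k`` steps (gait start-up transient)."""
    if k < 0:
        raise ValidationError("k must be >= 0")
    if k == 0:
        return StepIndex(events=list(idx.events), startup_discarded=idx.startup_discarded)
    if len(idx.events) <= k:
        raise InsufficientDataError(
            f"cannot discard {k} start-up steps from {len(idx.events)} events"
        )
    return StepIndex(events=list(idx.events[k:]),
                     startup_discarded=idx.startup_discarded + k)


def plan_windows(S: int, L: int, s: int) -> WindowingPlan:
    """Sliding-window plan; the i-th window covers steps [i*s, i*s + L)."""
    return WindowingPlan(S=S, L=L, s=s)


@dataclass(frozen=True)
class Window:
    """One step-level window: L consecutive contacts plus their frame span."""

    subject: str
    label: str
    length: int      # L, in steps
    start: int       # index of the first step within the (post-discard) index
    step_slice: tuple[int, int]   # [first, last) step indices
    frame_span: tuple[int, int]   # [onset of first step, end of last step)
    steps: tuple[StepEvent, ...] = field(repr=False)


def cut_windows(rec: Recording, idx: StepIndex, plan: WindowingPlan) -> list[Window]:
    """Materialise the plan's windows over a step index.

    Each window runs from the onset of its first step to the end of its
    last step and carries both feet's frames within that span, so feature
    extraction can exploit time order and continuity inside the window.
    """
    if plan.S != len(idx.events):
        raise ValidationError(
            f"plan S={plan.S} disagrees with step index of {len(idx.events)} events"
        )
    windows = []
    for start in plan.starts:
        steps = tuple(idx.events[start : start + plan.L])
        span = (steps[0].onset, max(e.end for e in steps))
        windows.append(
            Window(
                subject=rec.subject_id,
                label=rec.label,
                length=plan.L,
                start=start,
                step_slice=(start, start + plan.L),
                frame_span=span,
                steps=steps,
            )
        )
    return windows
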