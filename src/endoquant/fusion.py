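"""TIRF vesicle fusion-event classification by the 10% intensity-drop rule.

A fusion event observed in TIRF is classified as occurring *with* a second
marker when that marker's footprint intensity collapses along with the
fusion: taking the per-frame maximum intensity inside a small disk
footprint over the event window, the event is positive when

    (M0 - mean of the last k per-frame maxima) / M0 > drop_threshold

with M0 the maximum intensity of the initial frame, k = 3 and
drop_threshold = 0.10 by default. The inequality is strict, so a drop of
exactly 10% is negative. The rule is a ratio, hence invariant to positive
scaling of the whole trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FrameStack

__all__ = [
    "FusionTrace",
    "FusionParams",
    "CofusionSummary",
    "extract_event_trace",
    "classify_cofusion",
    "cofusion_percentage",
]


@dataclass
class FusionParams:
    drop_threshold: float = 0.10
    last_k: int = 3
    footprint_radius_px: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_threshold < 1.0:
            raise ValueError("drop_threshold must lie in (0, 1)")
        if self.last_k < 1:
            raise ValueError("last_k must be >= 1")
        if self.footprint_radius_px < 1:
            raise ValueError("footprint_radius_px must be >= 1")


@dataclass
class FusionTrace:
    """Per-frame footprint intensities of one event in one channel."""

    event_id: str
    center_px: tuple[float, float]
    radius_px: int
    frames: np.ndarray
    max_intensity: np.ndarray
    mean_intensity: np.ndarray
    channel: str = ""
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.max_intensity = np.asarray(self.max_intensity, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if len(self.frames) < 4:
            raise ValueError("event window must span at least 4 frames")
        if np.any(self.max_intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class CofusionSummary:
    condition: str
    n_events: int
    n_with_marker: int
    percent_with_marker: float


def _disk_footprint(
    shape: tuple[int, int], center: tuple[float, float], radius: int
) -> tuple[slice, slice, np.ndarray]:
    cy, cx = int(round(center[0])), int(round(center[1]))
    if (
        cy - radius < 0
        or cx - radius < 0
        or cy + radius >= shape[0]
        or cx + radius >= shape[1]
    ):
        raise ValueError("footprint extends beyond the image")
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = yy**2 + xx**2 <= radius**2
    return (
        slice(cy - radius, cy + radius + 1),
        slice(cx - radius, cx + radius + 1),
        disk,
    )


def extract_event_trace(
    stack: FrameStack,
    channel: int | str,
    event_center_px: tuple[float, float],
    window: tuple[int, int],
    params: FusionParams | None = None,
    event_id: str = "event",
) -> FusionTrace:
    """Per-frame maximum (and mean) intensity inside a disk footprint.

    ``window`` is (first_frame, last_frame), inclusive; it must contain at
    least ``last_k + 1`` frames so the rule has an initial frame and a
    final stretch to compare.
    """
    params = params or FusionParams()
    start, end = window
    if start < 0 or end >= stack.n_frames or end < start:
        raise ValueError("window outside the movie")
    n = end - start + 1
    if n < params.last_k + 1:
        raise ValueError(
            f"window of {n} frames is shorter than last_k+1={params.last_k + 1}"
        )
    ys, xs, disk = _disk_footprint(
        stack.shape_yx, event_center_px, params.footprint_radius_px
    )
    frames = np.arange(start, end + 1)
    maxima = np.empty(n)
    means = np.empty(n)
    for i, t in enumerate(frames):
        patch = np.asarray(stack.frame(t, channel), dtype=float)[ys, xs][disk]
        maxima[i] = patch.max()
        means[i] = patch.mean()
    return FusionTrace(
        event_id=event_id,
        center_px=tuple(event_center_px),
        radius_px=params.footprint_radius_px,
        frames=frames,
        max_intensity=maxima,
        mean_intensity=means,
        channel=stack.channel_names[stack.channel_index(channel)],
        frame_interval_s=stack.frame_interval_s,
    )


def classify_cofusion(
    trace: FusionTrace,
    params: FusionParams | None = None,
    reading: str = "mean-of-maxima",
) -> bool:
    """Apply the intensity-drop rule to one trace.

    ``reading="mean-of-maxima"`` (default) compares the initial frame's
    maximum against the mean of the last ``last_k`` per-frame maxima; the
    alternative reading ``"max-of-means"`` compares the initial frame's
    footprint mean against the maximum of the last ``last_k`` footprint
    means. Returns True when the relative drop strictly exceeds
    ``drop_threshold``.
    """
    params = params or FusionParams()
    if len(trace.frames) < params.last_k + 1:
        raise ValueError("trace shorter than last_k + 1 frames")
    if reading == "mean-of-maxima":
        m0 = trace.max_intensity[0]
        tail = float(np.mean(trace.max_intensity[-params.last_k :]))
    elif reading == "max-of-means":
        m0 = trace.mean_intensity[0]
        tail = float(np.max(trace.mean_intensity[-params.last_k :]))
    else:
        raise ValueError(f"unknown reading {reading!r}")
    if m0 <= 0:
        raise ValueError("no signal in initial frame")
    return bool((m0 - tail) / m0 > params.drop_threshold)


def cofusion_percentage(
    calls: Sequence[bool],
    condition: str = "all",
) -> CofusionSummary:
    """Percent of events classified as co-fusing, for one condition."""
    calls = list(calls)
    if not calls:
        raise ValueError("zero events")
    n_true = int(sum(bool(c) for c in calls))
    return CofusionSummary(
        condition=condition,
        n_events=len(calls),
        n_with_marker=n_true,
        percent_with_marker=100.0 * n_true / len(calls),
    )


def summarize_by_condition(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-condition (and optionally per-experiment) co-fusion summary.

    ``calls`` needs boolean column ``with_marker`` and a ``condition``
    column; an ``experiment`` column, when present, adds a grouping level.
    """
    keys = ["condition"] + (
        ["experiment"] if "experiment" in calls.columns else []
    )
    rows = []
    for key, sub in calls.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        s = cofusion_percentage(sub["with_marker"].tolist(), condition=str(key[0]))
        row = {
            "condition": key[0],
            "n_events": s.n_events,
            "n_with_marker": s.n_with_marker,
            "percent_with_marker": s.percent_with_marker,
        }
        if len(key) > 1:
            row["experiment"] = key[1]
        rows.append(row)
    return pd.DataFrame(rows)


def classify_events(
    stack: FrameStack,
    events: pd.DataFrame,
    channel: int | str = "marker",
    params: FusionParams | None = None,
    reading: str = "mean-of-maxima",
) -> pd.DataFrame:
    """Classify a table of manually supplied events.

    ``events`` columns: event_id, frame_start, frame_end, y_px, x_px
    (mirroring visually identified events); returns the table with an
    appended boolean ``with_marker`` column.
    """
    params = params or FusionParams()
    out = events.copy()
    calls = []
    for _, row in events.iterrows():
        trace = extract_event_trace(
            stack,
            channel,
            (row["y_px"], row["x_px"]),
            (int(row["frame_start"]), int(row["frame_end"])),
            params,
            event_id=str(row["event_id"]),
        )
        calls.append(classify_cofusion(trace, params, reading=reading))
    out["with_marker"] = calls
    return out
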