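"""Cargo signal inside a marker-defined endosomal compartment.

The marker channel (e.g. Rab5, Rab11a or flotillin) is thresholded into a
binary compartment mask; the cargo channel (e.g. fluorescent transferrin)
is background-zeroed and its mean intensity over the mask pixels reported.
Restriction to the mask — not zero-filling outside it — is used, so the
result is the mean cargo intensity *present in* the compartment and is
unaffected by cargo outside the mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .detection import NoCellFoundError, segment_cell
from .io import FrameStack

__all__ = [
    "CompartmentMask",
    "CompartmentSignalSeries",
    "threshold_compartment",
    "mean_cargo_in_compartment",
    "compartment_timecourse",
]


@dataclass
class CompartmentMask:
    """Per-frame binary compartment mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_value: float
    method: str
    marker_channel: str
    frame: int

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class CompartmentSignalSeries:
    """Per-frame masked mean cargo intensity; NaN where the mask was empty."""

    table: pd.DataFrame  # columns: time_s, mask_area_px, masked_mean, threshold
    marker_channel: str
    cargo_channel: str

    def values(self) -> np.ndarray:
        return self.table["masked_mean"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _threshold_value(img: np.ndarray, method: str, value, percentile) -> float:
    if method == "otsu":
        if np.ptp(img) == 0:
            # constant image: no separable foreground; threshold above max
            return float(img.max())
        return float(threshold_otsu(img))
    if method == "fixed":
        if value is None:
            raise ValueError("method='fixed' requires a threshold value")
        return float(value)
    if method == "percentile":
        if percentile is None:
            raise ValueError("method='percentile' requires a percentile")
        return float(np.percentile(img, percentile))
    raise ValueError(f"unknown threshold method {method!r}")


def threshold_compartment(
    stack: FrameStack,
    marker_channel: int | str,
    frame: int = 0,
    method: str = "otsu",
    value: float | None = None,
    percentile: float | None = None,
) -> CompartmentMask:
    """Binary mask of the marker channel; empty masks are flagged, not fatal.

    Otsu (default) is invariant to positive scaling of the marker
    intensities; fixed-value and percentile methods are selectable. The
    method and realized threshold are always recorded.
    """
    img = np.asarray(stack.frame(frame, marker_channel), dtype=float)
    thr = _threshold_value(img, method, value, percentile)
    return CompartmentMask(
        mask=img > thr,
        threshold_value=thr,
        method=method,
        marker_channel=stack.channel_names[stack.channel_index(marker_channel)],
        frame=frame,
    )


def estimate_cargo_background(
    stack: FrameStack, cargo_channel: int | str, frame: int = 0
) -> float:
    """Median cargo intensity outside the segmented cell.

    Falls back to the global median when no cell can be segmented (e.g. a
    blank frame) or the cell fills the frame.
    """
    img = np.asarray(stack.frame(frame, cargo_channel), dtype=float)
    try:
        cell = segment_cell(stack, channel=cargo_channel, frame=frame)
        outside = img[~cell.mask]
        if outside.size == 0:
            return float(np.median(img))
        return float(np.median(outside))
    except NoCellFoundError:
        return float(np.median(img))


def mean_cargo_in_compartment(
    stack: FrameStack,
    cargo_channel: int | str,
    mask: CompartmentMask,
    background: float | str | None = "auto",
) -> float:
    """Mean background-zeroed cargo intensity over the compartment mask.

    ``background="auto"`` estimates the cargo background as the median
    intensity outside the cell and subtracts it (clamped at zero);
    a float fixes it explicitly; ``None`` disables subtraction. An empty
    mask yields NaN (a missing value, not zero).
    """
    if mask.is_empty:
        return math.nan
    img = np.asarray(stack.frame(mask.frame, cargo_channel), dtype=float)
    if background == "auto":
        background = estimate_cargo_background(stack, cargo_channel, mask.frame)
    if background is not None:
        img = np.clip(img - float(background), 0.0, None)
    return float(img[mask.mask].mean())


def compartment_timecourse(
    stack: FrameStack,
    marker_channel: int | str,
    cargo_channel: int | str,
    method: str = "otsu",
    value: float | None = None,
    percentile: float | None = None,
    background: float | str | None = "auto",
    per_movie_threshold: bool = False,
) -> CompartmentSignalSeries:
    """Masked mean cargo intensity for every frame of the movie.

    Masks are computed per frame by default; with ``per_movie_threshold``
    a single threshold from the pooled marker intensities of all frames is
    applied to every frame. Frames with empty masks carry NaN.
    """
    fixed_value = value
    fixed_method = method
    if per_movie_threshold:
        ci = stack.channel_index(marker_channel)
        pooled = stack.data[:, ci].astype(float)
        fixed_value = _threshold_value(pooled, method, value, percentile)
        fixed_method = "fixed"

    times = stack.times_s()
    rows = []
    for t in range(stack.n_frames):
        m = threshold_compartment(
            stack,
            marker_channel,
            frame=t,
            method=fixed_method,
            value=fixed_value,
            percentile=percentile,
        )
        rows.append(
            {
                "time_s": times[t],
                "mask_area_px": m.area_px,
                "masked_mean": mean_cargo_in_compartment(
                    stack, cargo_channel, m, background=background
                ),
                "threshold": m.threshold_value,
            }
        )
    return CompartmentSignalSeries(
        table=pd.DataFrame(rows),
        marker_channel=stack.channel_names[stack.channel_index(marker_channel)],
        cargo_channel=stack.channel_names[stack.channel_index(cargo_channel)],
    )
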