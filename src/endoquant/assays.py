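"""Deterministic arithmetic for cytometry and immunoblot readouts.

Every operation here is a small, exactly reproducible transformation of a
tidy table: median-fluorescence fold changes between activated and resting
samples, recycling relative to t = 0, treated/control normalization
(labile-iron-pool and ROS readouts), T-cell:APC conjugate fractions with
non-specific-background subtraction, and immunoblot band normalization.
All ratios are invariant to a common positive rescaling of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConjugateCounts",
    "fold_change_activated_vs_resting",
    "recycling_relative_to_t0",
    "normalize_to_control",
    "conjugate_fraction",
    "normalize_bands",
]


MEDIAN_TABLE_COLUMNS = [
    "sample_id",
    "condition",
    "timepoint",
    "stain",
    "median_fi",
    "replicate",
]


@dataclass
class ConjugateCounts:
    """Flow-cytometry event counts of one conjugate-formation sample.

    ``singles_t`` / ``singles_b`` are single-positive events for the two
    dyes; ``conjugates`` are double-positive events. Which dye marks which
    cell type does not matter: only minority status does.
    """

    singles_t: int
    singles_b: int
    conjugates: int

    def __post_init__(self) -> None:
        for name in ("singles_t", "singles_b", "conjugates"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")

    def raw_percent(self) -> float:
        """Conjugates relative to the minority cell type's total."""
        total_t = self.singles_t + self.conjugates
        total_b = self.singles_b + self.conjugates
        minority_total = min(total_t, total_b)
        if minority_total == 0:
            raise ValueError("zero cells of the minority type")
        return 100.0 * self.conjugates / minority_total


def _condition_median(
    table: pd.DataFrame,
    condition: str,
    timepoint=None,
    subtract_unstained: bool = False,
) -> float:
    sub = table[table["condition"] == condition]
    if timepoint is not None:
        sub = sub[sub["timepoint"] == timepoint]
    stained = sub[sub["stain"] == "stained"] if "stain" in sub.columns else sub
    if stained.empty:
        raise ValueError(
            f"no stained rows for condition={condition!r}, timepoint={timepoint!r}"
        )
    value = float(stained["median_fi"].mean())  # mean of technical replicates
    if subtract_unstained:
        unstained = sub[sub["stain"] == "unstained"]
        if unstained.empty:
            raise ValueError(
                f"subtract_unstained requested but no unstained row for "
                f"condition={condition!r}"
            )
        value -= float(unstained["median_fi"].mean())
    return value


def fold_change_activated_vs_resting(
    table: pd.DataFrame,
    timepoint=None,
    subtract_unstained: bool = False,
) -> float:
    """Ratio of activated to resting median fluorescence intensity.

    Technical replicates are averaged per condition first. Unstained-
    background subtraction before the ratio is a per-assay choice
    (enabled for activation-marker panels, disabled for uptake/recycling
    readouts by default).
    """
    activated = _condition_median(table, "activated", timepoint, subtract_unstained)
    resting = _condition_median(table, "resting", timepoint, subtract_unstained)
    if resting <= 0:
        raise ValueError(f"resting median must be positive, got {resting}")
    return activated / resting


def recycling_relative_to_t0(
    table: pd.DataFrame,
    condition: str | None = None,
    value_col: str = "median_fi",
    time_col: str = "timepoint",
) -> pd.Series:
    """Each timepoint's median FI divided by the t = 0 median FI."""
    sub = table if condition is None else table[table["condition"] == condition]
    grouped = sub.groupby(time_col)[value_col].mean().sort_index()
    if 0 not in grouped.index:
        raise ValueError("missing t = 0 row")
    t0 = float(grouped.loc[0])
    if t0 <= 0:
        raise ValueError(f"t = 0 median must be positive, got {t0}")
    out = grouped / t0
    out.name = "fold_vs_t0"
    return out


def normalize_to_control(treated_median: float, control_median: float) -> float:
    """Treated/control median-FI ratio (LIP and ROS readouts)."""
    if control_median <= 0:
        raise ValueError(f"control median must be positive, got {control_median}")
    return float(treated_median) / float(control_median)


def conjugate_fraction(
    counts: ConjugateCounts,
    control: ConjugateCounts | float | None = None,
) -> float:
    """Specific conjugate percentage relative to the minority cell type.

    The double-positive count is expressed as a percentage of the total
    (singles + conjugates) of whichever cell type is in the minority; the
    non-specific level — the identically computed percentage of the paired
    unpulsed-control sample, or a precomputed percent — is subtracted.
    Negative corrected values are reported as computed, not clamped.
    """
    raw = counts.raw_percent()
    if control is None:
        return raw
    if isinstance(control, ConjugateCounts):
        control = control.raw_percent()
    return raw - float(control)


def normalize_bands(
    bands: pd.DataFrame,
    target_col: str = "target",
    loading_col: str = "actin",
) -> pd.Series:
    """Immunoblot band intensities, blot-referenced and loading-corrected.

    Target bands are scaled to the brightest target band on the blot; the
    loading-control (beta actin) bands are scaled to their own brightest
    band, and each lane's scaled target is divided by its scaled loading
    control. Both corrections are unitless, so the result is invariant to
    rescaling either channel.
    """
    target = bands[target_col].to_numpy(dtype=float)
    actin = bands[loading_col].to_numpy(dtype=float)
    if np.any(actin <= 0):
        raise ValueError("loading-control intensity must be positive in every lane")
    if np.any(target < 0):
        raise ValueError("band intensities must be non-negative")
    t_max = target.max()
    if t_max <= 0:
        raise ValueError("brightest target band must be positive")
    normalized = (target / t_max) / (actin / actin.max())
    return pd.Series(normalized, index=bands.index, name="normalized")
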