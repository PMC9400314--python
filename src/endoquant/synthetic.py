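"""Ground-truth-annotated synthetic data for every analysis stage.

Three generators emulate the data the pipeline consumes:

* :func:`generate_cell_image` — a roughly disk-shaped cell containing
  diffraction-limited vesicle spots in two channels, with a controllable
  fraction of cross-channel co-positioned spots and a controllable radial
  dispersion of spots about the cell centre;
* :func:`generate_tirf_series` — footprint-level fusion-event movies where
  the cargo spot collapses at fusion and a second marker either co-decays
  (co-fusion) or persists;
* :func:`generate_grouped_timeseries` — two-group per-timepoint intensity
  distributions whose medians separate after a known timepoint.

All randomness flows from one ``numpy.random.Generator`` seeded per call, so
identical configuration plus seed gives bit-identical arrays and labels.
Spots are rendered as 2-D Gaussian profiles; the noise model is
signal-dependent shot noise (Poisson) plus additive Gaussian read noise,
approximating sCMOS/PMT acquisition without modelling a specific camera.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .divergence import GroupedTimeSeries
from .io import FrameStack

__all__ = [
    "SynthImageConfig",
    "GroundTruth",
    "generate_cell_image",
    "generate_tirf_series",
    "generate_grouped_timeseries",
]


@dataclass
class SynthImageConfig:
    """Configuration of a synthetic two-channel cell image.

    Intensities are in photon counts. ``spot_intensity`` is the integrated
    (total) photon count per spot; the rendered Gaussian peak is
    ``spot_intensity / (2 pi psf_sigma_px**2)``. ``dispersion_scale`` (s)
    controls the radial placement of spots: the radial fraction of the
    usable cell radius is drawn from Beta(2s, 2), whose mean s/(s+1) is
    strictly increasing in s, so the generator's dial maps monotonically
    onto the measured dispersion statistic.

    ``min_spot_separation_nm`` keeps same-channel spots resolvable;
    ``exclusion_radius_nm`` keeps deliberately non-colocalized channel-B
    spots away from every channel-A spot so the imposed colocalization
    fraction is not contaminated by chance proximity.
    """

    image_size_px: tuple[int, int] = (128, 128)
    pixel_size_nm: float = 100.0
    cell_radius_px: float = 45.0
    cell_center_px: tuple[float, float] | None = None
    n_vesicles_per_channel: tuple[int, int] = (12, 12)
    coloc_fraction: float = 0.0
    coloc_offset_nm: float = 0.0
    dispersion_scale: float = 1.0
    psf_sigma_px: float = 1.5
    spot_intensity: float = 20000.0
    cell_level: float = 40.0
    background_level: float = 10.0
    read_noise_sd: float = 3.0
    min_spot_separation_nm: float = 800.0
    exclusion_radius_nm: float = 640.0
    n_frames: int = 1
    cumulative_spots: bool = False
    frame_interval_s: float = 1.0
    channel_names: tuple[str, str] = ("chA", "chB")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.cell_radius_px <= 0 or self.psf_sigma_px <= 0:
            raise ValueError("cell_radius_px and psf_sigma_px must be positive")
        if self.coloc_offset_nm < 0:
            raise ValueError("coloc_offset_nm must be non-negative")
        if self.dispersion_scale <= 0:
            raise ValueError("dispersion_scale must be positive")
        if any(n < 0 for n in self.n_vesicles_per_channel):
            raise ValueError("spot counts must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.cell_center_px is None:
            self.cell_center_px = (
                (self.image_size_px[0] - 1) / 2.0,
                (self.image_size_px[1] - 1) / 2.0,
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size_px"] = list(self.image_size_px)
        return d


@dataclass
class GroundTruth:
    """True annotations accompanying generated data.

    Only the fields relevant to the generator that produced the object are
    populated; positions are (y, x) in nm, matching the analysis modules'
    distance convention.
    """

    positions_nm: dict[str, np.ndarray] = field(default_factory=dict)
    intensities: dict[str, np.ndarray] = field(default_factory=dict)
    pairs: list[tuple[int, int]] = field(default_factory=list)
    cell_center_px: tuple[float, float] | None = None
    cell_radius_px: float | None = None
    compartment_mask: np.ndarray | None = None
    cofusion_labels: np.ndarray | None = None
    fusion_frames: np.ndarray | None = None
    event_windows: list[tuple[int, int]] = field(default_factory=list)
    divergence_index: int | None = None
    seed: int | None = None

    def n_spots(self, channel: str) -> int:
        return 0 if channel not in self.positions_nm else len(
            self.positions_nm[channel]
        )

    def to_json(self) -> str:
        def convert(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: convert(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [convert(x) for x in v]
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            return v

        return json.dumps(
            {k: convert(v) for k, v in dataclasses.asdict(self).items()},
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# confocal-like cell images
# ---------------------------------------------------------------------------


def _place_radial(
    rng: np.random.Generator, cfg: SynthImageConfig, n: int, existing_px: np.ndarray
) -> np.ndarray:
    """Radially distributed spot centres (px) inside the cell, separated."""
    cy, cx = cfg.cell_center_px
    margin = 3.0 * cfg.psf_sigma_px
    r_max = cfg.cell_radius_px - margin
    if r_max <= 0:
        raise ValueError("cell too small for the configured PSF")
    min_sep_px = cfg.min_spot_separation_nm / cfg.pixel_size_nm
    placed = list(existing_px)
    out = []
    for _ in range(n):
        for attempt in range(5000):
            frac = rng.beta(2.0 * cfg.dispersion_scale, 2.0)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            pos = np.array(
                [cy + frac * r_max * np.sin(theta), cx + frac * r_max * np.cos(theta)]
            )
            if placed:
                d = np.linalg.norm(np.asarray(placed) - pos, axis=1)
                if d.min() < min_sep_px:
                    continue
            placed.append(pos)
            out.append(pos)
            break
        else:
            raise ValueError(
                f"could not place {n} spots with separation "
                f"{cfg.min_spot_separation_nm} nm in a cell of radius "
                f"{cfg.cell_radius_px} px; reduce counts or separation"
            )
    return np.array(out).reshape(n, 2)


def _render_spots(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    intensities: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Sum of 2-D Gaussians with given integrated intensities."""
    img = np.zeros(shape, dtype=float)
    if len(centers_px) == 0:
        return img
    w = int(np.ceil(5 * sigma))
    yy, xx = np.mgrid[-w : w + 1, -w : w + 1]
    for (cy, cx), amp_int in zip(centers_px, intensities):
        iy, ix = int(round(cy)), int(round(cx))
        dy, dx = cy - iy, cx - ix
        g = np.exp(-(((yy - dy) ** 2 + (xx - dx) ** 2) / (2 * sigma**2)))
        g *= amp_int / (2 * np.pi * sigma**2)
        y0, y1 = max(0, iy - w), min(shape[0], iy + w + 1)
        x0, x1 = max(0, ix - w), min(shape[1], ix + w + 1)
        img[y0:y1, x0:x1] += g[
            y0 - (iy - w) : y1 - (iy - w), x0 - (ix - w) : x1 - (ix - w)
        ]
    return img


def _add_noise(
    expected: np.ndarray, rng: np.random.Generator, read_noise_sd: float
) -> np.ndarray:
    noisy = rng.poisson(np.clip(expected, 0, None)).astype(float)
    if read_noise_sd > 0:
        noisy += rng.normal(0.0, read_noise_sd, size=expected.shape)
    return np.clip(noisy, 0.0, None)


def generate_cell_image(
    config: SynthImageConfig,
) -> tuple[FrameStack, GroundTruth]:
    """Render a two-channel cell image with known spot positions and pairing.

    Channel A spots are placed first; ``round(coloc_fraction * n_B)``
    channel-B spots are then co-positioned with distinct A spots (random
    offset uniform in a disk of radius ``coloc_offset_nm``, so every true
    pair's distance is at most the offset), and the remaining B spots are
    rejection-sampled at more than ``exclusion_radius_nm`` from every A
    spot. The realized colocalization fraction among ground-truth spots is
    therefore imposed exactly, not sampled.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ny, nx = cfg.image_size_px
    n_a, n_b = cfg.n_vesicles_per_channel
    n_pair = int(round(cfg.coloc_fraction * n_b))
    if n_pair > 0 and n_a == 0:
        raise ValueError("coloc_fraction > 0 requires channel-A spots")
    if n_pair > n_a:
        raise ValueError(
            f"round(coloc_fraction*n_B)={n_pair} exceeds n_A={n_a}; "
            "cannot pair each co-positioned spot with a distinct A spot"
        )

    pos_a = _place_radial(rng, cfg, n_a, np.empty((0, 2)))

    # paired B spots: distinct A partners, offset uniform in a disk
    partner = rng.permutation(n_a)[:n_pair] if n_pair else np.array([], dtype=int)
    paired = []
    offset_px = cfg.coloc_offset_nm / cfg.pixel_size_nm
    for ia in partner:
        r = offset_px * np.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * np.pi)
        paired.append(pos_a[ia] + [r * np.sin(th), r * np.cos(th)])
    paired = np.array(paired).reshape(n_pair, 2)

    # unpaired B spots: far from every A spot
    excl_px = cfg.exclusion_radius_nm / cfg.pixel_size_nm
    min_sep_px = cfg.min_spot_separation_nm / cfg.pixel_size_nm
    cy, cx = cfg.cell_center_px
    r_max = cfg.cell_radius_px - 3.0 * cfg.psf_sigma_px
    unpaired = []
    for _ in range(n_b - n_pair):
        for attempt in range(5000):
            frac = rng.beta(2.0 * cfg.dispersion_scale, 2.0)
            th = rng.uniform(0.0, 2.0 * np.pi)
            pos = np.array(
                [cy + frac * r_max * np.sin(th), cx + frac * r_max * np.cos(th)]
            )
            if n_a and np.linalg.norm(pos_a - pos, axis=1).min() <= excl_px:
                continue
            others = list(paired) + unpaired
            if others and np.linalg.norm(
                np.asarray(others) - pos, axis=1
            ).min() < min_sep_px:
                continue
            unpaired.append(pos)
            break
        else:
            raise ValueError(
                "could not place non-colocalized channel-B spots outside "
                f"{cfg.exclusion_radius_nm} nm of all channel-A spots; "
                "cell too crowded for the requested geometry"
            )
    pos_b = np.concatenate([paired, np.array(unpaired).reshape(-1, 2)], axis=0)

    inten_a = np.full(n_a, cfg.spot_intensity)
    inten_b = np.full(n_b, cfg.spot_intensity)

    # cell body: disk at cell_level over background_level, blurred by the
    # PSF — the cell outline is diffraction-limited too, and a hard step
    # would be an imaging artefact no microscope produces
    from scipy.ndimage import gaussian_filter

    yy, xx = np.mgrid[0:ny, 0:nx]
    cell_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.cell_radius_px**2
    base = gaussian_filter(
        np.where(cell_mask, cfg.cell_level, cfg.background_level).astype(float),
        cfg.psf_sigma_px,
    )

    data = np.empty((cfg.n_frames, 2, ny, nx), dtype=float)
    for t in range(cfg.n_frames):
        if cfg.cumulative_spots:
            ka = min(t + 1, n_a)
            kb = min(t + 1, n_b)
        else:
            ka, kb = n_a, n_b
        for ci, (pos, inten, k) in enumerate(
            [(pos_a, inten_a, ka), (pos_b, inten_b, kb)]
        ):
            expected = base + _render_spots(
                (ny, nx), pos[:k], inten[:k], cfg.psf_sigma_px
            )
            data[t, ci] = _add_noise(expected, rng, cfg.read_noise_sd)

    stack = FrameStack(
        data=data,
        pixel_size_nm=cfg.pixel_size_nm,
        frame_interval_s=cfg.frame_interval_s,
        channel_names=list(cfg.channel_names),
    )
    na_name, nb_name = cfg.channel_names
    truth = GroundTruth(
        positions_nm={
            na_name: pos_a * cfg.pixel_size_nm,
            nb_name: pos_b * cfg.pixel_size_nm,
        },
        intensities={na_name: inten_a, nb_name: inten_b},
        pairs=[(int(ia), int(ib)) for ib, ia in enumerate(partner)],
        cell_center_px=tuple(cfg.cell_center_px),
        cell_radius_px=cfg.cell_radius_px,
        seed=cfg.seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# TIRF fusion-event series
# ---------------------------------------------------------------------------


def generate_tirf_series(
    config: SynthImageConfig,
    n_events: int,
    cofusion_rate: float,
    n_frames: int = 12,
    seed: int | None = None,
    fusion_tau_frames: float = 1.5,
) -> tuple[FrameStack, GroundTruth]:
    """Render a two-channel TIRF movie of vesicle fusion events.

    Each event is a spot pair (cargo channel 0, marker channel 1) at a fixed
    position. The cargo intensity collapses exponentially after the event's
    fusion frame. For true co-fusion events the marker co-decays identically;
    otherwise the marker persists at constant expected intensity. Exactly
    ``round(cofusion_rate * n_events)`` events are co-fusions; labels are
    shuffled and recorded in the ground truth.
    """
    if not 0.0 <= cofusion_rate <= 1.0:
        raise ValueError("cofusion_rate must lie in [0, 1]")
    if n_frames < 4:
        raise ValueError(
            "n_frames must be >= 4 (an initial frame plus a final three)"
        )
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ny, nx = cfg.image_size_px
    margin = 3.0 * cfg.psf_sigma_px + 4.0
    min_sep_px = cfg.min_spot_separation_nm / cfg.pixel_size_nm

    positions = []
    for _ in range(n_events):
        for attempt in range(5000):
            pos = rng.uniform([margin, margin], [ny - 1 - margin, nx - 1 - margin])
            if positions and np.linalg.norm(
                np.asarray(positions) - pos, axis=1
            ).min() < min_sep_px:
                continue
            positions.append(pos)
            break
        else:
            raise ValueError(
                f"could not place {n_events} events with separation "
                f"{cfg.min_spot_separation_nm} nm in a "
                f"{ny}x{nx} px field; reduce n_events"
            )
    positions = np.array(positions)

    n_co = int(round(cofusion_rate * n_events))
    labels = np.zeros(n_events, dtype=bool)
    labels[:n_co] = True
    rng.shuffle(labels)

    # fusion strictly after the initial frame, early enough for full decay
    hi = max(2, n_frames // 2)
    fusion_frames = rng.integers(1, hi, size=n_events)

    amp = cfg.spot_intensity
    data = np.empty((n_frames, 2, ny, nx), dtype=float)
    for t in range(n_frames):
        decay = np.where(
            t < fusion_frames,
            1.0,
            np.exp(-(t - fusion_frames) / fusion_tau_frames),
        )
        cargo_amp = amp * decay
        marker_amp = np.where(labels, amp * decay, amp)
        for ci, amps in enumerate([cargo_amp, marker_amp]):
            expected = cfg.background_level + _render_spots(
                (ny, nx), positions, amps, cfg.psf_sigma_px
            )
            data[t, ci] = _add_noise(expected, rng, cfg.read_noise_sd)

    stack = FrameStack(
        data=data,
        pixel_size_nm=cfg.pixel_size_nm,
        frame_interval_s=cfg.frame_interval_s,
        channel_names=["cargo", "marker"],
    )
    truth = GroundTruth(
        positions_nm={"events": positions * cfg.pixel_size_nm},
        cofusion_labels=labels,
        fusion_frames=fusion_frames,
        event_windows=[(0, n_frames - 1)] * n_events,
        seed=cfg.seed if seed is None else seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# grouped two-sample time series
# ---------------------------------------------------------------------------


def generate_grouped_timeseries(
    n_per_group_per_timepoint: int,
    timepoints: np.ndarray,
    shift_start_index: int,
    effect_size: float,
    noise_sd: float,
    seed: int = 0,
    baseline_start: float = 100.0,
    baseline_slope: float = 5.0,
) -> tuple[GroupedTimeSeries, GroundTruth]:
    """Two-group per-timepoint samples sharing a baseline trend.

    Both groups follow the same linear baseline with Gaussian noise of
    standard deviation ``noise_sd``; group B is location-shifted downward by
    ``effect_size`` from ``shift_start_index`` onward, emulating the sustained
    separation of pooled intensity distributions between genotypes. With
    ``effect_size == 0`` the true divergence index is ``None``.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    n = int(n_per_group_per_timepoint)
    if n <= 0:
        raise ValueError("n_per_group_per_timepoint must be positive")
    if not 0 <= shift_start_index < len(timepoints):
        raise ValueError("shift_start_index out of range")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    sa, sb = [], []
    for i in range(len(timepoints)):
        mu = baseline_start + baseline_slope * i
        shift = effect_size if i >= shift_start_index else 0.0
        sa.append(mu + rng.normal(0.0, noise_sd, size=n))
        sb.append(mu - shift + rng.normal(0.0, noise_sd, size=n))
    series = GroupedTimeSeries(
        timepoints, sa, sb, labels=("group_a", "group_b")
    )
    truth = GroundTruth(
        divergence_index=None if effect_size == 0 else int(shift_start_index),
        seed=seed,
    )
    return series, truth
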