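"""Image container and TIFF input/output.

The unit of image data throughout the package is the :class:`FrameStack`:
a ``T x C x Y x X`` intensity array together with the physical calibration
(pixel size in nm, frame interval in s) needed to express distances in nm
and times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class FrameStack:
    """A calibrated multi-channel time-lapse image stack.

    Parameters
    ----------
    data:
        Intensity array of shape ``(T, C, Y, X)``, non-negative.
    pixel_size_nm:
        Lateral pixel size in nanometres (> 0).
    frame_interval_s:
        Time between consecutive frames in seconds (> 0).
    channel_names:
        One label per channel; defaults to ``ch0, ch1, ...``.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float = 1.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be a (T, C, Y, X) array, got shape {self.data.shape}"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel axis")

    # -- shape helpers -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel given by index or name to an index."""
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        idx = int(channel)
        if not 0 <= idx < self.n_channels:
            raise IndexError(f"channel index {idx} out of range")
        return idx

    def frame(self, frame: int, channel: int | str) -> np.ndarray:
        """Return one ``(Y, X)`` plane."""
        if not 0 <= frame < self.n_frames:
            raise IndexError(f"frame {frame} out of range (T={self.n_frames})")
        return self.data[frame, self.channel_index(channel)]

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def px_to_nm(self, coords_px: np.ndarray) -> np.ndarray:
        return np.asarray(coords_px, dtype=float) * self.pixel_size_nm

    def nm_to_px(self, coords_nm: np.ndarray) -> np.ndarray:
        return np.asarray(coords_nm, dtype=float) / self.pixel_size_nm


def write_stack(path, stack: FrameStack) -> None:
    """Write a stack as a multi-page TIFF (pages = T*C, interleaved C fastest).

    Calibration is stored in the ImageDescription tag as JSON so that
    :func:`read_stack` round-trips losslessly. Output bytes are a pure
    function of the stack contents (no timestamps are written).
    """
    import json

    t, c, y, x = stack.data.shape
    pages = stack.data.reshape(t * c, y, x)
    meta = {
        "axes": "TCYX",
        "shape": [t, c, y, x],
        "pixel_size_nm": stack.pixel_size_nm,
        "frame_interval_s": stack.frame_interval_s,
        "channel_names": stack.channel_names,
    }
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_stack(
    path,
    pixel_size_nm: float | None = None,
    frame_interval_s: float | None = None,
    n_channels: int | None = None,
    channel_names: list[str] | None = None,
) -> FrameStack:
    """Read a multi-page TIFF into a :class:`FrameStack`.

    Calibration is taken from the JSON description written by
    :func:`write_stack` when present; explicit arguments override it.
    For foreign TIFFs lacking metadata, ``pixel_size_nm`` (and
    ``n_channels`` if the file interleaves channels) must be supplied.
    """
    import json

    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    try:
        parsed = json.loads(desc)
        if isinstance(parsed, dict):
            meta = parsed
    except (json.JSONDecodeError, TypeError):
        pass

    if pages.ndim == 2:
        pages = pages[None]
    if "shape" in meta:
        t, c, y, x = meta["shape"]
        data = pages.reshape(t, c, y, x)
    else:
        c = n_channels or 1
        if pages.shape[0] % c:
            raise ValueError(
                f"page count {pages.shape[0]} not divisible by n_channels={c}"
            )
        data = pages.reshape(pages.shape[0] // c, c, *pages.shape[1:])

    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise ValueError("pixel_size_nm not in file metadata; pass it explicitly")
    dt = (
        frame_interval_s
        if frame_interval_s is not None
        else meta.get("frame_interval_s", 1.0)
    )
    names = channel_names or meta.get("channel_names") or []
    return FrameStack(
        data=data,
        pixel_size_nm=float(px),
        frame_interval_s=float(dt),
        channel_names=list(names),
    )
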