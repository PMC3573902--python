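"""Reading, writing and validating grey-value time-lapse stacks.

A stack is a multi-page TIFF (one page per time point) plus a plain-text
sidecar carrying the acquisition timeline and the pixel calibration; TIFF
tags for timelines are non-standard, so the sidecar is authoritative.
Grey values are held as floating point internally, without any rescaling of
relative intensities: the brightness-constancy assumption behind the optical
flow needs the raw intensity ordering untouched.

Coordinate convention used throughout the package: row-major pixel grids,
origin top-left, ``x`` = column, ``y`` = row, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile
import yaml

from .errors import StackIOError, ValidationError

__all__ = [
    "Timeline",
    "ImageStack",
    "build_timeline",
    "calibrate_scale",
    "read_stack",
    "write_stack",
]


@dataclass(frozen=True)
class Timeline:
    """Nominal uniform acquisition cadence.

    Parameters
    ----------
    start_clock_time:
        Clock time of frame 0 in hours (0–24), used to place samples on the
        day/night schedule.
    interval_s:
        Nominal frame interval in seconds (90 s for leaf stacks, 30 s for
        root stacks in the study design).
    n_frames:
        Number of frames.
    """

    start_clock_time: float
    interval_s: float
    n_frames: int

    def __post_init__(self):
        if not (0.0 <= self.start_clock_time < 24.0):
            raise ValidationError(
                f"start_clock_time must be in [0, 24), got {self.start_clock_time}"
            )
        if not self.interval_s > 0:
            raise ValidationError(f"interval_s must be > 0, got {self.interval_s}")
        if self.n_frames < 2:
            raise ValidationError(f"n_frames must be >= 2, got {self.n_frames}")

    def timestamps(self) -> np.ndarray:
        """Seconds since experiment start, ``t_i = i * interval_s``."""
        return np.arange(self.n_frames, dtype=float) * self.interval_s

    def clock_times(self) -> np.ndarray:
        """Clock time in hours for each frame, wrapping at midnight."""
        return (self.start_clock_time + self.timestamps() / 3600.0) % 24.0


def build_timeline(start_clock_time: float, interval_s: float, n_frames: int) -> Timeline:
    """Construct a :class:`Timeline`; validates its invariants."""
    return Timeline(float(start_clock_time), float(interval_s), int(n_frames))


@dataclass
class ImageStack:
    """Ordered grey-value frames with timestamps and pixel calibration.

    ``frames`` is a ``(T, H, W)`` float array; ``timestamps`` are strictly
    increasing seconds from experiment start. ``source_dtype`` remembers the
    on-disk bit depth so a round trip preserves it.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float
    role: str = "leaf"
    start_clock_time: float = 0.0
    source_dtype: np.dtype = field(default_factory=lambda: np.dtype(np.uint8))

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.source_dtype = np.dtype(self.source_dtype)
        self.validate()

    def validate(self):
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise ValidationError("a stack needs at least 2 frames")
        if self.timestamps.shape != (self.n_frames,):
            raise ValidationError(
                f"{self.n_frames} frames but {self.timestamps.size} timestamps"
            )
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("grey values must be finite")
        if np.any(self.frames < 0):
            raise ValidationError("grey values must be non-negative")
        if self.role not in ("leaf", "root"):
            raise ValidationError(f"role must be 'leaf' or 'root', got {self.role!r}")

    # -- convenience -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def interval_s(self) -> float:
        """Median frame interval in seconds (nominal cadence if uniform)."""
        return float(np.median(np.diff(self.timestamps)))

    def clock_times(self) -> np.ndarray:
        return (self.start_clock_time + self.timestamps / 3600.0) % 24.0

    def with_frames(self, frames: np.ndarray) -> "ImageStack":
        return replace(self, frames=np.asarray(frames, dtype=np.float64))


def calibrate_scale(known_length_mm: float, measured_px: float) -> float:
    """Pixel calibration in mm/px from a known physical length.

    Needed so root velocities can be reported in mm h⁻¹.
    """
    if not (known_length_mm > 0 and measured_px > 0):
        raise ValidationError(
            f"calibration inputs must be positive, got {known_length_mm} mm / {measured_px} px"
        )
    return float(known_length_mm) / float(measured_px)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def read_stack(
    path,
    pixel_size: Optional[float] = None,
    timeline: Optional[Timeline] = None,
    role: Optional[str] = None,
    timestamps: Optional[Sequence[float]] = None,
) -> ImageStack:
    """Read a multi-page grey-value TIFF into an :class:`ImageStack`.

    ``pixel_size`` and ``timeline`` may be omitted when a sidecar written by
    :func:`write_stack` sits next to the TIFF. An explicit ``timestamps``
    sequence overrides the nominal timeline expansion (real rigs drift).
    """
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"stack file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.pages
            n = len(pages)
            if n < 2:
                raise ValidationError(f"stack must have >= 2 pages, got {n} in {path}")
            shape0 = pages[0].shape
            arrays = []
            for i, page in enumerate(pages):
                if page.shape != shape0:
                    raise ValidationError(
                        f"page {i} has shape {page.shape}, expected {shape0}"
                    )
                a = page.asarray()
                if a.ndim != 2:
                    raise ValidationError(
                        f"page {i} is not single-channel grey-value (shape {a.shape})"
                    )
                arrays.append(a)
    except tifffile.TiffFileError as exc:
        raise StackIOError(f"cannot read TIFF {path}: {exc}") from exc
    source_dtype = arrays[0].dtype
    frames = np.stack(arrays).astype(np.float64)

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}

    if pixel_size is None:
        pixel_size = meta.get("pixel_size")
    if pixel_size is None:
        raise ValidationError("pixel_size not given and no sidecar metadata found")
    if role is None:
        role = meta.get("role", "leaf")

    start_clock = 0.0
    if timestamps is not None:
        ts = np.asarray(timestamps, dtype=float)
        if timeline is not None:
            start_clock = timeline.start_clock_time
    elif timeline is not None:
        if timeline.n_frames != len(frames):
            raise ValidationError(
                f"timeline expects {timeline.n_frames} frames, stack has {len(frames)}"
            )
        ts = timeline.timestamps()
        start_clock = timeline.start_clock_time
    elif "timestamps" in meta:
        ts = np.asarray(meta["timestamps"], dtype=float)
        start_clock = float(meta.get("start_clock_time", 0.0))
    elif "interval_s" in meta:
        tl = build_timeline(meta.get("start_clock_time", 0.0), meta["interval_s"], len(frames))
        ts = tl.timestamps()
        start_clock = tl.start_clock_time
    else:
        raise ValidationError("no timeline given and no sidecar metadata found")

    return ImageStack(
        frames=frames,
        timestamps=ts,
        pixel_size=float(pixel_size),
        role=role,
        start_clock_time=float(start_clock),
        source_dtype=source_dtype,
    )


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as a multi-page TIFF plus a YAML sidecar.

    Frames are cast back to the stack's source bit depth (rounded and
    clipped for integer dtypes), preserving page order.
    """
    stack.validate()
    path = Path(path)
    dt = stack.source_dtype
    if np.issubdtype(dt, np.integer):
        info = np.iinfo(dt)
        data = np.clip(np.rint(stack.frames), info.min, info.max).astype(dt)
    else:
        data = stack.frames.astype(dt)
    try:
        tifffile.imwrite(path, data, photometric="minisblack")
    except OSError as exc:
        raise StackIOError(f"cannot write TIFF {path}: {exc}") from exc
    meta = {
        "pixel_size": float(stack.pixel_size),
        "role": stack.role,
        "start_clock_time": float(stack.start_clock_time),
        "interval_s": float(stack.interval_s),
        "timestamps": [float(t) for t in stack.timestamps],
        "dtype": str(dt),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path
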