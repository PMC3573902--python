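"""Leaf relative growth rate over a tracked area of interest (AOI).

Two estimators of the areal relative growth rate are computed side by side
and required to agree — the module's central self-check:

* divergence method: RGR = ⟨∂u/∂x + ∂v/∂y⟩ over the AOI interior, the mean
  divergence of the estimated velocity field (isotropic areal expansion at
  rate r has divergence exactly r);
* area method: RGR = (ln A₁ − ln A₀)/t from the areas of the AOI polygon
  advected with the flow across the analysis window (default ≈ 15 min).

Both are reported in h⁻¹. The AOI is a simple polygon whose vertices ride
the displacement field; where flow confidence fails (typically leaf edges),
vertex displacements are filled from the nearest valid pixels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .errors import QualityError, TrackingLostError, ValidationError
from .flow_engine import (
    DisplacementField,
    StructureTensorParams,
    VelocityField,
    _fill_invalid,
    estimate_flow_field,
)
from .stack_io import ImageStack

__all__ = [
    "AOI",
    "RGRWindow",
    "advect_aoi",
    "polygon_area",
    "rgr_area_method",
    "rgr_divergence_method",
    "rgr_series",
    "rgr_series_to_frame",
    "write_aoi_polygons",
]

log = logging.getLogger(__name__)

MIN_VALID_AOI_PIXELS = 100


@dataclass
class AOI:
    """A simple polygon on the leaf, tied to one frame of the stack."""

    vertices: np.ndarray  # (N, 2) xy pixel coordinates
    frame_index: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValidationError("AOI needs >= 3 (x, y) vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValidationError("AOI polygon must be simple with positive area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def mask(self, shape) -> np.ndarray:
        """Boolean rasterisation on a (H, W) grid (row, col) = (y, x)."""
        return polygon2mask(shape, self.vertices[:, ::-1])


def polygon_area(aoi: AOI, pixel_size: float) -> tuple:
    """(area_px², area_mm²) of the AOI polygon (shoelace, orientation-free)."""
    area_px = aoi.polygon.area
    if area_px <= 0:
        raise ValidationError("degenerate AOI polygon")
    return float(area_px), float(area_px * pixel_size ** 2)


def advect_aoi(aoi: AOI, disp: DisplacementField, frame_index: Optional[int] = None) -> AOI:
    """Move each AOI vertex by the locally interpolated displacement.

    Displacements at invalid flow pixels are filled from the nearest valid
    neighbours before bilinear sampling. A self-intersecting result is
    repaired by a convex-safe simplification (zero-width buffer, falling
    back to the convex hull) with a logged warning; a degenerate result
    raises :class:`TrackingLostError`.
    """
    du = _fill_invalid(np.nan_to_num(disp.du), disp.valid_mask)
    dv = _fill_invalid(np.nan_to_num(disp.dv), disp.valid_mask)
    xs, ys = aoi.vertices[:, 0], aoi.vertices[:, 1]
    coords = np.stack([ys, xs])
    new = np.stack(
        [
            xs + ndimage.map_coordinates(du, coords, order=1, mode="nearest"),
            ys + ndimage.map_coordinates(dv, coords, order=1, mode="nearest"),
        ],
        axis=1,
    )
    poly = Polygon(new)
    if not poly.is_valid:
        log.warning("advected AOI self-intersects; applying convex-safe simplification")
        repaired = poly.buffer(0)
        if repaired.is_empty or repaired.geom_type != "Polygon":
            repaired = poly.convex_hull
        new = np.asarray(repaired.exterior.coords[:-1])
        poly = Polygon(new)
    if poly.area <= 0:
        raise TrackingLostError("advected AOI degenerated to zero area")
    return AOI(new, frame_index if frame_index is not None else aoi.frame_index)


def rgr_area_method(A0: float, A1: float, dt_h: float) -> float:
    """RGR = (ln A₁ − ln A₀)/t in h⁻¹ from areas at the window boundaries."""
    if A0 <= 0 or A1 <= 0:
        raise ValidationError(f"areas must be positive, got A0={A0}, A1={A1}")
    if dt_h <= 0:
        raise ValidationError(f"window duration must be positive, got {dt_h} h")
    return (math.log(A1) - math.log(A0)) / dt_h


def rgr_divergence_method(
    field: VelocityField,
    aoi: AOI,
    frame_interval_s: float,
    smooth_sigma: float = 1.0,
) -> float:
    """Mean divergence of the flow over the AOI interior, in h⁻¹.

    Central differences on the confidence-masked, lightly smoothed field;
    pixels adjacent to invalid ones are excluded so no difference straddles
    a fill boundary.
    """
    mask = aoi.mask(field.u.shape)
    valid = mask & field.valid_mask
    n_valid = int(valid.sum())
    if n_valid < MIN_VALID_AOI_PIXELS:
        raise QualityError(
            f"only {n_valid} valid flow pixels inside the AOI "
            f"(need >= {MIN_VALID_AOI_PIXELS})",
            n_valid=n_valid,
        )
    u = _fill_invalid(np.nan_to_num(field.u), field.valid_mask)
    v = _fill_invalid(np.nan_to_num(field.v), field.valid_mask)
    if smooth_sigma > 0:
        u = ndimage.gaussian_filter(u, smooth_sigma, mode="nearest")
        v = ndimage.gaussian_filter(v, smooth_sigma, mode="nearest")
    dudx = np.gradient(u, axis=1)
    dvdy = np.gradient(v, axis=0)
    # keep only pixels whose 4-neighbourhood is fully valid
    eroded = ndimage.binary_erosion(valid, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if eroded.sum() < MIN_VALID_AOI_PIXELS:
        eroded = valid
    div_per_frame = float(np.mean(dudx[eroded] + dvdy[eroded]))
    return div_per_frame * 3600.0 / frame_interval_s


@dataclass
class RGRWindow:
    """One analysis window with both RGR estimates, time-stamped at centre."""

    window_start: float  # s
    window_end: float  # s
    A0_px2: float
    A1_px2: float
    A0_mm2: float
    A1_mm2: float
    rgr_area_h: float
    rgr_div_h: float
    n_valid_px: int
    window_minutes: float

    @property
    def centre_time(self) -> float:
        return 0.5 * (self.window_start + self.window_end)


def rgr_series(
    stack: ImageStack,
    aoi0: AOI,
    params: Optional[StructureTensorParams] = None,
    window_minutes: float = 15.0,
    overlap: bool = False,
    return_aois: bool = False,
):
    """RGR time series over tiled analysis windows (default ≈ 15 min).

    The AOI is advected frame-to-frame through the whole stack with the
    estimated flow; per window the area-method RGR comes from the advected
    polygon areas at the window boundaries and the divergence-method RGR is
    the time average of the per-frame mean divergence. If tracking is lost
    the series is truncated at the failing frame with a logged index.
    """
    params = params or StructureTensorParams()
    T = stack.n_frames
    dt = stack.interval_s
    fpw = max(1, int(round(window_minutes * 60.0 / dt)))
    if T - 1 < 2 * fpw:
        raise ValidationError(
            f"stack spans {T - 1} intervals; need at least two {window_minutes}-min windows"
        )
    half = params.temporal_halfwidth
    last_centre = T - 1 - half

    aois = {0: AOI(aoi0.vertices, 0)}
    div_by_frame = np.full(T - 1, np.nan)
    nvalid_by_frame = np.zeros(T - 1, dtype=int)
    truncated_at = None
    current = aois[0]
    step = fpw if not overlap else max(1, fpw // 2)

    for k in range(T - 1):
        centre = int(np.clip(k, half, last_centre))
        fld = estimate_flow_field(stack, centre, params)
        try:
            div_by_frame[k] = rgr_divergence_method(fld, current, dt)
            nvalid_by_frame[k] = int((current.mask(fld.u.shape) & fld.valid_mask).sum())
        except QualityError as exc:
            nvalid_by_frame[k] = exc.n_valid or 0
        disp = DisplacementField(
            du=np.nan_to_num(fld.u), dv=np.nan_to_num(fld.v), valid_mask=fld.valid_mask
        )
        try:
            current = advect_aoi(current, disp, frame_index=k + 1)
        except TrackingLostError:
            log.warning("AOI tracking lost at frame %d; truncating series", k + 1)
            truncated_at = k + 1
            break
        aois[k + 1] = current

    windows: List[RGRWindow] = []
    w0 = 0
    while w0 + fpw <= (truncated_at if truncated_at is not None else T - 1):
        w1 = w0 + fpw
        if w0 not in aois or w1 not in aois:
            break
        A0_px, A0_mm = polygon_area(aois[w0], stack.pixel_size)
        A1_px, A1_mm = polygon_area(aois[w1], stack.pixel_size)
        t0, t1 = stack.timestamps[w0], stack.timestamps[w1]
        dt_h = (t1 - t0) / 3600.0
        divs = div_by_frame[w0:w1]
        windows.append(
            RGRWindow(
                window_start=float(t0),
                window_end=float(t1),
                A0_px2=A0_px,
                A1_px2=A1_px,
                A0_mm2=A0_mm,
                A1_mm2=A1_mm,
                rgr_area_h=rgr_area_method(A0_mm, A1_mm, dt_h),
                rgr_div_h=float(np.nanmean(divs)) if np.isfinite(divs).any() else float("nan"),
                n_valid_px=int(np.min(nvalid_by_frame[w0:w1])),
                window_minutes=window_minutes,
            )
        )
        w0 += step
    if return_aois:
        return windows, [aois[k] for k in sorted(aois)]
    return windows


def write_aoi_polygons(aois: Sequence[AOI], path) -> Path:
    """Write tracked AOI polygons as text, one ``frame: x,y; x,y; ...`` line
    per frame (the same format the scene generator uses for truth)."""
    path = Path(path)
    with open(path, "w") as fh:
        for aoi in aois:
            verts = "; ".join(f"{x:.6f},{y:.6f}" for x, y in aoi.vertices)
            fh.write(f"{aoi.frame_index}: {verts}\n")
    return path


def rgr_series_to_frame(windows: Sequence[RGRWindow], stack: ImageStack) -> pd.DataFrame:
    """Long-format table of an RGR series with clock-time columns."""
    clock0 = stack.start_clock_time

    def clk(t_s):
        return (clock0 + t_s / 3600.0) % 24.0

    return pd.DataFrame(
        {
            "window_start_s": [w.window_start for w in windows],
            "window_end_s": [w.window_end for w in windows],
            "window_start_clock": [clk(w.window_start) for w in windows],
            "window_end_clock": [clk(w.window_end) for w in windows],
            "A0_mm2": [w.A0_mm2 for w in windows],
            "A1_mm2": [w.A1_mm2 for w in windows],
            "rgr_area_h": [w.rgr_area_h for w in windows],
            "rgr_div_h": [w.rgr_div_h for w in windows],
            "n_valid_px": [w.n_valid_px for w in windows],
        }
    )
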