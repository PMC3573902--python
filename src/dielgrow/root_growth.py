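"""Root tip tracking and elongation velocity on short analysis windows.

Root velocity is the speed at which the tip is dislocated from the fully
mature, spatially fixed part of the root — a point-tracking notion, so the
tip is located geometrically (segmentation → skeleton → geodesic-farthest
endpoint from a fixed anchor) rather than from the flow field, whose
estimates at the advancing tip edge are unreliable. Displacement is
measured along the growth path (geodesic), not the straight line, so curved
growth does not under-report elongation; the straight-line figure is
reported alongside.

The default window is 5 min (10 frames at the 30 s cadence); velocities are
in mm h⁻¹ via the pixel calibration.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize
from skimage.registration import phase_cross_correlation

from .errors import (
    AmbiguityError,
    QualityError,
    RegistrationError,
    SegmentationError,
    ValidationError,
)
from .stack_io import ImageStack

__all__ = [
    "TipTrack",
    "RootVelocityWindow",
    "RootVelocityResult",
    "segment_root",
    "locate_tip",
    "register_anchor",
    "tip_velocity_series",
    "auto_anchor",
]

log = logging.getLogger(__name__)

MIN_ELONGATION = 3.0  # major/minor axis ratio for a credible root component
ANCHOR_DRIFT_TOL_PX = 2.0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_root(frame: np.ndarray, min_object_px: int = 64) -> np.ndarray:
    """Binary root mask from a grey frame with a near-uniform background.

    Otsu threshold; polarity (root darker or brighter than background) is
    auto-detected by testing which side of the threshold yields an
    elongated largest connected component.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.std() < 1e-6:
        raise SegmentationError("blank frame: no foreground to segment")
    frame = ndimage.gaussian_filter(frame, 1.0)  # sensor-noise suppression
    thr = threshold_otsu(frame)

    best_mask, best_elong = None, 0.0
    for fg in (frame < thr, frame > thr):
        if not fg.any() or fg.mean() > 0.5:
            continue  # root occupies the minority of the image
        lbl = label(fg)
        sizes = np.bincount(lbl.ravel())
        sizes[0] = 0
        keep = sizes >= min_object_px
        if not keep.any():
            continue
        lbl[~keep[lbl]] = 0
        props = regionprops(lbl)
        biggest = max(props, key=lambda p: p.area)
        minor = max(biggest.axis_minor_length, 1e-9)
        elong = biggest.axis_major_length / minor
        if elong > best_elong:
            best_elong = elong
            best_mask = lbl == biggest.label
    if best_mask is None or best_elong < MIN_ELONGATION:
        raise SegmentationError(
            f"no elongated foreground component found (best elongation {best_elong:.2f}, "
            f"need >= {MIN_ELONGATION})"
        )
    return best_mask


# ---------------------------------------------------------------------------
# skeleton geodesics and tip location
# ---------------------------------------------------------------------------

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_geodesics(skel: np.ndarray, source_rc: Tuple[int, int]) -> np.ndarray:
    """Dijkstra distances along skeleton pixels (diagonal steps cost √2)."""
    H, W = skel.shape
    dist = np.full((H, W), np.inf)
    sr, sc = source_rc
    dist[sr, sc] = 0.0
    heap = [(0.0, sr, sc)]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in _NBRS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and skel[rr, cc]:
                nd = d + (1.4142135623730951 if dr and dc else 1.0)
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, rr, cc))
    return dist


def _skeleton_endpoints(skel: np.ndarray) -> list:
    """Skeleton pixels with exactly one 8-connected skeleton neighbour."""
    nb = ndimage.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant") - 1
    rr, cc = np.nonzero(skel & (nb == 1))
    return list(zip(rr.tolist(), cc.tolist()))


def _prune_spurs(skel: np.ndarray, max_spur_len: float) -> np.ndarray:
    """Iteratively remove short side branches (skeletonisation artifacts)."""
    skel = skel.copy()
    for _ in range(3):
        ends = _skeleton_endpoints(skel)
        if len(ends) <= 2:
            break
        removed_any = False
        for er, ec in ends:
            # walk inward until a branch point or the length budget runs out
            path = [(er, ec)]
            prev = None
            cur = (er, ec)
            length = 0.0
            while length <= max_spur_len:
                nbrs = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr, dc in _NBRS
                    if 0 <= cur[0] + dr < skel.shape[0]
                    and 0 <= cur[1] + dc < skel.shape[1]
                    and skel[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nbrs) != 1:
                    break  # branch point or isolated pixel
                nxt = nbrs[0]
                length += 1.4142135623730951 if (nxt[0] != cur[0] and nxt[1] != cur[1]) else 1.0
                path.append(nxt)
                prev, cur = cur, nxt
            else:
                continue  # budget exhausted without a branch point: keep
            nb_at_end = ndimage.convolve(
                skel.astype(int), np.ones((3, 3), int), mode="constant"
            )[cur] - 1
            if nb_at_end >= 3 and length <= max_spur_len:
                for r, c in path[:-1]:
                    skel[r, c] = False
                removed_any = True
        if not removed_any:
            break
    return skel


def locate_tip(
    mask: np.ndarray,
    anchor: Tuple[float, float],
    spur_prune_px: Optional[float] = None,
) -> Tuple[float, float]:
    """Root tip as the skeleton endpoint geodesically farthest from the anchor.

    ``anchor`` is (x, y) at/near the mature end. Geodesic (along-skeleton)
    distance — not Euclidean — picks the correct end of C-shaped roots. Two
    endpoints at indistinguishable geodesic distance (equal branches) raise
    :class:`AmbiguityError` listing the candidates.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask")
    skel = skeletonize(mask)
    if spur_prune_px is None:
        # prune spurs up to the local root radius
        spur_prune_px = 0.5 * np.sqrt(mask.sum() / max(1, skeletonize(mask).sum())) * 4
    skel = _prune_spurs(skel, spur_prune_px)
    rr, cc = np.nonzero(skel)
    if rr.size == 0:
        raise SegmentationError("skeleton vanished after pruning")
    ax, ay = anchor
    i0 = int(np.argmin((cc - ax) ** 2 + (rr - ay) ** 2))
    dist = _skeleton_geodesics(skel, (rr[i0], cc[i0]))
    ends = _skeleton_endpoints(skel)
    if not ends:
        # a closed-loop skeleton: fall back to the farthest skeleton pixel
        k = int(np.nanargmax(np.where(np.isfinite(dist[rr, cc]), dist[rr, cc], -1)))
        return float(cc[k]), float(rr[k])
    dists = np.array([dist[r, c] for r, c in ends])
    finite = np.isfinite(dists)
    if not finite.any():
        raise SegmentationError("anchor disconnected from skeleton")
    order = np.argsort(dists)[::-1]
    best = order[0]
    if len(ends) > 1:
        second = order[1]
        eb, es = dists[best], dists[second]
        er, ec_ = ends[best]
        sr, sc_ = ends[second]
        far_apart = (er - sr) ** 2 + (ec_ - sc_) ** 2 > 25.0
        if np.isfinite(es) and far_apart and (eb - es) < max(2.0, 0.02 * eb):
            raise AmbiguityError(
                "two skeleton endpoints at indistinguishable geodesic distance "
                f"({eb:.1f} vs {es:.1f} px) — lateral branch?",
                candidates=[(float(c), float(r)) for r, c in (ends[best], ends[second])],
            )
    r, c = ends[best]
    return float(c), float(r)


def _tangent_at_tip(skel: np.ndarray, tip_rc, back_px: float = 14.0):
    """Outward unit tangent at a skeleton endpoint: principal direction of
    the skeleton pixels within ``back_px`` geodesic distance of the tip,
    oriented outward (PCA is much less sensitive to the endpoint's pixel
    quantisation than a two-point difference)."""
    dist = _skeleton_geodesics(skel, tip_rc)
    sel = np.isfinite(dist) & (dist <= back_px)
    rr, cc = np.nonzero(sel)
    if rr.size < 3:
        return np.array([0.0, 0.0])
    pts = np.column_stack([cc, rr]).astype(float)
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    t = vt[0]
    outward = np.array([tip_rc[1], tip_rc[0]]) - pts.mean(axis=0)
    if t @ outward < 0:
        t = -t
    return t


def _edge_cross(frame, origin, direction, s_lo, s_hi, mid, sgn, span, step=0.125):
    """First inside→outside crossing of ``mid`` along a ray, sub-pixel.

    ``sgn`` is +1 when the outside (background) is brighter than the root.
    The crossing is refined by regressing every profile sample on the edge
    ramp, which beats two-point interpolation on noisy profiles.
    """
    ss = np.arange(s_lo, s_hi + step, step)
    ox, oy = origin
    ux, uy = direction
    prof = ndimage.map_coordinates(
        frame, [oy + ss * uy, ox + ss * ux], order=1, mode="nearest"
    )
    inside = (prof - mid) * sgn < 0
    if not inside[0] or inside[-1]:
        return None
    k = int(np.argmax(~inside))
    p0, p1 = prof[k - 1], prof[k]
    frac = (mid - p0) / (p1 - p0) if abs(p1 - p0) > 1e-9 else 0.5
    s_cross = float(ss[k - 1] + frac * (ss[k] - ss[k - 1]))
    band = (np.abs(prof - mid) < 0.3 * span) & (np.abs(ss - s_cross) < 3.0)
    if band.sum() >= 4:
        slope, intercept = np.polyfit(ss[band], prof[band], 1)
        if abs(slope) > 1e-9:
            s_fit = (mid - intercept) / slope
            if abs(s_fit - s_cross) < 1.5:
                return s_fit
    return s_cross


def _apex_position(
    frame: np.ndarray,
    origin,
    tangent,
    reach: float = 8.0,
):
    """Sub-pixel tip apex from the grey values of the rounded tip cap.

    Pipeline per frame: (1) an axial profile through the provisional tip
    fixes the polarity, the root/background plateau levels and a first
    apex estimate; (2) a perpendicular profile just behind the apex gives
    the local half-width and re-centres laterally; (3) a soft-edged
    capsule model is fitted to the whole tip patch by least squares and
    the apex read off as the cap-circle point farthest along the growth
    tangent. Returns ``(x, y)`` or None when no edge is found.
    """
    t = np.asarray(tangent, dtype=float)
    if np.hypot(*t) < 1e-9:
        return None
    t = t / np.hypot(*t)
    nvec = np.array([-t[1], t[0]])
    origin = np.asarray(origin, dtype=float)

    # --- axial profile: polarity, plateau levels, first apex estimate
    ss = np.arange(-2 * reach, 2 * reach + 0.25, 0.25)
    prof = ndimage.map_coordinates(
        frame, [origin[1] + ss * t[1], origin[0] + ss * t[0]], order=1, mode="nearest"
    )
    lo, hi = np.percentile(prof, 5), np.percentile(prof, 95)
    span = float(hi - lo)
    if span < 10.0:
        return None
    sgn = 1.0 if prof[-1] > prof[0] else -1.0
    mid = 0.5 * (lo + hi)
    inside = (prof - mid) * sgn < 0
    if not inside[0] or inside[-1]:
        return None
    k = int(np.argmax(~inside))
    s_rough = float(ss[k])
    # plateau means (not percentile extremes, whose noise would shift the
    # crossing on every ray at once) define the final mid level
    in_pl = prof[ss < s_rough - 2.5]
    out_pl = prof[ss > s_rough + 2.5]
    if in_pl.size >= 4 and out_pl.size >= 4:
        mid = 0.5 * (float(in_pl.mean()) + float(out_pl.mean()))
    s_apex0 = _edge_cross(frame, origin, t, s_rough - 4.0, s_rough + 4.0, mid, sgn, span)
    if s_apex0 is None:
        return None
    a0 = origin + s_apex0 * t

    # --- local half-width and lateral re-centring just behind the apex
    back = a0 - 3.5 * t
    s_left = _edge_cross(frame, back, -nvec, 0.0, reach, mid, sgn, span)
    s_right = _edge_cross(frame, back, nvec, 0.0, reach, mid, sgn, span)
    if s_left is None or s_right is None:
        return a0  # no clean cap geometry: axial estimate only
    radius0 = 0.5 * (s_left + s_right)
    if not (1.0 <= radius0 <= 25.0):
        return a0
    centre = back + 0.5 * (s_right - s_left) * nvec + (3.5 - radius0) * t

    # --- 2-D capsule model fit over the whole tip patch.
    # The tip region is modelled as a soft-edged capsule (a segment of the
    # root axis dilated by the radius, logistic edge profile) and fitted to
    # the raw grey values by least squares: every pixel on the cap edge
    # contributes, which is what pushes the localisation toward the
    # information limit instead of a handful of 1-D profiles.
    in_level = float(in_pl.mean()) if in_pl.size else mid - sgn * span / 2.0
    out_level = float(out_pl.mean()) if out_pl.size else mid + sgn * span / 2.0
    refined = _capsule_fit(frame, centre, t, radius0, in_level, out_level)
    if refined is None:
        return a0
    c_fit, radius = refined
    if not (1.0 <= radius <= 30.0) or float(np.hypot(*(c_fit - centre))) > radius0 + 3.0:
        return a0
    return c_fit + radius * t


def _capsule_fit(frame, centre0, t, radius0, in_level, out_level, seg_len=None):
    """Fit a soft-edged capsule to the tip patch; returns (cap centre, R).

    Model: I(p) = out + (in − out)·σ((R − d(p))/w) with d(p) the distance
    from p to the axis segment ending at the cap centre, σ the logistic
    function; free parameters are the cap centre, radius R, edge width w
    and the two grey levels.
    """
    from scipy.optimize import least_squares

    H, W = frame.shape
    half = int(np.ceil(radius0 + 6))
    if seg_len is None:
        # the segment's far end must stay well outside the fitted patch,
        # otherwise the model grows a phantom second cap inside it
        seg_len = 4.0 * half
    cx0, cy0 = float(centre0[0]), float(centre0[1])
    r0 = int(round(cy0))
    c0 = int(round(cx0))
    rows = slice(max(0, r0 - half), min(H, r0 + half + 1))
    cols = slice(max(0, c0 - half), min(W, c0 + half + 1))
    patch = frame[rows, cols]
    yy, xx = np.mgrid[rows, cols].astype(float)
    def seg_distance(cx, cy):
        ax, ay = cx - seg_len * t[0], cy - seg_len * t[1]
        vx, vy = cx - ax, cy - ay
        L2 = vx * vx + vy * vy
        tau = np.clip(((xx - ax) * vx + (yy - ay) * vy) / L2, 0.0, 1.0)
        return np.hypot(xx - (ax + tau * vx), yy - (ay + tau * vy))

    # only pixels near the capsule surface: the flat plateaus far from the
    # edge carry no position information
    d0 = seg_distance(cx0, cy0)
    keep = np.abs(d0 - radius0) < 4.0
    if keep.sum() < 30:
        return None
    obs = patch[keep]

    def residuals(p):
        cx, cy, R, w, lin, lout = p
        d = seg_distance(cx, cy)[keep]
        model = lout + (lin - lout) / (1.0 + np.exp((d - R) / max(w, 0.2)))
        return model - obs

    x0 = np.array([cx0, cy0, radius0, 1.2, in_level, out_level])
    try:
        sol = least_squares(residuals, x0, method="lm", max_nfev=80)
    except Exception:
        return None
    cx, cy, R = sol.x[0], sol.x[1], abs(sol.x[2])
    if not np.all(np.isfinite(sol.x)):
        return None
    return np.array([cx, cy]), float(R)


# ---------------------------------------------------------------------------
# anchor registration
# ---------------------------------------------------------------------------

@dataclass
class AnchorTrack:
    positions: np.ndarray  # (T, 2) xy
    drift_px: float
    fixed: bool

    @property
    def mean_position(self):
        return self.positions.mean(axis=0)


def register_anchor(
    stack: ImageStack, anchor0: Tuple[float, float], patch_half: int = 16
) -> AnchorTrack:
    """Track the anchor patch by sub-pixel cross-correlation against frame 0.

    Verifies the fixed-frame assumption for the mature root region: if the
    maximum drift stays below 2 px the anchor is treated as fixed (mean
    position); larger drift is reported so downstream velocities can be
    corrected by subtracting the anchor motion.
    """
    x0, y0 = anchor0
    H, W = stack.shape
    r0, c0 = int(round(y0)), int(round(x0))
    if not (patch_half <= r0 < H - patch_half and patch_half <= c0 < W - patch_half):
        raise ValidationError("anchor patch extends beyond the frame")
    ref = stack.frames[0, r0 - patch_half : r0 + patch_half, c0 - patch_half : c0 + patch_half]
    if ref.std() < 1e-3:
        raise RegistrationError("anchor patch is textureless; correlation impossible")
    shifts = np.zeros((stack.n_frames, 2))
    for k in range(1, stack.n_frames):
        cur = stack.frames[k, r0 - patch_half : r0 + patch_half, c0 - patch_half : c0 + patch_half]
        shift, _, _ = phase_cross_correlation(ref, cur, upsample_factor=20)
        shifts[k] = -shift[::-1]  # (dy, dx) of cur w.r.t. ref → anchor (dx, dy)
    # real rig drift is slow; smoothing keeps correlation noise out of the
    # drift verdict (and out of any downstream correction)
    if stack.n_frames >= 9:
        shifts = np.column_stack(
            [savgol_filter(shifts[:, d], 9, 2, mode="interp") for d in range(2)]
        )
    positions = np.array([x0, y0]) + shifts
    drift = float(np.max(np.hypot(shifts[:, 0], shifts[:, 1])))
    fixed = drift < ANCHOR_DRIFT_TOL_PX
    if not fixed:
        log.warning("anchor drift %.2f px exceeds %.1f px; correcting velocities", drift, ANCHOR_DRIFT_TOL_PX)
    return AnchorTrack(positions=positions, drift_px=drift, fixed=fixed)


def auto_anchor(stack: ImageStack) -> Tuple[float, float]:
    """Pick the mature-end anchor automatically: the skeleton endpoint of
    frame 0 that stays (nearly) static through the stack."""
    m0 = segment_root(stack.frames[0])
    mN = segment_root(stack.frames[-1])
    s0, sN = skeletonize(m0), skeletonize(mN)
    ends0 = _skeleton_endpoints(s0)
    endsN = _skeleton_endpoints(sN)
    if not ends0 or not endsN:
        raise SegmentationError("cannot find skeleton endpoints for auto-anchor")
    pN = np.array(endsN, dtype=float)
    best, best_d = None, np.inf
    for r, c in ends0:
        d = np.min(np.hypot(pN[:, 0] - r, pN[:, 1] - c))
        if d < best_d:
            best_d, best = d, (float(c), float(r))
    return best


# ---------------------------------------------------------------------------
# velocity series
# ---------------------------------------------------------------------------

@dataclass
class TipTrack:
    """Per-frame tip coordinates relative to the registered anchor."""

    positions: np.ndarray  # (T, 2) xy px, anchor-motion corrected
    anchor: Tuple[float, float]
    valid: np.ndarray  # (T,) bool
    anchor_drift_px: float = 0.0


@dataclass
class RootVelocityWindow:
    window_start: float  # s
    window_end: float  # s
    velocity_mm_h: float  # along-path
    straight_velocity_mm_h: float
    path_mm: float
    n_valid_frames: int
    window_minutes: float

    @property
    def centre_time(self) -> float:
        return 0.5 * (self.window_start + self.window_end)


@dataclass
class RootVelocityResult:
    windows: List[RootVelocityWindow]
    track: TipTrack
    segmentable_fraction: float

    def __iter__(self):
        return iter(self.windows)

    def __len__(self):
        return len(self.windows)

    def to_frame(self, start_clock_time: float = 0.0) -> pd.DataFrame:
        def clk(t_s):
            return (start_clock_time + t_s / 3600.0) % 24.0

        return pd.DataFrame(
            {
                "window_start_s": [w.window_start for w in self.windows],
                "window_end_s": [w.window_end for w in self.windows],
                "window_start_clock": [clk(w.window_start) for w in self.windows],
                "window_end_clock": [clk(w.window_end) for w in self.windows],
                "velocity_mm_h": [w.velocity_mm_h for w in self.windows],
                "straight_velocity_mm_h": [w.straight_velocity_mm_h for w in self.windows],
                "path_mm": [w.path_mm for w in self.windows],
                "n_valid_frames": [w.n_valid_frames for w in self.windows],
            }
        )


def tip_velocity_series(
    stack: ImageStack,
    anchor0: Optional[Tuple[float, float]] = None,
    pixel_size: Optional[float] = None,
    window_minutes: float = 5.0,
    smooth_window: int = 13,
    outlier_factor: float = 5.0,
) -> RootVelocityResult:
    """Root tip velocity on tiled windows (default 5 min), in mm h⁻¹.

    Per frame: segment → skeletonise → tip = geodesic-farthest endpoint from
    the anchor, refined to sub-pixel from the grey-value edge profile along
    the tip tangent. Tips are anchor-motion corrected, lightly smoothed
    (Savitzky–Golay), and frame-to-frame steps are projected on the local
    growth direction; steps beyond ``outlier_factor`` × the window median
    are replaced by the window median. Velocity is the along-path
    displacement per window over its duration; unsegmentable frames leave
    gaps and are interpolated over if they stay under 10% of the stack.
    """
    pixel_size = pixel_size or stack.pixel_size
    T = stack.n_frames
    dt = stack.interval_s
    if anchor0 is None:
        anchor0 = auto_anchor(stack)

    # provisional integer tips + tangents from the skeleton
    prov = np.full((T, 2), np.nan)
    tangents = np.zeros((T, 2))
    valid = np.zeros(T, dtype=bool)
    for k in range(T):
        try:
            mask = segment_root(stack.frames[k])
            tip = locate_tip(mask, anchor0)
            prov[k] = tip
            skel = _prune_spurs(skeletonize(mask), 10.0)
            tangents[k] = _tangent_at_tip(skel, (int(round(tip[1])), int(round(tip[0]))))
            valid[k] = True
        except (SegmentationError, AmbiguityError) as exc:
            log.warning("frame %d: tip lost (%s)", k, exc)
    frac = float(valid.mean())
    if frac < 0.5:
        raise QualityError(f"root segmentable in only {frac:.0%} of frames", n_valid=int(valid.sum()))
    if frac < 0.9:
        log.warning("root segmentable in only %.0f%% of frames; series has gaps", 100 * frac)
    idx = np.arange(T)
    for d in range(2):
        prov[:, d] = np.interp(idx, idx[valid], prov[valid, d])
        tangents[:, d] = np.interp(idx, idx[valid], tangents[valid, d])
    if T >= 15:
        prov_s = np.column_stack([savgol_filter(prov[:, d], 15, 2, mode="interp") for d in range(2)])
    else:
        prov_s = prov.copy()
    # the outward tangent at the tip rotates slowly (curvature × tip speed),
    # so a long temporal average removes skeleton-quantisation jitter
    # without biasing the direction
    tangents = np.column_stack(
        [ndimage.uniform_filter1d(tangents[:, d], size=min(31, T), mode="nearest") for d in range(2)]
    )
    norms = np.hypot(tangents[:, 0], tangents[:, 1])
    tangents[norms > 1e-9] /= norms[norms > 1e-9, None]

    # sub-pixel apex from the grey-value edge profile along the tangent;
    # a light blur suppresses sensor noise without biasing the symmetric
    # edge-crossing position
    denoised = ndimage.gaussian_filter(stack.frames, (0.0, 1.0, 1.0))

    def apex_pass(origins):
        out = origins.copy()
        ok = np.zeros(T, dtype=bool)
        for k in range(T):
            apex = _apex_position(denoised[k], origins[k], tangents[k])
            if apex is not None:
                out[k] = apex
                ok[k] = True
        if ok.any() and not ok.all():
            for d in range(2):
                out[:, d] = np.interp(idx, idx[ok], out[ok, d])
        return out, ok

    # two passes: the first tolerates the skeleton track's pixel jitter,
    # the second re-centres the rays on a smoothed version of the first
    tips1, _ = apex_pass(prov_s)
    if T >= 11:
        origins2 = np.column_stack(
            [savgol_filter(tips1[:, d], 11, 2, mode="interp") for d in range(2)]
        )
    else:
        origins2 = tips1
    tips, apex_ok = apex_pass(origins2)

    # anchor registration / motion correction
    anchor_track = register_anchor(stack, anchor0)
    drift = anchor_track.drift_px
    if not anchor_track.fixed:
        tips = tips - (anchor_track.positions - anchor_track.positions[0])
    # light smoothing before differencing: tames residual apex noise at the
    # window boundaries at the cost of ~half a window of latency. The series
    # ends are re-estimated from a longer linear fit: polynomial endpoint
    # extrapolation amplifies noise exactly where the first/last windows
    # take their boundary values
    if T >= smooth_window:
        tips_s = np.column_stack(
            [savgol_filter(tips[:, d], smooth_window, 2, mode="interp") for d in range(2)]
        )
        if T >= 15:
            k_fit, k_rep = 15, 4
            for d in range(2):
                for sl, xs in (
                    (slice(0, k_rep), np.arange(k_fit)),
                    (slice(T - k_rep, T), np.arange(T - k_fit, T)),
                ):
                    coef = np.polyfit(xs, tips[xs, d], 1)
                    tips_s[sl, d] = np.polyval(coef, np.arange(T)[sl])
    else:
        tips_s = tips
    steps = np.diff(tips_s, axis=0)

    fpw = max(1, int(round(window_minutes * 60.0 / dt)))
    windows: List[RootVelocityWindow] = []
    w0 = 0
    while w0 + fpw <= T - 1:
        w1 = w0 + fpw
        t0, t1 = stack.timestamps[w0], stack.timestamps[w1]
        dt_h = (t1 - t0) / 3600.0
        net = tips_s[w1] - tips_s[w0]
        straight_px = float(np.hypot(*net))
        if straight_px > 0.5:
            # signed projection on the window's growth direction; the noise
            # perpendicular to growth then cancels instead of rectifying
            that = net / straight_px
        else:
            # displacement below the noise floor: project on the skeleton
            # tangent so pure noise keeps a zero-mean signed value instead
            # of a rectified magnitude
            tmean = tangents[w0 : w1 + 1].mean(axis=0)
            tnorm = float(np.hypot(*tmean))
            that = tmean / tnorm if tnorm > 1e-9 else np.array([0.0, 1.0])
        proj = steps[w0:w1] @ that
        med = np.median(np.abs(proj))
        if med > 0:
            outl = np.abs(proj) > outlier_factor * med
            proj[outl] = np.sign(proj[outl]) * med
        path_px = float(np.sum(proj))
        windows.append(
            RootVelocityWindow(
                window_start=float(t0),
                window_end=float(t1),
                velocity_mm_h=path_px * pixel_size / dt_h,
                straight_velocity_mm_h=straight_px * pixel_size / dt_h,
                path_mm=path_px * pixel_size,
                n_valid_frames=int(valid[w0 : w1 + 1].sum()),
                window_minutes=window_minutes,
            )
        )
        w0 += fpw
    track = TipTrack(positions=tips, anchor=anchor0, valid=valid, anchor_drift_px=drift)
    return RootVelocityResult(windows=windows, track=track, segmentable_fraction=frac)


def tip_track_to_frame(result: RootVelocityResult, stack: ImageStack) -> pd.DataFrame:
    """Per-frame tip track table (frame, t_s, x_px, y_px, valid)."""
    t = result.track
    return pd.DataFrame(
        {
            "frame": np.arange(stack.n_frames),
            "t_s": stack.timestamps,
            "x_px": t.positions[:, 0],
            "y_px": t.positions[:, 1],
            "valid": t.valid,
        }
    )
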