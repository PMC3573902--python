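"""Synthetic leaf and root time-lapse scenes with exact ground truth.

Frames are always derived from continuous ground truth — a fixed master
speckle texture warped by an analytic material map for leaves, an
analytically-sampled curve for roots — never by iterated resampling, so
parameter-recovery tests compare against truth that is exact by
construction and free of cumulative blur.

Leaf scenes: textured tissue under isotropic areal expansion with a
prescribed relative growth rate profile r(t) (h⁻¹). Frame ``k`` samples the
master texture at the pulled-back coordinates of the material map

    x  →  c + exp(S(t_k)/2) · (x − c),      S(t) = ∫₀ᵗ r(τ) dτ,

so the true area of any tracked polygon is A₀·exp(S(t)) exactly, and the
true inter-frame displacement field is ``(exp(ΔS/2) − 1)·(x − c)``.

Root scenes: a thick smooth curve grown from a fixed base; between frames
the tip advances along the path tangent by ``v(t)·Δt / pixel_size`` px while
the mature region stays pixel-identical. Grey values encode the tip
position with sub-pixel precision through the soft edge profile.

Treatment presets reproduce the study's root-zone conditions as generator
settings: control ≈ 0.6 mm h⁻¹ with a small light-on dip, root cooling ≈
0.3 mm h⁻¹ constant, root illumination ≈ 0.4 mm h⁻¹ with a slow-recovering
morning trough and a brief post-dusk dip; the leaf profile (nocturnal ≈ 3×
diurnal with a transient light-on dip and day-by-day decline) is identical
across presets, mirroring the finding that leaf growth was insensitive to
the root-zone treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .stack_io import ImageStack, write_stack

__all__ = [
    "LeafSceneConfig",
    "RootSceneConfig",
    "GroundTruth",
    "make_leaf_stack",
    "make_root_stack",
    "make_translating_stack",
    "diel_rgr_profile",
    "treatment_presets",
    "export_truth",
    "PRESET_NAMES",
]

Profile = Union[float, Callable[[np.ndarray], np.ndarray]]

LIGHT_ON = 8.0   # study schedule: 12 h photoperiod
LIGHT_OFF = 20.0


def _as_profile(p: Profile) -> Callable[[np.ndarray], np.ndarray]:
    if callable(p):
        return p
    val = float(p)
    return lambda t: np.full_like(np.asarray(t, dtype=float), val)


# ---------------------------------------------------------------------------
# configs and truth container
# ---------------------------------------------------------------------------

@dataclass
class LeafSceneConfig:
    """Parameters of a rendered expanding-leaf scene.

    ``rgr_profile`` maps elapsed time (hours since frame 0) to areal RGR in
    h⁻¹; pass a float for a constant rate. ``texture_scale`` is the speckle
    feature size in px and ``contrast`` its grey-value standard deviation —
    high enough by default that the leaf interior passes flow confidence.
    """

    image_size: tuple = (192, 192)
    texture_scale: float = 2.5
    contrast: float = 35.0
    mean_grey: float = 120.0
    centroid: Optional[tuple] = None  # (x, y) px; default image centre
    rgr_profile: Profile = 0.02
    noise_sigma: float = 1.5
    interval_s: float = 90.0
    duration_h: float = 2.0
    start_clock_time: float = 8.0
    pixel_size: float = 0.02  # mm/px (plausible default; not from the study)
    aoi_radius_frac: float = 0.32
    seed: int = 0


@dataclass
class RootSceneConfig:
    """Parameters of a rendered elongating-root scene.

    ``velocity_profile`` maps elapsed hours to tip velocity in mm h⁻¹ (≥ 0);
    ``curvature`` bends the growth path (rad/px of arclength); ``polarity``
    selects a dark root on a bright background or the inverse.
    """

    image_size: tuple = (320, 240)
    root_width: float = 9.0
    curvature: float = 0.0015
    base_point: Optional[tuple] = None  # (x, y); default top centre
    initial_angle_deg: float = 90.0  # downward
    initial_length_px: float = 80.0
    velocity_profile: Profile = 0.6
    pixel_size: float = 0.01  # mm/px (plausible default; not from the study)
    polarity: str = "dark-on-bright"
    background_grey: float = 200.0
    depth_grey: float = 150.0
    edge_softness_px: float = 0.8
    noise_sigma: float = 2.0
    interval_s: float = 30.0
    duration_h: float = 1.0
    start_clock_time: float = 8.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-frame truth the renderer derived its frames from."""

    kind: str  # 'leaf' | 'root'
    times_s: np.ndarray
    clock_times: np.ndarray
    # leaf truth
    rgr_h: Optional[np.ndarray] = None
    cumulative_log_area: Optional[np.ndarray] = None  # S(t_k)
    centroid: Optional[tuple] = None
    aoi_polygons: Optional[list] = None  # list of (N, 2) xy vertex arrays
    # root truth
    velocity_mm_h: Optional[np.ndarray] = None
    tip_positions: Optional[np.ndarray] = None  # (T, 2) xy px
    arclength_px: Optional[np.ndarray] = None
    anchor: Optional[tuple] = None
    pixel_size: float = 1.0

    def displacement_field(self, k: int, shape) -> tuple:
        """Analytic (du, dv) px field from frame ``k`` to ``k+1`` (leaf)."""
        if self.kind != "leaf":
            raise ValidationError("analytic displacement fields exist for leaf scenes only")
        dS = self.cumulative_log_area[k + 1] - self.cumulative_log_area[k]
        f = np.exp(dS / 2.0) - 1.0
        H, W = shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        cx, cy = self.centroid
        return f * (xx - cx), f * (yy - cy)

    def window_mean_velocity(self, t0_s: float, t1_s: float) -> float:
        """True mean tip velocity (mm h⁻¹) over [t0, t1] from arclength."""
        s = np.interp([t0_s, t1_s], self.times_s, self.arclength_px)
        return float((s[1] - s[0]) * self.pixel_size / ((t1_s - t0_s) / 3600.0))

    def window_mean_rgr(self, t0_s: float, t1_s: float) -> float:
        """True mean RGR (h⁻¹) over [t0, t1] from the log-area integral."""
        S = np.interp([t0_s, t1_s], self.times_s, self.cumulative_log_area)
        return float((S[1] - S[0]) / ((t1_s - t0_s) / 3600.0))


# ---------------------------------------------------------------------------
# master texture
# ---------------------------------------------------------------------------

def _speckle_texture(shape, scale, contrast, mean, rng, supersample=2, pad=32):
    """Band-limited random speckle on a padded, supersampled canvas."""
    H, W = shape
    h = (H + 2 * pad) * supersample
    w = (W + 2 * pad) * supersample
    noise = rng.standard_normal((h, w))
    tex = ndimage.gaussian_filter(noise, scale * supersample, mode="wrap")
    tex = (tex - tex.mean()) / (tex.std() + 1e-12)
    return mean + contrast * tex


def _sample_texture(tex, xs, ys, pad, supersample):
    """Evaluate the master texture at image coordinates (cubic spline)."""
    rows = (ys + pad) * supersample
    cols = (xs + pad) * supersample
    return ndimage.map_coordinates(tex, [rows, cols], order=3, mode="reflect")


# ---------------------------------------------------------------------------
# leaf scene
# ---------------------------------------------------------------------------

def make_leaf_stack(config: LeafSceneConfig):
    """Render an expanding-leaf stack; returns ``(ImageStack, GroundTruth)``."""
    H, W = config.image_size
    n = int(round(config.duration_h * 3600.0 / config.interval_s)) + 1
    if n < 2:
        raise ValidationError("duration too short: need at least 2 frames")
    times_s = np.arange(n) * config.interval_s
    times_h = times_s / 3600.0
    clock = (config.start_clock_time + times_h) % 24.0

    r = np.asarray(_as_profile(config.rgr_profile)(times_h), dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValidationError("rgr_profile produced non-finite values")
    # S(t) by trapezoid; exact for piecewise-linear profiles
    S = np.concatenate([[0.0], np.cumsum(0.5 * (r[1:] + r[:-1]) * np.diff(times_h))])

    cx, cy = config.centroid if config.centroid is not None else ((W - 1) / 2.0, (H - 1) / 2.0)
    pad = 32
    max_scale = float(np.exp(S.max() / 2.0))
    radius = config.aoi_radius_frac * min(H, W)
    if max_scale * radius > min(cx, cy, W - 1 - cx, H - 1 - cy):
        k_bad = int(np.argmax(np.exp(S / 2.0) * radius > min(cx, cy, W - 1 - cx, H - 1 - cy)))
        raise ValidationError(f"leaf grows out of frame at frame {k_bad}; shorten or shrink")

    rng = np.random.default_rng(config.seed)
    ss = 2
    tex = _speckle_texture((H, W), config.texture_scale, config.contrast, config.mean_grey, rng, ss, pad)

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    frames = np.empty((n, H, W))
    for k in range(n):
        shrink = np.exp(-S[k] / 2.0)  # pull-back of the material map
        xs = cx + shrink * (xx - cx)
        ys = cy + shrink * (yy - cy)
        frames[k] = _sample_texture(tex, xs, ys, pad, ss)
    frames += rng.normal(0.0, config.noise_sigma, frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    # true AOI: regular polygon around the centroid, advected analytically
    m = 24
    ang = 2 * np.pi * np.arange(m) / m
    base = np.stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)], axis=1)
    polys = [
        np.stack([cx + np.exp(S[k] / 2.0) * (base[:, 0] - cx),
                  cy + np.exp(S[k] / 2.0) * (base[:, 1] - cy)], axis=1)
        for k in range(n)
    ]

    stack = ImageStack(
        frames=frames,
        timestamps=times_s,
        pixel_size=config.pixel_size,
        role="leaf",
        start_clock_time=config.start_clock_time,
        source_dtype=np.uint8,
    )
    truth = GroundTruth(
        kind="leaf",
        times_s=times_s,
        clock_times=clock,
        rgr_h=r,
        cumulative_log_area=S,
        centroid=(cx, cy),
        aoi_polygons=polys,
        pixel_size=config.pixel_size,
    )
    return stack, truth


def make_translating_stack(
    shift_per_frame=(1.0, 0.0),
    n_frames=20,
    image_size=(256, 256),
    texture_scale=2.5,
    contrast=35.0,
    mean_grey=120.0,
    noise_sigma=0.0,
    interval_s=90.0,
    pixel_size=0.02,
    seed=0,
):
    """Textured scene translating rigidly at a known (dx, dy) px/frame.

    A pure-translation benchmark for the flow solver: every frame samples
    the same master texture at analytically shifted coordinates.
    """
    H, W = image_size
    dx, dy = shift_per_frame
    pad = 32 + int(np.ceil(max(abs(dx), abs(dy)) * n_frames))
    rng = np.random.default_rng(seed)
    ss = 2
    tex = _speckle_texture((H, W), texture_scale, contrast, mean_grey, rng, ss, pad)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    frames = np.empty((n_frames, H, W))
    for k in range(n_frames):
        # content moves by +k·d: frame k samples the texture at x − k·d
        frames[k] = _sample_texture(tex, xx - k * dx, yy - k * dy, pad, ss)
    if noise_sigma > 0:
        frames += rng.normal(0.0, noise_sigma, frames.shape)
    np.clip(frames, 0.0, None, out=frames)
    return ImageStack(
        frames=frames,
        timestamps=np.arange(n_frames) * interval_s,
        pixel_size=pixel_size,
        role="leaf",
        source_dtype=np.uint8,
    )


# ---------------------------------------------------------------------------
# root scene
# ---------------------------------------------------------------------------

def _root_path(config: RootSceneConfig, max_len_px: float):
    """Dense arclength-parameterised growth path (step 0.2 px)."""
    ds = 0.2
    n = int(np.ceil(max_len_px / ds)) + 2
    s = np.arange(n) * ds
    phi = np.deg2rad(config.initial_angle_deg) + config.curvature * s
    H, W = config.image_size
    bx, by = config.base_point if config.base_point is not None else ((W - 1) / 2.0, 20.0)
    x = bx + np.concatenate([[0.0], np.cumsum(np.cos(phi[:-1]) * ds)])
    y = by + np.concatenate([[0.0], np.cumsum(np.sin(phi[:-1]) * ds)])
    return s, np.stack([x, y], axis=1)


def make_root_stack(config: RootSceneConfig):
    """Render an elongating-root stack; returns ``(ImageStack, GroundTruth)``."""
    if config.polarity not in ("dark-on-bright", "bright-on-dark"):
        raise ValidationError(f"unknown polarity {config.polarity!r}")
    H, W = config.image_size
    n = int(round(config.duration_h * 3600.0 / config.interval_s)) + 1
    if n < 2:
        raise ValidationError("duration too short: need at least 2 frames")
    times_s = np.arange(n) * config.interval_s
    times_h = times_s / 3600.0
    clock = (config.start_clock_time + times_h) % 24.0

    v = np.asarray(_as_profile(config.velocity_profile)(times_h), dtype=float)
    if np.any(v < 0):
        raise ValidationError("velocity_profile must be >= 0")
    # arclength in px: L(t) = L0 + ∫ v/pixel_size dτ (trapezoid)
    L = config.initial_length_px + np.concatenate(
        [[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(times_h))]
    ) / config.pixel_size

    s_dense, path = _root_path(config, L[-1] + 2.0)
    tips = np.stack(
        [np.interp(L, s_dense, path[:, 0]), np.interp(L, s_dense, path[:, 1])], axis=1
    )
    margin = config.root_width / 2.0 + 2.0
    out = (tips[:, 0] < margin) | (tips[:, 0] > W - 1 - margin) | \
          (tips[:, 1] < margin) | (tips[:, 1] > H - 1 - margin)
    if out.any():
        raise ValidationError(f"root tip leaves the frame at frame {int(np.argmax(out))}")

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    half_w = config.root_width / 2.0
    soft = config.edge_softness_px

    frames = np.empty((n, H, W))
    for k in range(n):
        m = int(np.searchsorted(s_dense, L[k]))
        seg = np.vstack([path[:m], tips[k]])  # exact sub-pixel tip endpoint
        d = cKDTree(seg).query(pts, workers=-1)[0].reshape(H, W)
        body = 1.0 / (1.0 + np.exp((d - half_w) / soft))
        if config.polarity == "dark-on-bright":
            frames[k] = config.background_grey - config.depth_grey * body
        else:
            frames[k] = (config.background_grey - config.depth_grey) + config.depth_grey * body
    rng = np.random.default_rng(config.seed)
    frames += rng.normal(0.0, config.noise_sigma, frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    stack = ImageStack(
        frames=frames,
        timestamps=times_s,
        pixel_size=config.pixel_size,
        role="root",
        start_clock_time=config.start_clock_time,
        source_dtype=np.uint8,
    )
    truth = GroundTruth(
        kind="root",
        times_s=times_s,
        clock_times=clock,
        velocity_mm_h=v,
        tip_positions=tips,
        arclength_px=L,
        anchor=tuple(path[0]),
        pixel_size=config.pixel_size,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# diel profiles and treatment presets
# ---------------------------------------------------------------------------

def _raised_cosine_dip(t_h, t_event_h, depth, duration_h):
    """Smooth transient dip of given depth centred after an event time."""
    t = np.asarray(t_h, dtype=float)
    x = (t - t_event_h) / duration_h
    dip = np.where((x >= 0) & (x <= 1), 0.5 * (1 - np.cos(2 * np.pi * x)), 0.0)
    return depth * dip


def diel_rgr_profile(
    nocturnal=0.036,
    diurnal=0.012,
    light_on=LIGHT_ON,
    light_off=LIGHT_OFF,
    dip_depth_pct=150.0,
    dip_duration_min=20.0,
    decline_per_day=0.85,
    start_clock_time=8.0,
):
    """Leaf RGR profile: high nocturnal, low diurnal plateau, a sharp
    transient dip at light-on (the rate can briefly go negative, as leaves
    transiently shrink when the light comes on) and a day-by-day decline.

    Returns a callable of elapsed hours since stack start.
    """

    def profile(t_h):
        t = np.asarray(t_h, dtype=float)
        clock = (start_clock_time + t) % 24.0
        is_day = _in_period(clock, light_on, light_off)
        day_idx = np.floor((start_clock_time + t - light_on) / 24.0)
        day_idx = day_idx - day_idx.min()
        decay = decline_per_day ** day_idx
        base = np.where(is_day, diurnal, nocturnal) * decay
        # light-on transient: subtract a dip proportional to nocturnal level
        t_on = ((light_on - start_clock_time) % 24.0)
        dips = np.zeros_like(t)
        for cycle in range(int(np.ceil((t.max() + 24) / 24.0)) + 1):
            dips += _raised_cosine_dip(
                t, t_on + 24.0 * cycle, dip_depth_pct / 100.0 * nocturnal, dip_duration_min / 60.0
            )
        return base - dips * decay

    return profile


def _in_period(clock, lo, hi):
    clock = np.asarray(clock, dtype=float)
    if lo < hi:
        return (clock >= lo) & (clock < hi)
    return (clock >= lo) | (clock < hi)


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _root_velocity_control(start_clock_time):
    def profile(t_h):
        t = np.asarray(t_h, dtype=float)
        base = np.full_like(t, 0.6)
        t_on = (LIGHT_ON - start_clock_time) % 24.0
        dips = np.zeros_like(t)
        for cycle in range(int(np.ceil((t.max() + 24) / 24.0)) + 1):
            dips += _raised_cosine_dip(t, t_on + 24.0 * cycle, 0.15, 0.5)
        return base - dips

    return profile


def _root_velocity_cooling(start_clock_time):
    return lambda t: np.full_like(np.asarray(t, dtype=float), 0.3)


def _root_velocity_illumination(start_clock_time):
    """Morning trough with gradual afternoon recovery, brief post-dusk dip.

    Numerics shaped so the diel mean is ≈ 0.4 mm h⁻¹ with nocturnal and
    diurnal means within ~10% of each other.
    """

    def profile(t_h):
        t = np.asarray(t_h, dtype=float)
        clock = (start_clock_time + t) % 24.0
        is_day = _in_period(clock, LIGHT_ON, LIGHT_OFF)
        tau_day = (clock - LIGHT_ON) % 24.0  # hours since light-on
        day_v = 0.25 + 0.23 * _smoothstep((tau_day - 1.0) / 8.0)
        night_v = np.full_like(t, 0.43)
        v = np.where(is_day, day_v, night_v)
        # post-dusk dip: 2 h raised cosine, depth 0.15
        t_off = (LIGHT_OFF - start_clock_time) % 24.0
        for cycle in range(int(np.ceil((t.max() + 24) / 24.0)) + 1):
            v = v - _raised_cosine_dip(t, t_off + 24.0 * cycle, 0.15, 2.0)
        return np.clip(v, 0.0, None)

    return profile


_ROOT_PROFILES = {
    "control": _root_velocity_control,
    "cooling": _root_velocity_cooling,
    "illumination": _root_velocity_illumination,
}
PRESET_NAMES = tuple(_ROOT_PROFILES)


def treatment_presets(
    name: str,
    duration_h: float = 24.0,
    start_clock_time: float = 8.0,
    seed: int = 0,
    leaf_image_size: tuple = (192, 192),
    root_image_size: Optional[tuple] = None,
):
    """Fully specified ``(LeafSceneConfig, RootSceneConfig)`` for a treatment.

    Root velocity profiles carry the study's treatment means (0.6 control,
    0.3 cooling, 0.4 illumination mm h⁻¹); the leaf profile is the same in
    every preset.
    """
    if name not in _ROOT_PROFILES:
        raise ValidationError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(_ROOT_PROFILES))}"
        )
    if root_image_size is None:
        # canvas tall enough for the initial root plus worst-case elongation
        height = int(80 + duration_h * 0.65 / 0.01 + 60)
        root_image_size = (max(220, height), 240)
    leaf = LeafSceneConfig(
        image_size=leaf_image_size,
        rgr_profile=diel_rgr_profile(start_clock_time=start_clock_time),
        duration_h=duration_h,
        start_clock_time=start_clock_time,
        seed=seed,
    )
    root = RootSceneConfig(
        image_size=root_image_size,
        velocity_profile=_ROOT_PROFILES[name](start_clock_time),
        duration_h=duration_h,
        start_clock_time=start_clock_time,
        seed=seed + 1,
    )
    return leaf, root


# ---------------------------------------------------------------------------
# truth export
# ---------------------------------------------------------------------------

def export_truth(truth: GroundTruth, out_dir) -> list:
    """Write per-frame ground truth as CSV (+ polygon text for leaf scenes).

    Column names and units match the analysis outputs (``rgr_h``,
    ``velocity_mm_h``, clock hours) so truth and estimate diff directly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    cols = {
        "frame": np.arange(truth.times_s.size),
        "t_s": truth.times_s,
        "clock_h": truth.clock_times,
    }
    if truth.kind == "leaf":
        cols["rgr_h"] = truth.rgr_h
        cols["cumulative_log_area"] = truth.cumulative_log_area
        path = out_dir / "truth_leaf.csv"
    else:
        cols["velocity_mm_h"] = truth.velocity_mm_h
        cols["tip_x_px"] = truth.tip_positions[:, 0]
        cols["tip_y_px"] = truth.tip_positions[:, 1]
        cols["arclength_px"] = truth.arclength_px
        path = out_dir / "truth_root.csv"
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    written.append(path)
    if truth.kind == "leaf" and truth.aoi_polygons is not None:
        ppath = out_dir / "truth_aoi_polygons.txt"
        with open(ppath, "w") as fh:
            for k, poly in enumerate(truth.aoi_polygons):
                verts = "; ".join(f"{x:.6f},{y:.6f}" for x, y in poly)
                fh.write(f"{k}: {verts}\n")
        written.append(ppath)
    return written


def simulate_to_dir(leaf_cfg: LeafSceneConfig, root_cfg: RootSceneConfig, out_dir) -> dict:
    """Render both scenes of a preset and write stacks + truth to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    leaf_stack, leaf_truth = make_leaf_stack(leaf_cfg)
    root_stack, root_truth = make_root_stack(root_cfg)
    manifest = {
        "leaf_stack": str(write_stack(leaf_stack, out_dir / "leaf.tif")),
        "root_stack": str(write_stack(root_stack, out_dir / "root.tif")),
    }
    manifest["truth"] = [str(p) for p in export_truth(leaf_truth, out_dir) + export_truth(root_truth, out_dir)]
    return manifest
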