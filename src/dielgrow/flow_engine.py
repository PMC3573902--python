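"""Dense 2-D velocity estimation by the spatiotemporal structure tensor.

The brightness-constancy constraint ``g_x·u + g_y·v + g_t = 0`` is solved in
the total-least-squares sense: per pixel, the 3×3 structure tensor
``J = ⟨∇g ∇gᵀ⟩`` (Gaussian-averaged over a local spatiotemporal window) is
eigendecomposed and the eigenvector ``e = (e_x, e_y, e_t)`` of the smallest
eigenvalue — the spatiotemporal direction of least intensity change, i.e.
the direction of motion ``∝ (u, v, 1)`` — yields

    u = e_x·e_t / (e_t² + ε),   v = e_y·e_t / (e_t² + ε)

for unit-normalised ``e``. Pixels where the two smallest eigenvalues are not
separated (the aperture problem: image structure varies in only one spatial
direction) or where ``e_t ≈ 0`` with a nonzero spatial part are marked
invalid rather than assigned the normal flow, which would bias divergence
estimates. A coarse-to-fine pyramid with inter-frame warping recovers
displacements beyond the ~1 px/frame linearisation range.

All velocities are px/frame at full resolution; the caller converts to
physical units via the stack's pixel calibration and cadence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ValidationError, WindowError
from .stack_io import ImageStack

__all__ = [
    "StructureTensorParams",
    "VelocityField",
    "DisplacementField",
    "spatiotemporal_gradients",
    "build_structure_tensor",
    "flow_confidence",
    "estimate_flow_field",
    "displacement_between",
    "write_velocity_field",
    "read_velocity_field",
]

EPS = 1e-12


@dataclass(frozen=True)
class StructureTensorParams:
    """Scales and gates of the structure-tensor solver.

    ``grad_sigma``/``grad_sigma_t`` set the Gaussian-derivative scale in
    pixels/frames; ``window_sigma``/``window_sigma_t`` the tensor-averaging
    window. The defaults were chosen on synthetic speckle fixtures; the
    physical study they serve does not pin them down, so everything is
    exposed here.
    """

    grad_sigma: float = 1.0
    grad_sigma_t: float = 1.0
    window_sigma: float = 4.0
    window_sigma_t: float = 1.5
    temporal_halfwidth: int = 2
    confidence_threshold: float = 0.3
    pyramid_levels: int = 2
    eigen_gap_rel: float = 1e-3  # aperture gate: λ₂−λ₃ < gap·λ₁ → invalid
    eps: float = EPS

    def __post_init__(self):
        if min(self.grad_sigma, self.grad_sigma_t, self.window_sigma, self.window_sigma_t) <= 0:
            raise ValidationError("all structure-tensor scales must be > 0")
        if self.temporal_halfwidth < 1:
            raise ValidationError("temporal_halfwidth must be >= 1")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValidationError("confidence_threshold must be in [0, 1]")
        if self.pyramid_levels < 1:
            raise ValidationError("pyramid_levels must be >= 1")

    @property
    def border_margin(self) -> int:
        """Invalid frame margin (no extrapolation past image borders)."""
        return int(math.ceil(3.0 * self.window_sigma))


@dataclass
class VelocityField:
    """Per-pixel 2-D velocity (px/frame) for one time window.

    ``valid_mask`` combines the confidence gate, the aperture-problem gate
    and the border margin; ``u``/``v`` are NaN outside it.
    """

    u: np.ndarray
    v: np.ndarray
    confidence: np.ndarray
    centre_time: float
    valid_mask: np.ndarray

    @property
    def valid_fraction(self) -> float:
        return float(self.valid_mask.mean())

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class DisplacementField:
    """Integrated displacement (px) between two frames."""

    du: np.ndarray
    dv: np.ndarray
    valid_mask: np.ndarray
    frame_a: int = 0
    frame_b: int = 0


# ---------------------------------------------------------------------------
# gradients and tensor
# ---------------------------------------------------------------------------

def _block_bounds(stack: ImageStack, centre: int, params: StructureTensorParams):
    half = params.temporal_halfwidth
    if centre - half < 0 or centre + half >= stack.n_frames:
        raise WindowError(
            f"centre frame {centre} ± halfwidth {half} exceeds stack bounds "
            f"[0, {stack.n_frames - 1}]; shrink temporal_halfwidth or skip this frame"
        )
    pad = max(2, int(math.ceil(3.0 * params.grad_sigma_t)))
    lo = max(0, centre - half - pad)
    hi = min(stack.n_frames, centre + half + pad + 1)
    return lo, hi


def _block_gradients(block: np.ndarray, params: StructureTensorParams):
    """Gaussian-derivative gradients (g_x, g_y, g_t) over a (T,H,W) block."""
    s = (params.grad_sigma_t, params.grad_sigma, params.grad_sigma)
    gx = ndimage.gaussian_filter(block, s, order=(0, 0, 1), mode="nearest")
    gy = ndimage.gaussian_filter(block, s, order=(0, 1, 0), mode="nearest")
    gt = ndimage.gaussian_filter(block, s, order=(1, 0, 0), mode="nearest")
    return gx, gy, gt


def spatiotemporal_gradients(stack: ImageStack, centre: int, params: StructureTensorParams):
    """∂g/∂x, ∂g/∂y, ∂g/∂t at the centre frame (2-D grids).

    Derivatives are Gaussian at scale ``grad_sigma`` (space) and
    ``grad_sigma_t`` (frames); temporal units are per-frame. Border pixels
    (within the solver margin) carry no guarantee and are flagged invalid
    downstream rather than extrapolated.
    """
    lo, hi = _block_bounds(stack, centre, params)
    gx, gy, gt = _block_gradients(stack.frames[lo:hi], params)
    c = centre - lo
    return gx[c], gy[c], gt[c]


def build_structure_tensor(gx, gy, gt, params: StructureTensorParams) -> np.ndarray:
    """Gaussian-windowed second-moment tensor J, shape ``(H, W, 3, 3)``.

    Accepts 2-D grids (purely spatial averaging) or (T,H,W) blocks with a
    ``centre`` temporal Gaussian weighting; J is symmetric PSD by
    construction (average of outer products).
    """
    gx, gy, gt = (np.asarray(a, dtype=np.float64) for a in (gx, gy, gt))
    if not (gx.shape == gy.shape == gt.shape):
        raise ValidationError(
            f"gradient grids must share dimensions, got {gx.shape}, {gy.shape}, {gt.shape}"
        )
    comps = [gx * gx, gx * gy, gx * gt, gy * gy, gy * gt, gt * gt]
    if gx.ndim == 2:
        sm = [ndimage.gaussian_filter(c, params.window_sigma, mode="nearest") for c in comps]
    elif gx.ndim == 3:
        s = (params.window_sigma_t, params.window_sigma, params.window_sigma)
        centre = gx.shape[0] // 2
        sm = [
            ndimage.gaussian_filter(c, s, mode="nearest")[centre]
            for c in comps
        ]
    else:
        raise ValidationError(f"gradients must be 2-D or 3-D, got ndim={gx.ndim}")
    H, W = sm[0].shape
    J = np.empty((H, W, 3, 3))
    J[..., 0, 0] = sm[0]
    J[..., 0, 1] = J[..., 1, 0] = sm[1]
    J[..., 0, 2] = J[..., 2, 0] = sm[2]
    J[..., 1, 1] = sm[3]
    J[..., 1, 2] = J[..., 2, 1] = sm[4]
    J[..., 2, 2] = sm[5]
    return J


def flow_confidence(tensor: np.ndarray) -> np.ndarray:
    """Coherence ``(λ₂ − λ₃)/(λ₂ + λ₃ + ε)`` with ``λ₁ ≥ λ₂ ≥ λ₃``.

    0 for isotropic/degenerate tensors, → 1 for well-conditioned motion.
    """
    w = np.linalg.eigvalsh(tensor)  # ascending: w0 ≤ w1 ≤ w2
    lam3, lam2 = w[..., 0], w[..., 1]
    conf = (lam2 - lam3) / (lam2 + lam3 + EPS)
    return np.clip(conf, 0.0, 1.0)


# ---------------------------------------------------------------------------
# single-level TLS solve
# ---------------------------------------------------------------------------

def _solve_tensor(J: np.ndarray, params: StructureTensorParams):
    """TLS velocity from the smallest-eigenvalue eigenvector of J."""
    w, V = np.linalg.eigh(J)  # ascending eigenvalues; V[..., :, k]
    e = V[..., :, 0]  # unit eigenvector of the smallest eigenvalue
    ex, ey, et = e[..., 0], e[..., 1], e[..., 2]
    denom = et * et + params.eps
    u = ex * et / denom
    v = ey * et / denom

    lam3, lam2, lam1 = w[..., 0], w[..., 1], w[..., 2]
    conf = np.clip((lam2 - lam3) / (lam2 + lam3 + params.eps), 0.0, 1.0)

    spatial = np.hypot(ex, ey)
    aperture = (lam2 - lam3) < params.eigen_gap_rel * np.maximum(lam1, params.eps)
    degenerate_t = (np.abs(et) < 1e-6) & (spatial > 1e-6)
    no_signal = lam1 <= 1e-10 * max(1.0, float(np.max(lam1)) if lam1.size else 1.0)
    valid = (conf >= params.confidence_threshold) & ~aperture & ~degenerate_t & ~no_signal
    return u, v, conf, valid


def _flow_block(block: np.ndarray, centre: int, params: StructureTensorParams):
    gx, gy, gt = _block_gradients(block, params)
    s = (params.window_sigma_t, params.window_sigma, params.window_sigma)
    comps = [gx * gx, gx * gy, gx * gt, gy * gy, gy * gt, gt * gt]
    sm = [ndimage.gaussian_filter(c, s, mode="nearest")[centre] for c in comps]
    H, W = sm[0].shape
    J = np.empty((H, W, 3, 3))
    J[..., 0, 0] = sm[0]
    J[..., 0, 1] = J[..., 1, 0] = sm[1]
    J[..., 0, 2] = J[..., 2, 0] = sm[2]
    J[..., 1, 1] = sm[3]
    J[..., 1, 2] = J[..., 2, 1] = sm[4]
    J[..., 2, 2] = sm[5]
    return _solve_tensor(J, params)


def _warp_block(block: np.ndarray, centre: int, u: np.ndarray, v: np.ndarray):
    """Pull every frame toward the centre frame along the current flow."""
    T, H, W = block.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    out = np.empty_like(block)
    for j in range(T):
        off = j - centre
        if off == 0:
            out[j] = block[j]
            continue
        coords = np.stack([yy + off * v, xx + off * u])
        out[j] = ndimage.map_coordinates(block[j], coords, order=1, mode="nearest")
    return out


def _downsample(block: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return block
    smoothed = ndimage.gaussian_filter(block, (0, factor * 0.6, factor * 0.6), mode="nearest")
    return smoothed[:, ::factor, ::factor]


def _upsample_to(a: np.ndarray, shape):
    zoom = (shape[0] / a.shape[0], shape[1] / a.shape[1])
    return ndimage.zoom(a, zoom, order=1, mode="nearest")


def _fill_invalid(a: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid entries by the nearest valid value (0 if none)."""
    if valid.all():
        return a
    if not valid.any():
        return np.zeros_like(a)
    _, (iy, ix) = ndimage.distance_transform_edt(~valid, return_indices=True)
    return a[iy, ix]


def estimate_flow_field(
    stack: ImageStack, centre: int, params: StructureTensorParams | None = None
) -> VelocityField:
    """Dense velocity (px/frame) at frame ``centre`` from its temporal window.

    Coarse-to-fine: when ``pyramid_levels > 1`` the block is warped by the
    current estimate before the residual solve, so displacements larger than
    the ~1 px/frame linear range are recovered. A globally constant stack
    yields an all-invalid field and a warning, not an exception.
    """
    params = params or StructureTensorParams()
    lo, hi = _block_bounds(stack, centre, params)
    block = stack.frames[lo:hi]
    c = centre - lo
    H, W = block.shape[1:]

    u_tot = np.zeros((H, W))
    v_tot = np.zeros((H, W))
    conf = np.zeros((H, W))
    valid = np.zeros((H, W), dtype=bool)

    for level in range(params.pyramid_levels - 1, -1, -1):
        factor = 2 ** level
        if factor >= min(H, W) // 8:
            continue  # level too coarse for this image
        warped = _warp_block(block, c, u_tot, v_tot) if (u_tot.any() or v_tot.any()) else block
        small = _downsample(warped, factor)
        du, dv, conf_l, valid_l = _flow_block(small, c, params)
        if factor > 1:
            # coarse levels exist to capture large displacements; for
            # sub-pixel motion they only add warping/resampling error, so
            # engage them solely when they actually detect one
            if valid_l.any():
                p90 = float(np.percentile(np.hypot(du, dv)[valid_l], 90)) * factor
            else:
                p90 = 0.0
            if p90 < 0.3:
                continue
        du = _fill_invalid(du, valid_l)
        dv = _fill_invalid(dv, valid_l)
        u_tot = u_tot + _upsample_to(du, (H, W)) * factor
        v_tot = v_tot + _upsample_to(dv, (H, W)) * factor
        conf = _upsample_to(conf_l, (H, W))
        valid = _upsample_to(valid_l.astype(float), (H, W)) > 0.5

    m = params.border_margin
    if m > 0 and min(H, W) > 2 * m:
        border = np.zeros((H, W), dtype=bool)
        border[m:-m, m:-m] = True
        valid &= border

    u = np.where(valid, u_tot, np.nan)
    v = np.where(valid, v_tot, np.nan)
    if not valid.any():
        warnings.warn(
            "flow field has no valid pixels (textureless or degenerate window)",
            stacklevel=2,
        )
    return VelocityField(
        u=u, v=v, confidence=conf, centre_time=float(stack.timestamps[centre]), valid_mask=valid
    )


# ---------------------------------------------------------------------------
# displacement integration
# ---------------------------------------------------------------------------

def write_velocity_field(field: VelocityField, path) -> Path:
    """Export a velocity field as 32-bit TIFF: pages (u, v, confidence).

    Invalid pixels carry NaN in the u/v planes, matching the in-memory
    representation.
    """
    import tifffile

    path = Path(path)
    data = np.stack([field.u, field.v, field.confidence]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_velocity_field(path) -> VelocityField:
    """Read a field written by :func:`write_velocity_field`."""
    import tifffile

    data = tifffile.imread(path)
    u, v, conf = data[0].astype(float), data[1].astype(float), data[2].astype(float)
    valid = np.isfinite(u) & np.isfinite(v)
    return VelocityField(u=u, v=v, confidence=conf, centre_time=0.0, valid_mask=valid)


def displacement_between(
    stack: ImageStack,
    frame_a: int,
    frame_b: int,
    params: StructureTensorParams | None = None,
    fields: dict | None = None,
) -> DisplacementField:
    """Integrated displacement (px) from ``frame_a`` to ``frame_b``.

    Per-step flow fields are summed along advected positions (forward Euler
    along the flow), so image structures can be followed across multi-minute
    analysis windows. ``fields`` optionally maps frame index → precomputed
    :class:`VelocityField` to avoid re-estimating flow in series analyses.
    Steps with under half their pixels valid are interpolated from the
    nearest valid pixels, with a warning.
    """
    params = params or StructureTensorParams()
    if frame_a >= frame_b:
        raise ValidationError(f"frame_a ({frame_a}) must be < frame_b ({frame_b})")
    if frame_a < 0 or frame_b >= stack.n_frames:
        raise ValidationError("frame indices out of stack bounds")

    H, W = stack.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    px, py = xx.copy(), yy.copy()
    n_ok = np.zeros((H, W))
    half = params.temporal_halfwidth
    last = stack.n_frames - 1 - half

    for k in range(frame_a, frame_b):
        centre = int(np.clip(k, half, last))
        fld = fields.get(centre) if fields is not None else None
        if fld is None:
            fld = estimate_flow_field(stack, centre, params)
            if fields is not None:
                fields[centre] = fld
        if fld.valid_fraction < 0.5:
            warnings.warn(
                f"step {k}: only {fld.valid_fraction:.0%} valid flow pixels; "
                "interpolating from nearest valid neighbours",
                stacklevel=2,
            )
        uf = _fill_invalid(np.nan_to_num(fld.u), fld.valid_mask)
        vf = _fill_invalid(np.nan_to_num(fld.v), fld.valid_mask)
        coords = np.stack([py, px])
        du = ndimage.map_coordinates(uf, coords, order=1, mode="nearest")
        dv = ndimage.map_coordinates(vf, coords, order=1, mode="nearest")
        ok = ndimage.map_coordinates(fld.valid_mask.astype(float), coords, order=0, mode="constant")
        n_ok += ok
        px += du
        py += dv

    n_steps = frame_b - frame_a
    inb = (px >= 0) & (px <= W - 1) & (py >= 0) & (py <= H - 1)
    valid = inb & (n_ok >= 0.5 * n_steps)
    return DisplacementField(du=px - xx, dv=py - yy, valid_mask=valid, frame_a=frame_a, frame_b=frame_b)
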