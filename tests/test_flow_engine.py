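"""Structure-tensor optical flow: gradient, tensor and solver contracts.

The flow oracles are rendered scenes whose motion is known analytically
(the renderer warps a fixed master texture), so median-flow assertions
compare against exact ground truth rather than another flow method.
"""

import numpy as np
import pytest

from dielgrow.errors import ValidationError, WindowError
from dielgrow.flow_engine import (
    StructureTensorParams,
    build_structure_tensor,
    displacement_between,
    estimate_flow_field,
    flow_confidence,
    read_velocity_field,
    spatiotemporal_gradients,
    write_velocity_field,
)
from dielgrow.stack_io import ImageStack
from dielgrow.synthetic_data import make_translating_stack

PARAMS = StructureTensorParams()


def median_flow(field):
    return (
        float(np.nanmedian(field.u[field.valid_mask])),
        float(np.nanmedian(field.v[field.valid_mask])),
    )


class TestGradients:
    def test_constant_sequence_zero_gradients(self):
        stack = ImageStack(np.full((7, 32, 32), 7.0), np.arange(7) * 90.0, 0.02)
        gx, gy, gt = spatiotemporal_gradients(stack, 3, PARAMS)
        assert np.allclose(gx, 0) and np.allclose(gy, 0) and np.allclose(gt, 0)

    def test_static_ramp(self):
        xx = np.tile(np.arange(40, dtype=float), (40, 1))
        stack = ImageStack(np.repeat(xx[None], 7, axis=0), np.arange(7) * 90.0, 0.02)
        gx, gy, gt = spatiotemporal_gradients(stack, 3, PARAMS)
        interior = (slice(8, -8), slice(8, -8))
        # kernel truncation leaves ~1e-4 slack on the analytic derivative
        assert np.allclose(gx[interior], 1.0, atol=1e-3)
        assert np.allclose(gy[interior], 0.0, atol=1e-6)
        assert np.allclose(gt[interior], 0.0, atol=1e-6)

    def test_translating_sinusoid_gt_equals_minus_gx(self):
        # g(x, t) = sin(k(x − t)): ∂g/∂t = −∂g/∂x identically
        x = np.arange(64, dtype=float)
        frames = np.stack([100 + 50 * np.sin(0.3 * (x[None, :] - t)) * np.ones((64, 1)) for t in range(9)])
        stack = ImageStack(frames, np.arange(9) * 90.0, 0.02)
        gx, gy, gt = spatiotemporal_gradients(stack, 4, PARAMS)
        interior = (slice(10, -10), slice(10, -10))
        assert np.allclose(gt[interior], -gx[interior], atol=0.02 * np.abs(gx[interior]).max())

    def test_window_error_near_stack_ends(self):
        stack = ImageStack(np.ones((6, 16, 16)), np.arange(6) * 90.0, 0.02)
        with pytest.raises(WindowError):
            spatiotemporal_gradients(stack, 0, PARAMS)


class TestStructureTensor:
    def test_zero_gradients_give_zero_tensor(self):
        z = np.zeros((8, 8))
        J = build_structure_tensor(z, z, z, PARAMS)
        assert np.allclose(J, 0)

    def test_single_direction_rank_one(self):
        g = np.ones((16, 16))
        z = np.zeros((16, 16))
        J = build_structure_tensor(g, z, z, PARAMS)
        w = np.linalg.eigvalsh(J)
        assert np.allclose(w[..., :2], 0, atol=1e-10)  # two zero eigenvalues
        assert np.all(w[..., 2] > 0)

    def test_random_gradients_psd(self):
        rng = np.random.default_rng(1)
        gx, gy, gt = rng.standard_normal((3, 24, 24))
        J = build_structure_tensor(gx, gy, gt, PARAMS)
        w = np.linalg.eigvalsh(J)  # dense eigendecomposition as the oracle
        assert w.min() >= -1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            build_structure_tensor(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((5, 4)), PARAMS)


class TestConfidence:
    def test_degenerate_and_limit_cases(self):
        zero = np.zeros((2, 2, 3, 3))
        assert np.allclose(flow_confidence(zero), 0.0)
        # rank-2 tensor, λ3 = 0, λ2 > 0 → coherence 1
        J = np.zeros((1, 1, 3, 3))
        J[0, 0] = np.diag([3.0, 2.0, 0.0])
        assert flow_confidence(J)[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((5, 5, 3, 3))
        J = A @ np.swapaxes(A, -1, -2)  # PSD by construction
        conf = flow_confidence(J)
        w = np.sort(np.linalg.eigvalsh(J), axis=-1)
        expected = (w[..., 1] - w[..., 0]) / (w[..., 1] + w[..., 0] + 1e-12)
        np.testing.assert_allclose(conf, np.clip(expected, 0, 1), atol=1e-9)
        assert conf.min() >= 0 and conf.max() <= 1


class TestFlowEstimation:
    def test_integer_translation_oracle(self, translating_stack_1px):
        f = estimate_flow_field(translating_stack_1px, 10, PARAMS)
        u, v = median_flow(f)
        assert abs(u - 1.0) <= 0.05 and abs(v) <= 0.05

    def test_subpixel_translation_oracle(self, translating_stack_subpx):
        f = estimate_flow_field(translating_stack_subpx, 10, PARAMS)
        u, v = median_flow(f)
        assert abs(u - 0.3) <= 0.1 and abs(v) <= 0.1

    def test_static_scene_zero_flow(self):
        stack = make_translating_stack(shift_per_frame=(0.0, 0.0), n_frames=9, image_size=(128, 128))
        f = estimate_flow_field(stack, 4, PARAMS)
        assert float(np.nanmedian(f.speed()[f.valid_mask])) <= 0.01

    def test_textureless_scene_all_invalid(self):
        stack = ImageStack(np.full((7, 64, 64), 100.0), np.arange(7) * 90.0, 0.02)
        with pytest.warns(UserWarning):
            f = estimate_flow_field(stack, 3, PARAMS)
        assert not f.valid_mask.any()

    def test_intensity_scale_invariance(self, translating_stack_subpx):
        f1 = estimate_flow_field(translating_stack_subpx, 10, PARAMS)
        scaled = translating_stack_subpx.with_frames(translating_stack_subpx.frames * 3.7)
        f2 = estimate_flow_field(scaled, 10, PARAMS)
        both = f1.valid_mask & f2.valid_mask
        assert both.sum() > 0.5 * f1.valid_mask.sum()
        np.testing.assert_allclose(f1.u[both], f2.u[both], atol=1e-6)
        np.testing.assert_allclose(f1.v[both], f2.v[both], atol=1e-6)

    def test_time_reversal_negates_flow(self, translating_stack_1px):
        fwd = estimate_flow_field(translating_stack_1px, 10, PARAMS)
        rev_stack = ImageStack(
            translating_stack_1px.frames[::-1].copy(),
            translating_stack_1px.timestamps,
            translating_stack_1px.pixel_size,
        )
        rev = estimate_flow_field(rev_stack, 9, PARAMS)
        u_f, _ = median_flow(fwd)
        u_r, _ = median_flow(rev)
        assert abs(u_f + u_r) <= 0.05


class TestDisplacementIntegration:
    def test_known_translation_integrates(self, translating_stack_subpx):
        d = displacement_between(translating_stack_subpx, 5, 15, PARAMS)
        m = d.valid_mask
        assert m.any()
        assert abs(float(np.median(d.du[m])) - 3.0) <= 0.1
        assert abs(float(np.median(d.dv[m]))) <= 0.1

    def test_equal_frames_rejected(self, translating_stack_subpx):
        with pytest.raises(ValidationError):
            displacement_between(translating_stack_subpx, 7, 7, PARAMS)

    def test_expansion_matches_material_trajectory(self, leaf_expansion):
        # closed form: a point at radius R ends at R·(e^{S/2} − 1) from start
        _, stack, truth = leaf_expansion
        k0, k1 = 0, 40
        d = displacement_between(stack, k0, k1, PARAMS)
        H, W = stack.shape
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        cx, cy = truth.centroid
        f = np.exp((truth.cumulative_log_area[k1] - truth.cumulative_log_area[k0]) / 2.0) - 1.0
        du_true = f * (xx - cx)
        dv_true = f * (yy - cy)
        m = d.valid_mask & (np.hypot(xx - cx, yy - cy) > 20)
        err = np.hypot(d.du - du_true, d.dv - dv_true)[m]
        assert float(np.median(err)) <= 0.08


class TestFieldIO:
    def test_tiff_round_trip(self, translating_stack_subpx, tmp_path):
        f = estimate_flow_field(translating_stack_subpx, 10, PARAMS)
        path = write_velocity_field(f, tmp_path / "field.tif")
        back = read_velocity_field(path)
        np.testing.assert_array_equal(back.valid_mask, f.valid_mask)
        np.testing.assert_allclose(
            back.u[back.valid_mask], f.u[f.valid_mask], atol=1e-6
        )
        np.testing.assert_allclose(back.confidence, f.confidence, atol=1e-6)
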