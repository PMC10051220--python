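"""Tomography: forward-model geometry, loss oracles, alignment reductions,
parameter census and the sparse projector's exactness."""

import numpy as np
import pytest

from diffray.autodiff import Tensor
from diffray.diffops import WaveletBasis
from diffray.losses import LossWeights
from diffray.synth import _volume_coeffs, make_volume_phantom, \
    simulate_sinogram
from diffray.tomo import (AlignmentParams, ProjectionGeometry,
                          ProjectionStack, TomographyModel, _SparseProjector,
                          apply_alignment, prealign_projections, tomo_forward,
                          tomo_loss, tomo_loss_aligned)


def _geometry(n_angles=8, shape=(1, 16, 16), span=120.0):
    return ProjectionGeometry(
        angles_deg=np.linspace(0.0, span, n_angles, endpoint=False),
        volume_shape=shape)


class TestForward:
    def test_zero_coefficients_zero_projection(self):
        geo = _geometry()
        basis = WaveletBasis((16, 16), levels=3)
        out = tomo_forward(Tensor(np.zeros((1, basis.n_coeffs))), geo, 0)
        assert np.all(out.value == 0)

    def test_index_out_of_range(self):
        geo = _geometry()
        basis = WaveletBasis((16, 16), levels=3)
        with pytest.raises(IndexError):
            tomo_forward(Tensor(np.zeros((1, basis.n_coeffs))), geo, 99)

    def test_radially_symmetric_phantom_angle_invariant(self):
        n = 32
        r = np.hypot(*np.meshgrid(np.arange(n) - (n - 1) / 2,
                                  np.arange(n) - (n - 1) / 2, indexing="ij"))
        vol = np.exp(-0.5 * (r / 5.0) ** 2)[None]
        geo = _geometry(n_angles=6, shape=vol.shape)
        proj = _SparseProjector.for_geometry(geo).forward(vol)
        spread = np.abs(proj - proj[0]).max() / np.abs(proj[0]).max()
        assert spread < 1e-2

    def test_axis_voxel_peak_position_angle_invariant(self):
        n = 33  # odd: the rotation axis sits exactly on a voxel
        vol = np.zeros((1, n, n))
        vol[0, 16, 16] = 1.0
        geo = _geometry(n_angles=10, shape=vol.shape)
        proj = _SparseProjector.for_geometry(geo).forward(vol)
        peaks = proj[:, 0, :].argmax(axis=1)
        assert np.abs(peaks - 16).max() <= 0.5

    def test_sparse_projector_matches_warp_path(self, rng):
        geo = _geometry(n_angles=5, shape=(2, 16, 16))
        vol = rng.standard_normal((2, 16, 16))
        coeffs = _volume_coeffs(vol, geo)
        fast = _SparseProjector.for_geometry(geo).forward(vol)
        slow = np.stack([tomo_forward(Tensor(coeffs), geo, i).value
                         for i in range(5)])
        assert np.abs(fast - slow).max() < 1e-9

    def test_joint_rotation_of_phantom_and_angles_is_invariant(self):
        # rotating the volume in-plane and offsetting every projection angle
        # by the same amount leaves the sinogram unchanged (interpolation
        # tolerance)
        from diffray.synth import make_volume_phantom
        vol = make_volume_phantom(2, 32, seed=6, margin=5.0, n_beads=0)
        delta = 17.0
        from diffray.diffops import rotate_volume
        vol_rot = rotate_volume(Tensor(vol), delta).value
        angles = np.linspace(0.0, 120.0, 8, endpoint=False)
        sino = _SparseProjector.for_geometry(ProjectionGeometry(
            angles_deg=angles, volume_shape=vol.shape)).forward(vol)
        # content rotation by +delta corresponds to shifting the beam angle
        # origin by -delta under the pull-back convention
        sino_rot = _SparseProjector.for_geometry(ProjectionGeometry(
            angles_deg=angles - delta, volume_shape=vol.shape)).forward(
            vol_rot)
        rel = (np.linalg.norm(sino - sino_rot)
               / np.linalg.norm(sino))
        assert rel < 1e-2

    def test_sparse_projector_adjoint(self, rng):
        from diffray.solver import LinearOperator
        geo = _geometry(n_angles=5, shape=(2, 16, 16))
        proj = _SparseProjector.for_geometry(geo)
        op = LinearOperator(proj.forward, proj.adjoint, (2, 16, 16),
                            (5, 2, 16))
        assert op.dot_test(seed=4) < 1e-10


class TestLosses:
    def test_forward_consistency_at_truth(self):
        vol = make_volume_phantom(4, 16, seed=1, margin=3.0)
        geo = _geometry(n_angles=6, shape=vol.shape)
        stack, _ = simulate_sinogram(vol, geo)
        x = _volume_coeffs(vol, geo)
        initial = float(tomo_loss(np.zeros_like(x), stack,
                                  LossWeights(0.0, 0.0)).value)
        at_truth = float(tomo_loss(x, stack, LossWeights(0.0, 0.0)).value)
        assert at_truth < 1e-6 * initial

    def test_empty_angle_list_gives_regularizer_only(self, rng):
        geo = ProjectionGeometry(angles_deg=np.zeros(0),
                                 volume_shape=(1, 16, 16))
        stack = ProjectionStack(np.zeros((0, 1, 16)), geo)
        basis = WaveletBasis((16, 16), levels=3)
        x = rng.standard_normal((1, basis.n_coeffs))
        w = LossWeights(lambda1=0.3, lambda2=0.0)
        val = float(tomo_loss(x, stack, w).value)
        assert val == pytest.approx(0.3 * np.abs(x).sum(), rel=1e-12)

    def test_matches_direct_evaluator(self, rng):
        from diffray.losses import l1_norm, tv2d
        geo = _geometry(n_angles=4, shape=(1, 16, 16))
        basis = WaveletBasis((16, 16), levels=3)
        x = rng.standard_normal((1, basis.n_coeffs)) * 0.2
        images = rng.standard_normal((4, 1, 16))
        stack = ProjectionStack(images, geo)
        w = LossWeights(lambda1=0.11, lambda2=0.07)
        slice_img = basis.synthesize_np(x[0])
        sims = _SparseProjector.for_geometry(geo).forward(slice_img[None])
        ref = (np.sum((sims - images) ** 2) + 0.11 * np.abs(x).sum()
               + 0.07 * float(tv2d(Tensor(slice_img)).value))
        val = float(tomo_loss(x, stack, w).value)
        assert abs(val - ref) / abs(ref) < 1e-8

    def test_zero_alignment_reduces_to_plain_loss(self, rng):
        geo = _geometry(n_angles=4, shape=(2, 16, 16))
        basis = WaveletBasis((16, 16), levels=3)
        x = rng.standard_normal((2, basis.n_coeffs)) * 0.2
        images = rng.standard_normal((4, 2, 16))
        stack = ProjectionStack(images, geo)
        w = LossWeights(lambda1=0.1, lambda2=0.05)
        plain = float(tomo_loss(x, stack, w).value)
        aligned = float(tomo_loss_aligned(
            x, stack, Tensor(np.zeros((4, 2))), Tensor(np.zeros(())),
            w).value)
        assert aligned == pytest.approx(plain, rel=1e-12)

    def test_alignment_gradients_match_finite_differences(self, rng):
        from diffray.solver import verify_gradients
        geo = _geometry(n_angles=8, shape=(2, 8, 8))
        basis = WaveletBasis((8, 8), levels=2)
        images = rng.standard_normal((8, 2, 8))
        stack = ProjectionStack(images, geo)
        w = LossWeights(lambda1=0.02, lambda2=0.02)

        def closure(p):
            return tomo_loss_aligned(p["x"], stack, p["shifts"], p["tilt"],
                                     w, levels=2)

        rep = verify_gradients(closure, {
            "x": rng.standard_normal((2, basis.n_coeffs)) * 0.2,
            "shifts": rng.uniform(-0.7, 0.7, (8, 2)),
            "tilt": np.asarray(1.3)})
        assert rep.worst_rel < 1e-4


class TestAlignment:
    def test_parameter_census_is_2n_plus_1(self):
        vol = make_volume_phantom(4, 16, seed=1, margin=3.0)
        geo = _geometry(n_angles=7, shape=vol.shape)
        stack, _ = simulate_sinogram(vol, geo)
        model = TomographyModel(stack, refine_alignment=True)
        base = TomographyModel(stack, refine_alignment=False)
        assert model.n_refinable - base.n_refinable == 2 * 7 + 1
        _, params = model.loss_closure()
        n_align = params["shifts"].size + params["tilt"].size
        assert n_align == 2 * 7 + 1

    def test_warp_inverse_construction(self):
        vol = make_volume_phantom(12, 24, seed=2, margin=3.0)
        geo = _geometry(n_angles=6, shape=vol.shape)
        clean, _ = simulate_sinogram(vol, geo)
        stack, truth = simulate_sinogram(vol, geo, shift_range_px=1.5,
                                         tilt_deg=1.0, seed=3)
        undone = apply_alignment(Tensor(stack.images), Tensor(truth.shifts),
                                 Tensor(np.asarray(truth.tilt_deg))).value
        # single bilinear-interpolation residual, worst at the sharp beads:
        # compare in energy, and against the no-correction baseline
        err = np.linalg.norm(undone - clean.images)
        base = np.linalg.norm(stack.images - clean.images)
        assert err / np.linalg.norm(clean.images) < 0.08
        assert err < 0.2 * base

    def test_gauge_normalization_removes_rigid_components(self, rng):
        geo = _geometry(n_angles=12, shape=(2, 16, 16))
        shifts = rng.uniform(-2, 2, (12, 2))
        th = np.deg2rad(geo.angles_deg)
        # inject pure gauge components
        shifts[:, 0] += 1.7
        shifts[:, 1] += 0.8 * np.cos(th) - 0.5 * np.sin(th) + 0.3
        a = AlignmentParams(shifts, 1.0).gauge_normalized(geo.angles_deg)
        assert abs(a.shifts[:, 0].mean()) < 1e-10
        basis = np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])
        coef, *_ = np.linalg.lstsq(basis, a.shifts[:, 1], rcond=None)
        assert np.abs(coef).max() < 1e-10

    def test_prealignment_estimates_tilt(self):
        vol = make_volume_phantom(16, 32, seed=5, margin=4.0)
        geo = ProjectionGeometry(
            angles_deg=np.linspace(0, 120, 24, endpoint=False),
            volume_shape=vol.shape)
        stack, truth = simulate_sinogram(vol, geo, shift_range_px=2.0,
                                         tilt_deg=2.0, seed=5)
        pre = prealign_projections(stack)
        assert abs(pre.tilt_deg - 2.0) < 0.5


class TestModelPlumbing:
    def test_requires_two_projections(self):
        geo = _geometry(n_angles=1)
        stack = ProjectionStack(np.zeros((1, 1, 16)), geo)
        with pytest.raises(ValueError):
            TomographyModel(stack)

    def test_projection_stack_validation(self):
        geo = _geometry(n_angles=3)
        with pytest.raises(ValueError):
            ProjectionStack(np.zeros((2, 1, 16)), geo)  # wrong count
        with pytest.raises(ValueError):
            ProjectionStack(np.full((3, 1, 16), np.nan), geo)

    def test_determinism_without_alignment(self):
        vol = make_volume_phantom(2, 16, seed=3, margin=3.0)
        geo = _geometry(n_angles=6, shape=vol.shape)
        stack, _ = simulate_sinogram(vol, geo)
        r1 = TomographyModel(stack).fit(max_iter=60, seed=0)
        r2 = TomographyModel(stack).fit(max_iter=60, seed=1)
        rmse = np.sqrt(np.mean((r1.volume - r2.volume) ** 2))
        assert rmse < 1e-4
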