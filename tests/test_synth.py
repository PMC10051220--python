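"""Synthetic generators: determinism, construction audits, and global
forward/loss consistency at simulation truth."""

import numpy as np
import pytest
import scipy.fft as sfft

from diffray import synth
from diffray.autodiff import Tensor
from diffray.diffops import PropagationSpec
from diffray.losses import LossWeights, tv1d
from diffray.sisr import DegradationSpec, degrade, gaussian_kernel
from diffray.tomo import ProjectionGeometry


class TestPhantoms:
    def test_sparse_dct_is_exactly_k_sparse(self):
        spec = synth.PhantomSpec(kind="sparse-dct", size=64, sparsity=40,
                                 seed=3)
        img = synth.make_phantom(spec)
        coeffs = sfft.dctn(img, type=2, norm="ortho")
        assert int(np.sum(np.abs(coeffs) > 1e-10)) == 40

    def test_sparse_dct_with_dc_keeps_k(self):
        spec = synth.PhantomSpec(kind="sparse-dct", size=32, sparsity=20,
                                 seed=3, dc_level=1.0)
        img = synth.make_phantom(spec)
        coeffs = sfft.dctn(img, type=2, norm="ortho")
        assert int(np.sum(np.abs(coeffs) > 1e-10)) == 20
        assert abs(img.mean() - 1.0) < 1e-10

    def test_same_seed_is_bitwise_identical(self):
        for kind in ("sparse-dct", "piecewise-constant-ellipses",
                     "cell-like-blobs"):
            spec = synth.PhantomSpec(kind=kind, size=32, seed=9)
            assert np.array_equal(synth.make_phantom(spec),
                                  synth.make_phantom(spec))

    def test_ellipse_kind_has_few_levels(self):
        img = synth.make_phantom(synth.PhantomSpec(
            kind="piecewise-constant-ellipses", size=64, seed=5))
        assert len(np.unique(img)) <= 8
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_invalid_kind(self):
        with pytest.raises(ValueError):
            synth.make_phantom(synth.PhantomSpec(kind="nope", size=32))

    def test_volume_phantom_has_empty_margins(self):
        vol = synth.make_volume_phantom(16, 48, seed=1, margin=5.0)
        assert np.all(vol[:4] == 0) and np.all(vol[-4:] == 0)
        assert vol.min() >= 0.0


class TestMasks:
    def test_full_fraction_all_true(self):
        assert synth.make_mask((8, 8), 1.0, "regular-stride").values.all()

    def test_regular_count_matches_printed_protocol(self):
        mask = synth.make_mask((400, 400), 0.10, "regular-stride")
        assert int(mask.values.sum()) == 16000

    def test_random_masks_differ_but_count_matches(self):
        m1 = synth.make_mask((40, 40), 0.3, "uniform-random", seed=1)
        m2 = synth.make_mask((40, 40), 0.3, "uniform-random", seed=2)
        assert not np.array_equal(m1.values, m2.values)
        assert abs(int(m1.values.sum()) - int(m2.values.sum())) <= 1

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            synth.make_mask((8, 8), 0.0, "regular-stride")


class TestCsScan:
    def test_reduces_to_masking_without_gain_or_noise(self, rng):
        img = rng.standard_normal((16, 16))
        mask = synth.make_mask((16, 16), 0.5, "uniform-random", seed=0)
        y, gain = synth.simulate_cs_scan(img, mask)
        assert np.array_equal(y, np.where(mask.values, img, 0.0))
        assert np.all(gain == 1.0)

    def test_gain_amplitude_bound_and_variation(self):
        gain = synth.smooth_gain((64, 64), 0.2, seed=4)
        assert np.abs(gain - 1.0).max() == pytest.approx(0.2)
        profile = gain[:, 0]
        assert float(tv1d(Tensor(profile)).value) > 0.0

    def test_deterministic(self, rng):
        img = rng.standard_normal((16, 16))
        mask = synth.make_mask((16, 16), 0.5, "uniform-random", seed=0)
        y1, g1 = synth.simulate_cs_scan(img, mask, gain_amplitude=0.2, seed=5)
        y2, g2 = synth.simulate_cs_scan(img, mask, gain_amplitude=0.2, seed=5)
        assert np.array_equal(y1, y2) and np.array_equal(g1, g2)


class TestLrSimulation:
    def test_reduces_to_degrade_without_noise(self, rng):
        hr = rng.standard_normal((16, 16))
        k = gaussian_kernel(5, 1.0)
        spec = DegradationSpec(factor=2, kernel_size=5)
        y = synth.simulate_lr(hr, k, spec)
        ref = degrade(Tensor(hr), Tensor(k), spec).value
        assert np.array_equal(y, ref)

    def test_gaussian_noise_std(self, rng):
        hr = rng.standard_normal((104, 104))
        k = gaussian_kernel(13, 2.0)
        spec = DegradationSpec(factor=4)
        clean = synth.simulate_lr(hr, k, spec)
        noisy = synth.simulate_lr(hr, k, spec,
                                  synth.NoiseSpec("additive-gaussian", 0.05,
                                                  seed=2))
        resid = noisy - clean
        assert abs(resid.std() - 0.05) / 0.05 < 0.1


class TestSinogram:
    def _setup(self):
        vol = synth.make_volume_phantom(8, 32, seed=2, margin=4.0)
        geo = ProjectionGeometry(
            angles_deg=np.linspace(0, 120, 10, endpoint=False),
            volume_shape=vol.shape)
        return vol, geo

    def test_zero_misalignment_matches_forward(self):
        from diffray.synth import _volume_coeffs
        from diffray.tomo import tomo_forward
        vol, geo = self._setup()
        stack, truth = synth.simulate_sinogram(vol, geo)
        coeffs = _volume_coeffs(vol, geo)
        ref = np.stack([tomo_forward(coeffs, geo, i).value
                        for i in range(10)])
        assert np.abs(stack.images - ref).max() < 1e-10
        assert np.all(truth.shifts == 0)

    def test_shift_bound(self):
        vol, geo = self._setup()
        _, truth = synth.simulate_sinogram(vol, geo, shift_range_px=3.0,
                                           seed=7)
        assert np.abs(truth.shifts).max() <= 3.0

    def test_deterministic(self):
        vol, geo = self._setup()
        s1, t1 = synth.simulate_sinogram(vol, geo, shift_range_px=2.0,
                                         tilt_deg=1.0, seed=6)
        s2, t2 = synth.simulate_sinogram(vol, geo, shift_range_px=2.0,
                                         tilt_deg=1.0, seed=6)
        assert np.array_equal(s1.images, s2.images)
        assert np.array_equal(t1.shifts, t2.shifts)

    def test_truth_alignment_undoes_misalignment(self):
        from diffray.synth import _volume_coeffs
        from diffray.tomo import tomo_loss_aligned
        vol, geo = self._setup()
        stack, truth = synth.simulate_sinogram(vol, geo, shift_range_px=2.0,
                                               tilt_deg=1.5, seed=8)
        x = _volume_coeffs(vol, geo)
        w0 = LossWeights(0.0, 0.0)
        at_truth = float(tomo_loss_aligned(
            x, stack, Tensor(truth.shifts),
            Tensor(np.asarray(truth.tilt_deg)), w0).value)
        at_zero = float(tomo_loss_aligned(
            x, stack, Tensor(np.zeros((10, 2))), Tensor(np.zeros(())),
            w0).value)
        assert at_truth < 0.05 * at_zero


class TestPtychoSimulation:
    spec = PropagationSpec(regime="farfield", wavelength_m=1e-9,
                           pixel_size_m=5e-8)

    def test_grid_size(self):
        obj = synth.make_ptycho_object(48, seed=1)
        probe = np.ones((16, 16), complex) * 0.1
        ds, _ = synth.simulate_ptycho(obj, probe, (5, 5, 6.0),
                                      spec=self.spec, seed=1)
        assert ds.n_patterns == 25

    def test_jitter_rms_in_expected_band(self):
        obj = synth.make_ptycho_object(64, seed=1)
        probe = np.ones((16, 16), complex) * 0.1
        ds, truth = synth.simulate_ptycho(obj, probe, (5, 5, 8.0),
                                          jitter_px=1.0, spec=self.spec,
                                          seed=3)
        rms = np.sqrt(np.mean((ds.positions - truth["positions"]) ** 2))
        assert 0.4 <= rms <= 0.7  # RMS of uniform(-1, 1) ~ 0.577

    def test_loss_zero_at_truth(self):
        from diffray.diffops import ComplexField
        from diffray.ptycho import ptycho_loss
        obj = synth.make_ptycho_object(48, seed=5)
        from diffray.ptycho import disk_probe
        probe = disk_probe(16, radius=5.0, power=1.0)
        ds, truth = synth.simulate_ptycho(obj, probe, (3, 3, 8.0),
                                          spec=self.spec, seed=5)
        loss = ptycho_loss(ComplexField.from_complex(obj),
                           [ComplexField.from_complex(probe)], ds,
                           weights=LossWeights(0.0))
        scale = float(np.sum(ds.intensities ** 2))
        assert float(loss.value) < 1e-8 * scale

    def test_deterministic(self):
        obj = synth.make_ptycho_object(48, seed=5)
        probe = np.ones((16, 16), complex) * 0.1
        d1, t1 = synth.simulate_ptycho(obj, probe, (3, 3, 8.0),
                                       jitter_px=0.7, spec=self.spec, seed=9)
        d2, t2 = synth.simulate_ptycho(obj, probe, (3, 3, 8.0),
                                       jitter_px=0.7, spec=self.spec, seed=9)
        assert np.array_equal(d1.intensities, d2.intensities)
        assert np.array_equal(t1["positions"], t2["positions"])
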