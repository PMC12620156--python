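"""Two-point Dixon initialisation and the multi-step magnitude fit."""

import numpy as np
import pytest

from llrpdff.fat_model import (
    EchoTrain,
    FatSpectrum,
    MultiEchoImage,
    VoxelSignalParams,
    fat_coefficients,
    forward_signal,
)
from llrpdff.dixon_fit import (
    FitConfig,
    fit_voxel,
    fit_volume,
    select_init_echoes,
    two_point_init,
)
from llrpdff.phantom import echo_images, make_phantom, pdff_series_config


class TestSelectInitEchoes:
    def test_low_field_protocol_picks_echo_near_opposed_phase(
        self, nine_peak, protocol1
    ):
        """At ~80 Hz separation the opposed-phase target sits near 6.25 ms."""
        idx_op, idx_in, warn = select_init_echoes(protocol1, nine_peak)
        # oracle: direct phase computation per TE with the main-peak model
        f = nine_peak.main_peak_ppm * 42.577 * 0.55
        phase = np.exp(2j * np.pi * f * protocol1.echo_times)
        assert idx_op == int(np.argmin(np.abs(phase + 1)))
        assert idx_in == int(np.argmin(np.abs(phase - 1)))
        assert protocol1.echo_times[idx_op] == pytest.approx(6.8e-3)
        assert not warn

    def test_exact_pair_returned_unchanged(self):
        # single peak at -200 Hz: TE = 2.5 ms gives C=-1, TE = 5 ms gives C=+1
        sp = FatSpectrum(np.array([-200 / (42.577 * 1.5)]), np.array([1.0]))
        et = EchoTrain(np.array([2.5e-3, 5.0e-3]), 1.5)
        idx_op, idx_in, warn = select_init_echoes(et, sp)
        assert (idx_op, idx_in) == (0, 1)
        assert not warn

    def test_high_field_product_echoes(self, nine_peak, protocol2_15):
        """2.4/4.8 ms at 1.5 T are near opposed/in phase at ~210-220 Hz."""
        idx_op, idx_in, _ = select_init_echoes(protocol2_15, nine_peak)
        assert (idx_op, idx_in) == (0, 1)

    def test_single_echo_rejected(self, nine_peak):
        with pytest.raises(ValueError):
            select_init_echoes(EchoTrain(np.array([2e-3]), 1.5), nine_peak)


class TestTwoPointInit:
    def make_pair(self, w, f, phase=0.0):
        c = np.array([-1.0 + 0j, 1.0 + 0j])
        imgs = np.stack(
            [
                np.full((1, 4, 4), (w + c[0] * f) * np.exp(1j * phase)),
                np.full((1, 4, 4), (w + c[1] * f) * np.exp(1j * phase)),
            ]
        )
        return imgs, c

    def test_pure_water_gives_zero_fat(self):
        imgs, c = self.make_pair(1.0, 0.0)
        est = two_point_init(imgs, c, smoothing_sigma=0)
        np.testing.assert_allclose(np.abs(est.fat), 0.0, atol=1e-12)
        np.testing.assert_allclose(np.abs(est.water), 1.0, atol=1e-12)

    def test_exact_opposed_in_phase_solve(self):
        imgs, c = self.make_pair(0.6, 0.4)
        est = two_point_init(imgs, c, smoothing_sigma=0)
        np.testing.assert_allclose(np.abs(est.water), 0.6, atol=1e-10)
        np.testing.assert_allclose(np.abs(est.fat), 0.4, atol=1e-10)

    def test_global_phase_error_removed(self):
        imgs, c = self.make_pair(0.6, 0.4, phase=np.deg2rad(40))
        est = two_point_init(imgs, c, smoothing_sigma=1.0)
        np.testing.assert_allclose(np.abs(est.water), 0.6, atol=1e-6)
        np.testing.assert_allclose(np.abs(est.fat), 0.4, atol=1e-6)

    def test_degenerate_pair_rejected(self):
        imgs, _ = self.make_pair(1.0, 0.0)
        with pytest.raises(ValueError):
            two_point_init(imgs, np.array([0.5 + 0j, 0.5 + 0j]))


class TestFitVoxel:
    def test_noiseless_recovery(self, nine_peak, protocol1):
        c = fat_coefficients(nine_peak, protocol1)
        y = forward_signal(
            VoxelSignalParams(0.8, 0.2, 40.0), c, protocol1, magnitude=True
        )
        mw, mf, r2, res, ok = fit_voxel(y, c, protocol1, init=(0.7, 0.3, 30.0))
        assert ok
        assert 100 * mf / (mw + mf) == pytest.approx(20.0, abs=0.05)
        assert r2 == pytest.approx(40.0, abs=0.5)

    def test_pure_water_gives_zero_fat(self, nine_peak, protocol1):
        c = fat_coefficients(nine_peak, protocol1)
        y = forward_signal(VoxelSignalParams(1.0, 0.0, 30.0), c, protocol1, magnitude=True)
        mw, mf, r2, _, _ = fit_voxel(y, c, protocol1, init=(0.9, 0.1, 30.0))
        assert 100 * mf / (mw + mf) == pytest.approx(0.0, abs=0.05)

    def test_all_zero_signal_is_flagged(self, nine_peak, protocol1):
        c = fat_coefficients(nine_peak, protocol1)
        mw, mf, r2, res, ok = fit_voxel(np.zeros(6), c, protocol1)
        assert (mw, mf, r2) == (0.0, 0.0, 0.0) and not ok

    def test_agrees_with_batched_volume_fitter(self, nine_peak, protocol1, rng):
        """Scalar scipy path and the batched LM land on the same optimum."""
        c = fat_coefficients(nine_peak, protocol1)
        for ff, r2s in [(10.0, 30.0), (45.0, 60.0), (85.0, 90.0)]:
            y = forward_signal(
                VoxelSignalParams(1 - ff / 100, ff / 100, r2s),
                c,
                protocol1,
                magnitude=True,
            )
            img = (y[:, None, None, None] * np.ones((1, 3, 3))).astype(complex)
            maps = fit_volume(
                MultiEchoImage(img, protocol1), nine_peak, config=FitConfig()
            )
            mw, mf, r2, _, _ = fit_voxel(y, c, protocol1, init=(1 - ff / 100, ff / 100, 30.0))
            assert maps.pdff[0, 1, 1] == pytest.approx(100 * mf / (mw + mf), abs=0.05)
            assert maps.r2s[0, 1, 1] == pytest.approx(r2, abs=0.5)


class TestFitVolume:
    def test_noiseless_phantom_recovery(self, nine_peak, protocol1):
        cfg = pdff_series_config(shape=(2, 48, 48), pdff_values=[0, 20, 50, 80, 100])
        ph = make_phantom(cfg)
        imgs = echo_images(ph, nine_peak, protocol1)
        maps = fit_volume(imgs, nine_peak)
        for v in ph.vials:
            yy, xx = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
            inside = (yy - v.center[0]) ** 2 + (xx - v.center[1]) ** 2 <= (
                0.8 * v.radius
            ) ** 2
            assert np.nanmean(maps.pdff[1][inside]) == pytest.approx(
                v.pdff_percent, abs=0.1
            )
        bath = ph.support & (ph.pdff_map == 0) & (ph.r2s_map == 5.0)
        assert np.nanmean(maps.pdff[1][bath[1]]) == pytest.approx(0.0, abs=0.1)

    def test_swap_resistance_on_noiseless_data(self, nine_peak, protocol1):
        cfg = pdff_series_config(shape=(1, 48, 48), pdff_values=[0, 30, 60, 90])
        ph = make_phantom(cfg)
        maps = fit_volume(echo_images(ph, nine_peak, protocol1), nine_peak)
        err = np.abs(maps.pdff - ph.pdff_map)
        inside = ph.support & np.isfinite(maps.pdff)
        assert np.sum(err[inside] > 50.0) == 0

    def test_magnitude_fit_invariant_to_per_echo_phasors(
        self, nine_peak, protocol1, rng
    ):
        """The magnitude fit depends on the echo magnitudes only (exact)."""
        c = fat_coefficients(nine_peak, protocol1)
        y = forward_signal(
            VoxelSignalParams(0.7, 0.3, 45.0), c, protocol1, magnitude=True
        )
        phasors = np.exp(1j * rng.uniform(-np.pi, np.pi, 6))
        # unit phasors leave the magnitudes unchanged up to rounding
        np.testing.assert_allclose(np.abs(y.astype(complex) * phasors), y, rtol=1e-15)
        a = fit_voxel(y, c, protocol1, init=(0.6, 0.4, 30.0))
        b = fit_voxel(np.abs(y.astype(complex) * phasors), c, protocol1, init=(0.6, 0.4, 30.0))
        assert a[:3] == pytest.approx(b[:3], rel=1e-6, abs=1e-9)

    def test_volume_fit_invariant_to_global_phase(self, nine_peak, protocol1):
        """A global phase is removed exactly by the smoothed-phasor init."""
        cfg = pdff_series_config(shape=(1, 24, 24), pdff_values=[15, 65])
        ph = make_phantom(cfg)
        imgs = echo_images(ph, nine_peak, protocol1).data
        base = fit_volume(MultiEchoImage(imgs, protocol1), nine_peak)
        mod = fit_volume(
            MultiEchoImage(imgs * np.exp(1j * np.deg2rad(40)), protocol1), nine_peak
        )
        np.testing.assert_allclose(mod.pdff, base.pdff, atol=1e-6)
        np.testing.assert_allclose(mod.r2s, base.r2s, atol=1e-6)

    def test_scale_equivariance(self, nine_peak, protocol1):
        cfg = pdff_series_config(shape=(1, 24, 24), pdff_values=[25, 75])
        ph = make_phantom(cfg)
        imgs = echo_images(ph, nine_peak, protocol1).data
        a = fit_volume(MultiEchoImage(imgs, protocol1), nine_peak)
        b = fit_volume(MultiEchoImage(3.0 * imgs, protocol1), nine_peak)
        mask = np.isfinite(a.pdff)
        np.testing.assert_allclose(b.pdff[mask], a.pdff[mask], atol=1e-6)
        np.testing.assert_allclose(b.r2s, a.r2s, atol=1e-6)
        np.testing.assert_allclose(b.water, 3.0 * a.water, rtol=1e-6, atol=1e-9)

    def test_noise_biases_extreme_pdff_inward(self, nine_peak, protocol1, rng):
        """Noise pushes 0% vials up and 100% vials down (magnitude-fit bias)."""
        c = fat_coefficients(nine_peak, protocol1)
        n = 300
        sd = 0.06
        for ff, direction in [(0.0, 1), (100.0, -1)]:
            clean = forward_signal(
                VoxelSignalParams(1 - ff / 100, ff / 100, 40.0), c, protocol1
            )
            noisy = clean[None] + sd * (
                rng.standard_normal((n, 6)) + 1j * rng.standard_normal((n, 6))
            )
            img = noisy.T.reshape(6, 1, n, 1)
            maps = fit_volume(MultiEchoImage(img, protocol1), nine_peak)
            bias = np.nanmean(maps.pdff) - ff
            assert np.sign(bias) == direction
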