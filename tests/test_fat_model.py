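"""Chemical-shift signal model: coefficients, forward signal, PDFF, temperature."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from llrpdff.constants import GAMMA_MHZ_PER_T
from llrpdff.fat_model import (
    EchoTrain,
    FatSpectrum,
    VoxelSignalParams,
    fat_coefficients,
    fat_coefficients_at,
    forward_signal,
    pdff,
    temperature_correct,
    water_fat_separation_hz,
)


def spectrum_from_amplitudes(amps, shifts=None):
    amps = np.asarray(amps, float)
    amps = amps / amps.sum()
    if shifts is None:
        shifts = np.linspace(-3.8, 0.6, amps.size)
    return FatSpectrum(np.asarray(shifts, float), amps)


class TestFatSpectrum:
    def test_nine_peak_model_is_normalised(self, nine_peak):
        assert nine_peak.n_peaks == 9
        assert nine_peak.amplitudes.sum() == pytest.approx(1.0, abs=1e-9)
        assert nine_peak.main_peak_ppm == pytest.approx(-3.40)

    @pytest.mark.parametrize(
        "amps", [[0.5, 0.6], [1.0, -0.1, 0.1]], ids=["unnormalised", "negative"]
    )
    def test_invalid_spectra_rejected(self, amps):
        with pytest.raises(ValueError):
            FatSpectrum(np.linspace(-3, 0, len(amps)), np.array(amps))

    def test_echo_train_validation(self):
        with pytest.raises(ValueError):
            EchoTrain(np.array([0.0, 1e-3]), 0.55)
        with pytest.raises(ValueError):
            EchoTrain(np.array([2e-3, 1e-3]), 0.55)
        with pytest.raises(ValueError):
            EchoTrain(np.array([1e-3]), -1.0)


class TestFatCoefficients:
    def test_zero_te_gives_unity(self, nine_peak):
        c = fat_coefficients_at(nine_peak, np.array([0.0]), 0.55)
        assert c[0] == pytest.approx(1.0 + 0.0j, abs=1e-12)

    def test_half_cycle_single_peak_is_opposed(self):
        # single peak at -210 Hz (1.5 T), TE = half a dephasing cycle
        shift_ppm = -210.0 / (GAMMA_MHZ_PER_T * 1.5)
        sp = FatSpectrum(np.array([shift_ppm]), np.array([1.0]))
        te = 1.0 / (2 * 210.0)
        c = fat_coefficients_at(sp, np.array([te]), 1.5)
        assert c[0] == pytest.approx(-1.0 + 0.0j, abs=1e-12)

    def test_direct_summation_oracle(self, nine_peak, protocol1):
        c = fat_coefficients(nine_peak, protocol1)
        # independent direct summation over the peak list
        expected = []
        for te in protocol1.echo_times:
            acc = 0.0 + 0.0j
            for w, d in zip(nine_peak.amplitudes, nine_peak.shifts_ppm):
                f = d * GAMMA_MHZ_PER_T * protocol1.field_strength
                acc += w * np.exp(2j * np.pi * f * te)
            expected.append(acc)
        np.testing.assert_allclose(c, expected, atol=1e-12)

    def test_single_dephasing_cycle_at_low_field(self, nine_peak, protocol1):
        """|C(t)| has exactly one interior minimum over the acquired TE range."""
        te = np.linspace(protocol1.echo_times[0], protocol1.echo_times[-1], 400)
        mag = np.abs(fat_coefficients_at(nine_peak, te, 0.55))
        sign = np.sign(np.diff(mag))
        n_minima = int(np.sum((sign[:-1] < 0) & (sign[1:] > 0)))
        assert n_minima == 1

    @given(
        amps=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=9),
        b0=st.sampled_from([0.55, 1.5, 3.0]),
    )
    def test_magnitude_bounded_by_one(self, amps, b0):
        sp = spectrum_from_amplitudes(amps)
        et = EchoTrain(np.linspace(1e-3, 15e-3, 6), b0)
        assert np.all(np.abs(fat_coefficients(sp, et)) <= 1.0 + 1e-12)


class TestForwardSignal:
    def test_water_only_decay(self):
        et = EchoTrain(np.array([10e-3]), 0.55)
        c = np.array([1.0 + 0j])
        m = forward_signal(VoxelSignalParams(1.0, 0.0, 30.0), c, et)
        assert np.abs(m[0]) == pytest.approx(np.exp(-0.3), abs=1e-12)

    def test_opposed_phase_cancellation(self):
        et = EchoTrain(np.array([5e-3]), 0.55)
        m = forward_signal(VoxelSignalParams(0.5, 0.5, 0.0), np.array([-1.0 + 0j]), et)
        assert abs(m[0]) < 1e-15

    def test_superposition_in_amplitudes(self, nine_peak, protocol1, rng):
        c = fat_coefficients(nine_peak, protocol1)
        mw, mf = rng.uniform(0, 2, 2)
        full = forward_signal(VoxelSignalParams(mw, mf, 40.0), c, protocol1)
        water = forward_signal(VoxelSignalParams(mw, 0.0, 40.0), c, protocol1)
        fat = forward_signal(VoxelSignalParams(0.0, mf, 40.0), c, protocol1)
        np.testing.assert_allclose(full, water + fat, rtol=1e-12)

    def test_magnitude_variant_drops_phase_errors(self, nine_peak, protocol1, rng):
        c = fat_coefficients(nine_peak, protocol1)
        phasors = np.exp(1j * rng.uniform(-np.pi, np.pi, protocol1.n_echoes))
        p = VoxelSignalParams(0.7, 0.3, 25.0, phase_errors=phasors)
        mag = forward_signal(p, c, protocol1, magnitude=True)
        np.testing.assert_allclose(
            mag, np.abs(forward_signal(p, c, protocol1)), rtol=1e-12
        )

    def test_shared_relaxation_signals_have_rank_two(self, nine_peak, protocol1, rng):
        """Voxels sharing R2* and phase errors span a two-dimensional space."""
        c = fat_coefficients(nine_peak, protocol1)
        cols = [
            forward_signal(
                VoxelSignalParams(rng.uniform(0.1, 1), rng.uniform(0.1, 1), 40.0),
                c,
                protocol1,
            )
            for _ in range(5)
        ]
        s = np.linalg.svd(np.stack(cols, axis=1), compute_uv=False)
        assert s[1] / s[0] > 1e-6
        assert np.all(s[2:] / s[0] < 1e-10)

    def test_grid_search_oracle_recovers_parameters(self, nine_peak, protocol2_15):
        """A dense (PDFF, R2*) grid search locates the generating parameters."""
        c = fat_coefficients(nine_peak, protocol2_15)
        truth_ff, truth_r2 = 40.0, 50.0
        target = forward_signal(
            VoxelSignalParams(1 - truth_ff / 100, truth_ff / 100, truth_r2),
            c,
            protocol2_15,
            magnitude=True,
        )
        ffs = np.arange(0, 100.25, 0.25)
        r2s = np.arange(0, 100.25, 0.25)
        te = protocol2_15.echo_times
        model = np.abs(
            (1 - ffs[:, None, None] / 100) + c[None, None, :] * (ffs[:, None, None] / 100)
        ) * np.exp(-r2s[None, :, None] * te[None, None, :])
        cost = np.sum((model - target[None, None, :]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(cost), cost.shape)
        assert ffs[i] == pytest.approx(truth_ff, abs=0.25)
        assert r2s[j] == pytest.approx(truth_r2, abs=0.25)


class TestPdff:
    @pytest.mark.parametrize(
        "mw,mf,expected", [(3, 1, 25.0), (0, 2, 100.0), (5, 5, 50.0), (1, 0, 0.0)]
    )
    def test_fraction_values(self, mw, mf, expected):
        assert pdff(mw, mf) == pytest.approx(expected)

    def test_zero_signal_is_flagged_missing(self):
        assert np.isnan(pdff(0.0, 0.0))
        arr = pdff(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        assert np.isnan(arr[0]) and arr[1] == pytest.approx(50.0)


class TestTemperatureCorrection:
    def test_reference_temperature_is_identity(self, nine_peak):
        out = temperature_correct(nine_peak, 37.0)
        np.testing.assert_array_equal(out.shifts_ppm, nine_peak.shifts_ppm)

    def test_room_temperature_increases_separation(self, nine_peak):
        out = temperature_correct(nine_peak, 22.0)
        shift = out.shifts_ppm - nine_peak.shifts_ppm
        np.testing.assert_allclose(np.abs(shift), 0.15, atol=1e-12)
        # oracle: apparent water-fat separation must change by 0.15 ppm * gamma * B0
        before = water_fat_separation_hz(nine_peak, 0.55)
        after = water_fat_separation_hz(out, 0.55)
        assert after - before == pytest.approx(0.15 * GAMMA_MHZ_PER_T * 0.55, abs=1e-9)
        np.testing.assert_array_equal(out.amplitudes, nine_peak.amplitudes)

    def test_linearity_between_temperatures(self, nine_peak):
        a = temperature_correct(nine_peak, 27.0)
        b = temperature_correct(nine_peak, 32.0)
        np.testing.assert_allclose(np.abs(b.shifts_ppm - a.shifts_ppm), 0.05, atol=1e-12)

    def test_implausible_temperature_rejected(self, nine_peak):
        with pytest.raises(ValueError):
            temperature_correct(nine_peak, 60.0)
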