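import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegbench import metrics as mx
from eegbench.core import NONTARGET, TARGET, BandSet, default_bands
from conftest import make_epochs


def sine_epochs(freq, amp, n_trials=4, n_ch=2, rate=500.0, n_samp=550,
                t_min=-0.3):
    t = t_min + np.arange(n_samp) / rate
    wave = amp * np.sin(2 * np.pi * freq * t)
    tensor = np.tile(wave, (n_trials, n_ch, 1))
    return make_epochs(tensor, rate=rate, t_min=t_min)


class TestPSN:
    def test_zero_prestim(self):
        tensor = np.zeros((3, 2, 550))
        tensor[:, :, 150:] = 50.0  # post-stimulus only
        res = mx.psn(make_epochs(tensor))
        assert res.grand_mean == 0.0
        assert np.all(res.per_trial == 0.0)

    def test_constant_prestim(self):
        tensor = np.zeros((2, 1, 550))
        tensor[:, :, :150] = 5.0
        res = mx.psn(make_epochs(tensor))
        assert res.grand_mean == pytest.approx(5.0)

    def test_sinusoid_rms(self):
        # RMS of a sinusoid over whole cycles is a / sqrt(2); 10 Hz fits
        # exactly 3 cycles in the 300 ms pre-stimulus window
        epochs = sine_epochs(10.0, amp=8.0)
        res = mx.psn(epochs)
        assert res.grand_mean == pytest.approx(8.0 / math.sqrt(2), rel=0.02)

    def test_rejected_trials_excluded(self, rng):
        tensor = np.zeros((2, 1, 550))
        tensor[0, :, :150] = 3.0
        tensor[1, :, :150] = 1000.0
        epochs = make_epochs(tensor)
        epochs.keep_mask[1] = False
        assert mx.psn(epochs).grand_mean == pytest.approx(3.0)

    def test_label_restriction(self):
        tensor = np.zeros((2, 1, 550))
        tensor[0, :, :150] = 3.0
        tensor[1, :, :150] = 7.0
        epochs = make_epochs(tensor, labels=[TARGET, NONTARGET])
        assert mx.psn(epochs, label=TARGET).grand_mean == pytest.approx(3.0)

    def test_empty_mask_is_error(self, rng):
        epochs = make_epochs(rng.normal(size=(2, 1, 550)))
        epochs.keep_mask[:] = False
        with pytest.raises(ValueError, match="no kept"):
            mx.psn(epochs)

    def test_nonnegative(self, rng):
        res = mx.psn(make_epochs(rng.normal(size=(10, 3, 550))))
        assert np.all(res.per_trial >= 0)
        assert res.grand_mean >= 0


class TestBandPower:
    def test_sinusoid_concentrates_in_alpha(self):
        # at 512-sample segments the Hamming mainlobe (~ +/-2 Hz) stays
        # inside the alpha band, so every other band sees only sidelobes
        epochs = sine_epochs(10.0, amp=20.0, n_trials=8)
        res = mx.band_power(epochs, seglen=512, nfft=512)
        alpha = res.channel_avg["alpha"]
        for band, val in res.channel_avg.items():
            if band != "alpha":
                assert alpha >= 10 * val

    def test_sinusoid_alpha_is_largest_at_defaults(self):
        # with the default 128-sample segments the mainlobe leaks into
        # neighboring bands, but alpha still dominates
        epochs = sine_epochs(10.0, amp=20.0, n_trials=8)
        res = mx.band_power(epochs)
        vals = res.channel_avg
        assert vals["alpha"] == max(vals.values())

    def test_quadratic_amplitude_scaling(self, rng):
        tensor = rng.normal(size=(6, 2, 550))
        res1 = mx.band_power(make_epochs(tensor))
        res2 = mx.band_power(make_epochs(2 * tensor))
        for band in res1.channel_avg:
            assert res2.channel_avg[band] == pytest.approx(
                4 * res1.channel_avg[band], rel=1e-6)

    def test_white_noise_is_flat(self, rng):
        tensor = rng.normal(0, 10, size=(160, 2, 550))
        res = mx.band_power(make_epochs(tensor))
        vals = np.array(list(res.channel_avg.values()))
        assert vals.max() / vals.min() < 2.0

    def test_band_above_nyquist_rejected(self, rng):
        epochs = make_epochs(rng.normal(size=(2, 1, 550)), rate=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            mx.band_power(epochs, default_bands())

    def test_short_epoch_rejected(self, rng):
        epochs = make_epochs(rng.normal(size=(2, 1, 64)))
        with pytest.raises(ValueError, match="seglen"):
            mx.band_power(epochs)

    def test_power_nonnegative(self, rng):
        res = mx.band_power(make_epochs(rng.normal(size=(5, 2, 550))))
        for vals in res.per_channel.values():
            assert np.all(vals >= 0)


class TestRatioWS:
    def test_identity(self, rng):
        tensor = rng.normal(size=(5, 2, 550))
        bp = mx.band_power(make_epochs(tensor))
        ratios = mx.ratio_ws(bp, bp)
        for v in ratios.values():
            assert v == pytest.approx(1.0)

    def test_doubled_power(self, rng):
        tensor = rng.normal(size=(5, 2, 550))
        seat = mx.band_power(make_epochs(tensor))
        walk = mx.band_power(make_epochs(np.sqrt(2) * tensor))
        for v in mx.ratio_ws(walk, seat).values():
            assert v == pytest.approx(2.0, rel=1e-6)

    def test_mismatched_bands_rejected(self, rng):
        tensor = rng.normal(size=(5, 2, 550))
        a = mx.band_power(make_epochs(tensor))
        b = mx.band_power(make_epochs(tensor),
                          BandSet({"alpha": (8.0, 13.0)}))
        with pytest.raises(ValueError):
            mx.ratio_ws(a, b)


class TestAverageERP:
    def test_single_epoch(self, rng):
        tensor = rng.normal(size=(1, 2, 550))
        erp = mx.average_erp(make_epochs(tensor), TARGET)
        assert np.array_equal(erp.data, tensor[0])
        assert erp.n_epochs == 1

    def test_antisymmetric_pair_cancels(self, rng):
        x = rng.normal(size=(1, 2, 550))
        tensor = np.concatenate([x, -x])
        erp = mx.average_erp(make_epochs(tensor), TARGET)
        assert np.allclose(erp.data, 0.0)

    def test_noise_shrinks_as_sqrt_n(self, rng):
        template = 10 * np.exp(-0.5 * ((np.arange(550) - 350) / 30) ** 2)
        sigma = 5.0
        errs = []
        for n in (10, 160):
            tensor = template[None, None, :] + rng.normal(
                0, sigma, size=(n, 1, 550))
            erp = mx.average_erp(make_epochs(tensor), TARGET)
            errs.append(np.abs(erp.data[0] - template).max())
        # 16x the trials -> ~4x smaller error; allow slack for randomness
        assert errs[1] < errs[0] / 2

    def test_only_kept_and_labeled(self, rng):
        tensor = np.ones((3, 1, 550))
        tensor[1] = 100.0
        tensor[2] = 50.0
        epochs = make_epochs(tensor, labels=[TARGET, NONTARGET, TARGET])
        epochs.keep_mask[2] = False
        erp = mx.average_erp(epochs, TARGET)
        assert np.allclose(erp.data, 1.0)
        assert erp.n_epochs == 1

    def test_no_epochs_error(self, rng):
        epochs = make_epochs(rng.normal(size=(2, 1, 550)),
                             labels=[NONTARGET, NONTARGET])
        with pytest.raises(ValueError, match=TARGET):
            mx.average_erp(epochs, TARGET)


class TestSNR:
    def _erp_with_peak(self, peak, n_ch=1):
        data = np.zeros((n_ch, 550))
        data[:, 350] = peak  # t = 0.4 s
        times = -0.3 + np.arange(550) / 500.0
        from eegbench.core import ERPWaveform
        return ERPWaveform(data, 10, TARGET, times,
                           [f"ch{i}" for i in range(n_ch)])

    def _psn(self, value, n_ch=1):
        return mx.PSNResult(np.full((5, n_ch), value),
                            np.full(n_ch, value), value,
                            [f"ch{i}" for i in range(n_ch)])

    def test_unit_ratio(self):
        out = mx.snr(self._erp_with_peak(10.0), self._psn(10.0))
        assert out[0] == pytest.approx(1.0)

    def test_arithmetic(self):
        out = mx.snr(self._erp_with_peak(20.0), self._psn(5.0))
        assert out[0] == pytest.approx(4.0)

    def test_peak_is_signed_maximum(self):
        erp = self._erp_with_peak(5.0)
        erp.data[0, 360] = -50.0  # large negative deflection must not win
        out = mx.snr(erp, self._psn(5.0))
        assert out[0] == pytest.approx(1.0)

    def test_peak_outside_window_ignored(self):
        erp = self._erp_with_peak(5.0)
        erp.data[0, 100] = 500.0  # pre-stimulus, outside 300-500 ms
        out = mx.snr(erp, self._psn(5.0))
        assert out[0] == pytest.approx(1.0)

    def test_zero_psn_is_error(self):
        with pytest.raises(ZeroDivisionError):
            mx.snr(self._erp_with_peak(10.0), self._psn(0.0))


class TestCV:
    def test_constant_window_zero(self):
        times = -0.3 + np.arange(550) / 500.0
        trial = np.full(550, 7.0)
        assert mx.cv_trial(trial, times) == 0.0

    def test_hand_arithmetic(self):
        # samples {1, 3}: mean 2, sample sd sqrt(2) -> CV ~ 0.7071
        times = np.array([0.3, 0.4])
        got = mx.cv_trial(np.array([1.0, 3.0]), times, (0.3, 0.5))
        assert got == pytest.approx(math.sqrt(2) / 2, abs=1e-12)

    def test_matches_statistics_module(self, rng):
        times = -0.3 + np.arange(550) / 500.0
        trial = rng.normal(10, 3, size=550)
        sel = (times >= 0.3 - 1e-9) & (times <= 0.5 + 1e-9)
        expected = statistics.stdev(trial[sel]) / statistics.fmean(trial[sel])
        assert mx.cv_trial(trial, times) == pytest.approx(expected, abs=1e-10)

    def test_zero_mean_is_nan(self):
        times = np.array([0.3, 0.4])
        assert math.isnan(mx.cv_trial(np.array([-1.0, 1.0]), times, (0.3, 0.5)))

    def test_variance_switch(self):
        times = np.array([0.3, 0.4])
        got = mx.cv_trial(np.array([1.0, 3.0]), times, (0.3, 0.5),
                          use_variance=True)
        assert got == pytest.approx(1.0)  # var 2 / mean 2


class TestCVERP:
    def test_identical_trials(self, rng):
        trial = rng.normal(10, 2, size=(1, 1, 550))
        tensor = np.tile(trial, (5, 1, 1))
        epochs = make_epochs(tensor)
        per_ch, overall, n_undef = mx.cv_erp(epochs)
        times = epochs.epoch_times
        expected = mx.cv_trial(tensor[0, 0], times)
        assert overall == pytest.approx(expected)
        assert n_undef == 0

    def test_mean_of_trial_cvs(self):
        times_samp = 550
        tensor = np.full((2, 1, times_samp), 10.0)
        # trial CVs of 0.2 and 0.4 via crafted window content
        epochs = make_epochs(tensor)
        sel = (epochs.epoch_times >= 0.3 - 1e-9) & \
              (epochs.epoch_times <= 0.5 + 1e-9)
        n_win = int(sel.sum())
        for i, cv in enumerate((0.2, 0.4)):
            x = np.full(n_win, 10.0)
            # two-point spread achieving sd = cv * mean around mean 10
            x[0] = 10 + cv * 10 * math.sqrt((n_win - 1) / 2)
            x[1] = 10 - cv * 10 * math.sqrt((n_win - 1) / 2)
            tensor[i, 0, sel] = x
        per_ch, overall, _ = mx.cv_erp(make_epochs(tensor))
        assert overall == pytest.approx(0.3, rel=1e-6)

    def test_monotone_in_noise(self, rng):
        template = np.full(550, 10.0)
        cvs = []
        for sd in (0.5, 2.0, 8.0):
            tensor = template[None, None, :] + rng.normal(
                0, sd, size=(100, 1, 550))
            _, overall, _ = mx.cv_erp(make_epochs(tensor))
            cvs.append(overall)
        assert cvs[0] < cvs[1] < cvs[2]

    def test_undefined_trials_excluded_and_counted(self):
        tensor = np.full((2, 1, 550), 10.0)
        sel_times = make_epochs(tensor).epoch_times
        sel = (sel_times >= 0.3 - 1e-9) & (sel_times <= 0.5 + 1e-9)
        n_win = int(sel.sum())
        pattern = np.zeros(n_win)
        pattern[: n_win // 2] = 1.0
        pattern[n_win // 2: 2 * (n_win // 2)] = -1.0  # exactly zero mean
        tensor[1, 0, sel] = pattern
        per_ch, overall, n_undef = mx.cv_erp(make_epochs(tensor))
        assert n_undef == 1
        assert overall == 0.0  # only the constant trial remains


class TestScalarSimilarity:
    def _erp(self, data):
        from eegbench.core import ERPWaveform
        data = np.atleast_2d(np.asarray(data, dtype=float))
        times = np.arange(data.shape[1]) / 500.0
        return ERPWaveform(data, 3, TARGET, times,
                           [f"ch{i}" for i in range(data.shape[0])])

    def test_identical_is_one(self, rng):
        a = self._erp(rng.normal(size=(2, 100)))
        r = mx.scalar_similarity(a, a)
        assert np.allclose(r, 1.0)

    def test_negated_is_minus_one(self, rng):
        x = rng.normal(size=(1, 100))
        r = mx.scalar_similarity(self._erp(x), self._erp(-x))
        assert r[0] == pytest.approx(-1.0)

    def test_hand_vectors(self):
        r = mx.scalar_similarity(self._erp([1.0, 2.0, 3.0]),
                                 self._erp([1.0, 2.0, 4.0]), channel=0)
        expected = np.corrcoef([1, 2, 3], [1, 2, 4])[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)
        assert r == pytest.approx(0.9820, abs=1e-4)

    def test_equals_pearson(self, rng):
        a = rng.normal(size=(3, 200))
        b = rng.normal(size=(3, 200))
        r = mx.scalar_similarity(self._erp(a), self._erp(b))
        for c in range(3):
            assert r[c] == pytest.approx(np.corrcoef(a[c], b[c])[0, 1],
                                         abs=1e-12)

    def test_symmetry_and_scale_invariance(self, rng):
        a, b = rng.normal(size=(1, 80)), rng.normal(size=(1, 80))
        r_ab = mx.scalar_similarity(self._erp(a), self._erp(b))[0]
        r_ba = mx.scalar_similarity(self._erp(b), self._erp(a))[0]
        r_scaled = mx.scalar_similarity(self._erp(a), self._erp(3.7 * b))[0]
        assert r_ab == pytest.approx(r_ba, abs=1e-12)
        assert r_ab == pytest.approx(r_scaled, abs=1e-12)

    def test_bounded(self, rng):
        a = rng.normal(size=(5, 60))
        b = rng.normal(size=(5, 60))
        r = mx.scalar_similarity(self._erp(a), self._erp(b))
        assert np.all(np.abs(r) <= 1.0)

    def test_zero_variance_is_nan(self, rng):
        a = self._erp(np.full((1, 50), 4.0))
        b = self._erp(rng.normal(size=(1, 50)))
        assert math.isnan(mx.scalar_similarity(a, b)[0])

    def test_uncentered_mode(self):
        a = self._erp([1.0, 1.0, 1.0])
        b = self._erp([2.0, 2.0, 2.0])
        r = mx.scalar_similarity(a, b, channel=0, center=False)
        assert r == pytest.approx(1.0)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mx.scalar_similarity(self._erp(np.zeros((1, 10))),
                                 self._erp(np.zeros((1, 12))))


class TestFisherAverage:
    def test_single_value_identity(self):
        assert mx.fisher_average([0.37]) == pytest.approx(0.37, abs=1e-12)

    def test_zeros(self):
        assert mx.fisher_average([0.0, 0.0, 0.0]) == 0.0

    def test_constant_list(self):
        assert mx.fisher_average([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form(self):
        expected = math.tanh((math.atanh(0.0) + math.atanh(0.8)) / 2)
        got = mx.fisher_average([0.0, 0.8])
        assert got == pytest.approx(expected, abs=1e-12)
        # closed form: tanh(atanh(0.8)/2) = 0.8 / (1 + sqrt(1 - 0.64))
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_clips_unit_correlations(self, caplog):
        with caplog.at_level("WARNING"):
            out = mx.fisher_average([1.0, 1.0])
        assert out == pytest.approx(1.0, abs=1e-6)
        assert "clipping" in caplog.text

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=-0.99, max_value=0.99), min_size=1,
                    max_size=8),
           st.floats(min_value=-0.99, max_value=0.99))
    def test_monotone_in_each_argument(self, rs, bump):
        base = mx.fisher_average(rs)
        larger = mx.fisher_average(rs + [min(0.99, max(rs))])
        assert mx.fisher_average([bump]) == pytest.approx(bump, abs=1e-9)
        # adding a value >= max cannot decrease the average
        assert larger >= base - 1e-12

    def test_empty_error(self):
        with pytest.raises(ValueError):
            mx.fisher_average([float("nan")])
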