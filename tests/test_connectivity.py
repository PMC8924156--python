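"""Epoch extraction, Welch coherence (incl. an independent scipy
cross-check and the 1/K bias of independent noise), normalized
cross-correlation against a direct-summation oracle, and lead-lag
recovery from generated cohorts."""

import numpy as np
import pytest
from scipy import signal as sps

import norcircuit as nc
from norcircuit.connectivity import (animal_connectivity, band_mean,
                                     extract_epochs, influx_lag, msc,
                                     xcorr_norm)


def xcorr_bruteforce(x, y, fs, max_lag):
    """Direct-summation oracle for r(l) = sum_t x(t) y(t+l) / sqrt(ExEy)."""
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(len(lags))
    for k, l in enumerate(lags):
        if l >= 0:
            r[k] = np.dot(x[: len(x) - l], y[l:]) / denom
        else:
            r[k] = np.dot(x[-l:], y[: len(y) + l]) / denom
    return lags * 1000.0 / fs, r


@pytest.fixture
def masked_rec(rng):
    rec = nc.Recording(nc.CHANNELS, rng.standard_normal((3, 20_000)), 1000.0,
                       animal_id="a")
    rec.artifact_mask[15_000:15_100] = True
    return rec


class TestExtractEpochs:
    def test_window_sample_arithmetic(self, masked_rec):
        # onset at 10 s, fs=1000 -> samples [8000, 11000), length 3000
        epochs, dropped = extract_epochs(masked_rec, [10.0])
        assert len(epochs) == 1 and not dropped
        ep = epochs[0]
        assert ep.data.shape == (3, 3000)
        np.testing.assert_array_equal(ep.data, masked_rec.data[:, 8000:11000])

    def test_truncated_prewindow_dropped(self, masked_rec):
        epochs, dropped = extract_epochs(masked_rec, [1.0])
        assert not epochs
        assert "truncated" in dropped[0][1]

    def test_masked_overlap_dropped(self, masked_rec):
        epochs, dropped = extract_epochs(masked_rec, [15.5])
        assert not epochs
        assert "artifact" in dropped[0][1]


class TestMsc:
    def test_identical_signals_unit_coherence(self, rng):
        x = rng.standard_normal(8000)
        coh = msc(x, x, fs=1000.0)
        assert np.all(np.abs(coh.msc - 1.0) < 1e-10)

    def test_independent_noise_bias_one_over_k(self, rng):
        # K=8 non-overlapping segments: E[msc] ~ 1/K for independent noise
        means = []
        for _ in range(200):
            x = rng.standard_normal(8000)
            y = rng.standard_normal(8000)
            coh = msc(x, y, fs=1000.0, overlap=0.0)
            assert coh.n_segments == 8
            means.append(coh.msc[1:-1].mean())
        assert np.mean(means) == pytest.approx(1 / 8, rel=0.2)

    def test_matches_scipy_on_continuous_signal(self, rng):
        x = rng.standard_normal(30_000)
        y = 0.6 * x + rng.standard_normal(30_000)
        coh = msc(x, y, fs=1000.0)
        f_ref, c_ref = sps.coherence(x, y, fs=1000.0, window="hann",
                                     nperseg=1000, noverlap=500,
                                     detrend="constant")
        np.testing.assert_allclose(coh.freqs, f_ref)
        np.testing.assert_allclose(coh.msc, c_ref, atol=1e-10)

    def test_pooled_epoch_list_input(self, rng):
        pairs = [(rng.standard_normal(3000), rng.standard_normal(3000))
                 for _ in range(4)]
        coh = msc(pairs, fs=1000.0)
        assert coh.n_segments == 20  # 5 Hann segments per 3 s epoch

    def test_single_segment_rejected(self, rng):
        with pytest.raises(ValueError, match="segment"):
            msc(rng.standard_normal(1000), rng.standard_normal(1000),
                fs=1000.0)

    def test_bounded_and_scale_invariant(self, rng):
        x = rng.standard_normal(10_000)
        y = 0.3 * x + rng.standard_normal(10_000)
        a = msc(x, y, fs=1000.0)
        b = msc(5.0 * x, 0.2 * y, fs=1000.0)
        assert np.all((a.msc >= 0) & (a.msc <= 1))
        np.testing.assert_allclose(a.msc, b.msc, atol=1e-10)


class TestBandMean:
    def _coh(self, freqs, vals):
        return nc.CoherenceSpectrum(("a", "b"), np.asarray(freqs, float),
                                    np.asarray(vals, float), 10)

    def test_constant_unit(self):
        coh = self._coh(np.arange(0, 501.0), np.ones(501))
        assert band_mean(coh, (4, 12)) == 1.0

    def test_disjoint_bands(self):
        freqs = np.arange(0, 501.0)
        vals = np.where((freqs >= 4) & (freqs <= 12), 1.0, 0.0)
        coh = self._coh(freqs, vals)
        assert band_mean(coh, (4, 12)) == 1.0
        assert band_mean(coh, (30, 80)) == 0.0

    def test_linear_ramp_hand_computed(self):
        # 10-bin grid 1..10 Hz with msc = 0.0, 0.1, ..., 0.9;
        # band (3, 7) covers bins 3,4,5,6,7 -> mean of 0.2..0.6 = 0.4
        coh = self._coh(np.arange(1, 11.0), np.arange(10) / 10.0)
        assert band_mean(coh, (3, 7)) == pytest.approx(0.4)

    def test_empty_band_rejected(self):
        coh = self._coh([10.0, 20.0], [0.5, 0.5])
        with pytest.raises(ValueError):
            band_mean(coh, (12, 15))


class TestXcorr:
    def test_autocorrelation_peak(self, rng):
        x = rng.standard_normal(10_000)
        ccr = xcorr_norm(x, x, 1000.0)
        assert ccr.r_max == pytest.approx(1.0)
        assert ccr.lag_at_max_ms == 0.0

    def test_known_delay_recovered(self, rng):
        x = rng.standard_normal(10_000)
        d = 20
        y = np.r_[np.zeros(d), x[:-d]]   # x leads y by 20 ms
        ccr = xcorr_norm(x, y, 1000.0)
        assert ccr.lag_at_max_ms == pytest.approx(20.0, abs=1.0)
        assert ccr.r_max >= 0.99

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(400)
        y = rng.standard_normal(400)
        ccr = xcorr_norm(x, y, 1000.0, max_lag_ms=50)
        lags_ref, r_ref = xcorr_bruteforce(x, y, 1000.0, 50)
        np.testing.assert_allclose(ccr.lags_ms, lags_ref)
        np.testing.assert_allclose(ccr.r, r_ref, atol=1e-10)

    def test_argument_swap_symmetry(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        a = xcorr_norm(x, y, 1000.0, max_lag_ms=30)
        b = xcorr_norm(y, x, 1000.0, max_lag_ms=30)
        np.testing.assert_allclose(a.r, b.r[::-1], atol=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        a = xcorr_norm(x, y, 1000.0)
        b = xcorr_norm(3.0 * x, 0.5 * y, 1000.0)
        np.testing.assert_allclose(a.r, b.r, atol=1e-12)
        assert np.all(np.abs(a.r) <= 1 + 1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            xcorr_norm(np.ones(1000), np.arange(1000.0), 1000.0)

    def test_max_lag_precondition(self, rng):
        with pytest.raises(ValueError, match="max_lag"):
            xcorr_norm(rng.standard_normal(300), rng.standard_normal(300),
                       1000.0, max_lag_ms=100)


class TestInfluxLag:
    def test_sign_readout(self, rng):
        x = rng.standard_normal(10_000)
        y = np.r_[np.zeros(15), x[:-15]]
        assert influx_lag(xcorr_norm(x, y, 1000.0)) == pytest.approx(15.0, abs=1)
        assert influx_lag(xcorr_norm(y, x, 1000.0)) == pytest.approx(-15.0, abs=1)

    def test_tie_breaks_positive(self):
        # 50 Hz sine shifted by a half period: equal peaks at +-10 ms
        t = np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 50 * t)
        y = -x
        ccr = xcorr_norm(x, y, 1000.0, max_lag_ms=15)
        assert ccr.lag_at_max_ms == 10.0


class TestAnimalConnectivity:
    def _epochs(self, rng, n, corr=0.7, n_samples=3000):
        epochs = []
        for k in range(n):
            shared = rng.standard_normal(n_samples)
            data = np.vstack([
                corr * shared + rng.standard_normal(n_samples),
                corr * shared + rng.standard_normal(n_samples),
                corr * shared + rng.standard_normal(n_samples)])
            epochs.append(nc.Epoch(nc.CHANNELS, data, 1000.0, t0=10.0 + 5 * k,
                                   animal_id="a", index=k))
        return epochs

    def test_zero_epochs_flagged_missing(self):
        with pytest.raises(ValueError, match="missing"):
            animal_connectivity([])

    def test_single_epoch_equals_trial_values(self, rng):
        epochs = self._epochs(rng, 1)
        ac = animal_connectivity(epochs, pool="trial")
        coh = msc(epochs[0].channel("OB"), epochs[0].channel("EC"), fs=1000.0)
        assert ac.coherence["OB-EC"]["theta"] == pytest.approx(
            band_mean(coh, nc.DEFAULT_BANDS["theta"]))
        assert ac.n_trials == 1

    def test_trial_means_match_manual_average(self, rng):
        epochs = self._epochs(rng, 3)
        ac = animal_connectivity(epochs)
        rs, ls = [], []
        for ep in epochs:
            xf = nc.bandpass(ep.channel("OB"), (4, 12), 1000.0)
            yf = nc.bandpass(ep.channel("EC"), (4, 12), 1000.0)
            ccr = xcorr_norm(xf, yf, 1000.0, max_lag_ms=250)
            rs.append(ccr.r_max)
            ls.append(ccr.lag_at_max_ms)
        assert ac.r_max["OB-EC"]["theta"] == pytest.approx(np.mean(rs))
        assert ac.lag_ms["OB-EC"]["theta"] == pytest.approx(np.mean(ls))

    def test_cohort_lag_recovery_within_2ms(self):
        # per-animal mean lags recover the injected 20 ms (OB->EC) and
        # 15 ms (EC->dHPC) delays
        params = nc.default_control_params(duration=120.0)
        sessions = nc.generate_cohort_sessions(params, params, 3, seed=21)
        got = {"OB-EC": [], "EC-dHPC": []}
        for _, _, rec, trace, gt in sessions:
            pp = nc.preprocess(rec)
            onsets = nc.novel_event_onsets(nc.detect_object_bouts(trace))
            epochs, _ = extract_epochs(pp, onsets)
            ac = animal_connectivity(epochs)
            for key in got:
                got[key].append(ac.lag_ms[key]["gamma"])
        assert np.mean(got["OB-EC"]) == pytest.approx(20.0, abs=2.0)
        assert np.mean(got["EC-dHPC"]) == pytest.approx(15.0, abs=2.0)
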