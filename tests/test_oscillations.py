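"""Spectral estimation, coherence, Granger, ROC and episode dynamics."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import norm

from freezeloop.core import TimeSeriesSignal
from freezeloop.markov import ACTIVE, FREEZE, BehaviouralTimeline
from freezeloop.oscillations import (
    Spectrogram,
    band_snr,
    bin_band_power,
    coherence,
    granger_band,
    micromovement_coupling,
    multitaper_spectrogram,
    normalized_episode_profile,
    roc_state_prediction,
    split_episode_spectra,
    transition_slope,
)
from freezeloop.synth import SyntheticConfig, simulate_accelerometer


def _sig(data, fs=250.0):
    return TimeSeriesSignal(np.asarray(data, float), fs)


def _tone(f, duration, fs=250.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return _sig(amp * np.cos(2 * np.pi * f * t), fs)


@pytest.fixture(scope="module")
def downsampled(short_session):
    q = 5
    ob = sps.decimate(short_session.ob.data, q, ftype="fir")
    pfc = sps.decimate(short_session.pfc.data, q, ftype="fir")
    fs = short_session.ob.rate_hz / q
    return _sig(ob, fs), _sig(pfc, fs)


class TestMultitaperSpectrogram:
    @staticmethod
    def _centroid(spec, lo, hi):
        sel = (spec.freqs >= lo) & (spec.freqs <= hi)
        p = spec.power[:, sel]
        return (spec.freqs[sel] * p).sum(axis=1) / p.sum(axis=1)

    def test_tone_peaks_at_its_frequency(self):
        spec = multitaper_spectrogram(_tone(4.0, 30.0))
        peak_f = spec.freqs[np.argmax(spec.power, axis=1)]
        # argmax lands anywhere inside the taper bandwidth NW/T = 1 Hz;
        # the band centroid pins the tone to within a bin
        assert (np.abs(peak_f - 4.0) <= 1.0 + np.diff(spec.freqs)[0]).all()
        cent = self._centroid(spec, 2.0, 6.0)
        assert np.abs(cent - 4.0).max() < np.diff(spec.freqs)[0]

    def test_white_noise_spectrum_flat(self, rng):
        spec = multitaper_spectrogram(_sig(rng.standard_normal(100 * 250)))
        # away from the one-sided doubling edge at DC; 4 Hz blocks tame the
        # sampling variance of individual bins
        sel = (spec.freqs > 2.0) & (spec.freqs < 120.0)
        mean_spec = spec.power.mean(axis=0)[sel]
        n_block = int(round(4.0 / np.diff(spec.freqs)[0]))
        blocks = mean_spec[: mean_spec.size // n_block * n_block]
        blocks = blocks.reshape(-1, n_block).mean(axis=1)
        assert blocks.max() / blocks.mean() < 1.2
        assert blocks.min() / blocks.mean() > 0.8

    def test_parseval(self, rng):
        x = rng.standard_normal(60 * 250)
        spec = multitaper_spectrogram(_sig(x))
        df = np.diff(spec.freqs)[0]
        total = spec.power.mean(axis=0).sum() * df
        assert total == pytest.approx(np.var(x), rel=0.1)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            multitaper_spectrogram(_sig(np.zeros(100)))

    def test_tracks_modulated_frequency(self):
        # slow FM around 5 Hz stays within one frequency bin of truth
        fs = 250.0
        t = np.arange(int(120 * fs)) / fs
        f_inst = 5.0 + 1.5 * np.sin(2 * np.pi * t / 60.0)
        x = np.cos(2 * np.pi * np.cumsum(f_inst) / fs)
        spec = multitaper_spectrogram(_sig(x, fs), fmax=20.0)
        cent = self._centroid(spec, 2.0, 10.0)
        truth = np.interp(spec.times, t, f_inst)
        df = np.diff(spec.freqs)[0]
        assert np.percentile(np.abs(cent - truth), 95) <= df

    def test_normalization_preserves_band_ratio(self, rng):
        spec = multitaper_spectrogram(_sig(rng.standard_normal(60 * 250)
                                           + _tone(4.0, 60.0).data))
        before = band_snr(spec.freqs, spec.mean_spectrum())
        after = band_snr(spec.freqs,
                         spec.normalize_total_power().mean_spectrum())
        assert after == pytest.approx(before, rel=1e-12)


class TestBandSnr:
    def test_white_noise_near_unity(self, rng):
        spec = multitaper_spectrogram(_sig(rng.standard_normal(200 * 250)))
        assert band_snr(spec.freqs, spec.mean_spectrum()) \
            == pytest.approx(1.0, abs=0.1)

    def test_tone_dominates(self, rng):
        x = _tone(4.0, 60.0).data + 0.01 * rng.standard_normal(60 * 250)
        spec = multitaper_spectrogram(_sig(x))
        assert band_snr(spec.freqs, spec.mean_spectrum()) > 10

    def test_synthetic_freeze_above_active(self, short_session, downsampled):
        ob, _ = downsampled
        spec = multitaper_spectrogram(ob, fmax=20.0)
        fz = short_session.timeline.state_at(spec.times) == FREEZE
        snr_fz = band_snr(spec.freqs, spec.mean_spectrum(fz))
        snr_act = band_snr(spec.freqs, spec.mean_spectrum(~fz))
        assert snr_fz > snr_act

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_snr(np.array([0.0, 1.0, 2.0]), np.ones(3), band=(5, 6))


class TestCoherence:
    def test_identical_signals(self, rng):
        x = _sig(rng.standard_normal(60 * 250))
        c = coherence(x, x)
        assert np.all(c["coherence"] > 0.999)

    def test_independent_noise_low(self, rng):
        a = _sig(rng.standard_normal(100 * 250))
        b = _sig(rng.standard_normal(100 * 250))
        c = coherence(a, b)
        assert c["band_mean"] < 0.2

    def test_synthetic_pair_freeze_above_active(self, short_session,
                                                downsampled):
        ob, pfc = downsampled
        tl = short_session.timeline
        c_fz = coherence(ob, pfc, epochs=tl.bout_epochs(FREEZE), fmax=20.0)
        c_act = coherence(ob, pfc, epochs=tl.bout_epochs(ACTIVE), fmax=20.0)
        assert c_fz["band_mean"] > c_act["band_mean"]

    def test_misaligned_signals_rejected(self, rng):
        a = _sig(rng.standard_normal(5000), 250.0)
        b = _sig(rng.standard_normal(5000), 125.0)
        with pytest.raises(ValueError):
            coherence(a, b)


class TestGranger:
    def test_delayed_copy_directionality(self, rng):
        n = 30_000
        x = rng.standard_normal(n)
        y = np.roll(x, 3) * 0.8 + 0.5 * rng.standard_normal(n)
        g = granger_band(_sig(x), _sig(y), band=(1, 100), target_rate=250.0,
                         max_order=10)
        assert g["g_a_to_b"] > g["g_b_to_a"]

    def test_independent_signals_below_surrogate(self, rng):
        a = _sig(rng.standard_normal(30_000))
        b = _sig(rng.standard_normal(30_000))
        g = granger_band(a, b, band=(3, 6), target_rate=250.0, max_order=10,
                         surrogate=True)
        thr = max(g["surrogate_threshold"], 0.01)
        assert g["g_a_to_b"] < 3 * thr
        assert g["g_b_to_a"] < 3 * thr

    def test_synthetic_ob_drives_pfc(self, short_session):
        tl = short_session.timeline
        g = granger_band(short_session.ob, short_session.pfc,
                         epochs=tl.bout_epochs(FREEZE))
        assert g["g_a_to_b"] > g["g_b_to_a"]


class TestRoc:
    def _timeline(self, n):
        states = np.zeros(n, dtype=int)
        states[: n // 2] = FREEZE
        return BehaviouralTimeline(states)

    def test_uninformative_power_near_half(self, rng):
        tl = self._timeline(4000)
        roc = roc_state_prediction(rng.standard_normal(4000), tl)
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_perfect_separation_is_exactly_one(self, rng):
        tl = self._timeline(200)
        power = rng.standard_normal(200)
        power[:100] += 100.0
        roc = roc_state_prediction(power, tl)
        assert roc.auc == 1.0

    def test_dprime_one_matches_closed_form(self, rng):
        tl = self._timeline(10_000)
        power = rng.standard_normal(10_000)
        power[:5000] += 1.0
        roc = roc_state_prediction(power, tl)
        assert roc.auc == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.02)

    @pytest.mark.parametrize("transform", [
        lambda p: np.log(p - p.min() + 1.0),
        lambda p: 3.5 * p + 11.0,
        lambda p: np.exp(p / 4.0),
    ])
    def test_invariant_under_monotone_transform(self, rng, transform):
        tl = self._timeline(500)
        power = rng.standard_normal(500) + 0.7 * (tl.states == FREEZE)
        base = roc_state_prediction(power, tl).auc
        assert roc_state_prediction(transform(power), tl).auc \
            == pytest.approx(base, abs=1e-12)

    def test_insufficient_data_excluded(self):
        states = np.zeros(100, dtype=int)
        states[:2] = FREEZE  # 4 s of freezing < 10 s minimum
        tl = BehaviouralTimeline(states)
        roc = roc_state_prediction(np.random.default_rng(0).random(100), tl)
        assert roc.excluded and "10" in roc.reason

    def test_bin_band_power_alignment(self, rng):
        spec = Spectrogram(times=np.arange(0, 20, 0.1),
                           freqs=np.linspace(0, 20, 41),
                           power=np.ones((200, 41)))
        tl = BehaviouralTimeline(np.zeros(10, dtype=int))
        bp = bin_band_power(spec, tl)
        assert bp.shape == (10,)
        assert np.allclose(bp, 1.0)


class TestEpisodeProfiles:
    def test_constant_series_flat_profile(self):
        t = np.arange(0, 100, 0.1)
        prof = normalized_episode_profile(t, np.full(t.size, 3.3),
                                          [[10, 20], [40, 70]])
        assert np.allclose(prof.mean, 3.3)
        assert prof.n_episodes == 2

    def test_ramp_is_length_invariant(self):
        t = np.arange(0, 200, 0.05)
        bouts = np.array([[10.0, 20.0], [50.0, 130.0]])
        v = np.zeros_like(t)
        for e0, e1 in bouts:
            m = (t >= e0) & (t < e1)
            v[m] = (t[m] - e0) / (e1 - e0)
        prof = normalized_episode_profile(t, v, bouts)
        # the final grid point touches the bout edge; compare the interior
        assert np.allclose(prof.mean[:-2], prof.normalized_time[:-2],
                           atol=0.02)

    def test_late_rising_power_monotone_first_half(self, short_session):
        tl = short_session.timeline
        gain = short_session.entrain_gain
        t = np.arange(gain.size) / short_session.ob.rate_hz
        prof = normalized_episode_profile(
            t[::25], gain[::25], tl.bout_epochs(FREEZE), min_dur=4.0)
        first_half = prof.mean[: 50]
        # entrainment ramps up after onset: increasing trend
        assert first_half[-1] > first_half[0]
        assert np.mean(np.diff(first_half) >= -1e-9) > 0.8

    def test_no_qualifying_bouts(self):
        prof = normalized_episode_profile(np.arange(10.0), np.arange(10.0),
                                          [[0.0, 2.0]], min_dur=5.0)
        assert prof.n_episodes == 0 and prof.reason


class TestTransitionSlope:
    def test_step_steeper_than_ramp(self):
        t = np.linspace(-3, 3, 61)
        step = (t >= 0).astype(float)
        ramp = np.clip((t + 3) / 6.0, 0, 1)
        s_step = transition_slope(t, step)
        s_ramp = transition_slope(t, ramp)
        assert s_step["converged"] and s_ramp["converged"]
        assert s_step["slope"] >= s_ramp["slope"]

    def test_logistic_rate_recovered(self):
        t = np.linspace(-3, 3, 121)
        k_true = 2.5
        y = 1.0 / (1.0 + np.exp(-k_true * (t - 0.3)))
        fit = transition_slope(t, y, normalize=False)
        assert fit["k"] == pytest.approx(k_true, rel=0.05)
        assert fit["slope"] == pytest.approx(k_true / 4.0, rel=0.05)

    def test_flat_curve_flagged(self):
        fit = transition_slope(np.linspace(0, 1, 20), np.ones(20))
        assert not fit["converged"]


class TestMicromovements:
    def _coupled_session(self, slope, seed):
        n_bins = 350
        tl = BehaviouralTimeline(np.ones(n_bins, dtype=int))
        cfg = SyntheticConfig(session_duration=n_bins * 2.0,
                              micromove_power_slope=slope)
        rng = np.random.default_rng(seed)
        power = rng.uniform(0, 1, n_bins)
        pips = np.arange(1.0, n_bins * 2.0 - 1, 1.1)
        accel, truth = simulate_accelerometer(tl, power, cfg, seed=seed,
                                              cs_pips=pips)
        t_bins = np.arange(n_bins) * 2.0 + 1.0
        return accel, t_bins, power, pips, tl, truth

    def test_no_coupling_recovered_as_null(self):
        accel, t, power, pips, tl, _ = self._coupled_session(0.0, 3)
        out = micromovement_coupling(accel, t, power, pips,
                                     tl.bout_epochs(FREEZE))
        assert len(out["events"]) >= 300
        assert abs(out["r"]) < 0.1

    def test_calibrated_coupling_recovered(self):
        accel, t, power, pips, tl, truth = self._coupled_session(1.0, 4)
        out = micromovement_coupling(accel, t, power, pips,
                                     tl.bout_epochs(FREEZE))
        r_truth = np.corrcoef(truth["amplitude"], truth["power_norm"])[0, 1]
        assert out["r"] < 0
        assert out["r"] == pytest.approx(r_truth, abs=0.1)

    def test_density_declines_when_power_ramps(self, short_session):
        out = micromovement_coupling(
            short_session.accel,
            np.arange(short_session.entrain_gain.size, step=25)
            / short_session.ob.rate_hz,
            short_session.entrain_gain[::25],
            short_session.cs_pips,
            short_session.timeline.bout_epochs(FREEZE))
        d = out["density"]["density"]
        assert d[: len(d) // 2].sum() > d[len(d) // 2:].sum()

    def test_few_events_no_correlation(self):
        accel, t, power, pips, tl, _ = self._coupled_session(0.0, 5)
        out = micromovement_coupling(accel, t, power, pips[:3],
                                     tl.bout_epochs(FREEZE))
        assert np.isnan(out["r"]) and "events" in out["reason"]


class TestSplitEpisodeSpectra:
    def _spec(self, bouts, grow):
        times = np.arange(0, 200, 0.5)
        freqs = np.linspace(0, 20, 41)
        band = (freqs >= 3) & (freqs <= 6)
        power = np.ones((times.size, freqs.size))
        for e0, e1 in bouts:
            m = (times >= e0) & (times < e1)
            level = 1.0 + (times[m] - e0) / 3.0 if grow else \
                np.full(m.sum(), 5.0)
            power[np.ix_(m, band)] = level[:, None] * 5.0
        return Spectrogram(times=times, freqs=freqs, power=power)

    def test_growing_power_long_above_short(self):
        bouts = np.array([[10.0, 16.0], [30.0, 38.0], [60.0, 90.0],
                          [120.0, 150.0]])
        out = split_episode_spectra(self._spec(bouts, grow=True), bouts)
        assert out["long"]["band_snr"] > out["short"]["band_snr"]

    def test_stationary_power_classes_agree(self):
        bouts = np.array([[10.0, 16.0], [30.0, 38.0], [60.0, 90.0]])
        out = split_episode_spectra(self._spec(bouts, grow=False), bouts)
        assert out["long"]["band_snr"] == pytest.approx(
            out["short"]["band_snr"], rel=0.1)

    def test_cutoff_beyond_max_all_short(self):
        bouts = np.array([[10.0, 16.0], [30.0, 38.0]])
        out = split_episode_spectra(self._spec(bouts, grow=False), bouts,
                                    cutoff=100.0)
        assert out["long"] is None
        assert out["short"]["n_episodes"] == 2
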