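"""Spectral analysis of the 4 Hz respiratory rhythm.

Multitaper spectrograms and coherence (Slepian tapers, 3 s windows with a
0.1 s shift, 5 tapers), band signal-to-noise ratio, parametric spectral
Granger causality, ROC prediction of behavioural state from 2 s-binned
band power, duration-normalized freezing-episode profiles, sigmoid
transition slopes, and accelerometer micromovement–power coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from scipy.optimize import curve_fit
from statsmodels.tsa.api import VAR

from .core import TimeSeriesSignal
from .markov import FREEZE, BehaviouralTimeline

DEFAULT_BAND = (3.0, 6.0)


@dataclass
class Spectrogram:
    """Multitaper time–frequency power estimate."""

    times: np.ndarray           # window centres, s
    freqs: np.ndarray           # Hz
    power: np.ndarray           # (n_times, n_freqs), >= 0
    params: dict = field(default_factory=dict)
    normalized: bool = False

    def band_power(self, band=DEFAULT_BAND) -> np.ndarray:
        m = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not m.any():
            raise ValueError("band outside frequency range")
        return self.power[:, m].mean(axis=1)

    def mean_spectrum(self, time_mask=None) -> np.ndarray:
        p = self.power if time_mask is None else self.power[time_mask]
        return p.mean(axis=0)

    def normalize_total_power(self) -> "Spectrogram":
        """Divide by total power so the subject contributes equally to
        group averages; within-subject band ratios are unchanged."""
        total = self.power.sum()
        return Spectrogram(self.times, self.freqs, self.power / total,
                           params=dict(self.params), normalized=True)


def _taper_frames(x: np.ndarray, fs: float, window_s: float, step_s: float,
                  n_tapers: int, nw: float = 3.0):
    n_win = int(round(window_s * fs))
    if x.size < n_win:
        raise ValueError("signal shorter than one analysis window")
    step = max(1, int(round(step_s * fs)))
    tapers = sps.windows.dpss(n_win, nw, Kmax=n_tapers)  # (K, n_win)
    n_frames = 1 + (x.size - n_win) // step
    starts = np.arange(n_frames) * step
    nfft = int(2 ** np.ceil(np.log2(n_win)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    times = (starts + n_win / 2.0) / fs
    return starts, n_win, tapers, nfft, freqs, times


def _chunked_ffts(x, starts, n_win, tapers, nfft, chunk=256):
    """Yield (slice, fft array of shape (chunk, K, n_freq))."""
    for i in range(0, starts.size, chunk):
        s = starts[i:i + chunk]
        frames = np.stack([x[a:a + n_win] for a in s])      # (c, n_win)
        tf = frames[:, None, :] * tapers[None, :, :]        # (c, K, n_win)
        yield slice(i, i + s.size), np.fft.rfft(tf, n=nfft, axis=-1)


def multitaper_spectrogram(
    sig: TimeSeriesSignal,
    window_s: float = 3.0,
    step_s: float = 0.1,
    n_tapers: int = 5,
    nw: float = 3.0,
    fmax: float | None = None,
) -> Spectrogram:
    """Slepian-taper averaged power spectrogram.

    Power is a one-sided density scaled so that summing over frequencies
    times the bin width recovers the windowed signal variance (Parseval).
    """
    x = sig.data
    fs = sig.rate_hz
    starts, n_win, tapers, nfft, freqs, times = _taper_frames(
        x, fs, window_s, step_s, n_tapers, nw)
    keep = slice(None) if fmax is None else freqs <= fmax
    power = np.empty((starts.size, freqs[keep].size))
    scale = 2.0 / fs  # dpss tapers have unit energy, so no 1/N factor
    for sl, F in _chunked_ffts(x, starts, n_win, tapers, nfft):
        p = (np.abs(F) ** 2).mean(axis=1) * scale
        p[:, 0] /= 2.0
        if nfft % 2 == 0:
            p[:, -1] /= 2.0
        power[sl] = p[:, keep]
    return Spectrogram(
        times=times + sig.t0, freqs=freqs[keep], power=power,
        params={"window_s": window_s, "step_s": step_s,
                "n_tapers": n_tapers, "nw": nw},
    )


def band_snr(freqs: np.ndarray, spectrum: np.ndarray,
             band=DEFAULT_BAND) -> float:
    """Mean per-frequency power inside the band over the mean outside it.

    Unity for a flat spectrum regardless of bandwidth; ≫ 1 when a
    spectral peak sits in the band.
    """
    freqs = np.asarray(freqs)
    spectrum = np.asarray(spectrum)
    inside = (freqs >= band[0]) & (freqs <= band[1])
    if not inside.any():
        raise ValueError("empty band")
    if inside.all():
        raise ValueError("band covers the whole spectrum")
    return float(spectrum[inside].mean() / spectrum[~inside].mean())


def coherence(
    sig_a: TimeSeriesSignal,
    sig_b: TimeSeriesSignal,
    window_s: float = 3.0,
    step_s: float = 0.1,
    n_tapers: int = 5,
    nw: float = 3.0,
    band=DEFAULT_BAND,
    epochs: np.ndarray | None = None,
    fmax: float | None = None,
) -> dict:
    """Magnitude-squared multitaper coherence, optionally epoch-restricted.

    Cross- and auto-spectra are averaged over tapers and over all windows
    lying fully inside the given epochs before forming
    ``|Sxy|^2 / (Sxx Syy)``.
    """
    if sig_a.rate_hz != sig_b.rate_hz or sig_a.n_samples != sig_b.n_samples:
        raise ValueError("signals must share sampling rate and length")
    fs = sig_a.rate_hz
    starts, n_win, tapers, nfft, freqs, times = _taper_frames(
        sig_a.data, fs, window_s, step_s, n_tapers, nw)
    times = times + sig_a.t0
    if epochs is not None:
        epochs = np.atleast_2d(epochs)
        half = n_win / 2.0 / fs
        ok = np.zeros(starts.size, dtype=bool)
        for e0, e1 in epochs:
            ok |= (times - half >= e0) & (times + half <= e1)
        starts = starts[ok]
        if starts.size == 0:
            raise ValueError("no analysis window fits inside the epochs")
    keep = slice(None) if fmax is None else freqs <= fmax
    nf = freqs[keep].size
    sxx = np.zeros(nf)
    syy = np.zeros(nf)
    sxy = np.zeros(nf, dtype=complex)
    gen_a = _chunked_ffts(sig_a.data, starts, n_win, tapers, nfft)
    gen_b = _chunked_ffts(sig_b.data, starts, n_win, tapers, nfft)
    for (sl, Fa), (_, Fb) in zip(gen_a, gen_b):
        Fa = Fa[..., keep]
        Fb = Fb[..., keep]
        sxx += (np.abs(Fa) ** 2).sum(axis=(0, 1))
        syy += (np.abs(Fb) ** 2).sum(axis=(0, 1))
        sxy += (Fa * np.conj(Fb)).sum(axis=(0, 1))
    coh = np.abs(sxy) ** 2 / np.maximum(sxx * syy, 1e-300)
    coh = np.clip(coh, 0.0, 1.0)
    fr = freqs[keep]
    m = (fr >= band[0]) & (fr <= band[1])
    return {"freqs": fr, "coherence": coh,
            "band_mean": float(coh[m].mean()), "n_windows": int(starts.size)}


# ---------------------------------------------------------------------------
# Granger causality


def _spectral_granger_from_var(coefs: np.ndarray, sigma: np.ndarray,
                               fs: float, freqs: np.ndarray):
    """Geweke frequency-domain causality from VAR coefficients.

    For the bivariate system with transfer function H(f) and residual
    covariance S, influence x->y at f is
    ln( Syy / (Syy - (Sxx - Sxy^2/Syy_noise) |Hyx|^2) ).
    """
    order = coefs.shape[0]
    eye = np.eye(2)
    g_xy = np.empty(freqs.size)
    g_yx = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        a = eye.astype(complex).copy()
        for k in range(order):
            a -= coefs[k] * np.exp(-2j * np.pi * f * (k + 1) / fs)
        h = np.linalg.inv(a)
        s = h @ sigma @ h.conj().T
        s00 = max(s[0, 0].real, 1e-300)
        s11 = max(s[1, 1].real, 1e-300)
        # x (index 0) -> y (index 1)
        num = sigma[0, 0] - sigma[0, 1] ** 2 / sigma[1, 1]
        g_xy[i] = np.log(s11 / max(s11 - num * np.abs(h[1, 0]) ** 2, 1e-300))
        num = sigma[1, 1] - sigma[0, 1] ** 2 / sigma[0, 0]
        g_yx[i] = np.log(s00 / max(s00 - num * np.abs(h[0, 1]) ** 2, 1e-300))
    return g_xy, g_yx


def granger_band(
    sig_a: TimeSeriesSignal,
    sig_b: TimeSeriesSignal,
    band=DEFAULT_BAND,
    max_order: int = 20,
    target_rate: float = 250.0,
    epochs: np.ndarray | None = None,
    surrogate: bool = False,
) -> dict:
    """Band-averaged spectral Granger causality in both directions.

    Signals are decimated to ``target_rate``, optionally restricted to
    concatenated epochs (e.g. freezing periods), a joint VAR is fitted
    with the order chosen by BIC (capped at ``max_order``), and Geweke's
    frequency-domain measure is averaged over the band.  With
    ``surrogate`` a time-reversed control gives a bias threshold.
    """
    if sig_a.rate_hz != sig_b.rate_hz:
        raise ValueError("signals must share sampling rate")
    fs = sig_a.rate_hz
    q = max(1, int(round(fs / target_rate)))
    a = sps.decimate(sig_a.data, q, ftype="fir") if q > 1 else sig_a.data
    b = sps.decimate(sig_b.data, q, ftype="fir") if q > 1 else sig_b.data
    fs_d = fs / q
    if epochs is not None:
        keep = np.zeros(a.size, dtype=bool)
        tt = sig_a.t0 + np.arange(a.size) / fs_d
        for e0, e1 in np.atleast_2d(epochs):
            keep |= (tt >= e0) & (tt < e1)
        a, b = a[keep], b[keep]
    data = np.column_stack([a - a.mean(), b - b.mean()])
    model = VAR(data)
    try:
        order = int(model.select_order(maxlags=max_order).bic)
    except Exception:
        order = min(max_order, 10)
    order = max(1, order)
    if data.shape[0] < 10 * order:
        raise ValueError("segment too short for the selected VAR order")
    res = model.fit(order)
    if not res.is_stable():
        raise ValueError("unstable VAR fit; Granger estimate unreliable")
    freqs = np.linspace(band[0], band[1], 25)
    g_ab, g_ba = _spectral_granger_from_var(res.coefs, res.sigma_u, fs_d, freqs)
    out = {
        "g_a_to_b": float(g_ab.mean()),
        "g_b_to_a": float(g_ba.mean()),
        "order": order,
        "freqs": freqs,
        "spectrum_a_to_b": g_ab,
        "spectrum_b_to_a": g_ba,
    }
    if surrogate:
        rev = np.column_stack([data[::-1, 0], data[::-1, 1]])
        res_r = VAR(rev).fit(order)
        s_ab, s_ba = _spectral_granger_from_var(
            res_r.coefs, res_r.sigma_u, fs_d, freqs)
        out["surrogate_threshold"] = float(max(s_ab.mean(), s_ba.mean()))
    return out


# ---------------------------------------------------------------------------
# ROC state prediction


@dataclass
class ROCResult:
    """Ideal-observer discrimination of freezing from band power."""

    thresholds: np.ndarray
    alpha: np.ndarray      # false-alarm rate P(r > z | active)
    beta: np.ndarray       # hit rate P(r > z | freezing)
    auc: float
    n_freeze: int
    n_active: int
    excluded: bool = False
    reason: str = ""


def roc_state_prediction(
    band_power: np.ndarray,
    timeline: BehaviouralTimeline,
    min_each: float = 10.0,
) -> ROCResult:
    """ROC analysis of 2 s-binned band power as a freezing predictor.

    Thresholds sweep the observed unique power values plus ±inf; a bin is
    called freezing when its power exceeds the threshold.  The trapezoidal
    area under hit rate vs false-alarm rate equals the probability that an
    ideal observer discriminates a freezing from an active bin: 0.5 when
    power carries no information, 1 when the distributions are perfectly
    separated.  Sessions with under ``min_each`` seconds of either state
    are excluded with a reason rather than scored.
    """
    power = np.asarray(band_power, dtype=float)
    if power.size != timeline.n_bins:
        raise ValueError("band power must be binned on the timeline grid")
    fz = power[timeline.states == FREEZE]
    act = power[timeline.states != FREEZE]
    need = int(np.ceil(min_each / timeline.bin_width))
    if fz.size < need or act.size < need:
        return ROCResult(np.empty(0), np.empty(0), np.empty(0),
                         float("nan"), fz.size, act.size, excluded=True,
                         reason=f"fewer than {min_each:g} s of one state")
    z = np.concatenate(([-np.inf], np.unique(power), [np.inf]))
    beta = np.array([(fz > zi).mean() for zi in z])
    alpha = np.array([(act > zi).mean() for zi in z])
    auc = float(np.trapezoid(beta[::-1], alpha[::-1]))
    return ROCResult(z, alpha, beta, auc, fz.size, act.size)


def bin_band_power(spec: Spectrogram, timeline: BehaviouralTimeline,
                   band=DEFAULT_BAND) -> np.ndarray:
    """Average spectrogram band power into the timeline's 2 s bins."""
    bp = spec.band_power(band)
    idx = ((spec.times - timeline.t0) / timeline.bin_width).astype(int)
    ok = (idx >= 0) & (idx < timeline.n_bins)
    out = np.zeros(timeline.n_bins)
    counts = np.bincount(idx[ok], minlength=timeline.n_bins)
    sums = np.bincount(idx[ok], weights=bp[ok], minlength=timeline.n_bins)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    if (~nz).any():
        out[~nz] = out[nz].mean() if nz.any() else 0.0
    return out


# ---------------------------------------------------------------------------
# normalized episode dynamics


@dataclass
class EpisodeProfile:
    """Mean ± SEM of a series over duration-normalized episodes."""

    normalized_time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_episodes: int
    pre_flank: dict | None = None
    post_flank: dict | None = None
    reason: str = ""


def normalized_episode_profile(
    times: np.ndarray,
    values: np.ndarray,
    bout_epochs: np.ndarray,
    n_bins: int = 100,
    min_dur: float = 0.0,
    flank_s: float | None = None,
    flank_bins: int = 20,
) -> EpisodeProfile:
    """Resample a series onto a duration-normalized grid per episode.

    Each qualifying bout is linearly interpolated onto ``n_bins`` points
    spanning its own duration, so episodes of any length contribute one
    trace each; optional un-normalized flanks of ``flank_s`` seconds are
    sampled on a fixed real-time grid.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    grid = np.linspace(0.0, 1.0, n_bins)
    rows, pre_rows, post_rows = [], [], []
    for e0, e1 in np.atleast_2d(bout_epochs):
        if e1 - e0 < min_dur:
            continue
        rows.append(np.interp(e0 + grid * (e1 - e0), times, values))
        if flank_s is not None:
            tpre = np.linspace(e0 - flank_s, e0, flank_bins, endpoint=False)
            tpost = np.linspace(e1, e1 + flank_s, flank_bins, endpoint=False)
            pre_rows.append(np.interp(tpre, times, values))
            post_rows.append(np.interp(tpost, times, values))
    if not rows:
        return EpisodeProfile(grid, np.full(n_bins, np.nan),
                              np.full(n_bins, np.nan), 0,
                              reason="no qualifying bouts")
    arr = np.vstack(rows)
    prof = EpisodeProfile(
        normalized_time=grid,
        mean=arr.mean(axis=0),
        sem=arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        if arr.shape[0] > 1 else np.zeros(n_bins),
        n_episodes=arr.shape[0],
    )
    if flank_s is not None:
        for name, rws, t_rel in (
            ("pre_flank", pre_rows, np.linspace(-flank_s, 0, flank_bins,
                                                endpoint=False)),
            ("post_flank", post_rows, np.linspace(0, flank_s, flank_bins,
                                                  endpoint=False)),
        ):
            a = np.vstack(rws)
            setattr(prof, name, {
                "time_s": t_rel, "mean": a.mean(axis=0),
                "sem": a.std(axis=0, ddof=1) / np.sqrt(a.shape[0])
                if a.shape[0] > 1 else np.zeros(flank_bins),
            })
    return prof


def _logistic(t, base, amp, k, t0):
    return base + amp / (1.0 + np.exp(-k * (t - t0)))


def transition_slope(t: np.ndarray, y: np.ndarray,
                     normalize: bool = True) -> dict:
    """Transition speed via a 4-parameter logistic fit.

    The curve is optionally normalized to [0, 1]; the reported slope is
    the maximal derivative magnitude ``|k * amp| / 4``.  Non-convergence
    is flagged rather than raised.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if normalize:
        rng_ = y.max() - y.min()
        if rng_ <= 0:
            return {"converged": False, "slope": float("nan"),
                    "reason": "flat curve"}
        y = (y - y.min()) / rng_
    rising = y[-1] >= y[0]
    p0 = [y.min() if rising else y.max(),
          (1.0 if rising else -1.0) * (y.max() - y.min()),
          4.0 / max(t[-1] - t[0], 1e-9), float(t[np.argmin(np.abs(y - 0.5))])]
    try:
        popt, _ = curve_fit(_logistic, t, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError):
        return {"converged": False, "slope": float("nan"),
                "reason": "fit did not converge"}
    base, amp, k, t0 = popt
    return {"converged": True, "base": float(base), "amp": float(amp),
            "k": float(k), "t0": float(t0),
            "slope": float(abs(k * amp) / 4.0),
            "fitted": _logistic(t, *popt)}


# ---------------------------------------------------------------------------
# micromovements


def micromovement_coupling(
    accel: TimeSeriesSignal,
    power_times: np.ndarray,
    power_values: np.ndarray,
    cs_pips: np.ndarray,
    freeze_epochs: np.ndarray,
    window_s: float = 0.2,
    threshold: float | None = None,
    min_events: int = 10,
    density_bins: int = 10,
) -> dict:
    """Pip-locked micromovement detection and power coupling.

    For each CS pip inside a freezing bout, the peak |acceleration| in a
    ±``window_s`` window is taken; windows whose peak clears a threshold
    (default six times the median freezing |acceleration|) count as
    micromovement events.  Event amplitude is correlated (Pearson) with
    the normalized band power interpolated at the event time, and event
    density is profiled over normalized episode time.
    """
    freeze_epochs = np.atleast_2d(freeze_epochs)
    tt = accel.times
    absa = np.abs(accel.data)
    fz_mask = np.zeros(tt.size, dtype=bool)
    for e0, e1 in freeze_epochs:
        fz_mask |= (tt >= e0) & (tt < e1)
    if threshold is None:
        base = np.median(absa[fz_mask]) if fz_mask.any() else np.median(absa)
        threshold = 6.0 * base
    pv = np.asarray(power_values, dtype=float)
    lo, hi = np.percentile(pv, [5, 95])
    pnorm = np.clip((pv - lo) / max(hi - lo, 1e-12), 0, 1)

    rows = []
    for t_pip in np.asarray(cs_pips, dtype=float):
        inside = [(e0, e1) for e0, e1 in freeze_epochs if e0 <= t_pip < e1]
        if not inside:
            continue
        e0, e1 = inside[0]
        i0 = max(0, int((t_pip - window_s - accel.t0) * accel.rate_hz))
        i1 = min(tt.size, int((t_pip + window_s - accel.t0) * accel.rate_hz))
        if i1 <= i0:
            continue
        amp = float(absa[i0:i1].max())
        if amp < threshold:
            continue
        pos = (t_pip - e0) / (e1 - e0)
        p = float(np.interp(t_pip, power_times, pnorm))
        rows.append((t_pip, amp, p, pos))
    events = pd.DataFrame(rows, columns=["time_s", "amplitude",
                                         "power_norm", "episode_pos"])
    out = {"events": events, "r": float("nan"), "p_value": float("nan"),
           "density": None}
    if len(events) >= min_events:
        r, p = stats.pearsonr(events["amplitude"], events["power_norm"])
        out["r"], out["p_value"] = float(r), float(p)
        edges = np.linspace(0, 1, density_bins + 1)
        counts, _ = np.histogram(events["episode_pos"], bins=edges)
        out["density"] = {
            "bin_centres": (edges[:-1] + edges[1:]) / 2,
            "count": counts,
            "density": counts / max(counts.sum(), 1),
        }
    else:
        out["reason"] = f"only {len(events)} events (< {min_events})"
    return out


def split_episode_spectra(
    spec: Spectrogram,
    bout_epochs: np.ndarray,
    cutoff: float = 10.0,
    band=DEFAULT_BAND,
) -> dict:
    """Average spectra and band SNR for short (<cutoff) vs long episodes."""
    bout_epochs = np.atleast_2d(bout_epochs)
    durs = bout_epochs[:, 1] - bout_epochs[:, 0]
    out = {"freqs": spec.freqs, "cutoff_s": float(cutoff)}
    for name, sel in (("short", durs < cutoff), (("long"), durs >= cutoff)):
        if not sel.any():
            out[name] = None
            out.setdefault("flags", []).append(f"no {name} episodes")
            continue
        mask = np.zeros(spec.times.size, dtype=bool)
        for e0, e1 in bout_epochs[sel]:
            mask |= (spec.times >= e0) & (spec.times < e1)
        if not mask.any():
            out[name] = None
            out.setdefault("flags", []).append(
                f"no spectrogram bins in {name} episodes")
            continue
        spectrum = spec.power[mask].mean(axis=0)
        out[name] = {
            "spectrum": spectrum,
            "band_snr": band_snr(spec.freqs, spectrum, band),
            "n_episodes": int(sel.sum()),
        }
    return out
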