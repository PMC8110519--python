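"""Spike–LFP phase locking.

Two instantaneous-phase estimators (narrow-band Hilbert, and broadband
peak–trough interpolation that follows a rhythm whose frequency wanders
between 2 and 15 Hz), circular statistics on spike phases (Rayleigh test
on Z = R²/n, von Mises concentration kappa, pairwise phase consistency),
an occupancy-equalization correction for asymmetric oscillation
waveforms, duration- and rate-matched state comparisons, the bounded
modulation index, and waveform-based cell-type clustering.

Phase convention: 0 at the LFP peak, π at the trough, for both methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.cluster import KMeans

from .core import SpikeTrain, TimeSeriesSignal

TWO_PI = 2.0 * np.pi


@dataclass
class PhaseSeries:
    """Instantaneous phase on the analysis interval.

    ``phase_unwrapped`` is monotone; ``phase`` is its value wrapped to
    [0, 2π), with 0 at LFP peaks and π at troughs.
    """

    times: np.ndarray
    phase_unwrapped: np.ndarray
    method: str
    reconstruction_mse: float | None = None

    @property
    def phase(self) -> np.ndarray:
        return np.mod(self.phase_unwrapped, TWO_PI)

    def at(self, t: np.ndarray) -> np.ndarray:
        """Interpolated wrapped phase at arbitrary times."""
        return np.mod(np.interp(t, self.times, self.phase_unwrapped), TWO_PI)

    def instantaneous_frequency(self) -> np.ndarray:
        return np.gradient(self.phase_unwrapped, self.times) / TWO_PI


@dataclass
class UnitPhaseStats:
    """Per-unit phase-locking summary."""

    unit_id: str
    n_spikes: int
    resultant_length: float          # R, in [0, n]
    log_z: float                     # ln(R^2 / n)
    p_rayleigh: float
    kappa: float
    ppc: float
    preferred_phase: float           # radians in [0, 2pi)
    corrected: bool = False


def _bandpass(x: np.ndarray, fs: float, band: tuple, order: int = 4):
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError("band upper edge at or above Nyquist")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def hilbert_phase(sig: TimeSeriesSignal, band=(4.0, 6.0)) -> PhaseSeries:
    """Analytic-signal phase of the band-passed LFP.

    For x = A cos(φ) the analytic signal is A e^{iφ}, so the angle is
    already 0 at peaks; it is unwrapped for interpolation.
    """
    filt = _bandpass(sig.data, sig.rate_hz, band)
    phase = np.unwrap(np.angle(sps.hilbert(filt)))
    return PhaseSeries(times=sig.times, phase_unwrapped=phase,
                       method=f"hilbert_{band[0]:g}_{band[1]:g}")


def peak_trough_phase(
    sig: TimeSeriesSignal,
    band=(1.0, 20.0),
    prominence_sd: float = 0.5,
    min_separation: float | None = None,
) -> PhaseSeries:
    """Phase by linear interpolation between detected peaks and troughs.

    The signal is filtered broadband (1–20 Hz), local peaks (phase 0) and
    troughs (phase π) are detected, and phase advances linearly between
    consecutive extrema — so the estimate tracks a rhythm whose frequency
    changes too fast for any fixed narrow band.  A reconstruction
    ``amplitude(t)·cos(phase(t))`` from the detected extrema gives a mean
    squared error quantifying how well the phase captures the signal.
    """
    fs = sig.rate_hz
    filt = _bandpass(sig.data, fs, band)
    prom = prominence_sd * filt.std()
    if min_separation is None:
        min_separation = 1.0 / (2.0 * band[1])
    dist = max(1, int(round(min_separation * fs)))
    peaks, _ = sps.find_peaks(filt, prominence=prom, distance=dist)
    troughs, _ = sps.find_peaks(-filt, prominence=prom, distance=dist)
    if peaks.size == 0 or troughs.size == 0:
        raise ValueError("no extrema detected; cannot build phase")

    idx = np.concatenate([peaks, troughs])
    kind = np.concatenate([np.zeros(peaks.size, int), np.ones(troughs.size, int)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    # enforce strict alternation: within a run of same-kind extrema keep the
    # most extreme one
    keep_idx, keep_kind = [idx[0]], [kind[0]]
    for i, k in zip(idx[1:], kind[1:]):
        if k == keep_kind[-1]:
            better = filt[i] > filt[keep_idx[-1]] if k == 0 else filt[i] < filt[keep_idx[-1]]
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
            keep_kind.append(k)
    idx = np.asarray(keep_idx)
    kind = np.asarray(keep_kind)
    # unwrapped phase at extrema: each step peak->trough or trough->peak is pi
    phase_ext = np.pi * np.arange(idx.size) + (0.0 if kind[0] == 0 else np.pi)
    t_ext = idx / fs + sig.t0

    times = sig.times
    phase = np.interp(times, t_ext, phase_ext)
    amp = np.interp(times, t_ext, np.abs(filt[idx]))
    recon = amp * np.cos(phase)
    inside = (times >= t_ext[0]) & (times <= t_ext[-1])
    mse = float(np.mean((recon[inside] - filt[inside]) ** 2))
    return PhaseSeries(times=times, phase_unwrapped=phase,
                       method=f"peak_trough_{band[0]:g}_{band[1]:g}",
                       reconstruction_mse=mse)


def spike_phases(spikes: SpikeTrain, phase: PhaseSeries,
                 epochs: np.ndarray | None = None) -> np.ndarray:
    """Wrapped phase of each spike falling inside the epochs."""
    t = spikes.times if epochs is None else spikes.in_epochs(epochs)
    t = t[(t >= phase.times[0]) & (t <= phase.times[-1])]
    return phase.at(t)


# ---------------------------------------------------------------------------
# circular statistics


def resultant(phases: np.ndarray) -> tuple[float, float]:
    """(resultant length R, circular mean) of a phase sample."""
    z = np.exp(1j * np.asarray(phases))
    s = z.sum()
    return float(np.abs(s)), float(np.mod(np.angle(s), TWO_PI))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh uniformity test.

    Returns (logZ, p) with Z = R²/n and the standard finite-n series
    approximation for p; logZ is the variance-stabilized statistic used
    for population comparisons.
    """
    phases = np.asarray(phases)
    n = phases.size
    if n < 2:
        raise ValueError("need at least 2 phases")
    r, _ = resultant(phases)
    z = r ** 2 / n
    p = np.exp(-z) * (
        1 + (2 * z - z ** 2) / (4 * n)
        - (24 * z - 132 * z ** 2 + 76 * z ** 3 - 9 * z ** 4) / (288 * n ** 2)
    )
    p = float(np.clip(p, np.finfo(float).tiny, 1.0))
    return float(np.log(max(z, np.finfo(float).tiny))), p


def kappa_ml(phases: np.ndarray) -> float:
    """Maximum-likelihood von Mises concentration.

    Inverts the Bessel ratio A(κ) = I1/I0 = R̄ with the standard
    piecewise approximation.
    """
    phases = np.asarray(phases)
    if phases.size < 2:
        raise ValueError("need at least 2 phases")
    rbar = resultant(phases)[0] / phases.size
    if rbar < 0.53:
        return float(2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6)
    if rbar < 0.85:
        return float(-0.4 + 1.39 * rbar + 0.43 / (1 - rbar))
    return float(1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar))


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency: mean over pairs of cos(θi − θj).

    Computed with the O(n) identity (R² − n) / (n(n−1)); unbiased by
    spike count, 0 in expectation under uniformity, 1 for identical
    phases, with minimum −1/(n−1).
    """
    phases = np.asarray(phases)
    n = phases.size
    if n < 2:
        raise ValueError("need at least 2 phases")
    r, _ = resultant(phases)
    return float((r ** 2 - n) / (n * (n - 1)))


def unit_phase_stats(phases: np.ndarray, unit_id: str = "",
                     corrected: bool = False) -> UnitPhaseStats:
    """All circular statistics for one unit's phase sample."""
    r, mean = resultant(phases)
    log_z, p = rayleigh_test(phases)
    return UnitPhaseStats(
        unit_id=unit_id, n_spikes=int(np.size(phases)),
        resultant_length=r, log_z=log_z, p_rayleigh=p,
        kappa=kappa_ml(phases), ppc=ppc(phases), preferred_phase=mean,
        corrected=corrected,
    )


def modulation_index(x1: float, x2: float) -> float:
    """Bounded contrast (x1 − x2) / (x1 + x2) ∈ [−1, 1] for x1, x2 ≥ 0."""
    if x1 + x2 == 0:
        raise ValueError("modulation index undefined for x1 = x2 = 0")
    return (x1 - x2) / (x1 + x2)


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Chi-squared comparison of two proportions (2×2 table, continuity
    corrected), e.g. fractions of significantly phase-modulated units."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=True)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}


# ---------------------------------------------------------------------------
# asymmetry correction


def asymmetry_correction(spike_ph: np.ndarray,
                         lfp_phase_sample: np.ndarray) -> np.ndarray:
    """Equalize phase occupancy before locking statistics.

    An asymmetric oscillation spends unequal time per phase bin, so even
    a unit firing uniformly in time looks phase locked.  Spike phases are
    mapped through the empirical CDF of the LFP's own phase occupancy,
    θ → 2π·F(θ), after which time spent per corrected-phase bin is
    uniform and uniform-in-time firing maps to uniform phases.
    """
    lfp = np.sort(np.mod(np.asarray(lfp_phase_sample), TWO_PI))
    if lfp.size < 10 or lfp[-1] - lfp[0] < 1e-9:
        raise ValueError("degenerate LFP phase occupancy")
    sp = np.mod(np.asarray(spike_ph), TWO_PI)
    ranks = np.searchsorted(lfp, sp, side="right")
    return TWO_PI * ranks / lfp.size


# ---------------------------------------------------------------------------
# matched state comparison


def matched_active_window(movement: TimeSeriesSignal, active_epochs: np.ndarray,
                          duration: float) -> np.ndarray:
    """Contiguous highest-movement active stretch of the given duration.

    Slides a window of ``duration`` seconds over each active epoch and
    returns the placement maximizing mean movement — the duration control
    for freeze/active locking comparisons.
    """
    best, best_val = None, -np.inf
    fs = movement.rate_hz
    w = int(round(duration * fs))
    for e0, e1 in np.atleast_2d(active_epochs):
        seg = movement.slice(e0, e1)
        if seg.n_samples < w or w == 0:
            continue
        c = np.convolve(seg.data, np.ones(w) / w, mode="valid")
        i = int(np.argmax(c))
        if c[i] > best_val:
            best_val = c[i]
            best = (seg.t0 + i / fs, seg.t0 + (i + w) / fs)
    if best is None:
        raise ValueError("no active epoch long enough for the matched window")
    return np.asarray([best])


def matched_state_comparison(
    spikes: SpikeTrain,
    phase: PhaseSeries,
    freeze_epochs: np.ndarray,
    active_epochs: np.ndarray,
    n_boot: int = 200,
    seed=None,
    min_spikes: int = 20,
    lfp_phase_occupancy: dict | None = None,
) -> dict:
    """Rate- and duration-matched phase-locking comparison across states.

    The caller supplies duration-matched epochs (see
    :func:`matched_active_window`).  The state with more spikes is
    subsampled without replacement to the other's count, ``n_boot``
    times; the median kappa and PPC over bootstraps is reported so firing
    -rate differences cannot masquerade as locking differences.  Units
    with too few spikes in either state are excluded with a reason.
    """
    rng = np.random.default_rng(seed)
    ph = {
        "freeze": spike_phases(spikes, phase, freeze_epochs),
        "active": spike_phases(spikes, phase, active_epochs),
    }
    if lfp_phase_occupancy is not None:
        ph = {k: asymmetry_correction(v, lfp_phase_occupancy[k])
              for k, v in ph.items()}
    n_min = min(ph["freeze"].size, ph["active"].size)
    if n_min < min_spikes:
        return {"excluded": True,
                "reason": f"only {n_min} spikes in one state (< {min_spikes})"}
    out = {"excluded": False, "n_matched": int(n_min)}
    for state, sample in ph.items():
        if sample.size == n_min:
            out[state] = {"kappa": kappa_ml(sample), "ppc": ppc(sample),
                          "n_spikes": int(sample.size)}
        else:
            kap = np.empty(n_boot)
            pp = np.empty(n_boot)
            for b in range(n_boot):
                sub = rng.choice(sample, size=n_min, replace=False)
                kap[b] = kappa_ml(sub)
                pp[b] = ppc(sub)
            out[state] = {"kappa": float(np.median(kap)),
                          "ppc": float(np.median(pp)),
                          "n_spikes": int(sample.size)}
    out["delta_kappa"] = out["freeze"]["kappa"] - out["active"]["kappa"]
    out["delta_ppc"] = out["freeze"]["ppc"] - out["active"]["ppc"]
    return out


# ---------------------------------------------------------------------------
# cell-type classification


@dataclass
class WaveformFeatures:
    """Waveform descriptors used for putative cell typing."""

    half_amplitude_duration: float   # ms
    trough_to_peak: float            # ms
    asymmetry_index: float           # in [-1, 1]
    cell_class: str = ""

    def __post_init__(self) -> None:
        if self.half_amplitude_duration <= 0 or self.trough_to_peak <= 0:
            raise ValueError("waveform durations must be positive")


def classify_cell_type(
    features: np.ndarray,
    reference_pool: np.ndarray | None = None,
    random_state: int = 0,
) -> dict:
    """Two-cluster cell typing on z-scored waveform features.

    ``features`` is (n_units, 3): half-amplitude duration, trough-to-peak
    latency, asymmetry index.  Units (optionally pooled with a larger
    reference set for robustness) are k-means clustered into two groups;
    the cluster with the longer mean trough-to-peak latency is labelled
    putative pyramidal, the other putative interneuron.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.isfinite(features).all():
        raise ValueError("waveform features must be finite")
    pool = features if reference_pool is None else np.vstack(
        [features, np.atleast_2d(reference_pool)])
    if pool.shape[0] < 2:
        raise ValueError("need at least 2 units (or a reference pool)")
    sd = pool.std(axis=0)
    degenerate = {"labels": np.array(["putative_pyramidal"]
                                     * features.shape[0]),
                  "degenerate": True,
                  "reason": "single-cluster degeneracy"}
    if np.any(sd <= 1e-9 * (np.abs(pool.mean(axis=0)) + 1.0)):
        return degenerate
    z = (pool - pool.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(z)
    lab = km.labels_
    if len(np.unique(lab)) < 2:
        return degenerate
    t2p = [pool[lab == c, 1].mean() for c in (0, 1)]
    pyr_cluster = int(np.argmax(t2p))
    names = np.where(lab == pyr_cluster, "putative_pyramidal",
                     "putative_interneuron")
    return {"labels": names[: features.shape[0]],
            "pool_labels": names, "degenerate": False,
            "frac_pyramidal": float(np.mean(names == "putative_pyramidal"))}
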