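"""Synthetic session generator.

Produces every input the analysis pipeline consumes, with the statistical
structure the analyses assume, so the full pipeline is testable without
any recorded data:

* a Markov-driven freeze/active timeline at 2 s resolution;
* breathing synthesized cycle by cycle — narrow-band ~4 Hz with enlarged
  tidal volume during freezing, irregular 3–12 Hz otherwise — so the
  per-cycle frequency/volume table is exact ground truth;
* olfactory-bulb (OB) and dorsomedial prefrontal (dmPFC) LFPs entrained
  by the breathing phase, the dmPFC receiving a delayed, attenuated copy
  of the OB oscillatory component (directional OB→dmPFC coupling) plus
  independent 1/f noise;
* spike trains as inhomogeneous point processes with von Mises phase
  locking to the OB rhythm and sustained/transition freezing responses;
* an accelerometer trace whose pip-triggered micromovement amplitude
  decreases with instantaneous 4 Hz power, and a separate video-like
  movement trace for threshold segmentation.

Entrainment gain ramps up slowly (a few seconds) after freezing onset and
collapses abruptly at offset, so 4 Hz power rises gradually and falls
sharply — the asymmetry the transition-slope and short/long-episode
analyses quantify.

All stochastic draws go through one seeded ``numpy`` Generator per call;
seeds are explicit arguments, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import i0 as bessel_i0

from .core import TimeSeriesSignal, SpikeTrain
from .markov import (
    FREEZE,
    BehaviouralTimeline,
    MarkovParams,
    simulate_timeline,
)

RESPONSE_CLASSES = (
    "sustained_off_transition_on",
    "nonresponsive",
    "sustained_on_transition_off",
)


@dataclass
class UnitSpec:
    """Ground-truth parameters of one simulated unit.

    ``kappa`` is the von Mises concentration of phase locking to the OB
    rhythm during freezing; ``kappa_active`` the (weaker) concentration
    during active behaviour.  ``sustained_gain`` multiplies the rate
    throughout freezing; ``transition_gain`` applies in a ±1 s window
    around freezing onset and offset.
    """

    baseline_rate: float
    kappa: float = 0.0
    preferred_phase: float = 0.0
    response_class: str = "nonresponsive"
    sustained_gain: float = 1.0
    transition_gain: float = 1.0
    kappa_active: float = 0.0
    unit_id: str = ""

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.kappa < 0 or self.kappa_active < 0:
            raise ValueError("kappa must be >= 0")
        if self.sustained_gain < 0 or self.transition_gain < 0:
            raise ValueError("gains must be >= 0 (rates stay non-negative)")
        if self.response_class not in RESPONSE_CLASSES:
            raise ValueError(f"unknown response_class {self.response_class!r}")


def default_unit_specs(
    n_sustained_off: int = 11,
    n_nonresponsive: int = 9,
    n_sustained_on: int = 4,
    seed: int = 0,
) -> list[UnitSpec]:
    """A mixed dmPFC-like population.

    Roughly half the units respond to freezing and most responders
    decrease their sustained rate, mirroring the recorded proportions.
    Responsive units are phase locked to the OB rhythm during freezing.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_sustained_off):
        specs.append(UnitSpec(
            baseline_rate=float(rng.uniform(6, 14)),
            kappa=2.0, kappa_active=0.5,
            preferred_phase=float(rng.uniform(0, 2 * np.pi)),
            response_class="sustained_off_transition_on",
            sustained_gain=0.45, transition_gain=2.5,
            unit_id=f"u{i:03d}",
        ))
    for i in range(n_sustained_off, n_sustained_off + n_nonresponsive):
        specs.append(UnitSpec(
            baseline_rate=float(rng.uniform(3, 10)),
            kappa=0.0, kappa_active=0.0,
            preferred_phase=0.0,
            response_class="nonresponsive",
            unit_id=f"u{i:03d}",
        ))
    n0 = n_sustained_off + n_nonresponsive
    for i in range(n0, n0 + n_sustained_on):
        specs.append(UnitSpec(
            baseline_rate=float(rng.uniform(2, 6)),
            kappa=2.0, kappa_active=0.5,
            preferred_phase=float(rng.uniform(0, 2 * np.pi)),
            response_class="sustained_on_transition_off",
            sustained_gain=2.0, transition_gain=0.3,
            unit_id=f"u{i:03d}",
        ))
    return specs


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic session.

    Defaults emulate a conditioned test session: two-thirds of time
    frozen (P_Fz/Fz = 0.9, P_Act/Act = 0.8 at 2 s bins), breathing at
    4.0 ± 0.2 Hz with 1.5× tidal volume while freezing and 3–12 Hz
    otherwise, LFPs at 1250 Hz with a 20 ms OB→dmPFC lag.
    """

    seed: int = 0
    session_duration: float = 900.0
    bin_width: float = 2.0
    markov: MarkovParams = field(
        default_factory=lambda: MarkovParams(0.9, 0.8, bin_width=2.0))
    breathing_freeze_hz: tuple = (4.0, 0.2)        # mean, sd
    breathing_active_range_hz: tuple = (3.0, 12.0)
    tidal_gain_freeze: float = 1.5
    tidal_sd_freeze: float = 0.08
    tidal_sd_active: float = 0.2
    waveform_asymmetry: float = 0.0                # |a|<1 warps the cycle shape
    lfp_rate_hz: float = 1250.0
    entrain_gain_freeze: float = 1.0
    entrain_gain_active: float = 0.25
    entrain_tau_on: float = 3.0                    # s, slow onset ramp
    lfp_noise_gain: float = 0.35
    pfc_attenuation: float = 0.6
    ob_to_pfc_lag: float = 0.020                   # s
    noise_exponent: float = 1.0                    # 1/f slope
    accel_noise_freeze: float = 0.05
    accel_noise_active: float = 1.0
    micromove_base_amp: float = 1.5
    micromove_power_slope: float = 1.0             # b in amp = a - b*power_norm
    micromove_noise_sd: float = 0.43
    cs_onsets: tuple = ()                          # () -> regular grid
    cs_pip_interval: float = 30.0 / 27.0
    n_pips_per_cs: int = 27
    unit_specs: list = field(default_factory=default_unit_specs)

    def __post_init__(self) -> None:
        if self.lfp_rate_hz <= 0 or self.session_duration <= 0:
            raise ValueError("rates and durations must be positive")
        if not 0 < self.ob_to_pfc_lag < 0.25:
            raise ValueError("ob_to_pfc_lag must be in (0, 0.25) s")
        if self.ob_to_pfc_lag * self.lfp_rate_hz < 1:
            raise ValueError("lag shorter than one sample")

    @property
    def n_bins(self) -> int:
        return int(round(self.session_duration / self.bin_width))

    def cs_onset_times(self) -> np.ndarray:
        if self.cs_onsets:
            return np.asarray(self.cs_onsets, dtype=float)
        # one 30 s sound per minute, starting 15 s in
        return np.arange(15.0, self.session_duration - 30.0, 60.0)

    def cs_pip_times(self) -> np.ndarray:
        pips = [on + k * self.cs_pip_interval
                for on in self.cs_onset_times()
                for k in range(self.n_pips_per_cs)]
        return np.asarray(pips)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["markov"] = asdict(self.markov)
        d["unit_specs"] = [asdict(u) for u in self.unit_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "markov" in d and isinstance(d["markov"], dict):
            d["markov"] = MarkovParams(**d["markov"])
        if "unit_specs" in d:
            d["unit_specs"] = [
                u if isinstance(u, UnitSpec) else UnitSpec(**u)
                for u in d["unit_specs"]
            ]
        for key in ("breathing_freeze_hz", "breathing_active_range_hz",
                    "cs_onsets"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# noise


def one_over_f_noise(n: int, rate_hz: float, exponent: float = 1.0,
                     seed=None) -> np.ndarray:
    """Unit-variance 1/f^exponent noise by spectral shaping of white noise."""
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n)
    sd = out.std()
    return out / sd if sd > 0 else out


# ---------------------------------------------------------------------------
# breathing


@dataclass
class BreathingResult:
    """Pressure trace plus exact per-cycle ground truth and phase."""

    pressure: TimeSeriesSignal
    cycles: pd.DataFrame        # t_start, freq_hz, volume, state
    phase: np.ndarray           # unwrapped breathing phase at pressure rate


def _warp(u: np.ndarray, asym: float) -> np.ndarray:
    """Monotone cycle-phase warp; asym=0 is the identity (symmetric cycle)."""
    return u + asym * np.sin(2 * np.pi * u) / (2 * np.pi)


def simulate_breathing(timeline: BehaviouralTimeline, cfg: SyntheticConfig,
                       seed=None) -> BreathingResult:
    """Cycle-by-cycle breathing synthesis.

    During freezing, cycle frequencies are Normal(4.0, 0.2) Hz and tidal
    volumes are scaled by ``tidal_gain_freeze`` with reduced variability;
    during active behaviour frequencies are uniform over 3–12 Hz.  The
    pressure trace is negative during inspiration.
    """
    rng = np.random.default_rng(seed)
    fs = cfg.lfp_rate_hz
    duration = timeline.duration
    f_mu, f_sd = cfg.breathing_freeze_hz
    f_lo, f_hi = cfg.breathing_active_range_hz

    t_starts, freqs, vols, states = [], [], [], []
    t = 0.0
    while t < duration:
        state = int(timeline.state_at(t))
        if state == FREEZE:
            f = float(np.clip(rng.normal(f_mu, f_sd), 0.5, None))
            v = float(np.clip(rng.normal(cfg.tidal_gain_freeze,
                                         cfg.tidal_sd_freeze), 0.05, None))
        else:
            f = float(rng.uniform(f_lo, f_hi))
            v = float(np.clip(rng.normal(1.0, cfg.tidal_sd_active), 0.05, None))
        t_starts.append(t)
        freqs.append(f)
        vols.append(v)
        states.append(state)
        t += 1.0 / f
    cycles = pd.DataFrame({
        "t_start": t_starts, "freq_hz": freqs,
        "volume": vols, "state": states,
    })

    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    idx = np.searchsorted(np.asarray(t_starts), tt, side="right") - 1
    idx = np.clip(idx, 0, len(t_starts) - 1)
    u = (tt - np.asarray(t_starts)[idx]) * np.asarray(freqs)[idx]
    u = np.clip(u, 0.0, 1.0)
    phase = 2 * np.pi * (idx + _warp(u, cfg.waveform_asymmetry))
    pressure = -np.asarray(vols)[idx] * np.sin(2 * np.pi * u)
    sig = TimeSeriesSignal(pressure, fs, channel="plethysmograph",
                           units="a.u. pressure")
    return BreathingResult(pressure=sig, cycles=cycles, phase=phase)


# ---------------------------------------------------------------------------
# LFP pair


def entrainment_gain(timeline: BehaviouralTimeline, cfg: SyntheticConfig,
                     n: int) -> np.ndarray:
    """Per-sample oscillation gain: low when active, ramping up over
    ``entrain_tau_on`` seconds after freezing onset, collapsing at offset."""
    fs = cfg.lfp_rate_hz
    g = np.full(n, cfg.entrain_gain_active)
    tt = np.arange(n) / fs
    for start, stop in timeline.bout_epochs(FREEZE):
        m = (tt >= start) & (tt < stop)
        dt = tt[m] - start
        g[m] = cfg.entrain_gain_active + (
            cfg.entrain_gain_freeze - cfg.entrain_gain_active
        ) * (1.0 - np.exp(-dt / cfg.entrain_tau_on))
    return g


def simulate_lfp_pair(
    breathing: BreathingResult,
    timeline: BehaviouralTimeline,
    cfg: SyntheticConfig,
    seed=None,
) -> tuple[TimeSeriesSignal, TimeSeriesSignal]:
    """OB and dmPFC LFPs entrained by the breathing phase.

    The dmPFC trace is an attenuated copy of the OB oscillatory component
    delayed by ``ob_to_pfc_lag`` plus independent 1/f noise, so the
    coupling is directional by construction.
    """
    rng = np.random.default_rng(seed)
    fs = cfg.lfp_rate_hz
    n = breathing.phase.size
    gain = entrainment_gain(timeline, cfg, n)
    osc = gain * np.cos(breathing.phase)

    lag_samples = int(round(cfg.ob_to_pfc_lag * fs))
    if lag_samples >= n:
        raise ValueError("lag exceeds signal length")
    osc_delayed = np.concatenate([osc[:1].repeat(lag_samples),
                                  osc[:n - lag_samples]])

    noise_ob = one_over_f_noise(n, fs, cfg.noise_exponent, seed=rng)
    noise_pfc = one_over_f_noise(n, fs, cfg.noise_exponent, seed=rng)
    ob = osc + cfg.lfp_noise_gain * noise_ob
    pfc = cfg.pfc_attenuation * osc_delayed + cfg.lfp_noise_gain * noise_pfc
    return (
        TimeSeriesSignal(ob, fs, channel="OB", units="a.u."),
        TimeSeriesSignal(pfc, fs, channel="dmPFC", units="a.u."),
    )


# ---------------------------------------------------------------------------
# spikes


def _transition_mask(timeline: BehaviouralTimeline, tt: np.ndarray,
                     half_width: float = 1.0) -> np.ndarray:
    mask = np.zeros(tt.size, dtype=bool)
    for b0, b1, s in timeline.bouts:
        if s != FREEZE:
            continue
        for edge_bin in (b0, b1):
            if edge_bin == 0 or edge_bin == timeline.n_bins:
                continue
            t_edge = timeline.t0 + edge_bin * timeline.bin_width
            mask |= np.abs(tt - t_edge) <= half_width
    return mask


def simulate_spikes(
    unit_spec: UnitSpec,
    phase: np.ndarray,
    timeline: BehaviouralTimeline,
    seed=None,
    rate_hz: float = 1250.0,
) -> SpikeTrain:
    """Inhomogeneous point process phase locked to the OB rhythm.

    Instantaneous rate = baseline × von Mises phase gain (normalized to
    unit mean, so kappa changes locking without changing rate) × the
    sustained/transition gains of the unit's response class.  Spikes are
    drawn by Bernoulli thinning on the sample grid.
    """
    rng = np.random.default_rng(seed)
    n = phase.size
    tt = np.arange(n) / rate_hz
    frozen = timeline.state_at(tt) == FREEZE

    kappa = np.where(frozen, unit_spec.kappa, unit_spec.kappa_active)
    vm_gain = np.exp(kappa * np.cos(phase - unit_spec.preferred_phase))
    vm_gain /= bessel_i0(kappa)

    gain = np.ones(n)
    if unit_spec.response_class != "nonresponsive":
        gain[frozen] = unit_spec.sustained_gain
        trans = _transition_mask(timeline, tt)
        gain[trans] = unit_spec.transition_gain

    rate = unit_spec.baseline_rate * vm_gain * gain
    if np.any(rate < 0):
        raise ValueError("negative instantaneous rate")
    p = rate / rate_hz
    if p.max() >= 1.0:
        raise ValueError("rate too high for sampling grid; increase rate_hz")
    hits = rng.random(n) < p
    times = tt[hits] + rng.uniform(0, 1.0 / rate_hz, int(hits.sum()))
    return SpikeTrain(np.sort(times), unit_id=unit_spec.unit_id)


# ---------------------------------------------------------------------------
# accelerometer and movement


def simulate_accelerometer(
    timeline: BehaviouralTimeline,
    band_power_4hz: np.ndarray,
    cfg: SyntheticConfig,
    seed=None,
    cs_pips: np.ndarray | None = None,
) -> tuple[TimeSeriesSignal, pd.DataFrame]:
    """Accelerometer trace with pip-locked micromovements during freezing.

    ``band_power_4hz`` is a per-timeline-bin 4 Hz power series; it is
    normalized over freezing bins and micromovement amplitude follows
    ``a - b * power_norm + noise`` (b > 0 gives the negative
    amplitude–power correlation).  Micromovements are emitted only at CS
    pip times inside freezing bouts, with emission probability declining
    as power rises, so event density falls over a freezing episode.
    Returns the trace and the ground-truth event table.
    """
    rng = np.random.default_rng(seed)
    fs = cfg.lfp_rate_hz
    n = int(round(timeline.duration * fs))
    tt = np.arange(n) / fs
    frozen = timeline.state_at(tt) == FREEZE
    sig = np.where(frozen, cfg.accel_noise_freeze,
                   cfg.accel_noise_active) * rng.standard_normal(n)

    power = np.asarray(band_power_4hz, dtype=float)
    if power.size != timeline.n_bins:
        raise ValueError("band power must have one value per timeline bin")
    fz_bins = timeline.states == FREEZE
    if fz_bins.any():
        lo = np.percentile(power[fz_bins], 5)
        hi = np.percentile(power[fz_bins], 95)
    else:
        lo, hi = power.min(), power.max() + 1e-12
    pnorm_bins = np.clip((power - lo) / max(hi - lo, 1e-12), 0.0, 1.0)

    if cs_pips is None:
        cs_pips = cfg.cs_pip_times()
    events = []
    burst_half = int(round(0.075 * fs))
    w = np.exp(-0.5 * (np.arange(-burst_half, burst_half + 1) / (burst_half / 2.5)) ** 2)
    carrier = np.sin(2 * np.pi * 20.0 * np.arange(w.size) / fs)
    for t_pip in cs_pips:
        b = int((t_pip - timeline.t0) / timeline.bin_width)
        if b < 0 or b >= timeline.n_bins or timeline.states[b] != FREEZE:
            continue
        pn = pnorm_bins[b]
        if rng.random() > (1.0 - 0.7 * pn):
            continue
        amp = cfg.micromove_base_amp - cfg.micromove_power_slope * pn \
            + cfg.micromove_noise_sd * rng.standard_normal()
        amp = max(amp, 0.02)
        i = int(round(t_pip * fs))
        sl = slice(max(0, i - burst_half), min(n, i + burst_half + 1))
        seg = (w * carrier)[: sl.stop - sl.start]
        sig[sl] += amp * seg
        events.append((t_pip, amp, pn))
    table = pd.DataFrame(events, columns=["time_s", "amplitude", "power_norm"])
    return (
        TimeSeriesSignal(sig, fs, channel="accelerometer", units="a.u."),
        table,
    )


def simulate_movement_trace(timeline: BehaviouralTimeline, seed=None,
                            rate_hz: float = 25.0) -> TimeSeriesSignal:
    """Video-like quantity-of-movement trace for threshold segmentation:
    near zero while freezing, well above threshold while active."""
    rng = np.random.default_rng(seed)
    n = int(round(timeline.duration * rate_hz))
    tt = np.arange(n) / rate_hz
    frozen = timeline.state_at(tt) == FREEZE
    raw = np.where(frozen,
                   np.abs(rng.normal(0.0, 0.04, n)),
                   0.3 + np.abs(rng.normal(0.5, 0.25, n)))
    k = max(1, int(round(0.4 * rate_hz)))
    smooth = np.convolve(raw, np.ones(k) / k, mode="same")
    return TimeSeriesSignal(smooth, rate_hz, channel="movement",
                            units="a.u. movement")


def simulate_waveform_features(n_units: int, frac_pyramidal: float = 0.74,
                               seed=None) -> pd.DataFrame:
    """Two-cluster waveform feature table (synthetic stand-in for measured
    mean waveforms): broad/slow putative pyramidal cells vs narrow/fast
    putative interneurons."""
    rng = np.random.default_rng(seed)
    n_pyr = int(round(frac_pyramidal * n_units))
    rows = []
    for i in range(n_units):
        if i < n_pyr:
            rows.append((
                rng.normal(0.35, 0.05), rng.normal(0.75, 0.08),
                rng.normal(0.25, 0.10), "putative_pyramidal",
            ))
        else:
            rows.append((
                rng.normal(0.15, 0.03), rng.normal(0.28, 0.05),
                rng.normal(-0.10, 0.10), "putative_interneuron",
            ))
    df = pd.DataFrame(rows, columns=[
        "half_amplitude_duration", "trough_to_peak", "asymmetry_index",
        "true_class",
    ])
    df[["half_amplitude_duration", "trough_to_peak"]] = \
        df[["half_amplitude_duration", "trough_to_peak"]].clip(lower=0.02)
    return df


# ---------------------------------------------------------------------------
# whole session


@dataclass
class SessionData:
    """Everything one synthetic session produces, plus ground truth."""

    config: SyntheticConfig
    timeline: BehaviouralTimeline
    breathing: BreathingResult
    ob: TimeSeriesSignal
    pfc: TimeSeriesSignal
    spikes: list
    accel: TimeSeriesSignal
    micromove_truth: pd.DataFrame
    movement: TimeSeriesSignal
    entrain_gain: np.ndarray
    cs_pips: np.ndarray


def generate_session(cfg: SyntheticConfig, seed=None) -> SessionData:
    """Run every generator with independent seeded streams."""
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    seeds = root.integers(0, 2**31 - 1, size=6 + len(cfg.unit_specs))
    timeline = simulate_timeline(cfg.markov, cfg.n_bins, seed=int(seeds[0]))
    breathing = simulate_breathing(timeline, cfg, seed=int(seeds[1]))
    ob, pfc = simulate_lfp_pair(breathing, timeline, cfg, seed=int(seeds[2]))
    spikes = [
        simulate_spikes(spec, breathing.phase, timeline,
                        seed=int(seeds[6 + i]), rate_hz=cfg.lfp_rate_hz)
        for i, spec in enumerate(cfg.unit_specs)
    ]
    gain = entrainment_gain(timeline, cfg, breathing.phase.size)
    # ground-truth per-bin 4 Hz drive for the accelerometer coupling
    per_bin = int(round(cfg.bin_width * cfg.lfp_rate_hz))
    nb = timeline.n_bins
    gain_bins = np.array([
        gain[i * per_bin: (i + 1) * per_bin].mean() for i in range(nb)
    ])
    cs_pips = cfg.cs_pip_times()
    accel, truth = simulate_accelerometer(timeline, gain_bins, cfg,
                                          seed=int(seeds[3]), cs_pips=cs_pips)
    movement = simulate_movement_trace(timeline, seed=int(seeds[4]))
    return SessionData(
        config=cfg, timeline=timeline, breathing=breathing,
        ob=ob, pfc=pfc, spikes=spikes, accel=accel,
        micromove_truth=truth, movement=movement,
        entrain_gain=gain, cs_pips=cs_pips,
    )
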