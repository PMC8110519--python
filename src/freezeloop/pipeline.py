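"""End-to-end orchestration: synthesize, segment, analyse, report.

``run_pipeline`` executes the stages in dependency order on one
synthetic session and returns a machine-readable summary;
``validate_against_truth`` compares every recovered quantity with the
generator's ground truth at stated tolerances.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from . import io as flio
from .core import TimeSeriesSignal
from .markov import (
    ACTIVE,
    FREEZE,
    estimate_params,
    segment_bouts,
    simulate_summary,
    summarize,
)
from .oscillations import (
    DEFAULT_BAND,
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
from .response import (
    assign_groups,
    detect_freezing_response,
    onset_offset_amplitudes,
    population_vector_matrix,
    response_pca,
    response_vector,
    unit_response,
)
from .spike_phase import (
    asymmetry_correction,
    classify_cell_type,
    compare_proportions,
    matched_active_window,
    matched_state_comparison,
    modulation_index,
    peak_trough_phase,
    spike_phases,
    unit_phase_stats,
)
from .synth import SyntheticConfig, generate_session, simulate_waveform_features

log = logging.getLogger("freezeloop")

ALL_STAGES = ("behaviour", "oscillations", "units", "response")


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seed: int = 0
    out_dir: str | None = None
    stages: tuple = ALL_STAGES
    band: tuple = DEFAULT_BAND
    spectral_rate: float = 250.0   # decimation target for spectral stages
    movement_threshold: float = 0.3
    n_sim_reps: int = 100
    n_shuffle: int = 1000
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "synthetic": self.synthetic.to_dict(),
            "seed": self.seed, "out_dir": self.out_dir,
            "stages": list(self.stages), "band": list(self.band),
            "spectral_rate": self.spectral_rate,
            "movement_threshold": self.movement_threshold,
            "n_sim_reps": self.n_sim_reps, "n_shuffle": self.n_shuffle,
            "alpha": self.alpha,
        }


def _decimate(sig: TimeSeriesSignal, target: float) -> TimeSeriesSignal:
    q = max(1, int(round(sig.rate_hz / target)))
    if q == 1:
        return sig
    return TimeSeriesSignal(sps.decimate(sig.data, q, ftype="fir"),
                            sig.rate_hz / q, t0=sig.t0,
                            channel=sig.channel, units=sig.units)


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage on one synthetic session.

    Stages depend on their predecessors; disabling one skips (with a
    warning) everything downstream that needs it.  Returns the summary
    dict; when ``out_dir`` is set, signals, spikes, timelines, ground
    truth and the summary are also written to disk.
    """
    t_start = time.time()
    rng = np.random.default_rng(config.seed)
    report: dict = {"config": config.to_dict(), "stages": {}, "timings": {},
                    "exclusions": [], "skipped": []}

    t0 = time.time()
    session = generate_session(config.synthetic, seed=config.seed)
    tl_true = session.timeline
    report["truth"] = {
        "p_stay_freeze": config.synthetic.markov.p_stay_freeze,
        "p_stay_active": config.synthetic.markov.p_stay_active,
        "stationary_freeze_fraction":
            config.synthetic.markov.stationary_freeze_fraction(),
        "pct_freezing_realized": tl_true.pct_freezing(),
        "ob_to_pfc_lag": config.synthetic.ob_to_pfc_lag,
        "units": [
            {"unit_id": u.unit_id, "kappa": u.kappa,
             "kappa_active": u.kappa_active,
             "preferred_phase": u.preferred_phase,
             "response_class": u.response_class}
            for u in config.synthetic.unit_specs
        ],
    }
    report["timings"]["synthesis"] = time.time() - t0

    enabled = set(config.stages)
    fz_epochs = tl_true.bout_epochs(FREEZE)
    act_epochs = tl_true.bout_epochs(ACTIVE)

    # ---------------- behaviour ----------------
    timeline = None
    if "behaviour" in enabled:
        t0 = time.time()
        timeline = segment_bouts(session.movement, config.movement_threshold,
                                 min_freeze_dur=2.0,
                                 bin_width=config.synthetic.bin_width)
        params = estimate_params(timeline)
        sim = simulate_summary(params, timeline.n_bins,
                               n_reps=config.n_sim_reps,
                               seed=int(rng.integers(2**31 - 1)))
        stats_ = summarize(timeline, cs_events=config.synthetic.cs_onset_times())
        observed_pct = timeline.pct_freezing()
        report["stages"]["behaviour"] = {
            "p_stay_freeze_hat": params.p_stay_freeze,
            "p_stay_active_hat": params.p_stay_active,
            "pct_freezing_observed": observed_pct,
            "pct_freezing_simulated_mean": sim["mean"]["pct_freezing"],
            "pct_freezing_simulated_sd": sim["sd"]["pct_freezing"],
            "initiation_freq_per_min": stats_.initiation_frequency,
            "n_bouts": stats_.n_bouts,
            "mean_bout_dur_s": stats_.mean_bout_dur,
            "per_block_pct": stats_.per_block_pct,
            "model_consistent": bool(
                abs(sim["mean"]["pct_freezing"] - observed_pct)
                <= 2 * max(sim["sd"]["pct_freezing"], 1e-9)),
        }
        report["timings"]["behaviour"] = time.time() - t0
    else:
        report["skipped"].append("behaviour")

    # ---------------- oscillations ----------------
    spec_ob = None
    if "oscillations" in enabled:
        t0 = time.time()
        ob = _decimate(session.ob, config.spectral_rate)
        pfc = _decimate(session.pfc, config.spectral_rate)
        spec_ob = multitaper_spectrogram(ob, fmax=20.0)
        fz_mask = tl_true.state_at(spec_ob.times) == FREEZE
        snr_fz = band_snr(spec_ob.freqs, spec_ob.mean_spectrum(fz_mask),
                          config.band)
        snr_act = band_snr(spec_ob.freqs, spec_ob.mean_spectrum(~fz_mask),
                           config.band)
        coh_fz = coherence(ob, pfc, band=config.band, epochs=fz_epochs,
                           fmax=20.0)
        coh_act = coherence(ob, pfc, band=config.band, epochs=act_epochs,
                            fmax=20.0)
        gr = granger_band(ob, pfc, band=config.band, epochs=fz_epochs,
                          surrogate=True)
        bp = bin_band_power(spec_ob, tl_true, config.band)
        roc = roc_state_prediction(bp, tl_true)
        prof = normalized_episode_profile(
            spec_ob.times, spec_ob.band_power(config.band), fz_epochs,
            min_dur=4.0, flank_s=2.0)
        # finer window for transition alignment: a 3 s window would smear
        # the sharp offset over its own length
        spec_trans = multitaper_spectrogram(ob, window_s=1.0, step_s=0.1,
                                            n_tapers=3, fmax=20.0)
        slopes = _transition_slopes(spec_trans, config.band, fz_epochs,
                                    min_bout_s=6.0)
        mm = micromovement_coupling(
            session.accel, spec_ob.times, spec_ob.band_power(config.band),
            session.cs_pips, fz_epochs)
        shortlong = split_episode_spectra(spec_ob, fz_epochs, cutoff=10.0,
                                          band=config.band)
        report["stages"]["oscillations"] = {
            "band_snr_freeze": snr_fz,
            "band_snr_active": snr_act,
            "coherence_band_freeze": coh_fz["band_mean"],
            "coherence_band_active": coh_act["band_mean"],
            "granger_ob_to_pfc": gr["g_a_to_b"],
            "granger_pfc_to_ob": gr["g_b_to_a"],
            "granger_order": gr["order"],
            "granger_surrogate_threshold": gr.get("surrogate_threshold"),
            "roc_auc": roc.auc,
            "roc_excluded": roc.excluded,
            "episode_profile_n": prof.n_episodes,
            "slope_onset": slopes.get("onset", {}).get("slope"),
            "slope_offset": slopes.get("offset", {}).get("slope"),
            "micromovement_r": mm["r"],
            "micromovement_n": int(len(mm["events"])),
            "snr_short_episodes": (shortlong["short"] or {}).get("band_snr"),
            "snr_long_episodes": (shortlong["long"] or {}).get("band_snr"),
        }
        if roc.excluded:
            report["exclusions"].append(f"ROC: {roc.reason}")
        report["timings"]["oscillations"] = time.time() - t0
    else:
        report["skipped"].append("oscillations")

    # ---------------- units (phase locking) ----------------
    if "units" in enabled:
        t0 = time.time()
        ob_ds = _decimate(session.ob, config.spectral_rate)
        phase = peak_trough_phase(ob_ds)
        occupancy = {
            "freeze": _phase_occupancy(phase, fz_epochs),
            "active": _phase_occupancy(phase, act_epochs),
        }
        total_fz = float(np.sum(fz_epochs[:, 1] - fz_epochs[:, 0]))
        try:
            matched_act = matched_active_window(session.movement, act_epochs,
                                                total_fz)
        except ValueError:
            matched_act = act_epochs
        per_unit = []
        n_mod_fz = n_mod_act = n_tested = 0
        mis = []
        for spk in session.spikes:
            ph_fz = spike_phases(spk, phase, fz_epochs)
            ph_act = spike_phases(spk, phase, act_epochs)
            if ph_fz.size < 20 or ph_act.size < 20:
                report["exclusions"].append(
                    f"{spk.unit_id}: too few spikes for phase stats")
                continue
            n_tested += 1
            st_fz = unit_phase_stats(
                asymmetry_correction(ph_fz, occupancy["freeze"]),
                unit_id=spk.unit_id, corrected=True)
            st_act = unit_phase_stats(
                asymmetry_correction(ph_act, occupancy["active"]),
                unit_id=spk.unit_id, corrected=True)
            n_mod_fz += st_fz.p_rayleigh < config.alpha
            n_mod_act += st_act.p_rayleigh < config.alpha
            rate_fz = ph_fz.size / max(total_fz, 1e-9)
            act_dur = float(np.sum(act_epochs[:, 1] - act_epochs[:, 0]))
            rate_act = ph_act.size / max(act_dur, 1e-9)
            mis.append(modulation_index(rate_fz, rate_act))
            matched = matched_state_comparison(
                spk, phase, fz_epochs, matched_act,
                seed=int(rng.integers(2**31 - 1)),
                lfp_phase_occupancy=occupancy)
            per_unit.append({
                "unit_id": spk.unit_id,
                "log_z_freeze": st_fz.log_z, "p_freeze": st_fz.p_rayleigh,
                "kappa_freeze": st_fz.kappa, "ppc_freeze": st_fz.ppc,
                "preferred_phase": st_fz.preferred_phase,
                "p_active": st_act.p_rayleigh,
                "matched": matched,
            })
        chi2 = compare_proportions(n_mod_fz, n_tested, n_mod_act, n_tested) \
            if n_tested else None
        wf = simulate_waveform_features(
            max(50, 2 * len(session.spikes)),
            seed=int(rng.integers(2**31 - 1)))
        typed = classify_cell_type(wf[["half_amplitude_duration",
                                       "trough_to_peak",
                                       "asymmetry_index"]].to_numpy())
        report["stages"]["units"] = {
            "n_tested": n_tested,
            "pct_modulated_freeze": 100.0 * n_mod_fz / max(n_tested, 1),
            "pct_modulated_active": 100.0 * n_mod_act / max(n_tested, 1),
            "proportion_chi2": chi2,
            "median_rate_modulation_index": float(np.median(mis)) if mis else None,
            "per_unit": per_unit,
            "cell_typing": {
                "frac_pyramidal": typed.get("frac_pyramidal"),
                "recovery": float(np.mean(
                    typed["labels"] == wf["true_class"].to_numpy())),
            },
        }
        report["timings"]["units"] = time.time() - t0
    else:
        report["skipped"].append("units")

    # ---------------- freezing responses ----------------
    if "response" in enabled:
        t0 = time.time()
        responses, detections = [], []
        for spk in session.spikes:
            resp = unit_response(spk, tl_true)
            det = detect_freezing_response(resp, n_shuffle=config.n_shuffle,
                                           alpha=config.alpha,
                                           seed=int(rng.integers(2**31 - 1)))
            responses.append(resp)
            detections.append(det)
        matrix = np.vstack([response_vector(r) for r in responses])
        pca = response_pca(np.nan_to_num(matrix), n_components=5)
        groups = assign_groups(responses, detections)
        # population profiles: pre-onset flank, normalized interior,
        # post-offset flank (the transition-PSTH halves outside the bout)
        n_half = responses[0].onset.size // 2
        profiles = np.vstack([
            np.concatenate([r.onset[:n_half], r.interior,
                            r.offset[n_half:]])
            for r in responses])
        pop = population_vector_matrix(np.nan_to_num(profiles))
        amp = [onset_offset_amplitudes(r) for r in responses]
        group_counts = {g: sum(1 for fr in groups if fr.group == g)
                        for g in ("sustained_off_transition_on",
                                  "nonresponsive",
                                  "sustained_on_transition_off")}
        truth_classes = [u.response_class for u in config.synthetic.unit_specs]
        recovery = float(np.mean([
            fr.group == tc for fr, tc in zip(groups, truth_classes)]))
        responsive_amp = [(a, o) for (a, _, o), fr in zip(amp, groups)
                          if fr.responsive]
        report["stages"]["response"] = {
            "n_units": len(responses),
            "pct_responsive": 100.0 * np.mean([d["responsive"]
                                               for d in detections]),
            "group_counts": group_counts,
            "group_recovery": recovery,
            "pc_variance": pca["explained_variance_ratio"][:2].tolist(),
            "mean_onset_amp": float(np.mean([a for a, _ in responsive_amp]))
            if responsive_amp else None,
            "mean_offset_amp": float(np.mean([o for _, o in responsive_amp]))
            if responsive_amp else None,
            "population_corr_diag_ok": bool(np.allclose(
                np.diag(pop.corr)[~pop.masked_bins], 1.0)),
            "population_flank_bins": int(n_half),
        }
        report["_population_matrix"] = pop
        report["timings"]["response"] = time.time() - t0
    else:
        report["skipped"].append("response")

    report["timings"]["total"] = time.time() - t_start

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        flio.save_signals(out / "signals.h5", {
            "OB": session.ob, "dmPFC": session.pfc,
            "plethysmograph": session.breathing.pressure,
            "accelerometer": session.accel, "movement": session.movement,
        })
        flio.save_spikes_csv(out / "spikes.csv", session.spikes)
        flio.save_timeline_csv(out / "timeline_true.csv", tl_true)
        if timeline is not None:
            flio.save_timeline_csv(out / "timeline_segmented.csv", timeline)
        flio.save_json(out / "ground_truth.json", report["truth"])
        summary = {k: v for k, v in report.items()
                   if not k.startswith("_")}
        flio.save_json(out / "summary.json", summary)
    return report


def _transition_slopes(spec, band, fz_epochs, min_bout_s: float = 6.0,
                       window_s: float = 3.0) -> dict:
    """Sigmoid slopes of transition-aligned band power.

    Band power is averaged over bouts at least ``min_bout_s`` long on a
    ±``window_s`` real-time grid around onset and offset, normalized to
    [0, 1], and fitted with a 4-parameter logistic.
    """
    bp = spec.band_power(band)
    grid = np.linspace(-window_s, window_s, 61)
    on_rows, off_rows = [], []
    for e0, e1 in np.atleast_2d(fz_epochs):
        if e1 - e0 < min_bout_s:
            continue
        on_rows.append(np.interp(e0 + grid, spec.times, bp))
        off_rows.append(np.interp(e1 + grid, spec.times, bp))
    if not on_rows:
        return {}
    return {
        "onset": transition_slope(grid, np.vstack(on_rows).mean(axis=0)),
        "offset": transition_slope(grid, np.vstack(off_rows).mean(axis=0)),
        "n_bouts": len(on_rows),
    }


def _phase_occupancy(phase, epochs, max_samples: int = 200_000) -> np.ndarray:
    mask = np.zeros(phase.times.size, dtype=bool)
    for e0, e1 in np.atleast_2d(epochs):
        mask |= (phase.times >= e0) & (phase.times < e1)
    ph = phase.phase[mask]
    if ph.size > max_samples:
        ph = ph[:: ph.size // max_samples + 1]
    return ph


def validate_against_truth(report: dict, truth: dict | None = None) -> list:
    """Compare recovered estimates against generator ground truth.

    Returns one row per check: (name, truth, estimate, tolerance, passed).
    Directional checks use the truth column for the expected ordering.
    """
    truth = truth or report["truth"]
    rows = []

    def row(name, tru, est, tol, passed):
        rows.append({"parameter": name, "truth": tru, "estimate": est,
                     "tolerance": tol, "passed": bool(passed)})

    beh = report["stages"].get("behaviour")
    if beh:
        for key, tkey, state in (
            ("p_stay_freeze_hat", "p_stay_freeze", "Fz"),
            ("p_stay_active_hat", "p_stay_active", "Act"),
        ):
            est, tru = beh[key], truth[tkey]
            # geometric bout lengths: SE(P_hat) ~= sqrt(P) (1-P) / sqrt(n)
            n = max(beh["n_bouts"].get(state, 1), 1)
            se = np.sqrt(max(tru, 1e-12)) * (1 - tru) / np.sqrt(n)
            tol = max(3 * se, 0.01)
            row(tkey, tru, est, round(tol, 4), abs(est - tru) <= tol)
        row("pct_freezing_model_consistency",
            beh["pct_freezing_observed"],
            beh["pct_freezing_simulated_mean"],
            "2 SD", beh["model_consistent"])
    osc = report["stages"].get("oscillations")
    if osc:
        row("coherence_contrast", "freeze > active",
            osc["coherence_band_freeze"] - osc["coherence_band_active"],
            "> 0",
            osc["coherence_band_freeze"] > osc["coherence_band_active"])
        row("granger_direction", "OB -> dmPFC",
            osc["granger_ob_to_pfc"] - osc["granger_pfc_to_ob"], "> 0",
            osc["granger_ob_to_pfc"] > osc["granger_pfc_to_ob"])
        row("band_snr_contrast", "freeze > active",
            osc["band_snr_freeze"] - osc["band_snr_active"], "> 0",
            osc["band_snr_freeze"] > osc["band_snr_active"])
        row("roc_auc", "> 0.5", osc["roc_auc"], "> 0.5",
            (not osc["roc_excluded"]) and osc["roc_auc"] > 0.5)
        if osc["micromovement_n"] >= 10:
            row("micromovement_r", "< 0", osc["micromovement_r"], "< 0",
                osc["micromovement_r"] < 0)
    units = report["stages"].get("units")
    if units:
        truth_kappa = {u["unit_id"]: u["kappa"] for u in truth["units"]}
        locked = [(pu["matched"]["freeze"]["kappa"], truth_kappa[pu["unit_id"]])
                  for pu in units["per_unit"]
                  if not pu["matched"].get("excluded")
                  and truth_kappa.get(pu["unit_id"], 0) > 0]
        if locked:
            rel_err = float(np.median([abs(k - t) / t for k, t in locked]))
            row("kappa_recovery_median_rel_err", 0.0, rel_err, 0.25,
                rel_err < 0.25)
        truth_locked = {u["unit_id"] for u in truth["units"]
                        if u["kappa"] > u["kappa_active"]}
        deltas = [pu["matched"]["delta_kappa"] for pu in units["per_unit"]
                  if not pu["matched"].get("excluded")
                  and pu["unit_id"] in truth_locked]
        if deltas:
            frac = float(np.mean(np.asarray(deltas) > 0))
            row("locking_contrast_matched", "kappa freeze > active",
                frac, ">= 0.95", frac >= 0.95)
    resp = report["stages"].get("response")
    if resp:
        row("group_recovery", 1.0, resp["group_recovery"], ">= 0.75",
            resp["group_recovery"] >= 0.75)
    return rows
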