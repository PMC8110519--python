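"""Per-unit freezing responses and population dynamics.

Units are tested for freezing modulation with a cumulative-sum change
detection against a bin-shuffle null — sensitive both to strong responses
in a few consecutive bins and to weak responses spread over many bins,
unlike bin-by-bin testing.  Responses are decomposed by PCA into a
sustained and a transition component, units are grouped into
sustained-off/transition-on, non-responsive, and
sustained-on/transition-off classes, onset/sustained/offset amplitudes
are quantified, and population-vector correlation matrices are computed
over duration-normalized episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .core import SpikeTrain
from .markov import FREEZE, BehaviouralTimeline

GROUPS = ("sustained_off_transition_on", "nonresponsive",
          "sustained_on_transition_off")


@dataclass
class UnitResponse:
    """Freezing-triggered, z-scored firing of one unit.

    ``onset`` and ``offset`` are transition-aligned PSTHs on a real-time
    grid; ``interior`` is the duration-normalized episode profile.
    """

    unit_id: str
    onset_t: np.ndarray
    onset: np.ndarray
    offset_t: np.ndarray
    offset: np.ndarray
    interior: np.ndarray
    n_bouts: int


@dataclass
class FreezingResponse:
    """Classification of one unit's freezing response."""

    unit_id: str
    responsive: bool
    sign: int                      # +1 / -1 (0 if not responsive)
    latency_s: float
    group: str = "nonresponsive"
    onset_amp: float = 0.0
    sustained_amp: float = 0.0
    offset_amp: float = 0.0
    sustained_sign: int = 0
    transition_sign: int = 0
    flags: list = field(default_factory=list)


def binned_zrate(spikes: SpikeTrain, duration: float,
                 bin_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Session-long binned firing rate z-scored against its own mean/SD."""
    edges = np.arange(0.0, duration + bin_s, bin_s)
    counts, _ = np.histogram(spikes.times, bins=edges)
    rate = counts / bin_s
    sd = rate.std()
    z = (rate - rate.mean()) / sd if sd > 0 else np.zeros_like(rate)
    centres = (edges[:-1] + edges[1:]) / 2
    return centres, z


def unit_response(
    spikes: SpikeTrain,
    timeline: BehaviouralTimeline,
    bin_s: float = 0.5,
    window_s: float = 4.0,
    n_norm_bins: int = 100,
    min_bout_s: float = 4.0,
) -> UnitResponse:
    """Average freezing-triggered response of one unit.

    Onset- and offset-aligned PSTHs (±``window_s`` at ``bin_s`` bins) and
    the duration-normalized episode interior, averaged over freezing
    bouts at least ``min_bout_s`` long that do not touch session edges.
    """
    centres, z = binned_zrate(spikes, timeline.duration, bin_s)
    rel = np.arange(-window_s + bin_s / 2, window_s, bin_s)
    grid = np.linspace(0, 1, n_norm_bins)
    on_rows, off_rows, int_rows = [], [], []
    for e0, e1 in timeline.bout_epochs(FREEZE, complete_only=True):
        if e1 - e0 < min_bout_s:
            continue
        on_rows.append(np.interp(e0 + rel, centres, z))
        off_rows.append(np.interp(e1 + rel, centres, z))
        int_rows.append(np.interp(e0 + grid * (e1 - e0), centres, z))
    n = len(on_rows)
    if n == 0:
        nanr = np.full(rel.size, np.nan)
        return UnitResponse(spikes.unit_id, rel, nanr, rel, nanr.copy(),
                            np.full(n_norm_bins, np.nan), 0)
    return UnitResponse(
        unit_id=spikes.unit_id,
        onset_t=rel, onset=np.vstack(on_rows).mean(axis=0),
        offset_t=rel, offset=np.vstack(off_rows).mean(axis=0),
        interior=np.vstack(int_rows).mean(axis=0),
        n_bouts=n,
    )


def response_vector(resp: UnitResponse) -> np.ndarray:
    """Concatenated onset PSTH, normalized interior, offset PSTH."""
    return np.concatenate([resp.onset, resp.interior, resp.offset])


# ---------------------------------------------------------------------------
# change detection


def change_detection(
    psth_z: np.ndarray,
    n_shuffle: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> dict:
    """CUSUM responsiveness test against a bin-shuffle null.

    The statistic is the peak |cumulative sum| of the mean-centred
    z-scored PSTH (centring removes the permutation-invariant drift of
    the window mean, without which the shuffle null has no power); the
    null distribution is built by recomputing the statistic on
    ``n_shuffle`` random reorderings of the bins.  A consistent response
    of either sign drives the cumulative sum away from zero whether it is
    concentrated in a few consecutive bins or spread over many.
    """
    x = np.asarray(psth_z, dtype=float)
    if x.size < 10:
        raise ValueError("PSTH must have at least 10 bins")
    if np.ptp(x) == 0:
        return {"responsive": False, "sign": 0, "latency": float("nan"),
                "statistic": 0.0, "threshold": 0.0, "degenerate": True}
    x = x - x.mean()
    rng = np.random.default_rng(seed)
    cs = np.cumsum(x)
    i_peak = int(np.argmax(np.abs(cs)))
    stat = float(np.abs(cs[i_peak]))
    # vectorized shuffles: argsort of uniforms is a uniform random permutation
    perms = np.argsort(rng.random((n_shuffle, x.size)), axis=1)
    null = np.abs(np.cumsum(x[perms], axis=1)).max(axis=1)
    thresh = float(np.quantile(null, 1.0 - alpha))
    # the |cusum| peak marks the change point; the response sign is the
    # direction of the change there (post-change mean minus pre-change),
    # which for a centred sequence is the negated cusum extremum sign
    return {
        "responsive": bool(stat > thresh),
        "sign": -int(np.sign(cs[i_peak])),
        "latency": float(i_peak),
        "statistic": stat,
        "threshold": thresh,
        "p_value": float((1 + np.sum(null >= stat)) / (1 + n_shuffle)),
        "degenerate": False,
    }


def detect_freezing_response(
    resp: UnitResponse,
    n_shuffle: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> dict:
    """Change detection on the onset- and offset-aligned PSTHs.

    Each transition window is monophasic (a single change point), the
    regime the cumulative-sum statistic is built for; the two windows are
    tested at ``alpha/2`` each (Bonferroni) and a unit is responsive if
    either rejects.  The sign comes from the significant window (onset
    taking precedence).
    """
    rng = np.random.default_rng(seed)
    if resp.n_bouts == 0 or np.any(np.isnan(resp.onset)):
        return {"responsive": False, "sign": 0, "latency": float("nan"),
                "degenerate": True}
    d_on = change_detection(resp.onset, n_shuffle, alpha / 2, seed=rng)
    d_off = change_detection(resp.offset, n_shuffle, alpha / 2, seed=rng)
    responsive = d_on["responsive"] or d_off["responsive"]
    # onset window: change direction = freezing-response sign; at offset
    # the response reverts, so the change sign is flipped
    sign = d_on["sign"] if d_on["responsive"] else -d_off["sign"]
    lead = d_on if d_on["responsive"] else d_off
    return {
        "responsive": responsive,
        "sign": sign if responsive else 0,
        "latency": lead.get("latency", float("nan")),
        "onset": d_on, "offset": d_off,
        "degenerate": d_on.get("degenerate", False)
        and d_off.get("degenerate", False),
    }


# ---------------------------------------------------------------------------
# PCA and grouping


def response_pca(matrix: np.ndarray, n_components: int | None = None) -> dict:
    """PCA of the unit-by-time response matrix.

    Returns time-course components, per-component explained-variance
    fractions, and per-unit scores.  Rank deficiency yields fewer
    components with a flag rather than an error.
    """
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    if m.shape[0] < 2:
        raise ValueError("need at least 2 units")
    rank = np.linalg.matrix_rank(m - m.mean(axis=0))
    k = min(n_components or min(m.shape), rank, min(m.shape))
    flags = []
    if n_components is not None and k < n_components:
        flags.append(f"rank-deficient matrix: {k} components instead of "
                     f"{n_components}")
    pca = PCA(n_components=k)
    scores = pca.fit_transform(m)
    return {
        "components": pca.components_,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "scores": scores,
        "flags": flags,
    }


def _window_mean(resp: UnitResponse, halfwidth_s: float = 1.0) -> dict:
    on = resp.onset[np.abs(resp.onset_t) <= halfwidth_s]
    off = resp.offset[np.abs(resp.offset_t) <= halfwidth_s]
    n = resp.interior.size
    mid = resp.interior[n // 4: (3 * n) // 4]
    return {"onset": float(np.nanmean(on)), "offset": float(np.nanmean(off)),
            "sustained": float(np.nanmean(mid))}


def onset_offset_amplitudes(resp: UnitResponse,
                            halfwidth_s: float = 1.0) -> tuple[float, float, float]:
    """(onset, sustained, offset) |z| amplitudes: transition windows of
    ±``halfwidth_s`` around each transition, sustained = middle 50% of the
    normalized episode."""
    w = _window_mean(resp, halfwidth_s)
    return abs(w["onset"]), abs(w["sustained"]), abs(w["offset"])


def assign_groups(
    responses: list,
    detections: list,
    halfwidth_s: float = 1.0,
) -> list[FreezingResponse]:
    """Classify each unit from its change-detection result and window means.

    Responsive units with negative sustained firing are
    sustained-off/transition-on; responsive units with positive sustained
    firing are sustained-on/transition-off; the rest are non-responsive.
    A transition sign agreeing with the sustained sign (rather than
    opposing it) is flagged but the sustained sign decides the group.
    """
    out = []
    for resp, det in zip(responses, detections):
        w = _window_mean(resp, halfwidth_s)
        trans = (w["onset"] + w["offset"]) / 2 - w["sustained"]
        fr = FreezingResponse(
            unit_id=resp.unit_id,
            responsive=det["responsive"],
            sign=det["sign"] if det["responsive"] else 0,
            latency_s=det.get("latency", float("nan")),
            onset_amp=abs(w["onset"]),
            sustained_amp=abs(w["sustained"]),
            offset_amp=abs(w["offset"]),
            sustained_sign=int(np.sign(w["sustained"])) if w["sustained"] else 0,
            transition_sign=int(np.sign(trans)) if trans else 0,
        )
        if not det["responsive"]:
            fr.group = "nonresponsive"
        elif fr.sustained_sign < 0:
            fr.group = "sustained_off_transition_on"
            if fr.transition_sign < 0:
                fr.flags.append("transition sign matches sustained sign")
        else:
            fr.group = "sustained_on_transition_off"
            if fr.transition_sign > 0:
                fr.flags.append("transition sign matches sustained sign")
        out.append(fr)
    return out


# ---------------------------------------------------------------------------
# population vectors


@dataclass
class PopulationMatrix:
    """Pairwise Pearson correlation of population vectors over episode time."""

    time_axis: np.ndarray          # normalized episode time with flanks
    corr: np.ndarray               # (n_time, n_time), masked bins are nan
    n_units: int
    onset_template_corr: np.ndarray
    offset_template_corr: np.ndarray
    masked_bins: np.ndarray


def population_vector_matrix(
    profiles: np.ndarray,
    time_axis: np.ndarray | None = None,
    onset_window: tuple = (0.0, 0.1),
    offset_window: tuple = (0.9, 1.0),
) -> PopulationMatrix:
    """Correlation structure of the population vector over episode time.

    ``profiles`` is (n_units, n_time): each unit's mean z-rate over the
    normalized episode (flanks included if desired).  Columns are the
    population vectors; their full pairwise Pearson correlation matrix is
    returned together with the correlation time-course against the mean
    vector in the onset and offset windows.  Zero-variance time bins are
    masked (NaN) rather than scored.
    """
    m = np.atleast_2d(np.asarray(profiles, dtype=float))
    if m.shape[0] < 10:
        raise ValueError("need at least 10 units for population vectors")
    n_t = m.shape[1]
    if time_axis is None:
        time_axis = np.linspace(0, 1, n_t)
    sd = m.std(axis=0)
    masked = sd <= 1e-12 * (np.abs(m).mean() + 1.0)
    corr = np.full((n_t, n_t), np.nan)
    ok = ~masked
    if ok.any():
        corr_ok = np.corrcoef(m[:, ok].T)
        ii = np.ix_(ok, ok)
        corr[ii] = corr_ok
    def _template(window):
        sel = (time_axis >= window[0]) & (time_axis <= window[1]) & ok
        if not sel.any():
            return np.full(n_t, np.nan)
        tmpl = m[:, sel].mean(axis=1)
        out = np.full(n_t, np.nan)
        for j in np.flatnonzero(ok):
            out[j] = np.corrcoef(tmpl, m[:, j])[0, 1]
        return out
    return PopulationMatrix(
        time_axis=np.asarray(time_axis, dtype=float),
        corr=corr,
        n_units=m.shape[0],
        onset_template_corr=_template(onset_window),
        offset_template_corr=_template(offset_window),
        masked_bins=masked,
    )
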