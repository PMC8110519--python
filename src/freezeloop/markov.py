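"""Two-state Markov model of freezing behaviour.

The animal's behavioural state is modelled as a first-order Markov chain
over {active, freezing} on a fixed time grid (2 s bins by default).  Two
self-transition probabilities fully specify the chain:

* ``p_stay_freeze``  (P_Fz/Fz) — probability of remaining frozen, which
  controls freezing *maintenance*;
* ``p_stay_active``  (P_Act/Act) — probability of remaining active, whose
  complement controls freezing *initiation*.

Under this model bout lengths are geometric, and the expected number of
self-transitions per bout of a state is ``P / (1 - P)``, so each
probability can be estimated directly from the mean bout duration of the
corresponding state.  Because total freezing time and bout-initiation
frequency depend on *both* probabilities, the model separates the two
processes: simulating with one probability changed and the other held at
its baseline value yields a counterfactual prediction of which process a
manipulation altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TimeSeriesSignal

FREEZE = 1
ACTIVE = 0
_STATE_NAMES = {FREEZE: "Fz", ACTIVE: "Act"}


class UndefinedParameterError(ValueError):
    """Raised when a Markov parameter cannot be estimated (no bouts)."""


@dataclass
class MarkovParams:
    """Self-transition probabilities of the two-state behaviour chain."""

    p_stay_freeze: float
    p_stay_active: float
    bin_width: float = 2.0

    def __post_init__(self) -> None:
        for name in ("p_stay_freeze", "p_stay_active"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")

    def p_stay(self, state: int) -> float:
        return self.p_stay_freeze if state == FREEZE else self.p_stay_active

    def stationary_freeze_fraction(self) -> float:
        """Long-run fraction of time frozen, (1-P_AA) / ((1-P_AA)+(1-P_FF))."""
        leave_f = 1.0 - self.p_stay_freeze
        leave_a = 1.0 - self.p_stay_active
        if leave_f == 0.0 and leave_a == 0.0:
            return 0.5  # chain never switches; fraction set by initial state
        return leave_a / (leave_a + leave_f)


@dataclass
class BehaviouralTimeline:
    """Binary freeze/active state sequence on a fixed time grid.

    ``bouts`` is the run-length encoding of ``states``: a list of
    ``(start_bin, end_bin_exclusive, state)`` that tiles the sequence.
    """

    states: np.ndarray
    bin_width: float = 2.0
    t0: float = 0.0
    bouts: list = field(init=False)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 1 or self.states.size == 0:
            raise ValueError("states must be a non-empty 1-D sequence")
        if not np.isin(self.states, (FREEZE, ACTIVE)).all():
            raise ValueError("states must be 0 (active) or 1 (freezing)")
        self.bouts = _run_length_encode(self.states)

    @property
    def n_bins(self) -> int:
        return self.states.size

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def state_at(self, t: float | np.ndarray) -> np.ndarray:
        idx = np.clip(((np.asarray(t) - self.t0) / self.bin_width).astype(int),
                      0, self.n_bins - 1)
        return self.states[idx]

    def bout_epochs(self, state: int, complete_only: bool = False) -> np.ndarray:
        """(start_s, stop_s) epochs of the given state.

        With ``complete_only`` bouts truncated by the session edges are
        dropped (their true length is censored).
        """
        rows = []
        for b0, b1, s in self.bouts:
            if s != state:
                continue
            if complete_only and (b0 == 0 or b1 == self.n_bins):
                continue
            rows.append((self.t0 + b0 * self.bin_width,
                         self.t0 + b1 * self.bin_width))
        return np.asarray(rows, dtype=float).reshape(-1, 2)

    def pct_freezing(self) -> float:
        return 100.0 * float(np.mean(self.states == FREEZE))


@dataclass
class BoutStatistics:
    """Summary of a behavioural timeline at the bout level."""

    mean_bout_dur: dict          # state name -> seconds
    n_bouts: dict                # state name -> count
    pct_freezing: float
    initiation_frequency: float  # freezing bouts started per minute
    bout_duration_ecdf: dict     # state name -> (durations_s, cum_prob)
    per_block_pct: list = field(default_factory=list)


def _run_length_encode(states: np.ndarray) -> list:
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    return [(int(a), int(b), int(states[a])) for a, b in zip(starts, ends)]


# ---------------------------------------------------------------------------
# segmentation


def segment_bouts(
    movement: TimeSeriesSignal,
    threshold: float,
    min_freeze_dur: float = 2.0,
    bin_width: float = 2.0,
) -> BehaviouralTimeline:
    """Segment freezing bouts from a continuous movement trace.

    A contiguous run of movement below ``threshold`` lasting at least
    ``min_freeze_dur`` seconds is scored as freezing; everything else is
    active.  The sample-resolution labelling is then discretized to
    ``bin_width`` bins (a bin is frozen if at least half its samples are).
    """
    if movement.n_samples == 0:
        raise ValueError("empty movement signal")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    below = movement.data < threshold
    freeze = np.zeros_like(below)
    min_run = int(round(min_freeze_dur * movement.rate_hz))
    for a, b, val in _run_length_encode(below.astype(int)):
        if val == 1 and (b - a) >= min_run:
            freeze[a:b] = True
    n_bins = max(1, int(round(movement.n_samples / (bin_width * movement.rate_hz))))
    per_bin = int(round(bin_width * movement.rate_hz))
    states = np.zeros(n_bins, dtype=int)
    for i in range(n_bins):
        chunk = freeze[i * per_bin:(i + 1) * per_bin]
        if chunk.size and np.mean(chunk) >= 0.5:
            states[i] = FREEZE
    return BehaviouralTimeline(states, bin_width=bin_width, t0=movement.t0)


# ---------------------------------------------------------------------------
# estimation and closed forms


def estimate_params(
    timeline: BehaviouralTimeline,
    include_truncated: bool = False,
) -> MarkovParams:
    """Fit the two self-transition probabilities from bout durations.

    For each state, with ``D`` the mean number of self-transitions per
    bout (bout length in bins minus one), the maximum-likelihood geometric
    estimate is ``P_stay = D / (1 + D)`` — the exact inverse of
    :func:`expected_bout_duration`.  Bouts truncated by the session edges
    are excluded by default (their length is censored).
    """
    p = {}
    for state in (FREEZE, ACTIVE):
        lengths = [
            b1 - b0 for b0, b1, s in timeline.bouts
            if s == state and (include_truncated or (b0 > 0 and b1 < timeline.n_bins))
        ]
        if not lengths:
            raise UndefinedParameterError(
                f"no {'complete ' if not include_truncated else ''}"
                f"{_STATE_NAMES[state]} bouts: P_stay undefined"
            )
        d = float(np.mean(lengths)) - 1.0
        p[state] = d / (1.0 + d)
    return MarkovParams(p_stay_freeze=p[FREEZE], p_stay_active=p[ACTIVE],
                        bin_width=timeline.bin_width)


def expected_bout_duration(params: MarkovParams, state: int) -> tuple[float, float]:
    """Expected bout duration for a state.

    Returns ``(self_transitions, seconds)``: the expected number of
    self-transitions per bout, ``P / (1 - P)``, and the expected total
    bout duration ``bin_width / (1 - P)`` seconds (the bout occupies
    one entry bin plus one bin per self-transition).
    """
    p = params.p_stay(state)
    if p >= 1.0:
        return float("inf"), float("inf")
    return p / (1.0 - p), params.bin_width / (1.0 - p)


# ---------------------------------------------------------------------------
# simulation


def simulate_timeline(
    params: MarkovParams,
    n_bins: int,
    seed=None,
    initial_state: int | None = None,
) -> BehaviouralTimeline:
    """Simulate the two-state chain for ``n_bins`` steps.

    The initial state is drawn from the stationary distribution unless
    forced via ``initial_state``.  ``seed`` may be an int or a Generator.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n_bins)
    states = np.empty(n_bins, dtype=int)
    if initial_state is None:
        states[0] = FREEZE if u[0] < params.stationary_freeze_fraction() else ACTIVE
    else:
        states[0] = initial_state
    stay = {FREEZE: params.p_stay_freeze, ACTIVE: params.p_stay_active}
    for i in range(1, n_bins):
        prev = states[i - 1]
        states[i] = prev if u[i] < stay[prev] else 1 - prev
    return BehaviouralTimeline(states, bin_width=params.bin_width)


def simulate_summary(
    params: MarkovParams,
    n_bins: int,
    n_reps: int = 100,
    seed=None,
    initial_state: int | None = None,
) -> dict:
    """Repeatedly simulate the chain and summarize each run.

    Returns per-repetition arrays of percent time frozen, freezing-bout
    initiation frequency (bouts/min) and freezing bout count, with their
    means and SDs — the model-validation quantities that depend on both
    chain parameters.
    """
    rng = np.random.default_rng(seed)
    pct = np.empty(n_reps)
    init_freq = np.empty(n_reps)
    n_bouts = np.empty(n_reps, dtype=int)
    mean_dur = np.full(n_reps, np.nan)
    for r in range(n_reps):
        tl = simulate_timeline(params, n_bins, seed=rng, initial_state=initial_state)
        pct[r] = tl.pct_freezing()
        fz = [(b0, b1) for b0, b1, s in tl.bouts if s == FREEZE]
        n_bouts[r] = len(fz)
        init_freq[r] = len(fz) / (tl.duration / 60.0)
        if fz:
            mean_dur[r] = float(np.mean([(b1 - b0) for b0, b1 in fz])) * tl.bin_width
    return {
        "pct_freezing": pct,
        "initiation_frequency": init_freq,
        "n_bouts": n_bouts,
        "mean_freeze_bout_dur": mean_dur,
        "mean": {
            "pct_freezing": float(pct.mean()),
            "initiation_frequency": float(init_freq.mean()),
            "n_bouts": float(n_bouts.mean()),
        },
        "sd": {
            "pct_freezing": float(pct.std(ddof=1)) if n_reps > 1 else 0.0,
            "initiation_frequency": float(init_freq.std(ddof=1)) if n_reps > 1 else 0.0,
            "n_bouts": float(n_bouts.std(ddof=1)) if n_reps > 1 else 0.0,
        },
    }


def counterfactual_bouts(
    params_baseline: MarkovParams,
    p_stay_freeze_new: float,
    n_bins: int,
    n_reps: int = 100,
    seed=None,
) -> dict:
    """Predict bout statistics with maintenance changed and initiation fixed.

    Simulates the chain with ``p_stay_freeze`` replaced by the new value
    while ``p_stay_active`` is held at baseline — the counterfactual that
    asks whether a change in freezing *maintenance* alone accounts for an
    observed change in bout counts.
    """
    cf = MarkovParams(
        p_stay_freeze=p_stay_freeze_new,
        p_stay_active=params_baseline.p_stay_active,
        bin_width=params_baseline.bin_width,
    )
    return simulate_summary(cf, n_bins, n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# summaries


def summarize(
    timeline: BehaviouralTimeline,
    cs_events: np.ndarray | None = None,
    cs_duration: float = 30.0,
    post_window: float = 30.0,
    block_size: int = 4,
) -> BoutStatistics:
    """Bout-level summary of a timeline, optionally per CS block.

    When conditioned-stimulus onset times are given, percent freezing is
    also reported for blocks of ``block_size`` consecutive sounds, each
    window covering the sound plus the subsequent ``post_window`` seconds
    (overlapping windows are merged with a warning).
    """
    mean_dur, n_bouts, ecdf = {}, {}, {}
    for state in (FREEZE, ACTIVE):
        durs = np.array([(b1 - b0) * timeline.bin_width
                         for b0, b1, s in timeline.bouts if s == state])
        name = _STATE_NAMES[state]
        n_bouts[name] = int(durs.size)
        mean_dur[name] = float(durs.mean()) if durs.size else float("nan")
        if durs.size:
            xs = np.sort(durs)
            ecdf[name] = (xs, np.arange(1, xs.size + 1) / xs.size)
        else:
            ecdf[name] = (np.empty(0), np.empty(0))
    n_fz = n_bouts["Fz"]
    init_freq = n_fz / (timeline.duration / 60.0)

    per_block = []
    if cs_events is not None and len(cs_events):
        cs_events = np.sort(np.asarray(cs_events, dtype=float))
        windows = np.column_stack([cs_events, cs_events + cs_duration + post_window])
        merged = [list(windows[0])]
        overlapped = False
        for a, b in windows[1:]:
            if a < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
                overlapped = True
            else:
                merged.append([a, b])
        if overlapped:
            import warnings
            warnings.warn("overlapping CS windows merged", stacklevel=2)
        for i in range(0, len(merged), block_size):
            block = merged[i:i + block_size]
            vals, weights = [], []
            for a, b in block:
                i0 = int(np.floor((a - timeline.t0) / timeline.bin_width))
                i1 = int(np.ceil((b - timeline.t0) / timeline.bin_width))
                chunk = timeline.states[max(0, i0):min(timeline.n_bins, i1)]
                if chunk.size:
                    vals.append(100.0 * float(np.mean(chunk == FREEZE)))
                    weights.append(chunk.size)
            if vals:
                per_block.append(float(np.average(vals, weights=weights)))

    return BoutStatistics(
        mean_bout_dur=mean_dur,
        n_bouts=n_bouts,
        pct_freezing=timeline.pct_freezing(),
        initiation_frequency=init_freq,
        bout_duration_ecdf=ecdf,
        per_block_pct=per_block,
    )
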