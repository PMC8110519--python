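# Methods

## The behavioural model

Freezing behaviour is modelled as a first-order two-state Markov chain on a
2 s grid. At each step the animal stays in its current state (freezing Fz or
active Act) with probability `P_Fz/Fz` or `P_Act/Act`, else it switches.
Under the chain, bout lengths are geometric, and the expected number of
*self-transitions* per bout of a state is

    D = P / (1 − P),

so the expected total bout duration is `bin_width / (1 − P)` seconds (one
entry bin plus `D` continuation bins). The estimator inverts this exactly:
`P̂ = D̂ / (1 + D̂)` with `D̂` the mean bout length in bins minus one. We read
the printed closed form as the self-transition count (not the total bin
count) precisely so that estimator and formula are an exact inverse pair and
bout lengths follow a geometric law; the total duration in seconds is
reported alongside. Bouts truncated by the session edges are excluded from
estimation by default (their length is censored); this is configurable, as
is the initial state of simulations (stationary draw by default).

The point of the model is separation of *initiation* (rate `1 − P_Act/Act`
out of the active state) from *maintenance* (`P_Fz/Fz`). Mean bout duration
identifies each parameter separately, while total freezing time and
bout-initiation frequency depend on both; `simulate_summary` (100
repetitions by default) reproduces the latter two for model validation, and
`counterfactual_bouts` simulates with one probability replaced and the other
held at baseline to ask which process a manipulation changed. The stationary
freezing fraction is `(1 − P_AA) / ((1 − P_AA) + (1 − P_FF))`, and the
bout-initiation rate per bin is `π_Act (1 − P_AA)` — both used as analytic
oracles in the tests.

Freezing is segmented from a movement trace as any sub-threshold run lasting
at least 2 s; the 2 s bin width matches that minimum.

## Spectral analysis

Spectrograms and coherence use Slepian (dpss) multitapers: 3 s windows,
0.1 s steps, 5 tapers, time–bandwidth NW = 3 (only the taper count is
prescribed by convention; NW = 3 is the standard pairing for K = 5 = 2NW − 1
tapers). Power is one-sided density scaled so that the sum over frequencies
times the bin width equals the windowed variance (a Parseval identity tested
directly). The effective resolution bandwidth is NW/T = 1 Hz; tests that pin
a tone's frequency therefore use the band centroid rather than the argmax
bin. Band signal-to-noise is the mean per-frequency power inside 3–6 Hz over
the mean outside it — unity for a flat spectrum regardless of bandwidth,
which resolves the ambiguity between "total" and "mean" band power in favour
of a bandwidth-independent quantity. Group averaging normalizes each
subject's spectrogram to its total power; within-subject band ratios are
unchanged by this (tested).

Directed influence between the olfactory-bulb (OB) and dorsomedial
prefrontal (dmPFC) signals uses parametric spectral Granger causality:
signals are decimated to 250 Hz, restricted to concatenated freezing
epochs, fitted with a joint VAR (order by BIC, capped at 20), and Geweke's
frequency-domain measure is averaged over 3–6 Hz. A time-reversed surrogate
provides a bias threshold. The VAR route was chosen over nonparametric
factorization because the downsampled, epoch-concatenated segments are short
and the band is narrow; an unstable fit raises rather than returning a
number.

The ideal-observer analysis thresholds 2 s-binned 3–6 Hz power: hit rate
= P(power > z | freezing), false alarm = P(power > z | active), thresholds
swept over the observed unique values plus ±∞, AUC by trapezoid. This equals
the Mann–Whitney probability of discriminating a freezing from an active
bin (ties counted half), is exactly 1 under perfect separation and 0.5 for
uninformative power, and is invariant under monotone transforms of power
(tested). Sessions with under 10 s of either state are excluded with a
recorded reason.

Episode dynamics resample each freezing bout onto a 100-point
duration-normalized grid (linear interpolation; optional real-time flanks).
Transition speed is the maximal derivative `|k·amp|/4` of a 4-parameter
logistic least-squares fit to the 0–1-normalized onset/offset curves of band
power, aligned in real time (±3 s) over bouts longer than 6 s and computed
from a finer 1 s / 3-taper spectrogram, since a 3 s window would smear a
sharp offset over its own length. Micromovements are detected as
accelerometer transients exceeding six times the median freezing
|acceleration| in ±0.2 s windows around CS pip times inside freezing bouts;
their amplitude is Pearson-correlated with the normalized instantaneous
band power, with correlations suppressed below 10 events.

## Phase and spike statistics

Two instantaneous-phase estimators share the convention 0 = LFP peak,
π = trough. The narrow-band estimator filters 4–6 Hz (4th-order Butterworth,
zero-phase) and takes the analytic-signal angle. The broadband estimator
filters 1–20 Hz, detects peaks and troughs (prominence 0.5 SD of the
filtered trace, minimum separation half a period of the upper band edge,
strict alternation enforced by keeping the more extreme of same-kind
neighbours), and interpolates phase linearly between extrema — this follows
a rhythm whose frequency wanders between 2 and 15 Hz, where any fixed band
fails; a chirp-tracking test quantifies this. Its quality metric is the MSE
between the signal and a reconstruction `amplitude(t)·cos(phase(t))` from
the detected extrema.

Spike locking uses the Rayleigh statistic `Z = R²/n` (log-transformed for
population plots; p by the standard finite-n series), the maximum-likelihood
von Mises concentration κ (piecewise Bessel-ratio inversion), and pairwise
phase consistency computed via the O(n) identity `(R² − n)/(n(n−1))` —
unbiased in spike count (0 in expectation under uniformity; converges to
`(I₁(κ)/I₀(κ))²` for von Mises phases; both tested against Monte-Carlo and
Bessel oracles).

Because an asymmetric oscillation spends unequal time per phase bin, raw
phase histograms of a unit firing uniformly in time look locked. The
correction maps spike phases through the empirical CDF of the LFP's own
phase occupancy, `θ → 2π·F(θ)`, the minimal transform guaranteeing that
uniform-in-time firing maps to uniform phases while genuine modulation
survives (both tested by construction).

Freeze/active locking comparisons control duration by comparing freezing
against the contiguous highest-movement active window of equal total length,
and control rate by subsampling the higher-count state to the lower count
(200 bootstrap draws, median κ and PPC reported). At simulated spike counts
the Rayleigh test detects even weak active-state locking, so the
state-contrast recovery check uses matched Δκ rather than the percentage of
significant units; the percentage and its chi-squared contrast are reported
descriptively. Rate changes use the bounded modulation index
`(X₁ − X₂)/(X₁ + X₂)`.

Cell typing k-means-clusters z-scored waveform features (half-amplitude
duration, trough-to-peak latency, asymmetry index) into two groups,
optionally pooled with a larger reference set; the longer-trough-to-peak
cluster is labelled putative pyramidal. Degenerate single-cluster inputs are
flagged, not forced.

## Freezing responses

Per-unit firing is binned at 0.5 s, z-scored against the unit's own
session-wide mean and SD, and averaged over freezing bouts ≥ 4 s into
onset- and offset-aligned PSTHs (±4 s) plus a 100-bin normalized interior
(bin sizes and window extents are our choices; the source analysis prints
none). Responsiveness is a cumulative-sum test: the PSTH is mean-centred
within the window, the statistic is the peak |cumsum|, and the null is that
statistic over 1000 random bin reorderings. Centring is essential — the
window sum is permutation-invariant, so without it the shuffle null has no
power. The onset and offset windows are tested separately at α/2 each
(Bonferroni): each is monophasic (a single change point), the regime the
statistic is built for, whereas a concatenated multiphasic vector partially
cancels in the cumulative sum. The response sign is the direction of the
change at the detected change point (the negated sign of the cusum
extremum; flipped for the offset window, where the response reverts). Known
limitation: against a bin-shuffle null, a response confined to a single
mid-window bin is near-undetectable in principle (the arrangement carries
almost no information); power is high for responses adjacent to the
alignment point or extended over several bins, which is where
transition-aligned responses live.

Responsive units with negative sustained firing (middle 50% of the
normalized interior) form the sustained-off/transition-on group; positive
sustained, the sustained-on/transition-off group; the rest non-responsive.
Onset/sustained/offset amplitudes are |mean z| over ±1 s transition windows
and the mid-episode window. PCA of the unit-by-time response matrix
separates the sustained (PC1) from the transition (PC2) component.
Population analysis stacks each unit's pre-onset flank, normalized interior
and post-offset flank, takes per-time-bin population vectors, and reports
their full pairwise Pearson correlation matrix plus correlation time-courses
against onset- and offset-window template vectors; zero-variance bins are
masked.

## The synthetic-data generator

The generator produces every pipeline input with the statistical structure
the analyses assume. Defaults emulate a post-conditioning test session:
900 s; `P_Fz/Fz = 0.9`, `P_Act/Act = 0.8` at 2 s bins (two-thirds freezing,
mean bouts 20 s / 10 s); breathing synthesized cycle by cycle — frequency
Normal(4.0, 0.2) Hz and tidal volume 1.5× with reduced variability during
freezing, uniform 3–12 Hz otherwise — so the per-cycle table is exact ground
truth; LFPs at 1250 Hz with 1/f noise (exponent 1): the OB is the breathing
phase oscillation with state-dependent gain, the dmPFC an attenuated copy
delayed by 20 ms plus independent noise, making the OB→dmPFC direction true
by construction. Entrainment gain rises with a 3 s time constant after
freezing onset and collapses at offset, producing the gradual-rise /
sharp-fall 4 Hz profile, stronger power in long episodes, and declining
micromovement density. Spikes are Bernoulli-thinned inhomogeneous point
processes with unit-mean von Mises phase gain (κ = 2 freezing, 0.5 active
for locked units) times sustained/transition gains per response class
(24 units: 11 sustained-off/transition-on, 9 non-responsive, 4
sustained-on/transition-off, echoing the recorded proportions). The
accelerometer has a low freezing noise floor, high active variance, and
pip-locked bursts whose amplitude is `1.5 − 1.0·power_norm + 0.43·ε` —
calibrated so the recovered amplitude–power correlation is ≈ −0.55 — with
emission probability declining in power. A separate video-like movement
trace drives threshold segmentation. All draws flow through one seeded
generator per call; identical configs are byte-identical.

What the generator does **not** emulate: spike-sorting contamination and
unit drift, volume conduction and shared noise between OB and dmPFC
(coherence during active behaviour is therefore lower than in real data),
breathing-cycle waveform detail (the cycle shape and noise spectra are
calibration choices, not claims), movement artifacts in the LFP, and any
slow non-stationarity across the session. Passing tests therefore
demonstrate that each analysis recovers the structure it targets at
realistic signal strengths — not that real recordings contain that
structure.

## Numerical choices and problem sizes

Analysis-stage tests run on 200–300 s sessions and the end-to-end recovery
on the 900 s default; spectral stages operate on LFPs decimated to 250 Hz.
Estimator calibrations use 10⁴ Monte-Carlo draws (Rayleigh, PPC), 2000 null
PSTHs (change detection), and 200 seeded chains per maintenance probability
(parameter recovery). Degenerate inputs are flagged rather than scored:
constant PSTHs, single-cluster waveform sets, zero-variance population
bins, sessions lacking 10 s of a state, units below 20 spikes per state.
Sigmoid fits report non-convergence instead of a slope. Ties in the ROC
threshold sweep count as half (Mann–Whitney convention).
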