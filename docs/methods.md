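# Methods

This note records the models, estimators and numerical choices behind
`dynconn`, in the order data flows through the pipeline, and what the
synthetic-data validation does and does not establish.

## Trace extraction and ΔF/F₀

A recording is a grayscale stack (frames × height × width) at a fixed frame
rate (default 22.7 Hz, a typical CCD acquisition rate for wide-field
GCaMP6s imaging). Stacks are read in temporal segments (default tenths) so
long recordings never occupy memory twice; segmented and whole reads are
frame-exact identical by construction and by test.

ROI seeds are user-supplied pixel coordinates — one per soma, chosen on the
temporal mean projection, plus exactly one seed in a fluorescence-free
region. Each signal is the per-frame mean of the plus-shaped 5-pixel
neighbourhood {centre, up, down, left, right}; a 5-pixel average suppresses
single-pixel shot noise without integrating neighbouring cells. The
background trace is subtracted frame-by-frame from every cell trace and is
reused for the whole recording (camera offset and stray light are assumed
stationary). Negative samples after subtraction are kept — clipping would
bias the baseline upward.

Baseline F₀ is the mean of the lowest `low_fraction` (default 10%) of
samples. A single global minimum would ride on the noise floor; averaging
the lowest decile estimates the quiescent fluorescence stably as long as
the cell spends ≳10% of the recording at rest (true at the firing rates
considered here; at sustained high rates F₀ is biased upward and ΔF/F₀
compressed — a limitation shared by any percentile baseline). F₀ ≤ 0
raises an error rather than producing infinite ΔF/F₀; it almost always
means the background seed actually contained signal. ΔF/F₀ = (F − F₀)/F₀.

Conventions: 0-based (row, col) pixels, 0-based frames, t = i/fs, all
windows half-open [t₀, t₀ + W).

## Composite connectivity weight

For each unordered cell pair, on each 1-minute interval, four Pearson-type
coefficients are computed and averaged with equal weight:

1. **w_time** — sample Pearson r of the two ΔF/F₀ traces on the interval.
2. **w_spectrum** — Pearson r of the traces' one-sided periodogram
   magnitudes, DC bin excluded (DC reflects baseline, not firing
   structure). This compares frequency content while discarding phase.
3. **w_window** — the mean of the Pearson r over six consecutive
   10-second sub-windows. Local co-fluctuations average away in a
   whole-interval coefficient; sub-windowing restores them.
4. **w_derivative** — Pearson r of first central differences of
   rloess-smoothed traces. Derivatives emphasise transient onsets and kill
   additive offsets; the metric is invariant to offset and positive
   rescaling of either trace.

A coefficient is *undefined* (NaN) when a window has zero variance; it is
then excluded from the composite rather than set to zero, because silent
zeros would bias weights toward zero exactly where data are least
informative. The four metrics are combined at the 1-minute level (w_time,
w_spectrum, w_derivative on the full interval; w_window from its
sub-windows); combining per-sub-window instead is a configuration switch
away but was not made the default, as the sub-window spectra at 10 s × 22.7
Hz have too few low-frequency bins to be individually meaningful.

The interval series (10 intervals for the canonical 10-minute recording; a
trailing partial interval is kept if it covers at least half an interval)
averages into the final per-pair weight, assembled into a symmetric
unit-diagonal matrix. Strength labels bin |w| left-closed/right-open at
0.3 / 0.5 / 0.7 / 0.9 (weak / low / moderate / strong / very strong), the
top bin closed at 1.

**Percent change.** 100·(w_t − w̄_base)/max(|w̄_base|, ε) with ε = 0.05:
near-zero baselines otherwise explode the ratio; 0.05 is the bottom of the
"weak" band and caps the amplification at 20×/unit. With the series itself
as baseline this is a fluctuation measure — saturated (post-glutamate)
networks show small relative fluctuation, controls large, matching the
qualitative behaviour the composite weight is meant to expose.

**rloess.** Robust local quadratic regression: `round(span·N)` nearest
samples per fit (floor 5; default span 2.5%), tricube distance weights,
five bisquare reweighting passes with scale 6·median|r|. Windows clamp at
the edges so every fit uses the full span; fits are batched as N
simultaneous 3×3 solves. The robustness scale is floored at 1e-8 of the
data range so that exactly-polynomial inputs (residuals at machine
precision) do not zero all weights. A consequence of bisquare
robustification worth knowing: in a noise-free trace that is baseline
almost everywhere, isolated transients are treated as outliers and can be
smoothed flat; with realistic noise and ≥ 60 s windows this does not occur.

## Event detection and IEI statistics

ΔF/F₀ is filtered with a 3 Hz low-pass 3rd-order Butterworth applied
forward-backward (zero phase, so peak times do not shift; the magnitude
response is applied twice). The closed-form two-pass amplitude gain,
`1/(1 + (tan(πf/fs)/tan(πf_c/fs))^(2n))`, is exposed for verification.

Candidate peaks are local maxima above µ + kσ of the *filtered* trace
(k = 1 by default, k = 2 available for noisy data); the µ-relative
threshold makes detection invariant to additive offsets. Peaks must be at
least 0.5 s wide, where width is the duration of the excursion above
half the peak's height over µ. Width-at-half-prominence was considered and
rejected: a genuine transient riding on the decay tail of the previous one
has vanishing prominence and would be discarded, inflating inter-event
intervals by over 20% at 0.2 Hz; excursion width keeps such events while
still rejecting narrow noise spikes (noise excursions after the 3 Hz
filter last ~0.15 s). Accepted peaks are finally separated by at least
0.5 s — the taller of a violating pair wins, ties go to the earlier peak.

IEIs are first differences of accepted peak times. The goodness-of-fit
summary reports the Kolmogorov–Smirnov distance against an exponential at
the moment-matched rate together with the asymptotic 95% critical value
(1.358/√n); it reports, it does not threshold. Detected trains carry a
0.5 s dead time from the separation rule, so large detected samples will
correctly *fail* a strict exponential KS even for Poisson ground truth;
the test is calibrated on the spike trains themselves.

**Resolution limit.** With GCaMP6s-like kinetics (rise 0.2 s, decay 1.0 s,
kernel FWHM ≈ 0.94 s) two spikes closer than the separation floor are one
fluorescence event by contract, and peak-time jitter grows with noise
because the kernel top is broad. Detection fidelity is therefore scored
against *resolvable* ground truth (true spikes closer than 0.5 s merged to
their cluster mean) at ±0.25 s matching tolerance; at an SNR of 10
(noise_sd = amplitude/10) the detector sustains F1 ≥ 0.9 at 0.2 Hz. At
0.5 Hz and above, kernel overlap dominates and per-spike recovery is not
achievable with any threshold detector on this indicator.

## Wavelet analysis

The continuous wavelet transform uses the analytic Morlet with ω₀ = 6 —
the standard choice for coherence, balancing time against frequency
resolution — evaluated in the Fourier domain,
ψ̂(sω) = π^(−1/4)·H(ω)·exp(−(sω − ω₀)²/2), on a record zero-padded to the
next power of two. Scales are log-spaced at 12 voices/octave between
f_max = fs/4 and f_min = 4 cycles per record; frequency = 
(ω₀ + √(2+ω₀²))/(4πs). The cone of influence marks coefficients within one
e-folding time (√2·s) of either edge; every scalar summary masks it.

Coherence smooths the auto- and cross-spectra (each pre-weighted 1/s) in
time with a Gaussian of standard deviation one scale and across scales
with a 0.6-octave boxcar before forming
|S(W_x W_y*)|²/(S(|W_x|²)·S(|W_y|²)). Without smoothing the ratio is
identically 1; with it, independent white noise averages ≈ 0.34 over the
COI-valid region while identical signals stay ≥ 0.99 — the dynamic range
the estimator actually has. The time smoothing runs as a per-scale Fourier
multiplication with reflect padding (the largest kernels span thousands of
samples). The cross-spectrum is assembled from real and imaginary parts
through identical real-valued smoothing paths, which makes the phase
antisymmetric under argument swap bit-exactly.

Phase convention: phase = arg S(W_x W_y*), positive when the first trace
leads; for a shared oscillation at frequency f delayed by τ the phase is
2πfτ. The direction estimate takes the circular mean phase over COI-valid
cells within half an octave of the pair's peak-coherence frequency that
exceed a coherence threshold (default 0.7), and returns "undetermined"
when fewer than 5% of band cells qualify or the mean phase is within
0.1 rad of zero — zero-lag synchrony has no meaningful leader. The
coherence–connectivity association uses all COI-valid cells (no frequency
band restriction) on both sides of the regression.

## Spatial statistics

Distances are Euclidean between seed centres times the pixel size.
Distance–connectivity association is a plain Pearson coefficient across
pairs. Condition contrasts use the two-tailed Welch's t-test
(Satterthwaite dof); no multiple-testing correction is applied, matching
the raw-threshold reporting style of the analysis this package supports —
callers needing familywise control should add it. Z-scoring (n−1 sd) is
applied per condition across pairs before pooling across cultures; both
raw and Z-scored pooling are supported since the choice is genuinely open.

## Synthetic data: what it emulates, what it does not

Spike trains are homogeneous Poisson. Pairwise synchrony is a mother-train
construction: a common train of rate `shared_fraction·base_rate` is shared
by all cells (exact coincidences), each cell adds a private train of rate
`(1 − shared_fraction)·base_rate`, so the marginal rate is `base_rate` for
every synchrony level and ground-truth synchrony is a single interpretable
parameter. Fluorescence is a unit-peak difference of exponentials
(rise 0.2 s, decay 1.0 s — GCaMP6s-like; needed only for synthesis, the
inference side assumes no kernel), baseline F₀ = 100, additive Gaussian
noise. Default conditions: 600 s at 22.7 Hz, base rate 0.2 Hz, trace noise
2% of event amplitude.

The stimulus is a piecewise-constant switch at `stimulus_time` (default
300 s): the glutamate-like condition triples the rate and raises the
shared fraction to 0.9 (global excitation → near-saturated synchrony); the
control applies a 1.3× rate gain with unchanged synchrony, emulating the
mild excitability shock of a media perfusion — firing accelerates in both
conditions, coupling changes only in one. Videos paint each cell as a
Gaussian-profile disk (σ = 2 px, 3σ cut) on a grid with a guaranteed
signal-free background slot, at 50 camera counts per unit fluorescence
over a 200-count offset, quantised to 16 bits; pixel noise uses the same
relative scale as trace noise. All randomness flows from one seed through
keyed SeedSequence substreams, so outputs are bit-reproducible and
per-cell streams independent.

Not emulated: bursting or refractory firing, indicator nonlinearity and
saturation, photobleaching, motion, spatially propagating waves, shot
noise (Gaussian only), overlapping somata. Passing tests therefore show
the estimators recover the generative parameters of this model — rate,
synchrony, delay, spectral content — not that they are robust to every
artifact of real recordings; the manual-seed extraction path in
particular assumes stationary, well-separated cells.

## Problem sizes in tests and acceptance runs

Validation runs use 600 s two-cell recordings for synchrony sweeps
(10 seeds per level), a 3000 s single-cell recording for IEI recovery
(~600 detected events), 21 pairs spanning shared fraction 0→1 for the
coherence–connectivity regression, 7-cell (21-pair) recordings for the
stimulus contrast with 10 four-cell seeds for the fluctuation comparison,
and a 5-cell, 240 s, 64×64 video for the round trip. These sizes put
Monte-Carlo error comfortably inside the asserted margins while keeping a
full validation run around a minute.
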