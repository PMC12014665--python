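# Methods

This note documents the models, the synthetic-data generator, the numerical
choices in the peak scorer and statistics layers, and the limits of what the
synthetic validation establishes.

## The measurement model

A cervical VEMP is recorded as stimulus-locked surface EMG over the tonic
sternocleidomastoid. The analysis unit is a *sequence*: the mean of exactly
300 accepted epochs at one bone-conduction stimulus level (dB HL on the
study-specific scale). Epochs containing any sample beyond ±800 µV are
rejected before averaging (strict inequality: a sample exactly at 800 µV is
kept). Each participant's *background EMG tension* is the RMS of the final
18 ms pre-onset span (half-open `[onset − 18 ms, onset)`) of the pointwise
mean of their first six sequences in acquisition order; all sequences are
divided by it. Amplitudes become dB response levels,
`RL = 20·log10(amp/background) − 20`, with 0 dB RL the projected response
threshold (amplitude 10× background).

Two distinct noise references coexist deliberately: the dB RL denominator is
the participant-level six-sequence background tension, while the
null-response rule compares the p1–n1 amplitude with 1.65× the pre-stimulus
RMS *of the sequence being evaluated*. Because the six-sequence background
is itself an average of 1,800 epochs, its RMS is far below the raw ~50 µV
muscle tension; the pipeline implements the definitions exactly as stated
and does not attempt to reconcile their physical interpretations.

## Peak scoring

Extrema are strict local maxima/minima with topographic prominence (as in
MATLAB `findpeaks` / `scipy.signal.peak_prominences`, window extending to
the trace ends). For the initial maximum-level sequence, n1 is the most
prominent trough with latency in the inclusive window [15, 37] ms; later
sequences search within ±5 ms of that initial n1 (clipped to the window).
Candidate peaks must satisfy 5 ms ≤ latency < n1. Points: 5/4/3 to the
three most prominent candidates; 3 (ratio ≥ 2/3), 2 (1/3 < ratio < 2/3) or
1 to those same three by prominence relative to the top candidate; 5…1 to
the five candidates with latencies closest to n1, over **all** surviving
candidates (the scheme names five peaks, so it cannot be restricted to the
top-3 subset). Highest total wins; ties resolve to the candidate closest to
n1, residual ties to the earlier latency. Decisions the source procedure
leaves open, resolved here: prominence-rank ties break to the earlier
latency; with fewer than 3 (or 5) candidates the awards simply run down the
available list; equal n1-distances share the award order by earlier
latency; the anchored-window half-width (5 ms) is configurable. A pick is
null when the p1–n1 amplitude is strictly below 1.65× the sequence's
normalized pre-stimulus RMS; null results propagate as flagged picks, never
exceptions. If the initial sequence itself yields no anchor, later
sequences fall back to the unanchored window. Picked latencies are always
integer multiples of the sample period (0.33 ms at 3 kHz).

The scorer is validated against a brute-force oracle that re-enumerates
extrema and re-derives every award by definition on 1,000 random waveforms.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
with defaults (`paper2025` preset) set to the study design it emulates:

| parameter | default | meaning |
|---|---|---|
| n_women / n_men | 24 / 24 | balanced cohort |
| latency mean ± SD (F) | 9.99 ± 2.74 ms | per-participant true p1–n1 latency |
| latency mean ± SD (M) | 12.41 ± 2.54 ms | idem, men |
| p1/n1 anchors (F) | 15.3 / 25.3 ms | absolute-latency centres |
| p1/n1 anchors (M) | 14.6 / 27.0 ms | idem, men |
| slope mean ± SD | 1.89 ± 0.25 dB RL per dB HL | amplitude growth |
| background RMS | 50 µV | biofeedback tension target |
| sample rate | 3 kHz | 0.33 ms latency grid |
| pre/post-stimulus window | 18 / 50 ms | epoch geometry |
| level series | 40,38,36,34,39,37,35,40 dB HL | two descending series + repeat |
| epochs per sequence | 300 | sequence average size |
| artifact probability / bound | 0.02 / 800 µV | contaminated epochs |
| threshold level | 37 dB HL | level where true amplitude is 10× background |
| jitter SD | 0.5 ms | per-sequence latency scatter (p1 and n1 independently) |

Waveform: two Gaussian lobes (positive at p1, negative at n1, width 3 ms,
automatically narrowed when the latencies are close so the analytic extrema
stay put), rescaled so max − min equals the target amplitude exactly on the
sample grid and zeroed outside the response region. True amplitude at level
L is `background · 10^((slope·(L − threshold) + 20)/20)`: 0 dB RL at the
threshold level, growing at the participant's slope on the RL scale. The
default threshold (37 dB HL) keeps the 40 dB HL amplitude below the ±800 µV
rejection bound — a geometric constraint of anchoring the RL scale to the
raw 50 µV background; a consequence is that default-level sequences have
high SNR and the 1.65× null rule only fires in constructed low-amplitude
scenarios, which is where the tests exercise it.

Noise: Gaussian, spectrally shaped to a 20–450 Hz surface-EMG band
(2nd-order Butterworth, configurable) and rescaled to the target RMS. The
band was chosen on physiological grounds — tonic sEMG carries negligible
power near the 1.5 kHz recording-chain corner — and it matters: noise that
is white to Nyquist decorates the averaged waveform's trough bottom with
sub-millisecond local maxima, and under the literal points scheme such a
bump (prominence rank 3 → 3+1 points, proximity → 5) can outscore a distant
true p1 (5+3+0), producing gross mislocations that the procedure's
visually-verified behaviour on real data rules out. With the EMG band the
spurious-candidate rate is ~0.1% of picks.

Per-sequence jitter is applied to p1 and n1 independently (SD 0.5 ms each),
so repeated sequences scatter in p1–n1 latency and per-participant SDs
grow as presentation counts shrink, qualitatively matching design-reduction
behaviour. Artifacts are brief ±(2.5–4)×800 µV deflections at random
positions in a randomly chosen 2% of epochs; epoch blocks are topped up
until at least 300 epochs survive rejection, mirroring the recorder's
online compensation. The planned session is 8 × 300 = 2,400 presentations;
real sessions averaged more because extra low-level sequences were optional
— the schedule is a config list, so longer sessions are a one-line change.

Two synthesis routes share one distribution: the epoch-level reference
route, and a fast route that draws each 300-epoch average directly from its
exact sampling law (template + shaped noise at RMS/√300 — exact for
Gaussian noise). The power-simulation layer uses the fast route by default;
parameter-recovery acceptance runs use the epoch route.

## Statistics

Mixed models are random-intercept fits estimated by **ML**, not REML,
because the likelihood-ratio comparisons change fixed effects; singular
fits are flagged, not raised. Sex is coded 0 = female, 1 = male, so a
positive coefficient means longer latency in men. The amplitude model uses
dB RL as response with stimulus level as a fixed slope
(`db_rl ~ stimulus_level + sex + (1|participant)`); the latency model omits
the stimulus term by default since latency does not grow with level.
Welch's t keeps the fractional Satterthwaite df internally and rounds only
for display. Conditional R² is the Nakagawa–Schielzeth plug-in
`(σ²_fixed + σ²_intercept)/(σ²_fixed + σ²_intercept + σ²_resid)` with
σ²_fixed the variance of the fixed-effect predictions. No multiple-testing
correction is applied by default; the absolute p1/n1 analyses can be
Bonferroni-corrected by the caller.

Analytic power follows the G*Power post-hoc convention: pooled-SD d,
df = 2n − 2 even under unequal variances, noncentrality d·√(n/2),
two-tailed α = 0.05. Empirical power simulates cohorts, keeps the first
`presentations/300` sequences in acquisition order (random subsets
optional) and the first k participants per sex (balanced; random subsets
optional), and reports the fraction of significant Welch tests; the default
1,000 cohorts give a binomial SE ≤ 0.016.

Meta-analysis pools raw mean differences (men − women, positive = longer
in men) with inverse-variance weights and DerSimonian–Laird τ² (REML
optional; both validated against R `metafor` references frozen in the
tests). Meta-regression uses weighted least squares with a
method-of-moments residual τ² and Wald z inference; studies missing the
moderator are excluded; repeated-measure rows enter unadjusted. For the
regression result the reported CI bounds are those of the moderator slope.

## Problem sizes

The acceptance computation uses 200 cohorts of 48 participants × 8
sequences × ≥300 epochs through the full epoch-level route (~3–4 minutes
on one CPU); empirical-power and type-I-error suites use the fast
sequence-level route with 400–500 cohorts.

## What the synthetic validation does and does not show

Passing tests establish that the implementation is internally correct: the
scorer equals a by-definition oracle, the processing chain preserves the
stated invariants, and the full pipeline recovers planted latency gaps and
growth slopes essentially unbiased under the generator's assumptions
(Gaussian latent traits, Gaussian band-limited noise, a single smooth
biphasic deflection per response). They do not certify behaviour on real
recordings, where responses carry secondary oscillations, noise is
non-stationary with participant-specific spectra, electrode placement and
muscle-tension drift add structure, and genuinely null responses at low
levels make the anchored search and null rule work much harder than the
high-SNR defaults exercise. Real-data features deliberately not modelled:
skull vibratory modes, electrode placement error, volume conduction,
biofeedback dynamics and instrument filter transients.
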