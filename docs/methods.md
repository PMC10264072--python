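# Methods

## Scope and model

The package implements the measurement side of an optogenetic
swallow–breathing coordination experiment: multi-channel EMG traces with
a stimulus train go in; per-stimulus behavior classifications, swallow
metrics, and respiratory phase/reset statistics come out. A synthetic
session generator with ground truth stands in for animal recordings, so
the whole chain is verifiable against known labels.

The behavioral model has three mutually exclusive responses to a brief
laser pulse at the PiCo region. A *swallow* is a delayed, stereotyped
submental + laryngeal burst pair: its duration is a property of the
swallow pattern generator, not of the stimulus (all-or-none), it always
outlasts the pulse, and it re-times the respiratory rhythm. A *laryngeal
activation* is a direct motor response locked to the pulse from onset to
offset (graded with pulse duration) that leaves the rhythm unchanged. *No
response* is the absence of either. Which response occurs depends on the
respiratory phase of the stimulus: swallows dominate during inspiration
and early expiration, laryngeal activation later in expiration.

## Signal conditioning

* Band-pass: linear-phase windowed-sinc FIR (Hamming), pass band
  200–700 Hz, 40 Hz transition on each edge, applied once with group
  delay compensated (zero phase). Tap count 3.3·fs/40 (~413 taps at
  5 kHz) gives ≥ 50 dB stop-band attenuation and < 0.1 dB pass-band
  ripple. A zero-phase filter is essential because every downstream
  metric is an onset/offset/peak time.
* Cardiac artifact: R peaks are detected on the dedicated ECG channel
  when present (|signal| peaks ≥ median + 8·scaled-MAD, ≥ 40 ms apart),
  otherwise on the target channel itself with a periodicity check
  (≥ 70 % of inter-peak intervals within 25 % of their median); without a
  convincing periodic artifact the signal is returned unchanged with a
  warning. Epochs of ±10 ms around each R peak are replaced by linear
  interpolation **before** filtering — the narrow-transition FIR would
  otherwise smear each spike over ±40 ms, far beyond the excision window.
* Envelope: full-wave rectification followed by a centered 20 ms boxcar
  moving average with shrinking windows at the array edges (length
  preserving). A boxcar keeps peak timing symmetric; exponential
  smoothing would bias peaks late.

## Burst and breath detection

Bursts are maximal intervals where the envelope exceeds baseline
mean + 3 SD, extended by hysteresis to the mean + 1 SD crossing,
with gaps < 10 ms merged, total supra-threshold time ≥ 15 ms, and peak
envelope ≥ mean + 5 SD. The peak criterion rejects long shallow noise
excursions (the 20 ms smoothing correlates the envelope over ~20 ms, so
3 SD alone is crossed for 15 ms spans a few times per minute); motor
bursts at the amplitudes this preparation produces exceed it by an order
of magnitude. By default the baseline is estimated robustly from the
whole envelope (median and scaled MAD), which tolerates bursts in the
signal; an explicit stimulus-free window can be nominated instead, with a
warning if detected activity overlaps it.

Respiratory cycles run from one diaphragm burst onset to the next.
Diaphragm bursts whose onset falls inside a detected submental burst are
swallow-related (Schluckatmung candidates) and are excluded from the
breath train before segmentation — otherwise a Schluckatmung would split
its cycle in two. Cycles containing a laser pulse or water bolus are
flagged perturbed; only control cycles provide the expected-phase
denominator.

## Classification thresholds

The verbal response templates are quantified by four tolerances
(configurable; defaults in ms): response horizon 500 after stimulus
offset, outlast margin 20, laryngeal onset tolerance 30, offset lock
tolerance 40, and an 800 ms horizon after a water bolus. The candidate
window opens 30 ms before stimulus onset because the centered smoothing
advances detected onsets by up to half the smoothing window. Decision
order: (1) swallow — submental + laryngeal pair, laryngeal offset beyond
stimulus offset + outlast margin, submental peak first; (2) a
submental/laryngeal pair with *reversed* peak order is an ambiguous
upper-airway response: flagged atypical, labeled no-response, excluded
from swallow/laryngeal statistics; (3) laryngeal activation — laryngeal
burst locked to the pulse with no diaphragm burst starting inside the
stimulus window (submental co-activity does not veto it, since it is
present in some animals); (4) otherwise no response, flagged atypical if
unmatched bursts were present. Bursts claimed by one stimulus are not
re-used by a later one.

## Phase statistics

Respiratory phase divides the stimulus latency from inspiratory onset by
the duration of the nearest preceding control cycle (the *expected
phase*); the phase shift divides the stimulated cycle's duration by that
same control duration, so both statistics share a denominator. Phases
above 1 (the stimulated cycle outlasting the control) are retained in
tables but counted as overflow rather than binned; bins are the ten
half-open tenths of [0, 1], the last closed. Probabilities are per-bin
means of class indicators, so they sum to 1 exactly in any non-empty bin;
empty bins are reported as missing, not zero. The reset regression is an
ordinary least-squares fit of phase shift against phase per group
(swallow vs. non-swallow, the latter pooling laryngeal activation and no
response), reporting Pearson r, slope, intercept, and the two-sided
regression p (t distribution, n − 2 df). Swallow-onset histograms divide
the swallow onset latency by the containing cycle's own duration.

## The synthetic generator

### What it emulates

One session is a seeded render of: a breathing rhythm (lognormal cycle
durations, mean 0.7 s, CV 0.1; 0.2 s inspiratory bursts); the laser
protocol (25 pulses of each 40/80/120/160/200 ms by default, one pulse
per host cycle with at least one stimulus-free cycle between pulses);
water boluses (10 by default, swallow probability 0.9); phase-dependent
behavior; and the rendered EMG. Every burst is band-limited Gaussian
noise (250–650 Hz, inside the analysis pass band) under a half-sine
envelope, over white noise (SD 0.03 a.u.) plus a periodic biphasic
cardiac artifact (derivative-of-Gaussian spikes, 10 Hz, amplitude 0.5,
per-channel gains). Identical config + seed is bit-identical.

Stimuli are placed at breath onset + u·(preceding realized cycle
duration) with u ~ U(0,1) — the same expected-phase scale the analysis
divides by, so the intended phase is recovered exactly on unperturbed
cycles. Placement against the *current* cycle duration would make the
measured phase equal u × (phase shift) and induce a structural
correlation (~0.24) between phase and shift in completely unperturbed
data, contaminating the reset statistics.

The evoked class is drawn from a phase-interval policy (defaults:
P(swallow) = 0.8/0.4/0.1 and P(laryngeal) = 0.05/0.3/0.7 on
[0, 0.4)/[0.4, 0.7)/[0.7, 1]); these rates are free parameters chosen to
give realistic phase dependence for this preparation, not measured
quantities.

Swallow rendering: latency 100 ± 15 ms after laser onset; submental
duration drawn from a lognormal parameterized by the configured group
mean/SD (defaults: laser 114 ± 19 ms, water 191 ± 63 ms, the
intersectional-genotype values); laryngeal onset lags the submental by
80 ± 10 ms and its duration co-varies with the submental (ratio
1.05 ± 0.08), with the laryngeal offset floored at stimulus offset +
60 ms — a swallow outlasts its trigger by definition. The lognormal is
used because durations are positive and the larger configurable SDs
(125 ms on a 199 ms mean) would force a clipped normal to realize a mean
several percent high; the lognormal preserves the requested mean
exactly. With
reset on, the next inspiration is re-timed to the swallow's laryngeal
offset + 0.3 s, which yields slope ≈ 1 reset lines with both advanced and
delayed next breaths. A swallow that starts during inspiration truncates
the ongoing diaphragm burst; with probability 0.25 a Schluckatmung burst
(80 ± 15 ms, lower amplitude) is added inside the swallow.

Laryngeal activation renders a laryngeal burst spanning the pulse
(gain 1.0, 2 % duration jitter, ≤ 3 ms onset jitter). If the pulse would
overlap the upcoming inspiration, the response is *gated to no-response*
and the rhythm runs on untouched (inspiratory drive suppressing the
evoked adduction). The alternative — delaying the next inspiration until
the adduction ends — places those events on a slope-1 phase/shift line
and makes non-swallows appear to reset the rhythm, contradicting the
reset dichotomy the model is built around.

Amplitudes: water swallows draw 0.80 ± 0.15 and laser swallows
0.45 ± 0.15 of the channel scale (clipped to [0.3, 1.0]), putting water
swallows near the per-channel maximum that anchors the "% of max" scale
and keeping the weakest bursts at ≥ 10× the noise floor.

### What it does not emulate

Anesthesia-depth drift, slow amplitude trends, electrode motion,
mains hum, crosstalk between leads, sighs/apneas, sequential swallows
under prolonged stimulation, and real inter-animal variability. Burst
envelopes are stereotyped half-sines rather than real interference
patterns. Passing tests therefore demonstrate that the measurement chain
recovers known structure under realistic noise, artifact and timing
jitter — not that it is robust to every failure mode of in vivo data.

### Renderer envelope choice

The half-sine envelope (rather than a flat-topped Tukey window) gives
each burst a unique central peak, which makes peak-order metrics (the
swallow sequence) well defined; a flat plateau would put the envelope
argmax anywhere on the plateau. Its gentle shoulders also interact
benignly with the 20 ms smoothing: measured durations run ~4 ms long,
versus ~10 ms for sharp-shouldered envelopes.

## Problem sizes

Default sessions are 400 s at 5 kHz (125 pulses, 10 boluses); the test
suite analyzes three such sessions plus two with the larger-variance
duration configuration, and the acceptance script six per configuration.
These sizes put ≥ 300 classified stimuli and ≥ 100 measured swallows
behind each pooled statistic while keeping a full run in tens of seconds.

## Known limitations

* Burst onset/offset detection carries a few ms of systematic bias from
  the smoothing window and threshold geometry; at the default settings
  measured swallow durations run ~3–5 % long.
* Very long swallows (several hundred ms) occasionally yield a reversed
  detected peak order from envelope noise and are conservatively flagged
  atypical, slightly truncating the right tail of measured duration
  distributions drawn with large SDs.
* The ECG detector assumes a near-periodic artifact; arrhythmic
  contamination without a reference channel is left in place (with a
  warning) rather than guessed at.
* Phase statistics require a control cycle before each stimulus; stimuli
  in the first cycle or after back-to-back perturbed cycles are excluded
  from phase tables (they are still classified).
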