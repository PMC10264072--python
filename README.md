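# pico-coord

Analysis pipeline for **swallow–breathing coordination** experiments in
which the postinspiratory complex (PiCo) — a medullary population of
glutamatergic/cholinergic interneurons — is optogenetically stimulated in
a spontaneously breathing, anesthetized mouse while EMG is recorded from
the diaphragm, the submental complex (geniohyoid/mylohyoid/digastric) and
the laryngeal complex. Brief laser pulses delivered at random respiratory
phases evoke one of three behaviors:

* **swallow** — a delayed submental + laryngeal burst pair that outlasts
  the laser, with the normal rostrocaudal motor sequence (submental peak
  before laryngeal peak); an *all-or-none* response whose duration is
  independent of pulse duration;
* **laryngeal activation** — a laryngeal burst locked to the pulse from
  onset to offset, with no stimulus-locked diaphragm activity; a *graded*
  response whose duration tracks pulse duration;
* **no response.**

The package is for electrophysiologists who need the full measurement
chain from raw multi-channel traces to tidy per-stimulus tables: signal
conditioning, burst and breath detection, response classification,
swallow metrics, and respiratory phase-reset statistics. Because the
experiment's raw recordings are not required, a first-class synthetic
session generator with ground truth reproduces the statistical structure
of such sessions, making every stage testable end to end.

## The measurements

Signals are band-pass filtered (200–700 Hz, 40 Hz transition), cleared of
cardiac artifact (R-peak-aligned excision with linear interpolation),
rectified and smoothed (20 ms moving average). Bursts are threshold
crossings of the envelope (baseline mean + 3 SD, hysteresis offset at
+1 SD), and the respiratory cycle runs from one diaphragm burst onset to
the next.

For a stimulus delivered at time *t* inside a cycle starting at *t₀*,
with preceding control cycle duration *T*ₑ (the *expected phase*):

* respiratory phase φ = (*t* − *t₀*) / *T*ₑ, with φ = 0 at inspiratory
  onset;
* phase shift = (duration of the stimulated cycle) / *T*ₑ — 1 means no
  reset, > 1 a delayed and < 1 an advanced next inspiration;
* per 1/10-phase bin: behavior probabilities (class indicators averaged
  per bin, summing to 1) and mean ± SD phase-shift curves;
* per group (swallow vs. non-swallow): Pearson *r* and least-squares
  slope of phase shift against phase — swallows reset the rhythm
  (*r* ≈ 0.8, slope ≈ 1), non-swallows do not (|*r*| small);
* swallow metrics in ms: swallow duration (submental onset→offset, XII
  fallback), swallow sequence (laryngeal − submental peak lag),
  Schluckatmung duration (swallow-locked diaphragm burst), laryngeal
  activation duration, inspiratory delay (laryngeal offset → next
  inspiration), and amplitudes as % of the maximum water-evoked swallow.

## Worked example

```python
from pico_coord import GeneratorConfig, generate_recording, analyze_recording

cfg = GeneratorConfig(seed=1)          # 125 pulses: 25 × {40,80,120,160,200} ms
rec, truth = generate_recording(cfg)   # synthetic session + ground truth
res = analyze_recording(rec)           # full measurement chain
print(res.summary())
```

prints (abridged):

```
session: 400 s, 125 laser pulses, 10 water boluses
classes: {'swallow': 60, 'no_response': 45, 'laryngeal_activation': 20}
laser swallows: 120 +/- 21 ms (n=60)
water swallows: 200 +/- 55 ms (n=10)
laryngeal duration by pulse (ms): {'40': 50, '80': 88, '120': 116, '160': 158, '200': 204}
reset: swallow r=0.83 slope=0.77 | non-swallow r=-0.13 slope=-0.07
```

Reading the numbers: laser-evoked swallow durations cluster near the
configured 114 ± 19 ms regardless of pulse duration (all-or-none), while
laryngeal-activation durations track the pulse (graded, gain ≈ 1). Water
swallows are longer and larger than laser swallows. The swallow group
shows a strong positive phase-shift correlation (each swallow re-times
the next inspiration), the non-swallow group essentially none.

The same chain is scriptable from a shell:

```bash
pico-coord simulate --seed 1 --out session/
pico-coord analyze --recording session/ --out session/results/ --plots
pico-coord report --results session/results/
```

`analyze` writes tidy CSV tables (`behavior_events.csv`,
`phase_samples.csv`, `probability_curves.csv`, `swallow_timing.csv`,
`bursts.csv`, `breaths.csv`) plus `summary.json`; group statistics
(ANOVA, post-hoc tests) are left to any downstream stats tool.

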