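"""Motor-burst detection and respiratory-cycle segmentation.

Bursts are maximal intervals where the rectified-smoothed envelope
exceeds a baseline-derived onset threshold, extended by hysteresis to a
lower offset threshold, with short gaps merged and short runs dropped.
The diaphragm burst train then delimits respiratory cycles (inspiratory
onset to next inspiratory onset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .sigproc import EnvelopeSignal

__all__ = [
    "Burst",
    "Breath",
    "detect_bursts",
    "segment_breaths",
    "exclude_perturbed_breaths",
]


@dataclass(frozen=True)
class Burst:
    """One supra-threshold motor burst on one channel."""

    channel: str
    onset: float        # s
    offset: float       # s
    peak_time: float    # s
    peak_amplitude: float  # a.u. (envelope units)

    @property
    def duration_ms(self) -> float:
        return (self.offset - self.onset) * 1e3


@dataclass(frozen=True)
class Breath:
    """One respiratory cycle, inspiratory onset to the next one."""

    insp_onset: float
    insp_peak_time: float
    insp_peak_amplitude: float
    insp_offset: float
    next_insp_onset: float

    @property
    def cycle_duration(self) -> float:
        return self.next_insp_onset - self.insp_onset

    @property
    def interburst_interval(self) -> float:
        """Diaphragm inter-burst interval: expiratory quiescence, s."""
        return self.next_insp_onset - self.insp_offset


def _baseline_stats(
    env: np.ndarray,
    sampling_rate: float,
    baseline_window: tuple[float, float] | float | None,
) -> tuple[float, float, tuple[int, int] | None]:
    if baseline_window is None:
        # robust global baseline: the envelope floor between bursts
        med = float(np.median(env))
        mad = float(np.median(np.abs(env - med)))
        return med, 1.4826 * mad, None
    if np.isscalar(baseline_window):
        lo, hi = 0.0, float(baseline_window)
    else:
        lo, hi = baseline_window
    i0, i1 = int(lo * sampling_rate), int(hi * sampling_rate)
    if i1 <= i0 or i1 > len(env):
        raise ValueError(f"baseline window [{lo}, {hi}] s outside the signal")
    seg = env[i0:i1]
    return float(seg.mean()), float(seg.std()), (i0, i1)


def detect_bursts(
    envelope: EnvelopeSignal,
    baseline_window: tuple[float, float] | float | None = None,
    k_onset: float = 3.0,
    k_offset: float = 1.0,
    min_duration_ms: float = 15.0,
    min_gap_ms: float = 10.0,
    channel: str | None = None,
    k_peak: float = 5.0,
) -> list[Burst]:
    """Threshold the envelope into bursts.

    Onset threshold is ``baseline_mean + k_onset * baseline_SD``; each
    supra-threshold run is extended outward (hysteresis) to where the
    envelope falls below ``baseline_mean + k_offset * baseline_SD``.
    Runs closer than ``min_gap_ms`` are merged, runs shorter than
    ``min_duration_ms`` discarded, and a run must reach
    ``baseline_mean + k_peak * baseline_SD`` at its peak (long shallow
    noise excursions are not motor bursts). With ``baseline_window=None``
    the baseline is estimated robustly from the whole envelope
    (median / scaled MAD), which tolerates bursts in the signal.
    """
    env = np.asarray(envelope.samples, dtype=float)
    if env.size == 0:
        raise ValueError("empty envelope")
    fs = envelope.sampling_rate
    mean, sd, win = _baseline_stats(env, fs, baseline_window)
    thr_on = mean + k_onset * sd
    thr_off = mean + k_offset * sd
    thr_peak = mean + k_peak * sd

    above = env > thr_on
    if not above.any():
        return []
    # supra-onset-threshold core runs
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])

    # merge cores separated by < min_gap, then drop cores whose total
    # supra-threshold time is too brief to be a motor burst (noise
    # excursions above the onset threshold are short)
    min_gap = int(round(min_gap_ms * 1e-3 * fs))
    min_len = int(round(min_duration_ms * 1e-3 * fs))
    cores: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if cores and s - cores[-1][1] <= min_gap:
            cores[-1][1] = max(cores[-1][1], e)
            cores[-1][2] += e - s + 1
        else:
            cores.append([s, e, e - s + 1])
    cores = [c[:2] for c in cores
             if c[2] >= min_len and env[c[0] : c[1] + 1].max() >= thr_peak]

    # hysteresis: extend each surviving core outward to the off threshold
    below = env <= mean if sd == 0 else env < thr_off
    n = len(env)
    extended: list[list[int]] = []
    for s, e in cores:
        i = s
        while i > 0 and not below[i - 1]:
            i -= 1
        j = e
        while j < n - 1 and not below[j + 1]:
            j += 1
        if extended and i - extended[-1][1] <= min_gap:
            extended[-1][1] = max(extended[-1][1], j)
        else:
            extended.append([i, j])

    bursts = []
    name = channel or envelope.source or ""
    for i, j in extended:
        pk = i + int(np.argmax(env[i : j + 1]))
        bursts.append(Burst(channel=name, onset=i / fs, offset=(j + 1) / fs,
                            peak_time=pk / fs, peak_amplitude=float(env[pk])))

    if win is not None:
        w0, w1 = win[0] / fs, win[1] / fs
        for b in bursts:
            if b.onset < w1 and b.offset > w0:
                warnings.warn(
                    "baseline window overlaps detected activity; threshold may be inflated",
                    stacklevel=2)
                break
    return bursts


def segment_breaths(diaphragm_bursts: list[Burst]) -> list[Breath]:
    """Respiratory cycles from consecutive inspiratory burst onsets."""
    if len(diaphragm_bursts) < 2:
        raise ValueError("need at least 2 diaphragm bursts to segment breaths")
    bursts = sorted(diaphragm_bursts, key=lambda b: b.onset)
    breaths = []
    for a, b in zip(bursts, bursts[1:]):
        breaths.append(Breath(
            insp_onset=a.onset,
            insp_peak_time=a.peak_time,
            insp_peak_amplitude=a.peak_amplitude,
            insp_offset=a.offset,
            next_insp_onset=b.onset,
        ))
    return breaths


def exclude_perturbed_breaths(
    breaths: list[Breath],
    stimuli: list,
    water_events: list[float],
) -> tuple[list[Breath], list[Breath]]:
    """Split cycles into control vs. perturbed.

    A cycle is perturbed when any laser pulse overlaps it or any water
    bolus lands in it; only control cycles serve as the "expected phase"
    / reset denominator.
    """
    intervals = [(s.onset, s.offset) for s in stimuli] + [(w, w) for w in water_events]
    control, flagged = [], []
    for br in breaths:
        lo, hi = br.insp_onset, br.next_insp_onset
        hit = any(a < hi and b >= lo for a, b in intervals)
        (flagged if hit else control).append(br)
    return control, flagged
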