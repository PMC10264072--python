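"""Respiratory phase, reset curves, probability curves, swallow timing.

Conventions: phase 0 is inspiratory (diaphragm) onset; the *expected
phase* is the duration of the nearest preceding control (unstimulated)
cycle; the *phase shift* of a stimulated cycle is its duration divided by
that same control duration, so 1 means no reset. Curves are binned into
tenths of the expected phase; samples with phase > 1 are kept in the
tables but counted as overflow rather than binned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .behavior import BehaviorEvent
from .events import Breath
from .synthgen import CLASSES, SWALLOW

logger = logging.getLogger("pico_coord")

NAN = float("nan")

__all__ = [
    "PhaseSample",
    "BinnedCurve",
    "SwallowTiming",
    "RegressionResult",
    "containing_breath",
    "expected_phase_duration",
    "respiratory_phase",
    "phase_shift",
    "make_phase_samples",
    "bin_curve",
    "probability_curves",
    "swallow_timing",
    "reset_correlation",
]


@dataclass(frozen=True)
class PhaseSample:
    """(phase, shift, class) for one stimulus."""

    stimulus_id: int
    respiratory_phase: float
    phase_shift: float
    behavior_class: str

    @property
    def group(self) -> str:
        # laryngeal activation and no-response pool as "non_swallow"
        return "swallow" if self.behavior_class == SWALLOW else "non_swallow"


@dataclass
class BinnedCurve:
    """Per-bin mean +/- SD over tenths of the respiratory phase."""

    n_bins: int
    centers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    overflow: int = 0  # samples with phase outside [0, 1]


@dataclass(frozen=True)
class SwallowTiming:
    stimulus_id: int
    onset_phase: float            # swallow onset within its cycle, 0..1+
    onset_rel_insp_peak_ms: float  # signed; negative = before the peak


@dataclass(frozen=True)
class RegressionResult:
    r: float
    slope: float
    intercept: float
    p: float
    n: int


def containing_breath(t: float, breaths: list[Breath]) -> int | None:
    for i, br in enumerate(breaths):
        if br.insp_onset <= t < br.next_insp_onset:
            return i
    return None


def expected_phase_duration(
    idx: int, breaths: list[Breath], is_control: list[bool]
) -> float | None:
    """Duration of the nearest preceding control cycle, s."""
    for j in range(idx - 1, -1, -1):
        if is_control[j]:
            return breaths[j].cycle_duration
    return None


def respiratory_phase(
    stim_onset: float, breaths: list[Breath], is_control: list[bool]
) -> tuple[float, int] | None:
    """Phase of a stimulus: latency from inspiratory onset over expected phase.

    Returns (phase, breath index), or None when the stimulus precedes the
    first cycle or no control cycle precedes it (such samples are
    excluded and logged).
    """
    idx = containing_breath(stim_onset, breaths)
    if idx is None:
        logger.info("stimulus at %.3fs outside the segmented breath train", stim_onset)
        return None
    expected = expected_phase_duration(idx, breaths, is_control)
    if expected is None:
        logger.info("stimulus at %.3fs has no preceding control cycle", stim_onset)
        return None
    return (stim_onset - breaths[idx].insp_onset) / expected, idx


def phase_shift(
    stim_onset: float, breaths: list[Breath], is_control: list[bool]
) -> float | None:
    """Containing-cycle duration over the preceding control duration."""
    idx = containing_breath(stim_onset, breaths)
    if idx is None:
        return None
    expected = expected_phase_duration(idx, breaths, is_control)
    if expected is None:
        return None
    return breaths[idx].cycle_duration / expected


def make_phase_samples(events: list[BehaviorEvent]) -> list[PhaseSample]:
    out = []
    for e in events:
        if e.trigger != "laser" or math.isnan(e.respiratory_phase) \
                or math.isnan(e.phase_shift):
            continue
        out.append(PhaseSample(e.stimulus_id, e.respiratory_phase,
                               e.phase_shift, e.behavior_class))
    return out


def _bin_index(phase: float, n_bins: int) -> int | None:
    """Half-open bins [i/n, (i+1)/n); the last bin closed at 1."""
    if phase < 0 or phase > 1:
        return None
    return min(int(phase * n_bins), n_bins - 1)


def bin_curve(samples: list, n_bins: int = 10, value: str = "phase_shift") -> BinnedCurve:
    """Mean +/- SD of ``value`` per phase bin."""
    if not samples:
        raise ValueError("bin_curve needs at least one sample")
    buckets: list[list[float]] = [[] for _ in range(n_bins)]
    overflow = 0
    for s in samples:
        i = _bin_index(s.respiratory_phase, n_bins)
        if i is None:
            overflow += 1
        else:
            buckets[i].append(getattr(s, value))
    mean = np.array([np.mean(b) if b else NAN for b in buckets])
    sd = np.array([np.std(b, ddof=1) if len(b) > 1 else (0.0 if b else NAN)
                   for b in buckets])
    n = np.array([len(b) for b in buckets])
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return BinnedCurve(n_bins=n_bins, centers=centers, mean=mean, sd=sd, n=n,
                       overflow=overflow)


def probability_curves(
    events: list[BehaviorEvent], n_bins: int = 10
) -> dict[str, BinnedCurve]:
    """Per-class probability of each behavior across phase bins.

    Each event scores 1 for its class and 0 for the others, so within any
    non-empty bin the class probabilities sum to exactly 1. Empty bins
    are reported as NaN (undefined), not zero.
    """
    usable = [e for e in events if e.trigger == "laser"
              and not math.isnan(e.respiratory_phase)]
    counts = np.zeros(n_bins)
    hits = {c: np.zeros(n_bins) for c in CLASSES}
    overflow = 0
    for e in usable:
        i = _bin_index(e.respiratory_phase, n_bins)
        if i is None:
            overflow += 1
            continue
        counts[i] += 1
        hits[e.behavior_class][i] += 1
    centers = (np.arange(n_bins) + 0.5) / n_bins
    curves = {}
    for c in CLASSES:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(counts > 0, hits[c] / np.where(counts > 0, counts, 1), NAN)
            sd = np.sqrt(np.where(counts > 0, p * (1 - p), NAN))
        curves[c] = BinnedCurve(n_bins=n_bins, centers=centers, mean=p, sd=sd,
                                n=counts.astype(int), overflow=overflow)
    return curves


def swallow_timing(
    events: list[BehaviorEvent], breaths: list[Breath], n_bins: int = 10
) -> tuple[list[SwallowTiming], np.ndarray]:
    """Swallow-onset phase histogram and latency to the inspiratory peak.

    The onset phase divides by the containing cycle's own duration (not
    the expected phase); the latency is measured to the nearest
    inspiratory diaphragm peak, negative when the swallow starts first.
    """
    rows = []
    hist = np.zeros(n_bins, dtype=int)
    peaks = np.array([br.insp_peak_time for br in breaths])
    for e in events:
        if e.behavior_class != SWALLOW or e.atypical or math.isnan(e.submental_onset):
            continue
        onset = e.submental_onset
        idx = containing_breath(onset, breaths)
        if idx is None:
            logger.info("swallow at %.3fs outside the breath train; excluded", onset)
            continue
        br = breaths[idx]
        ph = (onset - br.insp_onset) / br.cycle_duration
        rel = (onset - peaks[np.argmin(np.abs(peaks - onset))]) * 1e3
        rows.append(SwallowTiming(e.stimulus_id, ph, rel))
        b = _bin_index(ph, n_bins)
        if b is not None:
            hist[b] += 1
    return rows, hist


def reset_correlation(samples: list[PhaseSample], group: str) -> RegressionResult:
    """Pearson r and least-squares line of phase shift against phase.

    ``group`` is "swallow" or "non_swallow"; p is the two-sided
    regression p-value (t distribution, n - 2 df).
    """
    xs = np.array([s.respiratory_phase for s in samples if s.group == group])
    ys = np.array([s.phase_shift for s in samples if s.group == group])
    if len(xs) < 3:
        raise ValueError(f"need >= 3 samples in group {group!r}, got {len(xs)}")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance: correlation undefined")
    fit = sstats.linregress(xs, ys)
    return RegressionResult(r=float(fit.rvalue), slope=float(fit.slope),
                            intercept=float(fit.intercept), p=float(fit.pvalue),
                            n=len(xs))
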