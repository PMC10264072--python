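"""Signal conditioning for EMG/ENG traces.

The processing chain mirrors standard practice for interference-pattern
EMG: zero-phase band-pass (200-700 Hz), full-wave rectification, and a
20 ms moving-average smooth, plus optional cardiac-artifact excision.
All steps preserve signal length and burst timing (linear phase), which
the downstream burst-onset/offset metrics depend on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("pico_coord")

__all__ = [
    "EnvelopeSignal",
    "bandpass_filter",
    "rectify_smooth",
    "remove_ecg",
]


@dataclass
class EnvelopeSignal:
    """Non-negative rectified-smoothed envelope of one channel."""

    sampling_rate: float
    samples: np.ndarray
    source: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("envelope samples must be non-negative")

    def __len__(self) -> int:
        return len(self.samples)


def _fir_kernel(sampling_rate: float, low: float, high: float, transition: float) -> np.ndarray:
    # Hamming-window FIR: ~53 dB stop-band, <0.1 dB pass-band ripple.
    # Main-lobe width 3.3/N cycles/sample sets the tap count for the
    # requested transition band.
    numtaps = int(np.ceil(3.3 * sampling_rate / transition))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(
        numtaps,
        [low, high],
        width=transition,
        pass_zero=False,
        fs=sampling_rate,
    )


def bandpass_filter(
    x: np.ndarray,
    sampling_rate: float,
    low: float = 200.0,
    high: float = 700.0,
    transition: float = 40.0,
) -> np.ndarray:
    """Zero-phase FIR band-pass.

    The kernel is a symmetric (linear-phase) windowed-sinc applied once
    with its group delay compensated, so burst timing is not shifted.

    Parameters
    ----------
    x : array
        Raw samples.
    sampling_rate : float
        Hz; must exceed twice the upper band edge.
    low, high : float
        Pass-band edges in Hz.
    transition : float
        Transition width in Hz on each edge.
    """
    if low >= high:
        raise ValueError(f"low edge {low} Hz must be below high edge {high} Hz")
    if sampling_rate <= 2.0 * high:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz too low for a {high} Hz band edge; "
            f"need > {2.0 * high:.0f} Hz"
        )
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    h = _fir_kernel(sampling_rate, low, high, transition)
    # 'same' mode centers the odd-length symmetric kernel: zero phase.
    if x.size >= h.size:
        return sps.fftconvolve(x, h, mode="same")
    pad = h.size
    xp = np.pad(x, pad)
    return sps.fftconvolve(xp, h, mode="same")[pad:-pad]


def rectify_smooth(
    x: np.ndarray,
    sampling_rate: float,
    window_ms: float = 20.0,
    source: str = "",
) -> EnvelopeSignal:
    """Full-wave rectify then boxcar-average over ``window_ms``.

    The moving average is centered and the window shrinks at the array
    boundaries, so the envelope has the same length as the input and no
    edge roll-off artifacts.
    """
    if window_ms <= 0:
        raise ValueError("smoothing window must be positive")
    n_win = int(round(window_ms * 1e-3 * sampling_rate))
    if n_win < 1:
        raise ValueError(
            f"{window_ms} ms window is shorter than one sample period at "
            f"{sampling_rate} Hz"
        )
    x = np.asarray(x, dtype=float)
    r = np.abs(x)
    kernel = np.ones(n_win)
    sums = np.convolve(r, kernel, mode="same")
    counts = np.convolve(np.ones_like(r), kernel, mode="same")
    return EnvelopeSignal(
        sampling_rate=sampling_rate,
        samples=sums / counts,
        source=source,
        params={"window_ms": window_ms},
    )


def _detect_r_peaks(x: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Locate periodic large spikes (R peaks) on a single channel.

    Returns sample indices, or an empty array when no convincing periodic
    artifact is present (peaks too few or inter-peak intervals too
    irregular to be cardiac).
    """
    a = np.abs(x)
    mad = np.median(np.abs(a - np.median(a))) + 1e-12
    height = np.median(a) + 8.0 * 1.4826 * mad
    min_dist = max(1, int(0.04 * sampling_rate))  # < 1500 bpm
    peaks, _ = sps.find_peaks(a, height=height, distance=min_dist)
    if len(peaks) < 4:
        return np.array([], dtype=int)
    ipi = np.diff(peaks)
    med = np.median(ipi)
    # Cardiac artifact is near-periodic; EMG bursts are not.
    regular = np.abs(ipi - med) < 0.25 * med
    if np.mean(regular) < 0.7:
        return np.array([], dtype=int)
    return peaks


def remove_ecg(
    x: np.ndarray,
    sampling_rate: float,
    ecg_reference: np.ndarray | None = None,
    epoch_ms: float = 10.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Excise cardiac artifact epochs by linear interpolation.

    R peaks are detected on ``ecg_reference`` when given, otherwise on
    the target channel itself. Each epoch (peak +/- ``epoch_ms``) is
    replaced by a straight line between its edge samples; the signal
    outside epochs is untouched.

    Returns
    -------
    (cleaned, epochs)
        ``epochs`` is a list of (start_s, end_s) intervals that were
        interpolated. If no periodic artifact is found and no reference
        is given, the input is returned unchanged with a logged warning.
    """
    x = np.asarray(x, dtype=float)
    source = ecg_reference if ecg_reference is not None else x
    peaks = _detect_r_peaks(np.asarray(source, dtype=float), sampling_rate)
    if len(peaks) == 0:
        if ecg_reference is None:
            logger.warning("remove_ecg: no periodic artifact detected; signal unchanged")
        return x.copy(), []
    half = int(round(epoch_ms * 1e-3 * sampling_rate))
    out = x.copy()
    epochs: list[tuple[float, float]] = []
    n = len(x)
    for p in peaks:
        i0 = max(0, p - half)
        i1 = min(n - 1, p + half)
        if i1 - i0 < 2:
            continue
        out[i0 : i1 + 1] = np.linspace(out[i0], out[i1], i1 - i0 + 1)
        epochs.append((i0 / sampling_rate, i1 / sampling_rate))
    return out, epochs
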