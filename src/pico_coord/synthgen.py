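"""Synthetic optogenetic-stimulation sessions with ground truth.

Generates multi-channel EMG-like recordings that reproduce the
statistical structure of an anesthetized-mouse swallow/breathing session
under brief laser stimulation of the postinspiratory complex (PiCo):

* rhythmic diaphragm bursts (lognormal cycle length, ~0.7 s);
* laser pulse trains (by default 25 pulses of each 40/80/120/160/200 ms)
  placed at uniform-random respiratory phases;
* phase-dependent evoked behavior — swallows dominate during inspiration
  and early expiration, laryngeal activation late in expiration;
* all-or-none swallows: the submental/laryngeal swallow burst outlasts
  the laser and its duration is drawn independently of pulse duration;
* graded laryngeal activation: burst locked to the laser, duration equal
  to pulse duration times a gain;
* respiratory reset by swallows (next inspiration re-timed from the
  swallow's laryngeal offset), minimal effect of non-swallows;
* water-bolus evoked swallows (no laser) defining the "% of max"
  amplitude baseline;
* periodic biphasic cardiac artifact on every channel, plus broadband
  noise.

Every burst is amplitude-modulated band-limited Gaussian noise so it
survives the 200-700 Hz analysis band-pass like real interference-pattern
EMG. Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import Recording, StimEvent
from .sigproc import bandpass_filter

__all__ = [
    "GeneratorConfig",
    "TrueEvent",
    "GroundTruth",
    "generate_recording",
    "schedule_stimuli",
    "render_burst",
]

SWALLOW = "swallow"
LARYNGEAL = "laryngeal_activation"
NO_RESPONSE = "no_response"
CLASSES = (SWALLOW, LARYNGEAL, NO_RESPONSE)


class ConfigError(ValueError):
    pass


class CapacityError(RuntimeError):
    """Session too short to place all requested events."""


def _default_policy() -> list[tuple[float, float, dict[str, float]]]:
    # Phase intervals -> class probabilities. Swallows are favored during
    # inspiration/early expiration, laryngeal activation late in
    # expiration; the in-between mix and the no-response rates are free
    # choices (not constrained by any reported group value).
    return [
        (0.0, 0.4, {SWALLOW: 0.80, LARYNGEAL: 0.05, NO_RESPONSE: 0.15}),
        (0.4, 0.7, {SWALLOW: 0.40, LARYNGEAL: 0.30, NO_RESPONSE: 0.30}),
        (0.7, 1.01, {SWALLOW: 0.10, LARYNGEAL: 0.70, NO_RESPONSE: 0.20}),
    ]


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session.

    Swallow-duration distributions default to the ChATcre:Vglut2FlpO:ChR2
    group values (PiCo-evoked swallows 114 +/- 19 ms, water swallows
    191 +/- 63 ms); timing parameters without an established value
    (latency, submental->laryngeal delay, reset interval) are documented
    free choices.
    """

    sampling_rate: float = 5000.0          # Hz
    session_duration: float = 400.0        # s
    breath_period_mean: float = 0.7        # s
    breath_period_cv: float = 0.1
    insp_burst_duration: float = 0.2       # s
    pulse_durations: tuple[float, ...] = (40.0, 80.0, 120.0, 160.0, 200.0)  # ms
    pulses_per_duration: int = 25
    behavior_policy: list = field(default_factory=_default_policy)
    swallow_duration_mean: float = 114.0   # ms, laser-evoked
    swallow_duration_sd: float = 19.0
    water_swallow_duration_mean: float = 191.0  # ms
    water_swallow_duration_sd: float = 63.0
    swallow_latency_mean: float = 100.0    # ms after laser onset
    swallow_latency_sd: float = 15.0
    swallow_sequence_delay_mean: float = 80.0  # ms, submental->laryngeal onset lag
    swallow_sequence_delay_sd: float = 10.0
    laryngeal_response_gain: float = 1.0   # laryngeal-activation duration / laser duration
    schluckatmung_prob: float = 0.25
    schluckatmung_duration_mean: float = 80.0  # ms
    post_swallow_ibi: float = 0.3          # s, laryngeal offset -> next inspiration
    n_water_boluses: int = 10
    water_swallow_prob: float = 0.9
    # amplitudes (a.u.): per-channel burst scale; swallow bursts are drawn
    # as a fraction of the channel scale so water swallows sit near the
    # channel maximum and laser swallows lower, as reported.
    amplitude: dict = field(default_factory=lambda: {
        "diaphragm": 1.0, "submental": 1.0, "laryngeal": 1.0})
    water_amp_frac: tuple[float, float] = (0.80, 0.15)   # mean, sd of N, clipped
    laser_amp_frac: tuple[float, float] = (0.45, 0.15)
    amp_frac_clip: tuple[float, float] = (0.30, 1.00)
    laryngeal_activation_amp: float = 0.5
    schluckatmung_amp: float = 0.4
    ecg_rate: float = 10.0                 # Hz (~600 bpm)
    ecg_amplitude: float = 0.5             # a.u.
    ecg_gain: dict = field(default_factory=lambda: {
        "diaphragm": 1.0, "submental": 0.5, "laryngeal": 0.5})
    noise_sd: float = 0.03                 # a.u., broadband
    reset_policy: bool = True              # swallows reset the respiratory rhythm
    carrier_band: tuple[float, float] = (250.0, 650.0)  # Hz, burst carrier
    burst_taper_ms: float = 10.0
    burst_dome: float = 1.0                # 0 flat plateau .. 1 half-sine envelope
    gap_breaths: int = 1                   # stimulus-free breaths between events
    lead_in: float = 2.0                   # s of quiet + breathing before events
    genotype: str = "ChATcre:Vglut2FlpO:ChR2"
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate < 2 * 700.0:
            raise ConfigError(
                f"sampling_rate {self.sampling_rate} Hz < 1400 Hz (2x upper band edge)")
        for name in ("session_duration", "breath_period_mean", "insp_burst_duration",
                     "swallow_duration_mean", "water_swallow_duration_mean",
                     "swallow_latency_mean", "ecg_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if any(d <= 0 for d in self.pulse_durations):
            raise ConfigError("pulse durations must be positive")
        if self.pulses_per_duration < 0 or self.n_water_boluses < 0:
            raise ConfigError("event counts must be non-negative")
        lo = 0.0
        for a, b, probs in self.behavior_policy:
            if not math.isclose(a, lo, abs_tol=1e-9):
                raise ConfigError("behavior_policy intervals must tile [0, 1) without gaps")
            if b <= a:
                raise ConfigError("behavior_policy interval is empty")
            if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
                raise ConfigError(f"class probabilities in [{a},{b}) must sum to 1")
            if set(probs) - set(CLASSES):
                raise ConfigError(f"unknown behavior class in policy: {set(probs) - set(CLASSES)}")
            lo = b
        if lo < 1.0:
            raise ConfigError("behavior_policy must cover phases up to 1")

    def policy_probs(self, phase: float) -> dict[str, float]:
        for a, b, probs in self.behavior_policy:
            if a <= phase < b:
                return probs
        return self.behavior_policy[-1][2]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**raw)
        for name in ("pulse_durations", "water_amp_frac", "laser_amp_frac",
                     "amp_frac_clip", "carrier_band"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.behavior_policy = [(a, b, p) for a, b, p in cfg.behavior_policy]
        cfg.validate()
        return cfg


@dataclass
class TrueEvent:
    """Ground-truth record for one stimulus or water bolus."""

    event_id: int
    trigger: str                 # "laser" | "water"
    behavior_class: str
    onset: float                 # s; laser onset or water delivery time
    pulse_duration_ms: float     # 0 for water
    phase: float                 # intended phase within the containing cycle
    breath_index: int
    # realized burst geometry (s / a.u.); NaN when the channel is silent
    sub_onset: float = float("nan")
    sub_offset: float = float("nan")
    sub_peak_time: float = float("nan")
    sub_amp: float = float("nan")
    lar_onset: float = float("nan")
    lar_offset: float = float("nan")
    lar_peak_time: float = float("nan")
    lar_amp: float = float("nan")
    dia_onset: float = float("nan")      # Schluckatmung burst, when present
    dia_offset: float = float("nan")
    swallow_duration_ms: float = float("nan")
    laryngeal_duration_ms: float = float("nan")


@dataclass
class GroundTruth:
    events: list[TrueEvent]
    breath_onsets: np.ndarray      # realized inspiratory onsets, s
    ecg_times: np.ndarray          # R-peak centers, s
    config: GeneratorConfig

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(e) for e in self.events])
        return df

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path / "ground_truth.csv", index=False)
        self.config.to_json(path / "generator_config.json")


# ----------------------------------------------------------------------
# waveform synthesis
# ----------------------------------------------------------------------

def _burst_envelope(n: int, sampling_rate: float, taper_ms: float, dome: float) -> np.ndarray:
    """Raised-cosine-tapered envelope with a domed plateau.

    The dome gives the burst a unique central maximum (real EMG bursts
    wax and wane) so peak-time metrics are well defined; the tapers keep
    onset/offset sharp so threshold crossings track the true interval.
    """
    t = np.arange(n) / max(n - 1, 1)
    taper = min(taper_ms * 1e-3 * sampling_rate / max(n, 1), 0.5)
    env = np.ones(n)
    ramp = int(round(taper * n))
    if ramp > 0:
        k = np.arange(ramp) / ramp
        shape = 0.5 * (1 - np.cos(np.pi * k))
        env[:ramp] *= shape
        env[n - ramp:] *= shape[::-1]
    env *= (1.0 - dome) + dome * np.sin(np.pi * t)
    return env


def render_burst(
    duration_ms: float,
    amplitude: float,
    sampling_rate: float,
    rng: np.random.Generator,
    carrier_band: tuple[float, float] = (250.0, 650.0),
    taper_ms: float = 10.0,
    dome: float = 0.5,
) -> np.ndarray:
    """One motor burst: band-limited Gaussian noise under a smooth envelope.

    ``amplitude`` is the carrier RMS at the envelope maximum (a.u.).
    Returns a segment of ``round(duration_ms * fs / 1000)`` samples whose
    energy is confined to the segment.
    """
    if duration_ms <= 0:
        raise ValueError(f"burst duration must be positive, got {duration_ms}")
    n = max(int(round(duration_ms * 1e-3 * sampling_rate)), 2)
    if amplitude == 0:
        return np.zeros(n)
    pad = int(round(0.05 * sampling_rate))  # filter warm-up, trimmed off
    white = rng.standard_normal(n + 2 * pad)
    lo, hi = carrier_band
    carrier = bandpass_filter(white, sampling_rate, lo, hi, transition=100.0)
    carrier = carrier[pad:pad + n]
    rms = float(np.sqrt(np.mean(carrier**2)))
    if rms > 0:
        carrier = carrier / rms
    return amplitude * carrier * _burst_envelope(n, sampling_rate, taper_ms, dome)


def _ecg_wavelet(sampling_rate: float, sigma_ms: float = 1.0) -> np.ndarray:
    """Biphasic spike: derivative of a Gaussian, unit peak amplitude."""
    sigma = sigma_ms * 1e-3
    half = int(round(5 * sigma * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    w = -t / sigma * np.exp(0.5 - t**2 / (2 * sigma**2))
    return w / np.max(np.abs(w))


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws with the requested arithmetic mean and SD."""
    if sd <= 0:
        return np.full(size, mean) if size else mean
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * s2
    return rng.lognormal(mu, math.sqrt(s2), size)


# ----------------------------------------------------------------------
# scheduling
# ----------------------------------------------------------------------

def schedule_stimuli(
    breath_onsets: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    with_phases: bool = False,
):
    """Place the laser protocol on an existing breath train.

    Each pulse duration appears exactly ``pulses_per_duration`` times;
    each pulse is placed in its own respiratory cycle at a phase drawn
    uniformly on [0, 1) of the expected (preceding) cycle duration, with
    at least ``gap_breaths`` stimulus-free cycles between pulses so every
    stimulus has a control cycle before it. Pulses therefore never
    overlap.

    Returns the stimulus list, or ``(events, phases)`` when
    ``with_phases`` is set.
    """
    breath_onsets = np.asarray(breath_onsets, dtype=float)
    if len(breath_onsets) < 2:
        raise ValueError("need at least 2 breath onsets to schedule stimuli")
    durations = np.repeat(config.pulse_durations, config.pulses_per_duration)
    rng.shuffle(durations)
    n_stim = len(durations)
    stride = config.gap_breaths + 1
    # usable cycles: [k, k+1) for k = 1 .. n-2 (cycle 0 is the lead-in control)
    usable = np.arange(1, len(breath_onsets) - 1, stride)
    if len(usable) < n_stim:
        raise CapacityError(
            f"{len(breath_onsets) - 1} cycles can host {len(usable)} stimuli "
            f"with gap_breaths={config.gap_breaths}; {n_stim} requested")
    cycles = np.sort(rng.choice(usable, size=n_stim, replace=False))
    phases = rng.uniform(0.0, 1.0, size=n_stim)
    events = []
    for k, u, d in zip(cycles, phases, durations):
        # phase is defined against the expected (preceding) cycle duration,
        # so place the pulse on that same scale
        expected = breath_onsets[k] - breath_onsets[k - 1]
        events.append(StimEvent(onset=float(breath_onsets[k] + u * expected),
                                duration=float(d)))
    if with_phases:
        return events, phases
    return events


# ----------------------------------------------------------------------
# session generation
# ----------------------------------------------------------------------

def _draw_swallow_geometry(cfg, rng, trigger, stim_onset, stim_offset):
    """Times (s) for one swallow's submental/laryngeal bursts."""
    if trigger == "laser":
        dur_mean, dur_sd = cfg.swallow_duration_mean, cfg.swallow_duration_sd
        latency = max(rng.normal(cfg.swallow_latency_mean, cfg.swallow_latency_sd), 30.0)
    else:
        dur_mean, dur_sd = cfg.water_swallow_duration_mean, cfg.water_swallow_duration_sd
        latency = max(rng.normal(cfg.swallow_latency_mean, cfg.swallow_latency_sd), 30.0)
    d_sub = float(_lognormal(rng, dur_mean, dur_sd))
    delay = max(rng.normal(cfg.swallow_sequence_delay_mean,
                           cfg.swallow_sequence_delay_sd), 40.0)
    # laryngeal adduction co-varies with the oropharyngeal burst and, by
    # definition of a swallow, always outlasts the stimulus
    d_lar = d_sub * float(np.clip(rng.normal(1.05, 0.08), 0.95, 1.3))
    sub_on = stim_onset + latency * 1e-3
    sub_off = sub_on + d_sub * 1e-3
    lar_on = sub_on + delay * 1e-3
    lar_off = max(lar_on + d_lar * 1e-3, stim_offset + 0.06)
    return sub_on, sub_off, lar_on, lar_off, d_sub


def generate_recording(config: GeneratorConfig) -> tuple[Recording, GroundTruth]:
    """Simulate one session; returns the rendered recording + ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n_samples = int(round(cfg.session_duration * fs))

    # --- event plan -----------------------------------------------------
    durations = np.repeat(cfg.pulse_durations, cfg.pulses_per_duration).astype(float)
    rng.shuffle(durations)
    plan = [("laser", d) for d in durations] + [("water", 0.0)] * cfg.n_water_boluses
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    # --- walk the breath train, placing events --------------------------
    breath_onsets: list[float] = []
    # per-breath diaphragm burst intervals (inspiration may be truncated
    # by a swallow that interrupts it)
    dia_bursts: list[tuple[float, float, float]] = []  # onset, offset, amp
    resp_bursts: list[tuple[str, float, float, float]] = []  # chan, on, off, amp
    water_times: list[float] = []
    stim_events: list[StimEvent] = []
    truth: list[TrueEvent] = []

    t = cfg.lead_in
    prev_dur = cfg.breath_period_mean  # realized duration of the previous cycle
    next_event = 0
    breaths_since_event = cfg.gap_breaths + 1  # allow an event once a control exists
    k = 0
    tail = 2.0  # keep the session end quiet
    while t < cfg.session_duration - tail:
        period = float(_lognormal(rng, cfg.breath_period_mean,
                                  cfg.breath_period_cv * cfg.breath_period_mean))
        insp_end = t + cfg.insp_burst_duration
        dia_amp = max(cfg.amplitude["diaphragm"] * rng.normal(1.0, 0.05), 0.2)
        breath_onsets.append(t)
        next_onset = t + period
        dia_off = insp_end

        place = (next_event < len(plan) and k >= 1
                 and breaths_since_event > cfg.gap_breaths
                 and t + period < cfg.session_duration - tail)
        if place:
            trigger, pulse_ms = plan[next_event]
            next_event += 1
            breaths_since_event = 0
            u = float(rng.uniform(0.0, 1.0))
            # phase is measured against the preceding (expected) cycle, so
            # the pulse is placed on that scale; it may spill past the next
            # scheduled onset when the current cycle runs short (phase > 1)
            ev_onset = t + u * prev_dur
            stim_off = ev_onset + pulse_ms * 1e-3
            if trigger == "laser":
                klass = _draw_class(cfg, rng, u)
            else:
                klass = SWALLOW if rng.uniform() < cfg.water_swallow_prob else NO_RESPONSE
            ev = TrueEvent(event_id=len(truth), trigger=trigger, behavior_class=klass,
                           onset=ev_onset, pulse_duration_ms=pulse_ms, phase=u,
                           breath_index=k)
            if klass == SWALLOW:
                sub_on, sub_off, lar_on, lar_off, d_sub = _draw_swallow_geometry(
                    cfg, rng, trigger, ev_onset, stim_off)
                frac_mean, frac_sd = (cfg.laser_amp_frac if trigger == "laser"
                                      else cfg.water_amp_frac)
                sub_amp = cfg.amplitude["submental"] * float(
                    np.clip(rng.normal(frac_mean, frac_sd), *cfg.amp_frac_clip))
                lar_amp = cfg.amplitude["laryngeal"] * float(
                    np.clip(rng.normal(frac_mean, frac_sd), *cfg.amp_frac_clip))
                resp_bursts.append(("submental", sub_on, sub_off, sub_amp))
                resp_bursts.append(("laryngeal", lar_on, lar_off, lar_amp))
                ev.sub_onset, ev.sub_offset, ev.sub_amp = sub_on, sub_off, sub_amp
                ev.lar_onset, ev.lar_offset, ev.lar_amp = lar_on, lar_off, lar_amp
                ev.swallow_duration_ms = d_sub
                ev.laryngeal_duration_ms = (lar_off - lar_on) * 1e3
                # a swallow interrupts ongoing inspiration
                if sub_on < dia_off:
                    dia_off = max(t + 0.03, sub_on)
                if rng.uniform() < cfg.schluckatmung_prob:
                    s_on = sub_on + 0.02
                    s_dur = max(rng.normal(cfg.schluckatmung_duration_mean, 15.0), 40.0)
                    s_off = min(s_on + s_dur * 1e-3, sub_off)
                    if s_off - s_on > 0.04:
                        resp_bursts.append(("diaphragm", s_on, s_off, cfg.schluckatmung_amp))
                        ev.dia_onset, ev.dia_offset = s_on, s_off
                if cfg.reset_policy:
                    next_onset = lar_off + cfg.post_swallow_ibi
                else:
                    next_onset = max(next_onset, lar_off + 0.05)
            elif klass == LARYNGEAL:
                lar_on = ev_onset + abs(rng.normal(0.0, 0.003))
                lar_off = ev_onset + cfg.laryngeal_response_gain * pulse_ms * 1e-3 \
                    * float(np.clip(rng.normal(1.0, 0.02), 0.9, 1.1))
                if next_onset < lar_off + 0.03:
                    # inspiratory gating: a pulse overlapping the upcoming
                    # inspiration evokes no laryngeal adduction, and the
                    # rhythm runs on untouched
                    klass = NO_RESPONSE
                    ev.behavior_class = NO_RESPONSE
                else:
                    lar_amp = cfg.amplitude["laryngeal"] * max(
                        rng.normal(cfg.laryngeal_activation_amp, 0.1), 0.3)
                    resp_bursts.append(("laryngeal", lar_on, lar_off, lar_amp))
                    ev.lar_onset, ev.lar_offset, ev.lar_amp = lar_on, lar_off, lar_amp
                    ev.laryngeal_duration_ms = (lar_off - lar_on) * 1e3
            # no_response: nothing rendered, rhythm untouched
            if trigger == "laser":
                stim_events.append(StimEvent(onset=ev_onset, duration=pulse_ms))
            else:
                water_times.append(ev_onset)
            truth.append(ev)
        else:
            breaths_since_event += 1

        dia_bursts.append((t, dia_off, dia_amp))
        prev_dur = next_onset - t
        t = next_onset
        k += 1

    if next_event < len(plan):
        raise CapacityError(
            f"session_duration={cfg.session_duration}s fits only {next_event} of "
            f"{len(plan)} events; lengthen the session or reduce the protocol")

    # --- render ----------------------------------------------------------
    channels = {name: np.zeros(n_samples) for name in ("diaphragm", "submental", "laryngeal")}

    def _add(chan: str, onset: float, offset: float, amp: float):
        dur_ms = (offset - onset) * 1e3
        if dur_ms <= 1.0:
            return None
        seg = render_burst(dur_ms, amp, fs, rng, cfg.carrier_band,
                           cfg.burst_taper_ms, cfg.burst_dome)
        i0 = int(round(onset * fs))
        i1 = min(i0 + len(seg), n_samples)
        if i0 >= n_samples:
            return None
        channels[chan][i0:i1] += seg[: i1 - i0]
        return seg[: i1 - i0], i0

    for onset, offset, amp in dia_bursts:
        _add("diaphragm", onset, offset, amp)

    peak_info: dict[int, tuple[str, float, float]] = {}
    for idx, (chan, onset, offset, amp) in enumerate(resp_bursts):
        out = _add(chan, onset, offset, amp)
        if out is not None:
            # ground-truth peak: the maximum of the (noise-free) burst
            # envelope, i.e. the center of the domed burst
            peak_info[idx] = (chan, (onset + offset) / 2.0, amp)

    # map realized peaks back onto truth entries
    burst_idx = 0
    for ev in truth:
        if ev.behavior_class == SWALLOW:
            for _ in range(2):
                chan, pk_t, _pk = peak_info.get(burst_idx, ("", float("nan"), 0.0))
                if chan == "submental":
                    ev.sub_peak_time = pk_t
                elif chan == "laryngeal":
                    ev.lar_peak_time = pk_t
                burst_idx += 1
            if not math.isnan(ev.dia_onset):
                burst_idx += 1
        elif ev.behavior_class == LARYNGEAL:
            chan, pk_t, _pk = peak_info.get(burst_idx, ("", float("nan"), 0.0))
            if chan == "laryngeal":
                ev.lar_peak_time = pk_t
            burst_idx += 1

    # --- cardiac artifact + noise ----------------------------------------
    wav = _ecg_wavelet(fs)
    beat = 1.0 / cfg.ecg_rate
    ecg_times = []
    tt = 0.3
    while tt < cfg.session_duration - 0.3:
        ecg_times.append(tt)
        tt += beat * (1.0 + rng.normal(0.0, 0.03))
    ecg_times = np.asarray(ecg_times)
    ecg_clean = np.zeros(n_samples)
    half = len(wav) // 2
    for bt in ecg_times:
        i = int(round(bt * fs))
        i0, i1 = i - half, i + half + 1
        s0 = max(0, -i0)
        s1 = len(wav) - max(0, i1 - n_samples)
        ecg_clean[max(i0, 0):min(i1, n_samples)] += wav[s0:s1]
    for chan in channels:
        gain = cfg.ecg_gain.get(chan, 0.0)
        channels[chan] += cfg.ecg_amplitude * gain * ecg_clean
        channels[chan] += rng.normal(0.0, cfg.noise_sd, n_samples)
    channels["ecg"] = cfg.ecg_amplitude * ecg_clean + rng.normal(0.0, 0.1 * cfg.noise_sd, n_samples)

    recording = Recording(
        sampling_rate=fs,
        channels=channels,
        stimuli=stim_events,
        water_events=water_times,
        metadata={"genotype": cfg.genotype, "seed": cfg.seed, "units": "a.u."},
    )
    gt = GroundTruth(events=truth, breath_onsets=np.asarray(breath_onsets),
                     ecg_times=ecg_times, config=cfg)
    return recording, gt


def _draw_class(cfg: GeneratorConfig, rng: np.random.Generator, phase: float) -> str:
    probs = cfg.policy_probs(phase)
    names = list(probs)
    p = np.array([probs[n] for n in names])
    return names[int(rng.choice(len(names), p=p / p.sum()))]
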