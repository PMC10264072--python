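"""Stimulus-response classification and swallow metrics.

Each laser pulse (or water bolus) is assigned exactly one behavior
class:

* ``swallow`` — delayed submental + laryngeal burst pair whose laryngeal
  activity outlasts the stimulus, with the normal rostrocaudal sequence
  (submental peak before laryngeal peak);
* ``laryngeal_activation`` — laryngeal burst locked to the laser (onset
  and offset within tolerance of the pulse edges) with no stimulus-locked
  diaphragm burst;
* ``no_response`` — no motor response in the window. Responses with
  bursts that fit neither template (e.g. reversed peak sequence) are
  labeled ``no_response`` with an ``atypical`` flag and are excluded from
  swallow/laryngeal statistics.

Swallow metrics follow the onset-to-termination conventions: swallow
duration from the submental burst (hypoglossal fallback), swallow
sequence as the laryngeal-submental peak lag, Schluckatmung as a
swallow-locked diaphragm burst, and inspiratory delay from laryngeal
offset to the next inspiration. Amplitudes are normalized to the largest
water-evoked swallow per channel ("% of max").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .events import Breath, Burst
from .io_core import StimEvent
from .synthgen import LARYNGEAL, NO_RESPONSE, SWALLOW

logger = logging.getLogger("pico_coord")

NAN = float("nan")

__all__ = [
    "ClassifierParams",
    "BehaviorEvent",
    "BaselineAmplitudes",
    "classify_response",
    "measure_swallow",
    "compute_baseline",
    "normalize_amplitudes",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Quantified decision thresholds for the verbal behavior templates."""

    response_horizon_ms: float = 500.0   # window past stimulus offset
    outlast_margin_ms: float = 20.0      # "outlasting the laser"
    onset_tolerance_ms: float = 30.0     # laryngeal lock to laser onset
    lock_tolerance_ms: float = 40.0      # laryngeal lock to laser offset
    water_horizon_ms: float = 800.0      # window after a water bolus


@dataclass
class BehaviorEvent:
    """One classified response with every swallow-related metric."""

    stimulus_id: int
    trigger: str                      # "laser" | "water"
    behavior_class: str
    atypical: bool
    stim_onset: float                 # s
    pulse_duration_ms: float          # 0 for water
    respiratory_phase: float = NAN
    phase_shift: float = NAN
    breath_index: int = -1
    swallow_duration_ms: float = NAN
    swallow_sequence_ms: float = NAN
    schluckatmung_duration_ms: float = NAN
    laryngeal_duration_ms: float = NAN
    inspiratory_delay_ms: float = NAN
    submental_onset: float = NAN
    submental_offset: float = NAN
    submental_amp: float = NAN        # a.u. (envelope peak)
    submental_amp_pct: float = NAN    # % of water-swallow max
    laryngeal_onset: float = NAN
    laryngeal_offset: float = NAN
    laryngeal_amp: float = NAN
    laryngeal_amp_pct: float = NAN
    no_baseline: bool = False


@dataclass
class BaselineAmplitudes:
    """Per-channel maximum water-evoked swallow amplitude (a.u.)."""

    max_amp: dict = field(default_factory=dict)
    no_baseline: bool = False


def _in_window(bursts: list[Burst], lo: float, hi: float,
               assigned: set | None) -> list[Burst]:
    out = []
    for b in bursts:
        if lo <= b.onset <= hi and (assigned is None or (b.channel, b.onset) not in assigned):
            out.append(b)
    return out


def classify_response(
    stim: StimEvent,
    bursts: dict[str, list[Burst]],
    breaths: list[Breath],
    params: ClassifierParams = ClassifierParams(),
    trigger: str = "laser",
    stimulus_id: int = 0,
    assigned: set | None = None,
    diaphragm_all: list[Burst] | None = None,
) -> BehaviorEvent:
    """Assign one behavior class to one stimulus and measure it.

    ``bursts`` maps channel name to detected bursts; ``diaphragm``
    entries must be the *inspiratory* bursts (swallow-locked diaphragm
    bursts go in ``diaphragm_all`` for Schluckatmung measurement).
    ``assigned`` is a mutable set of (channel, onset) keys used to give
    each burst to the earliest claiming stimulus.
    """
    if "laryngeal" not in bursts or "diaphragm" not in bursts:
        raise ValueError("classification requires 'diaphragm' and 'laryngeal' channels")
    submental = bursts.get("submental")
    sub_channel = "submental"
    if submental is None:
        submental = bursts.get("xii")
        sub_channel = "xii"
    if submental is None:
        raise ValueError("classification requires a 'submental' (or fallback 'xii') channel")

    stim_off = stim.onset + stim.duration * 1e-3 if trigger == "laser" else stim.onset
    horizon = (params.response_horizon_ms if trigger == "laser"
               else params.water_horizon_ms) * 1e-3
    # smoothing advances detected onsets by up to half the envelope window,
    # so admit bursts starting just before the stimulus
    lo = stim.onset - params.onset_tolerance_ms * 1e-3
    hi = stim_off + horizon

    sub_cands = _in_window(submental, lo, hi, assigned)
    lar_cands = _in_window(bursts["laryngeal"], lo, hi, assigned)

    ev = BehaviorEvent(stimulus_id=stimulus_id, trigger=trigger,
                       behavior_class=NO_RESPONSE, atypical=False,
                       stim_onset=stim.onset,
                       pulse_duration_ms=stim.duration if trigger == "laser" else 0.0)

    # (1) swallow: submental + laryngeal pair, laryngeal outlasts the
    # stimulus, normal rostrocaudal peak order
    if sub_cands and lar_cands:
        sub = sub_cands[0]
        lar = next((b for b in lar_cands
                    if b.offset > stim_off + params.outlast_margin_ms * 1e-3), None)
        if lar is not None and lar.peak_time > sub.peak_time:
            ev.behavior_class = SWALLOW
            if assigned is not None:
                assigned.add((sub.channel, sub.onset))
                assigned.add((lar.channel, lar.onset))
            measure_swallow(ev, sub, lar, breaths,
                            diaphragm_all if diaphragm_all is not None else bursts["diaphragm"])
            return ev
        if any(b.peak_time <= sub.peak_time for b in lar_cands):
            # swallow-like burst pair with a reversed motor sequence:
            # an ambiguous upper-airway response, not laryngeal activation
            ev.atypical = True
            return ev

    # (2) laryngeal activation: laser-locked laryngeal burst, no
    # stimulus-locked diaphragm burst
    if trigger == "laser":
        lar = next((b for b in lar_cands
                    if abs(b.onset - stim.onset) <= params.onset_tolerance_ms * 1e-3
                    and b.offset <= stim_off + params.lock_tolerance_ms * 1e-3), None)
        dia_locked = any(stim.onset <= b.onset <= stim_off for b in bursts["diaphragm"])
        # submental co-activity does not veto laryngeal activation (it is
        # present in some animals)
        if lar is not None and not dia_locked:
            ev.behavior_class = LARYNGEAL
            ev.laryngeal_duration_ms = lar.duration_ms
            ev.laryngeal_onset, ev.laryngeal_offset = lar.onset, lar.offset
            ev.laryngeal_amp = lar.peak_amplitude
            if assigned is not None:
                assigned.add((lar.channel, lar.onset))
            return ev

    # (3) no response; bursts present but matching no template -> atypical
    if sub_cands or lar_cands:
        ev.atypical = True
        logger.debug("stimulus %d at %.3fs: atypical response", stimulus_id, stim.onset)
    return ev


def measure_swallow(
    ev: BehaviorEvent,
    sub: Burst,
    lar: Burst,
    breaths: list[Breath],
    diaphragm_bursts: list[Burst],
) -> BehaviorEvent:
    """Fill the swallow metrics of ``ev`` from its burst pair.

    * swallow duration: submental onset to termination (ms);
    * swallow sequence: laryngeal peak minus submental peak (ms);
    * Schluckatmung: diaphragm burst starting inside the swallow that is
      not the next rhythmic inspiration;
    * inspiratory delay: laryngeal offset to the next inspiratory onset.
    """
    ev.swallow_duration_ms = sub.duration_ms
    ev.submental_onset, ev.submental_offset = sub.onset, sub.offset
    ev.submental_amp = sub.peak_amplitude
    ev.swallow_sequence_ms = (lar.peak_time - sub.peak_time) * 1e3
    ev.laryngeal_duration_ms = lar.duration_ms
    ev.laryngeal_onset, ev.laryngeal_offset = lar.onset, lar.offset
    ev.laryngeal_amp = lar.peak_amplitude

    next_insp = next((br.insp_onset for br in breaths if br.insp_onset > lar.offset), None)
    if next_insp is not None:
        ev.inspiratory_delay_ms = (next_insp - lar.offset) * 1e3

    schluck = next(
        (b for b in diaphragm_bursts
         if sub.onset <= b.onset <= sub.offset
         and (next_insp is None or b.onset < next_insp)), None)
    if schluck is not None:
        ev.schluckatmung_duration_ms = schluck.duration_ms
    return ev


def compute_baseline(events: list[BehaviorEvent]) -> BaselineAmplitudes:
    """Max water-evoked swallow amplitude per channel (the 100% anchor)."""
    water = [e for e in events
             if e.trigger == "water" and e.behavior_class == SWALLOW and not e.atypical]
    out = BaselineAmplitudes()
    if not water:
        out.no_baseline = True
        logger.warning("no water-evoked swallows: amplitudes stay in a.u. (no-baseline)")
        return out
    sub = [e.submental_amp for e in water if not math.isnan(e.submental_amp)]
    lar = [e.laryngeal_amp for e in water if not math.isnan(e.laryngeal_amp)]
    if sub:
        out.max_amp["submental"] = max(sub)
    if lar:
        out.max_amp["laryngeal"] = max(lar)
    out.no_baseline = not out.max_amp
    return out


def normalize_amplitudes(events: list[BehaviorEvent], baseline: BaselineAmplitudes) -> None:
    """Fill ``*_amp_pct`` as percent of the water-swallow maximum."""
    for e in events:
        if baseline.no_baseline:
            e.no_baseline = True
            continue
        if "submental" in baseline.max_amp and not math.isnan(e.submental_amp):
            e.submental_amp_pct = 100.0 * e.submental_amp / baseline.max_amp["submental"]
        if "laryngeal" in baseline.max_amp and not math.isnan(e.laryngeal_amp):
            e.laryngeal_amp_pct = 100.0 * e.laryngeal_amp / baseline.max_amp["laryngeal"]
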