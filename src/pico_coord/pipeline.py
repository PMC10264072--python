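"""End-to-end analysis: conditioned signals -> classified behavior tables.

``analyze_recording`` runs the full chain on a :class:`Recording`:
band-pass, cardiac-artifact excision, rectified-smoothed envelopes, burst
detection, breath segmentation, stimulus classification, swallow metrics,
amplitude normalization, and the phase/reset statistics. The result
object holds tidy tables ready for any downstream stats tool.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import events as ev_mod
from . import phase_stats as ph
from . import sigproc
from .io_core import Recording, StimEvent, events_to_frame
from .synthgen import SWALLOW

logger = logging.getLogger("pico_coord")

__all__ = ["AnalysisParams", "AnalysisResult", "analyze_recording", "render_plots"]

EMG_CHANNELS = ("diaphragm", "submental", "laryngeal", "xii", "x")


@dataclass(frozen=True)
class AnalysisParams:
    band_low: float = 200.0
    band_high: float = 700.0
    band_transition: float = 40.0
    smooth_ms: float = 20.0
    ecg_removal: bool = True
    k_onset: float = 3.0
    k_offset: float = 1.0
    min_duration_ms: float = 15.0
    min_gap_ms: float = 10.0
    n_bins: int = 10
    classifier: bhv.ClassifierParams = field(default_factory=bhv.ClassifierParams)


@dataclass
class AnalysisResult:
    events: list[bhv.BehaviorEvent]
    phase_samples: list[ph.PhaseSample]
    probability_curves: dict[str, ph.BinnedCurve]
    reset: dict[str, ph.RegressionResult | None]
    timing: list[ph.SwallowTiming]
    timing_hist: np.ndarray
    breaths: list[ev_mod.Breath]
    bursts: dict[str, list[ev_mod.Burst]]
    baseline: bhv.BaselineAmplitudes
    params: AnalysisParams

    # ------------------------------------------------------------------
    def events_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events, bhv.BehaviorEvent)

    def phase_samples_frame(self) -> pd.DataFrame:
        df = events_to_frame(self.phase_samples, ph.PhaseSample)
        if not df.empty:
            df["group"] = [s.group for s in self.phase_samples]
        return df

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for klass, curve in self.probability_curves.items():
            for i in range(curve.n_bins):
                rows.append({
                    "behavior_class": klass, "bin": i,
                    "phase_center": curve.centers[i],
                    "probability": curve.mean[i], "sd": curve.sd[i],
                    "n": curve.n[i], "overflow": curve.overflow,
                })
        return pd.DataFrame(rows)

    def timing_frame(self) -> pd.DataFrame:
        return events_to_frame(self.timing, ph.SwallowTiming)

    def summary(self) -> dict:
        df = self.events_frame()
        out: dict = {"n_events": len(df)}
        if df.empty:
            return out
        laser = df[df.trigger == "laser"]
        out["class_counts"] = laser.behavior_class.value_counts().to_dict()
        for trig in ("laser", "water"):
            sw = df[(df.trigger == trig) & (df.behavior_class == SWALLOW) & ~df.atypical]
            if len(sw):
                out[f"{trig}_swallow_duration_ms"] = {
                    "mean": float(sw.swallow_duration_ms.mean()),
                    "sd": float(sw.swallow_duration_ms.std(ddof=1)) if len(sw) > 1 else 0.0,
                    "n": int(len(sw)),
                }
        lar = laser[laser.behavior_class == "laryngeal_activation"]
        if len(lar):
            out["laryngeal_duration_by_pulse_ms"] = {
                str(int(k)): float(v) for k, v in
                lar.groupby("pulse_duration_ms").laryngeal_duration_ms.mean().items()
            }
        out["reset"] = {
            g: (None if r is None else asdict(r)) for g, r in self.reset.items()
        }
        return out

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.events_frame().to_csv(outdir / "behavior_events.csv", index=False)
        self.phase_samples_frame().to_csv(outdir / "phase_samples.csv", index=False)
        self.curves_frame().to_csv(outdir / "probability_curves.csv", index=False)
        self.timing_frame().to_csv(outdir / "swallow_timing.csv", index=False)
        burst_rows = [b for bl in self.bursts.values() for b in bl]
        events_to_frame(burst_rows, ev_mod.Burst).to_csv(outdir / "bursts.csv", index=False)
        events_to_frame(self.breaths, ev_mod.Breath).to_csv(outdir / "breaths.csv", index=False)
        (outdir / "summary.json").write_text(json.dumps(self.summary(), indent=1))
        return outdir


def _prepare_envelopes(recording: Recording, params: AnalysisParams):
    fs = recording.sampling_rate
    reference = recording.channels.get("ecg")
    envelopes = {}
    for name in EMG_CHANNELS:
        if name not in recording.channels:
            continue
        raw = recording.channels[name]
        # excise cardiac epochs before filtering: the narrow-transition FIR
        # would otherwise smear each spike beyond the excision window
        if params.ecg_removal:
            raw, _ = sigproc.remove_ecg(raw, fs, ecg_reference=reference)
        band = sigproc.bandpass_filter(
            raw, fs, params.band_low, params.band_high, params.band_transition)
        envelopes[name] = sigproc.rectify_smooth(band, fs, params.smooth_ms, source=name)
    return envelopes


def analyze_recording(
    recording: Recording, params: AnalysisParams = AnalysisParams()
) -> AnalysisResult:
    """Run the full analysis chain on one recording."""
    recording.require("diaphragm", "laryngeal")
    if "submental" not in recording.channels and "xii" not in recording.channels:
        recording.require("submental")

    envelopes = _prepare_envelopes(recording, params)
    bursts = {
        name: ev_mod.detect_bursts(
            env, None, params.k_onset, params.k_offset,
            params.min_duration_ms, params.min_gap_ms, channel=name)
        for name, env in envelopes.items()
    }

    # diaphragm bursts starting inside a submental burst are swallow-related
    # (Schluckatmung), not inspirations
    sub_key = "submental" if "submental" in bursts else "xii"
    sub_intervals = [(b.onset, b.offset) for b in bursts[sub_key]]
    insp, swallow_dia = [], []
    for b in bursts["diaphragm"]:
        inside = any(lo <= b.onset <= hi for lo, hi in sub_intervals)
        (swallow_dia if inside else insp).append(b)

    breaths = ev_mod.segment_breaths(insp)
    control, flagged = ev_mod.exclude_perturbed_breaths(
        breaths, recording.stimuli, recording.water_events)
    flagged_onsets = {br.insp_onset for br in flagged}
    is_control = [br.insp_onset not in flagged_onsets for br in breaths]

    # classify in global time order so overlapping candidate bursts go to
    # the earlier stimulus
    merged: list[tuple[float, str, StimEvent]] = [
        (s.onset, "laser", s) for s in recording.stimuli
    ] + [
        (w, "water", StimEvent(onset=w, duration=1.0)) for w in recording.water_events
    ]
    merged.sort(key=lambda x: x[0])

    class_bursts = {k: v for k, v in bursts.items()}
    class_bursts["diaphragm"] = insp
    assigned: set = set()
    events: list[bhv.BehaviorEvent] = []
    for i, (onset, trigger, stim) in enumerate(merged):
        ev = bhv.classify_response(
            stim, class_bursts, breaths, params.classifier,
            trigger=trigger, stimulus_id=i, assigned=assigned,
            diaphragm_all=swallow_dia)
        res = ph.respiratory_phase(onset, breaths, is_control)
        if res is not None:
            ev.respiratory_phase, ev.breath_index = res[0], res[1]
            shift = ph.phase_shift(onset, breaths, is_control)
            ev.phase_shift = shift if shift is not None else float("nan")
        events.append(ev)

    baseline = bhv.compute_baseline(events)
    bhv.normalize_amplitudes(events, baseline)

    samples = ph.make_phase_samples(events)
    curves = ph.probability_curves(events, params.n_bins)
    reset: dict[str, ph.RegressionResult | None] = {}
    for group in ("swallow", "non_swallow"):
        try:
            reset[group] = ph.reset_correlation(samples, group)
        except ValueError as e:
            logger.warning("reset correlation (%s): %s", group, e)
            reset[group] = None
    timing, hist = ph.swallow_timing(events, breaths, params.n_bins)

    return AnalysisResult(
        events=events, phase_samples=samples, probability_curves=curves,
        reset=reset, timing=timing, timing_hist=hist, breaths=breaths,
        bursts=bursts, baseline=baseline, params=params)


def render_plots(result: AnalysisResult, outdir: str | Path) -> list[Path]:
    """Write the three standard figures as PNG files."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for klass, curve in result.probability_curves.items():
        ax.errorbar(curve.centers, curve.mean, yerr=curve.sd, marker="o",
                    capsize=2, label=klass.replace("_", " "))
    ax.set_xlabel("respiratory phase")
    ax.set_ylabel("probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = outdir / "probability_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, color in (("swallow", "tab:orange"), ("non_swallow", "tab:blue")):
        xs = [s.respiratory_phase for s in result.phase_samples if s.group == group]
        ys = [s.phase_shift for s in result.phase_samples if s.group == group]
        ax.scatter(xs, ys, s=8, alpha=0.6, color=color, label=group)
        r = result.reset.get(group)
        if r is not None and xs:
            gx = np.linspace(min(xs), max(xs), 2)
            ax.plot(gx, r.intercept + r.slope * gx, color=color,
                    label=f"{group}: r={r.r:.2f}, slope={r.slope:.2f}")
    ax.set_xlabel("respiratory phase")
    ax.set_ylabel("phase shift")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = outdir / "phase_shift.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    edges = np.arange(result.params.n_bins + 1) / result.params.n_bins
    ax.bar(edges[:-1], result.timing_hist, width=np.diff(edges), align="edge",
           edgecolor="k")
    ax.set_xlabel("swallow onset phase")
    ax.set_ylabel("count")
    fig.tight_layout()
    p = outdir / "swallow_histogram.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
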