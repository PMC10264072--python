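"""Recording container and on-disk formats.

A recording is stored as two plain-text files in a directory:

* ``signals.csv`` — one ``time_s`` column plus one column per channel,
  header row of channel names;
* ``recording.json`` — sampling rate, stimulus train, water-bolus times
  and free-form metadata.

Event tables (behavior events, phase samples, bursts, ...) are tidy CSV,
one row per event. Times are seconds from recording start; durations are
milliseconds; amplitudes are arbitrary units unless a column is
explicitly ``*_pct`` (percent of the water-swallow maximum).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimEvent",
    "Recording",
    "SchemaError",
    "write_recording",
    "read_recording",
    "write_events_table",
    "read_events_table",
]

REQUIRED_CHANNELS = ("diaphragm", "submental", "laryngeal")
OPTIONAL_CHANNELS = ("xii", "x", "ecg")

SIGNALS_FILE = "signals.csv"
SIDECAR_FILE = "recording.json"


class SchemaError(ValueError):
    """Recording files violate the expected schema."""


@dataclass(frozen=True)
class StimEvent:
    """One laser pulse: onset in s, duration in ms."""

    onset: float
    duration: float  # ms
    power_label: str = "0.75 mW"

    @property
    def offset(self) -> float:
        return self.onset + self.duration * 1e-3

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"stimulus onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"stimulus duration must be > 0, got {self.duration}")


@dataclass
class Recording:
    """Multi-channel sampled session plus its stimulus/water event trains."""

    sampling_rate: float
    channels: dict[str, np.ndarray]
    stimuli: list[StimEvent] = field(default_factory=list)
    water_events: list[float] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            raise SchemaError("recording has no channels")
        lengths = {name: len(s) for name, s in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise SchemaError(f"channel lengths differ: {lengths}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        validate_stimuli(self.stimuli)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def require(self, *names: str) -> None:
        for name in names:
            if name not in self.channels:
                raise SchemaError(f"required channel missing: {name!r}")


def validate_stimuli(stimuli: list[StimEvent]) -> None:
    for a, b in zip(stimuli, stimuli[1:]):
        if b.onset < a.onset:
            raise SchemaError("stimuli not sorted by onset")
        if b.onset < a.offset:
            raise SchemaError(
                f"overlapping stimuli at {a.onset:.4f}s and {b.onset:.4f}s"
            )


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write ``signals.csv`` + ``recording.json`` under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n = recording.n_samples
    t = np.arange(n) / recording.sampling_rate
    df = pd.DataFrame({"time_s": t} | dict(recording.channels))
    df.to_csv(path / SIGNALS_FILE, index=False)
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "stimuli": [
            {"onset": s.onset, "duration": s.duration, "power_label": s.power_label}
            for s in recording.stimuli
        ],
        "water_events": list(map(float, recording.water_events)),
        "metadata": recording.metadata,
    }
    (path / SIDECAR_FILE).write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path, require_channels: bool = True) -> Recording:
    """Read a recording directory written by :func:`write_recording`."""
    path = Path(path)
    signals = path / SIGNALS_FILE
    sidecar = path / SIDECAR_FILE
    if not signals.exists() or not sidecar.exists():
        raise FileNotFoundError(f"not a recording directory: {path}")
    try:
        df = pd.read_csv(signals)
    except pd.errors.ParserError as e:  # ragged rows etc.
        raise SchemaError(f"malformed signal file: {e}") from e
    if "time_s" not in df.columns:
        raise SchemaError("signal file lacks a 'time_s' column")
    meta = json.loads(sidecar.read_text())
    channels = {c: df[c].to_numpy(float) for c in df.columns if c != "time_s"}
    if require_channels:
        for name in REQUIRED_CHANNELS:
            if name not in channels:
                raise SchemaError(f"required channel missing: {name!r}")
    stimuli = [
        StimEvent(s["onset"], s["duration"], s.get("power_label", ""))
        for s in meta.get("stimuli", [])
    ]
    return Recording(
        sampling_rate=float(meta["sampling_rate"]),
        channels=channels,
        stimuli=stimuli,
        water_events=[float(w) for w in meta.get("water_events", [])],
        metadata=meta.get("metadata", {}),
    )


def write_events_table(events: list, path: str | Path, kind: type | None = None) -> Path:
    """Write a homogeneous list of event dataclasses as tidy CSV.

    ``kind`` (an event dataclass) supplies the header columns when
    ``events`` is empty, giving a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = events if isinstance(events, pd.DataFrame) else events_to_frame(events, kind)
    df.to_csv(path, index=False)
    return path


def events_to_frame(events: list, kind: type | None = None) -> pd.DataFrame:
    if len(events) == 0:
        cols = [f.name for f in dataclasses.fields(kind)] if kind else []
        return pd.DataFrame(columns=cols)
    types = {type(e) for e in events}
    if len(types) != 1:
        raise TypeError(f"mixed event types in one table: {sorted(t.__name__ for t in types)}")
    t = types.pop()
    if not dataclasses.is_dataclass(t):
        raise TypeError(f"events must be dataclass instances, got {t.__name__}")
    return pd.DataFrame([dataclasses.asdict(e) for e in events])


def read_events_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
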