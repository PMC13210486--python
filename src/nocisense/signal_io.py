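"""Session data model, on-disk layout, validation and cohort filtering.

A session is one subject's synchronized recording: an EDA channel (4 Hz,
microsiemens), a PPG channel (50 Hz, arbitrary units), protocol event
markers delimiting each trial's anticipation / stimulation / ramp-down
phases, and per-trial visual-analog-scale (VAS) self-reports of anxiety
(0-10, pre-exposure) and pain (0-10, post-exposure).

On disk a session is a directory::

    <session>/
        eda.csv       # header time_s,value
        ppg.csv       # header time_s,value
        events.json   # subject_id, baseline_window, trials[...]

All times are seconds from recording start; every interval is half-open
``[t_start, t_end)`` so adjacent phases share a boundary without overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalChannel",
    "EventMarker",
    "VASResponse",
    "Session",
    "ValidationError",
    "load_session",
    "write_session",
    "validate_session",
    "exclude_nonresponders",
]

MODALITIES = ("TGI", "TENS")
LEVEL_RANGE = {"TGI": (0, 2), "TENS": (0, 4)}
PHASES = ("baseline", "anticipation", "stimulation", "rampdown", "recovery")
#: phases that must appear, in order, inside each trial
TRIAL_PHASE_ORDER = ("anticipation", "stimulation", "rampdown")


class ValidationError(ValueError):
    """A session violates a structural invariant; message lists violations."""


@dataclass(frozen=True)
class SignalChannel:
    """One sampled biosignal channel.

    Parameters
    ----------
    name : str
        ``"eda"`` or ``"ppg"``.
    sampling_rate : float
        Samples per second, > 0.
    t0 : float
        Time of the first sample on the session clock (seconds).
    samples : ndarray
        Finite sample values (µS for EDA, arbitrary units for PPG).
    """

    name: str
    sampling_rate: float
    t0: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.name not in ("eda", "ppg"):
            raise ValidationError(f"unknown channel name {self.name!r}")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be > 0")
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise ValidationError(
                f"channel {self.name!r}: non-finite sample at index {bad[0]}"
            )

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def slice(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples whose timestamps fall in the half-open window."""
        t = self.times
        return self.samples[(t >= t_start) & (t < t_end)]


@dataclass(frozen=True)
class EventMarker:
    trial_index: int
    modality: str
    level: int
    phase: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        lo, hi = LEVEL_RANGE[self.modality]
        if not lo <= self.level <= hi:
            raise ValidationError(
                f"{self.modality} level {self.level} outside [{lo}, {hi}]"
            )
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if not self.t_end > self.t_start:
            raise ValidationError("marker interval must satisfy t_end > t_start")
        if self.trial_index < 0:
            raise ValidationError("trial_index must be >= 0")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class VASResponse:
    trial_index: int
    anxiety_score: int
    pain_score: int

    def __post_init__(self) -> None:
        for label, score in (("anxiety", self.anxiety_score), ("pain", self.pain_score)):
            if not 0 <= score <= 10:
                raise ValidationError(f"{label} VAS {score} outside [0, 10]")


@dataclass(frozen=True)
class Session:
    """One subject's recording with markers and self-reports."""

    subject_id: str
    eda: SignalChannel
    ppg: SignalChannel
    markers: tuple[EventMarker, ...]
    vas: tuple[VASResponse, ...]
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "vas", tuple(self.vas))
        object.__setattr__(self, "baseline_window", tuple(self.baseline_window))
        problems = validate_session(self)
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def trial_indices(self) -> list[int]:
        return sorted({m.trial_index for m in self.markers})

    def trial_markers(self, trial_index: int) -> list[EventMarker]:
        return [m for m in self.markers if m.trial_index == trial_index]

    def vas_for(self, trial_index: int) -> VASResponse:
        for v in self.vas:
            if v.trial_index == trial_index:
                return v
        raise KeyError(f"no VAS response for trial {trial_index}")


def validate_session(session: Session) -> list[str]:
    """Return a list of invariant violations (empty when valid)."""
    problems: list[str] = []
    if session.eda.name != "eda" or session.ppg.name != "ppg":
        problems.append("channels must be one 'eda' and one 'ppg'")
    b0, b1 = session.baseline_window
    if not b1 - b0 >= 5.0:
        problems.append("baseline_window shorter than 5 s")
    span_end = min(session.eda.t0 + session.eda.duration,
                   session.ppg.t0 + session.ppg.duration)
    span_start = max(session.eda.t0, session.ppg.t0)
    if b0 < span_start - 1e-9 or b1 > span_end + 1e-9:
        problems.append("baseline_window outside recording span")
    vas_trials = {v.trial_index for v in session.vas}
    for ti in sorted({m.trial_index for m in session.markers}):
        trial = sorted(session.trial_markers(ti), key=lambda m: m.t_start)
        if ti not in vas_trials:
            problems.append(f"trial {ti} has markers but no VAS response")
        phase_seq = [m.phase for m in trial if m.phase in TRIAL_PHASE_ORDER]
        if tuple(phase_seq) != TRIAL_PHASE_ORDER[: len(phase_seq)] or len(phase_seq) < 3:
            problems.append(
                f"trial {ti}: phases must be anticipation, stimulation, rampdown in order"
            )
        for a, b in zip(trial, trial[1:]):
            if b.t_start < a.t_end - 1e-9:
                problems.append(f"trial {ti}: overlapping markers {a.phase}/{b.phase}")
        for m in trial:
            if m.t_start < span_start - 1e-9 or m.t_end > span_end + 1e-9:
                problems.append(
                    f"trial {ti} marker {m.phase} [{m.t_start}, {m.t_end}) "
                    "outside recording span"
                )
        mods = {m.modality for m in trial}
        if len(mods) > 1:
            problems.append(f"trial {ti}: mixed modalities {sorted(mods)}")
    return problems


# ---------------------------------------------------------------------------
# on-disk layout

def _channel_to_csv(channel: SignalChannel, path: Path) -> None:
    t = channel.times
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s,value\n")
        for ti, vi in zip(t, channel.samples):
            fh.write(f"{ti:.9g},{vi:.12g}\n")


def _channel_from_csv(path: Path, name: str) -> SignalChannel:
    if not path.exists():
        raise FileNotFoundError(f"missing channel file: {path.name}")
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "value"]:
        raise ValidationError(f"{path.name}: expected header time_s,value")
    t = df["time_s"].to_numpy(float)
    v = df["value"].to_numpy(float)
    if len(t) < 2:
        raise ValidationError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    fs = 1.0 / np.median(dt)
    # snap to the nominal rates used by the recording hardware
    for nominal in (4.0, 50.0):
        if abs(fs - nominal) / nominal < 0.01:
            fs = nominal
    if np.any(np.abs(dt - 1.0 / fs) > 0.25 / fs):
        raise ValidationError(f"{path.name}: non-uniform sample times")
    return SignalChannel(name=name, sampling_rate=fs, t0=float(t[0]), samples=v)


def write_session(session: Session, path: str | Path) -> None:
    """Write ``eda.csv``, ``ppg.csv`` and ``events.json`` under *path*.

    Output is deterministic: identical sessions produce byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _channel_to_csv(session.eda, path / "eda.csv")
    _channel_to_csv(session.ppg, path / "ppg.csv")

    trials = []
    for ti in session.trial_indices:
        markers = {m.phase: m for m in session.trial_markers(ti)}
        vas = session.vas_for(ti)
        first = session.trial_markers(ti)[0]
        trials.append({
            "trial_index": ti,
            "modality": first.modality,
            "level": first.level,
            "phases": {
                phase: [markers[phase].t_start, markers[phase].t_end]
                for phase in TRIAL_PHASE_ORDER + ("recovery",)
                if phase in markers
            },
            "anxiety_vas": vas.anxiety_score,
            "pain_vas": vas.pain_score,
        })
    payload = {
        "subject_id": session.subject_id,
        "baseline_window": list(session.baseline_window),
        "trials": trials,
    }
    with open(path / "events.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_session(path: str | Path) -> Session:
    """Read a session directory written by :func:`write_session`.

    Raises a hard error naming the missing channel, a marker outside the
    recording span, or the index of any non-finite sample.
    """
    path = Path(path)
    eda = _channel_from_csv(path / "eda.csv", "eda")
    ppg = _channel_from_csv(path / "ppg.csv", "ppg")
    events_path = path / "events.json"
    if not events_path.exists():
        raise FileNotFoundError(f"missing events file: {events_path.name}")
    with open(events_path, encoding="utf-8") as fh:
        payload = json.load(fh)

    markers: list[EventMarker] = []
    vas: list[VASResponse] = []
    for trial in payload["trials"]:
        for phase, (s, e) in trial["phases"].items():
            markers.append(EventMarker(
                trial_index=int(trial["trial_index"]),
                modality=trial["modality"],
                level=int(trial["level"]),
                phase=phase,
                t_start=float(s),
                t_end=float(e),
            ))
        vas.append(VASResponse(
            trial_index=int(trial["trial_index"]),
            anxiety_score=int(trial["anxiety_vas"]),
            pain_score=int(trial["pain_vas"]),
        ))
    return Session(
        subject_id=str(payload["subject_id"]),
        eda=eda,
        ppg=ppg,
        markers=tuple(sorted(markers, key=lambda m: (m.trial_index, m.t_start))),
        vas=tuple(sorted(vas, key=lambda v: v.trial_index)),
        baseline_window=tuple(payload["baseline_window"]),
    )


def check_sample_count(channel: SignalChannel, declared_duration: float) -> None:
    """Declared duration x rate must match the sample count within ±1 sample."""
    expected = declared_duration * channel.sampling_rate
    if abs(len(channel.samples) - expected) > 1.0 + 1e-9:
        raise ValidationError(
            f"channel {channel.name!r}: sample count mismatch "
            f"(got {len(channel.samples)}, declared {declared_duration} s "
            f"@ {channel.sampling_rate} Hz -> {expected:.0f})"
        )


def exclude_nonresponders(sessions: Sequence[Session]) -> list[Session]:
    """Drop subjects whose every anxiety VAS is 4 or below.

    Such subjects reported low or no anxiety throughout and are removed
    as non-responders; a single anxiety score above 4 retains the subject.
    Input order is preserved and the operation is idempotent.
    """
    kept = []
    for s in sessions:
        if not s.vas:
            raise ValidationError(f"session {s.subject_id}: no VAS responses")
        if any(v.anxiety_score > 4 for v in s.vas):
            kept.append(s)
    return kept
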