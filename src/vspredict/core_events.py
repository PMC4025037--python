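"""Discretization of raw vital-sign measurements into labeled state events.

Timestamped numeric samples (systolic/diastolic blood pressure, SpO2, heart
rate) are binned onto a discrete 1-based time axis and classified against
standard clinical staging thresholds, producing a *complex event sequence*:
an ordered series of time ticks, each carrying the set of abnormal states
observed simultaneously at that tick.  This sequence is the sole input of
the episode miner.

Classification thresholds (Department-of-Health staging conventions):

======================  ==========================  =================
state                   criterion                   label
======================  ==========================  =================
prehypertension         SBP 120-139 or DBP 80-89    ``BP_HB``
stage 1 hypertension    SBP 140-159 or DBP 90-99    ``BP_H1``
stage 2 hypertension    SBP >=160  or DBP >=100     ``BP_H2``
mild hypoxemia          SpO2 < 94 %                 ``SpO2_Lmicro``
moderate hypoxemia      SpO2 < 89 %                 ``SpO2_Lmid``
severe hypoxemia        SpO2 < 75 %                 ``SpO2_Lhard``
tachycardia             HR > 100 bpm                ``Pulse_H``
bradycardia             HR < 60 bpm                 ``Pulse_L``
normal                  otherwise                   ``N``
======================  ==========================  =================

Blood pressure is staged jointly: the category is the *most severe* one
whose systolic or diastolic criterion is met.  The overlapping hypoxemia
bands are likewise resolved most-severe-first, yielding half-open bands
[89,94), [75,89), [0,75).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "Signal",
    "StateLabel",
    "VitalSample",
    "SimultaneousEventSet",
    "ComplexEventSequence",
    "classify_blood_pressure",
    "classify_oxygen",
    "classify_heart_rate",
    "classify_states",
    "discretize_stream",
    "read_samples_csv",
    "write_sequence_json",
    "read_sequence_json",
]


class Signal(str, Enum):
    """The four supported vital-sign channels."""

    SYS_BP = "SYS_BP"  # systolic blood pressure, mmHg
    DIA_BP = "DIA_BP"  # diastolic blood pressure, mmHg
    SPO2 = "SPO2"      # peripheral oxygen saturation, percent
    HR = "HR"          # heart rate, beats per minute


#: accepted spellings in input files, lower-cased
_SIGNAL_ALIASES = {
    "sys_bp": Signal.SYS_BP, "sys": Signal.SYS_BP, "sbp": Signal.SYS_BP,
    "systolic": Signal.SYS_BP,
    "dia_bp": Signal.DIA_BP, "dia": Signal.DIA_BP, "dbp": Signal.DIA_BP,
    "diastolic": Signal.DIA_BP,
    "spo2": Signal.SPO2, "oxygen": Signal.SPO2, "sao2": Signal.SPO2,
    "hr": Signal.HR, "pulse": Signal.HR, "heart_rate": Signal.HR,
    "heartrate": Signal.HR,
}


class StateLabel(str, Enum):
    """The nine discretized vital-sign states."""

    BP_HB = "BP_HB"              # prehypertension
    BP_H1 = "BP_H1"              # stage 1 hypertension
    BP_H2 = "BP_H2"              # stage 2 hypertension
    SPO2_LMICRO = "SpO2_Lmicro"  # mild hypoxemia
    SPO2_LMID = "SpO2_Lmid"      # moderate hypoxemia
    SPO2_LHARD = "SpO2_Lhard"    # severe hypoxemia
    PULSE_H = "Pulse_H"          # tachycardia
    PULSE_L = "Pulse_L"          # bradycardia
    N = "N"                      # normal


_BP_LABELS = {StateLabel.BP_HB.value, StateLabel.BP_H1.value, StateLabel.BP_H2.value}
_SPO2_LABELS = {
    StateLabel.SPO2_LMICRO.value,
    StateLabel.SPO2_LMID.value,
    StateLabel.SPO2_LHARD.value,
}
_PULSE_LABELS = {StateLabel.PULSE_H.value, StateLabel.PULSE_L.value}


def _require_finite_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and positive, got {value!r}")


def classify_blood_pressure(systolic: float, diastolic: float) -> StateLabel:
    """Stage a blood-pressure reading (mmHg) jointly over both components.

    Returns the most severe category whose systolic *or* diastolic criterion
    is met; ``N`` below the prehypertensive thresholds.
    """
    _require_finite_positive("systolic", systolic)
    _require_finite_positive("diastolic", diastolic)
    if systolic >= 160 or diastolic >= 100:
        return StateLabel.BP_H2
    if systolic >= 140 or diastolic >= 90:
        return StateLabel.BP_H1
    if systolic >= 120 or diastolic >= 80:
        return StateLabel.BP_HB
    return StateLabel.N


def classify_oxygen(spo2: float) -> StateLabel:
    """Classify an SpO2 reading (percent) into hypoxemia bands."""
    if not math.isfinite(spo2) or not 0 <= spo2 <= 100:
        raise ValueError(f"spo2 must lie in [0, 100], got {spo2!r}")
    if spo2 < 75:
        return StateLabel.SPO2_LHARD
    if spo2 < 89:
        return StateLabel.SPO2_LMID
    if spo2 < 94:
        return StateLabel.SPO2_LMICRO
    return StateLabel.N


def classify_heart_rate(hr: float) -> StateLabel:
    """Classify a heart-rate reading (bpm); boundaries are strict."""
    _require_finite_positive("heart rate", hr)
    if hr > 100:
        return StateLabel.PULSE_H
    if hr < 60:
        return StateLabel.PULSE_L
    return StateLabel.N


def classify_states(values: dict[Signal, float]) -> set[StateLabel]:
    """Classify one tick's worth of signal values into a state set.

    Blood pressure is staged from whichever of SYS_BP/DIA_BP are present
    (a lone component is staged on its own criterion).  At most one label
    per signal family is emitted; ``N`` is emitted once when every present
    family is normal.
    """
    states: set[StateLabel] = set()
    sys_v = values.get(Signal.SYS_BP)
    dia_v = values.get(Signal.DIA_BP)
    if sys_v is not None or dia_v is not None:
        states.add(_classify_bp_partial(sys_v, dia_v))
    if Signal.SPO2 in values:
        states.add(classify_oxygen(values[Signal.SPO2]))
    if Signal.HR in values:
        states.add(classify_heart_rate(values[Signal.HR]))
    abnormal = {s for s in states if s is not StateLabel.N}
    if abnormal:
        return abnormal
    return {StateLabel.N} if states else set()


def _classify_bp_partial(systolic: float | None, diastolic: float | None) -> StateLabel:
    # one component missing: stage on the available criterion alone
    if systolic is not None and diastolic is not None:
        return classify_blood_pressure(systolic, diastolic)
    if systolic is not None:
        _require_finite_positive("systolic", systolic)
        if systolic >= 160:
            return StateLabel.BP_H2
        if systolic >= 140:
            return StateLabel.BP_H1
        if systolic >= 120:
            return StateLabel.BP_HB
        return StateLabel.N
    assert diastolic is not None
    _require_finite_positive("diastolic", diastolic)
    if diastolic >= 100:
        return StateLabel.BP_H2
    if diastolic >= 90:
        return StateLabel.BP_H1
    if diastolic >= 80:
        return StateLabel.BP_HB
    return StateLabel.N


@dataclass(frozen=True)
class VitalSample:
    """One timestamped numeric measurement of one signal for one subject."""

    subject_id: str
    timestamp: float  # seconds (epoch or relative)
    signal: Signal
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.signal}: {self.value!r}")
        if self.signal is Signal.SPO2:
            if not 0 <= self.value <= 100:
                raise ValueError(f"SpO2 out of [0,100]: {self.value!r}")
        elif self.value <= 0:
            raise ValueError(f"non-positive {self.signal.value}: {self.value!r}")
        if not math.isfinite(self.timestamp):
            raise ValueError(f"non-finite timestamp: {self.timestamp!r}")


@dataclass(frozen=True)
class SimultaneousEventSet:
    """The set of state events observed at one integer time tick."""

    tick: int
    events: frozenset[str]

    def __post_init__(self) -> None:
        if self.tick < 1:
            raise ValueError(f"ticks are 1-based, got {self.tick}")
        if not isinstance(self.events, frozenset):
            object.__setattr__(self, "events", frozenset(self.events))
        # enforce one-label-per-family only for genuine vital-sign labels;
        # abstract alphabets (worked examples, tests) are unconstrained
        for family in (_BP_LABELS, _SPO2_LABELS, _PULSE_LABELS):
            if len(self.events & family) > 1:
                raise ValueError(
                    f"tick {self.tick} carries conflicting labels {sorted(self.events & family)}"
                )

    @property
    def sorted_events(self) -> tuple[str, ...]:
        return tuple(sorted(self.events))


@dataclass
class ComplexEventSequence:
    """An ordered sequence of simultaneous event sets on a discrete time axis."""

    sets: list[SimultaneousEventSet] = field(default_factory=list)
    tick_width: float = 60.0

    def __post_init__(self) -> None:
        ticks = [s.tick for s in self.sets]
        if any(b <= a for a, b in zip(ticks, ticks[1:])):
            raise ValueError("ticks must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @property
    def ticks(self) -> list[int]:
        return [s.tick for s in self.sets]

    def as_dict(self) -> dict[int, frozenset[str]]:
        """Mapping tick -> event set (non-empty ticks only)."""
        return {s.tick: s.events for s in self.sets if s.events}

    def restrict(self, first_tick: int, last_tick: int) -> "ComplexEventSequence":
        """The sub-sequence with ticks in [first_tick, last_tick]."""
        return ComplexEventSequence(
            [s for s in self.sets if first_tick <= s.tick <= last_tick],
            tick_width=self.tick_width,
        )


def discretize_stream(
    samples: Sequence[VitalSample],
    tick_width: float = 60.0,
    include_normal: bool = False,
) -> ComplexEventSequence:
    """Bin one subject's samples to ticks and classify each tick's signals.

    Ticks are ``floor(timestamp / tick_width) + 1`` (1-based).  When several
    samples of one signal fall into a tick the last one (by timestamp, then
    input order) wins — monitoring semantics.  With ``include_normal=False``
    (default) ``N`` labels are dropped and ticks left empty are omitted.
    """
    if tick_width <= 0:
        raise ValueError("tick_width must be positive")
    if not samples:
        return ComplexEventSequence([], tick_width=tick_width)
    subjects = {s.subject_id for s in samples}
    if len(subjects) > 1:
        raise ValueError(f"samples mix subjects {sorted(subjects)}; discretize one at a time")

    ordered = sorted(enumerate(samples), key=lambda p: (p[1].timestamp, p[0]))
    per_tick: dict[int, dict[Signal, float]] = {}
    for _, s in ordered:
        tick = int(math.floor(s.timestamp / tick_width)) + 1
        per_tick.setdefault(tick, {})[s.signal] = s.value  # last wins

    sets: list[SimultaneousEventSet] = []
    for tick in sorted(per_tick):
        states = classify_states(per_tick[tick])
        if not include_normal:
            states = {s for s in states if s is not StateLabel.N}
        if states:
            sets.append(SimultaneousEventSet(tick, frozenset(s.value for s in states)))
    return ComplexEventSequence(sets, tick_width=tick_width)


# ---------------------------------------------------------------------------
# file formats


def read_samples_csv(path: str | Path) -> list[VitalSample]:
    """Read `subject,timestamp,signal,value` delimited text (CSV or TSV).

    Timestamps may be epoch/relative seconds or ISO-8601 strings.  Samples
    are returned sorted by (subject, timestamp).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"subject", "timestamp", "signal", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"expected columns {sorted(required)}, got {list(df.columns)}")

    ts = pd.to_numeric(df["timestamp"], errors="coerce")
    if ts.isna().any():
        parsed = pd.to_datetime(df["timestamp"], errors="raise", format="ISO8601")
        ts = parsed.astype("int64") / 1e9
    samples = []
    for subj, t, sig, val in zip(df["subject"], ts, df["signal"], df["value"]):
        key = str(sig).strip().lower()
        if key not in _SIGNAL_ALIASES:
            raise ValueError(f"unknown signal name {sig!r}")
        samples.append(VitalSample(str(subj), float(t), _SIGNAL_ALIASES[key], float(val)))
    samples.sort(key=lambda s: (s.subject_id, s.timestamp))
    return samples


def write_sequence_json(seq: ComplexEventSequence, path: str | Path) -> None:
    """Write an event sequence as `[{"tick": 1, "events": [...]}, ...]`."""
    payload = {
        "tick_width": seq.tick_width,
        "sequence": [
            {"tick": s.tick, "events": list(s.sorted_events)} for s in seq.sets
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_sequence_json(path: str | Path) -> ComplexEventSequence:
    """Round-tripping reader for :func:`write_sequence_json` output.

    Also accepts a bare JSON list of ``{"tick":..,"events":[..]}`` records.
    """
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, list):
        records, width = raw, 60.0
    else:
        records, width = raw["sequence"], float(raw.get("tick_width", 60.0))
    sets = [
        SimultaneousEventSet(int(r["tick"]), frozenset(map(str, r["events"])))
        for r in records
    ]
    return ComplexEventSequence(sets, tick_width=width)
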