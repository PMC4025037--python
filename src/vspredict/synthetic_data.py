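"""Synthetic vital-sign streams with planted temporal dependencies.

The generator emulates a multi-signal monitoring stream: per tick it draws
heart rate, systolic/diastolic pressure and SpO2 from baseline
distributions clipped into the healthy bands, occasionally pushes a signal
into a random abnormal band (background noise), and realizes *planted
rules* — whenever a trigger state set is observed at tick t, the consequent
state set is written into the corresponding signal bands at t+lag with a
configured firing probability.  Because the planted structure is known,
every downstream stage (discretization, mining, rule generation,
prediction) can be tested for parameter recovery without external data.

The module also ships the small abstract worked-example sequence used
throughout the mining tests (five ticks over the alphabet {A, B, C}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_events import (
    ComplexEventSequence,
    Signal,
    SimultaneousEventSet,
    StateLabel,
    VitalSample,
    classify_states,
)

__all__ = ["PlantedRule", "GeneratorConfig", "generate_stream", "fig4_fixture"]


#: value ranges used when a state must be realized, chosen strictly inside
#: the classification bands so float jitter cannot cross a boundary
_STATE_BANDS: dict[str, dict[Signal, tuple[float, float]]] = {
    StateLabel.PULSE_H.value: {Signal.HR: (103.0, 140.0)},
    StateLabel.PULSE_L.value: {Signal.HR: (42.0, 57.0)},
    StateLabel.BP_HB.value: {Signal.SYS_BP: (122.0, 137.0), Signal.DIA_BP: (81.0, 88.0)},
    StateLabel.BP_H1.value: {Signal.SYS_BP: (142.0, 157.0), Signal.DIA_BP: (91.0, 98.0)},
    StateLabel.BP_H2.value: {Signal.SYS_BP: (162.0, 190.0), Signal.DIA_BP: (102.0, 115.0)},
    StateLabel.SPO2_LMICRO.value: {Signal.SPO2: (89.5, 93.5)},
    StateLabel.SPO2_LMID.value: {Signal.SPO2: (76.0, 88.0)},
    StateLabel.SPO2_LHARD.value: {Signal.SPO2: (55.0, 74.0)},
}

#: healthy clip ranges per signal (baseline draws never leave these)
_NORMAL_BANDS: dict[Signal, tuple[float, float]] = {
    Signal.HR: (60.0, 100.0),
    Signal.SYS_BP: (90.0, 119.0),
    Signal.DIA_BP: (55.0, 79.0),
    Signal.SPO2: (94.0, 100.0),
}

#: abnormal state choices per noise family
_NOISE_FAMILIES: dict[str, list[str]] = {
    "pulse": [StateLabel.PULSE_H.value, StateLabel.PULSE_L.value],
    "bp": [StateLabel.BP_HB.value, StateLabel.BP_H1.value, StateLabel.BP_H2.value],
    "spo2": [
        StateLabel.SPO2_LMICRO.value,
        StateLabel.SPO2_LMID.value,
        StateLabel.SPO2_LHARD.value,
    ],
}


@dataclass(frozen=True)
class PlantedRule:
    """A planted temporal dependency: trigger set ⇒ consequent set at t+lag."""

    trigger: frozenset[str]
    consequent: frozenset[str]
    lag: int = 1
    probability: float = 0.9

    def __post_init__(self) -> None:
        object.__setattr__(self, "trigger", frozenset(self.trigger))
        object.__setattr__(self, "consequent", frozenset(self.consequent))
        if not 0 <= self.probability <= 1:
            raise ValueError("firing probability must lie in [0, 1]")
        if self.lag < 1:
            raise ValueError("lag must be >= 1 tick")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic stream.

    Baselines are per-signal Normal(mean, sd) draws clipped into the healthy
    band of each signal, so a noise-free stream classifies entirely to N.
    ``background_abnormal_rate`` is the per-tick probability, independently
    per signal family (pulse, blood pressure, oxygen), of pushing that
    family into a uniformly chosen abnormal band.  Planted-rule consequents
    override both baseline and background values at the target tick.
    """

    seed: int = 0
    n_ticks: int = 500
    tick_width: float = 60.0
    subject_id: str = "synthetic-01"
    hr_mean: float = 80.0
    hr_sd: float = 8.0
    sys_mean: float = 115.0
    sys_sd: float = 8.0
    dia_mean: float = 72.0
    dia_sd: float = 6.0
    spo2_mean: float = 97.0
    spo2_sd: float = 1.2
    background_abnormal_rate: float = 0.05
    planted_rules: list[PlantedRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_ticks < 1:
            raise ValueError("n_ticks must be >= 1")
        if self.tick_width <= 0:
            raise ValueError("tick_width must be positive")
        if not 0 <= self.background_abnormal_rate <= 1:
            raise ValueError("background_abnormal_rate must lie in [0, 1]")


def _baseline(rng: np.random.Generator, mean: float, sd: float, signal: Signal) -> float:
    lo, hi = _NORMAL_BANDS[signal]
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _band_value(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def generate_stream(config: GeneratorConfig) -> list[VitalSample]:
    """Simulate one subject's stream; deterministic given ``config.seed``.

    Emits four samples (SYS_BP, DIA_BP, SPO2, HR) per tick, timestamped at
    ``(tick - 1) * tick_width`` so discretization maps them back onto the
    same tick axis.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[VitalSample] = []
    # consequent states scheduled by planted rules: tick -> set of labels
    pending: dict[int, set[str]] = {}

    for tick in range(1, config.n_ticks + 1):
        values: dict[Signal, float] = {
            Signal.HR: _baseline(rng, config.hr_mean, config.hr_sd, Signal.HR),
            Signal.SYS_BP: _baseline(rng, config.sys_mean, config.sys_sd, Signal.SYS_BP),
            Signal.DIA_BP: _baseline(rng, config.dia_mean, config.dia_sd, Signal.DIA_BP),
            Signal.SPO2: _baseline(rng, config.spo2_mean, config.spo2_sd, Signal.SPO2),
        }
        # background abnormality, independently per signal family
        for family in ("pulse", "bp", "spo2"):
            if rng.random() < config.background_abnormal_rate:
                label = _NOISE_FAMILIES[family][rng.integers(len(_NOISE_FAMILIES[family]))]
                for signal, (lo, hi) in _STATE_BANDS[label].items():
                    values[signal] = _band_value(rng, lo, hi)
        # planted consequents override everything at their target tick
        for label in sorted(pending.pop(tick, ())):
            for signal, (lo, hi) in _STATE_BANDS[label].items():
                values[signal] = _band_value(rng, lo, hi)

        states = {s.value for s in classify_states(values)}
        for rule in config.planted_rules:
            if rule.trigger <= states and rng.random() < rule.probability:
                target = tick + rule.lag
                if target <= config.n_ticks:
                    pending.setdefault(target, set()).update(rule.consequent)

        t0 = (tick - 1) * config.tick_width
        for signal in (Signal.SYS_BP, Signal.DIA_BP, Signal.SPO2, Signal.HR):
            samples.append(
                VitalSample(config.subject_id, t0, signal, round(values[signal], 3))
            )
    return samples


def fig4_fixture() -> ComplexEventSequence:
    """The five-tick abstract worked-example sequence over {A, B, C}.

    Ticks 1..5 carry {A,B,C}, {B,C}, {A,B,C}, {B}, {A}; mining the first
    four ticks at minimum support count 2 and window width 4 reproduces the
    reference support table (A:2, B:4, C:3, A→B:2, B→B:3, B→C:2, C→B:3,
    C→C:2, B→B→B:2), and sliding the window to tick 5 exercises events
    deletion, events addition and the temporal join.
    """
    sets = [
        SimultaneousEventSet(1, frozenset("ABC")),
        SimultaneousEventSet(2, frozenset("BC")),
        SimultaneousEventSet(3, frozenset("ABC")),
        SimultaneousEventSet(4, frozenset("B")),
        SimultaneousEventSet(5, frozenset("A")),
    ]
    return ComplexEventSequence(sets, tick_width=1.0)
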