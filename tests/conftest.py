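from __future__ import annotations

import numpy as np
import pytest

from vspredict.core_events import ComplexEventSequence, SimultaneousEventSet
from vspredict.episode_mining import MiningParams
from vspredict.synthetic_data import fig4_fixture


@pytest.fixture
def fig4() -> ComplexEventSequence:
    """The five-tick abstract worked-example sequence."""
    return fig4_fixture()


@pytest.fixture
def fig4_window1(fig4) -> ComplexEventSequence:
    """Its first sliding window (ticks 1-4)."""
    return fig4.restrict(1, 4)


@pytest.fixture
def example_params() -> MiningParams:
    """Worked-example thresholds: minimum support count 2, time interval 4."""
    return MiningParams(min_support_count=2, window_width=4)


def random_sequence(
    rng: np.random.Generator,
    alphabet_size: int = 5,
    max_ticks: int = 25,
    max_events_per_tick: int = 3,
) -> ComplexEventSequence:
    """A random complex event sequence over letters A.. with sparse ticks."""
    alphabet = [chr(ord("A") + i) for i in range(alphabet_size)]
    n_ticks = int(rng.integers(1, max_ticks + 1))
    sets = []
    for tick in range(1, n_ticks + 1):
        k = int(rng.integers(0, max_events_per_tick + 1))
        if k == 0:
            continue
        events = frozenset(rng.choice(alphabet, size=k, replace=False).tolist())
        sets.append(SimultaneousEventSet(tick, events))
    return ComplexEventSequence(sets, tick_width=1.0)
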