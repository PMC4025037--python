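"""Exhaustive reference implementations used only by the test suite.

These deliberately favor transparency over speed: occurrences are found by
full recursive enumeration and minimality is checked by pairwise interval
containment, so they are independent of the greedy/per-end logic and the
occurrence-list joins inside the package.
"""

from __future__ import annotations

from itertools import product

from vspredict.core_events import ComplexEventSequence
from vspredict.episode_mining import Episode, minimal_occurrences


def enumerate_occurrences(
    steps: tuple[frozenset[str], ...], contents: dict[int, frozenset[str]]
) -> list[tuple[int, ...]]:
    """All tick tuples (t1 < t2 < ... < tk) realizing the serial episode."""
    ticks = sorted(contents)

    def rec(step_idx: int, min_tick_idx: int) -> list[tuple[int, ...]]:
        if step_idx == len(steps):
            return [()]
        out = []
        for i in range(min_tick_idx, len(ticks)):
            if steps[step_idx] <= contents[ticks[i]]:
                for rest in rec(step_idx + 1, i + 1):
                    out.append((ticks[i],) + rest)
        return out

    return rec(0, 0)


def exhaustive_minimal_occurrences(
    episode: Episode,
    seq: ComplexEventSequence,
    window_width: int | None = None,
) -> list[tuple[int, int]]:
    """Minimal occurrences by full enumeration + pairwise containment."""
    contents = seq.as_dict()
    intervals = sorted({(o[0], o[-1]) for o in enumerate_occurrences(episode.steps, contents)})
    minimal = [
        (s, e)
        for s, e in intervals
        if not any(
            (s2, e2) != (s, e) and s <= s2 and e2 <= e for s2, e2 in intervals
        )
    ]
    if window_width is not None:
        minimal = [(s, e) for s, e in minimal if e - s < window_width]
    return minimal


def exhaustive_frequent_episodes(
    seq: ComplexEventSequence,
    min_support: int,
    window_width: int,
    max_length: int,
) -> dict[Episode, int]:
    """Every frequent singleton-step episode by flat alphabet enumeration.

    No pruning at all: every episode over the observed alphabet up to
    ``max_length`` steps is scored with the exhaustive counter.  Only
    usable on tiny instances.
    """
    alphabet = sorted({ev for ses in seq for ev in ses.events})
    out: dict[Episode, int] = {}
    for length in range(1, max_length + 1):
        for labels in product(alphabet, repeat=length):
            ep = Episode.of(*labels)
            support = len(exhaustive_minimal_occurrences(ep, seq, window_width))
            if support >= min_support:
                out[ep] = support
    return out


def oracle_frequent_episodes(
    seq: ComplexEventSequence,
    min_support: int,
    window_width: int,
    max_length: int,
) -> dict[Episode, int]:
    """Frequent singleton-step episodes scored by the package's per-end
    occurrence counter (itself validated against the exhaustive counter),
    grown breadth-first with extend-only-if-occurring pruning.

    Fast enough for the large randomized equivalence sweeps.
    """
    alphabet = sorted({ev for ses in seq for ev in ses.events})
    out: dict[Episode, int] = {}
    frontier = [Episode.of(a) for a in alphabet]
    while frontier:
        next_frontier = []
        for ep in frontier:
            support = len(minimal_occurrences(ep, seq, window_width))
            if support >= min_support:
                out[ep] = support
            # an episode that never occurs cannot occur extended; frequent
            # extension of an infrequent episode is ruled out by the
            # anti-monotonicity the exhaustive cross-checks validate
            if support >= min_support and len(ep) < max_length:
                next_frontier.extend(ep.append(frozenset((a,))) for a in alphabet)
        frontier = next_frontier
    return out
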