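"""Frequent serial-episode mining by minimal occurrences.

An *episode* here is a serial sequence of simultaneous event sets: it occurs
in an interval ``[s, e]`` of the complex event sequence when its steps match
(as subsets) a strictly increasing run of ticks, the first at ``s`` and the
last at ``e``.  An occurrence is *minimal* when no proper sub-interval of
``[s, e]`` contains another occurrence of the same episode.  The support of
an episode is its number of minimal occurrences whose span fits inside the
sliding time interval (``end - start < window_width``).

Mining is candidate-free pattern growth: candidate steps and their time
points are read off a prefix tree built in a single scan of the sequence
(each tick's event set, sorted lexicographically, is inserted as a root
path whose terminal node registers the tick; a header table links every
tick to its leaf).  An episode is then extended one step at a time by
joining its minimal-occurrence list with the step's time points and
re-minimizing.

Growth prunes on ``support < min_support_count``.  For contiguous (append)
extension this is sound: two distinct minimal occurrences of an extended
episode contain distinct minimal occurrences of its prefix, each of smaller
span, so minimal-occurrence support is anti-monotone along prefix growth
(see docs/methods.md for the argument; the test suite additionally checks
the miner's output against an exhaustive enumerator on random sequences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .core_events import ComplexEventSequence

__all__ = [
    "Episode",
    "EpisodeStats",
    "MiningParams",
    "PrefixTreeNode",
    "PrefixTree",
    "build_prefix_tree",
    "minimal_occurrences",
    "mine_frequent_episodes",
    "write_episodes_json",
    "read_episodes_json",
]

#: a minimal occurrence, (start_tick, end_tick)
Occurrence = tuple[int, int]


@dataclass(frozen=True)
class Episode:
    """A serial episode: an ordered tuple of simultaneous event sets."""

    steps: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("an episode has at least one step")
        steps = tuple(frozenset(s) for s in self.steps)
        if any(not s for s in steps):
            raise ValueError("episode steps must be non-empty event sets")
        object.__setattr__(self, "steps", steps)

    @classmethod
    def of(cls, *steps: str | Iterable[str]) -> "Episode":
        """Build an episode from labels; a bare string is a singleton step.

        ``Episode.of("C", "B", "A")`` is the three-step serial episode
        C→B→A; ``Episode.of(("Pulse_H", "BP_HB"))`` is one simultaneous
        two-event step.
        """
        return cls(
            tuple(
                frozenset((s,)) if isinstance(s, str) else frozenset(s)
                for s in steps
            )
        )

    @property
    def key(self) -> tuple[tuple[str, ...], ...]:
        """Canonical form: within-step lexicographic order."""
        return tuple(tuple(sorted(s)) for s in self.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def __lt__(self, other: "Episode") -> bool:
        return self.key < other.key

    def append(self, step: frozenset[str]) -> "Episode":
        return Episode(self.steps + (frozenset(step),))

    def prefix(self, n: int) -> "Episode":
        return Episode(self.steps[:n])

    def suffix(self, n: int) -> "Episode":
        return Episode(self.steps[-n:])

    def __str__(self) -> str:
        return "->".join("(" + " ".join(sorted(s)) + ")" for s in self.steps)

    __repr__ = __str__


@dataclass
class EpisodeStats:
    """An episode with its minimal-occurrence list (sorted by start)."""

    episode: Episode
    occurrences: list[Occurrence] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.occurrences)

    def copy(self) -> "EpisodeStats":
        return EpisodeStats(self.episode, list(self.occurrences))


@dataclass(frozen=True)
class MiningParams:
    """Thresholds governing one mining run.

    min_support_count
        minimum number of minimal occurrences for an episode to be frequent.
    window_width
        the sliding time interval, in ticks; occurrences must satisfy
        ``end - start < window_width``.
    max_episode_length
        hard cap on the number of steps grown (guards pathological growth;
        dependencies of clinical interest here are short).
    step_mode
        ``"singleton"`` grows steps that are single events (the default);
        ``"subset"`` additionally grows every non-empty subset of a tick's
        simultaneous set as one step, producing combined states such as
        (Pulse_H BP_HB) as rule antecedents.
    """

    min_support_count: int = 2
    window_width: int = 4
    max_episode_length: int = 5
    step_mode: str = "singleton"

    def __post_init__(self) -> None:
        if self.min_support_count < 1:
            raise ValueError("min_support_count must be >= 1")
        if self.window_width < 1:
            raise ValueError("window_width must be >= 1")
        if self.max_episode_length < 1:
            raise ValueError("max_episode_length must be >= 1")
        if self.step_mode not in ("singleton", "subset"):
            raise ValueError(f"unknown step_mode {self.step_mode!r}")


# ---------------------------------------------------------------------------
# prefix tree


@dataclass
class PrefixTreeNode:
    label: str | None  # None for the root
    children: dict[str, "PrefixTreeNode"] = field(default_factory=dict)
    leaf_ticks: set[int] = field(default_factory=set)

    def walk(self) -> Iterator["PrefixTreeNode"]:
        yield self
        for label in sorted(self.children):
            yield from self.children[label].walk()


@dataclass
class PrefixTree:
    """Prefix tree over lexicographically sorted simultaneous event sets.

    The path from the root to an internal node spells a simultaneous-event
    prefix; the terminal node of each inserted tick registers that tick in
    its leaf set, and the header table links every tick to its leaf node.
    """

    root: PrefixTreeNode
    header: dict[int, PrefixTreeNode]

    def paths(self) -> Iterator[tuple[tuple[str, ...], set[int]]]:
        """Yield (sorted event set, ticks) for every registered leaf."""

        def rec(node: PrefixTreeNode, prefix: tuple[str, ...]):
            if node.leaf_ticks:
                yield prefix, node.leaf_ticks
            for label in sorted(node.children):
                yield from rec(node.children[label], prefix + (label,))

        yield from rec(self.root, ())

    def event_ticks(self) -> dict[str, list[int]]:
        """Per-event sorted tick lists, collected from the tree paths."""
        out: dict[str, set[int]] = {}
        for labels, ticks in self.paths():
            for label in labels:
                out.setdefault(label, set()).update(ticks)
        return {label: sorted(t) for label, t in out.items()}

    def subset_ticks(self, max_step_size: int | None = None) -> dict[frozenset[str], list[int]]:
        """Per-subset sorted tick lists over all registered tick sets."""
        out: dict[frozenset[str], set[int]] = {}
        for labels, ticks in self.paths():
            limit = len(labels) if max_step_size is None else min(max_step_size, len(labels))
            for r in range(1, limit + 1):
                for combo in combinations(labels, r):
                    out.setdefault(frozenset(combo), set()).update(ticks)
        return {s: sorted(t) for s, t in out.items()}


def build_prefix_tree(seq: ComplexEventSequence) -> PrefixTree:
    """Construct the prefix tree and header table in one scan of ``seq``.

    Events within each tick are inserted in lexicographic order; shared
    prefixes are merged and only the terminal node of a tick's full set
    records the occurrence.
    """
    root = PrefixTreeNode(label=None)
    header: dict[int, PrefixTreeNode] = {}
    for ses in seq:
        if not ses.events:
            continue
        node = root
        for label in ses.sorted_events:
            node = node.children.setdefault(label, PrefixTreeNode(label))
        node.leaf_ticks.add(ses.tick)
        header[ses.tick] = node
    return PrefixTree(root=root, header=header)


# ---------------------------------------------------------------------------
# minimal occurrences


def latest_occurrence_end(
    episode: Episode, contents: Mapping[int, frozenset[str]], ticks: list[int], end_index: int
) -> int | None:
    """Latest possible start of an occurrence whose last step sits at
    ``ticks[end_index]``; None when no occurrence ends there.

    Greedy backward matching: each earlier step takes the latest feasible
    tick (an exchange argument shows this maximizes the start).
    """
    steps = episode.steps
    if not steps[-1] <= contents[ticks[end_index]]:
        return None
    idx = end_index
    for step in reversed(steps[:-1]):
        idx -= 1
        while idx >= 0 and not step <= contents[ticks[idx]]:
            idx -= 1
        if idx < 0:
            return None
    return ticks[idx]


def _minimize(candidates: list[Occurrence]) -> list[Occurrence]:
    """Keep candidates not strictly containing another candidate.

    Input must be sorted by end with at most one candidate per end (the
    latest-start one); an interval survives iff its start exceeds every
    earlier start.
    """
    out: list[Occurrence] = []
    best_start: int | None = None
    for s, e in candidates:
        if best_start is None or s > best_start:
            out.append((s, e))
            best_start = s
    return out


def minimal_occurrences(
    episode: Episode,
    seq: ComplexEventSequence,
    window_width: int | None = None,
) -> list[Occurrence]:
    """All minimal occurrences of ``episode`` in ``seq``, in start order.

    When ``window_width`` is given, occurrences with span
    ``end - start >= window_width`` are dropped (after minimization, so the
    result is the width-filtered minimal-occurrence list).  This routine is
    direct per-end greedy matching, independent of the tree miner, and
    doubles as its oracle.
    """
    contents = seq.as_dict()
    ticks = sorted(contents)
    candidates: list[Occurrence] = []
    for i in range(len(ticks)):
        start = latest_occurrence_end(episode, contents, ticks, i)
        if start is not None:
            candidates.append((start, ticks[i]))
    occs = _minimize(candidates)
    if window_width is not None:
        occs = [(s, e) for s, e in occs if e - s < window_width]
    return occs


def join_occurrences(
    prefix_occs: list[Occurrence],
    step_ticks: list[int],
    window_width: int | None,
) -> list[Occurrence]:
    """Minimal occurrences of ``prefix . step`` from the prefix's minimal
    occurrences and the step's time points (both sorted ascending)."""
    candidates: list[Occurrence] = []
    j = 0
    n = len(prefix_occs)
    for t in step_ticks:
        while j < n and prefix_occs[j][1] < t:
            j += 1
        # prefix_occs[j-1] is the latest prefix occurrence ending before t
        if j == 0:
            continue
        s = prefix_occs[j - 1][0]
        if window_width is None or t - s < window_width:
            candidates.append((s, t))
    return _minimize(candidates)


# ---------------------------------------------------------------------------
# the miner


def mine_frequent_episodes(
    seq: ComplexEventSequence,
    params: MiningParams,
) -> dict[Episode, EpisodeStats]:
    """All episodes with support >= ``params.min_support_count``.

    Tree-guided pattern growth: the prefix tree of the first scan supplies
    the candidate steps and their tick lists; episodes are grown
    depth-first, each extension's minimal-occurrence list obtained by
    joining the parent's list with the step's ticks.
    """
    if len(seq) == 0:
        return {}
    tree = build_prefix_tree(seq)
    if params.step_mode == "singleton":
        steps = {frozenset((ev,)): ticks for ev, ticks in tree.event_ticks().items()}
    else:
        steps = tree.subset_ticks()
    step_items = sorted(steps.items(), key=lambda kv: tuple(sorted(kv[0])))

    result: dict[Episode, EpisodeStats] = {}

    def grow(stats: EpisodeStats) -> None:
        result[stats.episode] = stats
        if len(stats.episode) >= params.max_episode_length:
            return
        for step, ticks in step_items:
            occs = join_occurrences(stats.occurrences, ticks, params.window_width)
            if len(occs) >= params.min_support_count:
                grow(EpisodeStats(stats.episode.append(step), occs))

    for step, ticks in step_items:
        occs = [(t, t) for t in ticks]
        if len(occs) >= params.min_support_count:
            grow(EpisodeStats(Episode((step,)), occs))
    return result


# ---------------------------------------------------------------------------
# file format


def write_episodes_json(stats: Mapping[Episode, EpisodeStats], path: str | Path) -> None:
    """Write episode stats as a JSON list, canonically ordered."""
    records = [
        {
            "episode": [list(step) for step in ep.key],
            "support": st.support,
            "occurrences": [list(o) for o in st.occurrences],
        }
        for ep, st in sorted(stats.items(), key=lambda kv: kv[0].key)
    ]
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


def read_episodes_json(path: str | Path) -> dict[Episode, EpisodeStats]:
    records = json.loads(Path(path).read_text())
    out: dict[Episode, EpisodeStats] = {}
    for r in records:
        ep = Episode(tuple(frozenset(step) for step in r["episode"]))
        out[ep] = EpisodeStats(ep, [tuple(o) for o in r["occurrences"]])
    return out
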