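"""Incremental maintenance of frequent episodes under a sliding window.

Only the most recent ``width`` ticks are live: tick ``t`` belongs to the
window ending at ``T`` iff ``T - t < width``.  When the window slides, the
oldest tick's events expire (*events deletion*) and the new tick's events
arrive (*events addition*); the tracked episode table is patched in place
rather than re-mined:

* deletion drops every minimal occurrence that starts at the expired tick
  (the expired tick is the window minimum, so an occurrence uses it iff it
  starts there); episodes falling below the support threshold move to the
  tracked-infrequent table, and episodes left with no occurrence are
  dropped;
* addition can create at most one new minimal occurrence per tracked
  episode — one ending at the new tick — found by greedy backward matching
  and appended when its start exceeds the last recorded start;
* a *temporal join* then extends every currently frequent episode that has
  an occurrence ending before the new tick with every currently frequent
  step of the new event set, creating episodes that end in the new event.
  Newly created episodes receive a full minimal-occurrence recomputation on
  the window contents and are retained as tracked candidates even below
  the threshold, until their occurrences expire.

The join deliberately fires for *every* frequent (episode, new-step) pair,
not only when the new event has just turned frequent: together with the
full recomputation at creation this makes the maintained frequent table
provably identical to batch re-mining of the window contents after every
slide (anti-monotonicity guarantees the prefix of any newly frequent
episode is itself frequent, hence already tracked — see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_events import ComplexEventSequence, SimultaneousEventSet
from .episode_mining import (
    Episode,
    EpisodeStats,
    MiningParams,
    latest_occurrence_end,
    mine_frequent_episodes,
    minimal_occurrences,
)

__all__ = ["SlidingWindow", "UpdateResult"]


@dataclass
class UpdateResult:
    """Outcome of one maintenance step.

    ``frequent`` and ``tracked_infrequent`` partition the tracked episodes
    by the support threshold; ``newly_generated`` lists episodes created by
    the temporal join during this step (with their full supports).
    """

    frequent: dict[Episode, int] = field(default_factory=dict)
    tracked_infrequent: dict[Episode, int] = field(default_factory=dict)
    newly_generated: dict[Episode, int] = field(default_factory=dict)


class SlidingWindow:
    """Live mining state over the most recent ``width`` ticks of a stream."""

    def __init__(self, params: MiningParams, tick_width: float = 60.0) -> None:
        self.params = params
        self.tick_width = tick_width
        self.contents: dict[int, frozenset[str]] = {}
        self.stats: dict[Episode, EpisodeStats] = {}

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_batch(
        cls, seq: ComplexEventSequence, params: MiningParams
    ) -> "SlidingWindow":
        """Seed a window from a batch mining run of ``seq``.

        ``seq`` must already fit inside the window width.
        """
        ticks = seq.ticks
        if ticks and ticks[-1] - ticks[0] >= params.window_width:
            raise ValueError("sequence span exceeds the window width")
        win = cls(params, tick_width=seq.tick_width)
        win.contents = dict(seq.as_dict())
        win.stats = mine_frequent_episodes(seq, params)
        return win

    # -- views --------------------------------------------------------------

    @property
    def oldest_tick(self) -> int | None:
        return min(self.contents) if self.contents else None

    @property
    def newest_tick(self) -> int | None:
        return max(self.contents) if self.contents else None

    def window_sequence(self) -> ComplexEventSequence:
        return ComplexEventSequence(
            [SimultaneousEventSet(t, self.contents[t]) for t in sorted(self.contents)],
            tick_width=self.tick_width,
        )

    def frequent_table(self) -> dict[Episode, int]:
        k = self.params.min_support_count
        return {ep: st.support for ep, st in self.stats.items() if st.support >= k}

    def infrequent_table(self) -> dict[Episode, int]:
        k = self.params.min_support_count
        return {ep: st.support for ep, st in self.stats.items() if 0 < st.support < k}

    def _result(self, newly: dict[Episode, int] | None = None) -> UpdateResult:
        return UpdateResult(
            frequent=self.frequent_table(),
            tracked_infrequent=self.infrequent_table(),
            newly_generated=dict(newly or {}),
        )

    # -- maintenance steps ---------------------------------------------------

    def _candidate_steps(self, events: frozenset[str]) -> list[frozenset[str]]:
        if self.params.step_mode == "singleton":
            return [frozenset((e,)) for e in sorted(events)]
        from itertools import combinations

        out = []
        for r in range(1, len(events) + 1):
            out.extend(frozenset(c) for c in combinations(sorted(events), r))
        return out

    def delete_oldest_events(self, expired_tick: int) -> UpdateResult:
        """Expire the window's oldest tick and patch every tracked episode.

        Minimal occurrences never gain members when events are removed from
        before the remaining window, so dropping the occurrences that start
        at the expired tick leaves every surviving list oracle-exact.
        """
        if self.oldest_tick is None or expired_tick != self.oldest_tick:
            raise ValueError(
                f"expired_tick {expired_tick} is not the oldest window tick "
                f"({self.oldest_tick})"
            )
        del self.contents[expired_tick]
        for ep in list(self.stats):
            st = self.stats[ep]
            st.occurrences = [o for o in st.occurrences if o[0] != expired_tick]
            if not st.occurrences:
                del self.stats[ep]
        return self._result()

    def add_new_events(self, new_set: SimultaneousEventSet) -> UpdateResult:
        """Ingest a new simultaneous event set at a strictly newer tick."""
        tick = new_set.tick
        newest = self.newest_tick
        if newest is not None and tick <= newest:
            raise ValueError(f"new tick {tick} not beyond window end {newest}")
        if newest is not None and tick - (self.oldest_tick or tick) >= self.params.window_width:
            raise ValueError("window overflow: expire old ticks before adding (use slide)")
        if not new_set.events:
            return self._result()
        self.contents[tick] = frozenset(new_set.events)
        width = self.params.window_width
        ticks_sorted = sorted(self.contents)
        end_index = len(ticks_sorted) - 1

        # 1. the new event sets themselves (single-step episodes)
        for step in self._candidate_steps(new_set.events):
            ep = Episode((step,))
            st = self.stats.setdefault(ep, EpisodeStats(ep))
            st.occurrences.append((tick, tick))

        # 2. tracked multi-step episodes whose suffix is the current event:
        #    the only possible new minimal occurrence ends at the new tick
        for ep, st in self.stats.items():
            if len(ep) < 2 or not ep.steps[-1] <= new_set.events:
                continue
            start = latest_occurrence_end(ep, self.contents, ticks_sorted, end_index)
            if start is None or tick - start >= width:
                continue
            if not st.occurrences or start > st.occurrences[-1][0]:
                st.occurrences.append((start, tick))

        # 3. temporal join: frequent episodes x frequent steps of the new set
        newly: dict[Episode, int] = {}
        k = self.params.min_support_count
        window_seq = self.window_sequence()
        join_steps = [
            step
            for step in self._candidate_steps(new_set.events)
            if self.stats[Episode((step,))].support >= k
        ]
        if join_steps:
            for length in range(1, self.params.max_episode_length):
                frequent_at_len = [
                    (ep, st)
                    for ep, st in sorted(self.stats.items(), key=lambda kv: kv[0].key)
                    if len(ep) == length and st.support >= k
                ]
                for ep, st in frequent_at_len:
                    # needs an occurrence ending before the new tick, close
                    # enough for the joined span to fit the window
                    if not any(e < tick and tick - s < width for s, e in st.occurrences):
                        continue
                    for step in join_steps:
                        joined = ep.append(step)
                        if joined in self.stats:
                            continue
                        occs = minimal_occurrences(joined, window_seq, width)
                        if occs:
                            self.stats[joined] = EpisodeStats(joined, occs)
                            newly[joined] = len(occs)
        return self._result(newly)

    def slide(self, new_set: SimultaneousEventSet) -> UpdateResult:
        """Advance the window to end at ``new_set.tick``: expire, then add."""
        width = self.params.window_width
        tick = new_set.tick
        newest = self.newest_tick
        if newest is not None and tick <= newest:
            raise ValueError(f"new tick {tick} not beyond window end {newest}")
        while self.contents and tick - min(self.contents) >= width:
            self.delete_oldest_events(min(self.contents))
        return self.add_new_events(new_set)
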