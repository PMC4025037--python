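"""Episode rules, state prediction, guideline mapping and scoring.

A frequent serial episode of length >= 2 yields one rule per non-trivial
split into a prefix (antecedent) and suffix (consequent):

    X -> Y,   confidence = support(X.Y) / support(X)

with supports counted as minimal occurrences.  Rules are kept when the
concatenated episode meets the support threshold and the confidence meets
the confidence threshold, and are ordered by confidence (descending), then
support (descending), then canonical episode key — a total order, so the
rule base is deterministic across runs.

Prediction matches the live event buffer against the ordered rules: a rule
fires when its antecedent has an occurrence inside the buffer whose last
step sits at the latest buffered tick (anchored-suffix matching), and the
first firing rule's consequent is asserted as the upcoming state (horizon
one tick per consequent step).  Predicted states are then looked up in a
guideline map; when no guideline matches, the bare state is reported.

Scoring follows the multi-category precision/recall/F-measure convention:
every distinct state set is one category, each position is scored
one-vs-rest, and precision/recall are macro-averaged over the M observed
categories (micro-averaging is available for sensitivity analysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .core_events import ComplexEventSequence
from .episode_mining import Episode, EpisodeStats, latest_occurrence_end

__all__ = [
    "EpisodeRule",
    "RuleBase",
    "GuidelineMap",
    "Prediction",
    "Recommendation",
    "EvalReport",
    "generate_rules",
    "match_predict",
    "recommend",
    "evaluate",
]


@dataclass(frozen=True)
class EpisodeRule:
    """An implication antecedent -> consequent with support and confidence."""

    antecedent: Episode
    consequent: Episode
    support: int
    confidence: float

    @property
    def full_episode(self) -> Episode:
        return Episode(self.antecedent.steps + self.consequent.steps)

    def __str__(self) -> str:
        return (
            f"{self.antecedent} => {self.consequent} "
            f"[sup={self.support}, conf={self.confidence:.3f}]"
        )


@dataclass
class RuleBase:
    """Episode rules in match-priority order plus the generating thresholds."""

    rules: list[EpisodeRule]
    min_support: int
    min_confidence: float

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "min_support": self.min_support,
            "min_confidence": self.min_confidence,
            "rules": [
                {
                    "antecedent": [list(s) for s in r.antecedent.key],
                    "consequent": [list(s) for s in r.consequent.key],
                    "support": r.support,
                    "confidence": r.confidence,
                }
                for r in self.rules
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleBase":
        raw = json.loads(Path(path).read_text())
        rules = [
            EpisodeRule(
                antecedent=Episode(tuple(frozenset(s) for s in r["antecedent"])),
                consequent=Episode(tuple(frozenset(s) for s in r["consequent"])),
                support=int(r["support"]),
                confidence=float(r["confidence"]),
            )
            for r in raw["rules"]
        ]
        return cls(rules, int(raw["min_support"]), float(raw["min_confidence"]))


def generate_rules(
    stats: Mapping[Episode, EpisodeStats],
    min_support: int,
    min_confidence: float,
) -> RuleBase:
    """Derive the ordered rule base from one mining run's episode stats.

    Every split of every qualifying episode into a non-empty prefix and
    suffix is considered; the antecedent's support is read from ``stats``
    (anti-monotonicity guarantees a frequent episode's prefix is present
    in any consistent mining result).
    """
    if not 0 <= min_confidence <= 1:
        raise ValueError(f"min_confidence must lie in [0, 1], got {min_confidence}")
    rules: list[EpisodeRule] = []
    for ep, st in stats.items():
        if len(ep) < 2 or st.support < min_support:
            continue
        for i in range(1, len(ep)):
            antecedent = ep.prefix(i)
            ant_stats = stats.get(antecedent)
            if ant_stats is None or ant_stats.support == 0:
                raise ValueError(
                    f"antecedent {antecedent} of {ep} missing from stats; "
                    "rules must be generated from a consistent mining run"
                )
            confidence = st.support / ant_stats.support
            if confidence >= min_confidence:
                rules.append(
                    EpisodeRule(antecedent, ep.suffix(len(ep) - i), st.support, confidence)
                )
    rules.sort(key=lambda r: (-r.confidence, -r.support, r.antecedent.key, r.consequent.key))
    return RuleBase(rules, min_support, min_confidence)


# ---------------------------------------------------------------------------
# prediction


@dataclass(frozen=True)
class Prediction:
    """Predicted upcoming state set; empty when no rule matched."""

    predicted_states: frozenset[str]
    matched_rule: EpisodeRule | None
    horizon: int = 1

    def __post_init__(self) -> None:
        if bool(self.predicted_states) != (self.matched_rule is not None):
            raise ValueError("predicted_states must be non-empty iff a rule matched")

    @property
    def is_empty(self) -> bool:
        return self.matched_rule is None


EMPTY_PREDICTION = Prediction(frozenset(), None)


def match_predict(
    rules: RuleBase,
    buffer: ComplexEventSequence,
    window_width: int,
) -> Prediction:
    """Match the rule base against the most recent event buffer.

    Rules are scanned in priority order; a rule matches when its antecedent
    occurs inside the buffer with its last step at the latest buffered tick
    and a span below ``window_width``.  The first match wins.  The
    prediction carries the first consequent step (asserted for the next
    tick); further consequent steps, if any, extend to consecutive ticks
    via the matched rule.
    """
    contents = buffer.as_dict()
    if not contents:
        return EMPTY_PREDICTION
    ticks = sorted(contents)
    last_index = len(ticks) - 1
    for rule in rules:
        start = latest_occurrence_end(rule.antecedent, contents, ticks, last_index)
        if start is not None and ticks[-1] - start < window_width:
            return Prediction(
                predicted_states=rule.consequent.steps[0],
                matched_rule=rule,
                horizon=1,
            )
    return EMPTY_PREDICTION


# ---------------------------------------------------------------------------
# guideline recommendation


@dataclass
class GuidelineMap:
    """Care-guideline lookup keyed by state patterns (sets of state labels)."""

    entries: dict[frozenset[str], tuple[str, str]] = field(default_factory=dict)
    # pattern -> (guideline id, guideline text)

    def add(self, pattern: Iterable[str], text: str, guideline_id: str | None = None) -> None:
        key = frozenset(pattern)
        if key in self.entries:
            raise ValueError(f"duplicate guideline pattern {sorted(key)}")
        self.entries[key] = (guideline_id or "+".join(sorted(key)), text)

    @classmethod
    def load(cls, path: str | Path) -> "GuidelineMap":
        """Read a guideline file: JSON ``{"A+B": "text"}`` or two-column TSV.

        Multi-label patterns join labels with ``+`` (or whitespace).
        """
        path = Path(path)
        gm = cls()
        text = path.read_text()
        if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
            for pattern, guideline in json.loads(text).items():
                gm.add(pattern.replace("+", " ").split(), str(guideline))
            return gm
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pattern, _, guideline = line.partition("\t")
            if not guideline:
                raise ValueError(f"malformed guideline line: {line!r}")
            gm.add(pattern.replace("+", " ").split(), guideline.strip())
        return gm


@dataclass(frozen=True)
class Recommendation:
    """Guidelines (or the bare state) attached to a prediction."""

    states: frozenset[str]
    guidelines: tuple[tuple[str, str], ...]  # (guideline id, text)
    state_only: bool


def recommend(
    prediction: Prediction, guidelines: GuidelineMap
) -> Recommendation | None:
    """Map a prediction to care guidelines.

    Exact pattern match first; otherwise each predicted label is looked up
    individually; with no match at all the states are reported alone,
    flagged state-only.  An empty prediction yields no recommendation.
    """
    if prediction.is_empty:
        return None
    states = prediction.predicted_states
    hit = guidelines.entries.get(states)
    if hit is not None:
        return Recommendation(states, (hit,), state_only=False)
    per_label = tuple(
        guidelines.entries[frozenset((label,))]
        for label in sorted(states)
        if frozenset((label,)) in guidelines.entries
    )
    if per_label:
        return Recommendation(states, per_label, state_only=False)
    return Recommendation(states, (), state_only=True)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Per-category confusion counts and (macro) P/R/F over M categories."""

    per_class: dict[tuple[str, ...], dict[str, int]]
    precision: float
    recall: float
    f_measure: float
    m: int
    average: str = "macro"


def _as_category(x: Iterable[str] | str) -> tuple[str, ...]:
    if isinstance(x, str):
        return (x,)
    return tuple(sorted(x))


def evaluate(
    predicted: Sequence[Iterable[str] | str],
    truth: Sequence[Iterable[str] | str],
    average: str = "macro",
) -> EvalReport:
    """Position-wise multi-category precision/recall/F-measure.

    Each element is a state-set label (a set of state labels or a bare
    string); each distinct set is one category.  Per category, position i
    is a TP when predicted and truth both equal the category, an FP when
    only the prediction does, an FN when only the truth does.  With
    ``average="macro"`` precision and recall are unweighted means over the
    M categories observed in truth or predictions and F is computed from
    the averaged P and R; ``average="micro"`` pools the counts first.
    """
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if average not in ("macro", "micro"):
        raise ValueError(f"unknown average {average!r}")
    pred_cats = [_as_category(p) for p in predicted]
    true_cats = [_as_category(t) for t in truth]
    categories = sorted(set(pred_cats) | set(true_cats))
    per_class: dict[tuple[str, ...], dict[str, int]] = {}
    for cat in categories:
        tp = sum(1 for p, t in zip(pred_cats, true_cats) if p == cat and t == cat)
        fp = sum(1 for p, t in zip(pred_cats, true_cats) if p == cat and t != cat)
        fn = sum(1 for p, t in zip(pred_cats, true_cats) if p != cat and t == cat)
        per_class[cat] = {"tp": tp, "fp": fp, "fn": fn}

    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    m = len(categories)
    if average == "macro":
        precision = sum(ratio(c["tp"], c["tp"] + c["fp"]) for c in per_class.values()) / m if m else 0.0
        recall = sum(ratio(c["tp"], c["tp"] + c["fn"]) for c in per_class.values()) / m if m else 0.0
    else:
        tp = sum(c["tp"] for c in per_class.values())
        fp = sum(c["fp"] for c in per_class.values())
        fn = sum(c["fn"] for c in per_class.values())
        precision = ratio(tp, tp + fp)
        recall = ratio(tp, tp + fn)
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(per_class, precision, recall, f, m, average)
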