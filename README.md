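# vspredict

Vital-signs state prediction by frequent serial-episode mining over sliding
windows.

`vspredict` is for health-informatics practitioners who monitor streams of
routine vital signs — systolic/diastolic blood pressure, SpO2 and heart
rate — and want short-horizon, rule-based early warnings ("tachycardia now
tends to be followed by prehypertension one interval later") together with
the care guideline attached to the predicted state. It implements the full
predictor pipeline as a library plus a thin CLI:

1. **Discretization.** Raw timestamped samples are binned to a 1-based tick
   axis and classified against standard staging thresholds into nine states
   (`BP_HB`, `BP_H1`, `BP_H2` for prehypertension / stage 1 / stage 2;
   `SpO2_Lmicro/Lmid/Lhard` for mild/moderate/severe hypoxemia; `Pulse_H`,
   `Pulse_L` for tachycardia/bradycardia; `N` for normal). Each tick
   carries a *simultaneous event set*; the whole stream is a *complex event
   sequence*.
2. **Episode mining.** A serial episode α = S₁ → S₂ → … → Sₖ (each Sᵢ a
   simultaneous state set) occurs in [s, e] when its steps match strictly
   increasing ticks, first at s, last at e. Its support is the number of
   *minimal occurrences* — intervals containing an occurrence but no proper
   sub-interval that does — with span `e − s < w` for the configured time
   interval w. Mining is candidate-free pattern growth guided by a prefix
   tree with a header table, built in one scan of the sequence.
3. **Streaming maintenance.** A sliding window keeps only the most recent w
   ticks; expiry triggers *events deletion*, arrivals trigger *events
   addition* and a *temporal join* that creates episodes ending in the new
   event. The maintained frequent table is identical to batch re-mining of
   the window after every slide (this equivalence is property-tested on
   hundreds of randomized streams).
4. **Episode rules and prediction.** Every frequent episode of length ≥ 2
   yields rules X → Y for each prefix/suffix split, with
   `conf(X → Y) = sup(X·Y) / sup(X)`. Rules are ordered by confidence, then
   support; the first rule whose antecedent occurs anchored at the latest
   buffered tick predicts the next state, which is mapped to a care
   guideline (or reported state-only).
5. **Evaluation.** Position-wise multi-category precision, recall and
   F-measure (`F = 2PR/(P+R)`), macro-averaged over the M observed state
   categories; micro-averaging is available as a sensitivity option.

A seeded synthetic-stream generator with planted temporal dependencies
makes every stage testable end to end without external data.

## Worked example

The mining and streaming machinery is usually introduced on a small
abstract sequence over the alphabet {A, B, C}, shipped as
`fig4_fixture()`: ticks 1–5 carry {A,B,C}, {B,C}, {A,B,C}, {B}, {A}.

```python
from vspredict import fig4_fixture, mine_frequent_episodes, MiningParams, Episode

seq = fig4_fixture().restrict(1, 4)          # first sliding window
stats = mine_frequent_episodes(seq, MiningParams(min_support_count=2, window_width=4))
for ep, st in sorted(stats.items(), key=lambda kv: (len(kv[0]), kv[0].key)):
    print(ep, st.support, st.occurrences)
```

prints

```
(A) 2 [(1, 1), (3, 3)]
(B) 4 [(1, 1), (2, 2), (3, 3), (4, 4)]
(C) 3 [(1, 1), (2, 2), (3, 3)]
(A)->(B) 2 [(1, 2), (3, 4)]
(B)->(B) 3 [(1, 2), (2, 3), (3, 4)]
(B)->(C) 2 [(1, 2), (2, 3)]
(C)->(B) 3 [(1, 2), (2, 3), (3, 4)]
(C)->(C) 2 [(1, 2), (2, 3)]
(B)->(B)->(B) 2 [(1, 3), (2, 4)]
(B)->(C)->(B) 2 [(1, 3), (2, 4)]
(C)->(B)->(B) 2 [(1, 3), (2, 4)]
(C)->(C)->(B) 2 [(1, 3), (2, 4)]
```

Read `(C)->(B) 3` as: the serial episode "C then B" has three minimal
occurrences ([1,2], [2,3], [3,4]) inside the four-tick window, so its
support is 3, and the rule (C) → (B) would carry confidence
sup(CB)/sup(C) = 3/3 = 1. Sliding the window to tick 5 (tick 1 expires,
{A} arrives) demotes A, A→B, B→C, C→C and B→B→B to support 1, keeps
B:3, C:2, B→B:2, C→B:2 frequent, and the temporal join creates the new
episodes ending in A (e.g. C→B→A with occurrence [3,5]); the final
frequent table equals batch re-mining of ticks 2–5.

On the clinical side, a one-minute pipeline from a synthetic stream:

```sh
vspredict simulate --seed 1 --ticks 500 --noise 0.05 \
    --config examples.yaml --out stream.csv      # planted Pulse_H => BP_HB
vspredict rules --input stream.csv --min-support 3 --window 3 \
    --min-confidence 0.5 --out rules.json
vspredict stream --input stream.csv --rules rules.json \
    --guidelines guide.json --window 3 --out predictions.jsonl
```

`rules.json` then contains `(Pulse_H) => (BP_HB)` with confidence close to
the planted firing probability 0.9, and each line of `predictions.jsonl`
records the predicted state and its guideline for one tick.

## Layout

| module | contents |
| --- | --- |
| `vspredict.core_events` | state classification, discretization, sample/sequence I/O |
| `vspredict.episode_mining` | episodes, prefix tree, minimal occurrences, the miner |
| `vspredict.stream_update` | sliding window: events deletion/addition, temporal join |
| `vspredict.rules_predictor` | rule generation, matching, guidelines, P/R/F evaluation |
| `vspredict.synthetic_data` | seeded stream generator, worked-example fixture |
| `vspredict.cli` | `vspredict simulate/discretize/mine/rules/stream/predict/evaluate` |

Design notes, parameter semantics and known limitations are documented in
`docs/methods.md`.
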