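# Methods

## Discretization model

Each vital-sign sample is mapped to a 1-based tick
`floor(timestamp / tick_width) + 1` (default tick width 60 s) and each
tick's signals are classified into at most one state per signal family:

* **Blood pressure** is staged jointly: the category is the most severe one
  whose systolic *or* diastolic criterion is met (prehypertension 120–139 /
  80–89, stage 1 140–159 / 90–99, stage 2 ≥160 / ≥100, all range bounds
  inclusive). Joint staging by max severity is the standard convention and
  makes classification total and unambiguous; a lone component is staged on
  its own criterion.
* **Oxygen** bands are printed overlapping (<94, <89, <75); they are
  resolved most-severe-first, i.e. as half-open bands [89,94), [75,89),
  [0,75).
* **Heart rate** boundaries are strict: >100 tachycardia, <60 bradycardia.

When several samples of one signal fall into one tick, the last wins —
monitoring semantics: the most recent reading is the current state. `N`
(normal) is emitted only when every present family is normal, and by
default normal events are dropped before mining (`include_normal=False`):
episodes over `N` would dominate any healthy stream and carry no warning
value. Whether normal states should participate in mining is genuinely
open; the flag exposes both behaviors.

## Episode semantics

An episode is a *serial* sequence of simultaneous event sets; a step
matches a tick when it is a subset of the tick's event set. This direction
sensitivity matters: on the worked five-tick example, B→C and C→B have
supports 2 and 3 respectively. Support is the number of **minimal
occurrences** — intervals [s,e] containing an occurrence (steps at strictly
increasing ticks, first at s, last at e) but no proper sub-interval that
does — further restricted to spans `e − s < window_width`, so that every
counted occurrence fits inside the sliding time interval. Minimal-occurrence
counting is the unique semantics consistent with the whole worked-example
support table (B:4, B→B:3, B→B→B:2, B→C:2, C→B:3, C→C:2, A→B:2 on ticks
1–4 at window 4).

With this semantics the first window of the worked example contains three
frequent episodes beyond the nine usually listed for it: B→C→B, C→B→B and
C→C→B, each with minimal occurrences [1,3] and [2,4]. These follow
mechanically from the definition (no alternative counting we examined —
consecutive-tick matching, non-overlapped counting, join-order variants —
removes them while preserving the listed counts), so the miner reports
them; the unit suite pins the complete 12-episode table.

By default steps are single events (`step_mode="singleton"`). With
`step_mode="subset"` every non-empty subset of a tick's simultaneous set is
also grown as one step, which is what produces combined-state antecedents
such as (Pulse_H BP_HB) → (BP_HB); subset mode is exponential in the
per-tick set size, which is at most three here (one state per family).

## The miner

`mine_frequent_episodes` is tree-guided, candidate-free pattern growth:

1. One scan builds a prefix tree: each tick's lexicographically sorted
   event set is inserted as a root path; only the terminal node registers
   the tick, and a header table links every tick to its leaf. Candidate
   steps and their tick lists are read off the tree paths.
2. Episodes grow depth-first, one appended step at a time. The extension's
   minimal-occurrence list is obtained by joining the parent's list with
   the step's ticks (for each step tick t, pair it with the latest parent
   occurrence ending before t, subject to the span bound) and keeping the
   intervals whose starts strictly increase.

Growth prunes on `support < min_support_count`. Minimal-occurrence support
is not anti-monotone under arbitrary sub-episode relations, but it *is*
anti-monotone under contiguous extension, which is the only relation the
grower uses: if [s₁,e₁] and [s₂,e₂] are distinct minimal occurrences of
α·e (s₁<s₂, e₁<e₂), each contains a minimal occurrence of α starting
exactly at its own start — a later inner start would yield a strictly
contained occurrence of α·e, contradicting minimality — and these are
distinct and of smaller span. Hence `sup(α·e) ≤ sup(α)` at the same span
bound, and pruning is lossless. The randomized oracle-equivalence suite
checks both soundness and completeness of the miner against (a) a flat,
unpruned exhaustive enumerator on tiny instances and (b) a direct per-end
occurrence counter on ~200 larger random sequences.

`max_episode_length` (default 5) caps growth; dependencies of clinical
interest in this setting are one to three steps long.

## Sliding-window maintenance

Tick t is live in the window ending at T iff `T − t < width`. A slide
expires old ticks one at a time (events deletion), then ingests the new
simultaneous set (events addition):

* **Deletion.** The expired tick is the window minimum, so an occurrence
  uses it iff it starts there; dropping exactly those occurrences leaves
  every surviving list occurrence-exact (removing events before the window
  can neither create a new occurrence nor make a non-minimal one minimal).
  Episodes falling below threshold are kept as tracked-infrequent;
  episodes with no occurrences left are dropped.
* **Addition.** A new occurrence must end at the new tick, so each tracked
  episode whose last step matches the arriving set gains at most one
  occurrence, found by greedy backward matching and appended iff its start
  exceeds the last recorded start (otherwise it would contain an existing
  minimal occurrence).
* **Temporal join.** Every *currently frequent* episode with an occurrence
  ending before the new tick is extended by every *currently frequent*
  step of the arriving set; newly created episodes get a full
  minimal-occurrence recomputation on the window contents and are retained
  as tracked candidates even below threshold until their occurrences
  expire.

Two deliberate strengthenings versus the minimal description of the
update procedure:

1. The join fires on every addition for every frequent (episode, step)
   pair, not only when the arriving event has just turned frequent.
   Firing only on infrequent→frequent transitions loses episodes: in the
   stream A,B,A,B at threshold 2, A→B is frequent in batch but would never
   be created, because when B turns frequent the earlier A→B occurrence is
   not revisited and later arrivals of already-frequent events would fire
   no join.
2. Newly joined episodes receive their complete occurrence list, not just
   the single occurrence ending at the new tick. In the worked example
   this means the join reports B→A and C→A with support 2 — each also
   occurs at ticks (2,3) inside the slid window — rather than counting
   only the join-produced occurrence.

With both, a short induction gives the package's central guarantee: after
any sequence of slides, every episode frequent on the window contents is
tracked with occurrence-exact support, so the maintained frequent table
equals batch re-mining — asserted after every slide of hundreds of
randomized streams in the suite. Tracked-infrequent episodes are retained
until empty rather than pruned eagerly; memory is bounded by the window
width and `max_episode_length`.

## Rules, matching, scoring

Confidence is `sup(X·Y)/sup(X)` on minimal-occurrence counts — the
standard episode-rule definition and the only one computable from the
statistics kept. All prefix/suffix splits are generated (so two-step
antecedents such as (Pulse_H),(BP_HB) are producible), ordered by
confidence desc, support desc, canonical key asc — a total order, hence
deterministic rule files. Matching is anchored-suffix: the antecedent must
occur with its last step at the latest buffered tick within the window
span; the first rule in priority order wins, and its consequent's first
step is asserted for the next tick (horizon 1; longer consequents map to
consecutive ticks via the matched rule).

Evaluation treats every distinct state set as one category (combined
states such as (Pulse_L BP_H1) are their own categories) and scores
positions one-vs-rest. Precision and recall are macro-averaged over the M
observed categories and F is computed from the averaged P and R; a
category never predicted contributes precision 0 (0/0 := 0). Micro
averaging is available behind a flag for sensitivity analysis; macro is
the default because the aggregation is defined per category over M
categories.

## Synthetic streams

The generator draws per tick: HR ~ N(80, 8) bpm, SBP ~ N(115, 8) mmHg,
DBP ~ N(72, 6) mmHg, SpO2 ~ N(97, 1.2) %, each **clipped into the healthy
band** of its signal (HR [60,100], SBP [90,119], DBP [55,79], SpO2
[94,100]). Clipping is essential to the generator's contract that
abnormality comes only from explicit mechanisms: an unclipped N(115,8)
systolic crosses 120 mmHg on ~27 % of ticks, which would both violate the
"zero noise ⇒ all normal" property and swamp planted dependencies. With
probability `background_abnormal_rate` (default 0.05) per tick and per
signal family, the family is pushed into a uniformly chosen abnormal band.
Planted rules fire with their configured probability whenever their trigger
set is a subset of the tick's classified states, writing the consequent's
signals into the corresponding bands at t+lag; planted consequents override
background noise at the target tick, so firing is deterministic in
placement. Streams are byte-identical given a seed.

What the generator does *not* emulate: physiological autocorrelation and
trends, measurement artifacts, missing samples, inter-subject variability,
or anesthesia dynamics. Passing the recovery tests therefore shows the
pipeline recovers planted first-order temporal structure under i.i.d.
background noise — not that it performs comparably on real monitoring
data.

## Problem sizes and numerical choices

The randomized verification suites use alphabets ≤ 5, sequences ≤ 25
ticks, windows ≤ 6 and episodes ≤ 4 steps (where the exhaustive reference
is feasible and failures are human-readable), with ~200 instances per
property; parameter recovery uses 50 seeded runs of 500-tick streams at
firing probability 0.9 and 5 % noise, mined at window 3 and support count
3. Ticks are integers throughout; all tie-breaks (step enumeration, rule
ordering, JSON serialization) are lexicographic on canonical episode keys,
so every artifact is reproducible byte for byte. Degenerate inputs —
empty sample lists, empty event sequences, windows of one tick — return
empty results rather than erroring; contract violations (mixed subjects,
non-monotone ticks, deleting a non-oldest tick, out-of-range thresholds)
raise `ValueError`.

## Known limitations

* Parallel (unordered) episodes, general partial orders and
  closed/maximal-episode condensation are out of scope; episodes are
  serial only.
* One sliding window serves one subject; concurrent multi-subject windows
  are the caller's composition.
* Rule matching is exact-anchored; no fuzzy or probabilistic matching.
* The incremental window keeps occurrence lists per tracked episode;
  for very wide windows with dense alphabets, memory grows with the
  number of tracked episodes times their occurrence counts.
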