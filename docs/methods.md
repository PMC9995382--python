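# Methods

## The simulation model

`interviewsim` models an investigative interview as a turn-based loop:
the interviewer asks a question; a classification pathway assigns it one
of 11 question types (or the `greeting` pseudo-label); the avatar's
answer-selection algorithm draws a response conditioned on the question
type, the avatar's age, and its mutable memory state; the dialogue
context advances. The loop assumes one question and exactly one played
answer per turn, questions arrive as text (speech-to-text is out of
scope), and that a repetition can only refer to the immediately
preceding question.

### Classification pathway

Precedence is strict and total — every utterance receives exactly one
label from exactly one source:

1. **Greeting rule**: substring match of normalized greeting patterns
   ("hello", "how old are you", …). Greetings are rapport, not
   substance: they are excluded from the outcome measures and from
   agreement statistics, and the taxonomy has no greeting member.
2. **Repetition rule**: presence-only Jaccard coefficient between the
   N-gram sets of the current and the immediately preceding question;
   flagged at similarity ≥ `jaccard_threshold` (default 0.5). The
   threshold is a tunable; `tune_jaccard_threshold` sweeps candidates
   against labeled pairs. Repetition precedes the model because a
   repeated question is its own type regardless of its surface form.
3. **Model**: XGBoost softmax over character N-gram frequencies
   (N = 1–5 by default; word units available for whitespace languages).
   Ties in the class scores break to the lowest taxonomy code.
4. **Suggestive override**: a recommended-looking model label is
   re-coded `unspecific_suggestive` when the text contains a suggestive
   keyword (substring match, so "hurt" catches "hurting") whose linked
   topic the avatar has not yet disclosed. Disclosure is tracked via the
   `incident` topic, credited when the avatar first emits a relevant
   detail. The override never touches a not-recommended model label.
5. **Topic tagging**: recommended questions are tagged with every topic
   whose trigger words occur in the text, in configuration order;
   not-recommended questions are never tagged (topical answers reward
   appropriate questioning only).

### Features

N-grams are counted over NFKC-normalized, case-folded text with
punctuation stripped; the character unit also removes whitespace.
Features feed the model as frequencies, but repetition detection uses
presence/absence only (the Jaccard coefficient's set semantics). The
Jaccard value of two empty key sets is defined as 0 — no evidence of
similarity — so two degenerate utterances are never called repetitions.
A `min_document_frequency` cutoff (default 1, i.e. keep everything) can
prune rare N-grams when building a vocabulary.

### Classifier training

The pipeline is: stratified 80/20 split → featurize the training
portion → SMOTE + Tomek-link rebalancing of the training portion only →
5-fold cross-validated selection over a small declared grid
(max_depth ∈ {3, 5}, min_child_weight ∈ {10, 100},
subsample ∈ {0.8, 0.9}, colsample_bytree ∈ {0.8, 0.9}) → refit →
held-out accuracy. The booster defaults (200 estimators, depth 3,
min_child_weight 100, subsample/colsample 0.9, L1/L2 0.05, learning
rate 0.01) are the deployed system's values; cross-validation tunes
everything except the learning rate. CV can be disabled (`cv=False`),
in which case the configured values are used as-is.

One scale effect is worth knowing: `min_child_weight` bounds the *sum
of softmax Hessians* in a leaf (≈ 0.08 per sample near uniform
probabilities over 11 classes), so a floor of 100 corresponds to over a
thousand samples per leaf. On corpora of a few hundred rows that
prevents any split; CV resolves this by selecting the smaller floor
from the grid. Tests that memorize tiny corpora set the floor to 0.

The resampler is implemented in-package on sklearn nearest neighbors:
SMOTE draws synthetic minority points x + u·(x′ − x), u ~ U(0, 1), with
x′ one of the k = 5 nearest same-class neighbors, oversampling every
class to the majority count; Tomek-link removal then deletes both
members of any cross-class mutual-nearest-neighbor pair, except that a
class is never emptied. Feature matrices stay in CSR form through
fitting and prediction — the two must share one representation, since
XGBoost treats absent sparse entries as missing values.

The model artifact is a directory of plain files: booster JSON,
newline-delimited vocabulary, featurizer config, label map, and the
training report (split sizes, CV scores, held-out accuracy).

### Avatar answer selection

Each avatar profile is (age ∈ {4, 6}, gender, abused ∈ {yes, no});
the roster holds 16 avatars, two per feature pattern, with two reserved
for the modeling intervention (a 4-year-old non-abused boy and a
6-year-old abused girl), leaving 14 interviewable.

Memory holds nine ordered relevant details; the last four are
conclusive — jointly sufficient to judge the case — for abused and
non-abused avatars alike, so case difficulty is comparable. Details are
emitted strictly in order, each at most once. Topic-keyed neutral
responses are played by lowest presentation-order number first.

Per recommended question, one categorical draw yields a relevant detail
with probability p_elicit (0.20 at age 4, 0.25 at age 6), a neutral
detail with the same probability, else a filler. The single-draw
interpretation (rather than independent relevant/neutral draws) was an
open design choice, fixed because exactly one answer is played per
turn; the exhausted-memory case falls through to neutral. Per
not-recommended question, an incorrect detail ("Yes.", logged as a
contradiction of the script) is created with probability 0.25, uniform
across the six not-recommended types and config-exposed; the deployed
system's per-type values are not public, and 0.25 is consistent with
observed first-interview means (≈ 5 incorrect details per ≈ 20
not-recommended questions). A repeated question flips a previous
non-affirmative answer to "Yes." with probability `yes_flip_probability`
(default 0.30, config-exposed); the flip is always logged as incorrect
because it contradicts the answer just given, and any question text can
flip at most once.

Scenario packs (profile, the nine details, topic response lists,
probabilities) are user-replaceable YAML; the bundled packs are
synthetic fixture text.

### Sessions and outcome measures

Scripted and test sessions bound interviews by `max_turns` (default 60,
roughly a 10-minute interview's question budget) — a deterministic
stand-in for the wall-clock limit that interactive use can honor
instead. Five measures summarize an interview over its substantive
turns: n_recommended, n_not_recommended, percent recommended, n_relevant
and n_incorrect. Repetition turns count as not-recommended. Relevant
details are counted per emission, which equals per distinct detail
because memory emits each detail once.

### Interventions

Feedback = ground-truth case outcome + up to two recommended and two
not-recommended questions sampled uniformly without replacement from
the transcript, each with a per-type comment template (praise or a
corrective rewrite suggestion; the wording is this package's own).
Modeling = ordered learning points, then four annotated text exemplars
covering good/bad × abused/non-abused, each framed by its background
scenario and outcome. Text transcripts stand in for the original video
material.

### Agreement statistics

Percent agreement is 100·(matches/n). Cohen's κ = (p_o − p_e)/(1 − p_e)
with p_e from the marginal products; the 95% CI uses the standard
large-sample standard error √(p_o(1 − p_o)/(n(1 − p_e)²)). κ is
undefined (reported as None) when both coders use a single shared
label. A collapse mode recomputes agreement on the two-way
recommended/not-recommended partition; since coarsening can only merge
matches, category-level percent agreement is never below type-level.
Published chance levels for this task (8% for 11 types, 33% for two
categories) have no stated derivation, so the package reports
marginal-based expected agreement instead of fixed chance constants.

## The synthetic corpus generator

Real training corpora of human-coded interviewer questions are not
publicly deposited, so the generator emits template-based stand-ins:
five or more templates per class seeded by published example utterances
("Tell me everything that happened from the beginning to the end", "Do
you play with dad?", …) with slot lexicons (names, persons, places,
objects) shared across classes so no class is separable by a filler
token alone. Suggestive-class templates always contain a suggestive
keyword, aligning the corpus with the rule layer's lexicon. Repetition
rows are emitted immediately after a near-duplicate of another row, as
in a live interview. The default class-count profile decays
geometrically across the 11 classes in taxonomy order (base 150, ratio
0.87, imbalance > 3×) so that rebalancing is a working part of the
pipeline — it mirrors the existence, not the values, of real class
imbalance. A `cjk_char` mode strips whitespace from the templates to
exercise the character-unit pathway used for languages written without
spaces.

What passing tests on this corpus do show: the full pipeline —
featurization, rebalancing, CV tuning, the rule layer, the simulator
contingencies — works end to end, classifies far above chance on held
out data, and is bit-reproducible under seeds. What they do not show:
accuracy on natural language. Real interviewer questions are
paraphrastic and noisy in ways five templates per class are not, so
held-out accuracies here (≈ 0.97) say nothing about field performance;
published figures on a real corpus (≈ 0.71) are not a reproduction
target for this generator.

## Problem sizes and numerical choices

The default corpus is ~900 questions; the full CV pipeline on it runs
in about three minutes on one core, and the whole test suite in under
five. Monte-Carlo rate checks use 10,000 trials, giving a 95% binomial
CI half-width of about 0.8 percentage points at p = 0.20–0.25. All
randomness flows through seeded `numpy` generators: corpus generation,
splitting, SMOTE, booster fitting, interviewer simulation, avatar
draws, and feedback sampling are each reproducible bit-for-bit given a
seed.

Degenerate inputs are defined rather than left to chance: empty or
punctuation-only utterances raise an empty-input error; an empty
transcript summarizes to zero counts with the proportion reported as
missing; correlation cells with zero variance are missing; stratified
splitting refuses classes with fewer than two members; SMOTE refuses
classes smaller than k + 1 with an error suggesting a smaller k.

## Known limitations

* Repetition detection is lexical (Jaccard on N-grams); paraphrased
  re-asks below the threshold pass undetected by design.
* The avatar has no natural-language generation: all responses come
  from scenario packs, and unmatched recommended questions receive
  generic fillers.
* The suggestive-keyword override is a lexicon lookup; it cannot see
  implicature beyond its keywords.
* Incorrect-detail probabilities are uniform across not-recommended
  types by default; the original per-type values are unknown.
* Interactive time-limited sessions are supported but untestable
  deterministically; tests use turn limits only.
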