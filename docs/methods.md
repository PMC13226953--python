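# Methods

## The problem

Fluent aphasia and formal thought disorder both disrupt meaningful speech,
but through different mechanisms: a breakdown of the machinery that maps
concepts to words versus a disorganisation of thought that surfaces in
speech. `speechmark` operationalises the quantitative markers used to
separate such groups from transcripts — syntactic complexity, local
semantic coherence, and disfluency rates — and the experimental protocol
around them (balanced grouped cross-validation, attribution, task-effect
control, zero-shot prompting). Because the clinical corpora such studies
rest on are access-restricted, the package ships a synthetic-corpus
generator that reproduces the *contrasts* those corpora exhibit; every
claim the test suite makes is therefore a claim about the pipeline's
behaviour under controlled conditions, not about clinical populations.

## Preprocessing

Cleaning operates per utterance on the participant's lines only, in a
fixed order: annotation symbols (bracketed codes, event markers, pause
marks) are stripped; filler tokens are removed against a configurable
lexicon (default `uh um er ah mhm hmm` — deliberately excluding
potentially contentful markers like "well" and "like"); tokens with a
trailing truncation marker are removed as incomplete words; finally,
immediate case-insensitive duplications of the same word form are
collapsed, a run of k identical tokens counting as k−1 repetitions.
Every removal is counted, so the identity

    cleaned + symbols + fillers + incompletes + repetitions = original

holds per utterance (property-tested), and cleaning is idempotent.
Repetition is defined as *immediate* duplication within an utterance: it
is the standard disfluency reading, it is deterministic, and it makes the
removed material exactly recoverable for the rate features. Rates restore
the removed tokens to the denominator: repetitionFreq =
1000·reps/(words + reps), and likewise for incomplete words.

Sentence boundaries: utterance boundaries always terminate a sentence
(spontaneous-speech transcripts have unreliable punctuation across
turns), with additional splits on `.!?` within an utterance. Word-
similarity pairs do not cross utterance boundaries by default
(consecutive words in different turns are not adjacent speech); this is
configurable (`cross_boundaries=True`).

## Syntactic features

Computed from Universal-Dependencies parses (produced by any external
parser; the package reads CoNLL-U). Dependency distance is
|position(dependent) − position(head)|; punctuation arcs are excluded
from all distance-based metrics because punctuation in speech transcripts
is a transcription artifact. Design points that were genuinely open:

* **NDD** uses the Lei–Jockers normalisation,
  |ln(MDD_s / √(root_position · sentence_length))| per sentence, averaged
  over sentences — the formulation the established UD-stylometrics
  tooling follows.
* **MDD** pools distances over all arcs of all sentences (configurable to
  a mean of per-sentence means).
* **Clause inventory**: CLS = 1 + number of arcs whose relation base is in
  {csubj, ccomp, xcomp, advcl, acl}; CLL = words/clauses. This is the
  standard UD clausal-dependent set.
* **MOD** counts `nmod` and `amod` bases per 1000 words ("nominal
  modifier" is ambiguous between them; both modify nominals); configurable
  to nmod-only.
* **Frequencies** (63-label dependency registry with subtypes, 17 UPOS
  tags) are reported per 1000 tokens rather than as proportions, matching
  the convention used for the repetition feature; absent labels are
  present with value 0 so feature vectors align across corpora, and
  unknown subtypes map to their base relation (logged). Since every token
  carries exactly one relation (root included), each frequency map sums
  to 1000.

The implementation is verified against a brute-force arc-enumeration
oracle on *every* rooted tree of up to 6 tokens (exhaustive enumeration
of head vectors), to 1e-12.

## Semantic features

Eight features per task instance from a pluggable `EmbeddingSource`:
mean and population variance of cosine similarity between consecutive
words (`wordAvg`, `wordVar`), and mean/variance of sentence similarity at
window sizes 1–3. The moving window is interpreted as a **lag** — window
w pairs sentence i with sentence i+w, so window 1 compares each sentence
only with its immediate successor; the all-pairs-within-window reading is
implemented as an option (`mode="all_pairs"`). Population (not sample)
variance is used: the observed pair set is the entire population of pairs
in the instance. Out-of-vocabulary words cause the affected *pair* to be
skipped and counted — never replaced by a zero vector, which would
corrupt cosines. A feature whose pair set is empty (e.g. window 3 on a
two-sentence task) is *absent*, not zero; absence propagates as NaN and
is imputed only at model time from training folds. Sentence vectors in
the table-backed source are unit-normalised means of word vectors; any
pretrained sentence-embedding model can stand behind the same contract.

## Aggregation and assembly

Classification is at participant level: task-instance features are
averaged per participant, weighted by the cleaned word count of each
instance ("length of the transcript" is interpreted as the cleaned
participant word count — the only length the pipeline defines per task).
A feature missing in some tasks aggregates over the tasks where it is
present. Contrasts whose groups span both source datasets are restricted
to open-ended tasks automatically (different picture-description prompts
are less comparable across corpora than different open-ended prompts);
within-dataset contrasts use all tasks. Remaining missing cells are
imputed with the training fold's median during cross-validation, never
dropped — dropping rows would bias the sample toward verbose
participants — and never computed from the held-out participant
(property-tested by poisoning).

## Classification protocol

Random-forest and Gaussian naive-Bayes backends run with library-default
hyperparameters; only the seed varies. Groups are balanced by uniform
undersampling to the smallest group's size. Cross-validation is
leave-one-participant-out with participant id as the grouping factor; the
fold structure is deterministic, so the 5 CV repeats differ only through
model randomness, and the 3 undersampling iterations × 5 repeats yield 15
run accuracies, reported as mean and SD. Confusion matrix and per-class
precision/recall/F1 come from the representative run — the one whose
accuracy is closest to the mean, ties broken toward the lowest run index.
Chance level is recorded as 1/#classes.

A known property of this design worth stating: with pure-noise features,
leave-one-out accuracy under label permutation sits slightly *below*
chance (≈ 2/(n−1) low), because the held-out participant's class is
underrepresented in its training fold. The null-calibration checks
therefore measure "within three binomial standard errors of one run's
accuracy" of chance, and the acceptance script reports the measured value
(≈ 0.46 at n = 50) rather than forcing 0.50.

## Feature attribution

For tree ensembles the package computes an exact additive decomposition
of the predicted class probabilities: walking each test instance's
decision path in every tree, the change in the node's class-probability
vector at each split is credited to the split feature, and the per-tree
results are averaged over the forest. The telescoping sum guarantees
local accuracy — base value + Σ attributions reproduces `predict_proba`
to floating-point error (measured < 1e-15, contract < 1e-6). Attributions
are computed per CV fold on the held-out instances and averaged as mean
absolute values to give global importances (top-10 reported). Backends
without path structure fall back to permutation importance, flagged in
the report. Reports are keyed by feature name, so column order is
irrelevant to interpretation; note that refitting a forest with reordered
columns is a different (equally valid) model, so scores are rank-stable
but not bitwise identical under column permutation.

## Task-effect statistics

Within-participant Wilcoxon signed-rank tests per group × feature, on
task-level values of participants who contributed both tasks (others
excluded and counted). W = min(W⁺, W⁻); zero differences are dropped
(Wilcoxon's exclusion method); tied absolute differences get mid-ranks.
For n ≤ 25 the two-sided p-value is exact over all 2ⁿ sign assignments,
computed by dynamic programming on integer-doubled rank sums so mid-ranks
are handled without approximation (scipy's exact mode refuses ties);
above that, a normal approximation with tie and continuity corrections.
Tests are two-sided. The Benjamini–Hochberg family is the full group ×
feature grid of one analysis call (2 × 2 = 4 tests in the default
design); the family is whatever the caller passes, and is recorded in
the output. Type-I error of the whole analysis under a null generator is
checked at ≤ 7% for nominal α = 0.05 over 2000 replicates.

## Zero-shot harness

Prompts have two parts: a system message with the classification
instructions — the *guided* variant adds short descriptions of typical
speech characteristics per group, the *unguided* variant does not — and a
user message containing the task description and the cleaned transcript.
Templates are shipped as editable data files and re-authored for this
package; the template id is logged. The backend contract is a single
stateless `generate(system, user)` call, so the model context is
necessarily reset between predictions; greedy decoding is the default.
Output parsing searches case-insensitively for exactly one label token
(aliases configurable); ambiguous or empty outputs get one retry and are
then excluded from the accuracy denominator with explicit counts —
silent coercion would bias accuracy. Accuracies are reported for
open-ended, picture, and all tasks separately, at task level. The
severity summary partitions task instances by *predicted* label and
reports quartiles and a difference of medians; it accepts any
per-participant nonnegative severity score without assuming a particular
clinical instrument.

## Synthetic corpus generator

The generator's purpose is controllability, not linguistic realism.
Surface vocabulary is pronounceable nonsense words (CV syllables,
collision-checked against the closed function-word and filler lists)
partitioned into topics and POS classes; embeddings place each content
word at a unit-normalised topic centroid plus isotropic noise, so
adjacent-word cosine similarity responds directly to the topic-drift
process (per content word, with probability `topic_jump_prob` the topic
state jumps to a different topic). Sentences are built from hand-written
dependency templates — simple clause, clause with determiners/modifiers
(`det`, `amod`, `advmod`, `nmod`/`nmod:poss`), clause plus subordinate
clause (`mark` + `advcl`/`ccomp`) — which guarantees well-formed
single-rooted trees and makes clause density (CLS), modifier frequency
(MOD) and dependency distances directly controllable. Sentence length is
normal(mean, sd) floored at 2; the subject is a pronoun with probability
pronoun_weight/(noun_weight+pronoun_weight); nominal-modifier slots are
weighted by noun_weight.

Disfluencies are injected *after* the clean sentence is fixed:
repetitions as immediate duplicates, incomplete words as truncated
prefixes with a trailing marker, fillers at a small fixed rate. The
clean stream is generated with no adjacent duplicate forms, so cleaning
the surface transcript recovers exactly the parsed token stream — the
parse of every task instance is the parse of its cleaned text, and the
CoNLL-U files round-trip losslessly.

Severity is drawn per participant from a normal left-censored at zero
(`max(0, N(loc, scale))`): clinician severity ratings of healthy controls
are strongly zero-inflated, which a censored normal reproduces and a
renormalised truncated normal would not. The preset control profile uses
loc 0.108, scale 0.315 and the thought-disorder-like preset loc 1.10,
scale 0.94, matching published clinician-rating summaries for mildly
affected cohorts; the aphasia-like preset uses a higher location (2.2)
on the same arbitrary scale. Other preset parameters (drift 0.5 vs 0.15,
repetition 80 vs 5 per 1000, noun:pronoun mixture 1:2 vs 2:1, sentence
length 7 vs 9, clause probability 0.15 vs 0.35) are not calibrated to any
clinical dataset — no per-group feature distributions are publicly
reported numerically — and were fixed once for qualitative agreement with
the reported directionality of group differences (aphasia: more
repetition, more drift, more pronouns, shorter and structurally simpler
sentences; thought disorder: more nouns, more clauses, longer sentences).

What the generator does *not* emulate: real lexical semantics and
morphology, annotation noise, parser errors, interviewer behaviour beyond
ignorable lines, acoustic phenomena, and the long-tailed length
distributions of real interviews. Passing tests therefore demonstrate
that the pipeline measures what it claims and that the experimental
protocol is calibrated — not that any particular accuracy is attainable
on clinical data.

## Problem sizes and numerical choices

Test and acceptance computations use sizes chosen to make the statistics
stable while keeping a full run inexpensive: 30 participants/group × 2
tasks × ~180 words for group-recovery checks (three base seeds), 100
label permutations at 25/group for the permutation null, 2000 replicates
of the 4-test family for task-effect calibration, and 5 drift levels × 20
single-participant corpora for the monotonicity check. Cosines are
clipped to [−1, 1] against rounding; zero vectors raise rather than
silently contribute; exact Wilcoxon switches to the normal approximation
above n = 25 (the two agree within 0.02 at n = 15); random seeds are
derived from the base seed via `numpy.random.SeedSequence` and kept below
2³¹.

## Known limitations

* The generator's vocabulary has no homonymy/polysemy, so embedding-based
  coherence is cleaner than in real speech; absolute similarity values
  are not comparable to those from pretrained embeddings.
* The undersampling/CV protocol reports accuracy only (groups are
  balanced by design); per-class metrics come from a single
  representative run, as in the protocol it implements.
* Zero-shot experiments with a real model require an external server; the
  shipped backends are deterministic mocks for protocol testing.
* CHAT dialect coverage is partial (speaker lines, task blocks and the
  common annotation symbols), not the full CLAN specification.
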