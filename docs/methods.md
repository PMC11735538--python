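# Methods

This note documents the measurement definitions, statistical procedures,
synthetic-data model and numerical choices behind `speechling`, including
the places where the design was genuinely open and a convention had to be
fixed.

## Inputs and conventions

A subject contributes (a) an annotated transcript — sentences of tokens
with Universal POS tags and dependency relations, read from CoNLL-U — and
(b) an interval track — a gap-free tiling of the recording into speech and
pause intervals, half-open `[start, end)` in float seconds, adjacent
same-kind intervals merged.  Cohort manifests bind subjects to group
(HC/PD/MSA), age, sex, one of seven discourse topics, an optional
MDS-UPDRS III speech-item score, and optional named clinical scores.

"Word" everywhere means a token whose UPOS is not PUNCT or SYM.
Punctuation inflating word counts would corrupt every ratio feature, so
these tokens are excluded from all denominators while remaining in the
transcript.  NUM, INTJ and X are words but belong to neither lexical
class: they count toward word totals and toward neither ratio's numerator,
which is why `content_words + function_words ≤ 1` with equality only in
their absence.  Filled pauses are assumed absent from transcripts (ASR
toolchains drop paralinguistic tokens); INTJ tokens, if present, are
handled by the neither-class rule.

## Lexical and syntactic features

* **Content/function ratios.** Content = {NOUN, PROPN, VERB, ADJ, ADV};
  function = {ADP, AUX, CCONJ, SCONJ, DET, PART, PRON}.  This is the
  conventional open/closed-class split; it is configurable
  (`WordClassScheme`) because no single partition is canonical.
* **MATTR** (window 84 words, step 1) is computed on case-folded surface
  forms without lemmatization — the least-assuming reading of "unique
  words"; both the folding and the window are configurable.  Texts shorter
  than the window fall back to the plain type-token ratio and carry a
  `short_text` flag rather than erroring, since toy and degraded inputs
  are expected.
* **N-gram repetition** pools orders 2–4: repeats at order *n* are
  (#*n*-gram tokens − #*n*-gram types) over the whole transcript, with
  *n*-grams enumerated within sentences only.  Crossing a sentence
  boundary would count phrase-final/phrase-initial coincidences that are
  not the restart/perseveration phenomenon of interest; re-using a phrase
  in a *later* sentence does count, because types are pooled
  transcript-wide.  The repeats/tokens normalization is this package's
  definition; the literature states the counting idea but not the
  denominator.
* **MLU** averages word counts over sentences with at least one word.
* **Coordinate-clause ratio.** Clause heads are VERB/AUX tokens whose base
  dependency relation (subtype stripped: `acl:relcl` → `acl`) is one of
  {root, conj, ccomp, xcomp, advcl, acl, csubj, parataxis}; coordinate
  heads are the `conj` subset.  This is one concrete operationalization of
  "clause"; the relation set is exposed as configuration.  Sentences
  without a dependency root contribute nothing (their annotation is not
  trusted).

A feature that cannot be computed (no words, no clause heads, no eligible
pause) is *missing*, with a reason string that propagates into the
feature-table flags file — never silently zero.

## Acoustic features

* **Net speech rate** = syllables / (total duration − Σ pauses **strictly
  longer** than 30 ms), in syllables/s.  The 30 ms exclusion is strict; a
  1 ns guard absorbs float representation error at the boundary.
* **Pause duration** = median of pauses **at least** 200 ms (inclusive
  threshold).  Pauses bounded by the recording start/end are included by
  default; `include_boundary_pauses=False` drops them, since whether
  leading/trailing silence is a "pause" is a protocol decision.
* **Syllables** come from a pluggable counter: the default deterministic
  vowel-nucleus mode counts maximal vowel groups plus syllabic liquids
  (r/l between consonants, for Czech-style clusters like "vlk"), minimum
  1; a hyphenation dictionary can be supplied as a callable.  Synthetic
  transcripts carry drawn syllable counts in the CoNLL-U MISC column
  (`Syllables=k`), which the counter prefers.  When comparing automated
  and manual arms, each arm counts syllables from its own word sequence.
* An optional RMS-energy segmenter (10 ms frames, −35 dB threshold
  relative to peak, sub-30 ms silences absorbed into speech) builds an
  interval track from a mono waveform.  It is a plain baseline for users
  without a pause annotation, not a tuned voice-activity detector.

## Agreement metrics

WER uses a unit-cost minimum-edit alignment on case-folded,
punctuation-stripped word sequences; ties prefer matches, then
substitutions.  WER = (S + D + I) / reference length and may exceed 1.
Feature agreement reports per-feature Pearson *r* and NRMSE = RMSE divided
by the mean of the *manual* (reference) values; pairs with a missing side
are dropped, and degenerate cases (zero variance, zero manual mean) are
reported as missing with a reason instead of a number.

## Group statistics

Per feature, a linear model `feature ~ group + age + sex + topic`
(optionally + speech item) is fitted by least squares; the group effect is
the partial *F* comparing against the covariates-only model.  Sex and
topic enter as indicator contrasts dropping a reference level; rare topics
can be collapsed into "other" (`min_topic_count`) to avoid rank
deficiency at small n, and a rank-deficient design raises an error naming
the collinear columns.  Adjusted means use g-computation: predictions
averaged over all subjects' observed covariates with group set
counterfactually; with covariates orthogonal to group this equals the raw
group means.  Fisher LSD contrasts are Wald *t*-tests on adjusted-mean
differences with the pooled residual variance and residual df, and no
multiplicity correction — with two groups the LSD *p* equals the omnibus
*p* exactly.  Subjects missing the feature (or the speech item when it is
a covariate) are dropped listwise with a logged count.  α = 0.05
two-tailed throughout; no correction is applied across the eight features,
the deliberately small feature set being the control on the type-I budget.
A zero-variance response short-circuits to the degenerate F = 0, p = 1.

Clinical correlations are partial correlations by the residual method
(regress both variables on the covariates, correlate residuals; rank
transform everything first for Spearman), with *p* from a *t* reference on
n − k − 2 df.  The Pearson/Spearman choice is gated per clinical variable
by a Shapiro–Wilk test at α = 0.05; constant input gates to Spearman.

## LOSO classification

For each held-out subject, z-scoring statistics and a logistic regression
are estimated on the remaining subjects only — no leakage of test
information into scaling or fitting — and the held-out disease probability
is recorded.  The logistic fit is Newton/IRLS with step halving and a
small ridge (default 1e-4, intercept unpenalized): near maximum
likelihood, but finite on linearly separable folds, which are common at
LOSO sample sizes.  Outside-fold scaling is available as an option for
replication of analyses that standardized globally.  AUC is the
Mann-Whitney statistic (ties count ½); sensitivity/specificity are read at
a 0.5 threshold, with the positive class fixed as the more-affected group
of the pair (PD against HC, MSA otherwise) so sensitivity means disease
detection.  Feature importance is |coefficient| of the all-data fit on
z-scored features — invariant to raw feature rescaling.  Subset search is
exhaustive over the ≤ 255 non-empty subsets, ranked by LOSO AUC with ties
broken toward smaller subsets, then canonical feature order.

**Known property: pessimistic permutation null.**  Pooled leave-one-out
probabilities are *anti-ranked* under the null: leaving out a subject
makes their class the training minority, so the fold intercept (and, more
diffusely, the fitted weights) tilt against them.  In the limit of
uninformative features the intercept alone yields AUC = 0; with noise
features at n = 80 the permutation-null mean AUC measures ≈ 0.40 (2
features) to ≈ 0.47 (8 features), not 0.50.  This is a property of the
pooled-LOSO procedure itself, not an implementation artifact, and it is
insensitive to the ridge strength; the acceptance suite records it
honestly.  Observed AUCs should be read against this mildly conservative
null — the bias makes real effects harder, not easier, to claim.

## Synthetic cohorts

The generator emulates the study conditions of a spontaneous-monologue
protocol: 39 subjects per group; monologue length ~ Normal(226, 76) words
(floor 30); narration around two minutes once pauses are added; seven
discourse topics with probabilities (.26, .20, .12, .12, .10, .09, .11);
ages ~ Normal(61.6/8.1, 60.9/12.6, 61.2/7.5) for HC/PD/MSA; male fractions
.49/.59/.49; speech-item scores ~ rounded Normal(0.1/0.2, 0.6/0.5,
1.8/0.7) clipped to 0–4.  MSA subjects additionally carry NNIPPS overall
(~N(81, 31)) and bulbar scores, the bulbar score linked negatively to the
subject's drawn sentence-length parameter so that the designed
"shorter utterances ↔ higher bulbar burden" correlation is recoverable.

Transcripts use an abstract vocabulary (all features are language-agnostic
given tags and relations): token classes are i.i.d. function-vs-content
draws; surfaces follow a Zipf–Mandelbrot law (exponent 1, shift 2.7) over
a 400-word content and 30-word function lexicon — the skew is what makes
repeated phrases arise at realistic rates; content tags are distributed
(NOUN .30, VERB .35, ADJ .12, ADV .18, PROPN .05), verbs frequent as in
connected speech.  With probability `phrase_repetition_prob` per token
slot, a previously emitted 2–4-word span is re-emitted verbatim.  The
dependency skeleton is deliberately minimal: the first fresh verb of a
sentence is the root; each further fresh verb becomes a clause head
attached by `conj` with a probability solved from the realized verb counts
so that the expected extracted coordinate-clause ratio equals the
requested rate (infeasible rates raise); copied spans take the inert
relation `dep` so repetition does not distort the clause inventory.
Timing: total speech time = syllables / (rate × lognormal noise), split
across runs by a Dirichlet draw; pauses are lognormal around the group
median (σ = 0.30), clipped up to the 200 ms floor — clipping below the
median leaves the sample median untouched while guaranteeing every pause
is eligible for the prolonged-pause feature.

The ASR error model applies per-word deletions, class-aware substitutions
and insertions at group-specific rates whose totals default to
13.6/14.8/37.9 % (HC/PD/MSA), split 60/20/20 across
substitution/deletion/insertion.  Substitutions are *consistent per word
type within a transcript* — a recognizer that confuses a word tends to
confuse it the same way each time — so repeated phrases survive as
(mis-recognized) repeated phrases; with `within_class_fraction = 1` the
content/function ratios are bit-identical by construction.  Group effect
directions follow the qualitative clinical pattern (MSA most affected on
function words, MLU, coordination, repetition, rate and pauses; PD
intermediate on MLU, coordination and pauses; articulation rate spared in
PD); the magnitudes are this package's own defaults, chosen to be
plausible for moderate disease, and a `large_msa_effects` preset amplifies
the MSA shifts for power checks.  Between-subject heterogeneity perturbs
each subject's parameters around the group values
(`between_subject_scale = 0` disables it for exact parameter-recovery
studies).  Everything is driven by spawned `SeedSequence` streams: a fixed
seed reproduces byte-identical files.

What the generator does **not** emulate — and hence what passing tests do
not establish about clinical data: real morphology and syntax (trees
beyond the clause-head skeleton), acoustic signal properties (only
interval timing is modeled), topic- or severity-dependent content,
correlated feature noise beyond the built-in parameter links, and
annotation errors in the *manual* arm (it is treated as exact ground
truth).  Pipeline correctness and calibration transfer to real data;
effect sizes and classification accuracies do not.

## Numerical choices

* Interval tracks validate to 1e-9 s; readers merge same-kind neighbours
  and fill coverage gaps as pauses with a warning, but reject overlaps.
* MATTR uses an O(n) sliding multiset rather than per-window sets; the
  two agree to 1e-12 in the oracle tests.
* Least squares via `numpy.linalg.lstsq`; collinearity detected by matrix
  rank with pivoted-QR naming of offending columns.
* Logistic Newton iterations cap at 100 with 1e-10 step tolerance and
  30 step-halvings; the fit matches scikit-learn's LBFGS at matched ridge
  to 1e-4.
* WER backtrace prefers diagonal moves (match/substitution) before
  deletion before insertion, making the reported operation counts
  deterministic among cost-equal alignments.
* Reported problem sizes: the acceptance script uses 400 ANCOVA null
  replicates, 300 LOSO permutation replicates and 500 partial-correlation
  replicates; the test suite runs the calibration checks at 2000
  replicates each.

## Known limitations

* The n-gram feature's NRMSE between analysis arms is large (~0.7)
  despite reasonable correlation, because the feature's mean is small
  (~0.04) and NRMSE is scale-sensitive near zero; absolute disagreement
  is ~0.02.
* The permutation-null LOSO AUC bias above means pooled-LOSO AUCs are not
  directly comparable to 0.5 without a matched permutation reference.
* The vowel-nucleus syllabifier is an approximation; for languages with
  opaque orthography a hyphenation dictionary should be plugged in.
* The energy segmenter is threshold-based and will mis-segment noisy
  recordings; it exists so the pipeline is runnable without external
  pause annotations, not as a contribution.
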