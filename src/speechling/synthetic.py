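"""Synthetic cohorts with known ground truth for every pipeline stage.

No recordings are distributed with studies of parkinsonian speech, so the
pipeline is exercised on fully synthetic cohorts: per-subject annotated
transcripts (abstract vocabulary, UPOS tags and a clause-head dependency
skeleton), speech/pause interval tracks, cohort manifests, and error-injected
"automated" transcript copies emulating ASR output.  Every generative knob
maps onto a pipeline feature, so parameter recovery is testable:

====================================  =================================
knob                                  recovered by
====================================  =================================
``function_word_prob``                function_words ratio
``sentence_length_mean``              mean length of utterance
``coordinate_clause_rate``            coordinate_clauses ratio
``phrase_repetition_prob``            ngram_repetition (monotone)
``speech_rate_syl_per_s``             net_speech_rate
``pause_median_s``                    pause_duration
ASR ``substitution_rate``             word error rate
====================================  =================================

Transcripts are language-agnostic: features depend only on tags, relations,
surfaces and timing, so an abstract vocabulary ("w0001", "f003") suffices;
per-word syllable counts are drawn once and stored in the CoNLL-U MISC
column (``Syllables=k``), bypassing hyphenation in synthetic mode.

Group defaults emulate a 39/39/39 cohort of ~226-word, ~2-minute monologues
with the qualitative clinical pattern: MSA most affected on every shifted
feature, PD intermediate (shorter utterances, fewer coordinate clauses,
longer pauses), and articulation-rate slowing in MSA only.  Effect
magnitudes are this package's own choices — no published effect sizes exist
for them.  ASR word-error levels default to 13.6/14.8/37.9% (HC/PD/MSA).

Everything is deterministic under a fixed seed, including written files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .data_model import (
    TOPICS,
    AnnotatedTranscript,
    IntervalTrack,
    Sentence,
    SubjectRecord,
    Token,
    write_conllu,
    write_interval_track,
    write_manifest,
)
from .lexsyn import DEFAULT_SCHEME

__all__ = [
    "AsrErrorModel",
    "GroupParams",
    "CohortSpec",
    "Cohort",
    "generate_transcript",
    "generate_track",
    "inject_asr_errors",
    "generate_cohort",
    "write_cohort",
]

_CONTENT_TAGS = ("NOUN", "VERB", "ADJ", "ADV", "PROPN")
#: Within-content tag distribution; verbs frequent, as in connected speech.
_CONTENT_TAG_PROBS = (0.30, 0.35, 0.12, 0.18, 0.05)
_FUNCTION_TAGS = ("ADP", "AUX", "CCONJ", "SCONJ", "DET", "PART", "PRON")

#: Discourse-topic probabilities of the elicitation protocol.
TOPIC_PROBS = (0.26, 0.20, 0.12, 0.12, 0.10, 0.09, 0.11)

_zipf_cum_cache: dict[tuple[int, float], np.ndarray] = {}


def _zipf_index(size: int, rng: np.random.Generator, s: float = 1.0,
                q: float = 2.7) -> int:
    """Word-rank draw under a Zipf-Mandelbrot law P(r) ~ 1/(r+q)^s.

    Natural vocabularies are heavily skewed; a skewed lexicon is what makes
    repeated phrases arise at realistic rates in the generated monologues.
    """
    key = (size, s)
    cum = _zipf_cum_cache.get(key)
    if cum is None:
        w = 1.0 / (np.arange(1, size + 1) + q) ** s
        cum = np.cumsum(w / w.sum())
        _zipf_cum_cache[key] = cum
    return int(np.searchsorted(cum, rng.random()))


@dataclass(frozen=True)
class AsrErrorModel:
    """Word-level ASR corruption: i.i.d. substitutions/deletions, geometric
    insertions after each word.  A within-class substitution keeps the word's
    content/function class (and UPOS), so class-based ratios are untouched."""

    substitution_rate: float = 0.08
    deletion_rate: float = 0.03
    insertion_rate: float = 0.03
    within_class_fraction: float = 0.5
    insertion_function_prob: float = 0.5

    def __post_init__(self):
        for name in ("substitution_rate", "deletion_rate", "insertion_rate",
                     "within_class_fraction", "insertion_function_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def total_rate(self) -> float:
        return self.substitution_rate + self.deletion_rate + self.insertion_rate


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one diagnostic group (defaults: HC)."""

    vocabulary_size: int = 400
    function_vocab_size: int = 30
    function_word_prob: float = 0.45
    sentence_length_mean: float = 11.0
    sentence_length_sd: float = 3.5
    phrase_repetition_prob: float = 0.02
    coordinate_clause_rate: float = 0.30
    target_words_mean: float = 226.0
    target_words_sd: float = 76.0
    speech_rate_syl_per_s: float = 5.0
    speech_rate_noise_sigma: float = 0.05
    pause_median_s: float = 0.55
    pause_sigma: float = 0.30
    pause_rate_per_s: float = 0.25
    syllable_lambda: float = 0.9  # syllables per word = 1 + Poisson(lambda)
    age_mean: float = 61.6
    age_sd: float = 8.1
    male_fraction: float = 0.49
    speech_item_mean: float = 0.1
    speech_item_sd: float = 0.2
    between_subject_scale: float = 1.0
    asr: AsrErrorModel = field(
        default_factory=lambda: AsrErrorModel(0.0816, 0.0272, 0.0272)
    )

    def __post_init__(self):
        if self.sentence_length_mean < 1:
            raise ValueError("sentence_length_mean must be >= 1")
        for name in ("function_word_prob", "phrase_repetition_prob",
                     "coordinate_clause_rate", "male_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("vocabulary_size", "function_vocab_size", "target_words_mean",
                     "speech_rate_syl_per_s", "pause_median_s", "pause_sigma",
                     "age_mean", "age_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _default_groups() -> dict[str, GroupParams]:
    hc = GroupParams()
    pd_ = replace(
        hc,
        sentence_length_mean=9.5,
        coordinate_clause_rate=0.24,
        phrase_repetition_prob=0.03,
        pause_median_s=0.68,
        age_mean=60.9,
        age_sd=12.6,
        male_fraction=0.59,
        speech_item_mean=0.6,
        speech_item_sd=0.5,
        asr=AsrErrorModel(0.0888, 0.0296, 0.0296),
    )
    msa = replace(
        hc,
        function_word_prob=0.41,
        sentence_length_mean=8.0,
        coordinate_clause_rate=0.18,
        # strong enough that the ordering survives the heavier MSA ASR
        # corruption on the automated arm
        phrase_repetition_prob=0.08,
        speech_rate_syl_per_s=4.1,
        pause_median_s=0.95,
        age_mean=61.2,
        age_sd=7.5,
        male_fraction=0.49,
        speech_item_mean=1.8,
        speech_item_sd=0.7,
        asr=AsrErrorModel(0.2274, 0.0758, 0.0758),
    )
    return {"HC": hc, "PD": pd_, "MSA": msa}


@dataclass(frozen=True)
class CohortSpec:
    """A full cohort design: group sizes, seed, per-group generative params."""

    n_per_group: int = 39
    seed: int = 0
    groups: Mapping[str, GroupParams] = field(default_factory=_default_groups)

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not self.groups:
            raise ValueError("at least one group required")

    @classmethod
    def null(cls, n_per_group: int = 39, seed: int = 0) -> "CohortSpec":
        """All groups share identical generative parameters (type-I-error
        calibration design)."""
        hc = GroupParams()
        return cls(n_per_group=n_per_group, seed=seed,
                   groups={g: hc for g in ("HC", "PD", "MSA")})

    @classmethod
    def large_msa_effects(cls, n_per_group: int = 39, seed: int = 0) -> "CohortSpec":
        """Defaults with amplified MSA shifts: a power check of the pipeline,
        not an emulation of any published effect size."""
        groups = _default_groups()
        groups["MSA"] = replace(
            groups["MSA"],
            function_word_prob=0.38,
            sentence_length_mean=6.5,
            coordinate_clause_rate=0.12,
            phrase_repetition_prob=0.14,
            speech_rate_syl_per_s=3.2,
            pause_median_s=1.4,
        )
        return cls(n_per_group=n_per_group, seed=seed, groups=groups)


@dataclass
class Cohort:
    """In-memory synthetic cohort: manifest records, manual and ASR-corrupted
    transcripts, interval tracks, and the ground-truth parameter record."""

    spec: CohortSpec
    records: list[SubjectRecord]
    manual: dict[str, AnnotatedTranscript]
    automated: dict[str, AnnotatedTranscript]
    tracks: dict[str, IntervalTrack]
    ground_truth: dict


# ---------------------------------------------------------------------------
# transcript generation
# ---------------------------------------------------------------------------


def _draw_word(params: GroupParams, rng: np.random.Generator,
               syllables: dict[str, int]) -> tuple[str, str]:
    """One fresh (surface, upos) draw; records the word's syllable count."""
    if rng.random() < params.function_word_prob:
        surface = f"f{_zipf_index(params.function_vocab_size, rng):03d}"
        upos = _FUNCTION_TAGS[rng.integers(len(_FUNCTION_TAGS))]
    else:
        surface = f"w{_zipf_index(params.vocabulary_size, rng):04d}"
        upos = _CONTENT_TAGS[rng.choice(len(_CONTENT_TAGS), p=_CONTENT_TAG_PROBS)]
    if surface not in syllables:
        syllables[surface] = 1 + int(rng.poisson(params.syllable_lambda))
    return surface, upos


def generate_transcript(
    params: GroupParams,
    subject_id: str,
    rng: np.random.Generator | int,
    source: str = "manual",
) -> AnnotatedTranscript:
    """Draw one annotated monologue.

    Token classes are i.i.d. (function with probability
    ``function_word_prob``); with ``phrase_repetition_prob`` a previously
    emitted 2-4-word span is re-emitted verbatim.  Dependency skeleton: the
    first freshly-drawn verb of a sentence is the root; every further fresh
    verb becomes a clause head, attached by ``conj`` with a probability
    solved (from the realized verb counts) so that the expected extracted
    coordinate-clause ratio equals ``coordinate_clause_rate``, and by
    ``advcl`` otherwise.  Copied spans take the inert relation ``dep`` so
    phrase repetition does not distort the clause inventory.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    syllables: dict[str, int] = {}
    target = max(30, int(round(rng.normal(params.target_words_mean, params.target_words_sd))))
    # (surface, upos, copied) specs per sentence
    emitted: list[tuple[str, str]] = []
    sentence_specs: list[list[tuple[str, str, bool]]] = []
    total = 0
    while total < target:
        L = max(1, int(round(rng.normal(params.sentence_length_mean, params.sentence_length_sd))))
        toks: list[tuple[str, str, bool]] = []
        while len(toks) < L:
            room = L - len(toks)
            if (
                len(emitted) >= 2
                and room >= 2
                and rng.random() < params.phrase_repetition_prob
            ):
                n = int(rng.integers(2, 5))
                n = min(n, room, len(emitted))
                start = int(rng.integers(0, len(emitted) - n + 1))
                for surface, upos in emitted[start: start + n]:
                    toks.append((surface, upos, True))
                    emitted.append((surface, upos))
            else:
                surface, upos = _draw_word(params, rng, syllables)
                toks.append((surface, upos, False))
                emitted.append((surface, upos))
        sentence_specs.append(toks)
        total += L

    # clause-head planning over the whole transcript
    roots: list[int | None] = []       # per-sentence root position (0-based)
    extra_heads: list[list[int]] = []  # per-sentence fresh non-root verb slots
    n_root_verbs = 0
    for toks in sentence_specs:
        fresh_verbs = [i for i, (_, upos, copied) in enumerate(toks)
                       if upos == "VERB" and not copied]
        if fresh_verbs:
            roots.append(fresh_verbs[0])
            extra_heads.append(fresh_verbs[1:])
            n_root_verbs += 1
        else:
            roots.append(None)
            extra_heads.append([])
    n_extra = sum(len(e) for e in extra_heads)
    r = params.coordinate_clause_rate
    if n_extra > 0 and r > 0:
        q = min(1.0, r * (n_root_verbs + n_extra) / n_extra)
    else:
        q = 0.0

    sentences = []
    for s_idx, toks in enumerate(sentence_specs):
        root_pos = roots[s_idx] if roots[s_idx] is not None else 0
        head_set = set(extra_heads[s_idx])
        tokens = []
        for i, (surface, upos, copied) in enumerate(toks):
            syl = syllables.get(surface)
            if syl is None:
                syllables[surface] = syl = 1 + int(rng.poisson(params.syllable_lambda))
            misc = {"Syllables": str(syl)}
            if i == root_pos:
                deprel, head = "root", 0
            elif i in head_set:
                deprel = "conj" if rng.random() < q else "advcl"
                head = root_pos + 1
            elif upos == "AUX":
                deprel, head = "aux", root_pos + 1
            else:
                deprel, head = "dep", root_pos + 1
            tokens.append(Token(surface=surface, upos=upos, deprel=deprel,
                                head_index=head, misc=misc))
        sentences.append(Sentence(tuple(tokens), index=s_idx))
    return AnnotatedTranscript(subject_id=subject_id, sentences=tuple(sentences),
                               source=source)


# ---------------------------------------------------------------------------
# timing generation
# ---------------------------------------------------------------------------


def generate_track(
    params: GroupParams,
    transcript: AnnotatedTranscript,
    rng: np.random.Generator | int,
) -> IntervalTrack:
    """Speech/pause tiling consistent with the transcript's syllable load.

    Total speech time = syllables / (rate x lognormal noise); pauses are
    lognormal around ``pause_median_s`` (clipped up to the 200 ms floor, which
    leaves the median untouched while guaranteeing every pause is eligible
    for the prolonged-pause median); the speech time is split across
    ``n_pauses + 1`` runs by a Dirichlet draw.  Tracks start and end with
    speech.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    syll = sum(int(t.misc.get("Syllables", 1)) for t in transcript.iter_words())
    syll = max(syll, 1)
    rate = params.speech_rate_syl_per_s * float(
        np.exp(rng.normal(0.0, params.speech_rate_noise_sigma))
    )
    speech_time = syll / rate
    n_pauses = int(round(speech_time * params.pause_rate_per_s))
    pause_durs = np.maximum(
        rng.lognormal(np.log(params.pause_median_s), params.pause_sigma, size=n_pauses),
        0.2,
    )
    runs = rng.dirichlet(np.full(n_pauses + 1, 4.0)) * speech_time
    intervals: list[tuple[float, float, str]] = []
    t = 0.0
    for i, run in enumerate(runs):
        intervals.append((t, t + run, "speech"))
        t += run
        if i < n_pauses:
            intervals.append((t, t + pause_durs[i], "pause"))
            t += pause_durs[i]
    return IntervalTrack.from_intervals(transcript.subject_id, intervals)


# ---------------------------------------------------------------------------
# ASR error injection
# ---------------------------------------------------------------------------


def _class_of(upos: str) -> str:
    if upos in DEFAULT_SCHEME.content_tags:
        return "content"
    if upos in DEFAULT_SCHEME.function_tags:
        return "function"
    return "excluded"


def inject_asr_errors(
    transcript: AnnotatedTranscript,
    model: AsrErrorModel,
    rng: np.random.Generator | int,
) -> AnnotatedTranscript:
    """Corrupt a transcript the way an ASR system would.

    Per word: deletion with probability ``deletion_rate``; else substitution
    with probability ``substitution_rate`` (keeping the content/function
    class — and the UPOS tag — with probability ``within_class_fraction``,
    crossing class otherwise); after each word, an insertion with probability
    ``insertion_rate``.  Substitutions are consistent per word type within a
    transcript — an ASR system that confuses a word tends to confuse it the
    same way every time — so repeated phrases survive as (mis-recognized)
    repeated phrases.  Dependency structure is rebuilt around the surviving
    root (survivors keep their relation labels; insertions are inert
    ``dep``).  Sentences emptied by deletion vanish.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    confusions: dict[str, Token] = {}  # per-type systematic substitution

    content_pool = sorted({t.surface for t in transcript.iter_words()
                           if _class_of(t.upos) == "content"}) or ["w0000"]
    function_pool = sorted({t.surface for t in transcript.iter_words()
                            if _class_of(t.upos) == "function"}) or ["f000"]

    def other_word(pool: list[str], current: str) -> str:
        if len(pool) == 1:
            return pool[0] + "x"
        while True:
            w = pool[rng.integers(len(pool))]
            if w != current:
                return w

    def fresh_misc() -> dict[str, str]:
        return {"Syllables": str(1 + int(rng.poisson(0.9)))}

    new_sentences = []
    for sent in transcript.sentences:
        kept: list[Token] = []
        root_surface_kept: int | None = None
        for i, tok in enumerate(sent.tokens):
            was_root = tok.head_index == 0
            if rng.random() < model.deletion_rate:
                pass  # deleted
            elif rng.random() < model.substitution_rate:
                if tok.surface in confusions:
                    proto = confusions[tok.surface]
                else:
                    cls = _class_of(tok.upos)
                    if rng.random() < model.within_class_fraction or cls == "excluded":
                        pool = content_pool if cls == "content" else function_pool
                        proto = Token(
                            surface=other_word(pool, tok.surface), upos=tok.upos,
                            deprel="dep", head_index=0, misc=fresh_misc(),
                        )
                    else:
                        if cls == "content":
                            upos = _FUNCTION_TAGS[rng.integers(len(_FUNCTION_TAGS))]
                            surface = function_pool[rng.integers(len(function_pool))]
                        else:
                            upos = _CONTENT_TAGS[
                                rng.choice(len(_CONTENT_TAGS), p=_CONTENT_TAG_PROBS)
                            ]
                            surface = content_pool[rng.integers(len(content_pool))]
                        proto = Token(surface=surface, upos=upos, deprel="dep",
                                      head_index=0, misc=fresh_misc())
                    confusions[tok.surface] = proto
                new_tok = Token(surface=proto.surface, upos=proto.upos,
                                deprel=tok.deprel, head_index=tok.head_index,
                                misc=proto.misc)
                if was_root:
                    root_surface_kept = len(kept)
                kept.append(new_tok)
            else:
                if was_root:
                    root_surface_kept = len(kept)
                kept.append(tok)
            if rng.random() < model.insertion_rate:
                if rng.random() < model.insertion_function_prob:
                    upos = _FUNCTION_TAGS[rng.integers(len(_FUNCTION_TAGS))]
                    surface = function_pool[rng.integers(len(function_pool))]
                else:
                    upos = _CONTENT_TAGS[rng.choice(len(_CONTENT_TAGS), p=_CONTENT_TAG_PROBS)]
                    surface = content_pool[rng.integers(len(content_pool))]
                kept.append(Token(surface=surface, upos=upos, deprel="dep",
                                  head_index=0, misc=fresh_misc()))
        if not kept:
            continue
        root_pos = root_surface_kept if root_surface_kept is not None else 0
        rebuilt = []
        for i, tok in enumerate(kept):
            if i == root_pos:
                rebuilt.append(dataclasses.replace(tok, deprel="root", head_index=0))
            else:
                rebuilt.append(dataclasses.replace(tok, head_index=root_pos + 1))
        new_sentences.append(Sentence(tuple(rebuilt), index=len(new_sentences)))
    if not new_sentences:
        new_sentences = [Sentence((transcript.sentences[0].tokens[0],), index=0)]
    return AnnotatedTranscript(
        subject_id=transcript.subject_id,
        sentences=tuple(new_sentences),
        source="automated",
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

#: Per-subject between-subject SDs (multiplied by ``between_subject_scale``).
_SUBJECT_SD = {
    "function_word_prob": 0.025,
    "sentence_length_mean": 1.2,
    "coordinate_clause_rate": 0.05,
    "phrase_repetition_prob": 0.01,
    "speech_rate_syl_per_s": 0.30,
}


def _draw_subject_params(
    params: GroupParams, rng: np.random.Generator
) -> GroupParams:
    """Subject-level heterogeneity around the group parameters."""
    s = params.between_subject_scale
    if s == 0:
        return params
    return replace(
        params,
        function_word_prob=float(np.clip(
            rng.normal(params.function_word_prob, _SUBJECT_SD["function_word_prob"] * s),
            0.05, 0.9)),
        sentence_length_mean=float(np.clip(
            rng.normal(params.sentence_length_mean, _SUBJECT_SD["sentence_length_mean"] * s),
            2.0, 40.0)),
        coordinate_clause_rate=float(np.clip(
            rng.normal(params.coordinate_clause_rate, _SUBJECT_SD["coordinate_clause_rate"] * s),
            0.0, 0.8)),
        phrase_repetition_prob=float(np.clip(
            rng.normal(params.phrase_repetition_prob, _SUBJECT_SD["phrase_repetition_prob"] * s),
            0.0, 0.5)),
        speech_rate_syl_per_s=float(np.clip(
            rng.normal(params.speech_rate_syl_per_s, _SUBJECT_SD["speech_rate_syl_per_s"] * s),
            1.0, 10.0)),
        pause_median_s=float(np.clip(
            params.pause_median_s * np.exp(rng.normal(0.0, 0.12 * s)),
            0.21, 5.0)),
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort: manifest, manual + automated transcripts,
    interval tracks, and a ground-truth record of group- and subject-level
    parameters."""
    root_seq = np.random.SeedSequence(spec.seed)
    records: list[SubjectRecord] = []
    manual: dict[str, AnnotatedTranscript] = {}
    automated: dict[str, AnnotatedTranscript] = {}
    tracks: dict[str, IntervalTrack] = {}
    truth_subjects: dict[str, dict] = {}

    group_names = list(spec.groups)
    child_seqs = root_seq.spawn(len(group_names))
    for g_idx, group in enumerate(group_names):
        params = spec.groups[group]
        subject_seqs = child_seqs[g_idx].spawn(spec.n_per_group)
        for k in range(spec.n_per_group):
            sid = f"{group}{k + 1:03d}"
            rng = np.random.default_rng(subject_seqs[k])
            sparams = _draw_subject_params(params, rng)
            transcript = generate_transcript(sparams, sid, rng)
            track = generate_track(sparams, transcript, rng)
            auto = inject_asr_errors(transcript, sparams.asr, rng)

            age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 35, 90))
            sex = "M" if rng.random() < params.male_fraction else "F"
            topic = TOPICS[rng.choice(len(TOPICS), p=TOPIC_PROBS)]
            speech_item = float(np.clip(
                round(rng.normal(params.speech_item_mean, params.speech_item_sd)), 0, 4))
            clinical: dict[str, float] = {}
            if group == "MSA":
                clinical["nnipps_overall"] = float(np.clip(
                    round(rng.normal(81, 31)), 30, 130))
                # bulbar severity tracks short utterances (negative MLU link)
                severity = -(sparams.sentence_length_mean - params.sentence_length_mean)
                sd = _SUBJECT_SD["sentence_length_mean"] * max(params.between_subject_scale, 1e-9)
                clinical["nnipps_bulbar"] = float(np.clip(
                    round(7.9 + 2.5 * severity / sd + rng.normal(0, 1.5))
                    if params.between_subject_scale > 0
                    else round(rng.normal(7.9, 3.4)),
                    3, 15))
            records.append(SubjectRecord(
                subject_id=sid, group=group, age=age, sex=sex, topic=topic,
                speech_item=speech_item, clinical_scores=clinical,
            ))
            manual[sid] = transcript
            automated[sid] = auto
            tracks[sid] = track
            truth_subjects[sid] = {
                "group": group,
                **{f.name: getattr(sparams, f.name)
                   for f in dataclasses.fields(GroupParams)
                   if f.name != "asr"},
                "asr": dataclasses.asdict(sparams.asr),
            }
    truth = {
        "seed": spec.seed,
        "n_per_group": spec.n_per_group,
        "groups": {
            g: {**{f.name: getattr(p, f.name)
                   for f in dataclasses.fields(GroupParams) if f.name != "asr"},
                "asr": dataclasses.asdict(p.asr)}
            for g, p in spec.groups.items()
        },
        "subjects": truth_subjects,
    }
    return Cohort(spec=spec, records=records, manual=manual, automated=automated,
                  tracks=tracks, ground_truth=truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write the cohort in the on-disk layout the readers and the CLI expect:

    ``manifest.csv``, ``conllu_manual/``, ``conllu_automated/``, ``tracks/``
    and ``ground_truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "conllu_manual").mkdir(parents=True, exist_ok=True)
    (outdir / "conllu_automated").mkdir(exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    write_manifest(cohort.records, outdir / "manifest.csv")
    for sid, t in cohort.manual.items():
        write_conllu(t, outdir / "conllu_manual" / f"{sid}.conllu")
    for sid, t in cohort.automated.items():
        write_conllu(t, outdir / "conllu_automated" / f"{sid}.conllu")
    for sid, tr in cohort.tracks.items():
        write_interval_track(tr, outdir / "tracks" / f"{sid}.csv")
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True)
    return outdir
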