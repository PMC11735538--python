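"""The six lexical and syntactic features of spontaneous-discourse analysis.

All six operate on an :class:`~speechling.data_model.AnnotatedTranscript`:

* ``content_words`` / ``function_words`` — fraction of words that are
  content-bearing (open-class) vs grammatical (closed-class), via UPOS tags;
* ``mattr`` — moving-average type-token ratio: lexical diversity averaged
  over all sliding windows of a fixed width (default 84 words, step 1);
* ``ngram_repetition`` — how often 2-, 3- and 4-word phrases recur, pooled
  over orders: (n-gram tokens - n-gram types) / n-gram tokens;
* ``mlu`` — mean length of utterance: average words per sentence;
* ``coordinate_clauses`` — verbal clause heads attached by ``conj``,
  normalized by all verbal clause heads.

A feature that cannot be computed (no words, no clause heads, no eligible
pauses) is *missing* — reported as ``None`` with a reason — rather than an
error, since short or degraded transcripts are expected inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .data_model import UPOS_TAGS, AnnotatedTranscript, Token, ValidationError

__all__ = [
    "WordClassScheme",
    "DEFAULT_SCHEME",
    "CLAUSE_DEPRELS",
    "FeatureValue",
    "classify_word",
    "content_word_ratio",
    "function_word_ratio",
    "mattr",
    "ngram_repetition",
    "mean_length_of_utterance",
    "coordinate_clause_ratio",
    "extract_linguistic_features",
]


@dataclass(frozen=True)
class WordClassScheme:
    """Partition of the 17 UPOS tags into content / function / excluded.

    ``excluded_tags`` splits conceptually in two: PUNCT and SYM are not words
    at all (they never enter any denominator), while NUM, INTJ and X are
    words that belong to neither lexical class — they count toward word
    totals but toward neither ratio's numerator.  This is why the two ratios
    complement each other without summing to exactly 1.
    """

    content_tags: frozenset[str] = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV"})
    function_tags: frozenset[str] = frozenset(
        {"ADP", "AUX", "CCONJ", "SCONJ", "DET", "PART", "PRON"}
    )
    excluded_tags: frozenset[str] = frozenset({"NUM", "INTJ", "X", "PUNCT", "SYM"})

    def __post_init__(self):
        sets = (self.content_tags, self.function_tags, self.excluded_tags)
        union = frozenset().union(*sets)
        if sum(map(len, sets)) != len(union):
            raise ValidationError("word-class sets must be disjoint")
        if union != UPOS_TAGS:
            raise ValidationError(f"word-class sets must cover all UPOS tags; missing {UPOS_TAGS - union}")


DEFAULT_SCHEME = WordClassScheme()

#: Dependency relations whose verbal bearers count as clause heads.
CLAUSE_DEPRELS = frozenset(
    {"root", "conj", "ccomp", "xcomp", "advcl", "acl", "csubj", "parataxis"}
)


@dataclass(frozen=True)
class FeatureValue:
    """A feature value with provenance: ``None`` value means missing, with
    ``reason``; ``flags`` carries quality notes such as ``short_text``."""

    value: float | None
    reason: str | None = None
    flags: tuple[str, ...] = ()

    @property
    def missing(self) -> bool:
        return self.value is None


def _missing(reason: str) -> FeatureValue:
    return FeatureValue(None, reason=reason)


def classify_word(token: Token, scheme: WordClassScheme = DEFAULT_SCHEME) -> str:
    """Return ``content``, ``function`` or ``excluded`` for one token."""
    if token.upos in scheme.content_tags:
        return "content"
    if token.upos in scheme.function_tags:
        return "function"
    if token.upos in scheme.excluded_tags:
        return "excluded"
    raise ValidationError(f"UPOS {token.upos!r} not covered by scheme")  # unreachable if scheme valid


def _word_counts(t: AnnotatedTranscript, scheme: WordClassScheme) -> tuple[int, int, int]:
    """(content, function, total-words).  Total counts every non-PUNCT/SYM
    token, including neither-class words (NUM/INTJ/X)."""
    content = function = total = 0
    for tok in t.iter_words():
        total += 1
        cls = classify_word(tok, scheme)
        if cls == "content":
            content += 1
        elif cls == "function":
            function += 1
    return content, function, total


def content_word_ratio(
    t: AnnotatedTranscript, scheme: WordClassScheme = DEFAULT_SCHEME
) -> FeatureValue:
    """Content words / total words."""
    content, _, total = _word_counts(t, scheme)
    if total == 0:
        return _missing("no words")
    return FeatureValue(content / total)


def function_word_ratio(
    t: AnnotatedTranscript, scheme: WordClassScheme = DEFAULT_SCHEME
) -> FeatureValue:
    """Function words / total words."""
    _, function, total = _word_counts(t, scheme)
    if total == 0:
        return _missing("no words")
    return FeatureValue(function / total)


def _word_sequence(t: AnnotatedTranscript) -> list[str]:
    """Case-folded surface forms of all words, transcript order."""
    return [tok.surface.casefold() for tok in t.iter_words()]


def mattr(t: AnnotatedTranscript, window_size: int = 84) -> FeatureValue:
    """Moving-average type-token ratio over a sliding window, step 1.

    Texts shorter than the window fall back to the plain type-token ratio of
    the whole text, flagged ``short_text``.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    words = _word_sequence(t)
    n = len(words)
    if n == 0:
        return _missing("no words")
    if n < window_size:
        return FeatureValue(len(set(words)) / n, flags=("short_text",))
    # incremental unique count: O(n) via multiset updates
    counts: dict[str, int] = {}
    for w in words[:window_size]:
        counts[w] = counts.get(w, 0) + 1
    unique = len(counts)
    total = unique
    n_windows = n - window_size + 1
    for i in range(1, n_windows):
        out_w, in_w = words[i - 1], words[i + window_size - 1]
        counts[out_w] -= 1
        if counts[out_w] == 0:
            del counts[out_w]
        counts[in_w] = counts.get(in_w, 0) + 1
        total += len(counts)
    return FeatureValue(total / (n_windows * window_size))


def ngram_repetition(
    t: AnnotatedTranscript, orders: Iterable[int] = (2, 3, 4)
) -> FeatureValue:
    """Pooled phrase-repetition rate over n-gram orders.

    For each order n, n-grams are enumerated *within* sentences (a phrase is
    not formed across a sentence boundary) but pooled into one transcript-wide
    inventory, so re-using a phrase in a later sentence counts as repetition.
    Repeats at order n = (#n-gram tokens - #distinct n-gram types); the
    feature is sum(repeats) / sum(tokens) over the orders that yielded at
    least one n-gram.
    """
    orders = sorted(set(orders))
    if not orders or any(n < 1 for n in orders):
        raise ValueError("orders must be positive integers")
    sent_words = [
        [tok.surface.casefold() for tok in s.words] for s in t.sentences
    ]
    total_tokens = 0
    total_repeats = 0
    any_order = False
    for n in orders:
        grams: dict[tuple[str, ...], int] = {}
        count = 0
        for words in sent_words:
            for i in range(len(words) - n + 1):
                g = tuple(words[i: i + n])
                grams[g] = grams.get(g, 0) + 1
                count += 1
        if count == 0:
            continue
        any_order = True
        total_tokens += count
        total_repeats += count - len(grams)
    if not any_order:
        return _missing("no n-gram of any requested order")
    return FeatureValue(total_repeats / total_tokens)


def mean_length_of_utterance(t: AnnotatedTranscript) -> FeatureValue:
    """Mean words per sentence; punctuation-only sentences are skipped."""
    lengths = [len(s.words) for s in t.sentences if len(s.words) > 0]
    if not lengths:
        return _missing("no sentence with words")
    return FeatureValue(sum(lengths) / len(lengths))


def coordinate_clause_ratio(
    t: AnnotatedTranscript, clause_deprels: frozenset[str] = CLAUSE_DEPRELS
) -> FeatureValue:
    """Coordinate clause heads / all clause heads.

    A clause head is a VERB or AUX token whose (base) dependency relation is
    one of ``clause_deprels``; it is coordinate when that relation is
    ``conj``.  Sentences without dependency roots contribute nothing.
    """
    clauses = 0
    coordinate = 0
    for s in t.sentences:
        if not s.has_root:
            continue
        for tok in s.tokens:
            if tok.upos in ("VERB", "AUX") and tok.base_deprel in clause_deprels:
                clauses += 1
                if tok.base_deprel == "conj":
                    coordinate += 1
    if clauses == 0:
        return _missing("no verbal clause heads")
    return FeatureValue(coordinate / clauses)


def extract_linguistic_features(
    t: AnnotatedTranscript,
    scheme: WordClassScheme = DEFAULT_SCHEME,
    window_size: int = 84,
) -> dict[str, FeatureValue]:
    """All six lexical/syntactic features keyed by canonical feature name."""
    return {
        "content_words": content_word_ratio(t, scheme),
        "function_words": function_word_ratio(t, scheme),
        "mattr": mattr(t, window_size=window_size),
        "ngram_repetition": ngram_repetition(t),
        "mlu": mean_length_of_utterance(t),
        "coordinate_clauses": coordinate_clause_ratio(t),
    }
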