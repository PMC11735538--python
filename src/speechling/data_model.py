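"""Domain types and readers/writers for transcripts, timing tracks and manifests.

The pipeline operates on three kinds of per-subject input:

* an **annotated transcript**: a POS/dependency-tagged tokenization of a
  spontaneous monologue, in CoNLL-U format (the standard output of UD
  taggers such as stanza);
* an **interval track**: an ordered, gap-free sequence of speech/pause
  intervals in seconds, from a Praat TextGrid tier or a plain CSV;
* a **cohort manifest** binding subjects to group (HC/PD/MSA), demographic
  covariates, discourse topic and optional clinical scores.

Feature tables — subjects x 8 named features — are plain :class:`pandas.DataFrame`
objects with a fixed column set (:data:`FEATURE_NAMES`), read and written as CSV.

Conventions: time is in float seconds, intervals are half-open ``[start, end)``;
"words" everywhere downstream exclude ``PUNCT`` and ``SYM`` tokens.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "UPOS_TAGS",
    "EXCLUDED_UPOS",
    "GROUPS",
    "TOPICS",
    "FEATURE_NAMES",
    "ParseError",
    "ValidationError",
    "Token",
    "Sentence",
    "AnnotatedTranscript",
    "Interval",
    "IntervalTrack",
    "SubjectRecord",
    "read_conllu",
    "write_conllu",
    "read_interval_track",
    "write_interval_track",
    "read_manifest",
    "write_manifest",
    "read_feature_table",
    "write_feature_table",
    "validate_feature_table",
]

#: The 17-tag Universal POS inventory.
UPOS_TAGS = frozenset(
    {
        "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
        "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
    }
)

#: Tags never counted as words (excluded from every denominator downstream).
EXCLUDED_UPOS = frozenset({"PUNCT", "SYM"})

GROUPS = ("HC", "PD", "MSA")

#: The seven discourse-topic categories of the elicitation protocol.
TOPICS = (
    "autobiographical",
    "hobby",
    "career",
    "social_event",
    "holiday",
    "typical_day",
    "other",
)

#: Canonical feature-table columns: 6 lexical/syntactic + 2 acoustic measures.
FEATURE_NAMES = (
    "content_words",
    "function_words",
    "mattr",
    "ngram_repetition",
    "mlu",
    "coordinate_clauses",
    "net_speech_rate",
    "pause_duration",
)


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


class ValidationError(ValueError):
    """A domain invariant was violated."""


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    """One syntactic word with its UPOS tag and dependency attachment.

    ``head_index`` is 1-based within the sentence; 0 marks the root.
    ``misc`` carries CoNLL-U MISC key/values (e.g. a stored syllable count
    under ``Syllables`` for synthetic transcripts).
    """

    surface: str
    upos: str
    deprel: str = "dep"
    head_index: int = 0
    misc: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.surface:
            raise ValidationError("token surface must be non-empty")
        if self.upos not in UPOS_TAGS:
            raise ValidationError(f"unknown UPOS tag {self.upos!r}")
        if self.head_index < 0:
            raise ValidationError("head_index must be >= 0")

    @property
    def is_word(self) -> bool:
        return self.upos not in EXCLUDED_UPOS

    @property
    def base_deprel(self) -> str:
        """Relation without UD subtype (``acl:relcl`` -> ``acl``)."""
        return self.deprel.split(":", 1)[0]


@dataclass(frozen=True)
class Sentence:
    """An utterance: ordered tokens, optionally dependency-annotated."""

    tokens: tuple[Token, ...]
    index: int = 0

    def __post_init__(self):
        if not self.tokens:
            raise ValidationError("sentence must contain at least one token")
        n = len(self.tokens)
        for i, tok in enumerate(self.tokens, start=1):
            if tok.head_index > n:
                raise ValidationError(
                    f"token {i} head_index {tok.head_index} exceeds sentence length {n}"
                )
            if tok.head_index == i:
                raise ValidationError(f"token {i} is its own head")

    @property
    def words(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.is_word)

    @property
    def has_root(self) -> bool:
        return any(t.head_index == 0 for t in self.tokens)


@dataclass(frozen=True)
class AnnotatedTranscript:
    """All sentences of one subject's monologue, from one annotation source."""

    subject_id: str
    sentences: tuple[Sentence, ...]
    source: str = "automated"  # {automated, manual}

    def __post_init__(self):
        if not self.sentences:
            raise ValidationError("transcript must contain at least one sentence")
        if self.source not in ("automated", "manual"):
            raise ValidationError(f"source must be 'automated' or 'manual', got {self.source!r}")

    @property
    def word_count(self) -> int:
        return sum(len(s.words) for s in self.sentences)

    def iter_words(self) -> Iterator[Token]:
        for s in self.sentences:
            yield from s.words


_MWT_ID = re.compile(r"^\d+-\d+$")
_EMPTY_ID = re.compile(r"^\d+\.\d+$")


def read_conllu(path: str | Path, subject_id: str | None = None,
                source: str = "automated") -> AnnotatedTranscript:
    """Parse a CoNLL-U file into an :class:`AnnotatedTranscript`.

    Multiword-token ranges (ids like ``3-4``) and empty nodes (``5.1``) are
    skipped in favour of their syntactic words.  A sentence lacking a root
    (no token with head 0) raises a warning but is kept; dependency-based
    features will report missing for it downstream.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    sentences: list[Sentence] = []
    tokens: list[Token] = []
    sent_index = 0

    def flush(line_no: int):
        nonlocal tokens, sent_index
        if not tokens:
            return
        sent = Sentence(tuple(tokens), index=sent_index)
        if not sent.has_root and any(t.deprel != "dep" for t in tokens):
            warnings.warn(
                f"{path.name}: sentence {sent_index + 1} (ending line {line_no}) has no root token",
                stacklevel=2,
            )
        sentences.append(sent)
        sent_index += 1
        tokens = []

    line_no = 0
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush(line_no)
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ParseError(
                    f"expected 10 tab-separated columns, got {len(cols)}", line_no
                )
            tok_id, form, _lemma, upos, _xpos, _feats, head, deprel, _deps, misc = cols
            if _MWT_ID.match(tok_id) or _EMPTY_ID.match(tok_id):
                continue
            if not tok_id.isdigit():
                raise ParseError(f"malformed token id {tok_id!r}", line_no)
            try:
                head_index = 0 if head == "_" else int(head)
            except ValueError:
                raise ParseError(f"malformed head index {head!r}", line_no) from None
            misc_map: dict[str, str] = {}
            if misc not in ("", "_"):
                for item in misc.split("|"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        misc_map[k] = v
            try:
                tokens.append(
                    Token(
                        surface=form,
                        upos=upos,
                        deprel=deprel if deprel != "_" else "dep",
                        head_index=head_index,
                        misc=misc_map,
                    )
                )
            except ValidationError as exc:
                raise ParseError(str(exc), line_no) from None
    flush(line_no)
    if not sentences:
        raise ParseError(f"{path}: no sentences found")
    return AnnotatedTranscript(subject_id=subject_id, sentences=tuple(sentences), source=source)


def write_conllu(transcript: AnnotatedTranscript, path: str | Path) -> None:
    """Write a transcript as 10-column CoNLL-U, one blank line per sentence."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subject_id = {transcript.subject_id}\n")
        fh.write(f"# source = {transcript.source}\n")
        for sent in transcript.sentences:
            fh.write(f"# sent_id = {sent.index + 1}\n")
            for i, tok in enumerate(sent.tokens, start=1):
                misc = "|".join(f"{k}={v}" for k, v in tok.misc.items()) or "_"
                fh.write(
                    "\t".join(
                        [
                            str(i),
                            tok.surface,
                            "_",
                            tok.upos,
                            "_",
                            "_",
                            str(tok.head_index),
                            tok.deprel,
                            "_",
                            misc,
                        ]
                    )
                    + "\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# interval tracks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    start: float
    end: float
    kind: str  # {speech, pause}

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(f"interval end {self.end} <= start {self.start}")
        if self.kind not in ("speech", "pause"):
            raise ValidationError(f"interval kind must be speech/pause, got {self.kind!r}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class IntervalTrack:
    """Gap-free, non-overlapping speech/pause tiling of one recording.

    Invariants: intervals sorted, contiguous from 0 to ``total_duration_s``,
    and adjacent intervals never share a kind (same-kind neighbours are merged
    at construction).
    """

    subject_id: str
    intervals: tuple[Interval, ...]
    total_duration_s: float

    def __post_init__(self):
        if not self.intervals:
            raise ValidationError("track must contain at least one interval")
        prev_end = 0.0
        prev_kind = None
        for iv in self.intervals:
            if abs(iv.start - prev_end) > 1e-9:
                raise ValidationError(
                    f"interval starting at {iv.start} not contiguous with previous end {prev_end}"
                )
            if iv.kind == prev_kind:
                raise ValidationError("adjacent intervals share a kind (must be merged)")
            prev_end = iv.end
            prev_kind = iv.kind
        if abs(prev_end - self.total_duration_s) > 1e-9:
            raise ValidationError(
                f"intervals end at {prev_end}, expected total duration {self.total_duration_s}"
            )

    @classmethod
    def from_intervals(
        cls,
        subject_id: str,
        intervals: Iterable[tuple[float, float, str]],
        fill_gaps: bool = True,
    ) -> "IntervalTrack":
        """Build a valid track: sort, reject overlaps, fill gaps as pauses
        (with a warning), merge adjacent same-kind intervals, anchor at 0."""
        items = sorted(intervals, key=lambda t: t[0])
        if not items:
            raise ValidationError("no intervals given")
        filled: list[tuple[float, float, str]] = []
        cursor = 0.0
        for start, end, kind in items:
            if start < cursor - 1e-9:
                raise ValidationError(
                    f"overlapping intervals near t={start:.3f}s for {subject_id}"
                )
            if start > cursor + 1e-9:
                if not fill_gaps:
                    raise ValidationError(f"gap in coverage at t={cursor:.3f}s")
                warnings.warn(
                    f"{subject_id}: gap [{cursor:.3f}, {start:.3f}) filled as pause",
                    stacklevel=2,
                )
                filled.append((cursor, start, "pause"))
            filled.append((start, end, kind))
            cursor = end
        merged: list[list] = []
        for start, end, kind in filled:
            if merged and merged[-1][2] == kind:
                merged[-1][1] = end
            else:
                merged.append([start, end, kind])
        ivs = tuple(Interval(s, e, k) for s, e, k in merged)
        return cls(subject_id=subject_id, intervals=ivs, total_duration_s=ivs[-1].end)

    def pauses(self) -> tuple[Interval, ...]:
        return tuple(iv for iv in self.intervals if iv.kind == "pause")

    def speech(self) -> tuple[Interval, ...]:
        return tuple(iv for iv in self.intervals if iv.kind == "speech")


#: TextGrid labels treated as pauses (case-insensitive), plus the empty label.
_PAUSE_LABELS = {"", "sil", "pause", "sp", "<sil>"}

_TG_NUM = re.compile(r"(?:xmin|xmax)\s*=\s*([-\d.eE+]+)")
_TG_TEXT = re.compile(r'text\s*=\s*"((?:[^"]|"")*)"')


def _read_textgrid(path: Path) -> list[tuple[float, float, str]]:
    """Extract (start, end, kind) triples from the first interval tier of a
    long-format Praat TextGrid."""
    text = path.read_text(encoding="utf-8")
    tier_starts = [m.start() for m in re.finditer(r'"IntervalTier"', text)]
    if not tier_starts:
        raise ParseError(f"{path}: no IntervalTier found")
    tier_text = text[tier_starts[0]: tier_starts[1] if len(tier_starts) > 1 else len(text)]
    out: list[tuple[float, float, str]] = []
    # each "intervals [k]:" block carries xmin, xmax, text
    blocks = re.split(r"intervals\s*\[\d+\]", tier_text)[1:]
    for block in blocks:
        nums = _TG_NUM.findall(block)
        label_m = _TG_TEXT.search(block)
        if len(nums) < 2 or label_m is None:
            raise ParseError(f"{path}: malformed interval block")
        start, end = float(nums[0]), float(nums[1])
        label = label_m.group(1).replace('""', '"').strip().lower()
        kind = "pause" if label in _PAUSE_LABELS else "speech"
        out.append((start, end, kind))
    return out


def read_interval_track(
    path: str | Path, dialect: str = "csv", subject_id: str | None = None
) -> IntervalTrack:
    """Read an interval track from ``csv`` (columns start_s,end_s,kind) or
    ``textgrid`` (first interval tier; empty/"sil"/"pause" labels = pause)."""
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    if dialect == "csv":
        rows: list[tuple[float, float, str]] = []
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"start_s", "end_s", "kind"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ParseError(f"{path}: CSV must have columns start_s,end_s,kind")
            for line_no, row in enumerate(reader, start=2):
                try:
                    rows.append((float(row["start_s"]), float(row["end_s"]), row["kind"].strip()))
                except (TypeError, ValueError):
                    raise ParseError("malformed interval row", line_no) from None
        if not rows:
            raise ParseError(f"{path}: empty interval file")
        return IntervalTrack.from_intervals(subject_id, rows)
    if dialect == "textgrid":
        return IntervalTrack.from_intervals(subject_id, _read_textgrid(path))
    raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'textgrid'")


def write_interval_track(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s", "kind"])
        for iv in track.intervals:
            writer.writerow([f"{iv.start:.6f}", f"{iv.end:.6f}", iv.kind])


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    """One manifest row: group membership, covariates, optional clinical scores."""

    subject_id: str
    group: str
    age: float
    sex: str
    topic: str
    speech_item: float | None = None  # MDS-UPDRS III speech item, 0-4
    clinical_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(
                f"subject {self.subject_id}: unknown group {self.group!r} (expected one of {GROUPS})"
            )
        if self.age <= 0:
            raise ValidationError(f"subject {self.subject_id}: age must be positive")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"subject {self.subject_id}: sex must be M or F")
        if self.topic not in TOPICS:
            raise ValidationError(
                f"subject {self.subject_id}: unknown topic {self.topic!r} (expected one of {TOPICS})"
            )
        if self.speech_item is not None and not (0 <= self.speech_item <= 4):
            raise ValidationError(f"subject {self.subject_id}: speech_item must be in [0, 4]")


_MANIFEST_REQUIRED = ("subject_id", "group", "age", "sex", "topic")


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort manifest CSV.  Columns beyond the required five and
    ``speech_item`` are treated as named clinical scores."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing required columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id(s) in manifest: {dupes}")
    extra = [c for c in df.columns if c not in _MANIFEST_REQUIRED and c != "speech_item"]
    records = []
    for i, row in df.iterrows():
        speech_item = None
        if "speech_item" in df.columns and pd.notna(row["speech_item"]):
            speech_item = float(row["speech_item"])
        scores = {c: float(row[c]) for c in extra if pd.notna(row[c])}
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    topic=str(row["topic"]),
                    speech_item=speech_item,
                    clinical_scores=scores,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"manifest row {i + 2}: {exc}") from None
    return records


def write_manifest(records: Sequence[SubjectRecord], path: str | Path) -> None:
    score_names = sorted({k for r in records for k in r.clinical_scores})
    rows = []
    for r in records:
        row: dict = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "topic": r.topic,
            "speech_item": r.speech_item,
        }
        for name in score_names:
            row[name] = r.clinical_scores.get(name)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def validate_feature_table(table: pd.DataFrame) -> None:
    """Check the feature-table contract: canonical columns, ratio features in
    [0, 1], non-negative speech rate, pause medians >= 0.2 s when present."""
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing}")
    ratio_cols = ["content_words", "function_words", "mattr", "ngram_repetition",
                  "coordinate_clauses"]
    for col in ratio_cols:
        vals = table[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError(f"feature {col} outside [0, 1]")
    if (table["net_speech_rate"].dropna() < 0).any():
        raise ValidationError("net_speech_rate must be >= 0")
    pauses = table["pause_duration"].dropna()
    if (pauses < 0.2 - 1e-12).any():
        raise ValidationError("pause_duration below its 200 ms construction floor")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="subject_id")
    table.index = table.index.astype(str)
    validate_feature_table(table)
    return table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table)
    table.to_csv(path, index_label="subject_id")
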