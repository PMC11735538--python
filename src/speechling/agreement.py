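"""Automated-vs-manual agreement: word error rate, Pearson r and NRMSE.

Automatic speech recognition introduces word-level substitutions, deletions
and insertions relative to a human reference transcript.  This module
quantifies (a) raw transcription accuracy via the word error rate under a
minimum-edit alignment, and (b) downstream robustness: how well each
extracted feature agrees between the automated and manual analysis arms
(Pearson correlation and root-mean-square error normalized by the mean of
the manual values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import FEATURE_NAMES, AnnotatedTranscript

__all__ = [
    "AlignmentCounts",
    "tokenize_for_wer",
    "word_error_rate",
    "transcript_wer",
    "feature_agreement",
    "robustness_report",
]


@dataclass(frozen=True)
class AlignmentCounts:
    """Edit-operation tally of a reference/hypothesis alignment."""

    substitutions: int
    deletions: int
    insertions: int
    matches: int
    reference_length: int

    def __post_init__(self):
        if min(self.substitutions, self.deletions, self.insertions, self.matches) < 0:
            raise ValueError("alignment counts must be non-negative")
        if self.matches + self.substitutions + self.deletions != self.reference_length:
            raise ValueError("matches + substitutions + deletions must equal reference length")


_PUNCT_STRIP = str.maketrans("", "", r"""!"#$%&'()*+,-./:;<=>?@[\]^_`{|}~«»„“”‚‘’…""")


def tokenize_for_wer(text: str) -> list[str]:
    """Whitespace-split, case-fold, strip punctuation; drops emptied tokens."""
    out = []
    for raw in text.split():
        w = raw.casefold().translate(_PUNCT_STRIP)
        if w:
            out.append(w)
    return out


def word_error_rate(
    reference: Sequence[str], hypothesis: Sequence[str]
) -> tuple[float, AlignmentCounts]:
    """WER = (S + D + I) / |reference| under a unit-cost minimum-edit alignment.

    Ties between alignments of equal cost are broken by preferring matches,
    then substitutions, then deletions, then insertions during backtrace.
    Can exceed 1 when the hypothesis inserts more words than the reference
    holds.  Raises on an empty reference.
    """
    ref = list(reference)
    hyp = list(hypothesis)
    if not ref:
        raise ValueError("reference transcript must be non-empty")
    n, m = len(ref), len(hyp)
    # D[i, j] = min edits aligning ref[:i] with hyp[:j]
    D = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        ri = ref[i - 1]
        row = D[i]
        prev = D[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (ri != hyp[j - 1])
            dele = prev[j] + 1
            ins = row[j - 1] + 1
            row[j] = min(sub, dele, ins)
    s = d = ins_count = match = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            if ref[i - 1] == hyp[j - 1]:
                match += 1
            else:
                s += 1
            i -= 1
            j -= 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            d += 1
            i -= 1
        else:
            ins_count += 1
            j -= 1
    counts = AlignmentCounts(
        substitutions=s,
        deletions=d,
        insertions=ins_count,
        matches=match,
        reference_length=n,
    )
    return (s + d + ins_count) / n, counts


def transcript_wer(
    reference: AnnotatedTranscript, hypothesis: AnnotatedTranscript
) -> tuple[float, AlignmentCounts]:
    """WER between two annotated transcripts' word sequences (case-folded,
    punctuation tokens dropped)."""
    ref = [t.surface.casefold() for t in reference.iter_words()]
    hyp = [t.surface.casefold() for t in hypothesis.iter_words()]
    return word_error_rate(ref, hyp)


def feature_agreement(auto: pd.DataFrame, manual: pd.DataFrame) -> pd.DataFrame:
    """Per-feature agreement between automated and manual feature tables.

    Returns a DataFrame indexed by feature with columns ``pearson_r``,
    ``nrmse``, ``n`` and ``note``.  Pairs with a missing value on either
    side are dropped per feature; fewer than 3 complete pairs, a zero-variance
    side (r undefined) or a zero manual mean (NRMSE undefined) yield NaN with
    an explanatory note.
    """
    common = auto.index.intersection(manual.index)
    rows = []
    for feat in FEATURE_NAMES:
        if feat not in auto.columns or feat not in manual.columns:
            continue
        a = auto.loc[common, feat].astype(float)
        m = manual.loc[common, feat].astype(float)
        ok = a.notna() & m.notna()
        a, m = a[ok].to_numpy(), m[ok].to_numpy()
        n = len(a)
        note = ""
        r = np.nan
        nrmse = np.nan
        if n < 3:
            note = "fewer than 3 complete pairs"
        else:
            if np.std(a) == 0 or np.std(m) == 0:
                note = "zero variance; r undefined"
            else:
                r = float(stats.pearsonr(a, m).statistic)
            rmse = float(np.sqrt(np.mean((a - m) ** 2)))
            mean_manual = float(np.mean(m))
            if mean_manual == 0:
                note = (note + "; " if note else "") + "zero manual mean; NRMSE undefined"
            else:
                nrmse = rmse / mean_manual
        rows.append({"feature": feat, "pearson_r": r, "nrmse": nrmse, "n": n, "note": note})
    return pd.DataFrame(rows).set_index("feature")


def robustness_report(
    auto_features: pd.DataFrame,
    manual_features: pd.DataFrame,
    wer_by_subject: pd.Series | None = None,
) -> pd.DataFrame:
    """Feature-agreement table augmented with the mean WER of the compared
    transcripts, for reporting robustness of each feature to ASR errors."""
    report = feature_agreement(auto_features, manual_features)
    if wer_by_subject is not None:
        report["mean_wer"] = float(np.mean(wer_by_subject))
    return report
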