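"""End-to-end glue: directory loading and subjects x features extraction."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acoustic import SyllabifierConfig, DEFAULT_SYLLABIFIER, extract_acoustic_features
from .data_model import (
    FEATURE_NAMES,
    AnnotatedTranscript,
    IntervalTrack,
    SubjectRecord,
    read_conllu,
    read_interval_track,
    read_manifest,
)
from .lexsyn import DEFAULT_SCHEME, WordClassScheme, extract_linguistic_features

__all__ = ["extract_feature_table", "load_transcript_dir", "load_track_dir", "load_cohort_dir"]

log = logging.getLogger("speechling")


def extract_feature_table(
    transcripts: Mapping[str, AnnotatedTranscript],
    tracks: Mapping[str, IntervalTrack] | None = None,
    scheme: WordClassScheme = DEFAULT_SCHEME,
    window_size: int = 84,
    syllabifier: SyllabifierConfig = DEFAULT_SYLLABIFIER,
    include_boundary_pauses: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row of the 8 canonical features per subject.

    Returns ``(values, flags)``: two DataFrames indexed by subject_id, the
    second holding per-cell provenance strings (missing reasons, quality
    flags such as ``short_text``) for every cell that has one.  Subjects
    without a track get missing acoustic features, with a warning.
    """
    rows, flag_rows = {}, {}
    for sid, transcript in transcripts.items():
        feats = extract_linguistic_features(transcript, scheme, window_size)
        track = tracks.get(sid) if tracks else None
        if track is not None:
            feats.update(extract_acoustic_features(
                track, transcript, cfg=syllabifier,
                include_boundary_pauses=include_boundary_pauses,
            ))
        else:
            log.warning("subject %s: no interval track; acoustic features missing", sid)
        row, frow = {}, {}
        for name in FEATURE_NAMES:
            fv = feats.get(name)
            if fv is None:
                row[name] = np.nan
                frow[name] = "no track"
                continue
            row[name] = np.nan if fv.value is None else fv.value
            notes = list(fv.flags)
            if fv.reason:
                notes.append(fv.reason)
                log.info("subject %s: %s missing (%s)", sid, name, fv.reason)
            frow[name] = ";".join(notes)
        rows[sid] = row
        flag_rows[sid] = frow
    values = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]
    flags = pd.DataFrame.from_dict(flag_rows, orient="index")[list(FEATURE_NAMES)]
    values.index.name = flags.index.name = "subject_id"
    return values, flags


def load_transcript_dir(path: str | Path, source: str = "automated") -> dict[str, AnnotatedTranscript]:
    """All ``*.conllu`` files of a directory, keyed by file stem."""
    path = Path(path)
    out = {}
    for f in sorted(path.glob("*.conllu")):
        out[f.stem] = read_conllu(f, source=source)
    return out


def load_track_dir(path: str | Path) -> dict[str, IntervalTrack]:
    """All ``*.csv`` / ``*.TextGrid`` interval tracks of a directory."""
    path = Path(path)
    out = {}
    for f in sorted(path.glob("*.csv")):
        out[f.stem] = read_interval_track(f, dialect="csv")
    for f in sorted(path.glob("*.TextGrid")):
        out[f.stem] = read_interval_track(f, dialect="textgrid")
    return out


def load_cohort_dir(
    path: str | Path,
) -> tuple[list[SubjectRecord], dict[str, AnnotatedTranscript],
           dict[str, AnnotatedTranscript], dict[str, IntervalTrack]]:
    """Load a cohort directory in the :func:`speechling.synthetic.write_cohort`
    layout: (records, manual transcripts, automated transcripts, tracks)."""
    path = Path(path)
    records = read_manifest(path / "manifest.csv")
    manual = load_transcript_dir(path / "conllu_manual", source="manual") \
        if (path / "conllu_manual").is_dir() else {}
    automated = load_transcript_dir(path / "conllu_automated", source="automated") \
        if (path / "conllu_automated").is_dir() else {}
    tracks = load_track_dir(path / "tracks") if (path / "tracks").is_dir() else {}
    return records, manual, automated, tracks
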