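"""Pause-timing acoustics: net speech rate and median prolonged-pause length.

Both features are computed from an :class:`~speechling.data_model.IntervalTrack`
(a speech/pause tiling of the recording) plus a syllable total:

* **net speech rate** (syllables/s): syllable count divided by the recording
  time remaining after removing every pause *longer than* 30 ms — an
  articulation-rate measure insensitive to how long the speaker pauses;
* **duration of pause interval** (s): the median length of pauses *at least*
  200 ms long — shorter gaps are articulatory, not cognitive-linguistic.

The 30 ms threshold is strict (>), the 200 ms threshold inclusive (>=).

Syllable counting is pluggable: a deterministic vowel-nucleus counter (with
syllabic-liquid handling for Czech-style consonant clusters) is the default;
a hyphenation dictionary can be plugged in as a callable.  An optional
RMS-energy segmenter turns a mono waveform into an interval track for users
without a pause annotation; it is a plain baseline, not a tuned VAD.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .data_model import AnnotatedTranscript, IntervalTrack
from .lexsyn import FeatureValue

__all__ = [
    "SyllabifierConfig",
    "syllable_count",
    "transcript_syllable_count",
    "net_speech_rate",
    "pause_interval_duration",
    "segment_energy",
    "extract_acoustic_features",
]

#: Threshold above which a pause stops counting as speech time (strict).
NET_RATE_PAUSE_FLOOR_S = 0.030
#: Minimum length for a pause to enter the prolonged-pause median (inclusive).
PAUSE_MEDIAN_FLOOR_S = 0.200

_VOWELS = set("aeiouyáéěíóúůàâäæãåèêëìîïòôöøõùûü")


@dataclass(frozen=True)
class SyllabifierConfig:
    """How to count syllables in a word.

    ``vowel_nucleus`` counts maximal vowel groups, plus syllabic liquids
    (default r/l, as in Czech "vlk", "krk") trapped between consonants.
    ``hyphenation_dictionary`` delegates to ``hyphenator``, a callable
    returning the hyphenation pieces of a word.
    """

    mode: str = "vowel_nucleus"  # {vowel_nucleus, hyphenation_dictionary}
    language: str = "cs"
    extra_nuclei: frozenset[str] = frozenset({"r", "l"})
    hyphenator: Callable[[str], Sequence[str]] | None = None

    def __post_init__(self):
        if self.mode not in ("vowel_nucleus", "hyphenation_dictionary"):
            raise ValueError(f"unknown syllabifier mode {self.mode!r}")
        if not self.language:
            raise ValueError("language must be non-empty")
        if self.mode == "hyphenation_dictionary" and self.hyphenator is None:
            raise ValueError("hyphenation_dictionary mode requires a hyphenator callable")


DEFAULT_SYLLABIFIER = SyllabifierConfig()


def syllable_count(word: str, cfg: SyllabifierConfig = DEFAULT_SYLLABIFIER) -> int:
    """Number of syllables in one word, always >= 1.

    Raises ``ValueError`` for input with no alphabetic characters.
    """
    stripped = "".join(ch for ch in word if ch.isalpha())
    if not stripped:
        raise ValueError(f"cannot syllabify non-alphabetic input {word!r}")
    if cfg.mode == "hyphenation_dictionary":
        pieces = cfg.hyphenator(stripped)  # type: ignore[misc]
        return max(1, len(pieces))
    w = stripped.casefold()
    count = 0
    prev_vowel = False
    for i, ch in enumerate(w):
        if ch in _VOWELS:
            if not prev_vowel:
                count += 1
            prev_vowel = True
        else:
            # syllabic liquid: r/l with no adjacent vowel on either side
            if ch in cfg.extra_nuclei:
                left_v = i > 0 and w[i - 1] in _VOWELS
                right_v = i + 1 < len(w) and w[i + 1] in _VOWELS
                if not left_v and not right_v:
                    count += 1
            prev_vowel = False
    return max(1, count)


def transcript_syllable_count(
    t: AnnotatedTranscript, cfg: SyllabifierConfig = DEFAULT_SYLLABIFIER
) -> int:
    """Total syllables over all words of a transcript.

    A token carrying a stored ``Syllables`` MISC value (synthetic transcripts
    store the drawn count there) uses it directly; otherwise the word is
    syllabified with ``cfg``.  Non-alphabetic words fall back to 1 syllable.
    """
    total = 0
    for tok in t.iter_words():
        if "Syllables" in tok.misc:
            total += int(tok.misc["Syllables"])
            continue
        try:
            total += syllable_count(tok.surface, cfg)
        except ValueError:
            total += 1
    return total


def net_speech_rate(track: IntervalTrack, total_syllables: int) -> FeatureValue:
    """Syllables per second of net speech time.

    Net time = total duration minus every pause longer than 30 ms.  Raises
    if the net time is non-positive (a track that is all pause).
    """
    if total_syllables < 1:
        raise ValueError("total_syllables must be >= 1")
    # strict threshold with a 1 ns guard so an exactly-30 ms pause expressed
    # in floats is not excluded by representation error
    removed = sum(
        iv.duration
        for iv in track.pauses()
        if iv.duration > NET_RATE_PAUSE_FLOOR_S + 1e-9
    )
    net = track.total_duration_s - removed
    if net <= 0:
        raise ValueError(f"{track.subject_id}: net speech time is non-positive")
    return FeatureValue(total_syllables / net)


def pause_interval_duration(
    track: IntervalTrack, include_boundary_pauses: bool = True
) -> FeatureValue:
    """Median duration of pauses >= 200 ms; missing if there are none.

    ``include_boundary_pauses=False`` drops pauses touching the start or end
    of the recording (leading/trailing silence rather than a within-speech
    gap).
    """
    pauses = track.pauses()
    if not include_boundary_pauses:
        pauses = tuple(
            iv
            for iv in pauses
            if iv.start > 1e-9 and iv.end < track.total_duration_s - 1e-9
        )
    durations = [iv.duration for iv in pauses if iv.duration >= PAUSE_MEDIAN_FLOOR_S - 1e-12]
    if not durations:
        return FeatureValue(None, reason="no pause >= 200 ms")
    return FeatureValue(statistics.median(durations))


def segment_energy(
    samples: np.ndarray,
    sample_rate: int,
    frame_ms: float = 10.0,
    threshold_db: float = -35.0,
    min_pause_ms: float = 30.0,
    subject_id: str = "signal",
) -> IntervalTrack:
    """Baseline energy-threshold speech/pause segmentation of a mono waveform.

    Frame RMS energy (dB re. full scale of the signal's peak) below
    ``threshold_db`` marks silence; silent runs shorter than ``min_pause_ms``
    are absorbed into speech.  Output tiles [0, duration) exactly.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty signal")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    frame_len = max(1, int(round(sample_rate * frame_ms / 1000.0)))
    n_frames = int(np.ceil(x.size / frame_len))
    padded = np.zeros(n_frames * frame_len)
    padded[: x.size] = x
    frames = padded.reshape(n_frames, frame_len)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    peak = rms.max()
    if peak <= 0:
        loud = np.zeros(n_frames, dtype=bool)
    else:
        with np.errstate(divide="ignore"):
            db = 20 * np.log10(np.maximum(rms, 1e-12) / peak)
        loud = db > threshold_db
    # frame flags -> runs
    duration = x.size / sample_rate
    frame_s = frame_len / sample_rate
    intervals: list[tuple[float, float, str]] = []
    start = 0
    for i in range(1, n_frames + 1):
        if i == n_frames or loud[i] != loud[start]:
            t0 = start * frame_s
            t1 = min(i * frame_s, duration)
            kind = "speech" if loud[start] else "pause"
            if t1 > t0:
                intervals.append((t0, t1, kind))
            start = i
    # absorb sub-threshold silences into speech
    min_pause_s = min_pause_ms / 1000.0
    has_speech = any(k == "speech" for _, _, k in intervals)
    if has_speech:
        intervals = [
            (t0, t1, "speech" if (k == "pause" and (t1 - t0) < min_pause_s) else k)
            for t0, t1, k in intervals
        ]
    return IntervalTrack.from_intervals(subject_id, intervals)


def extract_acoustic_features(
    track: IntervalTrack,
    transcript: AnnotatedTranscript | None = None,
    total_syllables: int | None = None,
    cfg: SyllabifierConfig = DEFAULT_SYLLABIFIER,
    include_boundary_pauses: bool = True,
) -> dict[str, FeatureValue]:
    """Both acoustic features keyed by canonical feature name.

    Syllables come from ``total_syllables`` if given, else from the
    transcript (mirroring the automated/manual duality: each analysis arm
    counts syllables from its own word sequence).
    """
    if total_syllables is None:
        if transcript is None:
            raise ValueError("need either total_syllables or a transcript")
        total_syllables = transcript_syllable_count(transcript, cfg)
    try:
        rate = net_speech_rate(track, total_syllables)
    except ValueError as exc:
        rate = FeatureValue(None, reason=str(exc))
    return {
        "net_speech_rate": rate,
        "pause_duration": pause_interval_duration(
            track, include_boundary_pauses=include_boundary_pauses
        ),
    }
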