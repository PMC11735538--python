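"""Extract the 8 speech features from one synthetic subject.

Builds a single annotated monologue plus its speech/pause track, runs the
six lexical/syntactic extractors and the two pause-timing extractors, and
prints each value.  The ratios live in [0, 1]; mlu is words per sentence;
net_speech_rate is syllables per second of pause-free speech; pause_duration
is the median prolonged (>= 200 ms) pause in seconds.
"""

from speechling import (
    GroupParams,
    extract_linguistic_features,
    generate_track,
    generate_transcript,
)
from speechling.acoustic import extract_acoustic_features

params = GroupParams()  # healthy-control defaults: ~226-word monologue
transcript = generate_transcript(params, "demo", rng=7)
track = generate_track(params, transcript, rng=8)

print(f"{transcript.word_count} words in {len(transcript.sentences)} sentences, "
      f"{track.total_duration_s:.1f} s of audio\n")

features = extract_linguistic_features(transcript)
features.update(extract_acoustic_features(track, transcript))
for name, fv in features.items():
    note = f"  [{';'.join(fv.flags)}]" if fv.flags else ""
    print(f"{name:>18}: {fv.value:.4f}{note}")
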