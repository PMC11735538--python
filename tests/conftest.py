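import numpy as np
import pytest

from speechling import AnnotatedTranscript, Sentence, Token


def make_sentence(specs, index=0):
    """Build a Sentence from (surface, upos[, deprel, head]) tuples."""
    tokens = []
    for spec in specs:
        surface, upos = spec[0], spec[1]
        deprel = spec[2] if len(spec) > 2 else "dep"
        head = spec[3] if len(spec) > 3 else 0
        tokens.append(Token(surface=surface, upos=upos, deprel=deprel, head_index=head))
    return Sentence(tuple(tokens), index=index)


def make_transcript(sentence_specs, subject_id="s1", source="manual"):
    sentences = tuple(
        make_sentence(specs, index=i) for i, specs in enumerate(sentence_specs)
    )
    return AnnotatedTranscript(subject_id=subject_id, sentences=sentences, source=source)


def words_transcript(words, subject_id="s1"):
    """Transcript of one sentence of NOUN tokens with the given surfaces."""
    return make_transcript([[(w, "NOUN") for w in words]], subject_id=subject_id)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12/12/12 default-parameter cohort shared across tests."""
    from speechling import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(n_per_group=12, seed=42))
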