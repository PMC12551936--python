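import numpy as np
import pytest

from convoscreen import (
    ClassSpec,
    Dataset,
    ErrorInjection,
    Segment,
    Transcript,
    generate_dataset,
)
from convoscreen.synth import DEFAULT_SPECS


@pytest.fixture
def simple_transcript() -> Transcript:
    """Two-speaker transcript with explicit start/end timestamps."""
    return Transcript(
        id="t1",
        segments=[
            Segment("therapist", start_s=0.0, end_s=5.0, text="How are you feeling today"),
            Segment("client", start_s=6.0, end_s=16.0,
                    text="I have been anxious about work and my sleep has been bad"),
            Segment("therapist", start_s=18.0, end_s=30.0,
                    text="Let us talk about some coping strategies for that anxiety"),
        ],
    )


@pytest.fixture
def single_ts_transcript() -> Transcript:
    """Single-timestamp dialect: only end times known."""
    return Transcript(
        id="t2",
        segments=[
            Segment("A", end_s=5.0, text="hello there"),
            Segment("A", end_s=10.0, text="still here"),
            Segment("B", end_s=20.0, text="yes I hear you"),
        ],
    )


@pytest.fixture(scope="session")
def mixed_dataset():
    """Seeded synthetic dataset covering all five classes, plus its labels."""
    dataset, labels = generate_dataset(
        {"session": 20, "case_management": 8, "answering_machine": 8, "noise": 8, "informal": 8},
        seed=202,
    )
    return dataset, labels


@pytest.fixture(scope="session")
def session_lm():
    """Bigram model trained on a disjoint set of session fixtures."""
    from convoscreen import train_ngram_lm, transcript_corpus

    train, _ = generate_dataset({"session": 20}, seed=77)
    return train_ngram_lm(transcript_corpus(list(train)), order=2, alpha=0.1)
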