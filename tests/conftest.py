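import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from phenonet.corpus import AnnotatedSentence, EntitySpan, RelationAnnotation, tokenize


def make_sentence(
    text: str,
    spans: list[tuple[str, int, int]] = (),
    relations: list[tuple[str, int, int, int]] = (),
    sid: str = "s1",
) -> AnnotatedSentence:
    sent = AnnotatedSentence(
        id=sid,
        text=text,
        tokens=tokenize(text),
        spans=[EntitySpan(c, a, b, text[a:b]) for c, a, b in spans],
        relations=[RelationAnnotation(t, s, o, l) for t, s, o, l in relations],
    )
    sent.validate()
    return sent


@pytest.fixture
def strain_sentence() -> AnnotatedSentence:
    text = "Strain X33 grows on LB and produces nisin."
    return make_sentence(
        text,
        spans=[
            ("STRAIN", 7, 10),
            ("MEDIUM", 20, 22),
            ("COMPOUND", 36, 41),
        ],
        relations=[("GROWS_ON", 0, 1, 1), ("PRODUCES", 0, 2, 1)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_spans(rng, n_tokens: int, max_spans: int = 4) -> list[tuple[int, int]]:
    """Random non-degenerate token-extent spans on a sentence of n_tokens."""
    spans = []
    for _ in range(int(rng.integers(0, max_spans + 1))):
        a = int(rng.integers(0, n_tokens))
        b = int(rng.integers(a + 1, n_tokens + 1))
        spans.append((a, b))
    return spans
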