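import numpy as np
import pytest

from volspan import (
    AnnotatedCorpus,
    Category,
    GeneratorConfig,
    Report,
    SpanAnnotation,
    generate_corpus,
    tokenize,
)

WORDS = [
    "no", "the", "is", "of", "atrophy", "volume", "loss", "hippocampal",
    "global", "regional", "normal", "mild", "severe", "brain", "seen",
    "there", "lobar", "preserved", "widening", "sulci",
]


def random_report(rng: np.random.Generator, report_id: str, sources=("gold",)) -> Report:
    """A random but valid report: random prose, random in-range spans."""
    n_words = int(rng.integers(1, 30))
    parts = []
    for _ in range(n_words):
        w = WORDS[rng.integers(len(WORDS))]
        if rng.random() < 0.15:
            w += "."
        parts.append(w)
    text = " ".join(parts)
    tokens = tokenize(text)
    sets = {}
    for source in sources:
        spans = set()
        for _ in range(int(rng.integers(0, 6))):
            start = int(rng.integers(0, len(tokens)))
            end = int(rng.integers(start + 1, min(start + 8, len(tokens)) + 1))
            label = list(Category)[rng.integers(6)]
            spans.add(SpanAnnotation(start, end, label))
        sets[source] = spans
    return Report(report_id, text, tokens, sets)


def random_corpus(rng: np.random.Generator, n_reports: int, sources=("gold",)) -> AnnotatedCorpus:
    return AnnotatedCorpus(
        [random_report(rng, f"r{i:03d}", sources) for i in range(n_reports)]
    )


def random_span_set(rng: np.random.Generator, n_tokens: int, max_spans: int) -> set[SpanAnnotation]:
    spans = set()
    for _ in range(int(rng.integers(0, max_spans + 1))):
        start = int(rng.integers(0, n_tokens))
        end = int(rng.integers(start + 1, min(start + 6, n_tokens) + 1))
        spans.add(SpanAnnotation(start, end, list(Category)[rng.integers(6)]))
    return spans


@pytest.fixture(scope="session")
def cohort_corpus():
    """Default-configuration synthetic cohort at full size (generated once)."""
    return generate_corpus(GeneratorConfig(n_reports=4007, seed=20260930))


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(GeneratorConfig(n_reports=40, seed=11))
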