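"""Shared fixtures and deterministic hypothesis configuration."""

from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

import pytest

from ppimine import Document, EntityAnnotation, load_term_lists


@pytest.fixture(scope="session")
def term_lists():
    return load_term_lists()


def make_doc(doc_id: str, title: str, abstract: str) -> Document:
    return Document(doc_id, title, abstract).segment()


def gene(doc, surface, norm_id, source="task", occurrence=0):
    """Gene annotation located at the n-th occurrence of ``surface``."""
    start = -1
    for _ in range(occurrence + 1):
        start = doc.text.index(surface, start + 1)
    return EntityAnnotation(
        doc.doc_id, start, start + len(surface), surface, "Gene", norm_id, source
    )
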