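from __future__ import annotations

from datetime import date

import pytest

from rdocnlp.dictionaries import (Dictionary, KeywordEntry, SentenceEntry,
                                  load_starter_dictionary)
from rdocnlp.domains import RdocDomain
from rdocnlp.embedding import make_test_backend
from rdocnlp.preprocess import ClinicalNote
from rdocnlp.synthetic import SimulationConfig, generate


@pytest.fixture(scope="session")
def starter():
    return load_starter_dictionary()


@pytest.fixture(scope="session")
def backend():
    return make_test_backend(dimension=512, seed=0)


@pytest.fixture
def tiny_dictionary():
    """Two-domain toy dictionary: one stress sentence, one sleep sentence."""
    return Dictionary(
        keywords=(
            KeywordEntry("stress", frozenset({RdocDomain.NEGATIVE_VALENCE})),
            KeywordEntry("sleep", frozenset({RdocDomain.AROUSAL_REGULATORY})),
        ),
        sentences=(
            SentenceEntry("s1", "Patient is stressed and refuses psychotherapy",
                          frozenset({RdocDomain.NEGATIVE_VALENCE})),
            SentenceEntry("s2", "Patient sleeps poorly most nights",
                          frozenset({RdocDomain.AROUSAL_REGULATORY})),
        ),
        version="toy-1",
    )


@pytest.fixture
def note_factory():
    def make(text: str, note_id: str = "n1", patient_id: str = "p1",
             when: date = date(2015, 6, 1)) -> ClinicalNote:
        return ClinicalNote(patient_id=patient_id, note_id=note_id,
                            date=when, text=text)
    return make


@pytest.fixture(scope="session")
def small_corpus(starter):
    """~200-note synthetic corpus with gold labels (fixed seed)."""
    return generate(SimulationConfig(seed=7, n_patients=70), starter)
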