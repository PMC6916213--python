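from __future__ import annotations

import datetime

import numpy as np
import pytest

from copdatlas import preprocess as pp
from copdatlas import synthetic_corpus as syn
from copdatlas.corpus_io import DeathRecord, NoteDocument
from copdatlas.progression_model import LSTMWeights


@pytest.fixture(scope="session")
def small_corpus() -> syn.SyntheticCorpus:
    """A 30-patient, 3-stage corpus shared by read-only tests."""
    cfg = syn.SyntheticConfig(n_patients=30, seed=42)
    return syn.generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_samples(small_corpus):
    vocab = pp.build_vocab((n.text for n in small_corpus.notes), 300)
    spec = pp.WindowLabelSpec(window_days=30, n_classes=6)
    samples = pp.make_samples(
        small_corpus.notes, small_corpus.death_dates, vocab, spec, max_len=60
    )
    return vocab, spec, samples


@pytest.fixture
def toy_notes() -> list[NoteDocument]:
    day = datetime.date(2016, 3, 1)
    return [
        NoteDocument("p1", day, "radiology", "Lungs hyperinflated."),
        NoteDocument("p1", day, "pulmonary", "Severe obstruction, FEV1 reduced."),
        NoteDocument("p1", day, "cardiology", "Sinus tachycardia 127 bpm."),
    ]


@pytest.fixture
def toy_deaths() -> list[DeathRecord]:
    return [DeathRecord("p1", datetime.date(2016, 6, 1))]


def zero_lstm_weights(L: int, v: int) -> LSTMWeights:
    z = np.zeros
    return LSTMWeights(
        W_hi=z((L, L)), W_hf=z((L, L)), W_ho=z((L, L)), W_hg=z((L, L)),
        W_xi=z((v, L)), W_xf=z((v, L)), W_xo=z((v, L)), W_xg=z((v, L)),
        b_i=z(L), b_f=z(L), b_o=z(L), b_g=z(L),
    )


def weights_from_dict(w: dict) -> LSTMWeights:
    """Convert a scalar-oracle weight dict to the vectorized container."""
    arr = {k: np.array(v, dtype=float) for k, v in w.items()}
    return LSTMWeights(**arr)
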