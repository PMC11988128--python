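"""Shared fixtures: small seeded corpora and prepared folds."""

import numpy as np
import pytest

from hanrisk.cohort import prepare_documents, stratified_split
from hanrisk.embeddings import train_embeddings
from hanrisk.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_separable_corpus():
    """300 patients, balanced-ish, perfectly separable planted signal."""
    cfg = GeneratorConfig(n_patients=300, prevalence=0.5, seed=101,
                          signal_rate_case=1.0, signal_rate_control=0.0,
                          vocab_size_background=300)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_folds(small_separable_corpus):
    docs = prepare_documents(small_separable_corpus)
    split = stratified_split(docs, seed=7)
    folds = {name: [d for d in docs
                    if split.assignment[d.patient_id] == name]
             for name in ("train", "tune", "test")}
    return docs, split, folds


@pytest.fixture(scope="session")
def small_embedding(small_folds):
    _, _, folds = small_folds
    return train_embeddings(folds["train"], dim=16, window=4, min_count=2,
                            epochs=5, seed=5)


@pytest.fixture(scope="session")
def big_corpus():
    """10k patients at study-like prevalence for marginal checks."""
    cfg = GeneratorConfig(n_patients=10_000, prevalence=0.0039, seed=42,
                          vocab_size_background=500,
                          visits_per_patient=(4.0, 4.0),
                          words_per_field=(3.0,))
    return generate_corpus(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
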