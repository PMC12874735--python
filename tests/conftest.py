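import numpy as np
import pytest

from raslit import (Corpus, Document, GeneDictionary, LabelMatrix,
                    PathwayRegistry, ScoreMatrix)


@pytest.fixture
def tiny_registry():
    return PathwayRegistry(
        pathway_ids=["RAS", "RS", "HCM"],
        branch_map={"RAS": "hypertension", "RS": "hypertension",
                    "HCM": "cardiac"},
    )


@pytest.fixture
def tiny_corpus():
    return Corpus(documents=[
        Document("d1", "Renin binds the renin receptor in the kidney"),
        Document("d2", "The ACE2 enzyme and angiotensin converting enzyme 2 studies"),
        Document("d3", "Cardiac muscle tissue with no gene mentions at all"),
    ])


@pytest.fixture
def tiny_dictionary(tiny_registry):
    return GeneDictionary(
        entries=[
            ("ACE2", ["ace2", "angiotensin converting enzyme 2"], {"RAS"}),
            ("REN", ["renin"], {"RAS", "RS"}),
            ("MYH7", ["myosin heavy chain 7"], {"HCM"}),
        ],
        registry=tiny_registry,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_labels_scores(rng, n_genes=8, n_labels=4):
    """A random truth/score pair where each gene has >= 1 positive label."""
    truth = rng.integers(0, 2, size=(n_genes, n_labels))
    for i in range(n_genes):
        if truth[i].sum() == 0:
            truth[i, rng.integers(0, n_labels)] = 1
    scores = rng.random((n_genes, n_labels))
    return truth, scores


def as_matrices(truth, scores):
    genes = [f"g{i}" for i in range(truth.shape[0])]
    paths = [f"p{j}" for j in range(truth.shape[1])]
    return (LabelMatrix(values=truth, gene_ids=genes, pathway_ids=paths),
            ScoreMatrix(values=scores, gene_ids=genes, pathway_ids=paths))
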