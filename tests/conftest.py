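"""Shared fixtures: synthetic corpora at two scales and toy inputs."""

from __future__ import annotations

import numpy as np
import pytest

from triagecap import (
    Corpus,
    Document,
    FeatureConfig,
    MaskingLexicon,
    SynthConfig,
    build_term_matrix,
    clustering_purity,
    filter_vocabulary,
    generate_corpus,
    select_distinguishing,
    spherical_kmeans,
)

#: Scaled-down generator settings for fast unit/integration tests.
SMALL_SYNTH = dict(
    vocab_size=300,
    n_rel=60,
    n_irr=600,
    k_subtopics=3,
    title_abstract_len=60.0,
    captions_len=120.0,
    n_rel_markers=20,
    n_subtopic_markers=20,
)


@pytest.fixture(scope="session")
def small_corpus():
    """Small 1:10 synthetic corpus with ground truth."""
    return generate_corpus(SynthConfig(seed=2024, **SMALL_SYNTH))


@pytest.fixture(scope="session")
def default_corpus():
    """Full-scale synthetic corpus at the default study conditions."""
    return generate_corpus(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def default_clustering(default_corpus):
    """Full-corpus feature selection and 5-seed cosine K-means (k = number of
    planted sub-topics) on the default synthetic corpus."""
    corpus, truth = default_corpus
    cfg = FeatureConfig()
    tm = build_term_matrix(corpus, config=cfg)
    stats = tm.stats(tm.rows_with_label("relevant"), tm.rows_with_label("irrelevant"))
    selected = select_distinguishing(filter_vocabulary(stats, cfg), cfg.z_threshold)
    irr_rows = tm.rows_with_label("irrelevant")
    V = tm.X[irr_rows][:, tm.columns(selected.terms)].astype(float)
    irr_ids = tm.ids[irr_rows]
    purities = []
    for seed in range(5):
        _, assign = spherical_kmeans(V, len(truth.subtopic_markers), seed=seed)
        purities.append(
            clustering_purity(dict(zip(irr_ids, (int(a) for a in assign))), truth)
        )
    return {"selected": selected, "purities": purities, "truth": truth}


@pytest.fixture()
def separable_corpus():
    """Toy corpus where the term 'xyz' perfectly separates the classes."""
    docs = []
    for i in range(12):
        docs.append(
            Document(
                id=f"r{i}",
                title="xyz study record",
                abstract=f"alpha beta xyz gamma delta case{i}",
                captions=("figure shows xyz pattern",),
                label="relevant",
            )
        )
    for i in range(24):
        docs.append(
            Document(
                id=f"i{i}",
                title="survey of topic record",
                abstract=f"alpha beta gamma delta case{i}",
                captions=("figure shows control pattern",),
                label="irrelevant",
            )
        )
    return Corpus(docs)


@pytest.fixture()
def lexicon():
    return MaskingLexicon(
        {
            "sox2": "PRGE",
            "forebrain": "ANAT",
            "wild type": "MUTN",
            "type": "MUTN",
            "alkaline phosphatase": "ENZI",
        }
    )
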