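"""Stacked meta-classification for imbalanced literature triage.

k base classifiers are trained, one per irrelevant cluster: each learns to
separate the full relevant training set from one topically cohesive
irrelevant subset, using its *own* Z-score feature selection and
probability-interval binning computed on exactly those two document sets.
Every document is then summarized by the k-dimensional vector C of base
relevance probabilities, C_l = Pr(relevant | base classifier l), and a
linear max-margin meta classifier over C assigns the final label.

The base classifiers are ensembles of randomized decision trees (Random
Forests); the meta classifier is a linear-kernel SVM, which keeps the
k-dimensional stacked model interpretable.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .corpus import IRRELEVANT, RELEVANT, Corpus, Document, MaskingLexicon
from .features import (
    BinSet,
    FeatureConfig,
    TermMatrix,
    TermStats,
    bin_terms,
    build_term_matrix,
    filter_vocabulary,
    select_distinguishing,
    vectorize_bins,
)
from .sampling import Partition, choose_k, partition_irrelevant, spherical_kmeans

FORMAT_VERSION = "triagecap-pipeline-1"

ALL_PARTS = ("title", "abstract", "captions")


class TrainingError(RuntimeError):
    """Raised when a training stage cannot proceed."""


class NotFittedError(RuntimeError):
    """Raised when prediction is attempted on an unfitted model."""


@dataclass
class BaseModel:
    """One relevant-vs-cluster classifier with its own feature artifacts."""

    cluster_index: int
    terms: np.ndarray                     # selected distinguishing terms, stats order
    binset: BinSet
    classifier: RandomForestClassifier
    seed: int
    stats: TermStats | None = None        # selected-term stats, kept for explanation
    _term_to_bin: dict | None = field(default=None, repr=False)

    def term_bin_map(self) -> dict[str, int]:
        if self._term_to_bin is None:
            self._term_to_bin = self.binset.term_to_bin()
        return self._term_to_bin

    def _positive_column(self) -> int:
        classes = list(self.classifier.classes_)
        return classes.index(1)

    def score_matrix(self, G: sparse.csr_matrix | np.ndarray) -> np.ndarray:
        """Relevance probability for each row of a bin-vector matrix."""
        proba = self.classifier.predict_proba(G)
        return proba[:, self._positive_column()]

    def bin_matrix(self, tm: TermMatrix) -> sparse.csr_matrix:
        """Bin-vector (G) rows for every document of a term matrix."""
        cols = tm.columns(self.terms)
        mapping = self.term_bin_map()
        n_bins = self.binset.n
        B = sparse.csr_matrix(
            (
                np.ones(len(self.terms), dtype=np.int8),
                (np.arange(len(self.terms)), [mapping[t] for t in self.terms]),
            ),
            shape=(len(self.terms), n_bins),
        )
        G = tm.X[:, cols] @ B
        G.data = np.ones_like(G.data)
        return G.astype(np.float32)

    def top_terms(self, limit: int = 5) -> list[str]:
        """Highest-|Z| distinguishing terms, for explaining decisions."""
        if self.stats is None:
            return list(self.terms[:limit])
        ordered = self.stats.table["z"].abs().sort_values(ascending=False)
        return list(ordered.index[:limit])


def _select_and_bin(stats: TermStats, config: FeatureConfig) -> tuple[TermStats, BinSet]:
    filtered = filter_vocabulary(stats, config)
    selected = select_distinguishing(filtered, config.z_threshold)
    if len(selected) == 0:
        raise TrainingError(
            "no distinguishing terms survive selection; consider lowering "
            f"z_threshold (currently {config.z_threshold}) or the rare-term cutoff"
        )
    binset = bin_terms(selected, config.bin_width)
    return selected, binset


def _fit_base_from_matrix(
    tm: TermMatrix,
    rel_rows: np.ndarray,
    irr_rows: np.ndarray,
    config: FeatureConfig,
    seed: int,
    cluster_index: int,
    n_estimators: int,
) -> BaseModel:
    stats = tm.stats(rel_rows, irr_rows)
    selected, binset = _select_and_bin(stats, config)
    model = BaseModel(
        cluster_index=cluster_index,
        terms=selected.terms,
        binset=binset,
        classifier=None,  # type: ignore[arg-type]
        seed=int(seed),
        stats=selected,
    )
    rows = np.concatenate([rel_rows, irr_rows])
    G = model.bin_matrix(tm)[rows]
    y = np.concatenate([np.ones(len(rel_rows), dtype=np.int64),
                        np.zeros(len(irr_rows), dtype=np.int64)])
    # max_features=1: each split uses one randomly drawn bin feature. Bins
    # aggregate many terms, and greedy split selection overfits bins whose
    # training contrast is a selection artifact; fully randomized splits
    # decorrelate the trees and generalize to out-of-cluster documents.
    # Trees are grown to pure leaves, so the forest probability equals the
    # fraction of trees voting relevant.
    clf = RandomForestClassifier(
        n_estimators=n_estimators, max_features=1,
        random_state=int(seed) % (2**32), n_jobs=1
    )
    clf.fit(G, y)
    model.classifier = clf
    return model


def train_base(
    rel_train: Corpus | Sequence[Document],
    irr_subset: Corpus | Sequence[Document],
    config: FeatureConfig | None = None,
    seed: int = 0,
    parts: Iterable[str] = ALL_PARTS,
    lexicon: MaskingLexicon | None = None,
    n_estimators: int = 100,
    cluster_index: int = 0,
) -> BaseModel:
    """Train one base classifier on a relevant slice vs one irrelevant subset.

    Feature selection (term stats -> vocabulary filtering -> Z selection ->
    binning) runs on these two slices only, so each base model owns a
    self-contained vocabulary and bin set.
    """
    config = config or FeatureConfig()
    rel_docs = list(rel_train)
    irr_docs = list(irr_subset)
    if not rel_docs or not irr_docs:
        raise TrainingError("both training slices must be non-empty")
    relabeled = [Document(d.id, d.title, d.abstract, d.captions, RELEVANT) for d in rel_docs]
    relabeled += [Document(d.id, d.title, d.abstract, d.captions, IRRELEVANT) for d in irr_docs]
    tm = build_term_matrix(Corpus(relabeled), parts, lexicon, config)
    rel_rows = np.arange(len(rel_docs))
    irr_rows = np.arange(len(rel_docs), len(rel_docs) + len(irr_docs))
    return _fit_base_from_matrix(tm, rel_rows, irr_rows, config, seed,
                                 cluster_index, n_estimators)


def score_base(model: BaseModel, doc_terms: set[str]) -> float:
    """Relevance probability of one document (given as a term set)."""
    if model.classifier is None or not hasattr(model.classifier, "classes_"):
        raise NotFittedError("base model is not fitted")
    g = vectorize_bins(doc_terms, model.binset).astype(np.float32).reshape(1, -1)
    return float(model.score_matrix(g)[0])


def build_meta_vector(doc_terms: set[str], models: Sequence[BaseModel]) -> np.ndarray:
    """k-dimensional vector of base relevance probabilities C^d."""
    return np.array([score_base(m, doc_terms) for m in models], dtype=np.float64)


@dataclass
class MetaModel:
    """Linear max-margin discriminant over k-dimensional meta vectors."""

    svc: SVC
    threshold: float = 0.0

    def decision(self, meta_X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(meta_X)

    def predict(self, meta_X: np.ndarray) -> np.ndarray:
        labels = np.where(self.decision(meta_X) > self.threshold, RELEVANT, IRRELEVANT)
        return labels.astype(object)


def train_meta(meta_vectors: np.ndarray, labels: Sequence[str], seed: int = 0,
               C: float = 1.0) -> MetaModel:
    """Fit the linear meta discriminant on stacked base scores."""
    meta_X = np.asarray(meta_vectors, dtype=np.float64)
    y = np.array([1 if lab == RELEVANT else 0 for lab in labels], dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise TrainingError("meta training requires at least one example of each class")
    svc = SVC(kernel="linear", C=C, random_state=int(seed) % (2**32))
    svc.fit(meta_X, y)
    return MetaModel(svc=svc)


@dataclass
class TriagePipeline:
    """Fitted end-to-end triage model: k base models plus the meta model."""

    config: FeatureConfig
    parts: tuple[str, ...]
    lexicon: MaskingLexicon | None
    k: int
    base_models: list[BaseModel]
    meta_model: MetaModel
    vocabulary: dict[str, int]
    partition: Partition
    seeds: dict[str, int]
    n_estimators: int = 100
    format_version: str = FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        payload = {"format_version": self.format_version, "pipeline": self}
        with Path(path).open("wb") as fh:
            pickle.dump(payload, fh, protocol=5)

    @classmethod
    def load(cls, path: str | Path) -> "TriagePipeline":
        with Path(path).open("rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported pipeline format: {payload.get('format_version')!r}")
        return payload["pipeline"]

    def to_bytes(self) -> bytes:
        return pickle.dumps({"format_version": self.format_version, "pipeline": self},
                            protocol=5)


def _derive_seeds(seed: int) -> tuple[int, int, int, np.random.Generator]:
    rng = np.random.default_rng(seed)
    split_seed, kmeans_seed, meta_seed = (int(s) for s in rng.integers(2**31, size=3))
    return split_seed, kmeans_seed, meta_seed, rng


def _train_from_matrix(
    tm: TermMatrix,
    rows: np.ndarray,
    config: FeatureConfig,
    parts: tuple[str, ...],
    lexicon: MaskingLexicon | None,
    k_override: int | None,
    seed: int,
    n_estimators: int,
) -> TriagePipeline:
    labels = tm.labels[rows]
    rel_rows = rows[labels == RELEVANT]
    irr_rows = rows[labels == IRRELEVANT]
    if len(rel_rows) == 0 or len(irr_rows) == 0:
        raise TrainingError("training corpus must contain both classes")
    split_seed, kmeans_seed, meta_seed, rng = _derive_seeds(seed)

    # stratified 75/25 split into base-training and meta-training documents
    base_rows, meta_rows = train_test_split(
        rows, test_size=0.25, random_state=split_seed % (2**32), stratify=labels
    )
    base_labels = tm.labels[base_rows]
    base_rel = base_rows[base_labels == RELEVANT]
    base_irr = base_rows[base_labels == IRRELEVANT]

    # feature selection over the full training set -> term vectors V
    full_stats = tm.stats(rel_rows, irr_rows)
    full_selected, _ = _select_and_bin(full_stats, config)
    v_cols = tm.columns(full_selected.terms)

    k = choose_k(len(rel_rows), len(irr_rows), k_override)
    V_irr = tm.X[base_irr][:, v_cols].astype(np.float64)
    cluster_model, assignments = spherical_kmeans(V_irr, k, seed=kmeans_seed)
    sims = _assignment_similarities(V_irr, cluster_model.centroids, assignments)
    base_irr_ids = tm.ids[base_irr]
    id_to_row = {tm.ids[r]: r for r in base_irr}
    partition = _partition_from_ids(base_irr_ids, assignments, k, sims)

    base_seeds = [int(s) for s in rng.integers(2**31, size=k)]
    base_models: list[BaseModel] = []
    for j, subset_ids in enumerate(partition.subsets):
        subset_rows = np.array([id_to_row[i] for i in subset_ids], dtype=np.int64)
        base_models.append(
            _fit_base_from_matrix(tm, base_rel, subset_rows, config, base_seeds[j],
                                  cluster_index=j, n_estimators=n_estimators)
        )

    meta_X = _meta_matrix(tm, base_models)[meta_rows]
    meta_model = train_meta(meta_X, tm.labels[meta_rows], seed=meta_seed)

    return TriagePipeline(
        config=config,
        parts=parts,
        lexicon=lexicon,
        k=k,
        base_models=base_models,
        meta_model=meta_model,
        vocabulary={t: i for i, t in enumerate(tm.vocab)},
        partition=partition,
        seeds={"master": int(seed), "split": split_seed, "kmeans": kmeans_seed,
               "meta": meta_seed, **{f"base_{j}": s for j, s in enumerate(base_seeds)}},
        n_estimators=n_estimators,
    )


def _assignment_similarities(V: sparse.csr_matrix, centroids: np.ndarray,
                             assignments: np.ndarray) -> np.ndarray:
    norms = np.sqrt(np.asarray(V.multiply(V).sum(axis=1)).ravel())
    scale = np.where(norms > 0, norms, 1.0)
    Vn = sparse.diags(1.0 / scale) @ V
    S = np.asarray(Vn @ centroids.T)
    return S[np.arange(V.shape[0]), assignments]


def _partition_from_ids(ids: np.ndarray, assignments: np.ndarray, k: int,
                        similarities: np.ndarray) -> Partition:
    docs = Corpus([Document(i, label=IRRELEVANT) for i in ids])
    return partition_irrelevant(docs, assignments, k=k, similarities=similarities)


def _meta_matrix(tm: TermMatrix, base_models: Sequence[BaseModel]) -> np.ndarray:
    """Meta vectors (base relevance probabilities) for every row of ``tm``."""
    cols = []
    for model in base_models:
        G = model.bin_matrix(tm)
        cols.append(model.score_matrix(G))
    return np.column_stack(cols)


def train_pipeline(
    train: Corpus,
    config: FeatureConfig | None = None,
    parts: Iterable[str] = ALL_PARTS,
    lexicon: MaskingLexicon | None = None,
    k_override: int | None = None,
    seed: int = 0,
    n_estimators: int = 100,
) -> TriagePipeline:
    """Train the full triage pipeline on a labeled corpus.

    Stages: compose+mask+extract terms per document; stratified 75/25 split
    into base-training and meta-training documents; full-training-set feature
    selection; cosine K-means over the base-training irrelevant documents;
    one base classifier per cluster; meta-classifier on the meta-training
    documents' stacked base scores. Deterministic under ``seed``.
    """
    config = config or FeatureConfig()
    parts = tuple(parts)
    tm = build_term_matrix(train, parts, lexicon, config)
    return _train_from_matrix(tm, np.arange(len(train)), config, parts, lexicon,
                              k_override, seed, n_estimators)


def _predict_matrix(pipeline: TriagePipeline, tm: TermMatrix) -> pd.DataFrame:
    meta_X = _meta_matrix(tm, pipeline.base_models)
    scores = pipeline.meta_model.decision(meta_X)
    labels = pipeline.meta_model.predict(meta_X)
    out = pd.DataFrame({"id": tm.ids, "label": labels, "score": scores})
    for j in range(pipeline.k):
        out[f"c{j + 1}"] = meta_X[:, j]
    return out


def predict(pipeline: TriagePipeline, docs: Corpus) -> pd.DataFrame:
    """Label a corpus: one row per document with id, label, meta decision
    score and the k base relevance probabilities c1..ck."""
    if not isinstance(pipeline, TriagePipeline) or pipeline.meta_model is None:
        raise NotFittedError("pipeline is not fitted")
    tm = build_term_matrix(docs, pipeline.parts, pipeline.lexicon, pipeline.config,
                           vocabulary=pipeline.vocabulary)
    return _predict_matrix(pipeline, tm)


# ---------------------------------------------------------------------------
# Random under-sampling baseline (single classifier, no clustering/stacking)
# ---------------------------------------------------------------------------

@dataclass
class BaselineModel:
    """One base-style classifier trained on a random irrelevant under-sample."""

    base: BaseModel
    config: FeatureConfig
    parts: tuple[str, ...]
    lexicon: MaskingLexicon | None
    vocabulary: dict[str, int]
    threshold: float = 0.5

    def predict(self, docs: Corpus) -> pd.DataFrame:
        tm = build_term_matrix(docs, self.parts, self.lexicon, self.config,
                               vocabulary=self.vocabulary)
        return self.predict_matrix(tm)

    def predict_matrix(self, tm: TermMatrix) -> pd.DataFrame:
        p = self.base.score_matrix(self.base.bin_matrix(tm))
        labels = np.where(p > self.threshold, RELEVANT, IRRELEVANT).astype(object)
        return pd.DataFrame({"id": tm.ids, "label": labels, "score": p})


def train_random_undersample_baseline(
    train: Corpus,
    config: FeatureConfig | None = None,
    parts: Iterable[str] = ALL_PARTS,
    lexicon: MaskingLexicon | None = None,
    seed: int = 0,
    n_estimators: int = 100,
    _tm: TermMatrix | None = None,
    _rows: np.ndarray | None = None,
) -> BaselineModel:
    """Single-classifier comparison point: the relevant training set plus a
    random irrelevant sample of equal size (the same per-classifier training
    budget as each base task), with the same feature pipeline."""
    config = config or FeatureConfig()
    parts = tuple(parts)
    tm = _tm if _tm is not None else build_term_matrix(train, parts, lexicon, config)
    rows = _rows if _rows is not None else np.arange(tm.X.shape[0])
    labels = tm.labels[rows]
    rel_rows = rows[labels == RELEVANT]
    irr_rows = rows[labels == IRRELEVANT]
    if len(rel_rows) == 0 or len(irr_rows) == 0:
        raise TrainingError("training corpus must contain both classes")
    rng = np.random.default_rng(seed)
    sample = rng.choice(irr_rows, size=min(len(rel_rows), len(irr_rows)), replace=False)
    base = _fit_base_from_matrix(tm, rel_rows, np.sort(sample), config,
                                 seed=int(rng.integers(2**31)), cluster_index=0,
                                 n_estimators=n_estimators)
    return BaselineModel(base=base, config=config, parts=parts, lexicon=lexicon,
                         vocabulary={t: i for i, t in enumerate(tm.vocab)})
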