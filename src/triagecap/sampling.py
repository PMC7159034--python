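"""Cluster-based under-sampling of the irrelevant (majority) class.

Rather than discarding majority examples at random, the irrelevant class is
partitioned into k topically cohesive clusters by K-means with cosine
similarity over the binary term vectors; each cluster is later paired with
the full relevant set to train one base classifier. k defaults to the
rounded imbalance ratio, so each cluster is roughly the size of the
relevant class.

Cosine K-means is realized as spherical K-means: rows and centroids are
length-normalized and the dot product is maximized, which is equivalent to
minimizing cosine distance. Initialization is a seeded farthest-first sweep,
making the whole procedure deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse

from .corpus import IRRELEVANT, RELEVANT, Corpus


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # (k, m), unit rows
    seed: int
    iterations_run: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)


@dataclass
class Partition:
    """Disjoint grouping of irrelevant document ids into k non-empty subsets."""

    subsets: list[list[str]]

    @property
    def sizes(self) -> list[int]:
        return [len(s) for s in self.subsets]

    def to_table(self) -> list[tuple[str, int]]:
        """Two-column export: (document id, 0-based cluster index)."""
        return [(doc_id, j) for j, subset in enumerate(self.subsets) for doc_id in subset]


def choose_k(n_rel: int, n_irr: int, override: int | None = None) -> int:
    """Number of clusters from the imbalance ratio: round(n_irr/n_rel), in [2, 20].

    An explicit ``override`` (e.g. the k tuned by downstream cross-validation)
    bypasses the heuristic.
    """
    if override is not None:
        if override < 1:
            raise ValueError("k override must be at least 1")
        return int(override)
    if n_rel < 1:
        raise ValueError("n_rel must be at least 1")
    return int(min(20, max(2, round(n_irr / n_rel))))


def _as_csr(vectors) -> sparse.csr_matrix:
    if sparse.issparse(vectors):
        return vectors.tocsr().astype(np.float64)
    arr = np.asarray(vectors, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("vectors must form a 2-D array")
    return sparse.csr_matrix(arr)


def _normalize_rows(X: sparse.csr_matrix) -> tuple[sparse.csr_matrix, np.ndarray]:
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    nonzero = norms > 0
    scale = np.where(nonzero, norms, 1.0)
    Xn = sparse.diags(1.0 / scale) @ X
    return Xn.tocsr(), nonzero


def _farthest_first_init(Xn: sparse.csr_matrix, rows: np.ndarray, k: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Pick k seed rows: a random first, then repeatedly the row least similar
    to its closest chosen seed (ties to the lowest row index)."""
    chosen = [rows[rng.integers(len(rows))]]
    max_sim = (Xn[rows] @ Xn[chosen[0]].T).toarray().ravel()
    for _ in range(1, k):
        nxt = rows[int(np.argmin(max_sim))]
        chosen.append(nxt)
        sim = (Xn[rows] @ Xn[nxt].T).toarray().ravel()
        np.maximum(max_sim, sim, out=max_sim)
    return Xn[np.array(chosen)].toarray()


def spherical_kmeans(
    vectors,
    k: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[ClusterModel, np.ndarray]:
    """K-means with cosine similarity on binary term vectors.

    Returns the fitted model and one cluster index per input row. Vectors
    are length-normalized; assignment alternates with centroid re-estimation
    (mean direction, renormalized) until the assignment reaches a fixpoint,
    the objective sum(1 - cos) changes by less than ``tol``, or ``max_iter``.
    All-zero vectors take no part in fitting and are assigned to the largest
    cluster at the end. Ties in assignment go to the lowest centroid index.
    """
    X = _as_csr(vectors)
    Xn, nonzero = _normalize_rows(X)
    rows = np.flatnonzero(nonzero)
    if len(rows) == 0:
        raise ValueError("no nonzero vectors to cluster")
    distinct = {tuple(Xn.indices[Xn.indptr[i]:Xn.indptr[i + 1]]) for i in rows}
    if k > len(distinct):
        raise ValueError(
            f"k={k} exceeds the number of distinct nonzero vectors ({len(distinct)})"
        )
    if k < 1:
        raise ValueError("k must be at least 1")

    rng = np.random.default_rng(seed)
    C = _farthest_first_init(Xn, rows, k, rng)  # (k, m), unit rows
    Xa = Xn[rows]
    assign = np.full(len(rows), -1, dtype=np.int64)
    history: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        S = (Xa @ C.T)  # (n_active, k) dense
        S = np.asarray(S)
        new_assign = np.argmax(S, axis=1)  # first max -> lowest index on ties
        objective = float(np.sum(1.0 - S[np.arange(len(rows)), new_assign]))
        history.append(objective)
        if np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign
        # centroid update: mean direction of members, renormalized
        for j in range(k):
            members = np.flatnonzero(assign == j)
            if len(members) == 0:
                continue  # keep previous centroid; repair happens in partitioning
            mean = np.asarray(Xa[members].sum(axis=0)).ravel()
            norm = np.linalg.norm(mean)
            if norm > 0:
                C[j] = mean / norm
        if len(history) >= 2 and abs(history[-2] - history[-1]) < tol:
            converged = True
            break

    full_assign = np.zeros(X.shape[0], dtype=np.int64)
    full_assign[rows] = assign
    zero_rows = np.flatnonzero(~nonzero)
    if len(zero_rows) > 0:
        sizes = np.bincount(assign, minlength=k)
        full_assign[zero_rows] = int(np.argmax(sizes))
    model = ClusterModel(k=k, centroids=C, seed=seed, iterations_run=iterations,
                         converged=converged, objective_history=history)
    return model, full_assign


def partition_irrelevant(
    corpus: Corpus,
    assignments: Sequence[int] | Mapping[str, int],
    k: int | None = None,
    similarities: np.ndarray | None = None,
) -> Partition:
    """Group the corpus's irrelevant documents by cluster assignment.

    ``assignments`` is either a sequence aligned with the corpus's
    irrelevant documents in order, or a mapping from document id to cluster
    index (which must cover exactly the irrelevant documents). Empty
    clusters are repaired by moving the largest cluster's farthest-from-
    centroid member (lowest similarity, when ``similarities`` aligned with
    the irrelevant documents is given; its last member otherwise).
    """
    irr_ids = [d.id for d in corpus if d.label == IRRELEVANT]
    if isinstance(assignments, Mapping):
        extra = set(assignments) - set(irr_ids)
        if extra:
            raise ValueError(f"assignments include non-irrelevant ids: {sorted(extra)[:5]}")
        missing = set(irr_ids) - set(assignments)
        if missing:
            raise ValueError(f"assignments missing irrelevant ids: {sorted(missing)[:5]}")
        assign = np.array([assignments[i] for i in irr_ids], dtype=np.int64)
    else:
        assign = np.asarray(assignments, dtype=np.int64)
        if len(assign) != len(irr_ids):
            raise ValueError(
                f"got {len(assign)} assignments for {len(irr_ids)} irrelevant documents"
            )
    if k is None:
        k = int(assign.max()) + 1 if len(assign) else 0
    if len(assign) and (assign.min() < 0 or assign.max() >= k):
        raise ValueError("assignment index out of range")
    if len(irr_ids) < k:
        raise ValueError(f"cannot form {k} non-empty subsets from {len(irr_ids)} documents")

    member_rows: list[list[int]] = [list(np.flatnonzero(assign == j)) for j in range(k)]
    # repair: move the farthest member of the largest cluster into each empty one
    while any(len(m) == 0 for m in member_rows):
        empty = next(j for j, m in enumerate(member_rows) if len(m) == 0)
        largest = int(np.argmax([len(m) for m in member_rows]))
        members = member_rows[largest]
        if similarities is not None:
            move = members[int(np.argmin([similarities[r] for r in members]))]
        else:
            move = members[-1]
        members.remove(move)
        member_rows[empty].append(move)
    return Partition([[irr_ids[r] for r in rows] for rows in member_rows])
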