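"""Bag-of-words features: term statistics, Z-score selection and binning.

The document representation is a binary (presence) bag of unigrams and
bigrams drawn from the masked text. Two class-conditional document
frequencies are attached to each term t: Pr(t|rel), the fraction of relevant
documents containing t, and Pr(t|irr), its counterpart in the irrelevant
class. A pooled two-proportion Z statistic on these frequencies selects the
*distinguishing* terms (|Z| above a cutoff, 1.96 by default, the two-sided
normal critical value at significance 0.05).

Two vector views are derived from the selected terms:

* ``TermVector`` (V): an m-dimensional binary vector over the selected terms
  themselves, used for cosine K-means clustering of the irrelevant class.
* ``BinVector`` (G): an n-dimensional binary vector over *bins* of terms.
  Feature binning groups terms whose two class-conditional probabilities
  fall in the same pair of equal-width half-open sub-intervals of (0,1)
  (width w = 0.0001 by default); a bin fires when any member term occurs.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.feature_extraction.text import CountVectorizer

from .corpus import CATEGORY_TOKENS, Corpus, MaskingLexicon, compose_text, mask_concepts

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_SENTENCE_RE = re.compile(r"(?<=\.)\s+")
_CATEGORY_SET = frozenset(CATEGORY_TOKENS)


def default_stopwords() -> frozenset[str]:
    """Standard English stopword list shipped with the package."""
    text = resources.files("triagecap.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction and selection parameters.

    Parameters
    ----------
    ngram_orders : n-gram orders to extract (subset of {1, 2}).
    stopwords : stopword set; ``None`` loads the packaged default list.
    rare_min_docfreq : drop terms occurring in fewer documents than this.
    frequent_max_docfrac : drop terms occurring in more than this fraction
        of all documents.
    z_threshold : |Z| cutoff for distinguishing terms. The default 1.96 is
        the two-sided standard-normal critical value at significance 0.05.
    bin_width : width w of the probability sub-intervals used for binning.
    """

    ngram_orders: frozenset[int] = frozenset({1, 2})
    stopwords: frozenset[str] | None = None
    rare_min_docfreq: int = 5
    frequent_max_docfrac: float = 0.5
    z_threshold: float = 1.96
    bin_width: float = 0.0001

    def __post_init__(self) -> None:
        object.__setattr__(self, "ngram_orders", frozenset(self.ngram_orders))
        if not self.ngram_orders or not self.ngram_orders <= {1, 2}:
            raise ValueError("ngram_orders must be a non-empty subset of {1, 2}")
        if not 0 < self.bin_width < 1:
            raise ValueError("bin_width must lie in (0, 1)")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.rare_min_docfreq < 0:
            raise ValueError("rare_min_docfreq must be non-negative")
        if not 0 < self.frequent_max_docfrac <= 1:
            raise ValueError("frequent_max_docfrac must lie in (0, 1]")
        if self.stopwords is not None:
            object.__setattr__(self, "stopwords", frozenset(self.stopwords))

    def resolved_stopwords(self) -> frozenset[str]:
        return self.stopwords if self.stopwords is not None else default_stopwords()


def tokenize(text: str) -> list[str]:
    """Lowercased alphanumeric tokens; punctuation stripped; hyphens split.

    The concept-category tokens PRGE/ENZI/MUTN/ANAT are preserved as single
    tokens in canonical uppercase.
    """
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text):
        upper = tok.upper()
        out.append(upper if upper in _CATEGORY_SET else tok.lower())
    return out


def extract_terms(tokens: Sequence[str], orders: Iterable[int] = (1, 2)) -> set[str]:
    """Set of contiguous n-grams of the requested orders (bigrams space-joined)."""
    orders = set(orders)
    if not orders <= {1, 2}:
        raise ValueError("orders must be a subset of {1, 2}")
    terms: set[str] = set()
    if 1 in orders:
        terms.update(tokens)
    if 2 in orders:
        terms.update(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    return terms


def document_terms(text: str, config: FeatureConfig | None = None) -> set[str]:
    """Unigram/bigram term set of one document's text.

    Bigrams do not cross sentence boundaries (a period followed by
    whitespace is treated as a sentence break).
    """
    config = config or FeatureConfig()
    orders = set(config.ngram_orders)
    terms: set[str] = set()
    if 2 in orders:
        for sentence in _SENTENCE_RE.split(text):
            toks = tokenize(sentence)
            terms.update(extract_terms(toks, orders))
    else:
        terms.update(extract_terms(tokenize(text), orders))
    return terms


# ---------------------------------------------------------------------------
# Term statistics and selection
# ---------------------------------------------------------------------------

@dataclass
class TermStats:
    """Per-term class-conditional document frequencies and Z-scores.

    ``table`` is indexed by term with columns df_rel, df_irr, p_rel, p_irr, z.
    """

    table: pd.DataFrame
    n_rel: int
    n_irr: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def terms(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="term")

    @classmethod
    def from_tsv(cls, path: str | Path, n_rel: int, n_irr: int) -> "TermStats":
        return cls(pd.read_csv(path, sep="\t", index_col="term"), n_rel, n_irr)


def z_score(df_rel: int, n_rel: int, df_irr: int, n_irr: int) -> float:
    """Pooled two-proportion Z statistic for one term.

    z = (p_rel − p_irr) / sqrt(phat (1 − phat) (1/n_rel + 1/n_irr)) with
    phat the pooled proportion; returns 0 when phat is 0 or 1 (the term is
    absent from, or present in, every document, carrying no contrast).
    """
    if n_rel < 1 or n_irr < 1:
        raise ValueError("class sizes must be at least 1")
    if not 0 <= df_rel <= n_rel or not 0 <= df_irr <= n_irr:
        raise ValueError("document frequency cannot exceed its class size")
    pooled = (df_rel + df_irr) / (n_rel + n_irr)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n_rel + 1.0 / n_irr))
    return (df_rel / n_rel - df_irr / n_irr) / se


def _z_scores(df_rel: np.ndarray, n_rel: int, df_irr: np.ndarray, n_irr: int) -> np.ndarray:
    pooled = (df_rel + df_irr) / (n_rel + n_irr)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n_rel + 1.0 / n_irr))
        z = (df_rel / n_rel - df_irr / n_irr) / se
    z[(pooled <= 0.0) | (pooled >= 1.0)] = 0.0
    return z


def _stats_from_counts(
    terms: np.ndarray, df_rel: np.ndarray, df_irr: np.ndarray, n_rel: int, n_irr: int
) -> TermStats:
    table = pd.DataFrame(
        {
            "df_rel": df_rel.astype(np.int64),
            "df_irr": df_irr.astype(np.int64),
            "p_rel": df_rel / n_rel,
            "p_irr": df_irr / n_irr,
            "z": _z_scores(df_rel.astype(float), n_rel, df_irr.astype(float), n_irr),
        },
        index=pd.Index(terms, name="term"),
    )
    return TermStats(table, n_rel, n_irr)


def compute_term_stats(
    rel_docs: Sequence[set[str]], irr_docs: Sequence[set[str]]
) -> TermStats:
    """Document frequencies and Z-scores over two classes of term sets.

    Each document contributes at most once per term (presence, not counts).
    """
    n_rel, n_irr = len(rel_docs), len(irr_docs)
    if n_rel < 1 or n_irr < 1:
        raise ValueError("both classes must contain at least one document")
    c_rel: Counter[str] = Counter()
    for s in rel_docs:
        c_rel.update(s)
    c_irr: Counter[str] = Counter()
    for s in irr_docs:
        c_irr.update(s)
    terms = np.array(sorted(set(c_rel) | set(c_irr)), dtype=object)
    df_rel = np.fromiter((c_rel.get(t, 0) for t in terms), dtype=np.int64, count=len(terms))
    df_irr = np.fromiter((c_irr.get(t, 0) for t in terms), dtype=np.int64, count=len(terms))
    return _stats_from_counts(terms, df_rel, df_irr, n_rel, n_irr)


def filter_vocabulary(stats: TermStats, config: FeatureConfig) -> TermStats:
    """Drop stopwords, single letters, rare terms and overly frequent terms.

    Rare/frequent cutoffs apply to the corpus-wide document count
    (df_rel + df_irr). Bigrams containing a stopword token are dropped.
    """
    stops = config.resolved_stopwords()
    table = stats.table
    df_total = table["df_rel"].to_numpy() + table["df_irr"].to_numpy()
    n_total = stats.n_rel + stats.n_irr
    keep = (df_total >= config.rare_min_docfreq) & (
        df_total <= config.frequent_max_docfrac * n_total
    )
    for i, term in enumerate(table.index):
        if not keep[i]:
            continue
        if " " in term:
            a, b = term.split(" ", 1)
            if a in stops or b in stops:
                keep[i] = False
        elif len(term) == 1 or term in stops:
            keep[i] = False
    return TermStats(table.loc[keep], stats.n_rel, stats.n_irr)


def select_distinguishing(stats: TermStats, z_threshold: float = 1.96) -> TermStats:
    """Keep exactly the terms with |Z| strictly above ``z_threshold``."""
    mask = stats.table["z"].abs().to_numpy() > z_threshold
    return TermStats(stats.table.loc[mask], stats.n_rel, stats.n_irr)


# ---------------------------------------------------------------------------
# Feature binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bin:
    bin_id: int
    terms: tuple[str, ...]
    rel_index: int
    irr_index: int


@dataclass
class BinSet:
    """Partition of the selected terms into probability-interval bins.

    Terms share a bin iff their Pr(t|rel) values fall in the same half-open
    sub-interval [i*w, (i+1)*w) *and* their Pr(t|irr) values do too. Bins are
    ordered by (rel interval index, irr interval index).
    """

    bins: list[Bin]
    width: float

    @property
    def n(self) -> int:
        return len(self.bins)

    def term_to_bin(self) -> dict[str, int]:
        mapping: dict[str, int] = {}
        for b in self.bins:
            for t in b.terms:
                mapping[t] = b.bin_id
        return mapping

    def to_file(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"# bin_width\t{self.width!r}\n")
            fh.write("bin_id\trel_index\tirr_index\tterms\n")
            for b in self.bins:
                fh.write(f"{b.bin_id}\t{b.rel_index}\t{b.irr_index}\t{'|'.join(b.terms)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "BinSet":
        bins: list[Bin] = []
        width = None
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# bin_width"):
                    width = float(line.split("\t")[1])
                    continue
                if not line or line.startswith("bin_id"):
                    continue
                bid, ri, ii, terms = line.split("\t")
                bins.append(Bin(int(bid), tuple(terms.split("|")), int(ri), int(ii)))
        if width is None:
            raise ValueError("bin file missing bin_width header")
        return cls(bins, width)


def _interval_indices(df: np.ndarray, n: int, width: float) -> np.ndarray:
    """Index of the half-open interval [i*w, (i+1)*w) containing df/n.

    When 1/width is (numerically) an integer the index is computed in exact
    integer arithmetic, so probabilities landing exactly on a boundary go to
    the upper interval rather than wherever float rounding drops them.
    """
    inv = round(1.0 / width)
    if inv > 0 and math.isclose(inv, 1.0 / width, rel_tol=1e-9):
        return (df.astype(np.int64) * inv) // n
    return np.floor((df / n) / width).astype(np.int64)


def bin_terms(stats: TermStats, width: float = 0.0001) -> BinSet:
    """Group selected terms sharing both probability sub-intervals.

    This grid grouping is the fixed point of iteratively merging any two
    bins whose members' Pr(t|rel) values share a sub-interval and whose
    Pr(t|irr) values also share one.
    """
    if not 0 < width < 1:
        raise ValueError("width must lie in (0, 1)")
    table = stats.table
    rel_idx = _interval_indices(table["df_rel"].to_numpy(), stats.n_rel, width)
    irr_idx = _interval_indices(table["df_irr"].to_numpy(), stats.n_irr, width)
    groups: dict[tuple[int, int], list[str]] = {}
    for term, ri, ii in zip(table.index, rel_idx, irr_idx):
        groups.setdefault((int(ri), int(ii)), []).append(term)
    bins = [
        Bin(bin_id=j, terms=tuple(groups[key]), rel_index=key[0], irr_index=key[1])
        for j, key in enumerate(sorted(groups))
    ]
    return BinSet(bins, width)


# ---------------------------------------------------------------------------
# Vectorization
# ---------------------------------------------------------------------------

def vectorize_terms(doc_terms: set[str], selected: Sequence[str]) -> np.ndarray:
    """m-dimensional binary vector V: V[i] = 1 iff selected[i] is in the document."""
    if len(selected) == 0:
        raise ValueError("selected term sequence must be non-empty")
    return np.fromiter((1 if t in doc_terms else 0 for t in selected), dtype=np.int8,
                       count=len(selected))


def vectorize_bins(doc_terms: set[str], binset: BinSet) -> np.ndarray:
    """n-dimensional binary vector G: G[j] = 1 iff bin j has a member in the document."""
    if binset.n == 0:
        raise ValueError("binset must be non-empty")
    out = np.zeros(binset.n, dtype=np.int8)
    mapping = binset.term_to_bin()
    for t in doc_terms:
        j = mapping.get(t)
        if j is not None:
            out[j] = 1
    return out


# ---------------------------------------------------------------------------
# Sparse incidence matrix over a whole corpus (shared fast path)
# ---------------------------------------------------------------------------

@dataclass
class TermMatrix:
    """Binary document-term incidence matrix for one composed corpus view.

    Rows follow corpus order; columns follow the (sorted) vocabulary. The
    same vocabulary can be imposed on new documents at prediction time.
    """

    ids: np.ndarray
    labels: np.ndarray  # object array of "relevant"/"irrelevant"/None
    vocab: np.ndarray
    X: sparse.csr_matrix
    term_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.term_index:
            self.term_index = {t: i for i, t in enumerate(self.vocab)}

    def rows_with_label(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def stats(self, rel_rows: np.ndarray, irr_rows: np.ndarray) -> TermStats:
        """TermStats restricted to the given relevant/irrelevant row sets."""
        n_rel, n_irr = len(rel_rows), len(irr_rows)
        if n_rel < 1 or n_irr < 1:
            raise ValueError("both classes must contain at least one document")
        df_rel = np.asarray(self.X[rel_rows].sum(axis=0)).ravel()
        df_irr = np.asarray(self.X[irr_rows].sum(axis=0)).ravel()
        present = (df_rel + df_irr) > 0
        return _stats_from_counts(
            self.vocab[present], df_rel[present], df_irr[present], n_rel, n_irr
        )

    def columns(self, terms: Sequence[str]) -> np.ndarray:
        return np.fromiter((self.term_index[t] for t in terms), dtype=np.int64,
                           count=len(terms))


def build_term_matrix(
    corpus: Corpus,
    parts: Iterable[str] = ("title", "abstract", "captions"),
    lexicon: MaskingLexicon | None = None,
    config: FeatureConfig | None = None,
    vocabulary: dict[str, int] | None = None,
) -> TermMatrix:
    """Compose, mask and vectorize every document of a corpus.

    With ``vocabulary`` given (a term -> column mapping from a fitted
    pipeline), unseen terms are dropped and column order is preserved.
    """
    config = config or FeatureConfig()
    parts = tuple(parts)
    texts = (mask_concepts(compose_text(d, parts), lexicon) for d in corpus)
    analyzer = lambda text: sorted(document_terms(text, config))  # noqa: E731
    vec = CountVectorizer(analyzer=analyzer, binary=True, vocabulary=vocabulary,
                          dtype=np.int8)
    X = vec.fit_transform(texts) if vocabulary is None else vec.transform(texts)
    vocab = np.asarray(vec.get_feature_names_out(), dtype=object)
    ids = np.array([d.id for d in corpus], dtype=object)
    labels = np.array([d.label for d in corpus], dtype=object)
    return TermMatrix(ids=ids, labels=labels, vocab=vocab, X=X.tocsr())
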