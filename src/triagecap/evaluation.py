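"""Confusion-matrix metrics, stratified cross-validation and run comparison.

Precision, recall and f-measure are reported alongside the Matthews
correlation coefficient (MCC), the robust summary metric under class
imbalance: MCC is +1 for total agreement, 0 for random assignment and -1
for total disagreement. Any 0/0 in a metric is set to 0 by convention (with
a warning). Runs are compared metric-by-metric with a two-sample Welch
t-test over per-fold values.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as scipy_stats
from sklearn.model_selection import StratifiedKFold

from .corpus import IRRELEVANT, LABELS, RELEVANT, Corpus, MaskingLexicon
from .features import FeatureConfig, build_term_matrix
from .metaclassifier import ALL_PARTS, _predict_matrix, _train_from_matrix

METRIC_NAMES = ("precision", "recall", "f_measure", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f_measure: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion(gold: Sequence[str], pred: Sequence[str]) -> ConfusionCounts:
    """Confusion counts with ``relevant`` as the positive class."""
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} predicted")
    bad = {g for g in gold if g not in LABELS} | {p for p in pred if p not in LABELS}
    if bad:
        raise ValueError(f"labels must be in {sorted(LABELS)}; got {sorted(bad)}")
    tp = fp = fn = tn = 0
    for g, p in zip(gold, pred):
        if g == RELEVANT:
            if p == RELEVANT:
                tp += 1
            else:
                fn += 1
        else:
            if p == RELEVANT:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        if num != 0:
            raise AssertionError("ratio numerator nonzero with zero denominator")
        warnings.warn(f"{name} is 0/0; returning 0 by convention", stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """Precision, recall, f-measure and MCC from confusion counts."""
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    if precision + recall == 0:
        f_measure = 0.0
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    denom2 = (
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    if denom2 == 0:
        warnings.warn("MCC denominator is 0; returning 0 by convention", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (float(c.tp) * c.tn - float(c.fp) * c.fn) / math.sqrt(denom2)
    return MetricSet(precision=precision, recall=recall, f_measure=f_measure, mcc=mcc)


def stratified_folds(corpus: Corpus, folds: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per document; each fold preserves the class ratio within
    one document. Deterministic under ``seed``."""
    if folds < 2:
        raise ValueError("folds must be at least 2")
    labels = np.array([d.label for d in corpus], dtype=object)
    for label in (RELEVANT, IRRELEVANT):
        if int(np.sum(labels == label)) < folds:
            raise ValueError(f"class {label!r} has fewer members than folds={folds}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**32))
    assignment = np.empty(len(corpus), dtype=np.int64)
    for j, (_, test_idx) in enumerate(skf.split(np.zeros(len(corpus)), labels)):
        assignment[test_idx] = j
    return assignment


@dataclass
class CVReport:
    """Per-fold metrics with mean and standard deviation (ddof=1)."""

    fold_metrics: list[MetricSet]
    mean: dict[str, float]
    std: dict[str, float]
    folds: int
    seed: int
    config_fingerprint: str
    arm: tuple[str, ...] = ALL_PARTS

    def metric_values(self, name: str) -> list[float]:
        return [getattr(m, name) for m in self.fold_metrics]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "fold_metrics": [m.as_dict() for m in self.fold_metrics],
            "mean": self.mean,
            "std": self.std,
            "folds": self.folds,
            "seed": self.seed,
            "config_fingerprint": self.config_fingerprint,
            "arm": list(self.arm),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CVReport":
        text = Path(source).read_text(encoding="utf-8") if Path(source).exists() else str(source)
        payload = json.loads(text)
        return cls(
            fold_metrics=[MetricSet(**m) for m in payload["fold_metrics"]],
            mean=payload["mean"],
            std=payload["std"],
            folds=payload["folds"],
            seed=payload["seed"],
            config_fingerprint=payload["config_fingerprint"],
            arm=tuple(payload.get("arm", ALL_PARTS)),
        )


def _fingerprint(config: FeatureConfig, parts: tuple[str, ...], k_override) -> str:
    blob = repr((config, parts, k_override)).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _aggregate(fold_metrics: list[MetricSet]) -> tuple[dict[str, float], dict[str, float]]:
    mean = {}
    std = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in fold_metrics])
        mean[name] = float(vals.mean())
        std[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return mean, std


def cross_validate(
    corpus: Corpus,
    config: FeatureConfig | None = None,
    parts: Iterable[str] = ALL_PARTS,
    lexicon: MaskingLexicon | None = None,
    k_override: int | None = None,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
) -> CVReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Every fold re-runs the entire training procedure (feature selection,
    clustering, base and meta training) on its 80% training share and is
    evaluated on the held-out 20%. Term extraction is per-document and
    split-independent, so the document-term matrix is built once.
    """
    config = config or FeatureConfig()
    parts = tuple(parts)
    assignment = stratified_folds(corpus, folds, seed)
    tm = build_term_matrix(corpus, parts, lexicon, config)
    gold = np.array([d.label for d in corpus], dtype=object)
    fold_metrics: list[MetricSet] = []
    for j in range(folds):
        test_rows = np.flatnonzero(assignment == j)
        train_rows = np.flatnonzero(assignment != j)
        try:
            pipeline = _train_from_matrix(tm, train_rows, config, parts, lexicon,
                                          k_override, seed + j, n_estimators)
            pred = _predict_matrix(pipeline, tm).iloc[test_rows]
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed in fold {j}: {exc}") from exc
        fold_metrics.append(metrics(confusion(list(gold[test_rows]), list(pred["label"]))))
    mean, std = _aggregate(fold_metrics)
    return CVReport(
        fold_metrics=fold_metrics,
        mean=mean,
        std=std,
        folds=folds,
        seed=seed,
        config_fingerprint=_fingerprint(config, parts, k_override),
        arm=parts,
    )


def compare_runs(metric_a: Sequence[float], metric_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Welch t-test (two-sided) over per-fold metric values."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each side needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0  # identical constant samples: no evidence of difference
    t, p = scipy_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
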