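"""Macro-averaged metrics, logistic ranking loss, and the split/CV protocol.

Per-class conventions are deliberate and differ from common library defaults:

* precision_i = TP_i/(TP_i+FP_i) if the denominator is positive, else 0 —
  and the zero-convention class is INCLUDED in the macro mean;
* recall_i and F1_i follow the same convention;
* ranking loss is the mean logistic penalty ln(1 + e^−(s_i−s_j)) over the
  pooled set of (true-label score, false-label score) pairs across genes;
* macro ROC-AUC uses the rank (Mann–Whitney) formulation with half credit
  for ties; classes without both positives and negatives are skipped.

The evaluation protocol splits genes 90/10 at random, runs 10-fold
cross-validation on the 90% partition, then retrains on the full 90% and
scores the held-out 10% — all reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .models import LabelMatrix, ModelConfig, ScoreMatrix, make_model

logger = logging.getLogger(__name__)


def _values(m) -> np.ndarray:
    if isinstance(m, (LabelMatrix, ScoreMatrix)):
        return np.asarray(m.values)
    return np.asarray(m)


def confusion_counts(pred, truth) -> dict[str, np.ndarray]:
    """Per-pathway TP/FP/FN/TN counts for binary predictions."""
    P = _values(pred).astype(bool)
    T = _values(truth).astype(bool)
    if P.shape != T.shape:
        raise ValueError("prediction and truth shapes differ")
    return {
        "tp": (P & T).sum(axis=0),
        "fp": (P & ~T).sum(axis=0),
        "fn": (~P & T).sum(axis=0),
        "tn": (~P & ~T).sum(axis=0),
    }


def per_class_precision_recall_f1(pred, truth):
    c = confusion_counts(pred, truth)
    tp, fp, fn = c["tp"].astype(float), c["fp"], c["fn"]
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(precision + recall > 0,
                      2 * precision * recall / (precision + recall), 0.0)
    return precision, recall, f1


def macro_precision(pred, truth) -> float:
    """Unweighted mean per-class precision (zero-denominator classes count 0)."""
    p, _, _ = per_class_precision_recall_f1(pred, truth)
    return float(p.mean())


def macro_recall(pred, truth) -> float:
    _, r, _ = per_class_precision_recall_f1(pred, truth)
    return float(r.mean())


def macro_f1(pred, truth) -> float:
    _, _, f1 = per_class_precision_recall_f1(pred, truth)
    return float(f1.mean())


def ranking_loss(scores, truth) -> float:
    """Mean ln(1 + e^−(s_pos − s_neg)) over pooled per-gene label pairs.

    For each gene, every (true-label, false-label) score pair contributes one
    term; pairs are pooled across genes. Returns 0 (with a warning) when no
    gene has both a positive and a negative label.
    """
    S = _values(scores).astype(float)
    T = _values(truth).astype(bool)
    if S.shape != T.shape:
        raise ValueError("score and truth shapes differ")
    total = 0.0
    n_pairs = 0
    for g in range(S.shape[0]):
        pos = S[g, T[g]]
        neg = S[g, ~T[g]]
        if pos.size == 0 or neg.size == 0:
            continue
        diff = pos[:, None] - neg[None, :]
        total += float(np.logaddexp(0.0, -diff).sum())
        n_pairs += diff.size
    if n_pairs == 0:
        warnings.warn("no (positive, negative) label pairs; ranking loss = 0",
                      stacklevel=2)
        return 0.0
    return total / n_pairs


def macro_roc_auc(scores, truth, return_skipped: bool = False):
    """Mean one-vs-rest AUC over classes, Mann–Whitney form with tie credit.

    AUC_i = (R_pos − n_pos(n_pos+1)/2) / (n_pos · n_neg) with average ranks.
    Classes lacking positives or negatives are skipped; skipping every class
    is an error.
    """
    S = _values(scores).astype(float)
    T = _values(truth).astype(bool)
    if S.shape != T.shape:
        raise ValueError("score and truth shapes differ")
    aucs = []
    skipped = 0
    for j in range(S.shape[1]):
        y = T[:, j]
        n_pos = int(y.sum())
        n_neg = y.size - n_pos
        if n_pos == 0 or n_neg == 0:
            skipped += 1
            continue
        ranks = rankdata(S[:, j])
        auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc)
    if not aucs:
        raise ValueError("every class lacks positives or negatives; AUC undefined")
    if skipped:
        logger.info("macro ROC-AUC skipped %d degenerate class(es)", skipped)
    mean = float(np.mean(aucs))
    return (mean, skipped) if return_skipped else mean


@dataclass
class MetricsReport:
    """The four macro metrics plus ranking loss with per-class breakdowns."""

    precision_macro: float
    recall_macro: float
    f1_macro: float
    ranking_loss: float
    roc_auc_macro: float
    per_class: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "ranking_loss": self.ranking_loss,
            "roc_auc_macro": self.roc_auc_macro,
            "per_class": {k: list(map(float, v)) if hasattr(v, "__len__") else v
                          for k, v in self.per_class.items()},
            "protocol": self.protocol,
        }


def compute_metrics(scores, truth, threshold: float = 0.5,
                    protocol: dict | None = None) -> MetricsReport:
    """All five metrics at once from probability scores."""
    S = _values(scores)
    pred = (S >= threshold).astype(np.int8)
    precision, recall, f1 = per_class_precision_recall_f1(pred, truth)
    auc, skipped = macro_roc_auc(scores, truth, return_skipped=True)
    return MetricsReport(
        precision_macro=float(precision.mean()),
        recall_macro=float(recall.mean()),
        f1_macro=float(f1.mean()),
        ranking_loss=ranking_loss(scores, truth),
        roc_auc_macro=auc,
        per_class={"precision": precision, "recall": recall, "f1": f1,
                   "auc_skipped_classes": skipped},
        protocol=protocol or {},
    )


@dataclass
class ProtocolConfig:
    """Train/test split and cross-validation settings."""

    test_fraction: float = 0.1
    n_folds: int = 10
    threshold: float = 0.5
    seed: int = 0


def _split_genes(n: int, protocol: ProtocolConfig):
    """Seeded 90/10 gene split plus CV folds over the train partition."""
    rng = np.random.default_rng(protocol.seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(protocol.test_fraction * n)))
    test_idx = np.sort(perm[:n_test])
    train_idx = perm[n_test:]
    folds = [np.sort(f) for f in np.array_split(train_idx, protocol.n_folds)]
    return train_idx, test_idx, folds


def evaluate_holdout(features, labels: LabelMatrix, model_config: ModelConfig,
                     protocol: ProtocolConfig | None = None) -> MetricsReport:
    """Only the held-out evaluation: train on the 90% split, score the 10%.

    Uses the same seeded split as :func:`evaluate_protocol`, so the two
    functions' test reports agree for a given seed.
    """
    protocol = protocol or ProtocolConfig()
    X = np.asarray(features, dtype=float)
    Y = labels.values
    train_idx, test_idx, _ = _split_genes(X.shape[0], protocol)
    model = make_model(model_config)
    model.fit(X[train_idx], Y[train_idx])
    return compute_metrics(
        model.predict_proba(X[test_idx]), Y[test_idx],
        threshold=protocol.threshold,
        protocol={"kind": "holdout_test", "seed": protocol.seed,
                  "train_size": int(train_idx.size),
                  "test_size": int(test_idx.size)})


def evaluate_protocol(features, labels: LabelMatrix,
                      model_config: ModelConfig,
                      protocol: ProtocolConfig | None = None
                      ) -> tuple[MetricsReport, MetricsReport]:
    """Random 90/10 gene split; 10-fold CV on the 90%; held-out test report.

    Returns ``(cv_report, test_report)``. The CV report's headline numbers are
    unweighted means of the per-fold metrics; both reports record the seed,
    the split sizes and the fold assignments, so a rerun with the same seed
    reproduces the fold structure bit-for-bit.
    """
    protocol = protocol or ProtocolConfig()
    X = np.asarray(features, dtype=float)
    Y = labels.values
    n = X.shape[0]
    if n < 20:
        raise ValueError("protocol evaluation requires at least 20 genes")
    train_idx, test_idx, folds = _split_genes(n, protocol)

    fold_reports: list[MetricsReport] = []
    for i, fold in enumerate(folds):
        tr = np.setdiff1d(train_idx, fold)
        model = make_model(model_config)
        model.fit(X[tr], Y[tr])
        scores = model.predict_proba(X[fold])
        fold_reports.append(
            compute_metrics(scores, Y[fold], threshold=protocol.threshold))

    def _mean(attr):
        return float(np.mean([getattr(r, attr) for r in fold_reports]))

    gene_ids = labels.gene_ids
    cv_report = MetricsReport(
        precision_macro=_mean("precision_macro"),
        recall_macro=_mean("recall_macro"),
        f1_macro=_mean("f1_macro"),
        ranking_loss=_mean("ranking_loss"),
        roc_auc_macro=_mean("roc_auc_macro"),
        per_class={"fold_f1_macro": [r.f1_macro for r in fold_reports]},
        protocol={
            "kind": "cross_validation",
            "n_folds": protocol.n_folds,
            "seed": protocol.seed,
            "train_size": int(train_idx.size),
            "test_size": int(test_idx.size),
            "fold_gene_ids": [[gene_ids[i] for i in f] for f in folds],
        },
    )

    final = make_model(model_config)
    final.fit(X[train_idx], Y[train_idx])
    test_scores = final.predict_proba(X[test_idx])
    test_report = compute_metrics(
        test_scores, Y[test_idx], threshold=protocol.threshold,
        protocol={
            "kind": "holdout_test",
            "seed": protocol.seed,
            "train_size": int(train_idx.size),
            "test_size": int(test_idx.size),
            "test_gene_ids": [gene_ids[i] for i in test_idx],
        },
    )
    return cv_report, test_report
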