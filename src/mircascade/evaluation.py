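"""Classification metrics, cross-validated pipeline evaluation, disease ranking.

Point metrics (accuracy, precision, recall, F1) follow the usual
confusion-matrix formulas at a fixed 0.5 probability threshold; ranking
metrics are the area under the ROC curve (equivalently the Mann-Whitney rank
statistic with ties counted half) and the area under the precision-recall
step curve swept in descending score order (no interpolation between points).

``cross_validate`` runs the full pipeline — optional per-fold PCA refit,
cascade fit, scoring — under stratified k-fold CV of the balanced feature
table.  ``rank_for_disease`` implements the leave-one-disease-out case-study
protocol: the target disease's known associations are masked, every upstream
stage (GIP kernels, fusion, features, balancing, PCA, cascade) is refit on the
masked data, and all candidate miRNAs are ranked for that disease.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import dim_reduction, similarity
from .cascade_forest import CascadeConfig, fit_cascade, predict_scores
from .data_io import AssociationMatrix, SimilarityMatrix, ValidationError, build_adjacency
from .pair_features import PairFeatureTable, assemble_balanced, build_feature_table

METRIC_KEYS = ("Acc", "Pre", "Rec", "F1", "AUC", "AUPR")


class UndefinedMetricWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(cls, labels: np.ndarray, predicted: np.ndarray) -> "ConfusionCounts":
        labels = np.asarray(labels).astype(int)
        predicted = np.asarray(predicted).astype(int)
        return cls(
            TP=int(np.sum((labels == 1) & (predicted == 1))),
            FP=int(np.sum((labels == 0) & (predicted == 1))),
            TN=int(np.sum((labels == 0) & (predicted == 0))),
            FN=int(np.sum((labels == 1) & (predicted == 0))),
        )


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    A metric with a zero denominator is reported as NaN (undefined), with a
    warning, rather than silently coerced to 0.
    """
    out: dict[str, float] = {}

    def ratio(name: str, num: int, den: int) -> None:
        if den == 0:
            warnings.warn(
                f"{name} undefined: zero denominator", UndefinedMetricWarning, stacklevel=3
            )
            out[name] = float("nan")
        else:
            out[name] = num / den

    ratio("Acc", counts.TP + counts.TN, counts.total)
    ratio("Pre", counts.TP, counts.TP + counts.FP)
    ratio("Rec", counts.TP, counts.TP + counts.FN)
    ratio("F1", 2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN)
    return out


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (rank statistic; ties count half)."""
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size != 2:
        raise ValidationError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def pr_aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall step curve (descending-score sweep)."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0:
        raise ValidationError("AUPR needs at least one positive")
    return float(average_precision_score(labels, scores))


def roc_points(labels: np.ndarray, scores: np.ndarray) -> list[tuple[float, float]]:
    fpr, tpr, _ = roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist()))


def pr_points(labels: np.ndarray, scores: np.ndarray) -> list[tuple[float, float]]:
    precision, recall, _ = precision_recall_curve(labels, scores)
    return list(zip(recall.tolist(), precision.tolist()))


def score_metrics(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict[str, float]:
    """All six metrics from raw scores: thresholded point metrics + AUC/AUPR."""
    counts = ConfusionCounts.from_predictions(labels, np.asarray(scores) >= threshold)
    metrics = classification_metrics(counts)
    metrics["AUC"] = roc_auc(labels, scores)
    metrics["AUPR"] = pr_aupr(labels, scores)
    return metrics


@dataclass
class EvalReport:
    """Per-fold and mean metrics plus ROC/PR curve points for one CV run."""

    per_fold: list[dict[str, float]]
    means: dict[str, float]
    roc_curves: list[list[tuple[float, float]]]
    pr_curves: list[list[tuple[float, float]]]
    k: int
    seed: int
    mode: str = "paper"

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "mode": self.mode,
            "per_fold": self.per_fold,
            "means": self.means,
            "roc_curves": self.roc_curves,
            "pr_curves": self.pr_curves,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def plot_curves(self, path: str | Path) -> None:
        """Write per-fold ROC and PR curves as an image (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(10, 4.5))
        for fold, (roc, pr) in enumerate(zip(self.roc_curves, self.pr_curves), 1):
            auc = self.per_fold[fold - 1]["AUC"]
            aupr = self.per_fold[fold - 1]["AUPR"]
            ax_roc.plot(*zip(*roc), lw=1, label=f"fold {fold} (AUC={auc:.3f})")
            ax_pr.plot(*zip(*pr), lw=1, label=f"fold {fold} (AUPR={aupr:.3f})")
        ax_roc.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax_roc.set(xlabel="false positive rate", ylabel="true positive rate",
                   title=f"ROC ({self.k}-fold CV)")
        ax_pr.set(xlabel="recall", ylabel="precision",
                  title=f"Precision-Recall ({self.k}-fold CV)")
        for ax in (ax_roc, ax_pr):
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


@dataclass
class RankedList:
    """Candidate miRNAs for one disease, sorted by predicted score descending."""

    disease_id: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValidationError("ranked scores must be nonincreasing")
        ids = [m for m, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("a miRNA appears twice in the ranking")

    def top(self, n: int) -> list[tuple[str, float]]:
        return self.entries[:n]

    def to_tsv(self, path: str | Path, top: int | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tmirna_id\tscore\n")
            for rank, (mirna, score) in enumerate(self.top(top or len(self.entries)), 1):
                fh.write(f"{rank}\t{mirna}\t{score:.6f}\n")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings shared by CV evaluation and case studies.

    ``mode="paper"`` fits PCA once on the full balanced table before
    splitting (the headline protocol); ``mode="leakage_safe"`` refits PCA
    inside each training fold.
    """

    pca_threshold: float = 0.95
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    mode: str = "paper"

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "leakage_safe"):
            raise ValidationError(f"unknown mode {self.mode!r}")


def _fit_score_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: PipelineConfig,
    fold_seed: int,
) -> np.ndarray:
    """Fit (optional per-fold PCA +) cascade on train, score test rows."""
    if config.mode == "leakage_safe":
        pca = dim_reduction.fit_pca(X_train, config.pca_threshold)
        pca.select()
        X_train = pca.transform(X_train)
        X_test = pca.transform(X_test)
    cascade_cfg = CascadeConfig(
        **{
            **{f: getattr(config.cascade, f) for f in config.cascade.__dataclass_fields__},
            "seed": fold_seed,
        }
    )
    model = fit_cascade(X_train, y_train, cascade_cfg)
    return predict_scores(model, X_test)


def cross_validate(
    table: PairFeatureTable,
    config: PipelineConfig,
    k: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold CV of the full pipeline on a balanced labeled table.

    In paper mode the PCA reduction is fitted once on the whole table; in
    leakage-safe mode PCA is refit inside every training fold.  Point metrics
    use the 0.5 threshold; AUC/AUPR use the raw calibrated scores.
    """
    if table.labels is None:
        raise ValidationError("cross_validate needs a labeled feature table")
    if k < 2:
        raise ValidationError("k must be >= 2")
    y = np.asarray(table.labels).astype(int)
    X = table.features
    if config.mode == "paper":
        X, _ = dim_reduction.fit_transform(X, config.pca_threshold)
    root = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(k)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31 - 1))
    per_fold, rocs, prs = [], [], []
    for fold_seed, (train_idx, test_idx) in zip(fold_seeds, skf.split(X, y)):
        y_test = y[test_idx]
        if np.unique(y_test).size != 2 or np.unique(y[train_idx]).size != 2:
            raise ValidationError("a CV fold contains a single class")
        scores = _fit_score_fold(X[train_idx], y[train_idx], X[test_idx], config, fold_seed)
        per_fold.append(score_metrics(y_test, scores))
        rocs.append(roc_points(y_test, scores))
        prs.append(pr_points(y_test, scores))
    means = {
        key: float(np.mean([fold[key] for fold in per_fold])) for key in METRIC_KEYS
    }
    return EvalReport(per_fold, means, rocs, prs, k=k, seed=seed, mode=config.mode)


def rank_for_disease(
    pairs: Sequence[tuple[str, str]],
    mirna_ids: Sequence[str],
    disease_ids: Sequence[str],
    mfs: SimilarityMatrix,
    dss: SimilarityMatrix,
    target_disease: str,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> RankedList:
    """Leave-one-disease-out ranking of candidate miRNAs for one disease.

    The target disease's column of A is zeroed before anything else is
    computed, so no information about its known links can leak through the
    GIP profiles, the fused similarities or the balanced sample.  The target
    column is also excluded from negative sampling: its pairs are exactly the
    candidates being ranked, and labeling them negative would bias the model
    against them.  The whole pipeline is refit on the masked data and all n_m
    (miRNA, target) pairs are scored; ties are broken by miRNA id
    (lexicographic).
    """
    config = config or PipelineConfig()
    if target_disease not in disease_ids:
        raise ValidationError(f"unknown disease id {target_disease!r}")
    adjacency = build_adjacency(pairs, mirna_ids, disease_ids)
    masked = adjacency.mask_disease(target_disease)
    sm, sd = similarity.fused_similarities(masked, mfs, dss)
    target_col = list(masked.disease_ids).index(target_disease)
    table, _ = assemble_balanced(sm, sd, masked, seed, exclude_disease=target_col)
    X, pca = dim_reduction.fit_transform(table.features, config.pca_threshold)
    cascade_cfg = CascadeConfig(
        **{
            **{f: getattr(config.cascade, f) for f in config.cascade.__dataclass_fields__},
            "seed": seed,
        }
    )
    model = fit_cascade(X, np.asarray(table.labels).astype(int), cascade_cfg)
    j = list(masked.disease_ids).index(target_disease)
    candidates = [(i, j) for i in range(masked.n_mirnas)]
    cand_table = build_feature_table(sm, sd, masked, candidates)
    scores = predict_scores(model, pca.transform(cand_table.features))
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], masked.mirna_ids[i])
    )
    entries = [(masked.mirna_ids[i], float(scores[i])) for i in order]
    return RankedList(target_disease, entries)
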