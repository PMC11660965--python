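"""Model/Results facade over the prediction pipeline.

:class:`AssociationModel` bundles the three data inputs (adjacency, miRNA
functional similarity, disease semantic similarity) with the pipeline
configuration, in the style of a statsmodels model object.  ``fit()`` runs
similarity fusion, balanced sampling, PCA reduction and the cascade forest,
and returns an :class:`AssociationResults` carrying the fitted components,
training diagnostics and a ``summary()`` table; cross-validation, pair
scoring and per-disease ranking hang off the model/results pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import dim_reduction, similarity
from .cascade_forest import CascadeConfig, CascadeModel, fit_cascade, predict_scores
from .data_io import (
    AssociationMatrix,
    SimilarityMatrix,
    ValidationError,
    build_adjacency,
    read_association_pairs,
    read_similarity_matrix,
)
from .evaluation import (
    EvalReport,
    PipelineConfig,
    RankedList,
    cross_validate,
    rank_for_disease,
    score_metrics,
)
from .pair_features import BalancedSample, PairFeatureTable, assemble_balanced, build_feature_table
from .synthetic_data import SyntheticSpec, generate


@dataclass
class AssociationModel:
    """miRNA-disease association predictor specification bound to data."""

    adjacency: AssociationMatrix
    mfs: SimilarityMatrix
    dss: SimilarityMatrix
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        self.mfs = self.mfs.reindex(self.adjacency.mirna_ids)
        self.dss = self.dss.reindex(self.adjacency.disease_ids)

    # ------------------------------------------------------------------ ctors
    @classmethod
    def from_files(
        cls,
        association_path: str | Path,
        mfs_path: str | Path,
        dss_path: str | Path,
        mirna_ids: Sequence[str] | None = None,
        disease_ids: Sequence[str] | None = None,
        config: PipelineConfig | None = None,
    ) -> "AssociationModel":
        """Build from an association list plus similarity matrix files.

        When id lists are omitted they are taken from the similarity matrix
        headers (every association id must then appear there).
        """
        pairs = read_association_pairs(association_path)
        mfs = read_similarity_matrix(mfs_path, kind="MFS")
        dss = read_similarity_matrix(dss_path, kind="DSS")
        mirna_ids = list(mirna_ids) if mirna_ids is not None else mfs.ids
        disease_ids = list(disease_ids) if disease_ids is not None else dss.ids
        adjacency = build_adjacency(pairs, mirna_ids, disease_ids)
        return cls(adjacency, mfs, dss, config or PipelineConfig())

    @classmethod
    def from_synthetic(
        cls, spec: SyntheticSpec | None = None, config: PipelineConfig | None = None
    ) -> "AssociationModel":
        """Build from a planted-block synthetic dataset."""
        adjacency, mfs, dss = generate(spec or SyntheticSpec())
        return cls(adjacency, mfs, dss, config or PipelineConfig())

    # ------------------------------------------------------------------- fit
    def fused(self) -> tuple[SimilarityMatrix, SimilarityMatrix]:
        """Fused miRNA (SM) and disease (SD) similarity matrices."""
        return similarity.fused_similarities(self.adjacency, self.mfs, self.dss)

    def balanced_table(self, seed: int = 0) -> tuple[PairFeatureTable, BalancedSample]:
        sm, sd = self.fused()
        return assemble_balanced(sm, sd, self.adjacency, seed)

    def fit(self, seed: int = 0) -> "AssociationResults":
        """Run the full training pipeline and return fitted results."""
        sm, sd = self.fused()
        table, sample = assemble_balanced(sm, sd, self.adjacency, seed)
        y = np.asarray(table.labels).astype(int)
        X, pca = dim_reduction.fit_transform(table.features, self.config.pca_threshold)
        cascade_cfg = replace_seed(self.config.cascade, seed)
        cascade = fit_cascade(X, y, cascade_cfg)
        train_scores = predict_scores(cascade, X)
        return AssociationResults(
            model=self,
            sm=sm,
            sd=sd,
            table=table,
            sample=sample,
            pca=pca,
            cascade=cascade,
            seed=seed,
            train_metrics=score_metrics(y, train_scores),
        )

    def cross_validate(self, k: int = 5, seed: int = 0) -> EvalReport:
        """Stratified k-fold CV of the pipeline on the balanced table."""
        table, _ = self.balanced_table(seed)
        return cross_validate(table, self.config, k=k, seed=seed)

    def rank_disease(self, target_disease: str, seed: int = 0) -> RankedList:
        """Leave-one-disease-out ranking of all miRNAs for one disease."""
        pairs = [
            (self.adjacency.mirna_ids[i], self.adjacency.disease_ids[j])
            for i, j in zip(*np.nonzero(self.adjacency.values))
        ]
        return rank_for_disease(
            pairs,
            self.adjacency.mirna_ids,
            self.adjacency.disease_ids,
            self.mfs,
            self.dss,
            target_disease,
            self.config,
            seed=seed,
        )


def replace_seed(config: CascadeConfig, seed: int) -> CascadeConfig:
    return replace(config, seed=seed)


@dataclass
class AssociationResults:
    """Fitted pipeline: fused similarities, PCA, cascade, diagnostics."""

    model: AssociationModel
    sm: SimilarityMatrix
    sd: SimilarityMatrix
    table: PairFeatureTable
    sample: BalancedSample
    pca: dim_reduction.PcaModel
    cascade: CascadeModel
    seed: int
    train_metrics: dict[str, float]

    @property
    def selected_components(self) -> int:
        return int(self.pca.selected_k)

    @property
    def retained_depth(self) -> int:
        return self.cascade.retained_depth

    def predict_pairs(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        """Score (miRNA id, disease id) pairs with the fitted pipeline."""
        m_index = {m: i for i, m in enumerate(self.model.adjacency.mirna_ids)}
        d_index = {d: j for j, d in enumerate(self.model.adjacency.disease_ids)}
        try:
            subset = [(m_index[m], d_index[d]) for m, d in pairs]
        except KeyError as exc:
            raise ValidationError(f"unknown id in pair list: {exc.args[0]!r}") from None
        cand = build_feature_table(self.sm, self.sd, self.model.adjacency, subset)
        return predict_scores(self.cascade, self.pca.transform(cand.features))

    def summary(self) -> str:
        """Human-readable fit summary (dimensions, PCA, cascade, training fit)."""
        adj = self.model.adjacency
        cfg = self.model.config
        ratios = self.pca.explained_variance_ratio
        cum = float(np.cumsum(ratios)[self.selected_components - 1])
        lines = [
            "          miRNA-Disease Association Model",
            "=" * 56,
            f"miRNAs: {adj.n_mirnas:>6d}    diseases: {adj.n_diseases:>6d}",
            f"known associations: {adj.n_positives:>6d}    unknown pairs: {adj.n_unknown}",
            f"balanced training rows: {len(self.table.rows)}",
            f"feature columns (2*n_m + 2*n_d): {self.table.n_columns}",
            "-" * 56,
            f"PCA threshold: {cfg.pca_threshold:.2f}   "
            f"selected components: {self.selected_components} "
            f"(cumulative variance {cum:.4f})",
            f"cascade roster: {', '.join(self.cascade.config.estimator_roster)} "
            f"x {self.cascade.config.n_trees_per_estimator} trees",
            f"levels grown: {len(self.cascade.levels)}   retained depth: {self.retained_depth}",
            "inner-CV accuracy by level: "
            + ", ".join(f"{a:.4f}" for a in self.cascade.level_accuracies),
            f"terminal predictor: {self.cascade.config.terminal_predictor} "
            f"(poly degree {self.cascade.config.predictor_degree})",
            "-" * 56,
            "training-set fit (resubstitution, threshold 0.5):",
            "  "
            + "  ".join(f"{k}={v:.4f}" for k, v in self.train_metrics.items()),
            f"mode: {cfg.mode}   seed: {self.seed}",
            "=" * 56,
        ]
        return "\n".join(lines)
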