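import numpy as np
import pytest

from mircascade.cascade_forest import CascadeConfig
from mircascade.data_io import ValidationError
from mircascade.evaluation import (
    ConfusionCounts,
    PipelineConfig,
    RankedList,
    UndefinedMetricWarning,
    classification_metrics,
    cross_validate,
    pr_aupr,
    roc_auc,
    score_metrics,
)


def brute_force_auc(labels, scores):
    """Oracle: count concordant positive-negative pairs, ties worth 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def step_curve_aupr(labels, scores):
    """Oracle: precision-recall sweep in descending score order, no interpolation."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    n_pos = labels.sum()
    tp = fp = 0
    area = 0.0
    prev_recall = 0.0
    for label in labels:
        if label == 1:
            tp += 1
        else:
            fp += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestClassificationMetrics:
    def test_hand_computed_values(self):
        m = classification_metrics(ConfusionCounts(TP=40, TN=45, FP=5, FN=10))
        assert m["Acc"] == pytest.approx(0.85)
        assert m["Pre"] == pytest.approx(40 / 45)
        assert m["Rec"] == pytest.approx(0.8)
        assert m["F1"] == pytest.approx(80 / 95)

    def test_all_true_positives_gives_ones(self):
        m = classification_metrics(ConfusionCounts(TP=7, TN=0, FP=0, FN=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_undefined_with_warning(self):
        with pytest.warns(UndefinedMetricWarning, match="Pre"):
            m = classification_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=5))
        assert np.isnan(m["Pre"])
        assert m["Acc"] == 0.5  # defined metrics are still returned

    def test_f1_is_harmonic_mean_of_pre_rec(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 40, size=4)
            m = classification_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            harmonic = 2 * m["Pre"] * m["Rec"] / (m["Pre"] + m["Rec"])
            assert m["F1"] == pytest.approx(harmonic)

    def test_counts_from_predictions_totals(self):
        labels = np.array([1, 1, 0, 0, 1])
        predicted = np.array([1, 0, 0, 1, 1])
        counts = ConfusionCounts.from_predictions(labels, predicted)
        assert counts.total == 5
        assert (counts.TP, counts.FP, counts.TN, counts.FN) == (2, 1, 1, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_six_point_fixture_matches_pairwise_oracle(self):
        labels = np.array([1, 0, 1, 0, 1, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.7, 0.3, 0.1])
        assert roc_auc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12
        )

    def test_random_fixtures_match_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            labels = rng.integers(0, 2, size=12)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=12)
            assert roc_auc(labels, scores) == pytest.approx(
                brute_force_auc(labels, scores), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        labels = np.array([0, 1] * 10)
        scores = rng.random(20)
        a = roc_auc(labels, scores)
        b = roc_auc(labels, np.exp(3 * scores) + 7)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestPrAupr:
    def test_perfect_ranking(self):
        assert pr_aupr([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_six_point_fixture_matches_step_sweep(self):
        labels = np.array([1, 0, 1, 1, 0, 0])
        scores = np.array([0.95, 0.85, 0.75, 0.55, 0.45, 0.15])
        assert pr_aupr(labels, scores) == pytest.approx(
            step_curve_aupr(labels, scores), abs=1e-12
        )

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(7)
        n, prevalence = 10_000, 0.2
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)
        assert pr_aupr(labels, scores) == pytest.approx(prevalence, abs=0.03)

    def test_no_positives_rejected(self):
        with pytest.raises(ValidationError):
            pr_aupr([0, 0], [0.1, 0.2])


class TestScoreMetrics:
    def test_acc_matches_recomputed_confusion(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        m = score_metrics(labels, scores)
        acc = np.mean((scores >= 0.5).astype(int) == labels)
        assert m["Acc"] == pytest.approx(acc)


def _small_table(synthetic_default, seed=0):
    from mircascade.pair_features import assemble_balanced
    from mircascade.similarity import fused_similarities

    adjacency, mfs, dss = synthetic_default
    sm, sd = fused_similarities(adjacency, mfs, dss)
    return assemble_balanced(sm, sd, adjacency, seed)[0]


FAST_PIPELINE = PipelineConfig(
    pca_threshold=0.9,
    cascade=CascadeConfig(n_trees_per_estimator=5, inner_folds=2, max_levels=1),
)


class TestCrossValidate:
    def test_report_bookkeeping(self, synthetic_default):
        table = _small_table(synthetic_default)
        report = cross_validate(table, FAST_PIPELINE, k=3, seed=1)
        assert report.k == 3 and len(report.per_fold) == 3
        for key, mean in report.means.items():
            assert mean == pytest.approx(
                np.mean([fold[key] for fold in report.per_fold]), abs=1e-12
            )
        assert len(report.roc_curves) == 3 and len(report.pr_curves) == 3

    def test_curve_plot_written(self, synthetic_default, tmp_path):
        pytest.importorskip("matplotlib")
        table = _small_table(synthetic_default)
        report = cross_validate(table, FAST_PIPELINE, k=2, seed=0)
        out = tmp_path / "curves.png"
        report.plot_curves(out)
        assert out.stat().st_size > 0

    def test_leakage_safe_mode_runs(self, synthetic_default):
        table = _small_table(synthetic_default)
        config = PipelineConfig(
            pca_threshold=0.9,
            cascade=FAST_PIPELINE.cascade,
            mode="leakage_safe",
        )
        report = cross_validate(table, config, k=2, seed=0)
        assert report.mode == "leakage_safe"
        assert 0.0 <= report.means["AUC"] <= 1.0

    def test_unlabeled_table_rejected(self, synthetic_default):
        table = _small_table(synthetic_default)
        table.labels = None
        with pytest.raises(ValidationError):
            cross_validate(table, FAST_PIPELINE, k=2, seed=0)

    def test_determinism(self, synthetic_default):
        table = _small_table(synthetic_default)
        a = cross_validate(table, FAST_PIPELINE, k=2, seed=5)
        b = cross_validate(table, FAST_PIPELINE, k=2, seed=5)
        assert a.means == b.means


class TestRankedList:
    def test_nonincreasing_enforced(self):
        with pytest.raises(ValidationError):
            RankedList("d", [("m1", 0.2), ("m2", 0.9)])

    def test_duplicate_mirna_rejected(self):
        with pytest.raises(ValidationError):
            RankedList("d", [("m1", 0.9), ("m1", 0.2)])

    def test_tsv_export(self, tmp_path):
        ranked = RankedList("d7", [("m2", 0.9), ("m1", 0.4)])
        path = tmp_path / "rank.tsv"
        ranked.to_tsv(path, top=1)
        lines = path.read_text().splitlines()
        assert lines[0] == "rank\tmirna_id\tscore"
        assert lines[1].startswith("1\tm2\t0.9")
        assert len(lines) == 2


class TestRankForDisease:
    def test_masking_and_planted_recovery(self, synthetic_default):
        # run near the method's real strength: with very small tree counts the
        # ranking of the out-of-distribution candidate rows is unstable
        from mircascade.evaluation import rank_for_disease
        from mircascade.synthetic_data import block_assignments

        adjacency, mfs, dss = synthetic_default
        pairs = [
            (adjacency.mirna_ids[i], adjacency.disease_ids[j])
            for i, j in zip(*np.nonzero(adjacency.values))
        ]
        target = adjacency.disease_ids[0]  # disease block 0
        config = PipelineConfig(
            cascade=CascadeConfig(n_trees_per_estimator=20, inner_folds=3, max_levels=1)
        )
        ranked = rank_for_disease(
            pairs,
            adjacency.mirna_ids,
            adjacency.disease_ids,
            mfs,
            dss,
            target,
            config,
            seed=1,
        )
        assert ranked.disease_id == target
        assert len(ranked.entries) == adjacency.n_mirnas
        scores = [s for _, s in ranked.entries]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        # planted miRNAs (same block as the target disease) rank higher on average
        m_blocks = block_assignments(adjacency.n_mirnas, 4)
        rank_of = {m: r for r, (m, _) in enumerate(ranked.entries)}
        planted = [
            rank_of[adjacency.mirna_ids[i]]
            for i in range(adjacency.n_mirnas)
            if m_blocks[i] == 0
        ]
        others = [
            rank_of[adjacency.mirna_ids[i]]
            for i in range(adjacency.n_mirnas)
            if m_blocks[i] != 0
        ]
        assert np.mean(planted) < np.mean(others)

    def test_unknown_disease_rejected(self, synthetic_default):
        from mircascade.evaluation import rank_for_disease

        adjacency, mfs, dss = synthetic_default
        with pytest.raises(ValidationError):
            rank_for_disease(
                [], adjacency.mirna_ids, adjacency.disease_ids, mfs, dss,
                "NOPE", FAST_PIPELINE,
            )
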