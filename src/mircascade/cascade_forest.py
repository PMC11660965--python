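"""Tuned cascade forest with a polynomial-kernel SVM terminal predictor.

A cascade forest is a stacked ensemble grown level by level.  Each level holds
four estimators — two random forests, an AdaBoost classifier (depth-1 trees)
and a gradient-boosted tree ensemble — with 50 trees apiece (200 trees per
level).  Every estimator is fitted with stratified inner k-fold
cross-validation (k = 5 by default) so that each training row receives
out-of-fold (OOF) class-probability pairs from models that never saw it.  The
four OOF pairs (8 columns) are concatenated to the *original* level-0 features
to form the next level's input; the augmentation is replaced, not stacked, so
the width stays p + 8 at every level past the first.

The cascade deepens only while the inner-CV accuracy of the averaged-estimator
vote improves by more than a tolerance, up to a level cap; the retained depth
is the level with the best inner-CV accuracy.  A polynomial-kernel SVM,
Platt-calibrated on out-of-fold decision values, consumes the retained level's
augmented features and emits class-1 probabilities.

At inference, each level's augmentation is the mean of its fold-models'
predicted probabilities, matching the distribution of the OOF features the
next level was trained on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_io import ValidationError

ARTIFACT_VERSION = 1

ESTIMATOR_KINDS = ("RF", "AdaBoost", "GBT")


@dataclass(frozen=True)
class CascadeConfig:
    """Hyper-parameters of the cascade and its terminal predictor.

    ``estimator_roster`` defaults to the tuned composition (RF, RF, AdaBoost,
    GBT); ``base_roster()`` gives the conventional all-random-forest cascade
    used as the untuned baseline.  ``terminal_predictor`` is ``"svm"`` or
    ``"mean_oof"`` (the latter bypasses the SVM and returns the averaged
    estimator probability — used as a structural test hook).
    ``terminal_features`` selects whether the SVM sees the augmented features
    (p + 8, default) or the 8 augmentation columns only.
    """

    n_trees_per_estimator: int = 50
    estimator_roster: tuple[str, ...] = ("RF", "RF", "AdaBoost", "GBT")
    inner_folds: int = 5
    max_levels: int = 10
    improvement_tolerance: float = 1e-4
    predictor_degree: int = 3
    terminal_predictor: str = "svm"
    terminal_features: str = "augmented"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees_per_estimator < 1:
            raise ValidationError("need at least one tree per estimator")
        if self.inner_folds < 2:
            raise ValidationError("inner_folds must be >= 2")
        if not self.estimator_roster:
            raise ValidationError("estimator roster is empty")
        for kind in self.estimator_roster:
            if kind not in ESTIMATOR_KINDS:
                raise ValidationError(f"unknown estimator kind {kind!r}")
        if self.terminal_predictor not in ("svm", "mean_oof"):
            raise ValidationError(f"unknown terminal predictor {self.terminal_predictor!r}")
        if self.terminal_features not in ("augmented", "augmentation_only"):
            raise ValidationError(f"unknown terminal_features {self.terminal_features!r}")
        if self.max_levels < 1:
            raise ValidationError("max_levels must be >= 1")

    @property
    def augmentation_width(self) -> int:
        return 2 * len(self.estimator_roster)

    @property
    def trees_per_level(self) -> int:
        return self.n_trees_per_estimator * len(self.estimator_roster)

    @staticmethod
    def base_roster() -> tuple[str, ...]:
        """The conventional untuned cascade: four random forests."""
        return ("RF", "RF", "RF", "RF")


def _make_estimator(kind: str, n_trees: int, seed: int) -> BaseEstimator:
    if kind == "RF":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    if kind == "AdaBoost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=n_trees,
            random_state=seed,
        )
    if kind == "GBT":
        return GradientBoostingClassifier(n_estimators=n_trees, random_state=seed)
    raise ValidationError(f"unknown estimator kind {kind!r}")


def _proba_01(model: BaseEstimator, X: np.ndarray) -> np.ndarray:
    """predict_proba with columns forced into (class 0, class 1) order."""
    proba = model.predict_proba(X)
    order = np.argsort(model.classes_)
    return proba[:, order]


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class CascadeLevel:
    """One fitted cascade level: fold-models per estimator plus OOF features."""

    fold_models: list[list[BaseEstimator]]  # [estimator][fold]
    oof_augmentation: np.ndarray  # (N, 2 * n_estimators)
    inner_cv_accuracy: float

    def infer_augmentation(self, X: np.ndarray) -> np.ndarray:
        """Mean class-probability pairs over fold-models, per estimator."""
        blocks = []
        for models in self.fold_models:
            probas = np.mean([_proba_01(m, X) for m in models], axis=0)
            blocks.append(probas)
        return np.hstack(blocks)


def augment(X0: np.ndarray, aug: np.ndarray) -> np.ndarray:
    """Concatenate augmentation columns onto the original level-0 features.

    The left block is always the level-0 input; between levels the previous
    augmentation is replaced, never stacked.
    """
    X0 = np.asarray(X0, dtype=float)
    aug = np.asarray(aug, dtype=float)
    if X0.shape[0] != aug.shape[0]:
        raise ValidationError(
            f"row mismatch: X0 has {X0.shape[0]} rows, augmentation {aug.shape[0]}"
        )
    return np.hstack([X0, aug])


def fit_level(
    X: np.ndarray, y: np.ndarray, config: CascadeConfig, level_seed: int
) -> CascadeLevel:
    """Fit one cascade level with stratified inner-CV OOF augmentation.

    Each roster estimator is fitted ``inner_folds`` times; held-out rows get
    that fold-model's class-probability pair, giving an (N, 2 * roster) OOF
    matrix.  ``inner_cv_accuracy`` scores the argmax of the estimator-averaged
    OOF probabilities against y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = X.shape[0]
    if n < config.inner_folds:
        raise ValidationError(f"{n} rows < {config.inner_folds} inner folds")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValidationError(f"need exactly 2 classes, got {classes.tolist()}")
    ss = np.random.SeedSequence(level_seed)
    est_seeds = [_seed_int(child) for child in ss.spawn(len(config.estimator_roster))]
    skf = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=_seed_int(ss)
    )
    folds = list(skf.split(X, y))
    fold_models: list[list[BaseEstimator]] = []
    oof_blocks: list[np.ndarray] = []
    for kind, est_seed in zip(config.estimator_roster, est_seeds):
        models = []
        oof = np.empty((n, 2))
        for train_idx, test_idx in folds:
            model = _make_estimator(kind, config.n_trees_per_estimator, est_seed)
            model.fit(X[train_idx], y[train_idx])
            oof[test_idx] = _proba_01(model, X[test_idx])
            models.append(model)
        fold_models.append(models)
        oof_blocks.append(oof)
    oof_aug = np.hstack(oof_blocks)
    mean_p1 = oof_aug[:, 1::2].mean(axis=1)
    accuracy = float(np.mean((mean_p1 >= 0.5).astype(int) == y))
    return CascadeLevel(fold_models, oof_aug, accuracy)


@dataclass
class _TerminalPredictor:
    """Polynomial-kernel SVM with Platt calibration on OOF decision values."""

    svm: Pipeline
    calibrator: LogisticRegression

    def predict_proba_1(self, X: np.ndarray) -> np.ndarray:
        decision = self.svm.decision_function(X).reshape(-1, 1)
        return self.calibrator.predict_proba(decision)[:, 1]


def _fit_terminal(
    X: np.ndarray, y: np.ndarray, config: CascadeConfig, seed: int
) -> _TerminalPredictor:
    def make_svm() -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    SVC(kernel="poly", degree=config.predictor_degree, gamma="scale"),
                ),
            ]
        )

    skf = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    oof_decision = np.empty(X.shape[0])
    for train_idx, test_idx in skf.split(X, y):
        svm = make_svm()
        svm.fit(X[train_idx], y[train_idx])
        oof_decision[test_idx] = svm.decision_function(X[test_idx])
    calibrator = LogisticRegression()
    calibrator.fit(oof_decision.reshape(-1, 1), y)
    final_svm = make_svm()
    final_svm.fit(X, y)
    return _TerminalPredictor(final_svm, calibrator)


@dataclass
class CascadeModel:
    """A fitted cascade: ordered levels, retained depth, terminal predictor."""

    levels: list[CascadeLevel]
    retained_depth: int
    terminal: _TerminalPredictor | None
    input_dim: int
    config: CascadeConfig

    @property
    def level_accuracies(self) -> list[float]:
        return [lvl.inner_cv_accuracy for lvl in self.levels]

    def save(self, directory: str | Path) -> None:
        """Persist as a directory artifact with a versioned manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "artifact": "cascade_model",
            "version": ARTIFACT_VERSION,
            "retained_depth": self.retained_depth,
            "input_dim": self.input_dim,
            "n_levels": len(self.levels),
            "config": {
                **{
                    k: getattr(self.config, k)
                    for k in (
                        "n_trees_per_estimator",
                        "inner_folds",
                        "max_levels",
                        "improvement_tolerance",
                        "predictor_degree",
                        "terminal_predictor",
                        "terminal_features",
                        "seed",
                    )
                },
                "estimator_roster": list(self.config.estimator_roster),
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump(self.levels, directory / "levels.joblib")
        joblib.dump(self.terminal, directory / "terminal.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "CascadeModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        if manifest.get("artifact") != "cascade_model":
            raise ValidationError(f"{directory}: not a cascade model artifact")
        cfg = dict(manifest["config"])
        cfg["estimator_roster"] = tuple(cfg["estimator_roster"])
        return cls(
            levels=joblib.load(directory / "levels.joblib"),
            retained_depth=manifest["retained_depth"],
            terminal=joblib.load(directory / "terminal.joblib"),
            input_dim=manifest["input_dim"],
            config=CascadeConfig(**cfg),
        )


def fit_cascade(X: np.ndarray, y: np.ndarray, config: CascadeConfig) -> CascadeModel:
    """Grow the cascade level by level and fit the terminal predictor.

    Level t >= 2 consumes the level-0 features concatenated with level t-1's
    OOF augmentation.  Growth stops when a new level fails to improve the
    inner-CV accuracy by more than ``improvement_tolerance`` or the level cap
    is reached; the retained depth is the accuracy argmax.  The terminal
    predictor is fitted on the retained level's augmented features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    root = np.random.SeedSequence(config.seed)
    level_seeds = [_seed_int(child) for child in root.spawn(config.max_levels + 1)]
    levels: list[CascadeLevel] = []
    best_acc = -np.inf
    for t in range(config.max_levels):
        X_in = X if t == 0 else augment(X, levels[-1].oof_augmentation)
        level = fit_level(X_in, y, config, level_seeds[t])
        levels.append(level)
        if level.inner_cv_accuracy <= best_acc + config.improvement_tolerance and t > 0:
            break
        best_acc = max(best_acc, level.inner_cv_accuracy)
    retained_depth = int(np.argmax([lvl.inner_cv_accuracy for lvl in levels])) + 1
    terminal = None
    if config.terminal_predictor == "svm":
        retained = levels[retained_depth - 1]
        X_term = _terminal_features(X, retained.oof_augmentation, config)
        terminal = _fit_terminal(X_term, y, config, level_seeds[config.max_levels])
    return CascadeModel(levels, retained_depth, terminal, X.shape[1], config)


def _terminal_features(
    X0: np.ndarray, aug: np.ndarray, config: CascadeConfig
) -> np.ndarray:
    if config.terminal_features == "augmentation_only":
        return np.asarray(aug, dtype=float)
    return augment(X0, aug)


def predict_scores(model: CascadeModel, X_new: np.ndarray) -> np.ndarray:
    """Score rows of X_new through the retained cascade levels.

    Each level's inference-time augmentation is the fold-model mean; the
    terminal predictor then emits calibrated class-1 probabilities (or, with
    the ``mean_oof`` hook, the averaged estimator probability itself).
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.input_dim:
        raise ValidationError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.input_dim}"
        )
    aug: np.ndarray | None = None
    for level in model.levels[: model.retained_depth]:
        X_in = X_new if aug is None else augment(X_new, aug)
        aug = level.infer_augmentation(X_in)
    assert aug is not None
    if model.config.terminal_predictor == "mean_oof":
        return aug[:, 1::2].mean(axis=1)
    X_term = _terminal_features(X_new, aug, model.config)
    return model.terminal.predict_proba_1(X_term)
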