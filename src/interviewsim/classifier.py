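"""Gradient-boosted question-type classifier.

Pipeline: stratified 80/20 split, SMOTE + Tomek-link rebalancing of the
training portion, 5-fold cross-validated hyperparameter selection over a
small declared grid, refit, and held-out evaluation. Features are N-gram
frequencies from :mod:`interviewsim.featurize`; the model is an XGBoost
softmax tree ensemble.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .featurize import EmptyInputError, FeaturizerConfig, VocabularyFile, extract_ngrams, vectorize
from .resample import rebalance_smote_tomek
from .taxonomy import label_codes as taxonomy_label_codes
from .taxonomy import qtype_from_code, validate_labels, QuestionType


class StratificationError(ValueError):
    """Raised when a class is too small to split with stratification."""


@dataclass(frozen=True)
class BoosterConfig:
    """XGBoost hyperparameters; defaults are the deployed model's values."""

    n_estimators: int = 200
    max_depth: int = 3
    min_child_weight: float = 100
    subsample: float = 0.9
    colsample_bytree: float = 0.9
    reg_lambda: float = 0.05
    reg_alpha: float = 0.05
    learning_rate: float = 0.01
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subsample", "colsample_bytree", "learning_rate"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.n_estimators <= 0 or self.max_depth <= 0:
            raise ValueError("n_estimators and max_depth must be positive")

    def to_dict(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "min_child_weight": self.min_child_weight,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "reg_lambda": self.reg_lambda,
            "reg_alpha": self.reg_alpha,
            "learning_rate": self.learning_rate,
            "random_seed": self.random_seed,
        }


#: CV grid centered on the deployed values (learning rate fixed, as deployed).
DEFAULT_CV_GRID: dict[str, tuple] = {
    "max_depth": (3, 5),
    "min_child_weight": (10, 100),
    "subsample": (0.8, 0.9),
    "colsample_bytree": (0.8, 0.9),
}


def _make_booster(cfg: BoosterConfig, n_classes: int) -> XGBClassifier:
    return XGBClassifier(
        objective="multi:softprob",
        num_class=n_classes,
        n_estimators=cfg.n_estimators,
        max_depth=cfg.max_depth,
        min_child_weight=cfg.min_child_weight,
        subsample=cfg.subsample,
        colsample_bytree=cfg.colsample_bytree,
        reg_lambda=cfg.reg_lambda,
        reg_alpha=cfg.reg_alpha,
        learning_rate=cfg.learning_rate,
        random_state=cfg.random_seed,
        tree_method="hist",
        n_jobs=1,
        verbosity=0,
    )


def stratified_split(
    texts: list[str],
    labels: list[str],
    test_fraction: float = 0.20,
    seed: int = 0,
) -> tuple[list[str], list[str], list[str], list[str]]:
    """Stratified train/test split of a labeled corpus.

    Returns (train_texts, train_labels, test_texts, test_labels); per-class
    test proportions are within one item of ``test_fraction``. Every class
    needs at least 2 members.
    """
    labels = list(labels)
    values, counts = np.unique(labels, return_counts=True)
    small = [str(v) for v, c in zip(values, counts) if c < 2]
    if small:
        raise StratificationError(
            f"classes with fewer than 2 members cannot be stratified: {small}"
        )
    idx = np.arange(len(texts))
    tr, te = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    tr, te = np.sort(tr), np.sort(te)
    return (
        [texts[i] for i in tr],
        [labels[i] for i in tr],
        [texts[i] for i in te],
        [labels[i] for i in te],
    )


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reproduce its features.

    ``booster`` is the raw fitted tree-ensemble state (not the sklearn
    wrapper), which keeps persistence a plain JSON round trip.
    """

    booster: xgb.Booster
    vocabulary: tuple[str, ...]
    label_codes: dict[str, int]
    featurizer_cfg: FeaturizerConfig
    training_report: dict
    #: taxonomy codes in the booster's class-index order
    class_codes: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def features_of(self, texts: list[str]) -> sparse.csr_matrix:
        # CSR throughout: training and prediction must share one
        # representation so absent N-grams mean the same thing in both
        cfg = replace(self.featurizer_cfg, vocabulary=self.vocabulary)
        mat, _ = vectorize(texts, cfg)
        return mat

    def predict_proba(self, texts: list[str]) -> np.ndarray:
        return self.booster.predict(xgb.DMatrix(self.features_of(texts)))

    def predict_types(self, texts: list[str]) -> list[QuestionType]:
        """Batch prediction; ties break to the lowest taxonomy code."""
        proba = self.predict_proba(texts)
        order = np.argsort(self.class_codes, kind="stable")
        best = order[np.argmax(proba[:, order], axis=1)]
        return [qtype_from_code(int(self.class_codes[b])) for b in best]

    def predict_type(self, text: str) -> tuple[QuestionType, dict[str, float]]:
        """Predicted type and per-class probabilities for one utterance.

        Argmax over class scores; exact ties break to the lowest taxonomy
        code. Raises :class:`EmptyInputError` for empty text.
        """
        proba = self.predict_proba([text])[0]
        order = np.argsort(self.class_codes, kind="stable")
        best = order[int(np.argmax(proba[order]))]
        qtype = qtype_from_code(int(self.class_codes[best]))
        scores = {
            qtype_from_code(int(c)).value: float(p)
            for c, p in zip(self.class_codes, proba)
        }
        return qtype, scores


def tune_and_train(
    texts: list[str],
    labels: list[str],
    booster_cfg: BoosterConfig | None = None,
    featurizer_cfg: FeaturizerConfig | None = None,
    seed: int = 0,
    *,
    cv: bool = True,
    cv_grid: dict[str, tuple] | None = None,
    rebalance: bool = True,
    test_fraction: float = 0.20,
    k_neighbors: int = 5,
) -> TrainedModel:
    """Full training pipeline, deterministic given ``seed``.

    Stratified split -> featurize -> rebalance (training portion only) ->
    5-fold CV over ``cv_grid`` (skipped with ``cv=False``, which keeps the
    configured values) -> refit -> held-out accuracy in the report. With
    ``test_fraction=0`` the whole corpus is used for fitting and no
    held-out accuracy is reported.
    """
    booster_cfg = booster_cfg or BoosterConfig(random_seed=seed)
    featurizer_cfg = featurizer_cfg or FeaturizerConfig()
    validate_labels(labels)

    if test_fraction > 0:
        tr_x, tr_y, te_x, te_y = stratified_split(texts, labels, test_fraction, seed)
    else:
        tr_x, tr_y, te_x, te_y = list(texts), list(labels), [], []

    X_tr, vocab = vectorize(tr_x, featurizer_cfg)
    all_codes = taxonomy_label_codes()
    present = sorted({all_codes[lab] for lab in labels})
    missing = sorted(set(all_codes.values()) - set(present))
    code_to_index = {c: i for i, c in enumerate(present)}
    y_tr = np.asarray([code_to_index[all_codes[lab]] for lab in tr_y])

    if rebalance and len(present) > 1:
        X_fit, y_fit = rebalance_smote_tomek(X_tr, y_tr, k_neighbors=k_neighbors, seed=seed)
    else:
        X_fit, y_fit = X_tr, y_tr
    if not sparse.issparse(X_fit):
        # back to CSR after resampling: fitting and prediction must use the
        # same sparse representation (and sparse fits are much faster)
        X_fit = sparse.csr_matrix(X_fit)

    cv_scores: dict[str, float] = {}
    chosen = booster_cfg
    if cv:
        grid = cv_grid or DEFAULT_CV_GRID
        chosen, cv_scores = _cv_select(X_fit, y_fit, booster_cfg, grid, len(present), seed)

    clf = _make_booster(chosen, len(present))
    clf.fit(X_fit, y_fit)

    model = TrainedModel(
        booster=clf.get_booster(),
        vocabulary=vocab,
        label_codes=all_codes,
        featurizer_cfg=featurizer_cfg,
        training_report={},
        class_codes=np.asarray(present),
    )
    report: dict = {
        "n_train": len(tr_x),
        "n_test": len(te_x),
        "n_fit_after_rebalance": int(len(y_fit)),
        "classes_present": [qtype_from_code(c).value for c in present],
        "classes_missing": [qtype_from_code(c).value for c in missing],
        "booster_config": chosen.to_dict(),
        "cv_scores": cv_scores,
        "seed": seed,
    }
    if te_x:
        report["holdout_accuracy"] = _accuracy(model, te_x, te_y)
    report["train_accuracy"] = _accuracy(model, tr_x, tr_y)
    model.training_report = report
    return model


def _cv_select(
    X, y, base: BoosterConfig, grid: dict[str, tuple], n_classes: int, seed: int
) -> tuple[BoosterConfig, dict[str, float]]:
    """5-fold CV accuracy for every grid point; ties keep the first point."""
    from itertools import product

    folds = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    splits = list(folds.split(X, y))
    names = list(grid)
    scores: dict[str, float] = {}
    best_key, best_score, best_cfg = None, -1.0, base
    for combo in product(*(grid[n] for n in names)):
        cfg = replace(base, **dict(zip(names, combo)))
        accs = []
        for tr, te in splits:
            booster = _make_booster(cfg, n_classes)
            booster.fit(X[tr], y[tr])
            accs.append(float(np.mean(booster.predict(X[te]) == y[te])))
        key = ",".join(f"{n}={v}" for n, v in zip(names, combo))
        scores[key] = float(np.mean(accs))
        if scores[key] > best_score:
            best_key, best_score, best_cfg = key, scores[key], cfg
    scores["selected"] = best_key  # type: ignore[assignment]
    return best_cfg, scores


def _accuracy(model: TrainedModel, texts: list[str], labels: list[str]) -> float:
    preds = [qt.value for qt in model.predict_types(texts)]
    return float(np.mean([p == l for p, l in zip(preds, labels)]))


def evaluate(model: TrainedModel, texts: list[str], labels: list[str]) -> dict:
    """Accuracy of a trained model on a labeled corpus."""
    validate_labels(labels)
    return {"n": len(texts), "accuracy": _accuracy(model, texts, labels)}


# ---------------------------------------------------------------- persistence

def save_model(model: TrainedModel, dirpath: str) -> None:
    """Write the model artifact directory (booster, vocabulary, configs)."""
    os.makedirs(dirpath, exist_ok=True)
    model.booster.save_model(os.path.join(dirpath, "booster.json"))
    VocabularyFile(os.path.join(dirpath, "vocabulary.txt")).write(model.vocabulary)
    meta = {
        "featurizer": model.featurizer_cfg.to_dict(),
        "label_codes": model.label_codes,
        "class_codes": [int(c) for c in model.class_codes],
    }
    with open(os.path.join(dirpath, "metadata.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    with open(os.path.join(dirpath, "training_report.json"), "w", encoding="utf-8") as fh:
        json.dump(model.training_report, fh, indent=2)


def load_model(dirpath: str) -> TrainedModel:
    with open(os.path.join(dirpath, "metadata.json"), encoding="utf-8") as fh:
        meta = json.load(fh)
    with open(os.path.join(dirpath, "training_report.json"), encoding="utf-8") as fh:
        report = json.load(fh)
    vocab = VocabularyFile(os.path.join(dirpath, "vocabulary.txt")).read()
    booster = xgb.Booster()
    booster.load_model(os.path.join(dirpath, "booster.json"))
    return TrainedModel(
        booster=booster,
        vocabulary=vocab,
        label_codes=meta["label_codes"],
        featurizer_cfg=FeaturizerConfig.from_dict(meta["featurizer"]),
        training_report=report,
        class_codes=np.asarray(meta["class_codes"]),
    )
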