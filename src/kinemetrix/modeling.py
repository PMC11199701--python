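"""Leave-one-subject-out cross-validation with LASSO selection and a bank of
seven classifiers.

Each repetition re-runs the full LOSO loop with a different seed; held-out
predictions are pooled per repetition to give one accuracy and one ROC/AUC
per classifier per repeat.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV, LogisticRegression, lasso_path
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import GroupKFold, LeaveOneGroupOut
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import feature_columns

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "CVReport",
    "loso_splits",
    "standardize",
    "lasso_select",
    "fit_classifier",
    "run_cv",
    "CLASSIFIER_NAMES",
    "DEFAULT_GRIDS",
]

CLASSIFIER_NAMES = ("lda", "lr", "svm", "rf", "ab", "knn", "gnb")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "lda": {},
    "lr": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "rf": {"max_depth": [3, 5, None]},
    "ab": {"n_estimators": [50, 100]},
    "knn": {"n_neighbors": [3, 5, 7, 11]},
    "gnb": {},
}

FPR_GRID = np.round(np.arange(0.0, 1.01, 0.01), 2)


@dataclass
class CVConfig:
    n_repeats: int = 16
    base_seed: int = 0
    inner_cv: str = "grouped_kfold"  # or "loso"
    inner_k: int = 5
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    grids: dict[str, dict[str, list]] = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_GRIDS.items()
    })
    lasso_alphas: tuple[float, ...] = tuple(np.logspace(-3, 0, 20))
    lasso_logistic: bool = False

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValueError(f"unknown classifiers {sorted(unknown)}")
        if len(self.lasso_alphas) == 0:
            raise ValueError("empty lasso alpha grid")


def loso_splits(table: pd.DataFrame) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
    """One fold per subject: (held-out subject_id, train index, test index).

    A subject's rows — across medication states and labels — are never split
    between train and test.
    """
    subjects = sorted(set(table["subject_id"].astype(str)))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 distinct subjects")
    subj = table["subject_id"].astype(str).to_numpy()
    for held_out in subjects:
        test_idx = np.flatnonzero(subj == held_out)
        train_idx = np.flatnonzero(subj != held_out)
        yield held_out, train_idx, test_idx


def standardize(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict]:
    """z-score both sets with train-only statistics.

    Zero-variance train columns get a unit divisor and are flagged in the
    scaler record.
    """
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    degenerate = std == 0
    safe_std = np.where(degenerate, 1.0, std)
    record = {
        "mean": mean,
        "std": safe_std,
        "degenerate": np.flatnonzero(degenerate).tolist(),
    }
    return (train - mean) / safe_std, (test - mean) / safe_std, record


def _inner_splitter(cfg: CVConfig, groups: np.ndarray):
    n_groups = len(set(groups))
    if cfg.inner_cv == "loso":
        return LeaveOneGroupOut()
    return GroupKFold(n_splits=min(cfg.inner_k, n_groups))


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    feature_names: list[str],
    cfg: CVConfig,
    seed: int,
) -> list[str]:
    """L1 feature selection: choose alpha by subject-grouped inner CV, return
    features with non-negligible coefficients.

    If the best alpha zeroes everything, fall back to the largest alpha on
    the grid that keeps at least one feature.
    """
    if len(set(y)) < 2:
        raise ValueError("training labels are single-class")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))  # vary inner-fold composition per repeat
    Xp, yp, gp = X[order], y[order], groups[order]
    splitter = _inner_splitter(cfg, gp)
    splits = [
        (tr, va) for tr, va in splitter.split(Xp, yp, gp) if len(set(yp[tr])) >= 2
    ]
    if not splits:
        raise ValueError("no valid inner folds for LASSO tuning")
    alphas = np.sort(np.asarray(cfg.lasso_alphas))[::-1]  # descending for the path
    cv_model = LassoCV(alphas=alphas, cv=splits, max_iter=3000, tol=1e-3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cv_model.fit(Xp, yp)
        sel = np.abs(cv_model.coef_) > 1e-8
        if not sel.any():
            # largest alpha on the grid that keeps at least one feature
            _, coef_path, _ = lasso_path(Xp, yp, alphas=alphas, max_iter=3000, tol=1e-3)
            n_active = (np.abs(coef_path) > 1e-8).sum(axis=0)
            keep = np.flatnonzero(n_active >= 1)
            idx = keep[0] if len(keep) else len(alphas) - 1
            sel = np.abs(coef_path[:, idx]) > 1e-8
    return [feature_names[i] for i in np.flatnonzero(sel)]


def _make_classifier(name: str, params: dict, seed: int):
    if name == "lda":
        return LinearDiscriminantAnalysis(**params)
    if name == "lr":
        return LogisticRegression(max_iter=2000, **params)
    if name == "svm":
        # Platt-scaled probabilities: raw decision values are not comparable
        # across folds and bias the pooled ROC on null data
        return CalibratedClassifierCV(
            SVC(kernel="rbf", gamma="scale", random_state=seed, **params),
            ensemble=False,
        )
    if name == "rf":
        return RandomForestClassifier(**{"n_estimators": 200, **params}, random_state=seed)
    if name == "ab":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "knn":
        return KNeighborsClassifier(**params)
    if name == "gnb":
        return GaussianNB(**params)
    raise ValueError(f"unknown classifier {name!r}")


def _param_grid(grid: dict[str, list]) -> list[dict]:
    items = sorted(grid.items())
    combos: list[dict] = [{}]
    for key, values in items:
        combos = [{**c, key: v} for c in combos for v in values]
    return combos


def _score_samples(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def fit_classifier(
    name: str,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    cfg: CVConfig,
    seed: int,
):
    """Fit one classifier with hyperparameters tuned by subject-grouped CV.

    Returns ``(model, chosen_params)``; the model exposes a continuous score
    via predict_proba or decision_function.
    """
    grid = cfg.grids.get(name, DEFAULT_GRIDS.get(name, {}))
    combos = _param_grid(grid)
    best_params = combos[0]
    if len(combos) > 1:
        splitter = _inner_splitter(cfg, groups)
        accs = np.zeros(len(combos))
        n_folds = 0
        for tr, va in splitter.split(X, y, groups):
            if len(set(y[tr])) < 2:
                continue
            n_folds += 1
            for i, params in enumerate(combos):
                model = _make_classifier(name, params, seed)
                model.fit(X[tr], y[tr])
                accs[i] += np.mean(model.predict(X[va]) == y[va])
        if n_folds:
            best_params = combos[int(np.argmax(accs))]
    model = _make_classifier(name, best_params, seed)
    model.fit(X, y)
    return model, best_params


@dataclass
class CVReport:
    """Aggregated CV results: per-repeat metrics, averaged ROC curves, and
    per-feature LASSO selection counts."""

    metrics: pd.DataFrame  # columns: repeat, classifier, accuracy, auc
    roc_curves: dict[str, np.ndarray]  # classifier -> mean TPR on FPR_GRID
    selection_counts: dict[str, int]
    n_iterations: int  # folds x repeats
    n_repeats: int
    n_folds: int
    config: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return (
            self.metrics.groupby("classifier")[["accuracy", "auc"]]
            .agg(["mean", "std"])
            .sort_index()
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metrics": self.metrics.to_dict(orient="list"),
            "roc_curves": {k: v.tolist() for k, v in self.roc_curves.items()},
            "fpr_grid": FPR_GRID.tolist(),
            "selection_counts": self.selection_counts,
            "n_iterations": self.n_iterations,
            "n_repeats": self.n_repeats,
            "n_folds": self.n_folds,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CVReport":
        payload = json.loads(Path(path).read_text())
        metric_cols = ["repeat", "classifier", "accuracy", "auc"]
        return cls(
            metrics=pd.DataFrame(payload["metrics"])[metric_cols],
            roc_curves={k: np.asarray(v) for k, v in payload["roc_curves"].items()},
            selection_counts=payload["selection_counts"],
            n_iterations=payload["n_iterations"],
            n_repeats=payload["n_repeats"],
            n_folds=payload["n_folds"],
            config=payload.get("config", {}),
        )


def run_cv(table: pd.DataFrame, cfg: CVConfig | None = None) -> CVReport:
    """Repeated LOSO CV: standardize -> LASSO select -> fit classifiers ->
    score held-out rows, pooled per repetition."""
    cfg = cfg or CVConfig()
    feats = feature_columns(table)
    if "label" not in table.columns:
        raise ValueError("table is not labeled")
    X_all = table[feats].to_numpy(dtype=float)
    y_all = (table["label"] == "high").to_numpy(dtype=float)
    subj_all = table["subject_id"].astype(str).to_numpy()
    folds = list(loso_splits(table))
    n_folds = len(folds)

    metric_rows = []
    tpr_acc: dict[str, list[np.ndarray]] = {name: [] for name in cfg.classifiers}
    selection_counts: dict[str, int] = {f: 0 for f in feats}

    for r in range(cfg.n_repeats):
        seed = cfg.base_seed + r
        pooled_scores: dict[str, list[np.ndarray]] = {n: [] for n in cfg.classifiers}
        pooled_preds: dict[str, list[np.ndarray]] = {n: [] for n in cfg.classifiers}
        pooled_truth: list[np.ndarray] = []
        for held_out, tr_idx, te_idx in folds:
            assert not set(subj_all[tr_idx]) & set(subj_all[te_idx])  # no leakage
            X_tr, X_te, _ = standardize(X_all[tr_idx], X_all[te_idx])
            y_tr, y_te = y_all[tr_idx], y_all[te_idx]
            g_tr = subj_all[tr_idx]
            selected = lasso_select(X_tr, y_tr, g_tr, feats, cfg, seed)
            for f in selected:
                selection_counts[f] += 1
            sel_idx = [feats.index(f) for f in selected]
            Xs_tr, Xs_te = X_tr[:, sel_idx], X_te[:, sel_idx]
            pooled_truth.append(y_te)
            for name in cfg.classifiers:
                model, params = fit_classifier(name, Xs_tr, y_tr, g_tr, cfg, seed)
                pooled_preds[name].append(model.predict(Xs_te))
                pooled_scores[name].append(_score_samples(model, Xs_te))
            logger.info("repeat %d fold %s: %d features selected", r, held_out, len(selected))
        y_true = np.concatenate(pooled_truth)
        for name in cfg.classifiers:
            y_pred = np.concatenate(pooled_preds[name])
            y_score = np.concatenate(pooled_scores[name])
            accuracy = float(np.mean(y_pred == y_true))
            fpr, tpr, _ = roc_curve(y_true, y_score)
            auc_val = float(auc(fpr, tpr))
            tpr_interp = np.interp(FPR_GRID, fpr, tpr)
            tpr_interp[0], tpr_interp[-1] = 0.0, 1.0
            tpr_acc[name].append(tpr_interp)
            metric_rows.append(
                {"repeat": r, "classifier": name, "accuracy": accuracy, "auc": auc_val}
            )

    return CVReport(
        metrics=pd.DataFrame(metric_rows),
        roc_curves={name: np.mean(np.stack(v), axis=0) for name, v in tpr_acc.items()},
        selection_counts=selection_counts,
        n_iterations=n_folds * cfg.n_repeats,
        n_repeats=cfg.n_repeats,
        n_folds=n_folds,
        config={
            "n_repeats": cfg.n_repeats,
            "base_seed": cfg.base_seed,
            "classifiers": list(cfg.classifiers),
            "inner_cv": cfg.inner_cv,
        },
    )
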