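"""Random-forest diagnostic models: stratified 10-fold cross-validation,
operating-point selection at a target specificity, bi-omics feature fusion,
and the CA19-9 OR-rule integration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

CA199_CUTOFF = 37.0

DEFAULT_RF_PARAMS = {"n_estimators": 500, "max_features": "sqrt", "max_depth": None}


@dataclass
class ModelBundle:
    """A deployable classifier: frozen feature order, fitted forest,
    decision threshold and the seed/folds that produced it."""

    feature_names: list[str]
    model: RandomForestClassifier
    threshold: float
    seed: int
    fold_assignments: pd.Series
    cv_auc: float
    rf_params: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        """JSON metadata plus a joblib sidecar holding the fitted forest."""
        path = Path(path)
        sidecar = path.with_suffix(".joblib")
        meta = {
            "feature_names": self.feature_names,
            "threshold": float(self.threshold),
            "seed": int(self.seed),
            "cv_auc": float(self.cv_auc),
            "rf_params": self.rf_params,
            "fold_assignments": {str(k): int(v)
                                 for k, v in self.fold_assignments.items()},
            "model_file": sidecar.name,
        }
        path.write_text(json.dumps(meta, indent=2))
        joblib.dump(self.model, sidecar)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        path = Path(path)
        meta = json.loads(path.read_text())
        model = joblib.load(path.parent / meta["model_file"])
        folds = pd.Series(meta["fold_assignments"])
        return cls(meta["feature_names"], model, meta["threshold"],
                   meta["seed"], folds, meta["cv_auc"], meta.get("rf_params", {}))


def train_rf_cv(X: pd.DataFrame, y, n_folds: int = 10, seed: int = 0,
                rf_params: dict | None = None
                ) -> tuple[ModelBundle, pd.Series, float]:
    """Stratified k-fold CV followed by a refit on all training rows.

    Returns (bundle, out-of-fold score per training sample, CV AUC on the
    pooled out-of-fold scores). The bundle's threshold is initialised to 0.5
    and is normally replaced via :func:`choose_threshold`.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < n_folds:
        raise ValueError(
            f"need >= {n_folds} samples per class for {n_folds}-fold CV")
    params = dict(DEFAULT_RF_PARAMS, **(rf_params or {}))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % 2 ** 31)
    oof = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        forest = RandomForestClassifier(random_state=(int(seed) + fold + 1) % 2 ** 31,
                                        n_jobs=1, **params)
        forest.fit(X.iloc[tr], y[tr])
        oof[te] = forest.predict_proba(X.iloc[te])[:, 1]
        fold_of[te] = fold
    cv_auc = float(roc_auc_score(y, oof))
    final = RandomForestClassifier(random_state=int(seed) % 2 ** 31, n_jobs=1, **params)
    final.fit(X, y)
    oof_series = pd.Series(oof, index=X.index, name="oof_score")
    bundle = ModelBundle(list(X.columns), final, 0.5, int(seed),
                         pd.Series(fold_of, index=X.index, name="fold"),
                         cv_auc, params)
    return bundle, oof_series, cv_auc


def choose_threshold(scores, labels, target_specificity: float) -> float:
    """Smallest threshold whose specificity on ``scores`` meets the target.

    A call is positive when score >= threshold. The returned cut is the
    midpoint between the bracketing observed scores (stable under small
    score perturbations); a target beyond what the controls allow yields a
    threshold above the maximum score with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes required to choose a threshold")
    controls = np.sort(scores[~labels])
    n_ctrl = len(controls)
    if n_ctrl == 0:
        raise ValueError("no controls supplied")
    all_sorted = np.unique(scores)
    if target_specificity <= 0:
        return float(all_sorted[0] - 1e-9)
    # candidate cuts sit just above each control score; specificity of a cut
    # above controls[i-1] is i / n_ctrl
    for i in range(n_ctrl):
        spec = (i + 1) / n_ctrl  # controls[0..i] called negative
        if spec >= target_specificity:
            boundary = controls[i]
            higher = all_sorted[all_sorted > boundary]
            if len(higher):
                return float((boundary + higher[0]) / 2.0)
            warnings.warn("threshold sits above every observed score "
                          "(score ties at the maximum); sensitivity may be 0")
            return float(boundary + 1e-9)
    raise AssertionError("unreachable: specificity 1.0 is always achievable")


def predict(bundle: ModelBundle, X: pd.DataFrame) -> pd.DataFrame:
    """Score samples with a fitted bundle; columns align by name."""
    X = pd.DataFrame(X)
    missing = [f for f in bundle.feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    if not len(X):
        return pd.DataFrame(columns=["score", "call"])
    scores = bundle.model.predict_proba(X[bundle.feature_names])[:, 1]
    return pd.DataFrame({"score": scores, "call": scores >= bundle.threshold},
                        index=X.index)


def fuse_bi_omics(methyl_X: pd.DataFrame, mutation_X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise fusion of methylation ratios and binary mutation features.

    Sample order follows ``methyl_X``; samples absent from the mutation
    matrix get zero rows (no variant detected) with a warning.
    """
    missing = methyl_X.index.difference(mutation_X.index)
    if len(missing):
        logger.warning("%d sample(s) missing mutation features; filled with 0",
                       len(missing))
    mut = mutation_X.reindex(methyl_X.index).fillna(0).astype(np.int64)
    return pd.concat([methyl_X, mut], axis=1)


def integrate_ca199(calls: pd.Series, ca199: pd.Series,
                    cutoff: float = CA199_CUTOFF) -> pd.Series:
    """OR-rule: positive iff methylation call OR CA19-9 strictly > cutoff.

    Missing CA19-9 reduces the rule to the methylation call alone.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = pd.Series(ca199).reindex(calls.index)
    if (ca.dropna() < 0).any():
        raise ValueError("negative CA19-9 value")
    elevated = (ca > cutoff).fillna(False)
    return calls.astype(bool) | elevated
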