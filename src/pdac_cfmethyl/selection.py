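"""Three-step marker-selection cascade for plasma DMR methylation features.

1. All-relevant selection by a shadow-feature (Boruta-style) procedure:
   every feature is duplicated as a within-column permutation ("shadow"),
   a random forest is fit on the augmented matrix, and a real feature
   scores a "hit" whenever its importance exceeds the best shadow
   importance; hit counts are tested against Binomial(n_iter, 1/2).
2. Minimal-optimal reduction by recursive feature elimination (RFE) with a
   cross-validated AUC curve and the one-standard-error size rule.
3. A tissue-plasma concordance filter that keeps only tissue-hyper markers
   whose plasma methylation is elevated in cases (one-sided rank-sum).

The final marker set is always nested: final <= stage2 <= stage1 <= input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    """Outcome of the cascade; feature lists are ordered and nested."""

    stage1_selected: list[str]
    stage2_selected: list[str]
    final_markers: list[str]
    boruta: dict = field(default_factory=dict)
    rfe_curve: pd.DataFrame | None = None
    concordance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not set(self.final_markers) <= set(self.stage2_selected) <= set(self.stage1_selected):
            raise ValueError("selection stages are not nested")


def _forest(seed: int, n_estimators: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt",
        random_state=int(seed) % (2 ** 31), n_jobs=1)


# ---------------------------------------------------------------------------
# stage 1: shadow-feature all-relevant selection
# ---------------------------------------------------------------------------

def boruta_select(X: pd.DataFrame, y, max_iter: int = 50, alpha: float = 0.05,
                  seed: int = 0, n_estimators: int = 200
                  ) -> tuple[list[str], dict]:
    """All-relevant feature selection via shadow features.

    Per iteration a permuted copy of every column is appended, a forest is
    fit on the augmented matrix, and each real feature records a hit when
    its impurity importance beats the maximum shadow importance. After
    ``max_iter`` iterations features are accepted/rejected by one-sided
    binomial tests at ``alpha`` with Holm step-down correction across
    features; unresolved ("tentative") features are resolved by comparing
    their median importance with the median of the per-iteration maximum
    shadow importances.
    """
    if max_iter < 20:
        warnings.warn("max_iter < 20 leaves the binomial test underpowered")
    X = pd.DataFrame(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    features = list(X.columns)
    hits = np.zeros(p, dtype=int)
    imp_history = np.empty((max_iter, p))
    shadow_max_history = np.empty(max_iter)
    values = X.to_numpy(float)
    for it in range(max_iter):
        shadow = rng.permuted(values, axis=0)  # each column shuffled independently
        aug = np.hstack([values, shadow])
        forest = _forest(rng.integers(2 ** 31), n_estimators)
        forest.fit(aug, y)
        imp = forest.feature_importances_
        real_imp, shadow_imp = imp[:p], imp[p:]
        shadow_max = shadow_imp.max() if p else 0.0
        hits += real_imp > shadow_max
        imp_history[it] = real_imp
        shadow_max_history[it] = shadow_max

    p_accept = np.array([stats.binomtest(h, max_iter, 0.5, alternative="greater").pvalue
                         for h in hits])
    p_reject = np.array([stats.binomtest(h, max_iter, 0.5, alternative="less").pvalue
                         for h in hits])
    accepted = _holm_reject(p_accept, alpha)
    rejected = _holm_reject(p_reject, alpha) & ~accepted
    tentative = ~accepted & ~rejected
    if tentative.any():
        med_shadow = float(np.median(shadow_max_history))
        med_imp = np.median(imp_history, axis=0)
        accepted |= tentative & (med_imp > med_shadow)
    selected = [f for f, a in zip(features, accepted) if a]
    report = {
        "hits": dict(zip(features, hits.tolist())),
        "n_iterations": max_iter,
        "p_accept": dict(zip(features, p_accept.tolist())),
        "decision": {f: ("accepted" if a else "rejected" if r else "tentative")
                     for f, a, r in zip(features, accepted, rejected)},
        "n_tentative_resolved": int(tentative.sum()),
        "median_shadow_importance": float(np.median(shadow_max_history)),
    }
    return selected, report


def _holm_reject(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Holm step-down rejections for a family of one-sided p-values."""
    m = len(pvalues)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(pvalues)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvalues[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


# ---------------------------------------------------------------------------
# stage 2: recursive feature elimination with one-SE size rule
# ---------------------------------------------------------------------------

def default_subset_sizes(p: int) -> list[int]:
    """Geometric-ish elimination grid from p down to 1."""
    sizes = set()
    s = p
    while s >= 1:
        sizes.add(int(s))
        s = int(np.floor(s * 0.75)) if int(np.floor(s * 0.75)) < s else s - 1
    sizes |= {x for x in (1, 2, 3, 4, 6, 8, 10, 13) if x <= p}
    return sorted(sizes, reverse=True)


def rfe_select(X: pd.DataFrame, y, subset_sizes: list[int] | None = None,
               cv_folds: int = 5, seed: int = 0, n_estimators: int = 200
               ) -> tuple[list[str], pd.DataFrame]:
    """Recursive feature elimination over a size grid.

    At each size the cross-validated AUC is recorded, then a forest fit on
    all rows ranks the surviving features and the lowest-ranked are dropped
    to reach the next size. The returned subset is the smallest whose CV
    AUC is within one standard error of the curve maximum.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    p = X.shape[1]
    if p == 0:
        raise ValueError("empty feature matrix")
    if p == 1:
        return list(X.columns), pd.DataFrame(
            {"size": [1], "cv_auc": [np.nan], "se": [np.nan],
             "features": [list(X.columns)]})
    if subset_sizes is None:
        subset_sizes = default_subset_sizes(p)
    else:
        clipped = sorted({min(s, p) for s in subset_sizes if s >= 1}, reverse=True)
        if clipped != sorted(set(subset_sizes), reverse=True):
            warnings.warn("subset_sizes clipped to the available feature count")
        subset_sizes = clipped
    rng = np.random.default_rng(seed)
    current = list(X.columns)
    records = []
    for size in subset_sizes:
        if size < len(current):
            forest = _forest(rng.integers(2 ** 31), n_estimators)
            forest.fit(X[current], y)
            ranked = [f for _, f in sorted(
                zip(forest.feature_importances_, current),
                key=lambda t: (-t[0], t[1]))]
            current = ranked[:size]
        aucs = _cv_aucs(X[current], y, cv_folds,
                        int(rng.integers(2 ** 31)), n_estimators)
        records.append({
            "size": size, "cv_auc": float(np.mean(aucs)),
            "se": float(np.std(aucs, ddof=1) / np.sqrt(len(aucs))),
            "features": list(current),
        })
    curve = pd.DataFrame(records)
    best = curve.loc[curve["cv_auc"].idxmax()]
    cutoff = best["cv_auc"] - best["se"]
    eligible = curve[curve["cv_auc"] >= cutoff]
    chosen = eligible.loc[eligible["size"].idxmin()]
    return list(chosen["features"]), curve


def _cv_aucs(X: pd.DataFrame, y: np.ndarray, folds: int, seed: int,
             n_estimators: int) -> list[float]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        forest = _forest(seed + len(aucs) + 1, n_estimators)
        forest.fit(X.iloc[tr], y[tr])
        score = forest.predict_proba(X.iloc[te])[:, 1]
        aucs.append(roc_auc_score(y[te], score))
    return aucs


# ---------------------------------------------------------------------------
# stage 3: tissue-plasma concordance filter
# ---------------------------------------------------------------------------

def concordance_filter(candidates: list[str], tissue_directions: dict[str, str],
                       plasma_X: pd.DataFrame, y, alpha: float = 0.05,
                       max_missing_frac: float = 0.5
                       ) -> tuple[list[str], pd.DataFrame]:
    """Keep candidates that are tissue-hyper AND plasma-elevated in cases.

    Plasma elevation requires both PDAC median > healthy median and a
    one-sided Wilcoxon rank-sum p < alpha on the non-missing values.
    Markers missing in more than ``max_missing_frac`` of plasma samples are
    excluded with a log message. ``y`` is 1 for PDAC, 0 for healthy.
    """
    y = np.asarray(y).astype(bool)
    final, rows = [], []
    for marker in candidates:
        direction = tissue_directions.get(marker, "unknown")
        col = plasma_X[marker]
        missing_frac = float(col.isna().mean())
        case_vals = col[y].dropna()
        ctrl_vals = col[~y].dropna()
        record = {"marker": marker, "tissue_direction": direction,
                  "missing_frac": missing_frac,
                  "median_pdac": float(case_vals.median()) if len(case_vals) else np.nan,
                  "median_healthy": float(ctrl_vals.median()) if len(ctrl_vals) else np.nan,
                  "p_one_sided": np.nan, "kept": False}
        if missing_frac > max_missing_frac:
            logger.info("marker %s missing in %.0f%% of plasma samples; excluded",
                        marker, 100 * missing_frac)
        elif direction == "hyper" and len(case_vals) and len(ctrl_vals):
            res = stats.mannwhitneyu(case_vals, ctrl_vals, alternative="greater")
            record["p_one_sided"] = float(res.pvalue)
            if (record["median_pdac"] > record["median_healthy"]
                    and res.pvalue < alpha):
                record["kept"] = True
                final.append(marker)
        rows.append(record)
    return final, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def impute_train_median(X: pd.DataFrame, train_index) -> pd.DataFrame:
    """Median-impute missing values using training rows only."""
    med = X.loc[train_index].median()
    med = med.fillna(0.5)  # all-missing feature: neutral methylation ratio
    return X.fillna(med)


def select_markers(plasma_X: pd.DataFrame, y, tissue_directions: dict[str, str],
                   seed: int = 0, boruta_iter: int = 50, alpha: float = 0.05,
                   cv_folds: int = 5, n_estimators: int = 200,
                   subset_sizes: list[int] | None = None) -> SelectionReport:
    """Run the three-step cascade on (training) plasma data.

    ``plasma_X`` may contain NaN; imputation by per-feature median happens
    here, on these rows only — callers must pass training rows exclusively.
    """
    y = np.asarray(y)
    X_imp = impute_train_median(plasma_X, plasma_X.index)
    ss = np.random.SeedSequence(seed).spawn(2)
    stage1, boruta_report = boruta_select(
        X_imp, y, max_iter=boruta_iter, alpha=alpha,
        seed=int(ss[0].generate_state(1)[0] % (2 ** 31)),
        n_estimators=n_estimators)
    if not stage1:
        logger.warning("shadow-feature selection accepted no features")
        return SelectionReport(stage1_selected=[], stage2_selected=[],
                               final_markers=[], boruta=boruta_report)
    stage2, curve = rfe_select(
        X_imp[stage1], y, subset_sizes=subset_sizes, cv_folds=cv_folds,
        seed=int(ss[1].generate_state(1)[0] % (2 ** 31)),
        n_estimators=n_estimators)
    final, conc = concordance_filter(stage2, tissue_directions, plasma_X, y,
                                     alpha=alpha)
    return SelectionReport(stage1_selected=stage1, stage2_selected=stage2,
                           final_markers=final, boruta=boruta_report,
                           rfe_curve=curve, concordance=conc)
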