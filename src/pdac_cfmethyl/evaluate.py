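"""Diagnostic performance metrics and group comparisons.

AUC is computed through the Mann-Whitney identity (all case/control pairs
concordance with ties counted one half), so it agrees exactly with
U / (n1 * n2) from the rank-sum statistic on the same data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

STAGE_GROUPS = ("0+I", "II", "III", "IV")


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """AUC plus ROC curve points at every distinct score.

    AUC = (R_cases - n1(n1+1)/2) / (n1 * n0) with midranks, i.e. the
    probability a random case outscores a random control, ties counting 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for ROC analysis")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    cuts = np.unique(scores)[::-1]
    tpr = [(scores[labels] >= c).mean() for c in cuts]
    fpr = [(scores[~labels] >= c).mean() for c in cuts]
    curve = pd.DataFrame({"threshold": cuts, "tpr": tpr, "fpr": fpr})
    curve = pd.concat([pd.DataFrame({"threshold": [np.inf], "tpr": [0.0], "fpr": [0.0]}),
                       curve], ignore_index=True)
    return float(auc), curve


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the AUC (resampling within class)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    point, _ = roc_auc(scores, labels)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(labels)
    ctrl_idx = np.flatnonzero(~labels)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(case_idx, len(case_idx)),
                              rng.choice(ctrl_idx, len(ctrl_idx))])
        draws[b], _ = roc_auc(scores[idx], labels[idx])
    lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
    return point, float(lo), float(hi)


def sensitivity_specificity(calls, labels) -> dict:
    calls = np.asarray(calls).astype(bool)
    labels = np.asarray(labels).astype(bool)
    n_case, n_ctrl = int(labels.sum()), int((~labels).sum())
    return {
        "sensitivity": float(calls[labels].mean()) if n_case else np.nan,
        "specificity": float((~calls[~labels]).mean()) if n_ctrl else np.nan,
        "n_cases": n_case, "n_controls": n_ctrl,
    }


def stage_group(stage: str, merge_stage0: bool = True) -> str:
    from .io import normalize_stage
    stage = normalize_stage(stage)
    if merge_stage0:
        return "0+I" if stage in ("0", "I") else stage
    return stage


def sensitivity_by_stage(calls, labels, stages,
                         merge_stage0: bool = True) -> pd.DataFrame:
    """Per-stage sensitivity table for the cases, plus an overall row.

    Stage 0 is merged with stage I by default (switchable) since stage-0
    cases are too rare to report alone.
    """
    calls = np.asarray(calls).astype(bool)
    labels = np.asarray(labels).astype(bool)
    stages = np.asarray(stages, dtype=object)
    rows = []
    case_calls = calls[labels]
    case_stages = np.array([stage_group(s, merge_stage0) for s in stages[labels]])
    groups = STAGE_GROUPS if merge_stage0 else ("0", "I", "II", "III", "IV")
    for g in groups:
        sel = case_stages == g
        n = int(sel.sum())
        rows.append({"stage": g, "n": n, "n_positive": int(case_calls[sel].sum()),
                     "sensitivity": float(case_calls[sel].mean()) if n else np.nan})
    rows.append({"stage": "overall", "n": int(labels.sum()),
                 "n_positive": int(case_calls.sum()),
                 "sensitivity": float(case_calls.mean()) if labels.any() else np.nan})
    return pd.DataFrame(rows)


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney test, two-sided.

    Exact null enumeration when min(n_a, n_b) <= 8 and there are no ties;
    otherwise the normal approximation with tie correction. Returns
    (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one value")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def rescue_analysis(calls: pd.Series, ca199: pd.Series,
                    cutoff: float = 37.0) -> dict:
    """Among CA19-9-negative cases (<= cutoff), how many does the
    methylation model still call positive?"""
    ca = pd.Series(ca199).reindex(calls.index)
    negative = ca.notna() & (ca <= cutoff)
    n_neg = int(negative.sum())
    n_rescued = int(calls[negative].astype(bool).sum())
    return {
        "n_ca199_negative": n_neg,
        "n_rescued": n_rescued,
        "fraction_rescued": n_rescued / n_neg if n_neg else np.nan,
    }


def evaluation_report(scores, calls, labels, stages=None, ca199=None,
                      threshold: float | None = None, n_boot: int = 1000,
                      seed: int = 0) -> dict:
    """Assemble the full evaluation: AUC (with bootstrap CI), operating
    point, optional per-stage sensitivities and CA19-9 rescue."""
    auc, lo, hi = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
    report = {"auc": auc, "auc_ci": [lo, hi], "threshold": threshold}
    report.update(sensitivity_specificity(calls, labels))
    if stages is not None:
        table = sensitivity_by_stage(calls, labels, stages)
        report["by_stage"] = table.to_dict("records")
    if ca199 is not None:
        labels_arr = np.asarray(labels).astype(bool)
        calls_s = pd.Series(np.asarray(calls).astype(bool))
        ca_s = pd.Series(np.asarray(ca199, dtype=float))
        case_calls = calls_s[labels_arr].reset_index(drop=True)
        case_ca = ca_s[labels_arr].reset_index(drop=True)
        report["rescue"] = rescue_analysis(case_calls, case_ca)
    return report
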