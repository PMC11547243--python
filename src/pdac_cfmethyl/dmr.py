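"""Differentially methylated region (DMR) calling from paired tumor/NAT
bisulfite count tables.

The model is an empirical-Bayes beta-binomial reading of a smoothed
hierarchical caller: per-sample methylation proportions are smoothed by a
coverage-weighted flat kernel, per-CpG overdispersion (the beta-binomial
intra-class correlation phi) is estimated by method of moments and shrunk
toward the genome-wide mean, and a paired Wald test aggregates per-pair
smoothed differences by inverse-variance weighting. Candidate regions are
maximal runs of same-direction differentially methylated CpGs, and a region
is emitted only if it passes all four criteria:

* |mean methylation difference| > 0.2 (on smoothed values),
* region length >= 50 bp,
* >= 3 CpG sites,
* >= 80% of member CpGs individually differentially methylated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io import CpGCountTable, AnnotationTrack, GENIC_CATEGORIES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DmrCriteria:
    """Region-level call criteria plus the per-CpG and smoothing knobs.

    The four region rules (min_abs_diff, min_len_bp, min_cpg, min_dm_frac)
    define what a DMR is; the per-CpG thresholds (p_cpg, diff_cpg) fix the
    otherwise-undefined notion of a "differentially methylated CpG" that the
    80% rule needs; max_gap_bp bounds region sprawl and smooth_window_bp is
    the flat-kernel width.
    """

    min_abs_diff: float = 0.2
    min_len_bp: int = 50
    min_cpg: int = 3
    min_dm_frac: float = 0.8
    p_cpg: float = 0.05
    diff_cpg: float = 0.1
    max_gap_bp: int = 500
    smooth_window_bp: int = 200
    min_pairs: int = 10
    dispersion_prior_weight: float = 20.0

    def __post_init__(self) -> None:
        if min(self.min_abs_diff, self.min_len_bp, self.min_cpg,
               self.p_cpg, self.diff_cpg, self.max_gap_bp,
               self.smooth_window_bp) <= 0:
            raise ValueError("all DmrCriteria thresholds must be positive")
        if not (0 < self.min_dm_frac <= 1):
            raise ValueError("min_dm_frac must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DmrCriteria":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# table stacking
# ---------------------------------------------------------------------------

def _stack(tables: Sequence[CpGCountTable]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Stack tables sharing one CpG universe into (index, meth, total) matrices."""
    if not tables:
        raise ValueError("no tables supplied")
    index = tables[0].df[["chrom", "pos"]].reset_index(drop=True)
    n_cpg = len(index)
    meth = np.empty((len(tables), n_cpg), dtype=np.int64)
    total = np.empty((len(tables), n_cpg), dtype=np.int64)
    for i, t in enumerate(tables):
        if len(t.df) != n_cpg or not (
                t.df["pos"].to_numpy() == index["pos"].to_numpy()).all() or not (
                t.df["chrom"].to_numpy() == index["chrom"].to_numpy()).all():
            raise ValueError(
                f"table {t.sample_id} does not share the CpG universe of {tables[0].sample_id}")
        meth[i] = t.df["n_meth"].to_numpy()
        total[i] = t.df["n_total"].to_numpy()
    return index, meth, total


def _window_bounds(pos: np.ndarray, window_bp: int) -> tuple[np.ndarray, np.ndarray]:
    half = window_bp / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    return lo, hi


def _window_sum(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Sliding-window sums along the last axis via cumulative sums."""
    csum = np.concatenate([np.zeros(values.shape[:-1] + (1,)),
                           np.cumsum(values, axis=-1)], axis=-1)
    return csum[..., hi] - csum[..., lo]


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_methylation(table: CpGCountTable, window_bp: int) -> pd.DataFrame:
    """Coverage-weighted flat-kernel smoothing of one sample's proportions.

    Each CpG's smoothed proportion is sum(n_meth)/sum(n_total) over CpGs on
    the same chromosome within +/- window_bp/2. An isolated CpG keeps its raw
    proportion; a CpG whose window has zero total coverage is missing (NaN).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    parts = []
    for chrom, sub in table.df.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        lo, hi = _window_bounds(pos, window_bp)
        mw = _window_sum(sub["n_meth"].to_numpy().astype(float), lo, hi)
        nw = _window_sum(sub["n_total"].to_numpy().astype(float), lo, hi)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nw > 0, mw / np.where(nw > 0, nw, 1), np.nan)
        parts.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                   "p_smooth": p, "n_window": nw}))
    if not parts:
        return pd.DataFrame(columns=["chrom", "pos", "p_smooth", "n_window"])
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

PHI_MIN, PHI_MAX = 1e-6, 0.99


def _raw_dispersion(meth: np.ndarray, total: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG method-of-moments phi for one group (samples x cpgs).

    Uses the chi-square moment estimator: with K covered samples of sizes
    n_k and pooled proportion p-bar,
      X^2 = sum n_k (p_k - p-bar)^2 / (p-bar (1 - p-bar)),
      phi-hat = (X^2 / (K - 1) - 1) / (n-bar - 1).
    Returns (phi, df) with df = K - 1 used as the shrinkage information
    weight; CpGs with < 2 covered samples or degenerate p-bar get df 0.
    """
    covered = total > 0
    k = covered.sum(axis=0)
    tot = np.where(covered, total, 0)
    met = np.where(covered, meth, 0)
    n_sum = tot.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(n_sum > 0, met.sum(axis=0) / np.where(n_sum > 0, n_sum, 1), np.nan)
        pk = np.where(covered & (tot > 0), met / np.where(tot > 0, tot, 1), 0.0)
        num = (tot * (pk - pbar) ** 2).sum(axis=0)
        denom = pbar * (1 - pbar)
        x2 = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
        nbar = np.where(k > 0, n_sum / np.where(k > 0, k, 1), 0.0)
        phi = (x2 / np.maximum(k - 1, 1) - 1.0) / np.maximum(nbar - 1.0, 1e-9)
    df = np.maximum(k - 1, 0).astype(float)
    usable = (k >= 2) & (denom > 0) & (nbar > 1)
    phi = np.where(usable, np.clip(phi, PHI_MIN, PHI_MAX), np.nan)
    df = np.where(usable, df, 0.0)
    return phi, df


def estimate_dispersion(tables: Sequence[CpGCountTable],
                        prior_weight: float = 20.0,
                        more_tables: Sequence[CpGCountTable] | None = None
                        ) -> np.ndarray:
    """Shrunk per-CpG beta-binomial dispersion for one or two groups.

    Raw method-of-moments estimates are shrunk toward the genome-wide
    df-weighted mean phi-bar with weight ``prior_weight`` pseudo-degrees of
    freedom (empirical Bayes); prior_weight = inf returns phi-bar everywhere.
    """
    _, meth, total = _stack(tables)
    phi, df = _raw_dispersion(meth, total)
    if more_tables is not None:
        _, m2, t2 = _stack(more_tables)
        phi2, df2 = _raw_dispersion(m2, t2)
        both = np.nan_to_num(phi * df) + np.nan_to_num(phi2 * df2)
        dfs = df + df2
        phi = np.where(dfs > 0, both / np.maximum(dfs, 1e-12), np.nan)
        df = dfs
    good = df > 0
    if not good.any():
        raise ValueError("no CpG with enough coverage to estimate dispersion")
    phi_bar = float(np.average(phi[good], weights=df[good]))
    if np.isinf(prior_weight):
        return np.full_like(df, phi_bar, dtype=float)
    shrunk = (np.nan_to_num(phi) * df + phi_bar * prior_weight) / (df + prior_weight)
    return np.clip(shrunk, PHI_MIN, PHI_MAX)


# ---------------------------------------------------------------------------
# per-CpG differential test
# ---------------------------------------------------------------------------

def test_cpg_differential(tumor_tables: Sequence[CpGCountTable],
                          nat_tables: Sequence[CpGCountTable],
                          criteria: DmrCriteria = DmrCriteria(),
                          phi: float | np.ndarray | None = None,
                          ) -> pd.DataFrame:
    """Paired beta-binomial Wald test on smoothed methylation.

    Per pair k the smoothed proportions are mapped to the variance-
    stabilizing arcsine-square-root scale g = arcsin(sqrt(p)), on which the
    beta-binomial model variance Var(g) = sum n_i (1 + (n_i - 1) phi_i) /
    (4 N^2) no longer depends on p — this keeps the test calibrated and
    powered at near-0/near-1 methylation, where the plain proportion-scale
    normal approximation collapses. The statistic is the inverse-variance
    weighted mean of per-pair g-differences divided by its standard error,
    referred to the normal distribution (two-sided). Reported ``diff`` (and
    the dm threshold) stay on the proportion scale; ``se`` is the
    delta-method proportion-scale equivalent.

    Returns a CpGStat frame (chrom, pos, mu_tumor, mu_nat, diff, se, z, p,
    is_dm) restricted to CpGs covered in >= criteria.min_pairs pairs; the
    exclusion count is stored in ``frame.attrs["qc"]``.
    """
    if len(tumor_tables) != len(nat_tables):
        raise ValueError("tumor and NAT table lists must pair up")
    n_pairs = len(tumor_tables)
    index, meth_t, total_t = _stack(list(tumor_tables))
    index_n, meth_n, total_n = _stack(list(nat_tables))
    if not index.equals(index_n):
        raise ValueError("tumor and NAT tables do not share a CpG universe")

    if phi is None:
        phi_arr = estimate_dispersion(list(tumor_tables),
                                      criteria.dispersion_prior_weight,
                                      more_tables=list(nat_tables))
    else:
        phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (len(index),)).copy()

    chrom_arr = index["chrom"].to_numpy()
    pos_all = index["pos"].to_numpy()
    p_hat = {}
    g_hat = {}
    var_g = {}
    for label, meth, total in (("T", meth_t, total_t), ("N", meth_n, total_n)):
        p = np.empty((n_pairs, len(index)))
        g = np.empty((n_pairs, len(index)))
        v = np.empty((n_pairs, len(index)))
        for chrom in pd.unique(chrom_arr):
            sel = chrom_arr == chrom
            pos = pos_all[sel]
            lo, hi = _window_bounds(pos, criteria.smooth_window_bp)
            m_c = meth[:, sel].astype(float)
            n_c = total[:, sel].astype(float)
            mw = _window_sum(m_c, lo, hi)
            nw = _window_sum(n_c, lo, hi)
            with np.errstate(invalid="ignore", divide="ignore"):
                ps = np.where(nw > 0, mw / np.where(nw > 0, nw, 1), np.nan)
            # Var(arcsin sqrt(p-hat)) = sum n_i (1 + (n_i - 1) phi_i) / (4 N^2)
            a = n_c * (1.0 + (n_c - 1.0) * phi_arr[sel])
            aw = _window_sum(a, lo, hi)
            with np.errstate(invalid="ignore", divide="ignore"):
                vs = np.where(nw > 0, aw / (4.0 * np.maximum(nw, 1) ** 2), np.nan)
            p[:, sel] = ps
            g[:, sel] = np.arcsin(np.sqrt(np.clip(ps, 0.0, 1.0)))
            v[:, sel] = vs
        p_hat[label] = p
        g_hat[label] = g
        var_g[label] = v

    d_g = g_hat["T"] - g_hat["N"]
    var_pair = var_g["T"] + var_g["N"]
    ok = np.isfinite(d_g) & np.isfinite(var_pair) & (var_pair > 0)
    w = np.where(ok, 1.0 / np.where(var_pair > 0, var_pair, 1.0), 0.0)
    w_sum = w.sum(axis=0)
    n_ok = ok.sum(axis=0)
    keep = n_ok >= min(criteria.min_pairs, n_pairs)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff_g = (w * np.nan_to_num(d_g)).sum(axis=0) / np.where(w_sum > 0, w_sum, np.nan)
        diff = (w * np.nan_to_num(p_hat["T"] - p_hat["N"])).sum(axis=0) \
            / np.where(w_sum > 0, w_sum, np.nan)
        mu_t = (w * np.nan_to_num(p_hat["T"])).sum(axis=0) / np.where(w_sum > 0, w_sum, np.nan)
        mu_n = (w * np.nan_to_num(p_hat["N"])).sum(axis=0) / np.where(w_sum > 0, w_sum, np.nan)
        se_g = np.where(w_sum > 0, 1.0 / np.sqrt(np.where(w_sum > 0, w_sum, 1.0)), np.nan)
        z = np.where(se_g > 0, diff_g / se_g, 0.0)
        # delta-method proportion-scale SE, reported for interpretability
        mid = np.clip((mu_t + mu_n) / 2.0, 0.02, 0.98)
        se = se_g * 2.0 * np.sqrt(mid * (1.0 - mid))
    p_val = 2.0 * stats.norm.sf(np.abs(z))
    is_dm = (p_val < criteria.p_cpg) & (np.abs(diff) > criteria.diff_cpg)

    out = pd.DataFrame({
        "chrom": chrom_arr, "pos": pos_all,
        "mu_tumor": mu_t, "mu_nat": mu_n, "diff": diff,
        "se": se, "z": z, "p": p_val, "is_dm": is_dm,
    })[keep].reset_index(drop=True)
    out.attrs["qc"] = {
        "n_cpg_input": int(len(index)),
        "n_cpg_tested": int(keep.sum()),
        "n_cpg_excluded_low_pairs": int((~keep).sum()),
        "n_pairs": n_pairs,
    }
    return out


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def call_dmrs(cpg_stats: pd.DataFrame,
              criteria: DmrCriteria = DmrCriteria()) -> pd.DataFrame:
    """Assemble DMRs from per-CpG statistics.

    Candidates are maximal runs of same-direction DM CpGs in which
    consecutive DM CpGs lie <= max_gap_bp apart; a candidate spans from its
    first to its last DM CpG, its members being *all* tested CpGs inside the
    span. A candidate is emitted iff it passes all four region criteria.
    Emitted regions never overlap.
    """
    cols = ["chrom", "start", "end", "n_cpg", "n_dm_cpg", "mean_diff", "direction"]
    if not len(cpg_stats):
        return pd.DataFrame(columns=cols)
    regions = []
    for chrom, sub in cpg_stats.groupby("chrom", sort=True):
        sub = sub.sort_values("pos").reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        diff = sub["diff"].to_numpy()
        dm = sub["is_dm"].to_numpy()
        dm_idx = np.flatnonzero(dm)
        if not len(dm_idx):
            continue
        sign = np.sign(diff[dm_idx])
        # cluster breaks: direction change or positional gap > max_gap_bp
        breaks = np.flatnonzero(
            (sign[1:] != sign[:-1]) |
            (pos[dm_idx[1:]] - pos[dm_idx[:-1]] > criteria.max_gap_bp))
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(dm_idx) - 1]])
        for a, b in zip(starts, ends):
            i0, i1 = dm_idx[a], dm_idx[b]
            member = slice(i0, i1 + 1)
            n_cpg = i1 - i0 + 1
            n_dm = int(dm[member].sum())
            span = int(pos[i1] - pos[i0] + 1)
            mean_diff = float(diff[member].mean())
            run_sign = sign[a]
            if span < criteria.min_len_bp:
                continue
            if n_cpg < criteria.min_cpg:
                continue
            if n_dm / n_cpg < criteria.min_dm_frac:
                continue
            # signed rule: the region mean must exceed the threshold in the
            # run's own direction, so direction always matches the DM CpGs
            if mean_diff * run_sign <= criteria.min_abs_diff:
                continue
            regions.append({
                "chrom": chrom, "start": int(pos[i0]), "end": int(pos[i1]),
                "n_cpg": n_cpg, "n_dm_cpg": n_dm, "mean_diff": mean_diff,
                "direction": "hyper" if run_sign > 0 else "hypo",
            })
    return pd.DataFrame(regions, columns=cols)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _overlaps_any(track: AnnotationTrack, chrom: str, start1: int, end1: int) -> bool:
    """Any >= 1 base overlap between a 1-based inclusive region and the track."""
    sub = track.df[track.df["chrom"] == chrom]
    if not len(sub):
        return False
    starts = sub["start"].to_numpy()
    cummax_end = np.maximum.accumulate(sub["end"].to_numpy())
    b_start, b_end = start1 - 1, end1  # to 0-based half-open
    i = np.searchsorted(starts, b_end, side="left")
    return i > 0 and cummax_end[i - 1] > b_start


def annotate_dmrs(dmrs: pd.DataFrame,
                  tracks: dict[str, AnnotationTrack]) -> pd.DataFrame:
    """Attach genic multi-labels and a single CpG context per DMR.

    Genic categories (and enhancer) are precedence-free multi-labels; CpG
    context is exactly one of CGI > CGI_shore > open_sea. Missing tracks
    skip their category with a warning.
    """
    dmrs = dmrs.copy()
    genic_names = [n for n in (*GENIC_CATEGORIES, "enhancer") if n in tracks]
    for name in (*GENIC_CATEGORIES, "enhancer"):
        if name not in tracks:
            logger.warning("annotation track %r missing; category skipped", name)
    genic_labels, contexts = [], []
    for _, r in dmrs.iterrows():
        labels = [n for n in genic_names
                  if _overlaps_any(tracks[n], r["chrom"], r["start"], r["end"])]
        genic_labels.append(",".join(labels))
        context = "open_sea"
        for c in ("CGI", "CGI_shore"):
            if c in tracks and _overlaps_any(tracks[c], r["chrom"], r["start"], r["end"]):
                context = c
                break
        contexts.append(context)
    dmrs["genic_annotations"] = genic_labels
    dmrs["cpg_context"] = contexts
    return dmrs


# ---------------------------------------------------------------------------
# region methylation quantification
# ---------------------------------------------------------------------------

def compute_region_methylation(tables: Sequence[CpGCountTable],
                               regions: pd.DataFrame) -> pd.DataFrame:
    """Per-sample region methylation ratios sum(n_meth)/sum(n_total).

    Returns samples x regions; a region with zero total coverage in a sample
    is missing (NaN) — imputation is a modeling-stage concern. Region ids are
    "chrom:start-end" (1-based inclusive).
    """
    region_ids = [f"{r['chrom']}:{int(r['start'])}-{int(r['end'])}"
                  for _, r in regions.iterrows()]
    out = np.full((len(tables), len(regions)), np.nan)
    region_chrom = regions["chrom"].to_numpy()
    region_start = regions["start"].to_numpy(np.int64)
    region_end = regions["end"].to_numpy(np.int64)
    for si, table in enumerate(tables):
        for chrom, sub in table.df.groupby("chrom", sort=False):
            ridx = np.flatnonzero(region_chrom == chrom)
            if not len(ridx):
                continue
            pos = sub["pos"].to_numpy()
            cm = np.concatenate([[0], np.cumsum(sub["n_meth"].to_numpy())])
            cn = np.concatenate([[0], np.cumsum(sub["n_total"].to_numpy())])
            i0 = np.searchsorted(pos, region_start[ridx], side="left")
            i1 = np.searchsorted(pos, region_end[ridx], side="right")
            m = cm[i1] - cm[i0]
            n = cn[i1] - cn[i0]
            with np.errstate(invalid="ignore", divide="ignore"):
                out[si, ridx] = np.where(n > 0, m / np.where(n > 0, n, 1), np.nan)
    return pd.DataFrame(out, index=[t.sample_id for t in tables], columns=region_ids)


# ---------------------------------------------------------------------------
# recovery scoring (planted vs called, used by validation and reporting)
# ---------------------------------------------------------------------------

def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Reciprocal overlap fraction of two 1-based inclusive intervals."""
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start + 1), inter / (b_end - b_start + 1))


def score_recovery(called: pd.DataFrame, truth: pd.DataFrame,
                   min_reciprocal: float = 0.5,
                   require_direction: bool = True) -> dict:
    """Recall/precision of called DMRs against planted truth."""
    def match(q: pd.Series, ref: pd.DataFrame) -> bool:
        sub = ref[ref["chrom"] == q["chrom"]]
        for _, r in sub.iterrows():
            if require_direction and r["direction"] != q["direction"]:
                continue
            if reciprocal_overlap(q["start"], q["end"], r["start"], r["end"]) >= min_reciprocal:
                return True
        return False

    n_truth, n_called = len(truth), len(called)
    recovered = sum(match(t, called) for _, t in truth.iterrows()) if n_called else 0
    true_pos = sum(match(c, truth) for _, c in called.iterrows()) if n_truth else 0
    return {
        "n_truth": n_truth, "n_called": n_called,
        "n_recovered": int(recovered), "n_called_matching": int(true_pos),
        "recall": recovered / n_truth if n_truth else float("nan"),
        "precision": true_pos / n_called if n_called else float("nan"),
    }
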