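"""Independent oracles used by the tests.

Everything here is deliberately re-derived from first principles (brute
force, enumeration, grid search) and shares no code with the package paths
it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as ss


# ---------------------------------------------------------------------------
# O(n^2) DMR enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_dmrs(cpg_stats: pd.DataFrame, criteria) -> list[tuple]:
    """Enumerate every window, keep maximal same-direction DM runs passing
    all four region criteria. Returns sorted (chrom, start, end, direction)."""
    out = []
    for chrom, sub in cpg_stats.groupby("chrom", sort=True):
        sub = sub.sort_values("pos").reset_index(drop=True)
        pos = sub["pos"].to_numpy()
        diff = sub["diff"].to_numpy()
        dm = sub["is_dm"].to_numpy()
        n = len(sub)
        for i in range(n):
            if not dm[i]:
                continue
            s = np.sign(diff[i])
            for j in range(i, n):
                if not dm[j] or np.sign(diff[j]) != s:
                    continue
                inner = [k for k in range(i, j + 1) if dm[k]]
                # run validity: all DM members share direction, gaps bounded
                if any(np.sign(diff[k]) != s for k in inner):
                    continue
                gaps_ok = all(pos[b] - pos[a] <= criteria.max_gap_bp
                              for a, b in zip(inner, inner[1:]))
                if not gaps_ok:
                    continue
                # maximality: no same-direction DM CpG adjoining within gap
                left = [k for k in range(i) if dm[k]]
                if left and np.sign(diff[left[-1]]) == s \
                        and pos[i] - pos[left[-1]] <= criteria.max_gap_bp:
                    continue
                right = [k for k in range(j + 1, n) if dm[k]]
                if right and np.sign(diff[right[0]]) == s \
                        and pos[right[0]] - pos[j] <= criteria.max_gap_bp:
                    continue
                members = diff[i:j + 1]
                n_cpg = j - i + 1
                n_dm = int(dm[i:j + 1].sum())
                span = int(pos[j] - pos[i] + 1)
                mean_diff = float(members.mean())
                if span < criteria.min_len_bp:
                    continue
                if n_cpg < criteria.min_cpg:
                    continue
                if n_dm / n_cpg < criteria.min_dm_frac:
                    continue
                if mean_diff * s <= criteria.min_abs_diff:
                    continue
                out.append((chrom, int(pos[i]), int(pos[j]),
                            "hyper" if s > 0 else "hypo"))
    return sorted(set(out))


# ---------------------------------------------------------------------------
# beta-binomial grid likelihood-ratio oracle
# ---------------------------------------------------------------------------

def betabinom_loglik(mu: float, ms, ns, phi: float) -> float:
    if mu <= 0:
        return 0.0 if all(m == 0 for m in ms) else -np.inf
    if mu >= 1:
        return 0.0 if all(m == n for m, n in zip(ms, ns)) else -np.inf
    s = 1.0 / phi - 1.0
    return float(sum(ss.betabinom.logpmf(m, n, mu * s, (1 - mu) * s)
                     for m, n in zip(ms, ns)))


def grid_lrt_pvalue(mt, nt, mn, nn, phi: float, grid_step: float = 0.01) -> float:
    """LRT of separate vs common beta-binomial mean, maximized on a mu grid."""
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    l1 = max(betabinom_loglik(m, mt, nt, phi) for m in grid) \
        + max(betabinom_loglik(m, mn, nn, phi) for m in grid)
    l0 = max(betabinom_loglik(m, list(mt) + list(mn), list(nt) + list(nn), phi)
             for m in grid)
    lr = max(0.0, 2.0 * (l1 - l0))
    return float(ss.chi2.sf(lr, 1))


# ---------------------------------------------------------------------------
# rank-sum / AUC enumeration oracles
# ---------------------------------------------------------------------------

def pairwise_auc(case_scores, control_scores) -> float:
    """All-pairs concordance with ties counting one half."""
    wins = 0.0
    for c in case_scores:
        for k in control_scores:
            wins += 1.0 if c > k else 0.5 if c == k else 0.0
    return wins / (len(case_scores) * len(control_scores))


def exact_ranksum_pvalue(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)
    ranks = ss.rankdata(pooled)
    obs = ranks[:n_a].sum()
    mean = n_a * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        w = ranks[list(combo)].sum()
        if abs(w - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total
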