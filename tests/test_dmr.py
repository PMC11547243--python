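import numpy as np
import pandas as pd
import pytest

from helpers import brute_force_dmrs, grid_lrt_pvalue
from pdac_cfmethyl import dmr as D
from pdac_cfmethyl.io import AnnotationTrack, CpGCountTable
from conftest import random_cpg_stats


def table(sample_id, pos, meth, total, chrom="chr1"):
    return CpGCountTable.from_arrays(sample_id, [chrom] * len(pos), pos, meth, total)


class TestSmoothing:
    def test_isolated_cpg_keeps_raw_proportion(self):
        t = table("s", [1000], [7], [10])
        out = D.smooth_methylation(t, window_bp=200)
        assert out["p_smooth"].iloc[0] == pytest.approx(0.7)

    def test_two_cpgs_pool_coverage_weighted(self):
        t = table("s", [100, 150], [5, 15], [10, 20])
        out = D.smooth_methylation(t, window_bp=200)
        assert np.allclose(out["p_smooth"], 20 / 30)

    def test_constant_profile_is_fixed_point(self):
        pos = np.arange(100, 2100, 40)
        t = table("s", pos, [4] * len(pos), [10] * len(pos))
        out = D.smooth_methylation(t, window_bp=300)
        assert np.allclose(out["p_smooth"], 0.4)

    def test_zero_coverage_propagates_missing(self):
        t = table("s", [100, 5000], [0, 3], [0, 10])
        out = D.smooth_methylation(t, window_bp=100)
        assert np.isnan(out["p_smooth"].iloc[0])
        assert out["p_smooth"].iloc[1] == pytest.approx(0.3)


class TestDispersion:
    def test_identical_replicates_give_floor(self):
        tables = [table(f"s{i}", [100], [50], [100]) for i in range(10)]
        phi = D.estimate_dispersion(tables, prior_weight=20.0)
        assert phi[0] < 0.005

    def test_parameter_recovery(self):
        """Counts simulated at phi=0.1 over 500 CpGs, 32 samples, 30x:
        the mean shrunk estimate should land near the truth."""
        rng = np.random.default_rng(0)
        n_cpg, k, phi_true = 500, 32, 0.1
        s = 1 / phi_true - 1
        pos = np.arange(1, n_cpg + 1) * 1000  # far apart: no smoothing overlap
        mu = rng.uniform(0.2, 0.8, n_cpg)
        tables = []
        for i in range(k):
            n = rng.poisson(30, n_cpg) + 1
            p = rng.beta(mu * s, (1 - mu) * s)
            tables.append(table(f"s{i}", pos, rng.binomial(n, p), n))
        phi = D.estimate_dispersion(tables, prior_weight=20.0)
        assert 0.05 <= phi.mean() <= 0.2

    def test_infinite_prior_weight_collapses_to_mean(self):
        rng = np.random.default_rng(1)
        pos = np.arange(1, 51) * 500
        tables = [table(f"s{i}", pos, rng.binomial(30, 0.5, 50),
                        np.full(50, 30)) for i in range(8)]
        phi = D.estimate_dispersion(tables, prior_weight=np.inf)
        assert len(np.unique(phi)) == 1


class TestPerCpGTest:
    def _paired(self, tumor_rows, nat_rows, pos=None, **crit):
        pos = pos or [100]
        tt = [table(f"T{i}", pos, m, n) for i, (m, n) in enumerate(tumor_rows)]
        nt = [table(f"N{i}", pos, m, n) for i, (m, n) in enumerate(nat_rows)]
        criteria = D.DmrCriteria(min_pairs=len(tt), **crit)
        return tt, nt, criteria

    def test_null_identity(self):
        rows = [([5, 8], [10, 16]), ([3, 4], [10, 8]), ([7, 2], [14, 4])]
        tt, nt, crit = self._paired(rows, rows, pos=[100, 5000])
        out = D.test_cpg_differential(tt, nt, crit, phi=0.05)
        assert np.allclose(out["diff"], 0)
        assert np.allclose(out["z"], 0)
        assert np.allclose(out["p"], 1)
        assert not out["is_dm"].any()

    def test_agrees_with_likelihood_oracle_on_spec_example(self):
        """Counts (8/10, 9/10) vs (2/10, 1/10) across 2 pairs: Wald and a
        brute-force beta-binomial LRT must agree on rejection at alpha=.05."""
        tt, nt, crit = self._paired([([8], [10]), ([9], [10])],
                                    [([2], [10]), ([1], [10])])
        out = D.test_cpg_differential(tt, nt, crit, phi=0.1)
        p_lrt = grid_lrt_pvalue([8, 9], [10, 10], [2, 1], [10, 10], phi=0.1)
        assert (out["p"].iloc[0] < 0.05) == (p_lrt < 0.05) == True  # noqa: E712

    def test_low_coverage_cpgs_excluded_and_counted(self):
        tt = [table(f"T{i}", [100, 900], [5, 0], [10, 0]) for i in range(3)]
        nt = [table(f"N{i}", [100, 900], [5, 0], [10, 0]) for i in range(3)]
        out = D.test_cpg_differential(tt, nt, D.DmrCriteria(min_pairs=3), phi=0.05)
        assert len(out) == 1
        assert out.attrs["qc"]["n_cpg_excluded_low_pairs"] == 1

    def test_mismatched_universe_rejected(self):
        tt = [table("T0", [100], [5], [10])]
        nt = [table("N0", [200], [5], [10])]
        with pytest.raises(ValueError):
            D.test_cpg_differential(tt, nt, D.DmrCriteria(min_pairs=1), phi=0.05)


class TestCallDmrs:
    def _stats(self, pos, diff, dm, chrom="chr1"):
        return pd.DataFrame({
            "chrom": chrom, "pos": pos, "mu_tumor": 0.5, "mu_nat": 0.5,
            "diff": diff, "se": 0.05, "z": np.asarray(diff) / 0.05,
            "p": np.where(dm, 1e-4, 0.6), "is_dm": dm,
        })

    def test_short_span_rejected(self):
        # 3 DM CpGs spanning 40 bp: fails the >= 50 bp rule only
        stats = self._stats([100, 120, 139], [0.3, 0.3, 0.3], [True] * 3)
        assert len(D.call_dmrs(stats, D.DmrCriteria())) == 0
        relaxed = D.DmrCriteria(min_len_bp=30)
        assert len(D.call_dmrs(stats, relaxed)) == 1

    def test_two_cpgs_rejected(self):
        # 2 DM CpGs spanning 80 bp: fails the >= 3 CpG rule only
        stats = self._stats([100, 179], [0.3, 0.3], [True] * 2)
        assert len(D.call_dmrs(stats, D.DmrCriteria())) == 0
        assert len(D.call_dmrs(stats, D.DmrCriteria(min_cpg=2))) == 1

    def test_eighty_percent_rule_boundary(self):
        # 5 CpGs, 4 DM, 200 bp, mean diff +0.25: 4/5 = 0.8 passes
        stats = self._stats([100, 150, 200, 250, 299],
                            [0.3, 0.25, 0.05, 0.3, 0.35],
                            [True, True, False, True, True])
        out = D.call_dmrs(stats, D.DmrCriteria())
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["direction"], r["n_cpg"], r["n_dm_cpg"]) == ("hyper", 5, 4)
        assert r["mean_diff"] == pytest.approx(0.25)

    def test_mean_diff_rule_binding(self):
        stats = self._stats([100, 160, 220], [0.21, 0.19, 0.21], [True] * 3)
        # mean 0.2033 passes > 0.2; shrink one diff so the mean drops below
        assert len(D.call_dmrs(stats, D.DmrCriteria())) == 1
        stats2 = self._stats([100, 160, 220], [0.21, 0.11, 0.21], [True] * 3)
        assert len(D.call_dmrs(stats2, D.DmrCriteria())) == 0
        assert len(D.call_dmrs(stats2, D.DmrCriteria(min_abs_diff=0.1))) == 1

    def test_direction_change_splits_runs(self):
        stats = self._stats(
            [100, 150, 200, 260, 310, 360],
            [0.3, 0.3, 0.3, -0.3, -0.3, -0.3], [True] * 6)
        out = D.call_dmrs(stats, D.DmrCriteria())
        assert out["direction"].tolist() == ["hyper", "hypo"]
        # regions never overlap
        assert out["start"].iloc[1] > out["end"].iloc[0]

    def test_gap_rule_splits_runs(self):
        stats = self._stats(
            [100, 150, 200, 1200, 1250, 1300],
            [0.3] * 6, [True] * 6)
        out = D.call_dmrs(stats, D.DmrCriteria(max_gap_bp=500))
        assert len(out) == 2
        merged = D.call_dmrs(stats, D.DmrCriteria(max_gap_bp=2000))
        assert len(merged) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_oracle(self, seed):
        stats = random_cpg_stats(seed, n=50)
        called = D.call_dmrs(stats, D.DmrCriteria())
        expected = brute_force_dmrs(stats, D.DmrCriteria())
        got = sorted((r["chrom"], r["start"], r["end"], r["direction"])
                     for _, r in called.iterrows())
        assert got == expected

    def test_direction_matches_member_dm_signs(self):
        for seed in range(3):
            stats = random_cpg_stats(seed, n=80)
            called = D.call_dmrs(stats, D.DmrCriteria())
            for _, r in called.iterrows():
                members = stats[(stats["pos"] >= r["start"])
                                & (stats["pos"] <= r["end"])]
                dm_signs = np.sign(members.loc[members["is_dm"], "diff"])
                expected = 1 if r["direction"] == "hyper" else -1
                assert (dm_signs == expected).all()


class TestAnnotation:
    @pytest.fixture()
    def tracks(self):
        def track(name, rows):
            return AnnotationTrack(name, pd.DataFrame(
                rows, columns=["chrom", "start", "end"]))
        return {
            "CGI": track("CGI", [("chr1", 99, 400)]),
            "CGI_shore": track("CGI_shore", [("chr1", 400, 2400)]),
            "exon": track("exon", [("chr1", 0, 250)]),
            "intron": track("intron", [("chr1", 250, 5000)]),
            "enhancer": track("enhancer", [("chr1", 3000, 3500)]),
        }

    def _dmrs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "direction", "mean_diff"])

    def test_cgi_context_and_precedence(self, tracks):
        out = D.annotate_dmrs(self._dmrs([("chr1", 150, 350, "hyper", 0.3)]), tracks)
        assert out["cpg_context"].iloc[0] == "CGI"

    def test_shore_when_no_cgi_overlap(self, tracks):
        out = D.annotate_dmrs(self._dmrs([("chr1", 500, 600, "hyper", 0.3)]), tracks)
        assert out["cpg_context"].iloc[0] == "CGI_shore"

    def test_open_sea_default(self, tracks):
        out = D.annotate_dmrs(self._dmrs([("chr1", 3600, 4000, "hypo", -0.3)]), tracks)
        assert out["cpg_context"].iloc[0] == "open_sea"

    def test_multilabel_genic(self, tracks):
        # spans the exon/intron boundary: both labels, no precedence
        out = D.annotate_dmrs(self._dmrs([("chr1", 200, 300, "hyper", 0.3)]), tracks)
        assert set(out["genic_annotations"].iloc[0].split(",")) == {"exon", "intron"}

    def test_fractions_match_hand_enumeration(self, tracks):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(20):
            start = int(rng.integers(1, 4500))
            rows.append(("chr1", start, start + int(rng.integers(20, 400)),
                         "hyper", 0.3))
        out = D.annotate_dmrs(self._dmrs(rows), tracks)
        for _, r in out.iterrows():
            # naive overlap check per track (1-based inclusive vs BED)
            expected = set()
            for name in ("exon", "intron", "enhancer"):
                t = tracks[name].df
                for _, iv in t.iterrows():
                    if r["start"] <= iv["end"] and r["end"] >= iv["start"] + 1:
                        expected.add(name)
            got = set(r["genic_annotations"].split(",")) - {""}
            assert got == expected


class TestRegionMethylation:
    def test_hand_computed_ratio(self):
        t = table("s", [100, 150], [3, 7], [10, 10])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [90], "end": [160]})
        out = D.compute_region_methylation([t], regions)
        assert out.iloc[0, 0] == pytest.approx(0.5)

    def test_uncovered_region_missing(self):
        t = table("s", [100], [3], [10])
        regions = pd.DataFrame({"chrom": ["chr2"], "start": [90], "end": [160]})
        out = D.compute_region_methylation([t], regions)
        assert np.isnan(out.iloc[0, 0])

    def test_ratios_bounded(self, tiny_tissue):
        from pdac_cfmethyl.simulate import true_dmrs_to_frame
        regions = true_dmrs_to_frame(tiny_tissue["true_dmrs"])
        out = D.compute_region_methylation(tiny_tissue["tumor"][:4], regions)
        vals = out.to_numpy()
        vals = vals[np.isfinite(vals)]
        assert ((vals >= 0) & (vals <= 1)).all()


class TestCriteriaRelaxationMonotone:
    """Relaxing exactly one threshold never reduces the emitted count."""

    @pytest.mark.parametrize("field,relaxed", [
        ("min_abs_diff", 0.05), ("min_len_bp", 10),
        ("min_cpg", 1), ("min_dm_frac", 0.4),
    ])
    def test_relaxation_weakly_increases_calls(self, field, relaxed):
        for seed in range(3):
            stats = random_cpg_stats(seed, n=120)
            base = len(D.call_dmrs(stats, D.DmrCriteria()))
            loose = len(D.call_dmrs(stats, D.DmrCriteria(**{field: relaxed})))
            assert loose >= base
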