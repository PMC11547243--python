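import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from pdac_cfmethyl import simulate as sim
from pdac_cfmethyl.mutation import af_concordance, filter_wbc_shared


class TestLandscape:
    def test_empty_landscape(self):
        cfg = sim.SimConfig(n_cpg=0, n_chrom=2)
        landscape = sim.generate_cpg_landscape(cfg)
        assert sum(len(v) for v in landscape.values()) == 0

    def test_counts_and_uniqueness(self):
        cfg = sim.SimConfig(n_cpg=1000, n_chrom=2)
        landscape = sim.generate_cpg_landscape(cfg)
        assert sum(len(v) for v in landscape.values()) == 1000
        for pos in landscape.values():
            assert (np.diff(pos) > 0).all()

    def test_deterministic_given_seed(self):
        cfg = sim.SimConfig(seed=5, n_cpg=500)
        a = sim.generate_cpg_landscape(cfg)
        b = sim.generate_cpg_landscape(cfg)
        assert a.keys() == b.keys()
        for c in a:
            np.testing.assert_array_equal(a[c], b[c])

    def test_invalid_config_rejected(self):
        with pytest.raises(sim.ConfigError):
            sim.SimConfig(mean_spacing_bp=0)
        with pytest.raises(sim.ConfigError):
            sim.SimConfig(effect_size=0.0)
        with pytest.raises(sim.ConfigError):
            sim.SimConfig(dmr_len_bp=(30, 100))


class TestPlantDmrs:
    def test_no_dmrs_gives_pure_null(self):
        cfg = sim.SimConfig(n_cpg=2000, n_hyper=0, n_hypo=0)
        landscape = sim.generate_cpg_landscape(cfg)
        dmrs, profile = sim.plant_dmrs(landscape, cfg)
        assert dmrs == []
        for c in landscape:
            np.testing.assert_array_equal(profile.baseline[c], profile.tumor[c])

    def test_size_and_cpg_invariants(self, tiny_tissue):
        for d in tiny_tissue["true_dmrs"]:
            assert d.end - d.start + 1 >= 50
            assert d.n_cpg >= 3

    def test_regions_do_not_overlap(self, tiny_tissue):
        by_chrom = {}
        for d in tiny_tissue["true_dmrs"]:
            by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
        for intervals in by_chrom.values():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert e1 < s2

    def test_planted_effect_recovered_in_counts(self):
        """Mean tumor-NAT difference inside a hyper-DMR equals the planted
        effect within 3 SE, averaging over many simulated pairs."""
        cfg = sim.SimConfig(seed=3, n_cpg=3000, n_chrom=1, n_tissue_pairs=60,
                            n_hyper=3, n_hypo=0, coverage_mean=30,
                            bb_dispersion=0.05)
        landscape = sim.generate_cpg_landscape(cfg)
        dmrs, profile = sim.plant_dmrs(landscape, cfg)
        tumor, nat = sim.simulate_tissue_pairs(landscape, profile, cfg)
        d = dmrs[0]
        pos = landscape[d.chrom]
        idx = (pos >= d.start) & (pos <= d.end)
        diffs = []
        for t, n in zip(tumor, nat):
            tm = t.df[idx.tolist()] if False else t.df[np.asarray(idx)]
            nm = n.df[np.asarray(idx)]
            diffs.append((tm["n_meth"] / tm["n_total"]).mean()
                         - (nm["n_meth"] / nm["n_total"]).mean())
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - cfg.effect_size) < 3 * se + 1e-9

    def test_landscape_too_small_raises(self):
        cfg = sim.SimConfig(n_cpg=60, n_chrom=1, n_hyper=40, n_hypo=40)
        landscape = sim.generate_cpg_landscape(cfg)
        with pytest.raises(sim.ConfigError, match="too small"):
            sim.plant_dmrs(landscape, cfg)


class TestTissueCounts:
    def test_coverage_mean(self, tiny_tissue, tiny_config):
        totals = np.concatenate([t.df["n_total"].to_numpy()
                                 for t in tiny_tissue["tumor"]])
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - tiny_config.coverage_mean) < 3 * se

    def test_null_cpgs_have_zero_mean_difference(self, tiny_tissue):
        landscape = tiny_tissue["landscape"]
        in_dmr = {c: np.zeros(len(p), dtype=bool) for c, p in landscape.items()}
        for d in tiny_tissue["true_dmrs"]:
            pos = landscape[d.chrom]
            in_dmr[d.chrom] |= (pos >= d.start) & (pos <= d.end)
        mask = np.concatenate([~in_dmr[c] for c in sorted(landscape)])
        diffs = []
        for t, n in zip(tiny_tissue["tumor"], tiny_tissue["nat"]):
            with np.errstate(invalid="ignore"):
                pt = t.df["n_meth"] / t.df["n_total"]
                pn = n.df["n_meth"] / n.df["n_total"]
            diffs.append((pt - pn)[mask].mean())
        assert abs(np.mean(diffs)) < 0.01

    def test_dispersion_zero_is_binomial(self):
        """phi -> 0 count variance approaches binomial variance."""
        rng = np.random.default_rng(0)
        n = np.full(5000, 40)
        mu = np.full(5000, 0.3)
        m0 = sim._beta_binomial(rng, n, mu, 0.0)
        m1 = sim._beta_binomial(rng, n, mu, 0.15)
        binom_var = 40 * 0.3 * 0.7
        assert m0.var() / binom_var == pytest.approx(1.0, rel=0.1)
        assert m1.var() / binom_var == pytest.approx(1 + 39 * 0.15, rel=0.15)


class TestPlasma:
    def test_zero_tumor_fraction_matches_healthy(self):
        cfg = sim.SimConfig(seed=2, n_cpg=3000, n_chrom=1, n_hyper=4, n_hypo=4,
                            n_pdac_plasma=25, n_healthy_plasma=25,
                            tumor_fraction_range=(0.0, 0.0))
        landscape = sim.generate_cpg_landscape(cfg)
        _, profile = sim.plant_dmrs(landscape, cfg)
        tables, sheet = sim.simulate_plasma_cohort(landscape, profile, cfg)
        means = {t.sample_id: (t.df["n_meth"].sum() / t.df["n_total"].sum())
                 for t in tables}
        sheet = sheet.set_index("sample_id")
        pdac = [means[s] for s in sheet.index[sheet["group"] == "PDAC"]]
        healthy = [means[s] for s in sheet.index[sheet["group"] == "healthy"]]
        assert abs(np.mean(pdac) - np.mean(healthy)) < 0.01

    def test_full_tumor_fraction_reaches_tumor_level(self):
        cfg = sim.SimConfig(seed=2, n_cpg=2000, n_chrom=1, n_hyper=4, n_hypo=0,
                            n_pdac_plasma=20, n_healthy_plasma=5,
                            tumor_fraction_range=(1.0, 1.0))
        landscape = sim.generate_cpg_landscape(cfg)
        dmrs, profile = sim.plant_dmrs(landscape, cfg)
        tables, sheet = sim.simulate_plasma_cohort(landscape, profile, cfg)
        d = dmrs[0]
        pos = landscape[d.chrom]
        idx = np.asarray((pos >= d.start) & (pos <= d.end))
        tumor_level = profile.tumor[d.chrom][idx].mean()
        pdac_ids = set(sheet.loc[sheet["group"] == "PDAC", "sample_id"])
        ratios = [t.df.loc[idx, "n_meth"].sum() / t.df.loc[idx, "n_total"].sum()
                  for t in tables if t.sample_id in pdac_ids]
        assert np.mean(ratios) == pytest.approx(tumor_level, abs=0.02)

    def test_stage_linked_tumor_fraction_monotone(self):
        cfg = sim.SimConfig(seed=4, n_cpg=200, n_chrom=1, n_hyper=0, n_hypo=0,
                            n_pdac_plasma=300, n_healthy_plasma=5)
        landscape = sim.generate_cpg_landscape(cfg)
        _, profile = sim.plant_dmrs(landscape, cfg)
        _, sheet = sim.simulate_plasma_cohort(landscape, profile, cfg)
        cases = sheet[sheet["group"] == "PDAC"]
        mean_f = cases.groupby("stage")["tumor_fraction"].mean()
        assert mean_f["IV"] > mean_f["III"] > mean_f["II"] > mean_f["I"]

    def test_discordant_hypo_dmr_elevated_in_plasma(self):
        cfg = sim.SimConfig(seed=9, n_cpg=2000, n_chrom=1, n_hyper=0, n_hypo=6,
                            hypo_discordance_prob=1.0)
        landscape = sim.generate_cpg_landscape(cfg)
        dmrs, profile = sim.plant_dmrs(landscape, cfg)
        assert all(not d.plasma_concordant for d in dmrs)
        for d in dmrs:
            pos = landscape[d.chrom]
            idx = np.asarray((pos >= d.start) & (pos <= d.end))
            assert (profile.plasma_tumor[d.chrom][idx]
                    > profile.baseline[d.chrom][idx] + 0.1).all()
            assert (profile.tumor[d.chrom][idx]
                    < profile.baseline[d.chrom][idx]).all()


@pytest.fixture(scope="module")
def cohort_sheet():
    cfg = sim.SimConfig(seed=8, n_cpg=100, n_chrom=1, n_hyper=0, n_hypo=0,
                        n_pdac_plasma=150, n_healthy_plasma=150)
    landscape = sim.generate_cpg_landscape(cfg)
    _, profile = sim.plant_dmrs(landscape, cfg)
    _, sheet = sim.simulate_plasma_cohort(landscape, profile, cfg)
    return cfg, sheet


class TestVariants:
    def test_ch_rate_zero_no_wbc(self, cohort_sheet):
        cfg, sheet = cohort_sheet
        cfg0 = dataclasses.replace(cfg, ch_rate=0.0)
        cfdna, wbc = sim.simulate_variants(cfg0, sheet)
        assert len(wbc) == 0
        assert not cfdna["wbc_shared"].any()

    def test_ch_af_concordance(self, cohort_sheet):
        cfg, sheet = cohort_sheet
        cfdna, wbc = sim.simulate_variants(cfg, sheet)
        _, shared = filter_wbc_shared(cfdna, wbc)
        conc = af_concordance(shared)
        assert conc["n"] >= 20
        assert conc["r2"] >= 0.9

    def test_pdac_af_exceeds_healthy(self, cohort_sheet):
        cfg, sheet = cohort_sheet
        cfdna, wbc = sim.simulate_variants(cfg, sheet)
        retained, _ = filter_wbc_shared(cfdna, wbc)
        groups = sheet.set_index("sample_id")["group"]
        af = retained.assign(group=retained["sample_id"].map(groups))
        pdac = af.loc[af["group"] == "PDAC", "allele_fraction"]
        healthy = af.loc[af["group"] == "healthy", "allele_fraction"]
        assert pdac.median() > healthy.median()
        assert ss.mannwhitneyu(pdac, healthy, alternative="greater").pvalue < 0.01


class TestCa199:
    def _sheet(self, n_pdac=1000, n_healthy=1000):
        return pd.DataFrame({
            "sample_id": [f"P{i}" for i in range(n_pdac)]
            + [f"H{i}" for i in range(n_healthy)],
            "group": ["PDAC"] * n_pdac + ["healthy"] * n_healthy,
        })

    def test_class_medians_match_reported_cohort(self):
        """PDAC median ~149 U/mL, healthy ~7.8 U/mL (within sampling error)."""
        values = sim.simulate_ca199(self._sheet(), sim.SimConfig(seed=1))
        pdac = values[[s.startswith("P") for s in values.index]]
        healthy = values[[s.startswith("H") for s in values.index]]
        assert 100 <= pdac.median() <= 220
        assert 5 <= healthy.median() <= 11

    def test_zero_spread_collapses_to_median(self):
        params = sim.Ca199Params(pdac_sigma=0.0, healthy_sigma=0.0)
        cfg = sim.SimConfig(seed=1, ca199_params=params)
        values = sim.simulate_ca199(self._sheet(5, 5), cfg)
        assert np.allclose(values[:5], 149.1, rtol=1e-3)
        assert np.allclose(values[5:], 7.8, rtol=1e-3)

    def test_configured_negative_fraction(self):
        params = sim.Ca199Params(pdac_negative_fraction=0.3)
        cfg = sim.SimConfig(seed=2, ca199_params=params)
        values = sim.simulate_ca199(self._sheet(1000, 0), cfg)
        frac = (values < 37.0).mean()
        assert frac == pytest.approx(0.3, abs=0.05)


class TestDeterminism:
    def test_identical_configs_identical_cohorts(self):
        cfg = sim.SimConfig(seed=11, n_cpg=1500, n_chrom=2, n_tissue_pairs=3,
                            n_pdac_plasma=8, n_healthy_plasma=8,
                            n_hyper=2, n_hypo=2)
        # n_tissue_pairs=3 below min guard of 2, fine
        a = sim.simulate_cohort(cfg)
        b = sim.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.sample_sheet, b.sample_sheet)
        pd.testing.assert_frame_equal(a.cfdna_variants, b.cfdna_variants)
        for ta, tb in zip(a.plasma_tables + a.tumor_tables,
                          b.plasma_tables + b.tumor_tables):
            pd.testing.assert_frame_equal(ta.df, tb.df)
        assert a.true_dmrs == b.true_dmrs
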