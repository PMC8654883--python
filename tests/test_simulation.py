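"""Simulator: LD structure, phenotype model, GWAS scan, error injection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dentist import (
    SimConfig,
    SimTruth,
    evaluate,
    gwas_scan,
    inject_allelic_errors,
    inject_genotyping_errors,
    simulate_panel_pair,
    simulate_phenotype,
    standard_qc,
)
from dentist.simulation import harmonized_from_scan


def _adjacent_r(panel):
    g = panel.genotypes.astype(float)
    r = np.array(
        [np.corrcoef(g[:, j], g[:, j + 1])[0, 1] for j in range(g.shape[1] - 1)]
    )
    return r


class TestPanelPair:
    def test_realized_adjacent_ld_matches_target(self):
        cfg = SimConfig(n_gwas=5000, n_ref=5000, m=400, rho_range=(0.8, 0.8), seed=3)
        gwas, ref, _ = simulate_panel_pair(cfg)
        r = _adjacent_r(gwas)
        # block-interior pairs only: boundaries are uncorrelated by design
        strong = r[np.abs(r) > 0.3]
        assert len(strong) > 300
        assert np.abs(np.abs(strong).mean() - 0.8) < 0.05

    def test_no_heterogeneity_panels_match_in_ld(self):
        cfg = SimConfig(n_gwas=5000, n_ref=5000, m=300, heterogeneity=0.0, seed=4)
        gwas, ref, _ = simulate_panel_pair(cfg)
        d = np.abs(_adjacent_r(gwas) - _adjacent_r(ref))
        assert d.mean() < 0.03

    def test_heterogeneity_knob_increases_ld_difference(self):
        base = SimConfig(n_gwas=3000, n_ref=3000, m=300, heterogeneity=0.0, seed=5)
        pert = SimConfig(n_gwas=3000, n_ref=3000, m=300, heterogeneity=0.4, seed=5)
        g0, r0, _ = simulate_panel_pair(base)
        g1, r1, _ = simulate_panel_pair(pert)
        d0 = np.abs(_adjacent_r(g0) - _adjacent_r(r0)).mean()
        d1 = np.abs(_adjacent_r(g1) - _adjacent_r(r1)).mean()
        assert d1 > d0

    def test_maf_within_configured_range(self):
        cfg = SimConfig(n_gwas=4000, n_ref=100, m=300, seed=6)
        gwas, _, _ = simulate_panel_pair(cfg)
        maf = gwas.maf()
        assert (maf > 0.005).all() and (maf <= 0.52).all()

    def test_variants_are_strand_unambiguous(self):
        cfg = SimConfig(n_gwas=100, n_ref=100, m=500, seed=7)
        gwas, _, _ = simulate_panel_pair(cfg)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        a1 = gwas.variants["a1"]
        a2 = gwas.variants["a2"]
        assert all(comp[x] != y for x, y in zip(a1, a2))


class TestPhenotype:
    def test_variance_share_exact(self, small_sim):
        _, gwas, _, rng = small_sim
        y, causal, eff = simulate_phenotype(gwas, 10, 0.2, np.random.default_rng(1))
        X = gwas.genotypes[:, causal].astype(float)
        X = (X - X.mean(0)) / X.std(0)
        g = X @ eff
        lm = np.polyfit(g, y, 1)
        frac = np.var(np.polyval(lm, g)) / np.var(y)
        assert frac == pytest.approx(0.2, abs=0.001)

    def test_null_trait(self, small_sim):
        _, gwas, _, _ = small_sim
        y, causal, eff = simulate_phenotype(gwas, 0, 0.2, np.random.default_rng(2))
        assert len(causal) == 0
        assert y.std() == pytest.approx(1.0, rel=0.1)

    def test_invalid_h2(self, small_sim):
        _, gwas, _, _ = small_sim
        with pytest.raises(ValueError):
            simulate_phenotype(gwas, 5, 1.5, np.random.default_rng(3))

    def test_single_causal_ncp(self):
        """Marginal z^2 at the causal variant ~ 1 + n q^2/(1-q^2) over replicates."""
        q2 = 0.02
        n = 2000
        zsq = []
        for seed in range(25):
            cfg = SimConfig(n_gwas=n, n_ref=100, m=60, m_causal=0, seed=100 + seed)
            gwas, _, _ = simulate_panel_pair(cfg)
            rng = np.random.default_rng(1000 + seed)
            y, causal, _ = simulate_phenotype(gwas, 1, q2, rng)
            summ = gwas_scan(gwas, y)
            row = summ.df[summ.df["snp"] == gwas.variants["id"].iloc[causal[0]]]
            zsq.append(float(row["z"].iloc[0]) ** 2)
        ncp = n * q2 / (1 - q2)
        observed = np.mean(zsq)
        # E[z^2] = 1 + NCP; se of the mean of 25 noncentral chi2 draws is wide
        assert observed == pytest.approx(1 + ncp, rel=0.35)


class TestGwasScan:
    def test_null_z_calibration(self, small_sim):
        _, gwas, _, _ = small_sim
        rng = np.random.default_rng(9)
        y = rng.normal(size=gwas.n_samples)
        summ = gwas_scan(gwas, y)
        z = summ.df["z"].to_numpy()
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert z.std() == pytest.approx(1.0, abs=0.1)

    def test_matches_statsmodels_ols(self, small_sim):
        import statsmodels.api as sm

        _, gwas, _, _ = small_sim
        rng = np.random.default_rng(10)
        y = rng.normal(size=gwas.n_samples)
        summ = gwas_scan(gwas, y)
        for j in (0, 5, 50):
            x = gwas.genotypes[:, j].astype(float)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            row = summ.df.iloc[j]
            assert row["b"] == pytest.approx(fit.params[1], rel=1e-8)
            assert row["se"] == pytest.approx(fit.bse[1], rel=1e-8)

    def test_summary_aligned_to_panel(self, small_sim):
        _, gwas, _, _ = small_sim
        y = np.random.default_rng(11).normal(size=gwas.n_samples)
        summ = gwas_scan(gwas, y)
        assert (summ.df["snp"].to_numpy() == gwas.variants["id"].to_numpy()).all()
        np.testing.assert_allclose(summ.df["freq"], gwas.af)


class TestAllelicErrors:
    def test_flip_negates_z_after_harmonization(self, small_sim):
        """A mislabeled effect allele surfaces as z -> -z, freq -> 1-freq
        once the summary file is aligned back to the panel."""
        _, gwas, _, _ = small_sim
        y = np.random.default_rng(12).normal(size=gwas.n_samples)
        summ = gwas_scan(gwas, y)
        flipped, ids = inject_allelic_errors(summ, 0.1, np.random.default_rng(13))
        sel = summ.df["snp"].isin(ids).to_numpy()
        # raw file: labels swapped, values untouched
        assert (flipped.df.loc[sel, "a1"].to_numpy() == summ.df.loc[sel, "a2"].to_numpy()).all()
        np.testing.assert_allclose(flipped.df.loc[sel, "z"], summ.df.loc[sel, "z"])
        h = harmonized_from_scan(flipped, gwas)
        h_aligned = h.df.set_index("snp")
        orig = summ.df.set_index("snp")
        np.testing.assert_allclose(
            h_aligned.loc[ids, "z"], -orig.loc[ids, "z"]
        )
        np.testing.assert_allclose(
            h_aligned.loc[ids, "freq"], 1 - orig.loc[ids, "freq"]
        )
        kept = [s for s in orig.index if s not in set(ids)]
        np.testing.assert_allclose(h_aligned.loc[kept, "z"], orig.loc[kept, "z"])

    def test_exact_count(self, small_sim):
        _, gwas, _, _ = small_sim
        y = np.random.default_rng(14).normal(size=gwas.n_samples)
        summ = gwas_scan(gwas, y)
        _, ids = inject_allelic_errors(summ, 0.005, np.random.default_rng(15))
        assert len(ids) == round(0.005 * summ.n_variants)

    def test_double_flip_is_identity(self, small_sim):
        _, gwas, _, _ = small_sim
        y = np.random.default_rng(16).normal(size=gwas.n_samples)
        summ = gwas_scan(gwas, y)
        rng_a = np.random.default_rng(17)
        once, ids1 = inject_allelic_errors(summ, 0.05, np.random.default_rng(17))
        # re-flip exactly the same variants
        idx = np.where(once.df["snp"].isin(ids1))[0]
        twice, _ = inject_allelic_errors(once, len(idx) / len(once.df), np.random.default_rng(17))
        pd.testing.assert_frame_equal(twice.df, summ.df)


class TestGenotypingErrors:
    def test_f_error_zero_is_identity(self, small_sim):
        _, gwas, _, _ = small_sim
        out, ids = inject_genotyping_errors(gwas, 0.05, 0.0, np.random.default_rng(18))
        np.testing.assert_array_equal(out.genotypes, gwas.genotypes)

    def test_attenuation_bounded_by_error_rate(self, small_sim):
        """Corrupting an f share attenuates self-correlation to ~1-f.

        Replacement draws are conditioned to differ from the current dosage,
        which anti-correlates them with the original; the attenuation
        therefore lies between 1-2f (perfect anti-correlation) and 1-f
        (independent replacement), decreasing in f either way.
        """
        _, gwas, _, _ = small_sim
        f = 0.2
        out, ids = inject_genotyping_errors(gwas, 0.2, f, np.random.default_rng(19))
        maf = gwas.maf()
        cors = []
        for vid in ids:
            j = int(np.where(gwas.variants["id"] == vid)[0][0])
            if maf[j] < 0.2:  # rare variants attenuate harder (variance inflation)
                continue
            cors.append(np.corrcoef(gwas.genotypes[:, j], out.genotypes[:, j])[0, 1])
        assert len(cors) > 5
        assert 1 - 2 * f - 0.05 < np.mean(cors) < 1 - f + 0.02

    def test_corrupted_dosages_differ(self, small_sim):
        _, gwas, _, _ = small_sim
        out, ids = inject_genotyping_errors(gwas, 0.1, 0.3, np.random.default_rng(20))
        j = int(np.where(gwas.variants["id"] == ids[0])[0][0])
        changed = (out.genotypes[:, j] != gwas.genotypes[:, j]).sum()
        assert changed == round(0.3 * gwas.n_samples)


class TestStandardQC:
    def test_delta_af_and_hwe_filters(self, small_sim):
        _, gwas, _, _ = small_sim
        y = np.random.default_rng(21).normal(size=gwas.n_samples)
        summ = gwas_scan(gwas, y)
        h = harmonized_from_scan(summ, gwas)
        # corrupt one variant's summary frequency beyond the 0.1 threshold
        h.df.loc[3, "freq"] = h.df.loc[3, "freq_ref"] + 0.15
        h.df.loc[3, "delta_af"] = 0.15
        out, tally = standard_qc(h, gwas_panel=gwas)
        assert tally["delta_af"] >= 1
        assert out.n_variants <= h.n_variants - 1

    def test_clean_data_mostly_survives(self, small_sim):
        _, gwas, _, _ = small_sim
        y = np.random.default_rng(22).normal(size=gwas.n_samples)
        h = harmonized_from_scan(gwas_scan(gwas, y), gwas)
        out, tally = standard_qc(h, gwas_panel=gwas)
        assert out.n_variants >= 0.99 * h.n_variants


class TestEvaluate:
    def _results(self, removed_ids, all_ids, z=None):
        n = len(all_ids)
        return pd.DataFrame(
            {
                "variant_id": all_ids,
                "removed": [int(v in removed_ids) for v in all_ids],
                "z_obs": z if z is not None else np.ones(n),
            }
        )

    def test_full_power(self):
        ids = [f"v{i}" for i in range(100)]
        truth = SimTruth(allelic_error_ids=["v1", "v2"])
        res = self._results({"v1", "v2"}, ids, z=np.full(100, 6.0))
        rep = evaluate(res, truth)
        assert rep.power_allelic == 1.0
        assert rep.power_allelic_gwsig == 1.0

    def test_fold_enrichment_ratio(self):
        # removed set 50% true errors, errors are 0.5% of all -> enrichment 100
        ids = [f"v{i}" for i in range(1000)]
        truth = SimTruth(allelic_error_ids=["v1", "v2", "v3", "v4", "v5"])
        removed = {"v1", "v2", "v10", "v11"}
        res = self._results(removed, ids)
        rep = evaluate(res, truth)
        assert rep.fold_enrichment == pytest.approx((2 / 4) / (5 / 1000))

    def test_nothing_removed(self):
        ids = [f"v{i}" for i in range(10)]
        truth = SimTruth(allelic_error_ids=["v1"])
        rep = evaluate(self._results(set(), ids), truth)
        assert rep.power_allelic == 0.0
        assert rep.fold_enrichment == 0.0

    def test_empty_truth_power_missing(self):
        ids = ["v0", "v1"]
        rep = evaluate(self._results({"v0"}, ids), SimTruth())
        assert rep.power_allelic is None
        assert rep.power_genotyping is None
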