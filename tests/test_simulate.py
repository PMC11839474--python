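"""Generator-level checks: LD structure, determinism, count model,
GWAS scenario semantics and annotation odds ratios."""

import numpy as np
import pytest
from scipy import stats

from mirqtl import enrichment, simulate
from mirqtl.containers import CausalEffect, MediationLink, SimTruth

from conftest import make_truth


class TestGenotypes:
    def test_independent_snps_have_null_scale_r2(self):
        p = simulate.simulate_genotypes(2000, 100, within_block_r=0.0, seed=1)
        R = np.corrcoef(p.dosage, rowvar=False)
        off = R[np.triu_indices(100, 1)] ** 2
        # E[r2] = 1/n under independence; allow 3 SE of the mean
        expected = 1.0 / 2000
        se = np.sqrt(2.0) * expected / np.sqrt(len(off))
        assert abs(off.mean() - expected) < 3 * max(se, expected)

    def test_seed_determinism_bit_identical(self):
        a = simulate.simulate_genotypes(200, 50, block_size=5, within_block_r=0.7, seed=9)
        b = simulate.simulate_genotypes(200, 50, block_size=5, within_block_r=0.7, seed=9)
        assert np.array_equal(a.dosage, b.dosage)
        assert np.array_equal(a.pos, b.pos)
        assert list(a.ref) == list(b.ref)

    def test_block_r2_targets(self):
        # 200 replicate blocks of 10 SNPs at r=0.9
        within, between = [], []
        for s in range(20):
            p = simulate.simulate_genotypes(
                1000, 100, block_size=10, within_block_r=0.9, seed=100 + s
            )
            R = np.corrcoef(p.dosage, rowvar=False) ** 2
            for b in range(10):
                blk = R[b * 10:(b + 1) * 10, b * 10:(b + 1) * 10]
                within.extend(blk[np.triu_indices(10, 1)])
            between.extend(R[:10, 10:20].ravel())
        assert 0.6 <= np.median(within) <= 0.9
        assert np.median(between) < 0.05

    def test_maf_within_requested_range(self, small_panel):
        # sampling error allowance around the (0.1, 0.5) request
        assert small_panel.maf.min() > 0.07
        assert small_panel.maf.max() <= 0.5

    def test_rejects_degenerate_requests(self):
        with pytest.raises(ValueError):
            simulate.simulate_genotypes(1, 10)
        with pytest.raises(ValueError):
            simulate.simulate_genotypes(10, 10, maf_range=(0.0, 0.5))
        # block_size > n_snps collapses to one block
        p = simulate.simulate_genotypes(10, 5, block_size=50, within_block_r=0.5, seed=0)
        assert p.n_snps == 5


class TestCounts:
    def test_null_beta_gives_calibrated_marginal_tests(self, small_panel):
        truth = SimTruth(
            causal_map=[], features=[f"m{k}" for k in range(50)]
        )
        em, _, _ = simulate.simulate_mirna_counts(
            small_panel, truth, dispersion=0.01, seed=3
        )
        lib = em.library_size
        y = np.log2(em.values / lib[:, None] * 1e6 + 0.5)
        pvals = []
        for j in range(50):
            for snp in range(0, 100, 10):
                g = small_panel.dosage[:, snp]
                r, p = stats.pearsonr(g, y[:, j])
                pvals.append(p)
        frac = np.mean(np.array(pvals) < 0.05)
        assert abs(frac - 0.05) <= 0.02

    def test_planted_fraction_recovered_on_log_scale(self, small_panel):
        # the planted fraction is defined net of batch/hidden-factor variance
        # (which covariates and SVs absorb downstream), so measure partial R2
        from mirqtl import expression_qc

        # one causal SNP per feature, as in a real study (a single SNP shared
        # by every feature would itself look like a hidden factor)
        feats = [
            (f"m{k:03d}", str(small_panel.snp_id[k]), 0.04) for k in range(100)
        ]
        em, truth, covars = simulate.simulate_mirna_counts(
            small_panel, make_truth(small_panel, feats), dispersion=0.01, seed=4
        )
        lib = em.library_size
        y = np.log2(em.values / lib[:, None] * 1e6 + 0.5)
        X = expression_qc.build_design(covars[["batch"]])
        sv = expression_qc.estimate_surrogate_variables(y, X, n_sv=5)
        y_res = expression_qc.residualize(y, np.column_stack([X, sv]))
        feat_col = {f: j for j, f in enumerate(em.feature_id)}
        r2 = np.array(
            [
                stats.pearsonr(
                    small_panel.dosage[:, k], y_res[:, feat_col[f"m{k:03d}"]]
                )[0] ** 2
                for k in range(100)
            ]
        )
        # n=2000 here, so the estimate is tight around the planted 4%
        assert abs(np.median(r2) - 0.04) < 0.015

    def test_poisson_limit_at_zero_dispersion(self, small_panel):
        truth = SimTruth(causal_map=[], features=["m0"])
        em, _, _ = simulate.simulate_mirna_counts(
            small_panel, truth, dispersion=0.0, sigma_log2=0.0, batch_sd=0.0,
            factor_sd=0.0, libsize_range=(1e6, 1e6), seed=6,
        )
        c = em.values[:, 0]
        assert abs(c.var() / c.mean() - 1.0) < 0.1

    def test_overcommitted_variance_rejected(self, small_panel):
        snp = str(small_panel.snp_id[0])
        bad = SimTruth(
            causal_map=[
                CausalEffect("m0", snp, 1.0, 0.6),
                CausalEffect("m0", str(small_panel.snp_id[1]), 1.0, 0.5),
            ]
        )
        with pytest.raises(ValueError, match="sum to >= 1"):
            simulate.simulate_mirna_counts(small_panel, bad, seed=0)


class TestGwas:
    def test_null_max_abs_z_tail(self, locus_panel):
        truth = SimTruth(causal_map=[])
        exceed = 0
        reps = 1000
        rng = np.random.default_rng(0)
        # draw all nulls from one LD matrix; MVN tail as Monte-Carlo oracle
        R = np.corrcoef(locus_panel.dosage, rowvar=False)
        L = np.linalg.cholesky(R + 1e-6 * np.eye(30))
        for _ in range(reps):
            z = L @ rng.standard_normal(30)
            if np.max(np.abs(z)) > 4.9:
                exceed += 1
        g = simulate.simulate_gwas_summary(locus_panel, truth, "null", 10000, seed=1)
        assert np.max(np.abs(g["z"])) < 4.9  # one draw from the same null
        assert exceed / reps < 0.01

    def test_mediated_sign_propagation(self, small_panel):
        snp = str(small_panel.snp_id[15])
        truth = SimTruth(
            causal_map=[CausalEffect("m0", snp, +0.3, 0.0)],
            mediation_map=[MediationLink("t", "m0", -0.5)],
        )
        g = simulate.simulate_gwas_summary(
            small_panel, truth, "mediated", 500_000, seed=2
        )
        z_at_causal = float(g.set_index("snp").loc[snp, "z"])
        assert z_at_causal < 0  # exposure beta>0, mediation<0

    def test_z_scales_with_sqrt_n(self, small_panel):
        snp = str(small_panel.snp_id[15])
        truth = SimTruth(causal_map=[CausalEffect("m0", snp, 0.1, 0.0)])
        ns = [10_000, 40_000, 160_000, 640_000]
        means = []
        for n in ns:
            zs = [
                abs(
                    simulate.simulate_gwas_summary(
                        small_panel, truth, "pleiotropy", n, seed=s,
                        pleiotropy_effect=0.05,
                    ).set_index("snp").loc[snp, "z"]
                )
                for s in range(5)
            ]
            means.append(np.mean(zs))
        slope = np.polyfit(np.sqrt(ns), means, 1)[0]
        # quadrupling n doubles |z|: linear in sqrt(n) through the origin
        ratios = np.array(means) / np.sqrt(ns)
        assert slope > 0
        assert ratios.std() / ratios.mean() < 0.15

    def test_linkage_requires_correlated_partner(self, locus_panel):
        truth = SimTruth(causal_map=[CausalEffect("m0", str(locus_panel.snp_id[15]), 0.3, 0.0)])
        with pytest.raises(ValueError, match="no SNP with r2"):
            simulate.simulate_gwas_summary(
                locus_panel, truth, "linkage", 10000, seed=0, linkage_r2=(0.99, 1.0)
            )


class TestAnnotations:
    def test_null_odds_ratio(self):
        panel = simulate.simulate_genotypes(
            300, 20_000, within_block_r=0.0, maf_range=(0.02, 0.5), seed=8, spacing=50
        )
        qtl = set(np.random.default_rng(1).choice(panel.snp_id, 2000, replace=False))
        iv = simulate.simulate_annotations(panel, qtl, target_or=1.0, seed=2)
        flags = enrichment.overlap_flags(panel.chrom, panel.pos, iv)
        tables = enrichment.build_stratified_tables(
            panel.maf, np.isin(panel.snp_id, list(qtl)), flags
        )
        orr, _, p = enrichment.cmh_test(tables)
        assert 0.9 < orr < 1.1
        assert p > 0.01

    def test_separation_gives_infinite_or_sentinel(self):
        panel = simulate.simulate_genotypes(50, 200, within_block_r=0.0, seed=3)
        qtl = set(panel.snp_id[:50])
        is_qtl = np.isin(panel.snp_id, list(qtl))
        tables = enrichment.build_stratified_tables(panel.maf, is_qtl, is_qtl)
        with pytest.warns(UserWarning, match="inf"):
            orr, _, _ = enrichment.cmh_test(tables)
        assert np.isinf(orr)

    def test_empty_qtl_set_rejected(self, small_panel):
        with pytest.raises(ValueError):
            simulate.simulate_annotations(small_panel, set(), 1.3)
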