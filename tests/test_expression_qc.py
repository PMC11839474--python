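"""Count filtering, dedup, TMM/log2 normalization, outlier removal,
surrogate variables and residualization."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from mirqtl import expression_qc as eq
from mirqtl.containers import ExpressionMatrix

from conftest import expr_from_values


def counts_em(values, features=None):
    return expr_from_values(np.asarray(values, dtype=float), tag="counts",
                            features=features)


class TestAbundanceFilter:
    def test_low_rpm_feature_dropped_and_boundary_kept(self):
        # library sizes 1e6 so count == RPM
        vals = np.zeros((4, 3))
        vals[:, 0] = [0.5, 0.5, 0.5, 0.5]     # always below 1 RPM -> drop
        vals[:, 1] = [1.0, 1.0, 0.0, 0.0]     # exactly 1 RPM in exactly half -> keep
        vals[:, 2] = [5.0, 5.0, 5.0, 5.0]
        lib = np.full(4, 1e6)
        em = ExpressionMatrix(
            sample_id=list("abcd"), feature_id=["lo", "edge", "hi"],
            values=vals, tag="counts", library_size=lib,
        )
        out = eq.filter_low_expression(em)
        assert list(out.feature_id) == ["edge", "hi"]

    def test_hand_computed_survivors(self):
        counts = np.array([[10, 1], [20, 1], [30, 0], [40, 0]], dtype=float)
        lib = np.array([1e6, 1e6, 1e6, 1e6])
        em = ExpressionMatrix(
            sample_id=list("abcd"), feature_id=["f1", "f2"],
            values=counts, tag="counts", library_size=lib,
        )
        # f1: RPM 10..40 everywhere; f2: 1 RPM in 2/4 samples (boundary kept)
        out = eq.filter_low_expression(em, min_rpm=1, min_frac=0.5)
        assert list(out.feature_id) == ["f1", "f2"]
        out2 = eq.filter_low_expression(em, min_rpm=1, min_frac=0.75)
        assert list(out2.feature_id) == ["f1"]


class TestDedup:
    def _em(self, totals):
        vals = np.tile(np.asarray(totals, dtype=float) / 4, (4, 1))
        em = counts_em(vals, features=[f"row{i}" for i in range(len(totals))])
        em.feature_meta = pd.DataFrame(
            {
                "mature_id": ["miR-x"] * len(totals),
                "precursor_id": [f"prec{chr(65+i)}" for i in range(len(totals))],
            }
        )
        return em

    def test_highest_total_kept(self):
        out = eq.dedup_multi_precursor(self._em([100, 90]))
        assert out.n_features == 1
        assert out.feature_meta.iloc[0]["precursor_id"] == "precA"

    def test_tie_broken_by_smaller_precursor_id(self):
        em = self._em([100, 100])
        with pytest.warns(UserWarning, match="tie"):
            out = eq.dedup_multi_precursor(em)
        assert out.feature_meta.iloc[0]["precursor_id"] == "precA"

    def test_no_duplicates_is_identity(self):
        em = counts_em(np.ones((4, 3)))
        em.feature_meta = pd.DataFrame(
            {"mature_id": ["a", "b", "c"], "precursor_id": ["pa", "pb", "pc"]}
        )
        out = eq.dedup_multi_precursor(em)
        assert list(out.feature_id) == ["a", "b", "c"]
        np.testing.assert_array_equal(out.values, em.values)


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        vals = np.tile(np.arange(1, 51, dtype=float), (5, 1))
        f = eq.tmm_norm_factors(vals)
        np.testing.assert_allclose(f, 1.0, atol=1e-12)

    def test_uniform_doubling_leaves_log2_values_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.negative_binomial(5, 0.01, size=(6, 100)).astype(float)
        em = counts_em(vals)
        doubled = vals.copy()
        doubled[2] *= 2
        em2 = counts_em(doubled)
        a = eq.normalize_log2(em).values
        b = eq.normalize_log2(em2).values
        np.testing.assert_allclose(a[2], b[2], atol=1e-6)

    def test_factors_match_edger(self):
        """Independent oracle: Bioconductor edgeR on the same matrix."""
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 0.01, size=(4, 200)).astype(float)
        ours = eq.tmm_norm_factors(counts)
        script = (
            "suppressMessages(library(edgeR));"
            "x <- matrix(scan('stdin', quiet=TRUE), ncol=4);"
            "cat(calcNormFactors(DGEList(counts=x), method='TMM',"
            " doWeighting=FALSE)$samples$norm.factors)"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script],
            input=" ".join(str(int(v)) for v in counts.T.ravel(order="F")),
            capture_output=True, text=True, timeout=120,
        )
        assert proc.returncode == 0, proc.stderr
        theirs = np.array([float(x) for x in proc.stdout.split()])
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestOutliers:
    def test_extreme_batch_metric_sample_removed_first_iteration(self):
        rng = np.random.default_rng(1)
        metrics = pd.DataFrame(
            {"total_reads": rng.normal(1e6, 1e4, 200)},
            index=[f"s{i}" for i in range(200)],
        )
        metrics.iloc[7, 0] += 10 * 1e4
        batch = pd.Series(["b1"] * 100 + ["b2"] * 100, index=metrics.index)
        kept = eq.remove_outlier_samples_batch(metrics, batch, n_sd=5)
        assert "s7" not in kept

    def test_homogeneous_metrics_rarely_removed(self):
        rng = np.random.default_rng(2)
        metrics = pd.DataFrame(
            {"m1": rng.normal(size=600), "m2": rng.normal(size=600)},
            index=[f"s{i}" for i in range(600)],
        )
        batch = pd.Series(np.repeat([f"b{k}" for k in range(6)], 100), index=metrics.index)
        kept = eq.remove_outlier_samples_batch(metrics, batch, n_sd=5)
        assert len(kept) >= 0.99 * 600

    def test_pca_recovers_planted_extreme_sample(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(120, 60))
        vals[11] += 6.0
        em = expr_from_values(vals, tag="log2")
        kept, pcs = eq.remove_outlier_samples_pca(em, n_sd=4)
        assert set(em.sample_id) - set(kept) == {"s11"}
        assert pcs.shape == (119, 2)


class TestSurrogateVariables:
    def test_planted_hidden_factor_recovered(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            n, m = 250, 150
            hidden = rng.normal(size=n)
            Y = rng.normal(size=(n, m)) + np.outer(hidden, rng.normal(0, 0.5, m))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            sv = eq.estimate_surrogate_variables(Y, X, n_sv=4)
            best = max(abs(np.corrcoef(sv[:, k], hidden)[0, 1]) for k in range(4))
            hits += best > 0.9
        assert hits >= 19

    def test_svs_orthogonal_to_known_covariates(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(100, 40))
        X = np.column_stack([np.ones(100), rng.normal(size=(100, 3))])
        sv = eq.estimate_surrogate_variables(Y, X, n_sv=5)
        assert np.max(np.abs(sv.T @ X)) < 1e-8 * 100
        gram = sv.T @ sv
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * 100

    def test_too_many_svs_fatal(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="too large"):
            eq.estimate_surrogate_variables(
                rng.normal(size=(20, 10)), np.ones((20, 1)), n_sv=19
            )


class TestResidualize:
    def test_intercept_only_centers(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(50, 3))
        r = eq.residualize(y, np.ones((50, 1)))
        np.testing.assert_allclose(r, y - y.mean(axis=0), atol=1e-12)

    def test_exact_linear_combination_vanishes(self):
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 2))])
        y = X @ np.array([1.0, -2.0, 0.5])
        r = eq.residualize(y[:, None], X)
        assert np.max(np.abs(r)) < 1e-8

    def test_matches_normal_equations_oracle(self):
        X = np.array([[1, 0.5], [1, 1.5], [1, 2.0], [1, 3.5], [1, 5.0]])
        y = np.array([1.0, 2.2, 2.9, 4.8, 7.1])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        r_oracle = y - X @ beta_oracle
        r = eq.residualize(y[:, None], X)[:, 0]
        np.testing.assert_allclose(r, r_oracle, atol=1e-10)

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        X = np.column_stack([np.ones(40), x, 2 * x])
        with pytest.warns(UserWarning, match="collinear"):
            r = eq.residualize(rng.normal(size=(40, 2)), X)
        assert r.shape == (40, 2)


def test_filter_and_normalize_commute_with_sample_reordering():
    rng = np.random.default_rng(10)
    vals = rng.negative_binomial(5, 0.005, size=(8, 60)).astype(float)
    em = counts_em(vals)
    perm = rng.permutation(8)
    em_perm = em.subset_samples(em.sample_id[perm])
    a = eq.normalize_log2(eq.filter_low_expression(em))
    b = eq.normalize_log2(eq.filter_low_expression(em_perm))
    np.testing.assert_allclose(a.values[perm], b.values, atol=1e-10)
    assert list(a.feature_id) == list(b.feature_id)
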