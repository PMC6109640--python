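"""Pairwise estimators, matrix building and conditioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spdcorr import (CorrelationMatrix, beta_pearson, build_matrix,
                     condition_matrix, observed_matrix, read_matrix,
                     rp_from_ldsc, run_gwas, write_matrix)
from spdcorr.ldscore import LdscFit, compute_ld_scores
from spdcorr.simcohort import _rng_for

from conftest import make_sumstats


def bivariate_fit(intercept, se=0.1):
    return LdscFit("bivariate", 0.0, 0.0, intercept, se, 0.0, 0.0,
                   1000, 10, intercept, n_mean1=5000, n_mean2=5000)


class TestRpFromLdsc:
    def test_known_overlap_rescales(self):
        rp, se = rp_from_ldsc(bivariate_fit(0.05, 0.01), 5000, 5000, 500)
        assert rp == pytest.approx(0.5)
        assert se == pytest.approx(0.1)

    def test_one_sample_default_is_identity(self):
        rp, se = rp_from_ldsc(bivariate_fit(0.47), 5000, 5000)
        assert rp == 0.47 and se == 0.1

    def test_zero_intercept_zero_rp(self):
        assert rp_from_ldsc(bivariate_fit(0.0), 9999, 123, 77)[0] == 0.0

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            rp_from_ldsc(bivariate_fit(0.1), 5000, 5000, 0)

    def test_univariate_fit_rejected(self):
        uni = LdscFit("univariate", 0, 0, 1, 0, 0.5, 0.1, 1000, 10, 1.0)
        with pytest.raises(ValueError):
            rp_from_ldsc(uni, 5000, 5000)


class TestBetaPearson:
    def test_proportional_betas_give_unity(self):
        ids = list("abcde")
        b = np.array([0.1, -0.2, 0.3, 0.05, -0.4])
        s1 = make_sumstats("t1", ids, z=None, beta=b, se=np.full(5, 0.1))
        s2 = make_sumstats("t2", ids, z=None, beta=2 * b, se=np.full(5, 0.1))
        assert beta_pearson(s1, s2) == pytest.approx(1.0)
        s3 = make_sumstats("t3", ids, z=None, beta=-b, se=np.full(5, 0.1))
        assert beta_pearson(s1, s3) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self):
        ids = list("abcde")
        b1 = np.array([0.12, -0.05, 0.30, 0.01, -0.22])
        b2 = np.array([0.10, 0.02, 0.25, -0.03, -0.15])
        expected = float(np.corrcoef(b1, b2)[0, 1])
        s1 = make_sumstats("t1", ids, z=None, beta=b1, se=np.full(5, 0.1))
        s2 = make_sumstats("t2", ids, z=None, beta=b2, se=np.full(5, 0.1))
        assert beta_pearson(s1, s2) == pytest.approx(expected, rel=1e-12)

    def test_constant_vector_rejected(self):
        ids = list("abc")
        s1 = make_sumstats("t1", ids, z=None, beta=[0.1, 0.1, 0.1],
                           se=[0.1] * 3)
        s2 = make_sumstats("t2", ids, z=None, beta=[0.1, 0.2, 0.3],
                           se=[0.1] * 3)
        with pytest.raises(ValueError, match="constant"):
            beta_pearson(s1, s2)

    def test_unharmonized_rejected(self):
        s1 = make_sumstats("t1", list("abc"), beta=[1, 2, 3], se=[1, 1, 1], z=None)
        s2 = make_sumstats("t2", list("abd"), beta=[1, 2, 3], se=[1, 1, 1], z=None)
        with pytest.raises(ValueError, match="harmonize"):
            beta_pearson(s1, s2)


def simulated_traits(n=800, m=600, k=3, seed=21):
    """k phenotypes with known correlation on one genotype panel."""
    rng = _rng_for(seed)
    G = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(np.int8)
    target = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.45], [0.3, 0.45, 1.0]])
    L = np.linalg.cholesky(target[:k, :k])
    Y = rng.standard_normal((n, k)) @ L.T
    ids = np.array([f"s{i}" for i in range(m)], dtype=object)
    traits = [run_gwas(G, Y[:, t], ids, trait_id=f"trait{t}")
              for t in range(k)]
    return G, Y, traits, target[:k, :k], ids


class TestBuildMatrix:
    def test_three_traits_all_pairs(self):
        G, Y, traits, target, ids = simulated_traits()
        ltab = compute_ld_scores(G, snp_ids=ids, window=50)
        mat, _ = build_matrix(traits, ltab, estimator="ldsc_intercept",
                              qc=False, n_blocks=30, min_snps=100)
        assert mat.na_count == 0
        assert np.allclose(np.diag(mat.values), 1.0)
        assert np.allclose(mat.values, mat.values.T)
        # one-sample traits: intercepts track the phenotype correlations
        off = mat.values[np.triu_indices(3, 1)]
        assert np.all(np.abs(off - target[np.triu_indices(3, 1)]) < 0.25)

    def test_within_group_policy_leaves_cross_cells_missing(self):
        _, _, traits, _, _ = simulated_traits(k=2)
        mat, _ = build_matrix(traits, None, estimator="beta_pearson",
                              qc=False,
                              pair_policy="within_group",
                              groups={"trait0": "g1", "trait1": "g2"})
        assert mat.na_count == 1

    def test_fewer_than_two_traits_rejected(self):
        _, _, traits, _, _ = simulated_traits(k=2)
        with pytest.raises(ValueError):
            build_matrix(traits[:1], None, estimator="beta_pearson", qc=False)

    def test_observed_matrix_equals_pearson(self, rng):
        Y = pd.DataFrame(rng.standard_normal((50, 4)),
                         columns=list("wxyz"))
        mat = observed_matrix(Y)
        np.testing.assert_allclose(mat.values, np.corrcoef(Y.to_numpy().T),
                                   atol=1e-12)

    def test_ldsc_matrix_converges_to_observed(self):
        # agreement with the observed correlation matrix improves with size
        maes = []
        for n, m in ((300, 300), (1500, 1200)):
            errs = []
            for seed in (1, 2):
                G, Y, traits, _, ids = simulated_traits(n=n, m=m, seed=seed)
                ltab = compute_ld_scores(G, snp_ids=ids, window=50)
                mat, _ = build_matrix(traits, ltab, estimator="ldsc_intercept",
                                      qc=False, n_blocks=30, min_snps=50)
                obs = np.corrcoef(Y.T)
                iu = np.triu_indices(3, 1)
                errs.append(np.mean(np.abs(mat.values[iu] - obs[iu])))
            maes.append(np.mean(errs))
        assert maes[1] < maes[0]


class TestConditionMatrix:
    def test_out_of_bound_entry_clipped(self):
        m = CorrelationMatrix(["a", "b"], np.array([[1.0, 1.08], [1.08, 1.0]]))
        out = condition_matrix(m, na_action="fail")
        assert out.values[0, 1] == 1.0
        assert out.conditioned

    def test_asymmetric_pair_averaged(self):
        m = CorrelationMatrix(["a", "b"], np.array([[1.0, 0.3], [0.5, 1.0]]))
        out = condition_matrix(m)
        assert out.values[0, 1] == out.values[1, 0] == pytest.approx(0.4)

    def test_na_fail_lists_pairs(self):
        vals = np.array([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="a.*b"):
            condition_matrix(CorrelationMatrix(["a", "b"], vals), "fail")

    def test_drop_trait_removes_worst_offender(self):
        vals = np.array([[1.0, np.nan, np.nan],
                         [np.nan, 1.0, 0.2],
                         [np.nan, 0.2, 1.0]])
        out = condition_matrix(CorrelationMatrix(list("abc"), vals),
                               "drop_trait")
        assert out.trait_ids == ["b", "c"]

    def test_drop_trait_tie_breaks_lexicographically_last(self):
        vals = np.array([[1.0, np.nan, 0.1],
                         [np.nan, 1.0, 0.2],
                         [0.1, 0.2, 1.0]])
        out = condition_matrix(CorrelationMatrix(list("abc"), vals),
                               "drop_trait")
        assert out.trait_ids == ["a", "c"]

    def test_zero_policy_substitutes(self):
        vals = np.array([[1.0, np.nan], [np.nan, 1.0]])
        out = condition_matrix(CorrelationMatrix(["a", "b"], vals), "zero")
        assert out.values[0, 1] == 0.0

    @given(st.integers(2, 6), st.integers(0, 1000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_idempotent(self, k, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(-1.4, 1.4, size=(k, k))
        m = CorrelationMatrix([f"t{i}" for i in range(k)], raw)
        once = condition_matrix(m)
        twice = condition_matrix(once)
        np.testing.assert_array_equal(once.values, twice.values)


class TestNearestPsd:
    def test_projects_indefinite_matrix(self):
        from spdcorr import nearest_psd
        # pairwise-estimated values can be jointly infeasible (non-PSD)
        vals = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9],
                         [-0.9, 0.9, 1.0]])
        cond = condition_matrix(CorrelationMatrix(list("abc"), vals))
        assert np.linalg.eigvalsh(cond.values).min() < 0
        proj = nearest_psd(cond)
        assert np.linalg.eigvalsh(proj.values).min() >= -1e-10
        assert np.allclose(np.diag(proj.values), 1.0)

    def test_psd_input_unchanged(self, rng):
        from spdcorr import nearest_psd
        from conftest import random_conditioned_matrix
        vals = random_conditioned_matrix(rng, 5)
        cond = CorrelationMatrix([f"t{i}" for i in range(5)], vals,
                                 conditioned=True)
        out = nearest_psd(cond)
        np.testing.assert_array_equal(out.values, vals)


class TestMatrixIO:
    @pytest.mark.parametrize("sep", ["\t", ","])
    def test_roundtrip(self, tmp_path, sep, rng):
        from conftest import random_conditioned_matrix
        vals = random_conditioned_matrix(rng, 4)
        m = CorrelationMatrix(list("abcd"), vals, conditioned=True)
        p = tmp_path / "m.txt"
        write_matrix(m, p, sep=sep)
        back = read_matrix(p)
        assert back.trait_ids == m.trait_ids
        np.testing.assert_allclose(back.values, vals, atol=1e-6)

    def test_non_square_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("id,a,b\nx,1,0\n")
        with pytest.raises(ValueError, match="square"):
            read_matrix(tmp_path / "bad.csv")
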