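"""Outlier-calling fixtures: expression filters, m-values, hidden factors,
residualization, methylation aggregation, joint calls, global-outlier
removal, replication and cross-omics sharing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raremics.outliers import (
    call_joint_outliers,
    cross_omics_sharing,
    estimate_hidden_factors,
    filter_expression_matrix,
    gene_level_methylation,
    mvalue_inverse,
    mvalue_transform,
    remove_global_outliers,
    replication_rate,
    residualize_and_scale,
)


def _mat(values, features=None, individuals=None):
    values = np.asarray(values, float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    individuals = individuals or [f"i{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=features, columns=individuals)


class TestExpressionFilter:
    def test_boundary_gene_retained(self):
        # 6 reads and TPM 0.2 in exactly 20% of 10 individuals -> kept
        counts = _mat([[6, 6] + [0] * 8])
        tpm = _mat([[0.2, 0.2] + [0.0] * 8])
        mat = _mat([np.log2(tpm.iloc[0] + 2)])
        out = filter_expression_matrix(mat, counts, tpm)
        assert list(out.index) == ["f0"]

    def test_silent_gene_removed_and_empty_raises(self):
        counts = _mat([[0] * 5, [10] * 5])
        tpm = _mat([[0.0] * 5, [1.0] * 5])
        mat = _mat(np.zeros((2, 5)))
        out = filter_expression_matrix(mat, counts, tpm)
        assert list(out.index) == ["f1"]
        with pytest.raises(ValueError, match="expression filter"):
            filter_expression_matrix(mat.iloc[[0]], counts.iloc[[0]],
                                     tpm.iloc[[0]])

    def test_ten_gene_hand_pattern(self):
        """Hand-constructed pass pattern over 10 genes, 10 individuals."""
        n_pass = [10, 2, 1, 0, 5, 2, 1, 3, 2, 0]  # individuals passing both
        counts = _mat([[6] * k + [5] * (10 - k) for k in n_pass])
        tpm = _mat([[0.5] * k + [0.05] * (10 - k) for k in n_pass])
        mat = _mat(np.zeros((10, 10)))
        out = filter_expression_matrix(mat, counts, tpm)
        expected = [f"f{i}" for i, k in enumerate(n_pass) if k >= 2]
        assert list(out.index) == expected


class TestMValue:
    def test_known_points(self):
        assert mvalue_transform(0.5) == pytest.approx(0.0, abs=1e-12)
        assert mvalue_transform(0.8) == pytest.approx(2.0, abs=1e-12)
        assert mvalue_transform(0.2) == pytest.approx(-2.0, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, beta):
        assert mvalue_inverse(mvalue_transform(beta)) == pytest.approx(
            beta, abs=1e-12)

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                mvalue_transform(bad)

    def test_strictly_increasing(self):
        grid = np.linspace(0.01, 0.99, 50)
        assert np.all(np.diff(mvalue_transform(grid)) > 0)


class TestHiddenFactors:
    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=15)
        mat = _mat(np.outer(u, v))
        fac = estimate_hidden_factors(mat, 1)
        # the single factor reconstructs >99.9% of centered variance
        X = mat.to_numpy() - mat.to_numpy().mean(axis=1, keepdims=True)
        proj = X @ fac.to_numpy() @ fac.to_numpy().T
        assert np.sum((X - proj) ** 2) / np.sum(X ** 2) < 1e-9

    def test_orthogonality_and_eigvalue_oracle(self, rng):
        mat = _mat(rng.normal(size=(20, 30)))
        k = 5
        fac = estimate_hidden_factors(mat, k).to_numpy()
        assert np.abs(fac.T @ fac - np.eye(k)).max() < 1e-8
        # explained variance per factor equals the eigenvalues of the
        # centered covariance (independent eigendecomposition oracle)
        X = mat.to_numpy() - mat.to_numpy().mean(axis=1, keepdims=True)
        eig = np.sort(np.linalg.eigvalsh(X.T @ X))[::-1][:k]
        ours = np.sum((X @ fac) ** 2, axis=0)
        assert np.abs(np.sort(ours)[::-1] - eig).max() < 1e-6 * eig[0]

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            estimate_hidden_factors(_mat(rng.normal(size=(5, 4))), 4)


class TestResidualize:
    def test_orthogonal_covariates_identity(self, rng):
        """Covariates orthogonal to the feature leave the standardized raw
        values unchanged."""
        n = 40
        y = rng.normal(size=n)
        y -= y.mean()
        c = rng.normal(size=n)
        c -= c.mean()
        c -= (c @ y) / (y @ y) * y      # orthogonalize to y
        mat = _mat(y[None, :])
        cov = pd.DataFrame({"c1": c}, index=mat.columns)
        z = residualize_and_scale(mat, cov, min_n=10)
        expected = (y - y.mean()) / y.std(ddof=1)
        assert np.abs(z.iloc[0].to_numpy() - expected).max() < 1e-10

    def test_hat_matrix_oracle(self, rng):
        """5 features x 8 individuals vs closed-form hat-matrix residuals."""
        Y = rng.normal(size=(5, 8))
        C = rng.normal(size=(8, 2))
        mat = _mat(Y)
        cov = pd.DataFrame(C, index=mat.columns, columns=["c1", "c2"])
        z = residualize_and_scale(mat, cov, min_n=5)
        X = np.column_stack([np.ones(8), C])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        for i in range(5):
            r = (np.eye(8) - H) @ Y[i]
            expected = (r - r.mean()) / r.std(ddof=1)
            assert np.abs(z.iloc[i].to_numpy() - expected).max() < 1e-10

    def test_feature_as_own_covariate_excluded(self, rng):
        """Regressing a feature on itself leaves zero residual variance:
        the feature is flagged and excluded."""
        Y = rng.normal(size=(2, 40))
        mat = _mat(Y)
        cov = pd.DataFrame({"x": Y[0]}, index=mat.columns)
        with pytest.warns(UserWarning, match="excluded"):
            z = residualize_and_scale(mat, cov, min_n=10)
        assert list(z.index) == ["f1"]

    def test_zscore_invariant(self, rng):
        mat = _mat(rng.normal(size=(6, 50)))
        cov = pd.DataFrame({"c": rng.normal(size=50)}, index=mat.columns)
        z = residualize_and_scale(mat, cov, min_n=10)
        assert np.abs(z.mean(axis=1)).max() < 1e-8
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-8

    def test_singular_design_names_columns(self, rng):
        mat = _mat(rng.normal(size=(1, 30)))
        c = rng.normal(size=30)
        cov = pd.DataFrame({"c1": c, "c2": 2 * c}, index=mat.columns)
        with pytest.raises(ValueError, match="collinear"):
            residualize_and_scale(mat, cov, min_n=10)


class TestGeneLevelMethylation:
    def _coords(self):
        cpg_z = _mat([[1.0, 1.0], [3.0, 3.0], [5.0, 5.0]],
                     features=["c1", "c2", "c3"], individuals=["i1", "i2"])
        coords = pd.DataFrame({"chrom": ["chr1"] * 3,
                               "pos": [900, 500, 10_000]},
                              index=["c1", "c2", "c3"])
        return cpg_z, coords

    def test_median_aggregation(self):
        cpg_z, coords = self._coords()
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [1000],
                            "strand": ["+"]}, index=["g1"])
        out = gene_level_methylation(cpg_z, coords, tss)
        # c1 (100bp upstream) and c2 (500bp upstream) qualify: median(1,3)=2
        assert out.loc["g1", "i1"] == pytest.approx(2.0)

    def test_single_cpg_identity_and_exclusion_boundary(self):
        cpg_z = _mat([[4.0]], features=["c1"], individuals=["i1"])
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [400]}, index=["c1"])
        tss_near = pd.DataFrame({"chrom": ["chr1"], "tss": [1900],
                                 "strand": ["+"]}, index=["g1"])
        out = gene_level_methylation(cpg_z, coords, tss_near)
        assert out.loc["g1", "i1"] == pytest.approx(4.0)
        # 1600 bp upstream -> excluded
        tss_far = pd.DataFrame({"chrom": ["chr1"], "tss": [2000],
                                "strand": ["+"]}, index=["g1"])
        out = gene_level_methylation(cpg_z, coords, tss_far)
        assert np.isnan(out.loc["g1", "i1"])

    def test_strand_awareness(self):
        cpg_z = _mat([[2.0]], features=["c1"], individuals=["i1"])
        coords = pd.DataFrame({"chrom": ["chr1"], "pos": [1200]}, index=["c1"])
        minus = pd.DataFrame({"chrom": ["chr1"], "tss": [1000],
                              "strand": ["-"]}, index=["g1"])
        out = gene_level_methylation(cpg_z, coords, minus)
        # upstream of a minus-strand TSS lies at larger coordinates
        assert out.loc["g1", "i1"] == pytest.approx(2.0)

    def test_unknown_cpg_raises(self):
        cpg_z = _mat([[1.0]], features=["cX"], individuals=["i1"])
        coords = pd.DataFrame({"chrom": [], "pos": []})
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [0], "strand": ["+"]},
                           index=["g1"])
        with pytest.raises(ValueError, match="cX"):
            gene_level_methylation(cpg_z, coords, tss)


class TestJointCalls:
    def test_status_examples(self):
        e1 = _mat([[3.2, 3.2, 0.5, -3.4]])
        e5 = _mat([[3.5, 1.5, -0.9, -3.1]])
        calls = call_joint_outliers(e1, e5, threshold=3.0)
        assert list(calls.status.iloc[0]) == [
            "over_outlier", "neither", "control", "under_outlier"]

    def test_outlier_and_control_disjoint(self, rng):
        e1 = _mat(rng.normal(size=(30, 30)) * 2)
        e5 = _mat(rng.normal(size=(30, 30)) * 2)
        calls = call_joint_outliers(e1, e5, threshold=2.0)
        isout = calls.status.isin(["over_outlier", "under_outlier"])
        isctl = calls.status == "control"
        assert not (isout & isctl).any().any()

    def test_misaligned_raises(self):
        with pytest.raises(ValueError):
            call_joint_outliers(_mat(np.zeros((2, 2))),
                                _mat(np.zeros((3, 2))))


class TestGlobalOutliers:
    def _calls(self, counts):
        """Build a call set where individual j has counts[j] outliers."""
        n_feat = max(counts) + 2
        z = np.zeros((n_feat, len(counts)))
        for j, c in enumerate(counts):
            z[:c, j] = 4.0
        e = _mat(z)
        return call_joint_outliers(e, e.copy(), threshold=3.0)

    def test_fence_removes_only_extreme(self):
        calls = self._calls([2, 3, 3, 4, 50])
        out = remove_global_outliers(calls)
        # type-7 quartiles of {2,3,3,4,50}: Q1=3, Q3=4, fence=5.5
        removed = (out.status == "missing").all(axis=0)
        assert list(removed) == [False, False, False, False, True]

    def test_equal_counts_remove_none(self):
        calls = self._calls([3, 3, 3, 3])
        out = remove_global_outliers(calls)
        assert not (out.status == "missing").any().any()

    def test_single_individual_never_removed(self):
        calls = self._calls([5])
        out = remove_global_outliers(calls)
        assert not (out.status == "missing").any().any()


class TestReplication:
    def test_all_replicate(self):
        e1 = _mat([[4.0, -4.0, 0.1]])
        e5 = _mat([[3.0, -2.5, 0.0]])
        assert replication_rate(e1, e5, 3.0) == 1.0

    def test_hand_fixture_half(self):
        e1 = _mat([[4, 4, 4, -4, -4, -4, 0]], individuals=list("abcdefg"))
        e5 = _mat([[3, 1, 1, -3, -3, 0, 0]], individuals=list("abcdefg"))
        assert replication_rate(e1, e5, 3.0) == pytest.approx(0.5)

    def test_sign_flip_not_replicated(self):
        e1 = _mat([[-4.0]])
        e5 = _mat([[4.0]])
        assert replication_rate(e1, e5, 3.0, direction="under") == 0.0

    def test_no_outliers_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            replication_rate(_mat([[0.1]]), _mat([[0.1]]), 3.0)

    def test_monotone_in_call_threshold(self, rng):
        """With nested outlier sets, the replication rate cannot increase
        as the call threshold loosens only by adding weaker calls."""
        z1 = np.abs(rng.normal(size=(50, 50))) * 2
        z2 = z1 + rng.normal(size=(50, 50)) * 0.5
        e1, e5 = _mat(z1), _mat(z2)
        rates = [replication_rate(e1, e5, t) for t in (2.0, 3.0, 4.0)]
        assert rates[0] <= rates[1] + 1e-12 or rates[1] <= rates[2] + 1e-12


class TestCrossOmicsSharing:
    def test_planted_shift(self, rng):
        z = rng.normal(size=(20, 40)) * 0.3
        e1 = _mat(z.copy())
        e1.iloc[0, :6] = 4.0
        calls = call_joint_outliers(e1, e1.copy(), threshold=3.0)
        zb = _mat(rng.normal(size=(20, 40)) * 0.3)
        zb.iloc[0, :6] = 4.0   # every a-outlier has |Z_b| = 4
        res = cross_omics_sharing(calls, zb, zb.copy())
        assert res["sharing"] == 1.0
        assert res["p_value"] < 1e-3

    def test_null_case(self, rng):
        z = rng.normal(size=(30, 60)) * 0.5
        e1 = _mat(z.copy())
        e1.iloc[0, :5] = 4.0
        calls = call_joint_outliers(e1, e1.copy(), threshold=3.0)
        zb = _mat(rng.normal(size=(30, 60)) * 0.5)
        res = cross_omics_sharing(calls, zb, zb.copy())
        assert res["p_value"] > 0.01

    def test_disjoint_features_raise(self, rng):
        e1 = _mat(np.full((2, 3), 4.0), features=["a", "b"])
        calls = call_joint_outliers(e1, e1.copy(), threshold=3.0)
        zb = _mat(np.zeros((2, 3)), features=["c", "d"])
        with pytest.raises(ValueError, match="overlap"):
            cross_omics_sharing(calls, zb, zb.copy())
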