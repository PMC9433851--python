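"""CCA engine: oracle equivalence, conventions, projection, serialization."""

import numpy as np
import pytest
import scipy.linalg
import scipy.optimize

from hcdn.cca import (CcaSolution, fit_cca, fit_cca_arrays,
                      population_canonical_correlations, project)
from hcdn.errors import NumericalError, ValidationError

from conftest import make_volume_matrix


def _sample_joint_gaussian(sxx, syy, sxy, n, seed):
    p, q = sxx.shape[0], syy.shape[0]
    cov = np.block([[sxx, sxy], [sxy.T, syy]])
    rng = np.random.default_rng(seed)
    draw = rng.multivariate_normal(np.zeros(p + q), cov, size=n,
                                   method="cholesky")
    return draw[:, :p], draw[:, p:]


def _population_rho_oracle(sxx, syy, sxy):
    """Independent closed form: symmetric whitened eigenproblem."""
    isxx = scipy.linalg.fractional_matrix_power(sxx, -0.5)
    m = isxx @ sxy @ np.linalg.solve(syy, sxy.T) @ isxx
    eig = np.clip(scipy.linalg.eigvalsh(m), 0, 1)
    return np.sqrt(eig)[::-1]


class TestFitAgainstOracles:
    def test_identical_single_columns_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=(100, 1))
        *_, rho = fit_cca_arrays(col, col.copy(), k=1)
        assert abs(rho[0] - 1.0) < 1e-12

    def test_independent_views_give_near_zero_leading_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10000, 2))
        y = rng.normal(size=(10000, 2))
        *_, rho = fit_cca_arrays(x, y, k=2)
        assert rho[0] < 0.05  # O(sqrt(p*q/n)) under independence

    def test_sample_rho_matches_closed_form_population_values(self):
        # block covariance with known canonical structure
        rng = np.random.default_rng(2)
        p, q, k = 6, 4, 3
        a = rng.normal(size=(k, p))
        b = rng.normal(size=(k, q))
        d = np.diag([3.0, 2.0, 1.0]) ** 2
        sxx = a.T @ d @ a + np.eye(p)
        syy = b.T @ d @ b + np.eye(q)
        sxy = a.T @ d @ b
        x, y = _sample_joint_gaussian(sxx, syy, sxy, n=20000, seed=3)
        *_, rho = fit_cca_arrays(x, y, k=q)
        expected = _population_rho_oracle(sxx, syy, sxy)[:q]
        assert np.abs(rho - expected).max() < 0.02
        # the package's own closed-form helper agrees with the independent one
        assert np.allclose(population_canonical_correlations(sxx, syy, sxy)[:q],
                           expected, atol=1e-6)

    def test_brute_force_maximization_reproduces_leading_mode(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(200, 1))
        x = z @ rng.normal(size=(1, 2)) + rng.normal(size=(200, 2))
        y = z @ rng.normal(size=(1, 2)) + rng.normal(size=(200, 2))
        *_, rho = fit_cca_arrays(x, y, k=2)

        xc, yc = x - x.mean(0), y - y.mean(0)

        def neg_corr(angles):
            v = np.array([np.cos(angles[0]), np.sin(angles[0])])
            u = np.array([np.cos(angles[1]), np.sin(angles[1])])
            return -abs(np.corrcoef(xc @ v, yc @ u)[0, 1])

        best = min(
            (scipy.optimize.minimize(neg_corr, t0, method="Nelder-Mead",
                                     options={"xatol": 1e-10, "fatol": 1e-14})
             for t0 in [(0.1, 0.2), (1.0, -1.0), (-1.2, 2.0), (2.5, 0.5)]),
            key=lambda r: r.fun)
        assert abs(rho[0] - (-best.fun)) < 1e-6


    def test_agrees_with_sklearn_cross_decomposition(self):
        # independent library route: sklearn's NIPALS-based CCA should find
        # the same canonical correlations on a well-conditioned problem
        from sklearn.cross_decomposition import CCA as SkCCA

        rng = np.random.default_rng(21)
        z = rng.normal(size=(500, 2))
        x = z @ rng.normal(size=(2, 5)) + rng.normal(size=(500, 5))
        y = z @ rng.normal(size=(2, 4)) + rng.normal(size=(500, 4))
        *_, rho = fit_cca_arrays(x, y, k=2)
        sk = SkCCA(n_components=2, max_iter=2000).fit(x, y)
        xs, ys = sk.transform(x, y)
        sk_rho = [abs(np.corrcoef(xs[:, l], ys[:, l])[0, 1]) for l in range(2)]
        assert np.allclose(rho, sk_rho, atol=1e-4)


class TestSolutionInvariants:
    def test_variate_structure(self, small_cohort):
        from hcdn.deconfound import deconfound

        dn = deconfound(small_cohort.dn_volumes, small_cohort.confounds)
        hc = deconfound(small_cohort.hc_volumes, small_cohort.confounds)
        sol = fit_cca(dn, hc, k=3)
        rho = sol.canonical_correlations
        assert np.all(np.diff(rho) <= 0) and np.all((rho >= 0) & (rho <= 1))
        lx, ly = sol.dn_variates, sol.hc_variates
        assert np.allclose(lx.std(axis=0, ddof=1), 1.0, atol=1e-10)
        assert np.allclose(ly.std(axis=0, ddof=1), 1.0, atol=1e-10)
        for l in range(3):
            for m in range(3):
                r = np.corrcoef(lx[:, l], ly[:, m])[0, 1]
                if l == m:
                    assert abs(r - rho[l]) < 1e-10
                else:
                    assert abs(r) < 1e-8
            for m in range(l + 1, 3):
                assert abs(np.corrcoef(lx[:, l], lx[:, m])[0, 1]) < 1e-8
                assert abs(np.corrcoef(ly[:, l], ly[:, m])[0, 1]) < 1e-8

    def test_scale_invariance_after_zscoring(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(300, 4))
        y = rng.normal(size=(300, 3))
        v1, u1, *_ , r1 = fit_cca_arrays(x, y, k=2)
        v2, u2, *_, r2 = fit_cca_arrays(x * 7.0, y, k=2)
        # weights rescale inversely; correlations are unchanged
        assert np.allclose(r1, r2, atol=1e-12)
        assert np.allclose(v1, v2 * 7.0, atol=1e-10)
        assert np.allclose(u1, u2, atol=1e-10)

    def test_repeated_fits_byte_identical(self, small_cohort):
        from hcdn.deconfound import deconfound

        dn = deconfound(small_cohort.dn_volumes, small_cohort.confounds)
        hc = deconfound(small_cohort.hc_volumes, small_cohort.confounds)
        s1, s2 = fit_cca(dn, hc, k=3), fit_cca(dn, hc, k=3)
        assert np.array_equal(s1.v_weights, s2.v_weights)
        assert np.array_equal(s1.u_weights, s2.u_weights)

    def test_sign_convention_largest_hc_weight_positive(self, small_cohort):
        from hcdn.deconfound import deconfound

        dn = deconfound(small_cohort.dn_volumes, small_cohort.confounds)
        hc = deconfound(small_cohort.hc_volumes, small_cohort.confounds)
        sol = fit_cca(dn, hc, k=3)
        for l in range(3):
            col = sol.u_weights[:, l]
            assert col[np.abs(col).argmax()] > 0

    def test_k_exceeding_rank_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValidationError, match="exceeds"):
            fit_cca_arrays(rng.normal(size=(50, 3)),
                           rng.normal(size=(50, 2)), k=3)

    def test_singular_covariance_raises_numerical_error(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 3))
        x = np.column_stack([x, x[:, 0]])  # duplicated column
        with pytest.raises(NumericalError, match="ridge"):
            fit_cca_arrays(x, rng.normal(size=(50, 2)), k=2)


class TestProjection:
    def test_training_projection_equals_stored_variates(self, small_cohort):
        from hcdn.deconfound import deconfound

        dn = deconfound(small_cohort.dn_volumes, small_cohort.confounds)
        hc = deconfound(small_cohort.hc_volumes, small_cohort.confounds)
        sol = fit_cca(dn, hc, k=3)
        lx, ly = project(sol, dn, hc)
        # fit centers internally; deconfounded inputs are already centered
        assert np.allclose(lx, sol.dn_variates, atol=1e-12)
        assert np.allclose(ly, sol.hc_variates, atol=1e-12)

    def test_zero_participant_maps_to_zero_variates(self, small_cohort):
        from hcdn.deconfound import deconfound

        dn = deconfound(small_cohort.dn_volumes, small_cohort.confounds)
        hc = deconfound(small_cohort.hc_volumes, small_cohort.confounds)
        sol = fit_cca(dn, hc, k=3)
        zero_dn = make_volume_matrix(np.zeros((1, dn.values.shape[1])))
        zero_dn.values.columns = dn.values.columns
        zero_dn.meta.index = dn.values.columns
        zero_hc = make_volume_matrix(np.zeros((1, hc.values.shape[1])))
        zero_hc.values.columns = hc.values.columns
        zero_hc.meta.index = hc.values.columns
        lx, ly = project(sol, zero_dn, zero_hc)
        assert np.all(lx == 0) and np.all(ly == 0)

    def test_column_mismatch_lists_offenders(self, small_cohort):
        from hcdn.deconfound import deconfound

        dn = deconfound(small_cohort.dn_volumes, small_cohort.confounds)
        hc = deconfound(small_cohort.hc_volumes, small_cohort.confounds)
        sol = fit_cca(dn, hc, k=3)
        with pytest.raises(ValidationError, match="col_0"):
            project(sol, make_volume_matrix(
                np.zeros((1, dn.values.shape[1]))), hc)

    def test_held_out_half_preserves_mode_correlations(self):
        from hcdn.deconfound import deconfound, zscore_columns
        from hcdn.synthetic import CohortSpec, generate_cohort

        spec = CohortSpec(n_per_group=5000, p_dn=20, q_hc=12, k_true=3,
                          factor_strengths=(3.0, 2.0, 1.0),
                          loading_sparsity=0.5, n_snps=20, seed=13)
        c = generate_cohort(spec)
        dn = deconfound(c.dn_volumes, c.confounds)
        hc = deconfound(c.hc_volumes, c.confounds)
        half = c.dn_volumes.values.index[:5000]
        rest = c.dn_volumes.values.index[5000:]

        def subset(vm, ids):
            from hcdn.deconfound import VolumeMatrix
            return zscore_columns(VolumeMatrix(values=vm.values.loc[ids],
                                               meta=vm.meta))

        sol = fit_cca(subset(dn, half), subset(hc, half), k=3)
        lx, ly = project(sol, subset(dn, rest), subset(hc, rest))
        for l in range(3):
            r = np.corrcoef(lx[:, l], ly[:, l])[0, 1]
            assert abs(r - sol.canonical_correlations[l]) < 0.05


def test_serialization_roundtrip_exact(tmp_path, small_cohort):
    from hcdn.deconfound import deconfound

    dn = deconfound(small_cohort.dn_volumes, small_cohort.confounds)
    hc = deconfound(small_cohort.hc_volumes, small_cohort.confounds)
    sol = fit_cca(dn, hc, k=3)
    sol.to_dir(tmp_path / "sol")
    back = CcaSolution.from_dir(tmp_path / "sol")
    assert np.array_equal(back.v_weights, sol.v_weights)
    assert np.array_equal(back.u_weights, sol.u_weights)
    assert np.array_equal(back.dn_variates, sol.dn_variates)
    assert np.array_equal(back.canonical_correlations,
                          sol.canonical_correlations)
    assert back.dn_labels == sol.dn_labels
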