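"""Dyadic mixed models: design construction, diallel LMM, NB GLMM,
likelihood-ratio tests and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

import kinface as kf
from kinface.dyadic import (
    Design,
    ModelSpec,
    build_design,
    fit_association_glmm,
    fit_facial_distance_lmm,
    lrt,
    residual_facial_distance,
    vif,
)

from helpers import irls_poisson, wls_normal_equations


def _dyads(rng, m, n, complete=False):
    if complete:
        ids = np.array([(i, j) for i in range(m) for j in range(i + 1, m)])
    else:
        pairs = rng.choice(m, size=(4 * n, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        ids = np.unique(np.sort(pairs, axis=1), axis=0)[:n]
    return ids


class TestBuildDesign:
    def test_sex_class_dummies_against_mm(self):
        tab = pd.DataFrame(
            {"count": [1, 2, 3], "sex_class": ["FF", "FM", "MM"],
             "x": [0.0, 1.0, 2.0]}
        )
        d = build_design(
            tab, ModelSpec("count", ("x",), {"sex_class": "MM"})
        )
        assert d.names == ["intercept", "x", "sex_class[FF]", "sex_class[FM]"]
        assert np.allclose(d.X[:, 2], [1, 0, 0])
        assert np.allclose(d.X[:, 3], [0, 1, 0])

    def test_continuous_standardized(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"y": rng.normal(size=50),
                            "x": rng.normal(3, 2, size=50)})
        d = build_design(tab, ModelSpec("y", ("x",)))
        assert abs(d.X[:, 1].mean()) < 1e-12
        assert abs(d.X[:, 1].std() - 1) < 1e-12
        assert d.centers["x"] == pytest.approx(tab["x"].mean())

    def test_zero_variance_continuous_rejected(self):
        tab = pd.DataFrame({"y": [1.0, 2.0], "rank_difference": [0, 0]})
        with pytest.raises(ValueError, match="rank_difference"):
            build_design(tab, ModelSpec("y", ("rank_difference",)))

    def test_single_level_categorical_rejected(self):
        tab = pd.DataFrame({"y": [1.0, 2.0], "sex_class": ["MM", "MM"]})
        with pytest.raises(ValueError, match="sex_class"):
            build_design(tab, ModelSpec("y", (), {"sex_class": "MM"}))


def _lmm_table(rng, m=25, sigma_a=0.7, beta_age=0.8, complete=True,
               noise=1.0):
    ids = _dyads(rng, m, 0, complete=True)
    n = len(ids)
    a = rng.normal(0, sigma_a, m)
    w = rng.integers(1, 11, n).astype(float)
    age = rng.normal(size=n)
    y = (5.0 + beta_age * age + a[ids[:, 0]] + a[ids[:, 1]]
         + rng.normal(0, noise / np.sqrt(w), n))
    return pd.DataFrame(
        {"id_a": [f"i{i}" for i in ids[:, 0]],
         "id_b": [f"i{i}" for i in ids[:, 1]],
         "mean_distance": y, "n_picture_pairs": w,
         "mean_age_distance": age}
    )


SPEC_LMM = ModelSpec("mean_distance", ("mean_age_distance",),
                     weights="n_picture_pairs")


class TestFacialDistanceLmm:
    def test_wls_closed_form_at_zero_random_variance(self):
        """With sigma_u^2 pinned at 0, estimates equal the weighted
        least-squares normal-equations oracle and the log-likelihood is
        the weighted Gaussian one."""
        rng = np.random.default_rng(1)
        tab = _lmm_table(rng, m=7, sigma_a=0.0)[:20]
        d = build_design(tab, SPEC_LMM)
        fit = fit_facial_distance_lmm(tab, d, include_random=False)
        beta_oracle = wls_normal_equations(d.y, d.X, d.weights)
        assert np.allclose(fit.beta, beta_oracle, atol=1e-8)
        r = d.y - d.X @ beta_oracle
        n = len(tab)
        se2 = np.sum(d.weights * r**2) / n
        ll = -0.5 * (n * np.log(2 * np.pi) + np.sum(np.log(se2 / d.weights))
                     + np.sum(d.weights * r**2) / se2)
        assert fit.loglik == pytest.approx(ll, abs=1e-8)

    def test_rho_half_under_additive_effects(self):
        """Data generated with additive individual random effects are
        recovered with rho ~ 0.5 (the general-combining-ability case)."""
        rng = np.random.default_rng(2)
        tab = _lmm_table(rng, m=60)
        fit = fit_facial_distance_lmm(tab, build_design(tab, SPEC_LMM))
        assert fit.converged
        assert abs(fit.rho - 0.5) < 0.1
        assert fit.beta[1] == pytest.approx(0.8, abs=0.05)

    def test_diallel_rho_half_equals_additive_covariance(self):
        """sigma_u^2 (I + A/2) is exactly the covariance of u_d = a_i +
        a_j with var(a) = sigma_u^2 / 2 (matrix identity)."""
        rng = np.random.default_rng(3)
        ids = _dyads(rng, 12, 30)
        n, m = len(ids), 12
        su2 = 1.7
        Z = np.zeros((n, m))
        Z[np.arange(n), ids[:, 0]] = 1
        Z[np.arange(n), ids[:, 1]] = 1
        A = Z @ Z.T - 2 * np.eye(n)
        assert np.allclose(su2 * (np.eye(n) + 0.5 * A),
                           Z @ ((su2 / 2) * np.eye(m)) @ Z.T)

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(4)
        tab = _lmm_table(rng, m=8)
        tab["dup"] = tab["mean_age_distance"]
        spec = ModelSpec("mean_distance", ("mean_age_distance", "dup"),
                         weights="n_picture_pairs")
        d = build_design(tab, spec)
        with pytest.raises(ValueError, match="singular"):
            fit_facial_distance_lmm(tab, d)

    def test_negative_same_father_contrast_recovered(self):
        """A simulated same-father reduction in facial distance yields a
        negative fitted contrast."""
        rng = np.random.default_rng(5)
        tab = _lmm_table(rng, m=30, beta_age=0.3)
        same_father = rng.random(len(tab)) < 0.2
        tab["paternity_class"] = np.where(same_father, "same_father",
                                          "different_alpha")
        tab["mean_distance"] -= 0.8 * same_father
        spec = ModelSpec(
            "mean_distance", ("mean_age_distance",),
            {"paternity_class": "different_alpha"},
            weights="n_picture_pairs",
        )
        fit = fit_facial_distance_lmm(tab, build_design(tab, spec))
        i = fit.names.index("paternity_class[same_father]")
        assert fit.beta[i] < 0


class TestResidualization:
    def test_zero_age_effect_leaves_centered_distances(self):
        rng = np.random.default_rng(6)
        tab = _lmm_table(rng, m=20, beta_age=0.0)
        out = residual_facial_distance(tab)
        resid = out["facial_distance_residual"]
        # the age slope absorbs nothing: residuals track y - intercept
        assert abs(np.corrcoef(resid, tab["mean_distance"])[0, 1]) > 0.99

    def test_residuals_uncorrelated_with_age(self):
        rng = np.random.default_rng(7)
        tab = _lmm_table(rng, m=25)
        out = residual_facial_distance(tab)
        r = np.corrcoef(out["facial_distance_residual"],
                        tab["mean_age_distance"])[0, 1]
        assert abs(r) < 2 / np.sqrt(len(tab))

    def test_doubling_distances_doubles_residuals(self):
        rng = np.random.default_rng(8)
        tab = _lmm_table(rng, m=12)
        r1 = residual_facial_distance(tab)["facial_distance_residual"]
        tab2 = tab.copy()
        tab2["mean_distance"] *= 2
        r2 = residual_facial_distance(tab2)["facial_distance_residual"]
        assert np.allclose(r2, 2 * r1, rtol=1e-4, atol=1e-6)

    def test_too_few_dyads(self):
        with pytest.raises(ValueError, match="3 dyads"):
            residual_facial_distance(_lmm_table(np.random.default_rng(9),
                                                m=5).iloc[:2])


def _glmm_table(rng, m=60, n=300, beta=(-2.2, -0.5), sigma_a=0.5,
                shape=2.5):
    ids = _dyads(rng, m, n)
    n = len(ids)
    a = rng.normal(0, sigma_a, m)
    x = rng.normal(size=n)
    tot = rng.poisson(170, n) + 1
    eta = np.log(tot) + beta[0] + beta[1] * x + a[ids[:, 0]] + a[ids[:, 1]]
    mu = np.exp(eta)
    y = rng.poisson(mu * rng.gamma(shape, 1 / shape, n))
    return pd.DataFrame(
        {"id_a": [f"i{i}" for i in ids[:, 0]],
         "id_b": [f"i{i}" for i in ids[:, 1]],
         "count": y, "total_scans": tot, "x": x}
    )


SPEC_GLMM = ModelSpec("count", ("x",), offset="total_scans")


class TestAssociationGlmm:
    def test_matches_poisson_irls_oracle(self):
        """No random effects, shape pinned huge, constant offset: the fit
        solves the Poisson score equations (IRLS oracle, 30 rows)."""
        rng = np.random.default_rng(10)
        n = 30
        x = rng.normal(size=n)
        tot = np.full(n, 100)
        y = rng.poisson(np.exp(np.log(tot) - 2 + 0.4 * x))
        tab = pd.DataFrame(
            {"id_a": [f"a{i}" for i in range(n)],
             "id_b": [f"b{i}" for i in range(n)],
             "count": y, "total_scans": tot, "x": x}
        )
        d = build_design(tab, SPEC_GLMM)
        fit = fit_association_glmm(tab, d, random_spec=None, fix_shape=1e6)
        beta_oracle = irls_poisson(y.astype(float), d.X, d.offset_log)
        assert np.allclose(fit.beta, beta_oracle, atol=1e-6)

    def test_negative_facial_coefficient_recovered(self):
        rng = np.random.default_rng(11)
        tab = _glmm_table(rng, n=400)
        fit = fit_association_glmm(tab, build_design(tab, SPEC_GLMM), "gca")
        assert fit.converged
        assert fit.beta[1] < 0
        assert abs(fit.beta[1] - (-0.5)) < 3 * fit.se[1]

    def test_shape_and_variance_recovered(self):
        rng = np.random.default_rng(12)
        tab = _glmm_table(rng, n=500)
        fit = fit_association_glmm(tab, build_design(tab, SPEC_GLMM), "gca")
        assert 1.5 < fit.nb_shape < 4.0
        assert 0.05 < fit.sigma_a2[0] < 0.8

    def test_crossed_random_effects_run(self):
        rng = np.random.default_rng(13)
        tab = _glmm_table(rng, n=250)
        fit = fit_association_glmm(tab, build_design(tab, SPEC_GLMM),
                                   "crossed")
        assert len(fit.sigma_a2) == 2
        assert fit.converged

    def test_non_integer_counts_rejected(self):
        rng = np.random.default_rng(14)
        tab = _glmm_table(rng, n=30)
        tab["count"] = tab["count"] + 0.5
        with pytest.raises(ValueError, match="integer"):
            fit_association_glmm(tab, build_design(tab, SPEC_GLMM), "gca")

    def test_deviance_trace_monotone(self):
        rng = np.random.default_rng(15)
        tab = _glmm_table(rng, n=150)
        fit = fit_association_glmm(tab, build_design(tab, SPEC_GLMM), "gca")
        assert all(b <= a + 1e-9 for a, b in zip(fit.trace, fit.trace[1:]))


class TestLrt:
    def _fits(self, rng, null=True):
        tab = _glmm_table(rng, n=200,
                          beta=(-2.2, 0.0 if null else -0.6))
        full = fit_association_glmm(tab, build_design(tab, SPEC_GLMM), "gca")
        reduced = fit_association_glmm(
            tab, build_design(tab, ModelSpec("count", (),
                                             offset="total_scans")), "gca"
        )
        return full, reduced

    def test_identical_models_give_zero(self):
        rng = np.random.default_rng(16)
        full, _ = self._fits(rng)
        res = lrt(full, full)
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_strong_effect_rejected(self):
        rng = np.random.default_rng(17)
        full, reduced = self._fits(rng, null=False)
        res = lrt(full, reduced)
        assert res.df == 1
        assert res.chi2 > 3.84

    def test_different_data_rejected(self):
        rng = np.random.default_rng(18)
        full, _ = self._fits(rng)
        other_full, _ = self._fits(np.random.default_rng(19))
        with pytest.raises(ValueError, match="different data"):
            lrt(full, other_full)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(20)
        tab = _glmm_table(rng, n=150)
        tab["z"] = np.random.default_rng(1).normal(size=len(tab))
        f1 = fit_association_glmm(tab, build_design(tab, SPEC_GLMM), "gca")
        f2 = fit_association_glmm(
            tab, build_design(tab, ModelSpec("count", ("z",),
                                             offset="total_scans")), "gca"
        )
        with pytest.raises(ValueError, match="subset"):
            lrt(f1, f2)


class TestVif:
    def test_orthogonal_predictors(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        out = vif(np.column_stack([x1, x2]), ["a", "b"])
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_duplicated_predictor_infinite(self):
        x = np.random.default_rng(21).normal(size=50)
        out = vif(np.column_stack([x, x]), ["a", "b"])
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_correlation_point_six(self):
        """Two predictors with empirical correlation exactly 0.6 give
        VIF = 1/(1-0.36) = 1.5625."""
        rng = np.random.default_rng(22)
        x1 = rng.normal(size=200)
        x1 = (x1 - x1.mean()) / x1.std()
        z = rng.normal(size=200)
        z = z - z.mean()
        z -= x1 * (x1 @ z) / (x1 @ x1)  # exactly orthogonal to x1
        z /= z.std()
        x2 = 0.6 * x1 + np.sqrt(1 - 0.36) * z
        out = vif(np.column_stack([x1, x2]), ["a", "b"])
        assert out["a"] == pytest.approx(1.5625, abs=1e-9)


class TestAssociationCorrelation:
    def _tables(self, rates_ii, rates_mi):
        ii = pd.DataFrame(
            {"id_a": [f"i{2*k}" for k in range(len(rates_ii))],
             "id_b": [f"i{2*k+1}" for k in range(len(rates_ii))],
             "count": (np.asarray(rates_ii) * 100).astype(int),
             "total_scans": 100}
        )
        rows = []
        for k, (r1, r2) in enumerate(rates_mi):
            rows.append({"id_a": f"m{2*k}", "id_b": f"i{2*k+1}",
                         "count": int(r1 * 100), "total_scans": 100})
            rows.append({"id_a": f"m{2*k+1}", "id_b": f"i{2*k}",
                         "count": int(r2 * 100), "total_scans": 100})
        mi = pd.DataFrame(rows)
        mother_of = {f"i{j}": f"m{j}" for j in range(2 * len(rates_ii))}
        return ii, mi, mother_of

    def test_identical_rates_perfect_correlation(self):
        rng = np.random.default_rng(23)
        r = rng.uniform(0.05, 0.6, 20)
        ii, mi, mother_of = self._tables(r, list(zip(r, r)))
        rr, r2 = kf.association_correlation(ii, mi, mother_of)
        assert rr == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_rates_near_zero(self):
        rng = np.random.default_rng(24)
        n = 282
        ii_r = rng.uniform(0.05, 0.6, n)
        mi_r = list(zip(rng.uniform(0.05, 0.6, n), rng.uniform(0.05, 0.6, n)))
        ii, mi, mother_of = self._tables(ii_r, mi_r)
        rr, _ = kf.association_correlation(ii, mi, mother_of)
        assert abs(rr) < 0.12

    def test_unmatched_dyads_warned_and_skipped(self):
        rng = np.random.default_rng(25)
        r = rng.uniform(0.1, 0.5, 10)
        ii, mi, mother_of = self._tables(r, list(zip(r, r)))
        mi = mi.iloc[:-2]
        with pytest.warns(UserWarning, match="no matching"):
            rr, _ = kf.association_correlation(ii, mi, mother_of)
        assert rr == pytest.approx(1.0)


class TestDirectionality:
    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kf.directionality_summary(pd.DataFrame())

    def test_even_split(self):
        ev = pd.DataFrame(
            {"mother_id": ["m"] * 2, "infant_id": ["i", "j"],
             "behavior": ["approach"] * 2,
             "n_events": [1000, 1000], "n_infant_initiated": [500, 500]}
        )
        out = kf.directionality_summary(ev)
        assert out.loc[0, "pct_infant_initiated"] == 50.0
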