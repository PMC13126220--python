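"""Marginal likelihood, profiled ML fitting and model-comparison statistics.

The likelihood oracles here are deliberately independent re-derivations:
per-study normal log-densities via scipy.stats and hand-built model-implied
moments, and a stand-alone moment-GLS minimizer for the single-sample CFA
equivalence.
"""

import numpy as np
import pytest
from scipy import optimize as sp_optimize
from scipy import stats as sp_stats

from metacfa.cfa_model import build_invariance_model
from metacfa.fit_engine import (
    FitOptions,
    FitResult,
    HeterogeneitySpec,
    fit,
    fit_saturated,
    information_criteria,
    lrt,
    marginal_loglik,
    prepare_data,
    rmsea,
    smd,
    wald_test,
)
from metacfa.simulation import base_spec
from metacfa.summary_data import StudyRecord, compute_sampling_covariance, vech, vech_indices

FAST = FitOptions(compute_se=False)


def _tiny_heterogeneity_eta(het):
    """Parameter vector placing T^2 ~ 0: -30 on the log-scale entries, 0 on
    the off-diagonal Cholesky entries."""
    vr, vc = vech_indices(het.p)
    chol = np.where(vr == vc, -30.0, 0.0)
    return np.concatenate([np.full(het.ns, -30.0), chol])


def _t2_oracle(eta, p):
    """Independent reconstruction of T^2: diagonal covariance-effect block on
    the log scale, Cholesky-parameterized mean-effect block."""
    ns = p * (p + 1) // 2
    d = ns + p
    T2 = np.zeros((d, d))
    T2[:ns, :ns] = np.diag(np.exp(eta[:ns]))
    L = np.zeros((p, p))
    k = ns
    for c in range(p):
        for r in range(c, p):
            L[r, c] = np.exp(eta[k]) if r == c else eta[k]
            k += 1
    T2[ns:, ns:] = L @ L.T
    return T2


def _strong_model_moments_oracle(params, group):
    """Hand-built [vech(Sigma); mu] for the strong invariance model."""
    lam = np.array([params[f"lambda[{i + 1},1]"] for i in range(5)])
    psi = np.array(
        [
            params[f"psi[{i + 1},{i + 1}]"] + group * params[f"psi[{i + 1},{i + 1}]@group"]
            for i in range(5)
        ]
    )
    tau = np.array([params[f"tau[{i + 1}]"] for i in range(5)])
    phi = 1.0 + group * params["phi[1,1]@group"]
    kappa = group * params["kappa[1]@group"]
    Sigma = phi * np.outer(lam, lam) + np.diag(psi)
    mu = tau + lam * kappa
    return np.concatenate([vech(Sigma), mu])


class TestMarginalLoglik:
    def test_matches_independent_density_summation(self, small_dataset):
        """Against per-study scipy multivariate-normal log-densities with
        hand-built moments and T^2, to 1e-8."""
        spec = build_invariance_model(base_spec(), "strong", "group")
        model = spec.compile()
        rng = np.random.default_rng(7)
        theta = model.theta.start + 0.1 * rng.standard_normal(model.t)
        het = HeterogeneitySpec(p=5)
        eta = rng.normal(-3.0, 0.3, het.n_params)
        prep = prepare_data(small_dataset, v_source="study")
        ll = marginal_loglik(spec, theta, het, eta, prep)

        params = dict(zip(model.theta.names, theta))
        T2 = _t2_oracle(eta, p=5)
        oracle = 0.0
        for rec in small_dataset:
            y = np.concatenate([vech(rec.S), rec.ybar])
            V = compute_sampling_covariance(rec.S, rec.n).V
            m = _strong_model_moments_oracle(params, rec.moderators["group"])
            oracle += sp_stats.multivariate_normal.logpdf(y, mean=m, cov=T2 + V)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_invariant_to_study_permutation(self, small_dataset, rng):
        spec = build_invariance_model(base_spec(), "strong", "group")
        model = spec.compile()
        theta = model.theta.start
        het = HeterogeneitySpec(p=5)
        eta = np.full(het.n_params, -3.0)
        ll1 = marginal_loglik(spec, theta, het, eta, small_dataset)
        perm = list(rng.permutation(len(small_dataset)))
        ll2 = marginal_loglik(spec, theta, het, eta, [small_dataset[i] for i in perm])
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_single_study_saturated_maximized_at_observation(self, small_dataset):
        """With one study and negligible T^2 the saturated likelihood peaks
        at m = y_1 with the normal density at zero residual."""
        rec = small_dataset[0]
        het = HeterogeneitySpec(p=5)
        eta0 = _tiny_heterogeneity_eta(het)
        sat = fit_saturated(het, [rec], moderated=False, options=FAST, fix_eta=eta0)
        y = np.concatenate([vech(rec.S), rec.ybar])
        np.testing.assert_allclose(np.array(list(sat.params.values())), y, atol=1e-6)
        V = compute_sampling_covariance(rec.S, rec.n).V
        expect = -2.0 * sp_stats.multivariate_normal.logpdf(y, mean=y, cov=V)
        assert sat.minus2LL == pytest.approx(expect, abs=1e-6)


class TestFit:
    def test_equal_weight_pooling_is_arithmetic_mean(self, rng):
        """Identical V_i across studies: the saturated pooled estimate is the
        plain average of the effect-size vectors."""
        S = np.eye(3) + 0.2
        recs = [
            StudyRecord(f"s{i}", 80, S, rng.standard_normal(3) * 0.1)
            for i in range(6)
        ]
        # identical S => identical V; only the mean part of y varies
        sat = fit_saturated(None, recs, moderated=False, options=FAST)
        ys = np.array([np.concatenate([vech(r.S), r.ybar]) for r in recs])
        np.testing.assert_allclose(
            np.array(list(sat.params.values())), ys.mean(axis=0), atol=1e-7
        )

    def test_single_study_equivalent_to_single_sample_cfa(self, small_dataset):
        """k=1 with T^2 ~ 0 reproduces a stand-alone moment-GLS CFA: the
        -2LL difference to the saturated model matches an independent
        minimizer of (y - m)' V^{-1} (y - m) to 1e-6."""
        rec = small_dataset[0]
        het = HeterogeneitySpec(p=5)
        eta0 = _tiny_heterogeneity_eta(het)
        spec = base_spec()
        res = fit(spec, het, [rec], options=FAST, fix_eta=eta0)
        sat = fit_saturated(het, [rec], moderated=False, options=FAST, fix_eta=eta0)
        engine_discrepancy = res.minus2LL - sat.minus2LL

        y = np.concatenate([vech(rec.S), rec.ybar])
        Vinv = np.linalg.inv(compute_sampling_covariance(rec.S, rec.n).V)
        vr, vc = vech_indices(5)

        def moments(par):
            lam, psi, tau = par[:5], par[5:10], par[10:15]
            Sigma = np.outer(lam, lam) + np.diag(psi)
            return np.concatenate([Sigma[vr, vc], tau])

        def objective(par):
            r = y - moments(par)
            return r @ Vinv @ r

        x0 = np.concatenate([np.full(5, 0.6), np.full(5, 0.5), rec.ybar])
        oracle = sp_optimize.minimize(objective, x0, method="BFGS",
                                      options={"gtol": 1e-10, "maxiter": 2000})
        assert engine_discrepancy == pytest.approx(oracle.fun, abs=1e-6)

    def test_refit_with_permuted_studies_identical(self, small_dataset, rng):
        spec = build_invariance_model(base_spec(), "strong", "group")
        f1 = fit(spec, None, small_dataset, options=FAST)
        perm = list(rng.permutation(len(small_dataset)))
        f2 = fit(spec, None, [small_dataset[i] for i in perm], options=FAST)
        assert f1.minus2LL == pytest.approx(f2.minus2LL, rel=1e-7)

    def test_dummy_relabeling_preserves_likelihood(self, small_dataset):
        """Swapping the 0/1 coding of the group dummy is a reparameterization:
        the strong model's -2LL is unchanged and the latent mean difference
        flips sign."""
        spec = build_invariance_model(base_spec(), "strong", "group")
        f1 = fit(spec, None, small_dataset, options=FAST)
        flipped = []
        for r in small_dataset:
            flipped.append(
                StudyRecord(r.study_id, r.n, r.S, r.ybar,
                            moderators={"group": 1.0 - r.moderators["group"]})
            )
        f2 = fit(spec, None, flipped, options=FAST)
        assert f1.minus2LL == pytest.approx(f2.minus2LL, abs=1e-4)
        assert f1.params["kappa[1]@group"] == pytest.approx(
            -f2.params["kappa[1]@group"], abs=5e-3
        )

    def test_parameter_recovery_no_heterogeneity(self, rng):
        """Single group, no between-study heterogeneity, large n: loadings
        recovered within a few standard errors of .70."""
        lam = np.full(5, 0.7)
        Sigma = np.outer(lam, lam) + 0.51 * np.eye(5)
        mu = np.full(5, 0.5)
        L = np.linalg.cholesky(Sigma)
        recs = []
        for i in range(10):
            X = rng.standard_normal((2000, 5)) @ L.T + mu
            recs.append(StudyRecord(f"s{i}", 2000, np.cov(X, rowvar=False),
                                    X.mean(axis=0)))
        res = fit(base_spec(), None, recs,
                  options=FitOptions(compute_se=True, outer_maxiter=3000))
        assert res.converged
        for i in range(5):
            est = res.params[f"lambda[{i + 1},1]"]
            se = res.se[f"lambda[{i + 1},1]"]
            assert abs(est - 0.7) < max(3 * se, 0.02)

    def test_nesting_chain_of_minus2ll(self, fitted_ladder):
        """saturated <= configural <= weak <= strong in -2LL."""
        tol = 1e-4
        chain = [fitted_ladder[m].minus2LL
                 for m in ("saturated", "configural", "weak", "strong")]
        assert all(fitted_ladder[m].converged
                   for m in ("saturated", "configural", "weak", "strong"))
        for lo, hi in zip(chain, chain[1:]):
            assert lo <= hi + tol

    def test_saturated_df_zero(self, fitted_ladder):
        assert fitted_ladder["saturated"].df == 0

    def test_df_ladder_in_fits(self, fitted_ladder):
        assert [fitted_ladder[m].df for m in ("configural", "weak", "strong")] == [10, 14, 18]


class TestComparisons:
    def test_lrt_model_with_itself(self, fitted_ladder):
        d, ddf, p = lrt(fitted_ladder["weak"], fitted_ladder["weak"])
        assert (d, ddf, p) == (0.0, 0, 1.0)

    def test_lrt_strong_vs_weak_df4(self, fitted_ladder):
        d, ddf, p = lrt(fitted_ladder["strong"], fitted_ladder["weak"])
        assert ddf == 4
        assert d >= 0 and 0 <= p <= 1

    def test_lrt_rejects_swapped_nesting(self, fitted_ladder):
        with pytest.raises(ValueError, match="fewer degrees of freedom"):
            lrt(fitted_ladder["weak"], fitted_ladder["strong"])

    def test_aic_penalty_of_one_extra_parameter(self, fitted_ladder):
        a = fitted_ladder["weak"]
        b = FitResult(**{**a.__dict__, "n_free": a.n_free + 1})
        aic_a, bic_a = information_criteria(a)
        aic_b, bic_b = information_criteria(b)
        assert aic_b - aic_a == pytest.approx(2.0)
        assert bic_b - bic_a == pytest.approx(np.log(a.N_total))

    def test_bic_penalizes_more_when_logn_exceeds_two(self, fitted_ladder):
        weak, strong = fitted_ladder["weak"], fitted_ladder["strong"]
        assert np.log(weak.N_total) > 2
        aic_gap = information_criteria(weak)[0] - information_criteria(strong)[0]
        bic_gap = information_criteria(weak)[1] - information_criteria(strong)[1]
        # weak has 4 more parameters; BIC penalizes them harder than AIC
        assert bic_gap - aic_gap == pytest.approx(4 * (np.log(weak.N_total) - 2))


class TestIndices:
    def test_rmsea_perfect_fit_boundary(self):
        assert rmsea(10.0, 10, 500) == 0.0

    def test_rmsea_closed_form(self):
        assert rmsea(20.0, 10, 1001) == pytest.approx(np.sqrt(10 / (10 * 1000)))

    def test_rmsea_monotone_in_chi2(self):
        vals = [rmsea(c, 10, 500) for c in (5.0, 10.0, 15.0, 30.0)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_rmsea_undefined_at_df_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(rmsea(3.0, 0, 500))

    def test_wald(self, fitted_ladder):
        base = fitted_ladder["strong"]
        fr = FitResult(**{**base.__dict__,
                          "params": {"kappa[1]@group": 0.0, "beta": 1.96},
                          "se": {"kappa[1]@group": 0.25, "beta": 1.0}})
        est, se, z, p = wald_test(fr, "kappa[1]@group")
        assert (z, p) == (0.0, 1.0)
        est, se, z, p = wald_test(fr, "beta")
        assert p == pytest.approx(0.05, abs=1e-3)
        with pytest.raises(ValueError, match="standard error"):
            wald_test(FitResult(**{**base.__dict__, "se": None}), "kappa[1]@group")

    def test_smd(self):
        assert smd(0.5, 1.0, 1.0) == 0.5
        assert smd(0.0, 0.3, 2.0) == 0.0
        assert smd(1.0, 1.0, 3.0) == pytest.approx(1 / np.sqrt(2))
        with pytest.raises(ValueError, match="positive"):
            smd(1.0, 0.0, 1.0)
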