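"""Model-implied moments, moderation mechanics, invariance models and dfs."""

import numpy as np
import pytest

from metacfa.cfa_model import (
    CFASpec,
    Free,
    InvarianceLevel,
    build_invariance_model,
    count_df,
    implied_moments,
)
from metacfa.simulation import base_spec

VARS5 = [f"y{i + 1}" for i in range(5)]


def _theta_for(spec, **by_prefix):
    """Starting vector with values assigned by parameter-name prefix."""
    model = spec.compile()
    th = model.theta.start.copy()
    for j, name in enumerate(model.theta.names):
        for prefix, val in by_prefix.items():
            if name.startswith(prefix):
                th[j] = val
    return model, th


class TestImpliedMoments:
    def test_one_factor_population_values(self):
        """Loadings .70, residual variances .51, intercepts .50 imply unit
        variances, covariances .49 and means .50."""
        spec = CFASpec.from_loadings(VARS5, {"F1": VARS5})
        _, th = _theta_for(spec, **{"lambda": 0.7, "psi": 0.51, "tau": 0.5})
        Sigma, mu = implied_moments(spec, th, {})
        np.testing.assert_allclose(np.diag(Sigma), np.ones(5), atol=1e-12)
        off = Sigma[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, np.full(20, 0.49), atol=1e-12)
        np.testing.assert_allclose(mu, np.full(5, 0.5), atol=1e-12)

    def test_nonzero_factor_mean_shifts_means(self):
        spec = CFASpec.from_loadings(VARS5, {"F1": VARS5})
        spec.kappa["F1"] = 0.5  # fixed nonzero factor mean
        _, th = _theta_for(spec, **{"lambda": 0.7, "psi": 0.51, "tau": 0.5})
        _, mu = implied_moments(spec, th, {})
        np.testing.assert_allclose(mu, np.full(5, 0.85), atol=1e-12)

    def test_zero_loadings_give_sigma_psi_mu_tau(self):
        spec = CFASpec.from_loadings(VARS5, {"F1": VARS5})
        spec.kappa["F1"] = 2.0
        _, th = _theta_for(spec, **{"lambda": 0.0, "psi": 0.3, "tau": 0.1})
        Sigma, mu = implied_moments(spec, th, {})
        np.testing.assert_allclose(Sigma, 0.3 * np.eye(5), atol=1e-12)
        np.testing.assert_allclose(mu, np.full(5, 0.1), atol=1e-12)

    def test_missing_moderator_value_rejected_by_name(self):
        spec = build_invariance_model(base_spec(), "configural", "group")
        model = spec.compile()
        with pytest.raises(ValueError, match="group"):
            implied_moments(spec, model.theta.start, {})

    def test_zero_slopes_reproduce_unmoderated_moments(self, rng):
        base = base_spec()
        mod = build_invariance_model(base, "configural", "group")
        m_base = base.compile()
        m_mod = mod.compile()
        th_base = rng.standard_normal(m_base.t)
        th_mod = np.zeros(m_mod.t)
        for j, name in enumerate(m_mod.theta.names):
            if "@" not in name:
                th_mod[j] = th_base[m_base.theta.index(name)]
        for x in (0.0, 1.0, 2.5):
            S0, mu0 = implied_moments(base, th_base, {})
            S1, mu1 = implied_moments(mod, th_mod, {"group": x})
            np.testing.assert_allclose(S1, S0, atol=1e-12)
            np.testing.assert_allclose(mu1, mu0, atol=1e-12)

    def test_moderated_loading_enters_linearly(self):
        spec = CFASpec.from_loadings(["a", "b", "c"], {"F": ["a", "b", "c"]})
        spec.moderation["lambda[1,1]"] = {"x": Free(0.0)}
        model, th = _theta_for(spec, **{"lambda": 0.6, "psi": 0.4, "tau": 0.0})
        th[model.theta.index("lambda[1,1]@x")] = 0.3
        S0, _ = implied_moments(spec, th, {"x": 0.0})
        S2, _ = implied_moments(spec, th, {"x": 2.0})
        assert S0[0, 1] == pytest.approx(0.36)
        assert S2[0, 1] == pytest.approx((0.6 + 0.3 * 2.0) * 0.6)  # 0.72

    def test_implied_sigma_symmetric_psd(self, rng):
        spec = base_spec()
        model = spec.compile()
        th = rng.standard_normal(model.t)
        for j, name in enumerate(model.theta.names):
            if name.startswith("psi"):
                th[j] = abs(th[j])  # nonnegative residual variances
        S, _ = implied_moments(spec, th, {})
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        assert np.linalg.eigvalsh(S)[0] > -1e-10


class TestInvarianceModels:
    def test_df_ladder_matches_10_14_18(self):
        spec = base_spec()
        assert count_df(build_invariance_model(spec, "configural", "group")) == 10
        assert count_df(build_invariance_model(spec, "weak", "group")) == 14
        assert count_df(build_invariance_model(spec, "strong", "group")) == 18

    def test_df_differences_decompose(self):
        """df(weak) - df(configural) = (#invariant loadings - #freed factor
        variances); df(strong) - df(weak) = (#invariant intercepts - #freed
        factor means)."""
        spec = base_spec()
        conf = build_invariance_model(spec, "configural", "group")
        weak = build_invariance_model(spec, "weak", "group")
        strong = build_invariance_model(spec, "strong", "group")
        assert count_df(weak) - count_df(conf) == 5 - 1
        assert count_df(strong) - count_df(weak) == 5 - 1

    def test_two_factor_weak_adds_three_dfs(self):
        """Five loadings made invariant, two factor-variance slopes added:
        the weak model gains three degrees of freedom."""
        spec = CFASpec.from_loadings(
            ["F", "O", "T", "E", "R"],
            {"Innovation": ["F", "O"], "Adaptation": ["T", "E", "R"]},
        )
        conf = build_invariance_model(spec, "configural", "group")
        weak = build_invariance_model(spec, "weak", "group")
        assert count_df(weak) - count_df(conf) == 3

    def test_partial_weak_frees_one_loading_slope(self):
        spec = base_spec()
        weak = build_invariance_model(spec, "weak", "group")
        partial = build_invariance_model(spec, "weak", "group",
                                         partial_free=("lambda[3,1]",))
        assert count_df(partial) == count_df(weak) - 1
        assert "group" in partial.moderation["lambda[3,1]"]

    def test_partial_strong_frees_one_intercept_slope(self):
        spec = base_spec()
        strong = build_invariance_model(spec, "strong", "group")
        partial = build_invariance_model(spec, "strong", "group",
                                         partial_free=("tau[2]",))
        assert count_df(partial) == count_df(strong) - 1

    def test_partial_free_validation(self):
        with pytest.raises(ValueError, match="loadings"):
            InvarianceLevel("weak", ("tau[1]",))
        with pytest.raises(ValueError, match="configural"):
            InvarianceLevel("configural", ("lambda[1,1]",))
        with pytest.raises(ValueError, match="unknown parameter"):
            build_invariance_model(base_spec(), "weak", "group",
                                   partial_free=("lambda[9,1]",))

    def test_strong_model_kappa_slope_is_mean_difference(self):
        strong = build_invariance_model(base_spec(), "strong", "group")
        model = strong.compile()
        assert "kappa[1]@group" in model.theta.names
        # baseline factor mean stays fixed at zero
        assert "kappa[1]" not in model.theta.names

    def test_single_indicator_factor_residual_fixed_zero(self):
        spec = CFASpec.from_loadings(
            ["a", "b", "c"], {"F": ["a", "b"], "G": ["c"]}, fix_residual_zero=("c",)
        )
        model = spec.compile()
        assert "psi[3,3]" not in model.theta.names
        S, _ = implied_moments(spec, model.theta.start, {})
        assert S[2, 2] == pytest.approx(model.theta.start[
            model.theta.index("lambda[3,2]")] ** 2)


class TestIdentification:
    def test_unscaled_factor_rejected(self):
        spec = base_spec()
        spec.phi[("F1", "F1")] = Free(1.0)  # no fixed loading, no fixed variance
        with pytest.raises(ValueError, match="scale"):
            count_df(spec)

    def test_unanchored_mean_structure_rejected(self):
        spec = base_spec()
        spec.kappa["F1"] = Free(0.0)  # free mean with all intercepts free
        with pytest.raises(ValueError, match="origin"):
            count_df(spec)

    def test_marker_identification_accepted(self):
        spec = base_spec()
        spec.phi[("F1", "F1")] = Free(1.0)
        spec.loadings[("y1", "F1")] = 1.0  # fixed marker loading
        spec.kappa["F1"] = Free(0.0)
        spec.tau["y1"] = 0.0  # fixed marker intercept
        count_df(spec)  # does not raise

    def test_parameter_vector_bijection(self):
        spec = build_invariance_model(base_spec(), "strong", "group")
        model = spec.compile()
        assert len(model.theta.names) == len(set(model.theta.names))
        assert len(model.theta) == spec.n_free == 22
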