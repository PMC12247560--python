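"""Design matrix, model specs, log-joint decomposition and gradients."""

import logging

import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import approx_fprime

import shashnorm as sn
from shashnorm.models import SubModelKind, _default_priors
from shashnorm.shash import delta_link_inv


class TestDesignMatrix:
    def test_seven_columns(self):
        age = np.array([25.0, 40.0, 55.0, 70.0])
        sex = np.array([0.0, 1.0, 0.0, 1.0])
        X, knots = sn.build_design_matrix(age, sex)
        assert X.shape == (4, 7)
        np.testing.assert_array_equal(X[:, 5], age)
        np.testing.assert_array_equal(X[:, 6], sex)

    def test_spline_partition_of_unity(self):
        age = np.linspace(20, 80, 50)
        X, _ = sn.build_design_matrix(age, np.zeros(50))
        np.testing.assert_allclose(X[:, :5].sum(axis=1), 1.0, atol=1e-12)
        assert np.all(X[:, :5] >= 0)

    def test_constant_age_gives_constant_spline_rows(self):
        age = np.full(6, 42.0)
        X, _ = sn.build_design_matrix(age, np.r_[np.zeros(3), np.ones(3)])
        assert np.ptp(X[:, :5], axis=0).max() == 0.0

    def test_stored_knots_reproducible(self):
        age = np.linspace(30, 60, 20)
        sex = (np.arange(20) % 2).astype(float)
        X1, knots = sn.build_design_matrix(age, sex)
        X2, _ = sn.build_design_matrix(age, sex, knots=knots)
        np.testing.assert_array_equal(X1, X2)

    def test_out_of_span_clamped_with_warning(self, caplog):
        X1, knots = sn.build_design_matrix(
            np.linspace(20, 80, 10), np.zeros(10)
        )
        with caplog.at_level(logging.WARNING, logger="shashnorm"):
            Xp, _ = sn.build_design_matrix(
                np.array([10.0, 90.0]), np.zeros(2), knots=knots
            )
        assert "clamped" in caplog.text
        assert np.all(np.isfinite(Xp))
        # spline values equal the boundary evaluations; raw age passes through
        np.testing.assert_array_equal(Xp[:, 5], [10.0, 90.0])

    def test_validates_inputs(self):
        with pytest.raises(ValueError):
            sn.build_design_matrix(np.array([1.0, 2.0]), np.array([0.0, 2.0]))
        with pytest.raises(ValueError):
            sn.build_design_matrix(np.array([np.nan, 2.0]), np.zeros(2))


class TestModelSpec:
    @pytest.mark.parametrize("name,family,shape", [
        ("N", "normal", None),
        ("So1", "shash_o", SubModelKind.CONSTANT),
        ("Sb1", "shash_b", SubModelKind.CONSTANT),
        ("Sb2", "shash_b", SubModelKind.FIXED_LINEAR),
    ])
    def test_variants(self, name, family, shape):
        spec = sn.ModelSpec.by_name(name)
        assert spec.family == family
        if shape is not None:
            assert spec.shape == shape
        assert spec.mu == SubModelKind.LINEAR_RANDOM_INTERCEPT

    def test_priors_table(self):
        pr = sn.ModelSpec.Sb1().priors
        assert pr["w_mu"] == (0.0, 1.0)
        assert pr["tau_sigma"] == (1.0, 1.0)
        assert pr["epsilon"] == (0.0, 1.0)
        assert pr["delta_raw"] == (1.0, 1.0)
        pr2 = sn.ModelSpec.Sb2().priors
        assert pr2["w_epsilon"][1] == pytest.approx(np.sqrt(0.2))
        assert pr2["tau_delta"] == (1.0, pytest.approx(np.sqrt(0.3)))

    def test_round_trip_serialisation(self):
        spec = sn.ModelSpec.Sb2()
        spec.knots = np.array([20.0] * 4 + [50.0] + [80.0] * 4)
        back = sn.ModelSpec.from_json(spec.to_json())
        assert back.family == spec.family
        assert back.shape == spec.shape
        assert back.priors == spec.priors
        np.testing.assert_array_equal(back.knots, spec.knots)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            sn.ModelSpec(family="cauchy")
        with pytest.raises(ValueError):
            sn.ModelSpec.by_name("Sb9")


def _independent_log_joint(model, theta):
    """Brute-force re-summation of priors + likelihood with scipy.stats."""
    p = model.unpack(theta)
    pr = model.spec.priors
    lp = 0.0
    for name, sl in model.slices.items():
        x = np.atleast_1d(theta[sl])
        if name == "log_sigma_tau_mu":
            s = np.exp(x)
            lp += sps.halfnorm.logpdf(s, scale=pr["sigma_tau_mu"][1]).sum() + x.sum()
        else:
            loc, sd = pr[name]
            lp += sps.norm.logpdf(x, loc, sd).sum()

    X, batch, y = model.X, model.batch, model.y
    if model.spec.mu is SubModelKind.LINEAR_RANDOM_INTERCEPT:
        offs = p["mu_tau_mu"] + np.exp(p["log_sigma_tau_mu"]) * p["nu_tau_mu"]
        mu = X @ p["w_mu"] + offs[batch]
    else:
        mu = X @ p.get("w_mu", np.zeros(X.shape[1])) + p["tau_mu"]
    if model.spec.sigma is SubModelKind.FIXED_LINEAR:
        sigma = np.log1p(np.exp(X @ p["w_sigma"] + p["tau_sigma"]))
    else:
        sigma = np.log1p(np.exp(np.full(len(y), p["tau_sigma"])))

    if model.spec.family == "normal":
        lp += sps.norm.logpdf(y, mu, sigma).sum()
        return lp
    if model.spec.shape is SubModelKind.CONSTANT:
        eps = p["epsilon"]
        dlt = np.log1p(np.exp(10.0 * p["delta_raw"])) / 10.0 + 0.3
    else:
        eps = X @ p["w_epsilon"] + p["tau_epsilon"]
        dlt = np.log1p(np.exp(10.0 * (X @ p["w_delta"] + p["tau_delta"]))) / 10.0 + 0.3
    if model.spec.family == "shash_o":
        lp += np.sum(sn.shasho_logpdf(y, mu, sigma, eps, dlt))
    else:
        lp += np.sum(sn.shashb_logpdf(y, mu, sigma, eps, dlt))
    return lp


class TestLogJoint:
    @pytest.mark.parametrize("variant", ["N", "So1", "Sb1", "Sb2"])
    def test_decomposition_oracle(self, variant, small_design):
        X, batch, y = small_design
        model = sn.make_model(sn.ModelSpec.by_name(variant), X, batch, y)
        rng = np.random.default_rng(3)
        for _ in range(3):
            theta = model.initial_point(rng, jitter=0.2)
            lp, _ = model.logp_and_grad(theta)
            assert lp == pytest.approx(
                _independent_log_joint(model, theta), rel=1e-10
            )

    @pytest.mark.parametrize("variant", ["N", "So1", "Sb1", "Sb2"])
    def test_gradient_matches_numerical(self, variant, small_design):
        X, batch, y = small_design
        model = sn.make_model(sn.ModelSpec.by_name(variant), X, batch, y)
        rng = np.random.default_rng(8)
        theta = model.initial_point(rng, jitter=0.0)
        theta += 0.01 * model.parameter_scales() * rng.standard_normal(model.dim)
        _, g = model.logp_and_grad(theta)
        g_num = approx_fprime(theta, lambda t: model.logp_and_grad(t)[0], 1e-7)
        np.testing.assert_allclose(g, g_num, rtol=2e-3, atol=2e-3)

    def test_gaussian_hand_computed(self):
        # all weights/offsets zero, sigma-raw solving softplus = 1:
        # likelihood reduces to sum of standard-normal log-densities
        X = np.column_stack([np.ones((5, 5)) / 5, np.zeros(5), np.zeros(5)])
        y = np.array([-1.2, 0.0, 0.4, 1.1, 2.0])
        batch = np.zeros(5, dtype=int)
        model = sn.make_model(sn.ModelSpec.N(), X, batch, y)
        theta = np.zeros(model.dim)
        theta[model.slices["tau_sigma"]] = np.log(np.e - 1.0)  # softplus -> 1
        lik = sps.norm.logpdf(y).sum()
        prior = _independent_log_joint(model, theta) - lik
        lp, _ = model.logp_and_grad(theta)
        assert lp == pytest.approx(lik + prior, rel=1e-12)

    def test_gaussian_nesting(self, small_design):
        # Sb1 at epsilon=0 and linked delta=1 gives the Gaussian likelihood
        X, batch, y = small_design
        rng = np.random.default_rng(5)
        n_model = sn.make_model(sn.ModelSpec.N(), X, batch, y)
        s_model = sn.make_model(sn.ModelSpec.Sb1(), X, batch, y)
        theta_n = n_model.initial_point(rng, jitter=0.05)
        theta_s = np.zeros(s_model.dim)
        for name, sl in n_model.slices.items():
            theta_s[s_model.slices[name]] = theta_n[sl]
        theta_s[s_model.slices["epsilon"]] = 0.0
        theta_s[s_model.slices["delta_raw"]] = delta_link_inv(1.0)

        def likelihood_only(model, theta):
            lp, _ = model.logp_and_grad(theta)
            g = np.zeros(model.dim)
            return lp - model._prior_logp_grad(theta, g)

        assert likelihood_only(s_model, theta_s) == pytest.approx(
            likelihood_only(n_model, theta_n), rel=1e-10
        )

    def test_site_permutation_invariance(self, small_design):
        # permuting site labels together with their offsets leaves the
        # log-joint unchanged (random-intercept exchangeability)
        X, batch, y = small_design
        model = sn.make_model(sn.ModelSpec.Sb1(), X, batch, y)
        rng = np.random.default_rng(11)
        theta = model.initial_point(rng, jitter=0.1)
        perm = rng.permutation(model.S)
        batch_p = perm[batch]
        model_p = sn.make_model(sn.ModelSpec.Sb1(), X, batch_p, y)
        theta_p = theta.copy()
        nu = theta[model.slices["nu_tau_mu"]]
        inv = np.argsort(perm)
        theta_p[model_p.slices["nu_tau_mu"]] = nu[inv]
        assert model_p.logp(theta_p) == pytest.approx(model.logp(theta), rel=1e-12)

    def test_unseen_batch_rejected_at_fit(self, small_design):
        X, batch, y = small_design
        with pytest.raises(ValueError):
            sn.make_model(sn.ModelSpec.Sb1(), X, batch, y, n_sites=batch.max())


class TestPredictParams:
    def test_zero_weights_zero_mu(self, small_design):
        X, batch, y = small_design
        model = sn.make_model(sn.ModelSpec.Sb1(), X, batch, y)
        theta = np.zeros(model.dim)
        theta[model.slices["log_sigma_tau_mu"]] = -30.0  # offset sd ~ 0
        mu, sigma, eps, dlt = model.predict_likelihood_params(theta)
        np.testing.assert_allclose(mu, 0.0, atol=1e-12)
        assert np.all(sigma > 0)

    def test_links_enforced(self, small_design):
        X, batch, y = small_design
        model = sn.make_model(sn.ModelSpec.Sb1(), X, batch, y)
        rng = np.random.default_rng(0)
        for _ in range(5):
            theta = rng.normal(0, 2, size=model.dim)
            _, sigma, _, dlt = model.predict_likelihood_params(theta)
            assert np.all(sigma > 0)
            assert np.all(dlt >= sn.DELTA_FLOOR)

    def test_constant_shape_is_shared(self, small_design):
        X, batch, y = small_design
        model = sn.make_model(sn.ModelSpec.Sb1(), X, batch, y)
        theta = model.initial_point(np.random.default_rng(2), jitter=0.3)
        _, _, eps, dlt = model.predict_likelihood_params(theta)
        assert np.unique(eps).size == 1
        assert np.unique(dlt).size == 1

    def test_site_offsets_additive(self):
        X = np.column_stack([np.ones((4, 5)) / 5, np.zeros(4), np.zeros(4)])
        y = np.zeros(4)
        batch = np.array([0, 0, 1, 1])
        model = sn.make_model(sn.ModelSpec.Sb1(), X, batch, y)
        a = 0.7
        theta = np.zeros(model.dim)
        theta[model.slices["log_sigma_tau_mu"]] = 0.0  # sd 1
        theta[model.slices["nu_tau_mu"]] = [a, -a]
        mu, *_ = model.predict_likelihood_params(theta)
        assert mu[0] - mu[2] == pytest.approx(2 * a, rel=1e-12)

    def test_unseen_site_gets_group_mean(self, small_design):
        X, batch, y = small_design
        model = sn.make_model(sn.ModelSpec.Sb1(), X, batch, y)
        theta = model.initial_point(np.random.default_rng(4), jitter=0.2)
        p = model.unpack(theta)
        unseen = np.full(len(batch), model.S, dtype=int)
        mu_u, *_ = model.predict_likelihood_params(theta, X=X, batch=unseen)
        np.testing.assert_allclose(mu_u, X @ p["w_mu"] + p["mu_tau_mu"], atol=1e-12)


def test_default_priors_cover_all_parameters():
    for variant in ["N", "So1", "Sb1", "Sb2"]:
        spec = sn.ModelSpec.by_name(variant)
        shape = spec.shape if spec.family != "normal" else SubModelKind.CONSTANT
        pr = _default_priors(spec.family, shape)
        X = np.zeros((3, 7))
        X[:, 0] = 1.0
        model = sn.make_model(spec, X, np.zeros(3, int), np.zeros(3))
        for name in model.slices:
            key = "sigma_tau_mu" if name == "log_sigma_tau_mu" else name
            assert key in pr
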