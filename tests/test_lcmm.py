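"""Latent class mixed model likelihood, fitting and prediction."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from expotraj import (
    AnnualSeries,
    LCMMParams,
    LCMMSpec,
    LinkFunction,
    TimeBasis,
    fit,
    generate,
    loglik,
    ncs_design,
    posterior_probs,
    predict_trajectory,
    transform,
    two_class_preset,
)
from expotraj.lcmm import _Stacked


def _identity_params(series, spec, beta, sigma, xi=None):
    """Parameters with an exact identity link H(y) = y on the spec's knots."""
    st = _Stacked(series, spec)
    link = LinkFunction.identity_like(spec.link_knots)
    G = beta.shape[0]
    xi = np.zeros(G - 1) if xi is None else xi
    return LCMMParams(xi, beta, np.asarray(sigma, float), link.weights, st.x_scale), st


def _dense_mvn_loglik(series, spec, params):
    """Independent dense-matrix likelihood for the identity-link one-class
    model: MVN with compound-symmetric covariance, Jacobian 1."""
    ll = 0.0
    for s in series:
        Z = ncs_design(s.times, spec.time_basis) / params.x_scale
        X = np.column_stack([np.ones(len(s)), Z])
        mu = X @ params.beta[0]
        n = len(s)
        V = params.sigma[0] ** 2 * np.ones((n, n)) + np.eye(n)
        ll += multivariate_normal.logpdf(s.values, mu, V)
    return ll


class TestLoglik:
    def test_matches_dense_mvn_oracle_constant_series(self, small_spec):
        series = [
            AnnualSeries(f"S{i}", np.arange(4.0), np.full(4, 5.0 + 2.0 * i))
            for i in range(3)
        ]
        beta = np.zeros((1, 5))
        beta[0, 0] = 7.0
        params, _ = _identity_params(series, small_spec, beta, [1.5])
        assert loglik(params, series, small_spec) == pytest.approx(
            _dense_mvn_loglik(series, small_spec, params), abs=1e-8
        )

    def test_duplicating_subjects_doubles_loglik(self, small_spec, tiny_series):
        beta = np.array([[10.0, 0.5, -0.3, 0.2, 0.1]])
        params, _ = _identity_params(tiny_series, small_spec, beta, [1.0])
        ll1 = loglik(params, tiny_series, small_spec)
        doubled = tiny_series + [
            AnnualSeries(s.subject_id + "b", s.times, s.values) for s in tiny_series
        ]
        assert loglik(params, doubled, small_spec) == pytest.approx(2 * ll1, rel=1e-12)

    def test_class_label_permutation_invariance(self, tiny_series, time_basis):
        spec = LCMMSpec(n_classes=3, link_knots=(0.0, 10.0, 40.0), time_basis=time_basis)
        rng = np.random.default_rng(7)
        beta = rng.normal(8.0, 2.0, size=(3, 5))
        params, _ = _identity_params(
            tiny_series, spec, beta, [0.5, 1.0, 1.5], xi=np.array([0.3, -0.2])
        )
        ll = loglik(params, tiny_series, spec)
        for perm in ([1, 2, 0], [2, 0, 1], [1, 0, 2]):
            assert loglik(params.permuted(perm), tiny_series, spec) == pytest.approx(
                ll, abs=1e-9
            )

    def test_nonfinite_params_give_minus_inf(self, small_spec, tiny_series):
        beta = np.full((1, 5), np.nan)
        params, _ = _identity_params(tiny_series, small_spec, np.zeros((1, 5)), [1.0])
        params.beta = beta
        assert loglik(params, tiny_series, small_spec) == -np.inf

    def test_monotone_recoding_shifts_loglik_by_jacobian_constant(
        self, small_spec, tiny_series
    ):
        """Doubling all intensities and composing the link accordingly changes
        the log-likelihood by exactly -n_obs ln 2 (the recoding Jacobian), so
        the model's own Jacobian term is consistent."""
        beta = np.array([[10.0, 0.5, -0.3, 0.2, 0.1]])
        params, _ = _identity_params(tiny_series, small_spec, beta, [1.0])
        ll = loglik(params, tiny_series, small_spec)

        doubled = [AnnualSeries(s.subject_id, s.times, 2.0 * s.values) for s in tiny_series]
        spec2 = LCMMSpec(
            n_classes=1, link_knots=(0.0, 20.0, 80.0), time_basis=small_spec.time_basis
        )
        link2 = LinkFunction.identity_like((0.0, 20.0, 80.0), scale=2.0)
        st2 = _Stacked(doubled, spec2, x_scale=params.x_scale)
        params2 = LCMMParams(
            params.xi, params.beta, params.sigma, link2.weights, st2.x_scale
        )
        n_obs = sum(len(s) for s in tiny_series)
        assert loglik(params2, doubled, spec2) == pytest.approx(
            ll - n_obs * math.log(2.0), abs=1e-8
        )


class TestPosterior:
    def test_single_class_posterior_is_one(self, small_spec, tiny_series):
        beta = np.array([[10.0, 0.0, 0.0, 0.0, 0.0]])
        params, _ = _identity_params(tiny_series, small_spec, beta, [1.0])
        P = posterior_probs(params, tiny_series, small_spec)
        assert np.all(P == 1.0)

    def test_rows_sum_to_one_and_match_naive_computation(self, tiny_series, time_basis):
        spec = LCMMSpec(n_classes=2, link_knots=(0.0, 10.0, 40.0), time_basis=time_basis)
        beta = np.array([[8.0, 0.2, 0.1, 0.0, 0.0], [14.0, -0.1, 0.0, 0.1, 0.0]])
        params, _ = _identity_params(
            tiny_series, spec, beta, [1.0, 1.2], xi=np.array([0.4])
        )
        P = posterior_probs(params, tiny_series, spec)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

        # naive per-class densities without log-space stabilisation
        pi = params.class_probs
        for i, s in enumerate(tiny_series):
            Z = ncs_design(s.times, spec.time_basis) / params.x_scale
            X = np.column_stack([np.ones(len(s)), Z])
            dens = []
            for g in range(2):
                n = len(s)
                V = params.sigma[g] ** 2 * np.ones((n, n)) + np.eye(n)
                dens.append(pi[g] * multivariate_normal.pdf(s.values, X @ params.beta[g], V))
            naive = np.array(dens) / np.sum(dens)
            assert np.allclose(P[i], naive, atol=1e-10)

    def test_equidistant_subject_splits_evenly(self, time_basis):
        spec = LCMMSpec(n_classes=2, link_knots=(0.0, 10.0, 40.0), time_basis=time_basis)
        series = [AnnualSeries("mid", np.arange(5.0), np.full(5, 10.0))]
        beta = np.zeros((2, 5))
        beta[0, 0], beta[1, 0] = 8.0, 12.0  # symmetric around the subject
        params, _ = _identity_params(series, spec, beta, [1.0, 1.0], xi=np.array([0.0]))
        P = posterior_probs(params, series, spec)
        assert np.allclose(P[0], [0.5, 0.5], atol=1e-12)


class TestFit:
    def test_one_class_recovers_trend(self):
        """G=1 on synthetic linear-trend data recovers the latent curve."""
        rng = np.random.default_rng(12)
        tb = TimeBasis(boundary_knots=(0.0, 45.0))
        series = []
        for i in range(300):
            t = np.arange(0.0, rng.integers(25, 45), dtype=float)
            truth_lat = 4.0 + 0.08 * t
            y = np.clip(
                3.0 * (truth_lat + rng.normal(0, 0.8) + rng.normal(0, 1, t.size)),
                0.0,
                40.0,
            )
            series.append(AnnualSeries(f"S{i}", t, y))
        spec = LCMMSpec(n_classes=1, link_knots=(0.0, 10.0, 40.0), time_basis=tb, seed=0)
        f = fit(series, spec)
        assert f.converged
        tgrid = np.linspace(0.0, 40.0, 9)
        pred = predict_trajectory(f.params, 0, tgrid, spec, scale="latent")
        link_fit = LinkFunction(spec.link_knots, f.params.link_weights)
        nat = transform(3.0 * (4.0 + 0.08 * tgrid), LinkFunction.identity_like((0.0, 10.0, 40.0)))
        # compare on the natural scale: H_fit^-1(pred) vs the generating curve
        from expotraj import inverse_transform

        nat_pred = inverse_transform(pred, link_fit)
        assert np.allclose(nat_pred, 3.0 * (4.0 + 0.08 * tgrid), rtol=0.05)

    def test_well_separated_two_class_accuracy(self):
        truth = two_class_preset()
        subjects, series, labels = generate(truth, 300, seed=21)
        spec = LCMMSpec(
            n_classes=2,
            link_knots=truth.link.knots,
            time_basis=truth.time_basis,
            n_starts=8,
            seed=1,
        )
        f = fit(series, spec)
        from expotraj import classification_accuracy

        assert f.converged
        assert classification_accuracy(labels[labels >= 0], f.modal_class, 2) >= 0.95

    def test_multistart_robust_to_seed(self):
        truth = two_class_preset()
        _, series, _ = generate(truth, 200, seed=3)
        lls = []
        for seed in (1, 99):
            spec = LCMMSpec(
                n_classes=2,
                link_knots=truth.link.knots,
                time_basis=truth.time_basis,
                n_starts=8,
                seed=seed,
            )
            lls.append(fit(series, spec).loglik)
        assert abs(lls[0] - lls[1]) <= 1e-4

    def test_aic_bic_definitions(self):
        truth = two_class_preset()
        _, series, _ = generate(truth, 120, seed=5)
        spec = LCMMSpec(
            n_classes=1, link_knots=truth.link.knots, time_basis=truth.time_basis, seed=0
        )
        f = fit(series, spec)
        assert f.aic == pytest.approx(-2 * f.loglik + 2 * f.n_params)
        assert f.bic == pytest.approx(-2 * f.loglik + f.n_params * math.log(f.n_subjects))
        assert np.allclose(f.posterior.sum(axis=1), 1.0, atol=1e-10)


class TestPredict:
    def setup_method(self):
        self.truth = two_class_preset()
        _, self.series, _ = generate(self.truth, 150, seed=8)
        self.spec = LCMMSpec(
            n_classes=2,
            link_knots=self.truth.link.knots,
            time_basis=self.truth.time_basis,
            n_starts=6,
            seed=2,
        )
        self.fit = fit(self.series, self.spec)

    def test_natural_close_to_latent_for_identity_like_link(self):
        t = np.linspace(0.0, 40.0, 9)
        lat = predict_trajectory(self.fit.params, 0, t, self.spec, scale="latent")
        nat = predict_trajectory(self.fit.params, 0, t, self.spec, scale="natural")
        link = LinkFunction(self.spec.link_knots, self.fit.params.link_weights)
        from expotraj import inverse_transform

        plug_in = inverse_transform(lat, link)
        # identity-like link: marginal mean ~= plug-in away from boundaries
        assert np.allclose(nat, plug_in, rtol=0.1, atol=0.5)

    def test_natural_bounded_by_link_knots(self):
        t = np.linspace(0.0, 45.0, 12)
        for g in range(2):
            nat = predict_trajectory(self.fit.params, g, t, self.spec, scale="natural")
            assert np.all(nat >= 0.0 - 1e-9)
            assert np.all(nat <= 40.0 + 1e-9)

    def test_quadrature_node_count_converged(self):
        t = np.linspace(0.0, 40.0, 7)
        spec60 = LCMMSpec(
            n_classes=2,
            link_knots=self.spec.link_knots,
            time_basis=self.spec.time_basis,
            control=self.spec.control.__class__(gh_nodes=60),
        )
        n30 = predict_trajectory(self.fit.params, 1, t, self.spec, scale="natural")
        n60 = predict_trajectory(self.fit.params, 1, t, spec60, scale="natural")
        assert np.max(np.abs(n30 - n60)) < 1e-4

    def test_degenerate_link_errors(self):
        bad = LCMMParams(
            self.fit.params.xi,
            self.fit.params.beta,
            self.fit.params.sigma,
            np.zeros_like(self.fit.params.link_weights),
            self.fit.params.x_scale,
        )
        with pytest.raises(ValueError, match="degenerate"):
            predict_trajectory(bad, 0, [5.0], self.spec, scale="natural")


class TestLatentClassGrowthAnalysis:
    """random_intercept=False fixes all sigma_g at 0 (LCGA): independent
    errors, so the one-class MLE of beta given the link is ordinary least
    squares of H(y) on the time design."""

    def test_sigma_zero_loglik_matches_independent_error_oracle(
        self, small_spec, tiny_series
    ):
        from scipy.stats import norm

        beta = np.array([[10.0, 0.5, -0.3, 0.2, 0.1]])
        params, st = _identity_params(tiny_series, small_spec, beta, [0.0])
        ll = loglik(params, tiny_series, small_spec)
        mu = st.X @ beta[0]
        oracle = norm.logpdf(st.y, mu, 1.0).sum()  # identity link: Jacobian 1
        assert ll == pytest.approx(oracle, abs=1e-9)

    def test_lcga_fit_beta_is_least_squares_of_transformed_outcome(self):
        truth = two_class_preset()
        _, series, _ = generate(truth, 150, seed=13)
        spec = LCMMSpec(
            n_classes=1,
            link_knots=truth.link.knots,
            time_basis=truth.time_basis,
            random_intercept=False,
            seed=0,
        )
        f = fit(series, spec)
        assert np.all(f.params.sigma == 0.0)
        st = _Stacked(series, spec, x_scale=f.params.x_scale)
        h = st.I @ f.params.link_weights**2
        beta_ols, *_ = np.linalg.lstsq(st.X, h, rcond=None)
        assert np.allclose(f.params.beta[0], beta_ols, atol=1e-5)
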