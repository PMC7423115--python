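"""Latent class mixed model for lifetime exposure-intensity trajectories.

Model.  The population is a mixture of G latent classes.  Class membership
follows a multinomial logistic sub-model with class-specific intercepts
only: pi_g = softmax(xi)_g, with the last class as reference (xi_G = 0).
Within class g, the transformed annual intensity of subject i at time t_ij
(years before the index date) follows a linear mixed model

    H(Y_ij) = X(t_ij)' beta_g + u_i + eps_ij,
    u_i ~ N(0, sigma_g^2),  eps_ij ~ N(0, sigma_eps^2),

where X(t) is an intercept plus natural-cubic-spline functions of time and
H is a monotone I-spline link shared across classes.  The observed-data
likelihood multiplies the multivariate normal density of the transformed
series (compound-symmetric covariance, closed form — no numerical
integration is needed for a random intercept) by the Jacobian
prod_j H'(y_ij), once per observation regardless of class.

Identifiability.  The link intercept is fixed at 0 and sigma_eps at 1:
location and scale of the latent process are carried by the class
trajectory coefficients, leaving one location and one scale redundancy
removed from the measurement part.

Estimation is maximum likelihood by BFGS with an analytic gradient, with a
multi-start grid (default 50 starts, matching common practice for these
models) to guard against local maxima: the one-class solution is fitted
first, perturbed starts are run for a few iterations each, and the best is
refined to full convergence.  Convergence requires three criteria at once:
max parameter change, log-likelihood change, and the scaled gradient
criterion g' H^{-1} g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .exposure import AnnualSeries
from .splines import ISplineBasis, LinkFunction, TimeBasis, inverse_transform, ncs_design

__all__ = [
    "FitControl",
    "LCMMSpec",
    "LCMMParams",
    "LCMMFit",
    "ConvergenceError",
    "loglik",
    "fit",
    "posterior_probs",
    "predict_trajectory",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FitControl:
    """Optimizer and convergence configuration."""

    max_iter: int = 500
    short_iters: int = 15
    tol_param: float = 1e-4
    tol_loglik: float = 1e-8
    tol_grad: float = 1e-4
    gtol: float = 1e-6
    min_class_size: int = 5
    gh_nodes: int = 30


@dataclass(frozen=True)
class LCMMSpec:
    """Model specification: number of classes, time basis, link knots,
    multi-start grid size and seed."""

    n_classes: int = 1
    time_basis: TimeBasis = field(default_factory=TimeBasis)
    link_knots: tuple = (0.0, 20.0, 100.0)
    link_order: int = 3
    random_intercept: bool = True
    n_starts: int = 50
    seed: int = 0
    control: FitControl = field(default_factory=FitControl)

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class LCMMParams:
    """Estimated parameters.

    ``xi``: class-membership intercepts (G-1; reference class fixed at 0).
    ``beta``: per-class trajectory coefficients, rows = classes, columns =
    intercept followed by scaled natural-spline columns.
    ``sigma``: per-class random-intercept SDs (>= 0).
    ``link_weights``: unconstrained link coefficients entering squared.
    ``x_scale``: per-column divisors applied to the natural-spline design
    (conditioning; part of the model definition for prediction).
    ``sigma_eps`` is fixed at 1 for identifiability.
    """

    xi: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    link_weights: np.ndarray
    x_scale: np.ndarray
    sigma_eps: float = 1.0

    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]

    @property
    def class_probs(self) -> np.ndarray:
        xi_full = np.append(self.xi, 0.0)
        e = np.exp(xi_full - xi_full.max())
        return e / e.sum()

    def permuted(self, perm) -> "LCMMParams":
        """Relabel classes by ``perm`` (perm[k] = old index of new class k)."""
        perm = list(perm)
        pi = self.class_probs[perm]
        xi = np.log(pi[:-1]) - np.log(pi[-1])
        return LCMMParams(
            xi, self.beta[perm], self.sigma[perm], self.link_weights.copy(),
            self.x_scale.copy(), self.sigma_eps,
        )


@dataclass
class LCMMFit:
    params: LCMMParams
    loglik: float
    n_params: int
    aic: float
    bic: float
    converged: bool
    criteria: dict
    posterior: np.ndarray
    modal_class: np.ndarray
    subject_ids: list
    spec: LCMMSpec

    @property
    def n_subjects(self) -> int:
        return self.posterior.shape[0]


class ConvergenceError(RuntimeError):
    """No multi-start run converged; carries the best non-converged fit."""

    def __init__(self, message: str, best_fit: LCMMFit | None = None):
        super().__init__(message)
        self.best_fit = best_fit


# ---------------------------------------------------------------------------
# Stacked data and likelihood
# ---------------------------------------------------------------------------


class _Stacked:
    """Per-dataset precomputations shared across likelihood evaluations."""

    def __init__(self, data: list[AnnualSeries], spec: LCMMSpec, x_scale=None):
        if not data:
            raise ValueError("no subjects")
        if any(len(s) == 0 for s in data):
            raise ValueError("every subject needs at least one observation")
        self.ids = [s.subject_id for s in data]
        self.n_i = np.array([len(s) for s in data])
        self.starts = np.r_[0, np.cumsum(self.n_i)[:-1]]
        self.subj = np.repeat(np.arange(len(data)), self.n_i)
        t = np.concatenate([s.times for s in data])
        self.y = np.concatenate([s.values for s in data])
        Z = ncs_design(t, spec.time_basis)
        if x_scale is None:
            x_scale = Z.std(axis=0)
            x_scale[x_scale == 0] = 1.0
        self.x_scale = np.asarray(x_scale, dtype=float)
        self.X = np.column_stack([np.ones(t.size), Z / self.x_scale])
        self.p = self.X.shape[1]
        basis = ISplineBasis(spec.link_knots, spec.link_order)
        self.I = basis.ibasis(self.y)
        self.M = basis.mbasis(self.y)
        self.K = basis.n_basis
        self.basis = basis

    def n_theta(self, G: int) -> int:
        return (G - 1) + G * self.p + G + self.K


def _unpack(theta, G, p, K):
    xi = theta[: G - 1]
    beta = theta[G - 1 : G - 1 + G * p].reshape(G, p)
    a = theta[G - 1 + G * p : G - 1 + G * p + G]
    w = theta[G - 1 + G * p + G :]
    return xi, beta, a, w


def _pack(xi, beta, a, w):
    return np.concatenate([xi, beta.ravel(), a, w])


_PENALTY = 1e12


def _nll_grad(theta, st: _Stacked, G: int, fix_sigma: bool = False):
    """Negative log-likelihood and its gradient, vectorized over subjects.

    The compound-symmetric covariance sigma_g^2 J + I is handled in closed
    form (Sherman-Morrison): for a subject with n observations,
    log|V| = log(1 + n v_g) and the quadratic form is r'r - v_g/(1+n v_g)
    (1'r)^2, with v_g = sigma_g^2.
    """
    if not np.all(np.isfinite(theta)):
        return _PENALTY, np.zeros_like(theta)
    xi, beta, a, w = _unpack(theta, G, st.p, st.K)
    if fix_sigma:  # latent class growth analysis: no random effects
        a = np.zeros_like(a)
    c = w * w
    h = st.I @ c
    hp = st.M @ c
    if np.any(hp <= 0.0):
        return _PENALTY, np.zeros_like(theta)
    lj = np.add.reduceat(np.log(hp), st.starts)  # (N,)

    mu = st.X @ beta.T  # (nobs, G)
    r = h[:, None] - mu
    S1 = np.add.reduceat(r, st.starts, axis=0)  # (N, G)
    S2 = np.add.reduceat(r * r, st.starts, axis=0)
    v = a * a
    denom = 1.0 + st.n_i[:, None] * v
    quad = S2 - (v / denom) * S1**2
    logf = -0.5 * st.n_i[:, None] * _LOG2PI - 0.5 * np.log(denom) - 0.5 * quad
    logf += lj[:, None]

    xi_full = np.append(xi, 0.0)
    lpi = xi_full - (xi_full.max() + np.log(np.exp(xi_full - xi_full.max()).sum()))
    A = lpi + logf
    m = A.max(axis=1)
    lse = m + np.log(np.exp(A - m[:, None]).sum(axis=1))
    ll = lse.sum()
    if not np.isfinite(ll):
        return _PENALTY, np.zeros_like(theta)
    P = np.exp(A - lse[:, None])  # posterior class probabilities (N, G)

    pi = np.exp(lpi)
    g_xi = (P - pi).sum(axis=0)[: G - 1]
    coef = v / denom  # (N, G)
    Vinvr = r - (coef * S1)[st.subj]  # (nobs, G)
    Pobs = P[st.subj]
    g_beta = (st.X.T @ (Pobs * Vinvr)).T  # (G, p)
    g_v = (P * (-st.n_i[:, None] / (2.0 * denom) + S1**2 / (2.0 * denom**2))).sum(axis=0)
    g_a = np.zeros_like(a) if fix_sigma else g_v * 2.0 * a
    q = (Pobs * Vinvr).sum(axis=1)
    g_c = -(st.I.T @ q) + st.M.T @ (1.0 / hp)
    g_w = g_c * 2.0 * w
    grad = _pack(g_xi, g_beta, g_a, g_w)
    return -ll, -grad


def _posterior(theta, st, G):
    """Posterior class probabilities (log-sum-exp stabilized) and loglik."""
    xi, beta, a, w = _unpack(theta, G, st.p, st.K)
    c = w * w
    h = st.I @ c
    hp = st.M @ c
    lj = np.add.reduceat(np.log(hp), st.starts)
    mu = st.X @ beta.T
    r = h[:, None] - mu
    S1 = np.add.reduceat(r, st.starts, axis=0)
    S2 = np.add.reduceat(r * r, st.starts, axis=0)
    v = a * a
    denom = 1.0 + st.n_i[:, None] * v
    logf = (
        -0.5 * st.n_i[:, None] * _LOG2PI
        - 0.5 * np.log(denom)
        - 0.5 * (S2 - (v / denom) * S1**2)
        + lj[:, None]
    )
    xi_full = np.append(xi, 0.0)
    lpi = xi_full - (xi_full.max() + np.log(np.exp(xi_full - xi_full.max()).sum()))
    A = lpi + logf
    m = A.max(axis=1)
    lse = m + np.log(np.exp(A - m[:, None]).sum(axis=1))
    return np.exp(A - lse[:, None]), float(lse.sum())


def _params_to_theta(params: LCMMParams) -> np.ndarray:
    return _pack(params.xi, params.beta, params.sigma, params.link_weights)


def _theta_to_params(theta, st, G) -> LCMMParams:
    xi, beta, a, w = _unpack(theta, G, st.p, st.K)
    return LCMMParams(xi.copy(), beta.copy(), np.abs(a), w.copy(), st.x_scale.copy())


def loglik(params: LCMMParams, data: list[AnnualSeries], spec: LCMMSpec) -> float:
    """Observed-data log-likelihood at ``params`` (-inf if non-finite)."""
    st = _Stacked(data, spec, x_scale=params.x_scale)
    nll, _ = _nll_grad(_params_to_theta(params), st, params.n_classes)
    return -np.inf if nll >= _PENALTY else -nll


def posterior_probs(params: LCMMParams, data: list[AnnualSeries], spec: LCMMSpec) -> np.ndarray:
    """N x G posterior class-membership probabilities; rows sum to 1."""
    st = _Stacked(data, spec, x_scale=params.x_scale)
    P, _ = _posterior(_params_to_theta(params), st, params.n_classes)
    return P


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _optimize(theta0, st, G, control: FitControl, maxiter=None, check=True,
              fix_sigma=False):
    """BFGS run; when ``check``, polish with a restart and evaluate the
    three convergence criteria on the final step."""
    fun = lambda th: _nll_grad(th, st, G, fix_sigma)
    res = minimize(
        fun, theta0, jac=True, method="BFGS",
        options={"maxiter": maxiter or control.max_iter, "gtol": control.gtol},
    )
    if not check:
        return res.x, -res.fun, False, {}
    hist = []
    res2 = minimize(
        fun, res.x, jac=True, method="BFGS",
        callback=hist.append,
        options={"maxiter": control.max_iter, "gtol": control.gtol},
    )
    x1 = res2.x
    f1 = res2.fun
    if hist:
        x0_last = hist[-2] if len(hist) >= 2 else res.x
    else:
        x0_last = res.x
    d_param = float(np.max(np.abs(x1 - x0_last)))
    f0_last, _ = fun(x0_last)
    d_ll = float(abs(f1 - f0_last))
    g = res2.jac
    g_crit = float(g @ res2.hess_inv @ g)
    criteria = {
        "d_param": d_param,
        "d_loglik": d_ll,
        "grad_crit": g_crit,
        "param_ok": d_param < control.tol_param,
        "loglik_ok": d_ll < control.tol_loglik,
        "grad_ok": g_crit < control.tol_grad,
    }
    converged = criteria["param_ok"] and criteria["loglik_ok"] and criteria["grad_ok"]
    return x1, -f1, converged, criteria


def _g1_start(st: _Stacked) -> np.ndarray:
    """Deterministic one-class start: link scaled to unit latent SD, OLS
    trajectory coefficients, between-subject residual SD."""
    sd = st.y.std()
    if sd <= 0:
        raise ValueError("degenerate data: no variation in intensities")
    c0 = st.basis._norms / sd
    w0 = np.sqrt(c0)
    h = st.I @ c0
    beta0, *_ = np.linalg.lstsq(st.X, h, rcond=None)
    resid = h - st.X @ beta0
    subj_means = np.add.reduceat(resid, st.starts) / st.n_i
    a0 = math.sqrt(max(float(np.var(subj_means)), 1e-2))
    return _pack(np.zeros(0), beta0[None, :], np.array([a0]), w0)


def fit(
    data: list[AnnualSeries],
    spec: LCMMSpec,
    extra_starts: list[LCMMParams] | None = None,
) -> LCMMFit:
    """Maximum-likelihood fit with the multi-start grid.

    The one-class model is fitted first from a deterministic start.  For
    G > 1, ``spec.n_starts`` perturbed starts (class intercepts spread by
    the total latent SD, membership intercepts ~ N(0,1)) are each run for
    ``control.short_iters`` BFGS iterations; the best candidates are
    refined to full convergence, discarding solutions where a class holds
    fewer than ``control.min_class_size`` subjects (a degenerate-solution
    guard).  Deterministic given ``spec.seed``.  ``extra_starts`` lets a
    caller (e.g. the model-selection ladder) seed additional starting
    values.
    """
    G = spec.n_classes
    ctl = spec.control
    fix_sigma = not spec.random_intercept
    st = _Stacked(data, spec)

    theta1 = _g1_start(st)
    if fix_sigma:
        theta1[-(st.K + 1) : -st.K] = 0.0
    x1, ll1, conv1, crit1 = _optimize(theta1, st, 1, ctl, fix_sigma=fix_sigma)
    if G == 1:
        return _package(x1, st, 1, spec, ll1, conv1, crit1)

    rng = np.random.default_rng(spec.seed)
    _, beta1, a1, w1 = _unpack(x1, 1, st.p, st.K)
    s_tot = math.sqrt(a1[0] ** 2 + 1.0)  # total latent-scale SD

    # subject-level mean residuals: a one-dimensional summary of where each
    # subject sits relative to the common trajectory, used for level-split
    # starting values (much of the class separation is in the level)
    h1 = st.I @ (w1 * w1)
    resid1 = h1 - st.X @ beta1[0]
    subj_means = np.add.reduceat(resid1, st.starts) / st.n_i

    starts = []
    if extra_starts:
        for pr in extra_starts:
            if pr.n_classes == G:
                starts.append(_params_to_theta(pr))
    # deterministic quantile-split start: class intercepts at the subject-mean
    # quantiles, within-class SD at a fraction of the one-class estimate
    q = np.quantile(subj_means, (2.0 * np.arange(G) + 1.0) / (2.0 * G))
    beta_q = np.tile(beta1, (G, 1))
    beta_q[:, 0] += q
    starts.append(
        _pack(np.zeros(G - 1), beta_q, np.full(G, 0.5 * abs(a1[0]) + 0.05), w1)
    )
    for _ in range(spec.n_starts):
        beta_g = np.tile(beta1, (G, 1))
        beta_g[:, 0] += rng.normal(0.0, 1.5 * s_tot, size=G)
        beta_g[:, 1:] += rng.normal(0.0, 0.5 * s_tot, size=(G, st.p - 1))
        xi0 = rng.normal(0.0, 1.0, size=G - 1)
        a0 = 0.5 * np.abs(a1[0]) * np.exp(rng.normal(0.0, 0.3, size=G)) + 0.02
        w0 = w1 * np.exp(rng.normal(0.0, 0.1, size=st.K))
        starts.append(_pack(xi0, beta_g, a0, w0))

    short = []
    if fix_sigma:
        for th0 in starts:
            th0[G - 1 + G * st.p : G - 1 + G * st.p + G] = 0.0
    for th0 in starts:
        x, ll, _, _ = _optimize(th0, st, G, ctl, maxiter=ctl.short_iters, check=False,
                                fix_sigma=fix_sigma)
        short.append((ll, x))
    short.sort(key=lambda t: -t[0])

    best_fail: LCMMFit | None = None
    for ll_short, x0 in short:
        if not np.isfinite(ll_short):
            continue
        x, ll, conv, crit = _optimize(x0, st, G, ctl, fix_sigma=fix_sigma)
        P, _ = _posterior(x, st, G)
        modal_counts = np.bincount(P.argmax(axis=1), minlength=G)
        degenerate = modal_counts.min() < ctl.min_class_size
        fitted = _package(x, st, G, spec, ll, conv and not degenerate, crit)
        if conv and not degenerate:
            return fitted
        if best_fail is None or fitted.loglik > best_fail.loglik:
            best_fail = fitted
    raise ConvergenceError(
        f"no start converged to a non-degenerate {G}-class solution", best_fail
    )


def _package(theta, st, G, spec, ll, converged, criteria) -> LCMMFit:
    params = _theta_to_params(theta, st, G)
    P, _ = _posterior(theta, st, G)
    N = len(st.ids)
    k = st.n_theta(G)
    return LCMMFit(
        params=params,
        loglik=ll,
        n_params=k,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * math.log(N),
        converged=converged,
        criteria=criteria,
        posterior=P,
        modal_class=P.argmax(axis=1),
        subject_ids=list(st.ids),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_trajectory(
    params: LCMMParams,
    class_index: int,
    times,
    spec: LCMMSpec,
    scale: str = "latent",
) -> np.ndarray:
    """Mean trajectory of class ``class_index`` at ``times``.

    ``scale="latent"`` returns X(t)'beta_g.  ``scale="natural"`` returns
    E[H^{-1}(X(t)'beta_g + u + eps)] by Gauss-Hermite quadrature over the
    combined Gaussian deviation u + eps ~ N(0, sigma_g^2 + sigma_eps^2),
    i.e. the marginal mean intensity on the observed scale.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    Z = ncs_design(times, spec.time_basis) / params.x_scale
    X = np.column_stack([np.ones(times.size), Z])
    lat = X @ params.beta[class_index]
    if scale == "latent":
        return lat
    if scale != "natural":
        raise ValueError("scale must be 'latent' or 'natural'")
    link = LinkFunction(spec.link_knots, params.link_weights, 0.0, spec.link_order)
    if link.is_degenerate():
        raise ValueError("degenerate flat link: natural-scale prediction undefined")
    s = math.sqrt(params.sigma[class_index] ** 2 + params.sigma_eps**2)
    nodes, weights = np.polynomial.hermite_e.hermegauss(spec.control.gh_nodes)
    weights = weights / math.sqrt(2.0 * math.pi)
    grid = lat[:, None] + s * nodes[None, :]
    vals = inverse_transform(grid.ravel(), link).reshape(grid.shape)
    return vals @ weights
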