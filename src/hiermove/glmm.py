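"""Maximum-likelihood fitters for the random-intercept logistic model.

Two estimators of the same model the Bayesian sampler targets (minus the
priors): a Laplace-approximation marginal-likelihood fitter (the glmer
route) and a penalized quasi-likelihood fitter (the glmmPQL route), plus
an adaptive Gauss-Hermite quadrature evaluator of the marginal
log-likelihood used as an independent accuracy oracle.

For a random-intercept-only model the inner problem is one-dimensional
per group, so the random-effect modes are found by a vectorized Newton
iteration across all groups simultaneously, and the Laplace objective

    l(beta, sigma) = sum_i [z_i eta_i - log(1 + e^{eta_i})]
                     - sum_j u_j^2 / (2 sigma^2)
                     - (1/2) sum_j log(1 + sigma^2 W_j)

(eta evaluated at the modes u_j-hat, W_j = sum_i mu_i (1 - mu_i)) is
maximized by BFGS over (beta, log sigma) with an analytic gradient
obtained by implicit differentiation of the mode equations.

PQL is known to attenuate fixed-effect estimates for binary responses
when the random-effect standard deviation is large; it is provided for
comparison, flagged as quasi-likelihood (no true log-likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, logsumexp

from .hierbayes import HierLogitModel

__all__ = [
    "GLMMFit",
    "fit_laplace",
    "fit_pql",
    "marginal_loglik_quadrature",
    "laplace_loglik_and_grad",
]


@dataclass
class GLMMFit:
    """Estimate bundle for a fitted random-intercept logistic model."""

    beta: np.ndarray
    sigma_u: float
    se_beta: np.ndarray
    loglik: float | None  # None for PQL (quasi-likelihood, no true loglik)
    converged: bool
    n_iter: int
    method: str
    coef_names: tuple
    boundary: bool = False  # sigma_u at (or numerically on) zero
    u_hat: np.ndarray | None = None

    def wald_intervals(self, level: float = 0.95) -> np.ndarray:
        from scipy.stats import norm

        zcrit = norm.ppf(0.5 + level / 2.0)
        return np.column_stack(
            [self.beta - zcrit * self.se_beta, self.beta + zcrit * self.se_beta]
        )

    def estimates_frame(self):
        import pandas as pd

        ci = self.wald_intervals()
        return pd.DataFrame(
            {
                "parameter": list(self.coef_names),
                "estimate": self.beta,
                "se": self.se_beta,
                "lower": ci[:, 0],
                "upper": ci[:, 1],
            }
        )


def _check_model(model: HierLogitModel) -> None:
    if model.n_groups < 2:
        raise ValueError("need at least 2 groups to estimate a random effect")
    if model.z.min() == model.z.max():
        raise ValueError("response is constant; model not estimable")
    spans = model.X.max(axis=0) - model.X.min(axis=0)
    dead = [model.coef_names[k] for k in range(1, model.n_coef) if spans[k] == 0]
    if dead:
        raise ValueError(
            f"design column(s) {dead} are constant; the coefficient is not "
            "identifiable — drop the column or supply data with variation"
        )


def _find_modes(
    model: HierLogitModel, beta: np.ndarray, sigma2: float,
    u0: np.ndarray | None = None, tol: float = 1e-10, max_iter: int = 100,
):
    """Vectorized per-group Newton search for the random-effect modes.

    Returns (u_hat, eta, mu, W) where W_j = sum_i mu_i(1-mu_i).
    """
    starts0 = model.track_index.starts0
    row_group = model.track_index.row_groups()
    Xb = model.X @ beta
    u = np.zeros(model.n_groups) if u0 is None else u0.copy()
    for it in range(max_iter):
        eta = Xb + u[row_group]
        mu = expit(eta)
        score = np.add.reduceat(model.z - mu, starts0) - u / sigma2
        W = np.add.reduceat(mu * (1.0 - mu), starts0)
        H = W + 1.0 / sigma2
        step = score / H
        # penalized log-concave objective: full Newton with a step cap
        np.clip(step, -4.0, 4.0, out=step)
        u = u + step
        if np.max(np.abs(score)) < tol and it > 0:
            break
    eta = Xb + u[row_group]
    mu = expit(eta)
    W = np.add.reduceat(mu * (1.0 - mu), starts0)
    return u, eta, mu, W


def laplace_loglik_and_grad(
    model: HierLogitModel, beta: np.ndarray, log_sigma: float,
    u0: np.ndarray | None = None,
):
    """Laplace marginal log-likelihood and its exact gradient.

    The gradient in (beta, log sigma) accounts for the dependence of the
    modes u_j-hat and the curvature terms W_j on the parameters via the
    implicit function theorem; third-derivative terms
    V_j = sum_i mu(1-mu)(1-2mu) enter through the log-determinant.
    """
    sigma2 = float(np.exp(2.0 * log_sigma))
    starts0 = model.track_index.starts0
    row_group = model.track_index.row_groups()
    u, eta, mu, W = _find_modes(model, beta, sigma2, u0=u0)
    H = W + 1.0 / sigma2
    resid = model.z - mu

    ll = (
        float(model.z @ eta - np.logaddexp(0.0, eta).sum())
        - 0.5 * float(u @ u) / sigma2
        - 0.5 * float(np.sum(np.log1p(sigma2 * W)))
    )

    w = mu * (1.0 - mu)
    v = w * (1.0 - 2.0 * mu)
    V = np.add.reduceat(v, starts0)  # dW_j / du_j at the mode
    # C[j, k] = sum_{i in j} w_i x_ik ;  T[j, k] = sum_{i in j} v_i x_ik
    C = np.add.reduceat(w[:, None] * model.X, starts0, axis=0)
    T = np.add.reduceat(v[:, None] * model.X, starts0, axis=0)
    du_dbeta = -C / H[:, None]  # implicit differentiation of the mode eqn
    a = 1.0 / H  # = sigma2 / (1 + sigma2 W)

    grad_beta = (
        resid @ model.X
        - 0.5 * (a[:, None] * (T + V[:, None] * du_dbeta)).sum(axis=0)
    )
    du_drho = 2.0 * u / (sigma2 * H)
    grad_rho = float(
        np.sum(u**2) / sigma2
        - np.sum(sigma2 * W / (1.0 + sigma2 * W))
        - 0.5 * np.sum(a * V * du_drho)
    )
    return ll, np.append(grad_beta, grad_rho), u


def _pooled_logistic_start(model: HierLogitModel) -> np.ndarray:
    import statsmodels.api as sm

    try:
        res = sm.GLM(model.z, model.X, family=sm.families.Binomial()).fit(
            maxiter=50
        )
        beta = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(beta)):
            return beta
    except Exception:
        pass
    return np.zeros(model.n_coef)


def fit_laplace(model: HierLogitModel, start: np.ndarray | None = None) -> GLMMFit:
    """Maximum-likelihood fit via the Laplace-approximated marginal
    likelihood, maximized by BFGS over (beta, log sigma_u).

    Standard errors come from the observed information (numerical Hessian
    of the Laplace objective at the optimum).  A vanishing random-effect
    variance is reported as converged-at-boundary rather than an error.
    """
    _check_model(model)
    p = model.n_coef
    beta0 = _pooled_logistic_start(model) if start is None else np.asarray(start)
    theta0 = np.append(beta0, 0.0)  # log sigma = 0
    state = {"u": None}

    def negloglik(theta):
        ll, grad, u = laplace_loglik_and_grad(
            model, theta[:p], float(theta[p]), u0=state["u"]
        )
        state["u"] = u
        return -ll, -grad

    res = optimize.minimize(
        negloglik, theta0, jac=True, method="BFGS",
        options={"gtol": 1e-6, "maxiter": 500},
    )
    beta = res.x[:p]
    log_sigma = float(res.x[p])
    sigma_u = float(np.exp(log_sigma))
    boundary = log_sigma < -6.0
    ll, _, u_hat = laplace_loglik_and_grad(model, beta, log_sigma)

    # observed information from central differences of the analytic gradient
    h = 1e-5
    hess = np.empty((p + 1, p + 1))
    for k in range(p + 1):
        tp = res.x.copy()
        tm = res.x.copy()
        tp[k] += h
        tm[k] -= h
        _, gp, _ = laplace_loglik_and_grad(model, tp[:p], float(tp[p]))
        _, gm, _ = laplace_loglik_and_grad(model, tm[:p], float(tm[p]))
        hess[k] = -(gp - gm) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
        se_beta = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, np.inf))
        se_ok = np.all(np.isfinite(se_beta)) and np.all(se_beta > 0)
    except np.linalg.LinAlgError:
        se_beta = np.full(p, np.nan)
        se_ok = False

    converged = bool(res.success or np.linalg.norm(res.jac) < 1e-3)
    if not converged and not boundary:
        raise RuntimeError(
            f"Laplace fit did not converge: {res.message}; "
            f"|grad| = {np.linalg.norm(res.jac):.3e} at {res.x}"
        )
    if not se_ok:
        se_beta = np.full(p, np.nan)
    return GLMMFit(
        beta=beta, sigma_u=sigma_u, se_beta=se_beta, loglik=float(ll),
        converged=converged, n_iter=int(res.nit), method="laplace",
        coef_names=model.coef_names, boundary=boundary, u_hat=u_hat,
    )


def marginal_loglik_quadrature(
    model: HierLogitModel, beta: np.ndarray, sigma_u: float, n_nodes: int = 50
) -> float:
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

    Nodes are centered at each group's random-effect mode and scaled by
    the curvature there, so a single node reproduces the Laplace
    approximation exactly; increasing the node count refines toward the
    exact marginal likelihood.  ``sigma_u = 0`` collapses to the plain
    pooled logistic log-likelihood.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if sigma_u < 0:
        raise ValueError("sigma_u must be non-negative")
    beta = np.asarray(beta, dtype=float)
    Xb = model.X @ beta
    if sigma_u == 0.0:
        return float(model.z @ Xb - np.logaddexp(0.0, Xb).sum())
    sigma2 = sigma_u**2
    starts0 = model.track_index.starts0
    row_group = model.track_index.row_groups()
    u, _, _, W = _find_modes(model, beta, sigma2)
    H = W + 1.0 / sigma2
    s = 1.0 / np.sqrt(H)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    # u-values per (group, node)
    U = u[:, None] + np.sqrt(2.0) * s[:, None] * nodes[None, :]
    # g_j(u) = sum_i z_i eta_i - softplus(eta_i) with eta = Xb + u
    terms = np.empty((model.n_groups, n_nodes))
    for q in range(n_nodes):
        eta = Xb + U[:, q][row_group]
        ll_rows = model.z * eta - np.logaddexp(0.0, eta)
        terms[:, q] = np.add.reduceat(ll_rows, starts0)
    log_integrand = (
        terms
        - 0.5 * U**2 / sigma2
        - 0.5 * np.log(2 * np.pi * sigma2)
        + nodes[None, :] ** 2
        + np.log(weights[None, :])
        + 0.5 * np.log(2.0)
        + np.log(s)[:, None]
    )
    return float(logsumexp(log_integrand, axis=1).sum())


def fit_pql(
    model: HierLogitModel, max_iter: int = 100, tol: float = 1e-6
) -> GLMMFit:
    """Penalized quasi-likelihood fit by iterated working-response LMM.

    Each cycle linearizes the logit link around the current (beta, u) to
    form a working response and weights, then fits the one-variance-
    component weighted linear mixed model (random-intercept covariance
    handled per group in closed form; sigma_u estimated by REML of the
    working model).  Converges on max |delta beta| < ``tol``.  No true
    log-likelihood exists for PQL; ``loglik`` is None and the standard
    errors come from the final weighted LMM, documented as approximate.
    """
    _check_model(model)
    starts0 = model.track_index.starts0
    row_group = model.track_index.row_groups()
    X, z = model.X, model.z.astype(float)
    p = model.n_coef

    beta = _pooled_logistic_start(model)
    u = np.zeros(model.n_groups)
    sigma2 = 1.0

    def lmm_profile(log_sigma2, ystar, wvec):
        """REML criterion pieces and GLS solution for fixed sigma_u^2."""
        s2 = float(np.exp(log_sigma2))
        sw = np.add.reduceat(wvec, starts0)
        shrink = s2 / (1.0 + s2 * sw)  # Woodbury factor per group
        WX = wvec[:, None] * X
        Wy = wvec * ystar
        gX = np.add.reduceat(WX, starts0, axis=0)
        gy = np.add.reduceat(Wy, starts0)
        XtVX = X.T @ WX - gX.T @ (shrink[:, None] * gX)
        XtVy = X.T @ Wy - gX.T @ (shrink * gy)
        bhat = np.linalg.solve(XtVX, XtVy)
        r = ystar - X @ bhat
        Wr = wvec * r
        gr = np.add.reduceat(Wr, starts0)
        rVr = float(r @ Wr - gr @ (shrink * gr))
        logdetV = float(-np.sum(np.log(wvec)) + np.sum(np.log1p(s2 * sw)))
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        reml = 0.5 * (rVr + logdetV + logdetXtVX)
        uhat = shrink * gr
        return reml, bhat, uhat, XtVX

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta + u[row_group]
        mu = expit(eta)
        wvec = np.clip(mu * (1.0 - mu), 1e-10, None)
        ystar = eta + (z - mu) / wvec

        opt = optimize.minimize_scalar(
            lambda ls2: lmm_profile(ls2, ystar, wvec)[0],
            bounds=(-12.0, 8.0), method="bounded",
            options={"xatol": 1e-8},
        )
        _, beta_new, u_new, XtVX = lmm_profile(opt.x, ystar, wvec)
        sigma2 = float(np.exp(opt.x))
        delta = float(np.max(np.abs(beta_new - beta)))
        beta, u = beta_new, u_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"PQL did not converge in {max_iter} iterations "
            f"(last max |delta beta| = {delta:.3e})"
        )
    try:
        se_beta = np.sqrt(np.diag(np.linalg.inv(XtVX)))
    except np.linalg.LinAlgError:
        se_beta = np.full(p, np.nan)
    return GLMMFit(
        beta=beta, sigma_u=float(np.sqrt(sigma2)), se_beta=se_beta,
        loglik=None, converged=True, n_iter=it, method="pql",
        coef_names=model.coef_names, boundary=sigma2 < 1e-10, u_hat=u,
    )
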