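"""Hierarchical Bernoulli-logit movement model and its MCMC sampler.

The model: for row i belonging to individual j = g(i),

    z_i ~ Bernoulli(mu_i),   logit(mu_i) = beta . x_i + u_j,
    u_j ~ Normal(0, 1/tau),  beta_k ~ Normal(0, 10),  tau ~ Gamma(0.1, 0.01)

where the design row x_i is (1, Spring, Summer, Winter, L, Sex, MEI) with
Fall absorbed into the intercept, u_j is the individual's random intercept,
and s = 1/sqrt(tau) is the process (individual-variation) standard
deviation.  The Gamma(0.1, 0.01) prior on the precision tau has mean 10
and variance 1000; the Normal coefficient priors have variance 10
(precision 0.1).

Sampling is Metropolis-within-Gibbs: an adaptive joint random-walk
Metropolis update for beta (empirical-covariance proposal after a warm
start), independent adaptive scalar random-walk updates for every u_j
(vectorized — each u_j's conditional involves only its own rows), an
exact conjugate Gibbs draw for tau, and likelihood-invariant translation
moves that shift a group-constant coefficient against the random
intercepts to decorrelate, e.g., the intercept from the mean of u.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .preprocess import TrackIndex, build_track_index

__all__ = [
    "PriorSpec",
    "HierLogitModel",
    "MCMCConfig",
    "PosteriorDraws",
    "log_unnormalized_posterior",
    "sample_posterior",
    "sample_tau_conditional",
    "gelman_rubin",
    "summarize_posterior",
    "run_priors_only",
    "prior_influence_check",
]

COEF_NAMES = ("B0", "B1", "B2", "B3", "B4", "B5", "B6")
DESIGN_COLUMNS = ("Spring", "Summer", "Winter", "L", "Sex", "MEI_Index")


@dataclass(frozen=True)
class PriorSpec:
    """Normal priors on the coefficients, Gamma prior on the precision tau.

    Defaults are the vague choices used throughout: Normal(0, variance 10)
    for every beta (precision 0.1) and Gamma(shape 0.1, rate 0.01) for tau,
    i.e. prior mean 10 and prior variance 1000 for the precision of the
    individual random intercepts.
    """

    beta_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    beta_var: np.ndarray = field(default=None)  # type: ignore[assignment]
    tau_shape: float = 0.1
    tau_rate: float = 0.01
    n_coef: int = 7

    def __post_init__(self) -> None:
        bm = self.beta_mean
        bv = self.beta_var
        bm = np.zeros(self.n_coef) if bm is None else np.broadcast_to(
            np.asarray(bm, dtype=float), (self.n_coef,)
        ).copy()
        bv = np.full(self.n_coef, 10.0) if bv is None else np.broadcast_to(
            np.asarray(bv, dtype=float), (self.n_coef,)
        ).copy()
        if np.any(bv <= 0):
            raise ValueError("prior variances must be positive")
        if self.tau_shape <= 0 or self.tau_rate <= 0:
            raise ValueError("gamma shape and rate must be positive")
        object.__setattr__(self, "beta_mean", bm)
        object.__setattr__(self, "beta_var", bv)

    @property
    def beta_precision(self) -> np.ndarray:
        return 1.0 / self.beta_var

    @property
    def tau_prior_mean(self) -> float:
        return self.tau_shape / self.tau_rate

    @property
    def tau_prior_var(self) -> float:
        return self.tau_shape / self.tau_rate**2

    def expand(self, which, factor: float = 10.0) -> "PriorSpec":
        """Return a copy with the variance of the named/indexed coefficients
        multiplied by ``factor`` (the vague-prior broadening step)."""
        bv = self.beta_var.copy()
        for w in which:
            idx = COEF_NAMES.index(w) if isinstance(w, str) else int(w)
            bv[idx] *= factor
        return replace(self, beta_var=bv)


@dataclass(frozen=True)
class HierLogitModel:
    """Design matrix, response and track index of the hierarchical model.

    ``X`` has a leading column of ones (intercept, Fall as the reference
    season) followed by Spring, Summer, Winter, L, Sex, MEI.
    """

    X: np.ndarray
    z: np.ndarray
    track_index: TrackIndex
    coef_names: tuple = COEF_NAMES

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        z = np.asarray(self.z, dtype=np.int64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "z", z)
        if X.ndim != 2 or X.shape[0] != z.shape[0]:
            raise ValueError("design matrix and response shapes disagree")
        if X.shape[0] != self.track_index.n_rows:
            raise ValueError("track index does not cover the table rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix contains non-finite values")
        if not np.isin(z, (0, 1)).all():
            raise ValueError("response must be binary 0/1")

    @classmethod
    def from_analysis_table(cls, table: pd.DataFrame, group_col: str = "ptt") -> "HierLogitModel":
        idx = build_track_index(table, group_col)
        sex = table["sex"]
        sex_num = (
            sex.map({"F": 0.0, "M": 1.0}).to_numpy()
            if sex.dtype == object or str(sex.dtype).startswith("category")
            else sex.to_numpy(dtype=float)
        )
        cols = [np.ones(len(table))]
        for c in DESIGN_COLUMNS:
            cols.append(sex_num if c == "Sex" else table[c].to_numpy(dtype=float))
        X = np.column_stack(cols)
        return cls(X, table["z"].to_numpy(dtype=np.int64), idx)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return self.track_index.n_groups

    def group_constant_columns(self) -> list[tuple[int, np.ndarray]]:
        """Design columns constant within every group, as (column index,
        per-group value) pairs.  These admit likelihood-invariant
        translation moves against the random intercepts."""
        starts = self.track_index.starts0
        counts = self.track_index.counts
        out = []
        for k in range(self.n_coef):
            col = self.X[:, k]
            first = col[starts]
            if np.all(np.repeat(first, counts) == col):
                out.append((k, first.astype(float)))
        return out


_PRESETS = {
    "desk": dict(n_chains=4, n_adapt=2000, n_burn=2000, n_iter=20000, thin=10),
    "paper": dict(n_chains=4, n_adapt=100000, n_burn=10000, n_iter=500000, thin=10),
}


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 4
    n_adapt: int = 2000
    n_burn: int = 2000
    n_iter: int = 20000
    thin: int = 10
    seed: int = 0
    preset: str = "desk"

    def __post_init__(self) -> None:
        for f in ("n_chains", "n_adapt", "n_burn", "n_iter", "thin"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    @classmethod
    def from_preset(cls, name: str, seed: int = 0) -> "MCMCConfig":
        if name not in _PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
        return cls(seed=seed, preset=name, **_PRESETS[name])

    @property
    def n_kept(self) -> int:
        return self.n_iter // self.thin


@dataclass
class PosteriorDraws:
    """Per-chain MCMC output: arrays of shape (chains, kept, #params)."""

    beta: np.ndarray
    u: np.ndarray
    s: np.ndarray  # process sd, = 1/sqrt(tau), shape (chains, kept)
    coef_names: tuple
    acceptance: dict
    config: MCMCConfig
    warnings: list = field(default_factory=list)

    @property
    def tau(self) -> np.ndarray:
        return 1.0 / self.s**2

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    def parameter_names(self) -> list[str]:
        return list(self.coef_names) + ["s"] + [
            f"u[{j + 1}]" for j in range(self.u.shape[2])
        ]

    def stacked(self, include_u: bool = True) -> tuple[np.ndarray, list[str]]:
        """(chains, kept, P) array over beta, s and optionally the u's."""
        parts = [self.beta, self.s[..., None]]
        names = list(self.coef_names) + ["s"]
        if include_u:
            parts.append(self.u)
            names += [f"u[{j + 1}]" for j in range(self.u.shape[2])]
        return np.concatenate(parts, axis=2), names

    def pooled(self, name: str) -> np.ndarray:
        arr, names = self.stacked()
        return arr[:, :, names.index(name)].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        arr, names = self.stacked()
        c, k, p = arr.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(1, c + 1), k * p),
                "iteration": np.tile(np.repeat(np.arange(1, k + 1), p), c),
                "parameter": np.tile(names, c * k),
                "value": arr.reshape(-1),
            }
        )


def _bernoulli_loglik(z: np.ndarray, eta: np.ndarray) -> float:
    # log p = z*eta - log(1 + exp(eta)), stable via logaddexp
    return float(z @ eta - np.logaddexp(0.0, eta).sum())


def log_unnormalized_posterior(
    model: HierLogitModel, beta: np.ndarray, u: np.ndarray, tau: float,
    priors: PriorSpec,
) -> float:
    """Log joint density (up to a constant) of data and parameters.

    Bernoulli-logit likelihood plus Normal priors on beta, Normal(0, 1/tau)
    on each u_j, and the Gamma prior on tau; computed with numerically
    stable log1p/softplus forms.
    """
    beta = np.asarray(beta, dtype=float)
    u = np.asarray(u, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(u))):
        raise ValueError("parameters must be finite")
    N = model.n_groups
    lp = 0.0
    if model.n_rows:
        eta = model.X @ beta + np.repeat(u, model.track_index.counts)
        lp += _bernoulli_loglik(model.z, eta)
    lp += float(
        -0.5 * np.sum((beta - priors.beta_mean) ** 2 / priors.beta_var)
        - 0.5 * np.sum(np.log(2 * np.pi * priors.beta_var))
    )
    lp += float(
        0.5 * N * np.log(tau / (2 * np.pi)) - 0.5 * tau * np.sum(u**2)
    )
    lp += float(stats.gamma.logpdf(tau, priors.tau_shape, scale=1.0 / priors.tau_rate))
    return lp


def sample_tau_conditional(
    u: np.ndarray, priors: PriorSpec, rng: np.random.Generator, size: int | None = None
):
    """Exact conjugate Gibbs draw of the random-intercept precision:
    tau | u ~ Gamma(shape + N/2, rate + sum(u^2)/2)."""
    u = np.asarray(u, dtype=float)
    shape = priors.tau_shape + 0.5 * u.size
    rate = priors.tau_rate + 0.5 * float(u @ u)
    return rng.gamma(shape, 1.0 / rate, size=size)


# Number of beta random-walk sub-steps per Gibbs scan.  The beta block is
# the cheapest update (one rank-1 linear-predictor shift) but carries the
# slowest-mixing directions, so repeating it raises effective sample size
# at modest cost.
_BETA_SUBSTEPS = 5


def _run_chain(
    model: HierLogitModel, priors: PriorSpec, config: MCMCConfig,
    rng: np.random.Generator,
):
    X, z = model.X, model.z
    p = model.n_coef
    N = model.n_groups
    starts0 = model.track_index.starts0
    counts = model.track_index.counts
    row_group = model.track_index.row_groups()

    bm, bv = priors.beta_mean, priors.beta_var

    beta = rng.uniform(0.0, 1.0, size=p)
    u = np.zeros(N)
    tau = float(rng.gamma(priors.tau_shape, 1.0 / priors.tau_rate))
    tau = max(tau, 1e-8)

    eta = X @ beta + u[row_group]
    ll = _bernoulli_loglik(z, eta)

    # adaptation state
    beta_scale = 0.1 / np.sqrt(p)
    chol = np.eye(p)
    u_scales = np.full(N, 0.5)
    const_cols = model.group_constant_columns()
    trans_scales = np.full(len(const_cols), 0.5)
    adapt_hist = np.empty((min(config.n_adapt, 4000), p))
    hist_n = 0
    target = 0.30

    n_total = config.n_adapt + config.n_burn + config.n_iter
    kept = config.n_kept
    out_beta = np.empty((kept, p))
    out_u = np.empty((kept, N))
    out_s = np.empty(kept)
    k_out = 0

    acc_beta = np.zeros(2)  # accepted, proposed (post-adaptation)
    acc_u = np.zeros(2)
    acc_trans = np.zeros(2)

    for t in range(n_total):
        adapting = t < config.n_adapt

        # --- joint RW Metropolis on beta (several cheap sub-steps per scan
        # to push the effective sample size of the slowest slopes up) ---
        for _ in range(_BETA_SUBSTEPS):
            step = beta_scale * (chol @ rng.standard_normal(p))
            beta_prop = beta + step
            eta_prop = eta + X @ step
            ll_prop = _bernoulli_loglik(z, eta_prop)
            dprior = -0.5 * np.sum((beta_prop - bm) ** 2 / bv) + 0.5 * np.sum(
                (beta - bm) ** 2 / bv
            )
            accept = np.log(rng.uniform()) < ll_prop - ll + dprior
            if accept:
                beta, eta, ll = beta_prop, eta_prop, ll_prop
            if adapting:
                gamma = (t + 1) ** -0.6
                beta_scale *= np.exp(gamma * ((1.0 if accept else 0.0) - target))
            else:
                acc_beta += (1.0 if accept else 0.0, 1.0)
        if adapting:
            if hist_n < adapt_hist.shape[0]:
                adapt_hist[hist_n] = beta
                hist_n += 1
            if t == config.n_adapt // 2 and hist_n > 10 * p:
                cov = np.cov(adapt_hist[: hist_n].T) + 1e-8 * np.eye(p)
                chol = np.linalg.cholesky(cov)
                beta_scale = 2.38 / np.sqrt(p)

        # --- translation moves: shift a group-constant coefficient against u
        # (likelihood invariant; only the priors change) ---
        for m, (k, v) in enumerate(const_cols):
            delta = trans_scales[m] * rng.standard_normal()
            bk_new = beta[k] + delta
            u_new = u - delta * v
            dlp = (
                -0.5 * (bk_new - bm[k]) ** 2 / bv[k]
                + 0.5 * (beta[k] - bm[k]) ** 2 / bv[k]
                - 0.5 * tau * float(u_new @ u_new - u @ u)
            )
            acc = np.log(rng.uniform()) < dlp
            if acc:
                beta = beta.copy()
                beta[k] = bk_new
                u = u_new
            if adapting:
                gamma = (t + 1) ** -0.6
                trans_scales[m] *= np.exp(gamma * ((1.0 if acc else 0.0) - target))
            else:
                acc_trans += (1.0 if acc else 0.0, 1.0)

        # --- vectorized scalar RW Metropolis on each u_j ---
        delta = u_scales * rng.standard_normal(N)
        eta_prop = eta + delta[row_group]
        ll_rows_old = z * eta - np.logaddexp(0.0, eta)
        ll_rows_new = z * eta_prop - np.logaddexp(0.0, eta_prop)
        dll = np.add.reduceat(ll_rows_new - ll_rows_old, starts0)
        u_prop = u + delta
        dlp = dll - 0.5 * tau * (u_prop**2 - u**2)
        acc = np.log(rng.uniform(size=N)) < dlp
        if acc.any():
            u = np.where(acc, u_prop, u)
            eta = eta + np.where(acc, delta, 0.0)[row_group]
            ll = _bernoulli_loglik(z, eta)
        if adapting:
            gamma = (t + 1) ** -0.6
            u_scales *= np.exp(gamma * (acc.astype(float) - 0.35))
        else:
            acc_u += (float(acc.sum()), float(N))

        # --- conjugate Gibbs draw of tau ---
        tau = float(sample_tau_conditional(u, priors, rng))

        # periodic recomputation guards against float drift in eta
        if t % 5000 == 4999:
            eta = X @ beta + u[row_group]
            ll = _bernoulli_loglik(z, eta)

        post = t - config.n_adapt - config.n_burn
        if post >= 0 and (post + 1) % config.thin == 0:
            out_beta[k_out] = beta
            out_u[k_out] = u
            out_s[k_out] = 1.0 / np.sqrt(tau)
            k_out += 1

    rates = {
        "beta": acc_beta[0] / max(acc_beta[1], 1.0),
        "u": acc_u[0] / max(acc_u[1], 1.0),
        "translation": acc_trans[0] / max(acc_trans[1], 1.0),
    }
    return out_beta[:k_out], out_u[:k_out], out_s[:k_out], rates


def sample_posterior(
    model: HierLogitModel, priors: PriorSpec, config: MCMCConfig
) -> PosteriorDraws:
    """Run ``config.n_chains`` independent chains of the Metropolis-within-
    Gibbs sampler and collect thinned post-burn-in draws.

    Each chain initializes every beta from Uniform(0, 1), the random
    intercepts at zero, and tau from its Gamma prior.  Proposal scales are
    adapted only during the first ``n_adapt`` iterations (then frozen, so
    the kept draws come from a fixed-kernel Markov chain); ``n_burn``
    further iterations are discarded before monitoring starts.  Fully
    reproducible from ``config.seed``.
    """
    if model.n_rows == 0:
        raise ValueError(
            "empty model; use run_priors_only for data-free sampling"
        )
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    betas, us, ss, rates_all = [], [], [], []
    warns: list[str] = []
    for c, ss_child in enumerate(children):
        b, u, s, rates = _run_chain(
            model, priors, config, np.random.Generator(np.random.PCG64(ss_child))
        )
        betas.append(b)
        us.append(u)
        ss.append(s)
        rates_all.append(rates)
        for block, r in rates.items():
            if not (0.05 <= r <= 0.95):
                warns.append(
                    f"chain {c + 1}: acceptance rate {r:.3f} for block "
                    f"{block!r} outside [0.05, 0.95] after adaptation"
                )
    return PosteriorDraws(
        beta=np.stack(betas),
        u=np.stack(us),
        s=np.stack(ss),
        coef_names=model.coef_names,
        acceptance={
            k: float(np.mean([r[k] for r in rates_all])) for k in rates_all[0]
        },
        config=config,
        warnings=warns,
    )


def gelman_rubin(draws, parameters: list[str] | None = None) -> dict[str, float]:
    """Classic (non-split) multi-chain potential scale reduction factor.

    For each parameter, with m chains of n kept draws, W = mean within-chain
    variance, B/n = variance of the chain means; R-hat is
    sqrt(((n-1)/n * W + B/n) / W).  Requires at least two chains.
    """
    if isinstance(draws, PosteriorDraws):
        arr, names = draws.stacked()
    else:
        arr = np.asarray(draws, dtype=float)
        if arr.ndim == 2:
            arr = arr[..., None]
        names = [f"p{i}" for i in range(arr.shape[2])]
    m, n = arr.shape[0], arr.shape[1]
    if m < 2:
        raise ValueError("Gelman-Rubin diagnostic requires >= 2 chains")
    if n < 10:
        raise ValueError("need >= 10 kept iterations per chain")
    out = {}
    for k, name in enumerate(names):
        if parameters is not None and name not in parameters:
            continue
        x = arr[:, :, k]
        W = float(np.mean(np.var(x, axis=1, ddof=1)))
        B_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
        if W == 0.0:
            out[name] = 1.0
            continue
        var_plus = (n - 1) / n * W + B_over_n
        out[name] = float(np.sqrt(var_plus / W))
    return out


def split_rhat(draws) -> dict[str, float]:
    """Split-chain variant: each chain halved before the classic formula."""
    if isinstance(draws, PosteriorDraws):
        arr, names = draws.stacked()
    else:
        arr = np.asarray(draws, dtype=float)
        names = None
    n = arr.shape[1] // 2
    split = np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)
    res = gelman_rubin(split)
    if names is not None:
        res = {names[i]: v for i, (_, v) in enumerate(res.items())}
    return res


def summarize_posterior(draws: PosteriorDraws, include_u: bool = True) -> pd.DataFrame:
    """Pooled-chain mean, sd and equal-tailed 95% interval per parameter."""
    arr, names = draws.stacked(include_u=include_u)
    flat = arr.reshape(-1, arr.shape[2])
    if flat.shape[0] == 0:
        raise ValueError("no draws to summarize")
    return pd.DataFrame(
        {
            "parameter": names,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else 0.0,
            "q2.5": np.quantile(flat, 0.025, axis=0),
            "q97.5": np.quantile(flat, 0.975, axis=0),
        }
    )


def run_priors_only(
    model: HierLogitModel, priors: PriorSpec, config: MCMCConfig,
    mode: str = "prior_predictive",
) -> PosteriorDraws:
    """Data-free counterpart used to check that the priors are vague.

    ``prior_predictive`` drops the likelihood entirely: beta, tau and the
    u_j are sampled independently from the prior hierarchy (the design
    matrix is never consulted).  ``paper_literal`` instead keeps the
    response but replaces every covariate with 1, so the linear predictor
    is sum(beta) + u_j; the individual betas are then informed only through
    their sum.
    """
    if mode == "prior_predictive":
        rng_children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        kept = config.n_kept
        p, N = model.n_coef, model.n_groups
        betas, us, ss = [], [], []
        for child in rng_children:
            rng = np.random.Generator(np.random.PCG64(child))
            tau = rng.gamma(priors.tau_shape, 1.0 / priors.tau_rate, size=kept)
            s = 1.0 / np.sqrt(tau)
            b = priors.beta_mean + np.sqrt(priors.beta_var) * rng.standard_normal(
                (kept, p)
            )
            u = s[:, None] * rng.standard_normal((kept, N))
            betas.append(b)
            us.append(u)
            ss.append(s)
        return PosteriorDraws(
            beta=np.stack(betas),
            u=np.stack(us),
            s=np.stack(ss),
            coef_names=model.coef_names,
            acceptance={"beta": 1.0, "u": 1.0, "translation": 1.0},
            config=config,
        )
    if mode == "paper_literal":
        literal = HierLogitModel(
            np.ones_like(model.X), model.z, model.track_index, model.coef_names
        )
        return sample_posterior(literal, priors, config)
    raise ValueError(f"unknown priors-only mode {mode!r}")


def overlap_coefficient(x: np.ndarray, y: np.ndarray, gridsize: int = 512) -> float:
    """Overlapping coefficient of two samples' kernel density estimates:
    integral of min(f, g) on a shared grid (1 = identical distributions)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    pad = 0.1 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, gridsize)
    fx = stats.gaussian_kde(x)(grid)
    fy = stats.gaussian_kde(y)(grid)
    return float(np.trapezoid(np.minimum(fx, fy), grid))


def prior_influence_check(
    data_draws: PosteriorDraws,
    prior_only_draws: PosteriorDraws,
    priors: PriorSpec,
    threshold: float = 0.35,
    expansion: float = 10.0,
) -> pd.DataFrame:
    """Flag coefficients whose posterior visibly overlaps the priors-only
    distribution — evidence the prior is informative rather than vague.

    For each beta the overlapping coefficient of the two kernel densities
    is computed; overlap above ``threshold`` flags the prior, and a
    broadened variance (current x ``expansion``) is proposed for the next
    round.  Truly vague priors leave the priors-only density flat and wide
    where the posterior is concentrated, giving low overlap.
    """
    if data_draws.coef_names != prior_only_draws.coef_names:
        raise ValueError("draw sets cover different coefficients")
    rows = []
    for k, name in enumerate(data_draws.coef_names):
        ovl = overlap_coefficient(
            data_draws.beta[:, :, k].reshape(-1),
            prior_only_draws.beta[:, :, k].reshape(-1),
        )
        flagged = ovl > threshold
        rows.append(
            {
                "parameter": name,
                "overlap": ovl,
                "flagged": flagged,
                "current_variance": priors.beta_var[k],
                "proposed_variance": priors.beta_var[k]
                * (expansion if flagged else 1.0),
            }
        )
    return pd.DataFrame(rows)
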