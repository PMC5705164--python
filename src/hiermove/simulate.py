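"""Synthetic telemetry-like grouped binary data with known parameters.

The generator emulates the structure of a multi-year shark SLRT dataset:
34 tracked individuals with on the order of 278 daily-filtered locations
each, a binary east/west response generated from the hierarchical
logit-linear model, one-hot meteorological seasons from real calendar
dates, one z-scored body length and one sex per individual, and shared
slowly varying environmental index series (standardized AR(1) processes
on a daily grid) sampled at each location's date.  The ground-truth
coefficients, random-intercept standard deviation and realized
per-individual intercepts are recorded alongside the table so the full
simulate -> fit -> recover loop can be scored.

Default truth beta = (-1.0, 0.75, -1.0, 0.0, 1.0, 0.1, -0.5) for
(intercept, Spring, Summer, Winter, L, Sex, MEI) with sigma_u = 2.5 —
fixture values chosen to echo the magnitudes such telemetry analyses
report, not estimates from any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .hierbayes import COEF_NAMES, HierLogitModel
from .preprocess import build_track_index, encode_season, zscore

__all__ = ["SimConfig", "SimulatedDataset", "simulate_covariates",
           "simulate_dataset", "recovery_study"]

DEFAULT_TRUTH_BETA = (-1.0, 0.75, -1.0, 0.0, 1.0, 0.1, -0.5)
DEFAULT_SIGMA_U = 2.5


@dataclass(frozen=True)
class SimConfig:
    """Ground truth and covariate-process settings for one simulation.

    ``beta`` is ordered (intercept, Spring, Summer, Winter, L, Sex, MEI);
    Fall is the reference season.  Per-individual location counts are
    Poisson around ``mean_locations`` truncated below at ``min_locations``.
    ``index_ar_coef`` governs the AR(1) persistence of the shared daily
    environmental index (standardized to unit stationary sd).
    """

    n_individuals: int = 34
    mean_locations: float = 278.0
    min_locations: int = 30
    beta: tuple = DEFAULT_TRUTH_BETA
    sigma_u: float = DEFAULT_SIGMA_U
    start_year: int = 2004
    end_year: int = 2015
    track_span_days: int = 450
    length_mean_cm: float = 200.0
    length_sd_cm: float = 25.0
    male_fraction: float = 0.5
    index_ar_coef: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.mean_locations < 1:
            raise ValueError("mean_locations must be >= 1")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")
        if len(self.beta) != len(COEF_NAMES):
            raise ValueError(f"beta must have {len(COEF_NAMES)} entries")


@dataclass
class SimulatedDataset:
    """Analysis table plus the truth that generated it."""

    table: pd.DataFrame
    truth: dict

    def model(self) -> HierLogitModel:
        return HierLogitModel.from_analysis_table(self.table)


def _ar1_series(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) with unit marginal variance, then re-standardized."""
    innov_sd = np.sqrt(1.0 - phi**2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    eps = innov_sd * rng.standard_normal(n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    sd = x.std(ddof=1)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_covariates(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Covariate table without the response: dated per-individual location
    runs, seasons, constant per-individual length (z-scored across
    individuals) and sex, and shared environmental index series.

    Extra columns mimicking a raw exploratory table (NPGO/PDO indices,
    moon phase, SST, chlorophyll) are included so the variable-screening
    stage has realistic non-informative candidates to reject.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cal_start = pd.Timestamp(f"{config.start_year}-01-01")
    cal_end = pd.Timestamp(f"{config.end_year}-12-31")
    calendar = pd.date_range(cal_start, cal_end, freq="D")
    n_days = len(calendar)
    mei = _ar1_series(n_days, config.index_ar_coef, rng)
    npgo = _ar1_series(n_days, config.index_ar_coef, rng)
    pdo = _ar1_series(n_days, config.index_ar_coef, rng)
    doy = calendar.dayofyear.to_numpy()
    sst_daily = 16.0 + 4.0 * np.sin(2 * np.pi * (doy - 120) / 365.25)

    counts = rng.poisson(config.mean_locations, size=config.n_individuals)
    counts = np.maximum(counts, config.min_locations)
    lengths_cm = config.length_mean_cm + config.length_sd_cm * rng.standard_normal(
        config.n_individuals
    )
    L, _ = zscore(lengths_cm, "length")
    sexes = np.where(rng.uniform(size=config.n_individuals) < config.male_fraction,
                     "M", "F")

    frames = []
    span = config.track_span_days
    for j in range(config.n_individuals):
        m = int(counts[j])
        window = max(span, m)
        start_max = n_days - window - 1
        t0 = int(rng.integers(0, max(start_max, 1)))
        days = t0 + np.sort(
            rng.choice(window, size=min(m, window), replace=False)
        )
        dates = calendar[days]
        df = pd.DataFrame(
            {
                "ptt": 40000 + j,
                "sex": sexes[j],
                "date": dates,
                "L": L[j],
                "MEI_Index": mei[days],
                "NPGO_Index": npgo[days],
                "PDO_Index": pdo[days],
                "Moon": 0.5 * (1 - np.cos(2 * np.pi * days / 29.53)),
                "sst": sst_daily[days] + 0.8 * rng.standard_normal(len(days)),
                "chl": np.exp(-1.0 + 0.5 * rng.standard_normal(len(days))),
            }
        )
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table = pd.concat([table, encode_season(table["date"])], axis=1)
    return table


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw one grouped binary dataset from the hierarchical model.

    u_j ~ Normal(0, sigma_u^2) per individual; each row's response is
    Bernoulli(logistic(beta . x + u_j)).  The realized u_j and the
    generating parameters are recorded in ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    table = simulate_covariates(config, rng)
    u = config.sigma_u * rng.standard_normal(config.n_individuals)
    beta = np.asarray(config.beta, dtype=float)

    idx = build_track_index(table)
    sex_num = table["sex"].map({"F": 0.0, "M": 1.0}).to_numpy()
    X = np.column_stack(
        [
            np.ones(len(table)),
            table["Spring"].to_numpy(float),
            table["Summer"].to_numpy(float),
            table["Winter"].to_numpy(float),
            table["L"].to_numpy(float),
            sex_num,
            table["MEI_Index"].to_numpy(float),
        ]
    )
    eta = X @ beta + np.repeat(u, idx.counts)
    table = table.copy()
    table["z"] = (rng.uniform(size=len(table)) < expit(eta)).astype(np.int64)
    cols = ["ptt", "sex", "Spring", "Summer", "Fall", "Winter", "L", "z",
            "NPGO_Index", "PDO_Index", "MEI_Index", "Moon", "sst", "chl",
            "date"]
    table = table[cols]
    truth = {
        "beta": beta.copy(),
        "coef_names": COEF_NAMES,
        "sigma_u": float(config.sigma_u),
        "u": u.copy(),
        "seed": config.seed,
    }
    return SimulatedDataset(table=table, truth=truth)


def recovery_study(
    config: SimConfig,
    n_datasets: int,
    fitter,
    base_seed: int | None = None,
    max_failure_rate: float = 0.10,
) -> dict:
    """Simulate ``n_datasets`` datasets, fit each, and score recovery.

    ``fitter(dataset) -> DataFrame`` must return columns
    (parameter, estimate, lower, upper) covering the beta coefficients.
    Returns a dict with a per-parameter report (bias, RMSE, 95%-interval
    coverage) and the raw estimates for density plots.  More than
    ``max_failure_rate`` fit failures aborts the study.
    """
    if n_datasets < 2:
        raise ValueError("n_datasets must be >= 2")
    import dataclasses

    seeds = np.random.SeedSequence(
        config.seed if base_seed is None else base_seed
    ).generate_state(n_datasets) % (2**31 - 1)
    truth_beta = np.asarray(config.beta, dtype=float)
    rows = []
    failures = []
    for d in range(n_datasets):
        ds = simulate_dataset(dataclasses.replace(config, seed=int(seeds[d])))
        try:
            est = fitter(ds)
        except Exception as exc:  # noqa: BLE001 - recorded, rate-checked below
            failures.append((d, repr(exc)))
            continue
        est = est.set_index("parameter")
        for k, name in enumerate(COEF_NAMES):
            rows.append(
                {
                    "dataset": d,
                    "parameter": name,
                    "truth": truth_beta[k],
                    "estimate": float(est.loc[name, "estimate"]),
                    "lower": float(est.loc[name, "lower"]),
                    "upper": float(est.loc[name, "upper"]),
                }
            )
    if len(failures) > max_failure_rate * n_datasets:
        raise RuntimeError(
            f"{len(failures)}/{n_datasets} fits failed; first: {failures[0]}"
        )
    estimates = pd.DataFrame(rows)
    err = estimates["estimate"] - estimates["truth"]
    covered = (estimates["lower"] <= estimates["truth"]) & (
        estimates["truth"] <= estimates["upper"]
    )
    estimates = estimates.assign(error=err, covered=covered)
    report = (
        estimates.groupby("parameter", sort=False)
        .agg(
            truth=("truth", "first"),
            bias=("error", "mean"),
            rmse=("error", lambda e: float(np.sqrt(np.mean(e**2)))),
            coverage=("covered", "mean"),
            n_fits=("dataset", "count"),
        )
        .reset_index()
    )
    return {"report": report, "estimates": estimates, "failures": failures}
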