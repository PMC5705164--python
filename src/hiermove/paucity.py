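"""Data-paucity robustness experiment.

How do population-level inferences degrade as telemetry data thin out?
The experiment re-fits the model on repeated random subsets of the full
analysis table at fixed retention fractions (by default 25 replicates at
75, 50, 25 and 10 percent — 100 "data poor" datasets), with rows removed
across the whole table without regard to individuals.  Accuracy is the
shift of each reduced-data point estimate from its full-data value;
precision is the width of the 95% interval.  The expectation for a
well-specified model is that intervals widen roughly as 1/sqrt(fraction)
while point-estimate signs for strong effects stay put.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierbayes import (
    COEF_NAMES,
    HierLogitModel,
    MCMCConfig,
    PriorSpec,
    sample_posterior,
    summarize_posterior,
)

__all__ = [
    "PaucityDesign",
    "PaucityResult",
    "subset_dataset",
    "run_paucity_experiment",
    "summarize_accuracy_precision",
    "make_fitter",
]

DEFAULT_FRACTIONS = (0.75, 0.50, 0.25, 0.10)


@dataclass(frozen=True)
class PaucityDesign:
    fractions: tuple = DEFAULT_FRACTIONS
    replicates: int = 25
    seed: int = 0
    fitter: str = "laplace"  # one of {"hier_bayes", "laplace", "pql"}

    def __post_init__(self) -> None:
        if any(not 0.0 < f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class PaucityResult:
    """Long-format per-(fraction, replicate, parameter) records plus the
    full-data reference estimates."""

    records: pd.DataFrame
    full_estimates: pd.DataFrame
    design: PaucityDesign
    failures: list = field(default_factory=list)


def subset_dataset(table: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Simple random sample of round(fraction * n) rows without
    replacement, drawn across all rows ignoring group membership.

    Surviving rows keep their original order, so group blocks stay
    contiguous and individuals that lose every row simply drop out of the
    track index.  A subset left with fewer than two groups or a single
    response class is rejected.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(table)
    m = int(round(fraction * n))
    if fraction == 1.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=m, replace=False))
    sub = table.iloc[keep].reset_index(drop=True)
    n_groups = sub["ptt"].nunique()
    z_classes = sub["z"].nunique()
    if n_groups < 2 or z_classes < 2:
        raise ValueError(
            f"subset degenerate: {n_groups} groups, {z_classes} response "
            f"classes at fraction {fraction} (seed {seed})"
        )
    return sub


def make_fitter(name: str, mcmc_config: MCMCConfig | None = None,
                priors: PriorSpec | None = None):
    """Build a ``fitter(table, seed) -> DataFrame`` with columns
    (parameter, estimate, lower, upper) for the named method.

    The Bayesian fitter reports posterior means and equal-tailed 95%
    credible intervals; the MLE fitters report estimates with Wald 95%
    confidence intervals.
    """
    if name in ("laplace", "pql"):
        from .glmm import fit_laplace, fit_pql

        fit_fn = fit_laplace if name == "laplace" else fit_pql

        def fitter(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
            model = HierLogitModel.from_analysis_table(table)
            fit = fit_fn(model)
            return fit.estimates_frame()[["parameter", "estimate", "lower", "upper"]]

        return fitter
    if name == "hier_bayes":
        base = mcmc_config or MCMCConfig.from_preset("desk")
        pr = priors or PriorSpec()

        def fitter(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
            import dataclasses

            model = HierLogitModel.from_analysis_table(table)
            cfg = dataclasses.replace(base, seed=int(seed))
            draws = sample_posterior(model, pr, cfg)
            summ = summarize_posterior(draws, include_u=False)
            summ = summ[summ["parameter"].isin(COEF_NAMES)]
            return summ.rename(
                columns={"mean": "estimate", "q2.5": "lower", "q97.5": "upper"}
            )[["parameter", "estimate", "lower", "upper"]]

        return fitter
    raise ValueError(f"unknown fitter {name!r}")


def _replicate_seed(master: int, fraction_index: int, replicate: int) -> int:
    """Counter-based per-replicate seed: independent of execution order.

    ``fraction_index`` -1 (the full-data fit) maps to a reserved counter.
    """
    ss = np.random.SeedSequence([master, fraction_index + 1, replicate])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_paucity_experiment(
    table: pd.DataFrame,
    design: PaucityDesign,
    fitter=None,
    max_failure_rate: float = 0.20,
) -> PaucityResult:
    """Fit the full table once, then every (fraction, replicate) subset.

    Individual replicate failures are recorded and skipped; more than
    ``max_failure_rate`` failures at any single fraction aborts the
    experiment.  Per-replicate seeds derive from the design seed by a
    counter scheme, so the experiment is reproducible and each subset is
    distinct.
    """
    if fitter is None:
        fitter = make_fitter(design.fitter)
    full = fitter(table, _replicate_seed(design.seed, -1, 0)).set_index("parameter")
    records = []
    failures = []
    for fi, frac in enumerate(design.fractions):
        n_failed = 0
        for rep in range(design.replicates):
            seed = _replicate_seed(design.seed, fi, rep)
            try:
                sub = subset_dataset(table, frac, seed)
                est = fitter(sub, seed).set_index("parameter")
            except Exception as exc:  # noqa: BLE001 - rate-checked below
                failures.append((frac, rep, repr(exc)))
                n_failed += 1
                continue
            for name in full.index:
                e = float(est.loc[name, "estimate"])
                lo = float(est.loc[name, "lower"])
                hi = float(est.loc[name, "upper"])
                records.append(
                    {
                        "fraction": frac,
                        "replicate": rep,
                        "parameter": name,
                        "estimate": e,
                        "lower": lo,
                        "upper": hi,
                        "accuracy": e - float(full.loc[name, "estimate"]),
                        "width": hi - lo,
                    }
                )
        if n_failed > max_failure_rate * design.replicates:
            raise RuntimeError(
                f"{n_failed}/{design.replicates} replicates failed at "
                f"fraction {frac}; first failure: {failures[0]}"
            )
    full_out = full.reset_index().assign(
        width=lambda d: d["upper"] - d["lower"]
    )
    return PaucityResult(
        records=pd.DataFrame(records),
        full_estimates=full_out,
        design=design,
        failures=failures,
    )


def summarize_accuracy_precision(result: PaucityResult) -> pd.DataFrame:
    """Per (fraction, parameter): accuracy spread, median interval width,
    width ratio against the full-data interval, and sign stability (the
    share of replicates whose point estimate matches the full-data
    estimate's sign)."""
    full = result.full_estimates.set_index("parameter")
    rows = []
    for (frac, name), grp in result.records.groupby(
        ["fraction", "parameter"], sort=True
    ):
        full_est = float(full.loc[name, "estimate"])
        full_width = float(full.loc[name, "width"])
        sign_match = np.sign(grp["estimate"]) == np.sign(full_est)
        rows.append(
            {
                "fraction": frac,
                "parameter": name,
                "mean_accuracy": float(grp["accuracy"].mean()),
                "min_accuracy": float(grp["accuracy"].min()),
                "max_accuracy": float(grp["accuracy"].max()),
                "median_width": float(grp["width"].median()),
                "width_ratio": float(grp["width"].median() / full_width)
                if full_width > 0
                else np.nan,
                "sign_stability": float(sign_match.mean()),
                "n_replicates": len(grp),
            }
        )
    return pd.DataFrame(rows)
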