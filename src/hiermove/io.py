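"""Readers, writers, configuration and pipeline orchestration.

Every stage exchanges one common currency: the analysis table, a CSV with
the columns

    ptt, sex, Spring, Summer, Fall, Winter, L, z,
    [NPGO_Index, PDO_Index,] MEI_Index [, Moon, sst, chl]

where ptt is the per-animal tag id (rows contiguous per tag), sex is
F/M, exactly one season indicator is 1 per row, L is z-scored body
length, and z is the binary east/west response.  Outputs carry a JSON
provenance sidecar (config hash, master seed, package version) so any
artifact can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import SEASONS, build_track_index

__all__ = [
    "REQUIRED_COLUMNS",
    "read_analysis_table",
    "write_analysis_table",
    "validate_analysis_table",
    "RunConfig",
    "run_pipeline",
    "write_provenance",
]

REQUIRED_COLUMNS = ("ptt", "sex", "Spring", "Summer", "Fall", "Winter", "L", "z")
OPTIONAL_COLUMNS = ("NPGO_Index", "PDO_Index", "MEI_Index", "Moon", "sst", "chl")
SEX_LEVELS = ("F", "M")


def validate_analysis_table(df: pd.DataFrame) -> pd.DataFrame:
    """Schema, factor-level, missing-value and contiguity validation."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"analysis table missing required column(s): {missing}")
    modeled = [c for c in df.columns if c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    na = df[modeled].isna()
    if na.any().any():
        col = na.any()[na.any()].index[0]
        row = int(na[col].idxmax())
        raise ValueError(f"missing value in modeled column {col!r} at row {row}")
    bad_sex = ~df["sex"].astype(str).isin(SEX_LEVELS)
    if bad_sex.any():
        row = int(bad_sex.idxmax())
        raise ValueError(
            f"unknown sex level {df['sex'].iloc[row]!r} at row {row}; "
            f"allowed: {SEX_LEVELS}"
        )
    z = df["z"].to_numpy()
    if not np.isin(z, (0, 1)).all():
        row = int(np.flatnonzero(~np.isin(z, (0, 1)))[0])
        raise ValueError(f"response z must be 0/1; found {z[row]!r} at row {row}")
    seas = df[list(SEASONS)].to_numpy()
    if not np.isin(seas, (0, 1)).all() or not (seas.sum(axis=1) == 1).all():
        row = int(np.flatnonzero(seas.sum(axis=1) != 1)[0]) if np.isin(
            seas, (0, 1)
        ).all() else 0
        raise ValueError(
            f"season indicators must be one-hot; offending row {row}"
        )
    build_track_index(df)  # raises on non-contiguous tag blocks
    return df


def read_analysis_table(path) -> pd.DataFrame:
    """Read and validate an analysis-table CSV."""
    df = pd.read_csv(path, dtype={"ptt": str, "sex": str})
    for c in ("Spring", "Summer", "Fall", "Winter", "z"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="raise")
    return validate_analysis_table(df)


def write_analysis_table(df: pd.DataFrame, path) -> None:
    validate_analysis_table(df)
    ordered = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    df[ordered + extra].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline

_STAGES = (
    "preprocess",
    "simulate",
    "select-vars",
    "check-linearity",
    "fit-bayes",
    "fit-glmm",
    "priors-check",
    "paucity",
    "recover",
)


@dataclass
class RunConfig:
    """Structured per-stage settings with named presets.

    ``preset`` selects {desk, paper} scale for the sampler and the forest;
    CLI flags override individual values.  The master seed feeds every
    stage's random stream.
    """

    stages: list = field(default_factory=lambda: ["simulate", "fit-bayes"])
    out_dir: str = "hiermove_out"
    input_table: str | None = None
    preset: str = "desk"
    seed: int = 0
    prior: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    rf: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    paucity: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        from dataclasses import asdict

        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {_STAGES}")
        if self.preset not in ("desk", "paper"):
            raise ValueError(f"unknown preset {self.preset!r}")


def write_provenance(path: Path, config: RunConfig, extra: dict | None = None) -> None:
    meta = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "preset": config.preset,
        "package": "hiermove 0.1.0",
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in canonical order.

    Returns a manifest mapping stage name to the artifacts it wrote; a
    stage failure halts downstream stages (partial artifacts are kept)
    and re-raises.  Every artifact directory gets a provenance JSON with
    the config hash and master seed.
    """
    from . import hierbayes, linearity, paucity as paucity_mod, simulate, varselect
    from .glmm import fit_laplace, fit_pql

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"artifacts": {}, "timings": {}, "config_hash": config.config_hash(),
                      "seed": config.seed}
    ordered = [s for s in _STAGES if s in config.stages]

    table = None
    if config.input_table:
        header = pd.read_csv(config.input_table, nrows=0).columns
        if set(REQUIRED_COLUMNS) <= set(header):
            table = read_analysis_table(config.input_table)
        elif "preprocess" not in ordered:
            raise ValueError(
                f"{config.input_table} lacks the analysis-table columns; "
                "run the preprocess stage on raw locations first"
            )

    priors = hierbayes.PriorSpec(**config.prior)

    def mcmc_config():
        cfg = hierbayes.MCMCConfig.from_preset(config.preset, seed=config.seed)
        if config.mcmc:
            import dataclasses

            cfg = dataclasses.replace(cfg, **config.mcmc)
        return cfg

    for stage in ordered:
        t0 = time.perf_counter()
        paths: list[str] = []
        if stage == "simulate":
            sim_cfg = simulate.SimConfig(**{"seed": config.seed, **config.sim})
            ds = simulate.simulate_dataset(sim_cfg)
            p = out / "simulated_table.csv"
            write_analysis_table(ds.table.drop(columns=["date"]), p)
            truth_p = out / "simulated_truth.json"
            truth_p.write_text(
                json.dumps(
                    {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in ds.truth.items()},
                    indent=2,
                )
            )
            paths = [str(p), str(truth_p)]
            table = ds.table
        elif stage == "preprocess":
            if config.input_table is None:
                raise ValueError("preprocess stage needs input_table")
            raw = pd.read_csv(config.input_table)
            if {"tag_id", "timestamp", "lon", "lat", "argos_class"} <= set(
                raw.columns
            ):
                from .preprocess import (
                    derive_response,
                    encode_season,
                    filter_daily_best,
                )

                kept = filter_daily_best(raw)
                kept = pd.concat(
                    [kept.reset_index(drop=True),
                     encode_season(kept["timestamp"]).reset_index(drop=True)],
                    axis=1,
                )
                kept["z"] = derive_response(kept["lon"].to_numpy())
                p = out / "filtered_locations.csv"
                kept.to_csv(p, index=False)
                side = out / "preprocess_counts.json"
                side.write_text(
                    json.dumps(
                        {"rows_in": len(raw), "rows_kept": len(kept),
                         "tags": int(kept["tag_id"].nunique())}
                    )
                )
                paths = [str(p), str(side)]
            else:
                table = read_analysis_table(config.input_table)
                p = out / "analysis_table.csv"
                write_analysis_table(
                    table.drop(columns=["date"], errors="ignore"), p
                )
                paths = [str(p)]
        elif stage == "select-vars":
            rf_defaults = (
                varselect.RFConfig.desk(seed=config.seed)
                if config.preset == "desk"
                else varselect.RFConfig(seed=config.seed)
            )
            import dataclasses

            rf_cfg = dataclasses.replace(rf_defaults, **config.rf)
            predictors = [
                c for c in table.columns
                if c not in ("z", "ptt", "date") and table[c].nunique() > 1
            ]
            res = varselect.permutation_importance_test(
                table, rf_cfg, predictors=predictors
            )
            kept = varselect.select_variables(res)
            rep = res.table.assign(selected=res.table["variable"].isin(kept))
            p = out / "importance_report.csv"
            rep.to_csv(p, index=False)
            paths = [str(p)]
        elif stage == "check-linearity":
            smooth = [
                v for v in ("L", "MEI_Index")
                if v in table.columns and table[v].nunique() >= 10
            ]
            lin = [v for v in ("Spring", "Summer", "Winter", "sex") if v in table.columns]
            fit = linearity.fit_additive_logistic(table, smooth, lin)
            p = out / "linearity_report.csv"
            linearity.linearity_report(fit).to_csv(p, index=False)
            paths = [str(p)]
        elif stage == "fit-bayes":
            model = hierbayes.HierLogitModel.from_analysis_table(table)
            draws = hierbayes.sample_posterior(model, priors, mcmc_config())
            p1 = out / "posterior_draws.csv"
            draws.to_frame().to_csv(p1, index=False)
            p2 = out / "posterior_summary.csv"
            hierbayes.summarize_posterior(draws).to_csv(p2, index=False)
            p3 = out / "diagnostics.json"
            p3.write_text(
                json.dumps(
                    {
                        "rhat": hierbayes.gelman_rubin(draws),
                        "acceptance": draws.acceptance,
                        "warnings": draws.warnings,
                        "seed": config.seed,
                        "preset": config.preset,
                    },
                    indent=2,
                )
            )
            paths = [str(p1), str(p2), str(p3)]
        elif stage == "fit-glmm":
            model = hierbayes.HierLogitModel.from_analysis_table(table)
            rows = []
            for fit in (fit_laplace(model), fit_pql(model)):
                rec = {"method": fit.method, "sigma_u": fit.sigma_u,
                       "loglik": fit.loglik, "converged": fit.converged}
                rec.update(dict(zip(fit.coef_names, fit.beta)))
                rows.append(rec)
            p = out / "glmm_fits.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            paths = [str(p)]
        elif stage == "priors-check":
            model = hierbayes.HierLogitModel.from_analysis_table(table)
            cfg = mcmc_config()
            data_draws = hierbayes.sample_posterior(model, priors, cfg)
            prior_draws = hierbayes.run_priors_only(
                model, priors, cfg, mode="prior_predictive"
            )
            rep = hierbayes.prior_influence_check(data_draws, prior_draws, priors)
            p = out / "prior_influence.csv"
            rep.to_csv(p, index=False)
            paths = [str(p)]
        elif stage == "paucity":
            design = paucity_mod.PaucityDesign(
                **{"seed": config.seed, **config.paucity}
            )
            result = paucity_mod.run_paucity_experiment(table, design)
            p1 = out / "paucity_records.csv"
            result.records.to_csv(p1, index=False)
            p2 = out / "paucity_summary.csv"
            paucity_mod.summarize_accuracy_precision(result).to_csv(p2, index=False)
            paths = [str(p1), str(p2)]
        elif stage == "recover":
            sim_cfg = simulate.SimConfig(**{"seed": config.seed, **config.sim})
            n_datasets = int(config.recovery.get("n_datasets", 100))
            fitter_name = config.recovery.get("fitter", "laplace")
            fitter = paucity_mod.make_fitter(fitter_name)
            res = simulate.recovery_study(
                sim_cfg, n_datasets,
                lambda ds: fitter(ds.table, sim_cfg.seed),
                base_seed=config.seed,
            )
            p = out / "recovery_report.csv"
            res["report"].to_csv(p, index=False)
            paths = [str(p)]
        manifest["artifacts"][stage] = paths
        manifest["timings"][stage] = round(time.perf_counter() - t0, 3)

    write_provenance(out / "provenance.json", config, {"stages": ordered})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
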