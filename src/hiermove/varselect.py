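"""Variable screening with a balanced random forest and permutation tests.

Candidate predictors of the binary response are screened with a
classification random forest in which every tree is grown on an equal
number of rows from each response class, drawn without replacement
(guarding against class imbalance and against split biases when predictor
scales differ).  Importance is the mean decrease in Gini impurity summed
over each tree's splits and averaged across trees.  Significance comes
from a permutation test: the response column is randomly permuted and the
whole forest refit ``n_perm`` times; a predictor's p-value is the
add-one-corrected fraction of null importances at least as large as the
observed one, so p can never be exactly zero and is bounded below by
1/(n_perm + 1).

Perfect predictors (e.g. the longitude the response was derived from)
must be removed before fitting — they would be rediscovered with maximal
importance and say nothing about the biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "RFConfig",
    "ImportanceResult",
    "detect_perfect_predictors",
    "fit_balanced_forest",
    "permutation_importance_test",
    "select_variables",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest and permutation-test settings.

    Full-scale defaults: 10,000 trees, 1,000 rows per class per tree
    without replacement, 100 permutation replicates, significance level
    0.1.  ``desk()`` shrinks the forest (500 trees, 50 permutations) for
    interactive-scale runs.
    """

    n_trees: int = 10_000
    samp_per_class: int = 1_000
    with_replacement: bool = False
    n_perm: int = 100
    alpha: float = 0.1
    max_features: str | int = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_perm < 1:
            raise ValueError("n_trees and n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def desk(cls, **overrides) -> "RFConfig":
        return replace(cls(n_trees=500, n_perm=50), **overrides)


@dataclass
class ImportanceResult:
    """Observed importances, their permutation nulls and p-values."""

    table: pd.DataFrame  # variable, importance, p_value
    null_importances: np.ndarray  # (n_perm, n_vars)
    oob_error: float
    class_errors: dict
    config: RFConfig

    @property
    def p_values(self) -> pd.Series:
        return self.table.set_index("variable")["p_value"]


def detect_perfect_predictors(
    table: pd.DataFrame, response: str = "z", predictors: list[str] | None = None
) -> list[str]:
    """Variables that classify the response with zero training error.

    Numeric variables are flagged when a single threshold separates the
    classes; categorical variables when every level maps to one class.
    """
    z = table[response].to_numpy()
    if not np.isin(z, (0, 1)).all():
        raise ValueError("response must be binary 0/1")
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    flagged = []
    for var in predictors:
        col = table[var]
        if pd.api.types.is_numeric_dtype(col):
            x = col.to_numpy(dtype=float)
            x0, x1 = x[z == 0], x[z == 1]
            if len(x0) == 0 or len(x1) == 0:
                continue
            if x0.max() < x1.min() or x1.max() < x0.min():
                flagged.append(var)
        else:
            per_level = table.groupby(col, observed=True)[response].nunique()
            if (per_level <= 1).all():
                flagged.append(var)
    return flagged


def _encode(table: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    cols = []
    for var in predictors:
        col = table[var]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            cols.append(pd.factorize(col, sort=True)[0].astype(float))
    return np.column_stack(cols)


def _grow_forest(X, z, config: RFConfig, rng, compute_oob: bool):
    n = len(z)
    idx0 = np.flatnonzero(z == 0)
    idx1 = np.flatnonzero(z == 1)
    importances = np.zeros(X.shape[1])
    votes = np.zeros((n, 2)) if compute_oob else None
    in_bag = np.empty(2 * config.samp_per_class, dtype=np.int64)
    for _ in range(config.n_trees):
        in_bag[: config.samp_per_class] = rng.choice(
            idx0, size=config.samp_per_class, replace=config.with_replacement
        )
        in_bag[config.samp_per_class :] = rng.choice(
            idx1, size=config.samp_per_class, replace=config.with_replacement
        )
        tree = DecisionTreeClassifier(
            max_features=config.max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[in_bag], z[in_bag])
        importances += tree.tree_.compute_feature_importances(normalize=False)
        if compute_oob:
            oob = np.ones(n, dtype=bool)
            oob[in_bag] = False
            if oob.any():
                pred = tree.predict(X[oob])
                votes[np.flatnonzero(oob), pred] += 1.0
    importances /= config.n_trees
    oob_error = np.nan
    class_errors: dict = {}
    if compute_oob:
        voted = votes.sum(axis=1) > 0
        pred = votes.argmax(axis=1)
        wrong = (pred != z) & voted
        oob_error = float(wrong.sum() / max(voted.sum(), 1))
        for cls in (0, 1):
            mask = voted & (z == cls)
            class_errors[cls] = float(wrong[mask].sum() / max(mask.sum(), 1))
    return importances, oob_error, class_errors


def fit_balanced_forest(
    table: pd.DataFrame,
    config: RFConfig,
    response: str = "z",
    predictors: list[str] | None = None,
    check_perfect: bool = True,
):
    """Grow the class-balanced forest; returns (importances as a Series,
    OOB error, per-class OOB error dict).

    Every tree sees exactly ``samp_per_class`` rows of each class; OOB
    error is scored on the rows a tree did not see.
    """
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    z = table[response].to_numpy(dtype=np.int64)
    classes, counts = np.unique(z, return_counts=True)
    if len(classes) < 2:
        raise ValueError("response has a single class; nothing to classify")
    if not config.with_replacement and counts.min() < config.samp_per_class:
        raise ValueError(
            f"samp_per_class = {config.samp_per_class} exceeds the smaller "
            f"class ({dict(zip(classes.tolist(), counts.tolist()))})"
        )
    if check_perfect:
        perfect = detect_perfect_predictors(table, response, predictors)
        if perfect:
            raise ValueError(
                f"perfect predictors present, remove before fitting: {perfect}"
            )
    X = _encode(table, predictors)
    rng = np.random.default_rng(config.seed)
    imp, oob, cls_err = _grow_forest(X, z, config, rng, compute_oob=True)
    return pd.Series(imp, index=predictors, name="importance"), oob, cls_err


def permutation_importance_test(
    table: pd.DataFrame,
    config: RFConfig,
    response: str = "z",
    predictors: list[str] | None = None,
) -> ImportanceResult:
    """Observed Gini importances with permutation-null p-values.

    For each of ``n_perm`` replicates the response is permuted (class
    counts preserved exactly) and the full forest refit; the p-value per
    variable is (1 + #{null >= observed}) / (n_perm + 1).
    """
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    obs_imp, oob, cls_err = fit_balanced_forest(
        table, config, response, predictors
    )
    X = _encode(table, predictors)
    z = table[response].to_numpy(dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    rng.integers(0, 2**31 - 1)  # advance past the observed-forest stream
    null = np.empty((config.n_perm, len(predictors)))
    for r in range(config.n_perm):
        z_perm = rng.permutation(z)
        null[r], _, _ = _grow_forest(X, z_perm, config, rng, compute_oob=False)
    exceed = (null >= obs_imp.to_numpy()[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (config.n_perm + 1.0)
    tbl = pd.DataFrame(
        {
            "variable": predictors,
            "importance": obs_imp.to_numpy(),
            "p_value": p,
        }
    )
    return ImportanceResult(
        table=tbl, null_importances=null, oob_error=oob,
        class_errors=cls_err, config=config,
    )


def select_variables(result: ImportanceResult, alpha: float | None = None) -> list[str]:
    """Variables with permutation p-value <= alpha (inclusive at the
    boundary).  Emits a warning, not an error, when nothing survives."""
    alpha = result.config.alpha if alpha is None else alpha
    kept = result.table.loc[result.table["p_value"] <= alpha, "variable"].tolist()
    if not kept:
        warnings.warn(
            f"no variable reached the significance level {alpha}", stacklevel=2
        )
    return kept
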