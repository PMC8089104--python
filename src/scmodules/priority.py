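"""Module prioritization by the deviance ratio of a per-module Gaussian GLM.

Each module's per-cell score is regressed on one categorical metadata factor
at a time with a Gaussian identity-link GLM (one-hot factor plus intercept).
The model deviance is the residual sum of squares, the null deviance the
total sum of squares about the mean, and the deviance ratio

    delta_dev = (dev_null - dev_model) / dev_null

measures how much of a module's expression pattern the factor explains; in
this Gaussian setting delta_dev is exactly the coefficient of determination
R^2 and always lies in [0, 1].  Modules are ranked per factor by descending
delta_dev.  Modules dominated by ribosomal/mitochondrial housekeeping genes
can be flagged and dropped from the default ranking while staying in the
table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "fit_module_glm",
    "delta_deviance",
    "prioritize_modules",
    "flag_housekeeping_modules",
]


def fit_module_glm(score: np.ndarray, factor) -> tuple[float, float]:
    """Gaussian GLM of a module score on one categorical factor.

    Returns ``(dev_model, dev_null)``: residual sum of squares of the
    group-means fit and total sum of squares about the grand mean.  The OLS
    fit of a score on a one-hot factor with intercept has fitted values equal
    to the per-level means, so the deviances are computed directly from the
    group means.
    """
    score = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(score)):
        raise ValueError("non-finite module scores")
    factor = pd.Series(list(factor))
    if len(factor) != len(score):
        raise ValueError("score and factor lengths differ")
    levels = factor.unique()
    if len(levels) < 2:
        raise ValueError("factor must have at least 2 levels present")
    if len(levels) >= len(score):
        raise ValueError("factor has at least as many levels as cells")
    dev_null = float(np.sum((score - score.mean()) ** 2))
    fitted = factor.map(pd.Series(score).groupby(factor).mean()).to_numpy()
    dev_model = float(np.sum((score - fitted) ** 2))
    return dev_model, dev_null


def delta_deviance(dev_null: float, dev_model: float) -> float:
    """Deviance ratio (dev_null - dev_model) / dev_null, defined as 0 when
    the null deviance vanishes (constant score)."""
    if dev_null < 0 or dev_model < 0:
        raise ValueError("deviances must be non-negative")
    if dev_null == 0:
        warnings.warn("null deviance is 0 (constant score); delta_dev set to 0")
        return 0.0
    return (dev_null - dev_model) / dev_null


def prioritize_modules(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    factors=None,
    housekeeping: pd.Series | None = None,
) -> pd.DataFrame:
    """Score every (module, factor) pair by delta_dev and rank per factor.

    ``scores`` is modules x cells; ``metadata`` a per-cell table of
    categorical factors (every score column must be covered).  Returns a
    table (module_id, factor, dev_null, dev_model, delta_dev, rank,
    housekeeping_flag) sorted by factor then rank.  Flagged housekeeping
    modules keep their rows but are excluded from rank numbering.
    """
    missing = scores.columns.difference(metadata.index)
    if len(missing) > 0:
        raise ValueError(f"metadata missing for cells: {list(missing)}")
    meta = metadata.loc[scores.columns]
    factors = list(factors) if factors is not None else list(meta.columns)
    hk = (
        housekeeping.reindex(scores.index).fillna(False)
        if housekeeping is not None
        else pd.Series(False, index=scores.index)
    )
    rows = []
    for factor in factors:
        fvals = meta[factor]
        for mod in scores.index:
            dev_model, dev_null = fit_module_glm(scores.loc[mod].to_numpy(), fvals)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dd = delta_deviance(dev_null, dev_model)
            rows.append((mod, factor, dev_null, dev_model, dd, bool(hk[mod])))
    table = pd.DataFrame(
        rows,
        columns=["module_id", "factor", "dev_null", "dev_model", "delta_dev", "housekeeping_flag"],
    )
    table["rank"] = np.nan
    for factor, sub in table.groupby("factor"):
        eligible = sub[~sub["housekeeping_flag"]]
        ranks = eligible["delta_dev"].rank(ascending=False, method="first")
        table.loc[ranks.index, "rank"] = ranks
    table = table.sort_values(["factor", "delta_dev"], ascending=[True, False])
    return table.reset_index(drop=True)[
        ["module_id", "factor", "dev_null", "dev_model", "delta_dev", "rank", "housekeeping_flag"]
    ]


def flag_housekeeping_modules(
    assignment: pd.Series, annotation: pd.DataFrame, max_frac: float = 0.5
) -> pd.Series:
    """Flag modules in which more than ``max_frac`` of genes are ribosomal or
    mitochondrial."""
    hk_gene = (annotation["ribo"] | annotation["mito"]).reindex(assignment.index)
    frac = hk_gene.groupby(assignment).mean()
    out = frac > max_frac
    out.name = "housekeeping_flag"
    return out
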