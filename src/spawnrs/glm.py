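"""Poisson log-linear models of individual reproductive success.

Offspring counts are modelled with a log link as a function of spawning
year, sea-winter class, stocking stage and sex, optionally with all two-way
interactions among sea-winter class, stocking stage and sex.  Treatment
coding is used against fixed reference levels (year 2002, MSW, fry-stocked,
female), and nested fits are compared by chi-square analysis of deviance.
Rows with an undetermined level of any term in the model are excluded from
that fit (with a logged count), which is why a model without sex can use
more rows than one with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

#: Reference level of each factor (first level under treatment coding).
REFERENCE_LEVELS: dict[str, str] = {
    "year": "2002",
    "seawinter": "MSW",
    "stockstage": "fry",
    "sex": "F",
}

#: Values that mark an undetermined factor level.
UNKNOWN_LEVELS = {"U", "unknown", "", None}

INTERACTION_FACTORS = ("seawinter", "stockstage", "sex")


@dataclass
class ModelSpec:
    """A Poisson log-linear model for RS counts.

    ``terms`` are main effects among year / seawinter / stockstage / sex;
    ``interactions=True`` adds all two-way interactions among seawinter,
    stockstage and sex that are present in ``terms``.
    """

    terms: tuple[str, ...] = ("year", "seawinter", "stockstage", "sex")
    interactions: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        for t in self.terms:
            if t not in REFERENCE_LEVELS:
                raise ValueError(f"unknown model term {t!r}")

    def interaction_pairs(self) -> list[tuple[str, str]]:
        inter = [t for t in INTERACTION_FACTORS if t in self.terms]
        if not self.interactions:
            return []
        return [
            (inter[i], inter[j])
            for i in range(len(inter))
            for j in range(i + 1, len(inter))
        ]

    def formula(self) -> str:
        rhs = [f"C({t})" for t in self.terms]
        rhs += [f"C({a}):C({b})" for a, b in self.interaction_pairs()]
        return "rs ~ " + " + ".join(rhs)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        mine = set(self.terms) | set(self.interaction_pairs())
        theirs = set(other.terms) | set(other.interaction_pairs())
        return mine <= theirs


#: The three model specifications used in the analysis of RS counts.
MODEL_1 = ModelSpec(("year", "seawinter", "stockstage", "sex"), True, "model1")
MODEL_2 = ModelSpec(("year", "seawinter", "stockstage", "sex"), False, "model2")
MODEL_3 = ModelSpec(("year", "seawinter", "stockstage"), True, "model3")


@dataclass
class ModelFit:
    """Fitted Poisson GLM with the quantities used downstream."""

    spec: ModelSpec
    coefficients: pd.Series
    std_errors: pd.Series
    deviance: float
    df_resid: int
    n: int
    llf: float
    converged: bool
    dispersion: float  # Pearson chi2 / df, diagnostic only
    n_excluded: int
    result: object = field(repr=False, default=None)


def _prepare(rs_table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    df = rs_table.copy()
    df["year"] = df["year"].astype(str)
    keep = pd.Series(True, index=df.index)
    for t in spec.terms:
        if t not in df.columns:
            raise ValueError(f"RS table lacks column {t!r}")
        col = df[t].astype(object)
        keep &= ~col.isin(UNKNOWN_LEVELS) & col.notna()
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "fit_poisson_loglinear(%s): excluded %d rows with undetermined levels",
            spec.name or spec.formula(),
            n_excluded,
        )
    df = df[keep].copy()
    for t in spec.terms:
        levels = sorted(df[t].astype(str).unique())
        ref = REFERENCE_LEVELS[t]
        if ref in levels:
            levels = [ref] + [l for l in levels if l != ref]
        df[t] = pd.Categorical(df[t].astype(str), categories=levels)
        empty = df[t].cat.categories[df[t].value_counts().reindex(df[t].cat.categories) == 0]
        if len(empty):
            logger.warning("factor %s: dropping empty levels %s", t, list(empty))
            df[t] = df[t].cat.remove_unused_categories()
    return df, n_excluded


def fit_poisson_loglinear(rs_table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Maximum-likelihood Poisson fit of an RS-count model."""
    df, n_excluded = _prepare(rs_table, spec)
    if len(df) == 0:
        raise ValueError("no usable rows after exclusions")
    model = smf.glm(spec.formula(), data=df, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        logger.warning("Poisson GLM %s did not converge", spec.name)
    dispersion = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else np.nan
    return ModelFit(
        spec=spec,
        coefficients=res.params,
        std_errors=res.bse,
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        n=int(res.nobs),
        llf=float(res.llf),
        converged=bool(res.converged),
        dispersion=dispersion,
        n_excluded=n_excluded,
        result=res,
    )


def deviance_test(
    deviance_reduced: float,
    df_reduced: int,
    deviance_full: float,
    df_full: int,
) -> dict:
    """Chi-square analysis of deviance from the printed deviances/df."""
    delta_dev = deviance_reduced - deviance_full
    delta_df = df_reduced - df_full
    if delta_df < 0 or delta_dev < -1e-8:
        raise ValueError("reduced model must have higher deviance and df")
    p = 1.0 if delta_df == 0 else float(stats.chi2.sf(delta_dev, delta_df))
    return {"delta_deviance": float(delta_dev), "delta_df": int(delta_df), "p": p}


def analysis_of_deviance(full: ModelFit, reduced: ModelFit) -> dict:
    """Compare a reduced model nested in a full model on the same rows."""
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError("reduced model is not nested in the full model")
    if reduced.n != full.n:
        raise ValueError(
            "models were fitted on different rows; refit on a common subset"
        )
    return deviance_test(reduced.deviance, reduced.df_resid, full.deviance, full.df_resid)


def predict_mean_rs(fit: ModelFit, profile: dict) -> float:
    """Expected RS (exp of the linear predictor) for a covariate profile,
    e.g. ``{"year": "2004", "seawinter": "SSW", "stockstage": "smolt",
    "sex": "M"}``."""
    row = {}
    for t in fit.spec.terms:
        if t not in profile:
            raise ValueError(f"profile lacks level for {t!r}")
        row[t] = str(profile[t])
    exog = pd.DataFrame([row])
    try:
        return float(fit.result.predict(exog).iloc[0])
    except Exception as exc:  # unknown level -> patsy raises
        raise ValueError(f"cannot predict for profile {profile}: {exc}") from exc


def model_comparison_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Deviance/df summary of several fits, with a chi-square test of each
    model against the first (taken as the full model)."""
    full = fits[0]
    rows = []
    for fit in fits:
        row = {
            "model": fit.spec.name or fit.spec.formula(),
            "deviance": fit.deviance,
            "df": fit.df_resid,
            "n": fit.n,
        }
        if fit is not full and fit.spec.is_nested_in(full.spec) and fit.n == full.n:
            row["p_vs_full"] = analysis_of_deviance(full, fit)["p"]
        else:
            row["p_vs_full"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
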