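"""Accuracy models: what image features predict hits and misses.

The instance-level model is a logistic regression with crossed random
intercepts for worker and trial: the outcome is whether a ground-truth
instance was selected (true positive) or missed (false negative); false
positives are excluded because instance features exist only for true
objects. Instance area enters as its natural log — bbox areas are heavily
right-skewed — and the distance-from-center covariate is in raw pixels.

Variance explained is summarized with the latent-scale pseudo-R^2
decomposition for logit models: with sigma2_f the variance of the
fixed-effect linear predictor over the estimation sample,

    R2_marginal    = sigma2_f / (sigma2_f + sigma2_w + sigma2_t + pi^2/3)
    R2_conditional = (sigma2_f + sigma2_w + sigma2_t) / (same denominator)

Per-predictor contributions come from single-fixed-effect models compared
against a random-effects-only baseline (whose marginal R^2 is 0 by
construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glmm import MixedModelFit, SeparationError, fit_crossed_logistic
from .metrics import distance_from_center

__all__ = [
    "LinearModelFit",
    "build_instance_table",
    "build_selection_table",
    "build_trial_table",
    "fit_instance_model",
    "predict_selection_probability",
    "pseudo_r2",
    "delta_r2_by_predictor",
    "fit_trial_model",
    "fit_false_positive_model",
    "vif",
    "EXP1_PREDICTORS",
    "EXP2_PREDICTORS",
]

EXP1_PREDICTORS = ("log_area", "dist_center", "n_targets")
EXP2_PREDICTORS = ("clarity", "color_match", "dist_center", "log_area",
                   "n_targets")
LOGIT_RESIDUAL_VAR = math.pi ** 2 / 3.0


@dataclass
class LinearModelFit:
    """OLS fit summary for trial-level models."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    resid_sd: float
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "t": self.tvalues, "p": self.pvalues})


# -- table builders -----------------------------------------------------------

def build_instance_table(scored: pd.DataFrame,
                         image_side: float = 800.0) -> pd.DataFrame:
    """One row per (participant, trial, true instance) with outcome
    ``selected``; false positives are excluded."""
    df = scored[scored["role"].isin(["TP", "FN"])].copy()
    df["selected"] = (df["role"] == "TP").astype(int)
    df["log_area"] = np.log(df["area"].astype(float))
    df["dist_center"] = distance_from_center(df["cx"], df["cy"], image_side)
    return df[["participant_id", "trial_id", "instance_id", "selected",
               "log_area", "dist_center", "n_targets", "clarity",
               "color_match", "area"]].reset_index(drop=True)


def build_selection_table(scored: pd.DataFrame,
                          image_side: float = 800.0) -> pd.DataFrame:
    """One row per selection (TP or FP) with outcome ``false_positive``."""
    df = scored[scored["role"].isin(["TP", "FP"])].copy()
    df["false_positive"] = (df["role"] == "FP").astype(int)
    df["dist_center"] = distance_from_center(df["x"], df["y"], image_side)
    return df[["participant_id", "trial_id", "false_positive",
               "dist_center", "n_targets", "order_index"]].reset_index(drop=True)


def build_trial_table(scored: pd.DataFrame,
                      trial_ratings: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-trial averages for the trial-level linear model.

    Columns: mean true-positive rate across participants, mean instance
    clarity, fraction of color-matched instances, target count; plus mean
    template clarity and difficulty when a trial-rating table is supplied.
    """
    rows = []
    for tid, grp in scored.groupby("trial_id"):
        per_part = grp.groupby("participant_id").apply(
            lambda g: (g["role"] == "TP").sum()
            / max((g["role"].isin(["TP", "FN"])).sum(), 1),
            include_groups=False)
        inst = grp.dropna(subset=["instance_id"]).drop_duplicates("instance_id")
        rows.append({
            "trial_id": tid,
            "tp_rate": float(per_part.mean()),
            "mean_clarity": float(inst["clarity"].mean()),
            "pct_color_match": float(inst["color_match"].mean()),
            "n_targets": int(grp["n_targets"].iloc[0]),
        })
    out = pd.DataFrame(rows).set_index("trial_id")
    if trial_ratings is not None:
        agg = trial_ratings.groupby("trial_id").agg(
            template_clarity=("template_clarity", "mean"),
            difficulty=("difficulty", "mean"))
        out = out.join(agg)
    return out


# -- mixed-effects accuracy models --------------------------------------------

def fit_instance_model(
    instance_table: pd.DataFrame,
    predictors: tuple[str, ...] = EXP1_PREDICTORS,
) -> MixedModelFit:
    """Crossed random-intercepts logistic model of instance selection.

    ``predictors`` are column names of the instance table; pass
    ``EXP2_PREDICTORS`` for the five-predictor variant with clarity and
    color match.
    """
    df = instance_table.dropna(subset=["selected", *predictors])
    if df.empty:
        raise ValueError("instance table has no complete rows")
    X = df.loc[:, list(predictors)].astype(float)
    return fit_crossed_logistic(
        df["selected"].to_numpy(), X,
        groups={"worker": df["participant_id"], "trial": df["trial_id"]})


def fit_false_positive_model(selection_table: pd.DataFrame) -> MixedModelFit:
    """Model of whether a selection was a false positive (1) vs true positive
    (0), from the click's distance-from-center and the trial's target count."""
    df = selection_table.dropna(subset=["false_positive", "dist_center",
                                        "n_targets"])
    if df["false_positive"].nunique() < 2:
        raise SeparationError(
            "outcome is one-sided (no false positives or no true positives); "
            "the logistic fit is degenerate")
    X = df.loc[:, ["dist_center", "n_targets"]].astype(float)
    return fit_crossed_logistic(
        df["false_positive"].to_numpy(), X,
        groups={"worker": df["participant_id"], "trial": df["trial_id"]})


def predict_selection_probability(
    coefficients,
    area: float,
    distance: float,
    n_targets: float,
    clarity: float | None = None,
    color_match: float | None = None,
) -> float:
    """Inverse-logit of the fixed-effect linear predictor, random effects at 0.

    ``coefficients`` maps predictor names (``intercept``, ``log_area``,
    ``dist_center``, ``n_targets``, optionally ``clarity`` /
    ``color_match``) to logit-scale values; a MixedModelFit is also accepted
    (its ``Intercept`` is used).
    """
    if isinstance(coefficients, MixedModelFit):
        coefs = {k.lower(): v for k, v in coefficients.params.items()}
    else:
        coefs = {k.lower(): v for k, v in dict(coefficients).items()}
    eta = coefs.get("intercept", 0.0)
    eta += coefs.get("log_area", 0.0) * math.log(area)
    eta += coefs.get("dist_center", 0.0) * distance
    eta += coefs.get("n_targets", 0.0) * n_targets
    for name, value in (("clarity", clarity), ("color_match", color_match)):
        if name in coefs:
            if value is None:
                raise ValueError(f"model includes {name!r} but no value given")
            eta += coefs[name] * value
    return 1.0 / (1.0 + math.exp(-np.clip(eta, -500, 500)))


def pseudo_r2(fit: MixedModelFit) -> tuple[float, float]:
    """(marginal, conditional) latent-scale R^2 of a logistic mixed model."""
    s2f = fit.fixed_lp_var
    s2r = sum(fit.vc.values())
    denom = s2f + s2r + LOGIT_RESIDUAL_VAR
    return s2f / denom, (s2f + s2r) / denom


def delta_r2_by_predictor(
    instance_table: pd.DataFrame,
    predictors: tuple[str, ...] = EXP1_PREDICTORS,
    outcome: str = "selected",
) -> pd.DataFrame:
    """Marginal-R^2 gain of each predictor over a random-effects-only model.

    Each single-predictor model keeps both random intercepts; the baseline
    (intercept + random effects only) has marginal R^2 = 0 by construction,
    so the gain equals the single-predictor model's marginal R^2.
    """
    rows = []
    for pred in predictors:
        df = instance_table.dropna(subset=[outcome, pred])
        fit = fit_crossed_logistic(
            df[outcome].to_numpy(), df.loc[:, [pred]].astype(float),
            groups={"worker": df["participant_id"], "trial": df["trial_id"]})
        r2m, r2c = pseudo_r2(fit)
        rows.append({"predictor": pred, "delta_r2_marginal": r2m,
                     "r2_conditional": r2c,
                     "estimate": float(fit.params[pred])})
    return pd.DataFrame(rows).set_index("predictor")


# -- trial-level linear models -------------------------------------------------

def fit_trial_model(
    trial_table: pd.DataFrame,
    outcome: str = "tp_rate",
    predictors: tuple[str, ...] = ("mean_clarity", "pct_color_match",
                                   "template_clarity", "n_targets"),
) -> LinearModelFit:
    """Ordinary least squares on per-trial averages."""
    df = trial_table.dropna(subset=[outcome, *predictors])
    if len(df) <= len(predictors) + 1:
        raise ValueError(
            f"only {len(df)} complete trials for {len(predictors)} "
            "predictors; cannot fit")
    X = df.loc[:, list(predictors)].astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax()
        raise ValueError(f"design is rank deficient; columns {pair} are "
                         "collinear")
    res = sm.OLS(df[outcome].astype(float), sm.add_constant(X)).fit()
    params = res.params.rename(index={"const": "Intercept"})
    return LinearModelFit(
        params=params,
        bse=res.bse.rename(index={"const": "Intercept"}),
        tvalues=res.tvalues.rename(index={"const": "Intercept"}),
        pvalues=res.pvalues.rename(index={"const": "Intercept"}),
        r2=float(res.rsquared),
        resid_sd=float(np.sqrt(res.mse_resid)),
        n_obs=int(res.nobs),
    )


def vif(covariates: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate: 1 / (1 - R^2_j).

    Exact collinearity yields ``inf`` for the involved columns.
    """
    X = covariates.dropna().astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col))
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
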