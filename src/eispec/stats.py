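"""Cohort-level statistics: control-referenced z-scores, repeated-measures
association models, and FDR-thresholded regional group maps.

The association model regresses a per-ROI z-scored outcome (a model parameter
or a band power) on regional tau and amyloid-beta SUVR in patients, with a
subject-level random intercept to absorb the within-subject correlation of
the 68 repeated ROIs.  Residual variances can optionally be allowed to differ
by ROI (two-stage reweighting).  Regional group contrasts are unpaired
t-tests per ROI thresholded with the Benjamini--Hochberg procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "DegenerateROIError",
    "zscore_vs_controls",
    "association_model",
    "regional_group_map",
]


class DegenerateROIError(ValueError):
    """One or more ROIs cannot be z-scored (too few controls or zero spread)."""


@dataclass(frozen=True)
class AssociationResult:
    """Per-predictor fixed-effect estimates from a repeated-measures model."""

    table: pd.DataFrame  # index: predictor; columns: estimate, se, t, p
    outcome: str
    n_subjects: int
    n_obs: int
    variance: str
    fit_lines: pd.DataFrame | None = None

    def __getitem__(self, predictor: str) -> pd.Series:
        return self.table.loc[predictor]


def zscore_vs_controls(
    table: pd.DataFrame, measure: str, group_col: str = "group"
) -> pd.Series:
    """Per-ROI z-scores of ``measure`` against the control cohort.

    For each ROI, z = (value - control mean) / control SD, applied to every
    subject (controls standardize themselves to mean 0, SD 1 per ROI).
    """
    if measure not in table.columns:
        raise KeyError(f"measure {measure!r} not in table")
    ctrl = table[table[group_col] == "control"]
    if ctrl.empty:
        raise DegenerateROIError("no control subjects to z-score against")
    grp = ctrl.groupby("roi")[measure]
    counts, means, sds = grp.count(), grp.mean(), grp.std(ddof=1)
    bad = sorted(counts.index[(counts < 2) | (sds <= 0) | sds.isna()])
    if bad:
        raise DegenerateROIError(f"ROIs with <2 controls or zero control SD: {bad}")
    z = (table[measure].to_numpy() - means.reindex(table.roi).to_numpy()) / sds.reindex(
        table.roi
    ).to_numpy()
    return pd.Series(z, index=table.index, name=f"{measure}_z")


def _per_roi_weights(df: pd.DataFrame, outcome: str, predictors: tuple[str, ...]) -> np.ndarray:
    """1/sigma_roi from OLS residuals, for the heteroscedastic variant."""
    X = sm.add_constant(df[list(predictors)].to_numpy())
    resid = sm.OLS(df[outcome].to_numpy(), X).fit().resid
    sd = pd.Series(resid, index=df.index).groupby(df.roi).transform("std")
    sd = sd.replace(0.0, np.nan).fillna(sd.mean())
    return (1.0 / sd).to_numpy()


def association_model(
    z_table: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...] = ("tau_suvr", "ab_suvr"),
    variance: str = "homogeneous",
    df_method: str = "between_within",
) -> AssociationResult:
    """Mixed-effects association of a z-scored measure with SUVR predictors.

    Fits ``outcome ~ 1 + predictors`` with a subject random intercept on the
    patient rows of ``z_table``.  ``variance='per_roi'`` reweights rows by
    ROI-specific residual SDs estimated in a first pass.  p-values use a
    between--within degrees-of-freedom approximation by default
    (``df_method='normal'`` for the asymptotic normal reference).

    Also returns predicted-fit lines per predictor, computed with every other
    predictor fixed at its mean.
    """
    df = z_table[z_table.group == "patient"] if "group" in z_table.columns else z_table
    df = df.dropna(subset=[outcome, *predictors])
    if df.empty:
        raise ValueError("no complete-case patient rows")
    X = df[list(predictors)].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < len(predictors) + 1:
        raise ValueError("collinear or constant predictors")

    y = df[outcome].to_numpy(float)
    w = np.ones(len(df))
    if variance == "per_roi":
        w = _per_roi_weights(df, outcome, predictors)
    elif variance != "homogeneous":
        raise ValueError(f"unknown variance structure {variance!r}")

    # Row-weighting by 1/sigma_roi turns the heteroscedastic model into a
    # homoscedastic one: w*y = w*X b + w*u_subj + e  <=>  y = X b + u + e/w.
    exog = pd.DataFrame(X * w[:, None], columns=list(predictors), index=df.index)
    exog.insert(0, "const", w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y * w, exog, groups=df.subject_id, exog_re=w[:, None])
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            # the default gradient-based optimizer can hit a singular profiled
            # information matrix mid-iteration; Powell never evaluates it
            fit = model.fit(reml=True, method="powell", maxiter=2000)
    if not np.all(np.isfinite(fit.params)):
        raise RuntimeError(f"mixed model did not converge: {fit.summary()}")

    est = fit.fe_params.reindex(predictors)
    se = fit.bse_fe.reindex(predictors)
    tvals = est / se
    n_subj = df.subject_id.nunique()
    if df_method == "between_within":
        # predictors vary within subject across ROIs
        dof = len(df) - n_subj - len(predictors)
        pvals = 2 * sps.t.sf(np.abs(tvals), dof)
    elif df_method == "normal":
        pvals = 2 * sps.norm.sf(np.abs(tvals))
    else:
        raise ValueError(f"unknown df_method {df_method!r}")

    table = pd.DataFrame(
        {"estimate": est, "se": se, "t": tvals, "p": pvals}, index=list(predictors)
    )

    # predicted-fit lines with the other covariates held at their means
    lines = []
    means = df[list(predictors)].mean()
    intercept = fit.fe_params["const"]
    for pred in predictors:
        xs = np.linspace(df[pred].min(), df[pred].max(), 50)
        yhat = np.full_like(xs, intercept)
        for other in predictors:
            if other == pred:
                yhat = yhat + est[other] * xs
            else:
                yhat = yhat + est[other] * means[other]
        lines.append(pd.DataFrame({"predictor": pred, "x": xs, "fitted": yhat}))
    fit_lines = pd.concat(lines, ignore_index=True)

    return AssociationResult(table, outcome, n_subj, len(df), variance, fit_lines)


def regional_group_map(
    table: pd.DataFrame,
    measure: str,
    q: float = 0.10,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-ROI unpaired t-map (patient vs control) with a BH/FDR mask.

    Returns a DataFrame indexed by ROI with columns t, p and significant
    (Benjamini--Hochberg across ROIs at level ``q``).
    """
    out = []
    for roi, sub in table.groupby("roi", sort=True):
        a = sub.loc[sub.group == "patient", measure].to_numpy(float)
        b = sub.loc[sub.group == "control", measure].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"ROI {roi} lacks at least 2 subjects per group")
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
        out.append((roi, float(t), float(p)))
    df = pd.DataFrame(out, columns=["roi", "t", "p"]).set_index("roi")
    df["significant"] = multipletests(df.p.to_numpy(), alpha=q, method="fdr_bh")[0]
    return df
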