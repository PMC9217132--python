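"""Decomposition of proteinopathy effects on band power into direct and
time-constant-mediated parts.

Product-of-coefficients mediation: with treatment T (a SUVR), mediator M (a
time-constant z-score) and outcome Y (a band-power z-score),

    path a:      M ~ T (+ covariates)
    paths b, c': Y ~ T + M (+ covariates)
    total c:     Y ~ T (+ covariates)

indirect = a*b, direct = c', and for ordinary least squares on a common
complete-case dataset the identity total = direct + indirect holds exactly.
Uncertainty comes from the Sobel approximation or a cluster bootstrap that
resamples subjects (keeping each subject's ROIs together).  A mixed-model
variant swaps each regression for a subject-random-intercept model; its
decomposition is only approximately additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = ["MediationSpec", "MediationResult", "mediate", "HYPOTHESES", "run_hypotheses"]


@dataclass(frozen=True)
class MediationSpec:
    """One mediation decomposition to estimate."""

    outcome: str
    treatment: str
    mediator: str
    covariates: tuple[str, ...] = ()
    estimator: str = "ols_product"
    ci_method: str = "sobel"
    n_boot: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mediator == self.treatment or self.outcome == self.mediator:
            raise ValueError("outcome, treatment and mediator must be distinct")
        if self.estimator not in ("ols_product", "mixed_product"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.ci_method not in ("sobel", "bootstrap"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        if self.ci_method == "bootstrap" and self.n_boot < 100:
            raise ValueError("bootstrap requires n_boot >= 100")


@dataclass(frozen=True)
class Effect:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class MediationResult:
    """Total, direct and mediated effect for one hypothesis."""

    spec: MediationSpec
    total: Effect
    direct: Effect
    indirect: Effect
    path_a: Effect
    path_b: Effect
    n_obs: int
    n_subjects: int

    def to_row(self) -> dict:
        row = {
            "outcome": self.spec.outcome,
            "treatment": self.spec.treatment,
            "mediator": self.spec.mediator,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }
        for name in ("total", "direct", "indirect", "path_a", "path_b"):
            eff: Effect = getattr(self, name)
            row |= {
                f"{name}": eff.estimate,
                f"{name}_se": eff.se,
                f"{name}_ci_low": eff.ci_low,
                f"{name}_ci_high": eff.ci_high,
                f"{name}_p": eff.p,
            }
        return row


def _regress(y, X, groups, mixed: bool):
    """Slopes and SEs of y ~ 1 + X (optionally with subject random intercept)."""
    exog = sm.add_constant(X)
    if mixed:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
        # fe_params is a Series or ndarray depending on the exog container
        return np.asarray(fit.fe_params)[1:], np.asarray(fit.bse_fe)[1:]
    fit = sm.OLS(y, exog).fit()
    return fit.params[1:], fit.bse[1:]


def _effects(df: pd.DataFrame, spec: MediationSpec) -> tuple[float, float, float, float, float, float, float, float]:
    """(a, se_a, b, se_b, direct, se_direct, total, se_total)."""
    mixed = spec.estimator == "mixed_product"
    covs = [df[c].to_numpy(float) for c in spec.covariates]
    t = df[spec.treatment].to_numpy(float)
    m = df[spec.mediator].to_numpy(float)
    y = df[spec.outcome].to_numpy(float)
    g = df["subject_id"].to_numpy()

    est, se = _regress(m, np.column_stack([t, *covs]), g, mixed)
    a, se_a = est[0], se[0]
    est, se = _regress(y, np.column_stack([t, m, *covs]), g, mixed)
    direct, se_direct, b, se_b = est[0], se[0], est[1], se[1]
    est, se = _regress(y, np.column_stack([t, *covs]), g, mixed)
    total, se_total = est[0], se[0]
    return a, se_a, b, se_b, direct, se_direct, total, se_total


def mediate(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Estimate one mediation decomposition on complete cases."""
    cols = [spec.outcome, spec.treatment, spec.mediator, *spec.covariates]
    df = data.dropna(subset=cols)
    if "group" in df.columns:
        df = df[df.group == "patient"]
    if len(df) < 10:
        raise ValueError(f"only {len(df)} complete cases; need at least 10")
    r_tm = np.corrcoef(df[spec.treatment], df[spec.mediator])[0, 1]
    if abs(r_tm) > 0.999:
        raise ValueError(f"treatment and mediator are collinear (r = {r_tm:.4f})")

    a, se_a, b, se_b, direct, se_direct, total, se_total = _effects(df, spec)
    indirect = a * b
    zcrit = sps.norm.ppf(0.975)

    if spec.ci_method == "sobel":
        se_ind = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
        ci = (indirect - zcrit * se_ind, indirect + zcrit * se_ind)
        p_ind = 2 * sps.norm.sf(abs(indirect) / se_ind) if se_ind > 0 else np.nan
    else:
        rng = np.random.default_rng(spec.seed)
        subjects = df.subject_id.unique()
        by_subj = {s: sub for s, sub in df.groupby("subject_id")}
        draws = np.empty(spec.n_boot)
        for i in range(spec.n_boot):
            picks = rng.choice(subjects, size=len(subjects), replace=True)
            boot = pd.concat([by_subj[s] for s in picks], ignore_index=True)
            ab, _, bb, *_ = _effects(boot, spec)
            draws[i] = ab * bb
        se_ind = float(np.std(draws, ddof=1))
        ci = tuple(np.quantile(draws, [0.025, 0.975]))
        # two-sided percentile-bootstrap p
        frac = np.mean(draws > 0) if indirect > 0 else np.mean(draws < 0)
        p_ind = float(np.clip(2 * (1 - frac), 0.0, 1.0))

    def eff(est, se):
        p = 2 * sps.norm.sf(abs(est) / se) if se > 0 else np.nan
        return Effect(float(est), float(se), float(est - zcrit * se), float(est + zcrit * se), float(p))

    return MediationResult(
        spec=spec,
        total=eff(total, se_total),
        direct=eff(direct, se_direct),
        indirect=Effect(float(indirect), se_ind, float(ci[0]), float(ci[1]), float(p_ind)),
        path_a=eff(a, se_a),
        path_b=eff(b, se_b),
        n_obs=len(df),
        n_subjects=df.subject_id.nunique(),
    )


#: The five canonical decompositions: amyloid-beta acting through the
#: inhibitory time-constant on delta-theta, alpha and beta power, and tau
#: acting through the excitatory time-constant on alpha and beta power.
HYPOTHESES: tuple[tuple[str, str, str, str], ...] = (
    ("delta_theta_z", "ab_suvr", "tau_i_ms_z", "tau_suvr"),
    ("alpha_z", "ab_suvr", "tau_i_ms_z", "tau_suvr"),
    ("beta_z", "ab_suvr", "tau_i_ms_z", "tau_suvr"),
    ("alpha_z", "tau_suvr", "tau_e_ms_z", "ab_suvr"),
    ("beta_z", "tau_suvr", "tau_e_ms_z", "ab_suvr"),
)


def run_hypotheses(
    data: pd.DataFrame,
    estimator: str = "ols_product",
    ci_method: str = "sobel",
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the five canonical mediation decompositions; tidy results table."""
    missing = sorted(
        {c for h in HYPOTHESES for c in h} - set(data.columns)
    )
    if missing:
        raise KeyError(f"data is missing required measures: {missing}")
    rows = []
    for outcome, treatment, mediator, covariate in HYPOTHESES:
        spec = MediationSpec(
            outcome, treatment, mediator, (covariate,),
            estimator=estimator, ci_method=ci_method, n_boot=n_boot, seed=seed,
        )
        rows.append(mediate(data, spec).to_row())
    return pd.DataFrame(rows)
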