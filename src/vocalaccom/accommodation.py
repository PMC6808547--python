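"""Mixed-effects modeling of ln vocal distance over exposure time.

Fits, per call type, ``ln_distance ~ sex + week + sex:week`` with a random
intercept per individual (ML estimation); drops a non-significant interaction
and refits; reports t-based fixed-effect tests, a likelihood-ratio test
against the intercept+random-effects null, Nakagawa marginal/conditional R²,
the pre-vs-5+-weeks window comparison, and bootstrapped weekly summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "AccommodationModel",
    "PrePostResult",
    "fit_accommodation_lme",
    "lrt_vs_null",
    "nakagawa_r2",
    "compare_prepost",
    "weekly_bootstrap_summary",
]

#: female is the reference sex level throughout
_SEX_REF = "F"


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if "sex_male" not in df.columns:
        df["sex_male"] = (df["sex"].astype(str) == "M").astype(float)
    return df


@dataclass
class AccommodationModel:
    """Fitted accommodation model for one call type."""

    call_type: str | None
    terms: pd.DataFrame  # index: term; columns: B, SE, t, p
    re_variance: float
    resid_variance: float
    loglik: float
    r2_marginal: float
    r2_conditional: float
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    n_obs: int
    n_individuals: int
    interaction_kept: bool
    # sex-averaged exposure-time slope: equals the week coefficient in the
    # reduced model; with a retained interaction it averages the two sexes'
    # slopes (week + interaction/2), the population-level summary — the week
    # main effect alone is then the female slope and is not interpreted on
    # its own (only the highest-order term containing a predictor is)
    week_slope: float = float("nan")
    week_slope_se: float = float("nan")
    singular_re: bool = False
    result: object = field(default=None, repr=False)  # statsmodels fit


class _BoundaryFit:
    """Zero-variance boundary fit: OLS presented through the MixedLM surface.

    Used when the random-intercept variance estimate collapses to zero and
    the mixed-model Hessian becomes singular; at the boundary the ML
    solution coincides with ordinary least squares.
    """

    def __init__(self, ols_res):
        self._ols = ols_res
        self.fe_params = ols_res.params
        self.bse_fe = ols_res.bse
        self.llf = float(ols_res.llf)
        n = int(ols_res.nobs)
        # ML residual variance (OLS llf is already the ML Gaussian loglik)
        self.scale = float(np.sum(ols_res.resid**2) / n)
        self.cov_re = np.zeros((1, 1))
        self.model = ols_res.model
        self.cov_params = ols_res.cov_params
        self.boundary = True


def _fit_mixedlm(df: pd.DataFrame, formula: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["caller_id"])
        try:
            return model.fit(reml=False)
        except np.linalg.LinAlgError:
            pass
        try:
            return model.fit(reml=False, method="lbfgs")
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular random-effect variance; falling back to the "
                "zero-variance boundary (OLS) fit"
            )
            return _BoundaryFit(smf.ols(formula, df).fit())


def _term_table(res, n_obs: int) -> pd.DataFrame:
    """t statistics with residual df (n_obs - n_fixed)."""
    fe = res.fe_params
    se = res.bse_fe
    t = fe / se
    df_resid = max(n_obs - len(fe), 1)
    p = 2 * stats.t.sf(np.abs(t), df_resid)
    return pd.DataFrame({"B": fe, "SE": se, "t": t, "p": p})


def nakagawa_r2(res) -> tuple[float, float]:
    """Marginal and conditional R² from the variance decomposition.

    ``R²_m = var_f / (var_f + var_r + var_e)`` and
    ``R²_c = (var_f + var_r) / (var_f + var_r + var_e)`` where ``var_f`` is
    the sample variance (ddof=1) of the fixed-effect linear predictor,
    ``var_r`` the random-intercept variance and ``var_e`` the residual
    variance.
    """
    exog = res.model.exog
    pred_fixed = exog @ res.fe_params
    var_f = float(np.var(pred_fixed, ddof=1))
    var_r = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    var_e = float(res.scale)
    total = var_f + var_r + var_e
    if total <= 0:
        raise ValueError("zero total variance; R² undefined")
    return var_f / total, (var_f + var_r) / total


def lrt_vs_null(res_full, res_null) -> tuple[float, int, float]:
    """Likelihood-ratio test of a full ML fit against the intercept-only null.

    Both fits must use the same rows; chi2 = 2*(LL_full - LL_null), df =
    difference in fixed-effect count.
    """
    if res_full.model.exog.shape[0] != res_null.model.exog.shape[0]:
        raise ValueError("full and null models were fit on different rows")
    df = res_full.model.exog.shape[1] - res_null.model.exog.shape[1]
    if df < 0:
        raise ValueError("models are not nested (null has more fixed effects)")
    chi2 = max(0.0, 2.0 * (res_full.llf - res_null.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p


def fit_accommodation_lme(
    records: pd.DataFrame,
    call_type: str | None = None,
    *,
    drop_ns_interaction: bool = True,
    alpha: float = 0.05,
) -> AccommodationModel:
    """Fit the accommodation model for one call type's distance records.

    ML fit of ``ln_distance ~ sex + week + sex:week`` with a random
    intercept per caller.  If the sex-by-week interaction is non-significant
    (p >= alpha, t test on residual df) the model is refit without it and
    the reduced model is reported (``interaction_kept=False``).
    """
    df = _prepare(records)
    if call_type is not None:
        df = df[df["call_type"] == call_type]
    if df["caller_id"].nunique() < 2:
        raise ValueError("need >= 2 individuals")
    if df["week"].nunique() < 2:
        raise ValueError("need >= 2 distinct weeks")
    n_obs = len(df)

    full = "ln_distance ~ sex_male + week + sex_male:week"
    res = _fit_mixedlm(df, full)
    terms = _term_table(res, n_obs)
    interaction_kept = True
    if drop_ns_interaction and terms.loc["sex_male:week", "p"] >= alpha:
        res = _fit_mixedlm(df, "ln_distance ~ sex_male + week")
        terms = _term_table(res, n_obs)
        interaction_kept = False

    if interaction_kept:
        # sex-averaged slope = B_week + B_int/2, SE from the fe covariance
        cov = np.asarray(res.cov_params())
        names = list(res.fe_params.index)
        iw, ii = names.index("week"), names.index("sex_male:week")
        week_slope = float(res.fe_params["week"] + 0.5 * res.fe_params["sex_male:week"])
        var = cov[iw, iw] + 0.25 * cov[ii, ii] + cov[iw, ii]
        week_slope_se = float(np.sqrt(var))
    else:
        week_slope = float(terms.loc["week", "B"])
        week_slope_se = float(terms.loc["week", "SE"])

    res_null = _fit_mixedlm(df, "ln_distance ~ 1")
    chi2, df_lrt, p_lrt = lrt_vs_null(res, res_null)
    r2m, r2c = nakagawa_r2(res)
    re_var = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    singular = re_var <= 1e-10
    if singular:
        warnings.warn("random-intercept variance at the zero boundary")
    return AccommodationModel(
        call_type=call_type,
        terms=terms,
        re_variance=re_var,
        resid_variance=float(res.scale),
        loglik=float(res.llf),
        r2_marginal=r2m,
        r2_conditional=r2c,
        lrt_chi2=chi2,
        lrt_df=df_lrt,
        lrt_p=p_lrt,
        n_obs=n_obs,
        n_individuals=int(df["caller_id"].nunique()),
        interaction_kept=interaction_kept,
        week_slope=week_slope,
        week_slope_se=week_slope_se,
        singular_re=singular,
        result=res,
    )


@dataclass
class PrePostResult:
    """Pre- vs post-translocation window comparison (ordinary linear model)."""

    call_type: str | None
    condition_effect: float  # post minus pre, ln-distance units
    condition_se: float
    condition_t: float
    condition_p: float
    terms: pd.DataFrame
    n_pre: int
    n_post: int


def compare_prepost(
    records: pd.DataFrame,
    call_type: str | None = None,
    *,
    pre_condition: str = "NewPhys",
    post_condition: str = "NewSoc",
    post_min_week: float = 5.0,
) -> PrePostResult:
    """Linear model of ln distance: immediately-before vs 5+ weeks after.

    The pre window is the quarantine condition (last weeks before the second
    translocation); the post window is weeks >= 5 of the new social
    environment, when transient environmental effects have decayed.  Fits
    ``ln_distance ~ post * sex`` by OLS and reports the condition effect.
    """
    df = _prepare(records)
    if call_type is not None:
        df = df[df["call_type"] == call_type]
    pre = df[df["condition"] == pre_condition]
    post = df[(df["condition"] == post_condition) & (df["week"] >= post_min_week)]
    if pre.empty or post.empty:
        raise ValueError(
            f"empty window: {len(pre)} pre ({pre_condition!r}), "
            f"{len(post)} post ({post_condition!r} weeks >= {post_min_week})"
        )
    sub = pd.concat([pre.assign(post=0.0), post.assign(post=1.0)])
    res = smf.ols("ln_distance ~ post * sex_male", sub).fit()
    terms = pd.DataFrame(
        {"B": res.params, "SE": res.bse, "t": res.tvalues, "p": res.pvalues}
    )
    return PrePostResult(
        call_type=call_type,
        condition_effect=float(res.params["post"]),
        condition_se=float(res.bse["post"]),
        condition_t=float(res.tvalues["post"]),
        condition_p=float(res.pvalues["post"]),
        terms=terms,
        n_pre=len(pre),
        n_post=len(post),
    )


def weekly_bootstrap_summary(
    records: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
    *,
    min_calls: int = 5,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per (caller, call type, week) mean ln distance with bootstrap 95% CI.

    Percentile bootstrap over calls within each cell; cells below the
    five-call minimum are excluded, consistent with the weekly inclusion
    rule.
    """
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    for (caller, ct, week), grp in records.groupby(
        ["caller_id", "call_type", "week"], sort=True
    ):
        v = grp["ln_distance"].to_numpy()
        if v.size < min_calls:
            continue
        idx = rng.integers(0, v.size, size=(n_boot, v.size))
        boot_means = v[idx].mean(axis=1)
        rows.append(
            {
                "caller_id": caller,
                "call_type": ct,
                "week": week,
                "n_calls": v.size,
                "mean_ln_distance": float(v.mean()),
                "ci_low": float(np.quantile(boot_means, lo_q)),
                "ci_high": float(np.quantile(boot_means, hi_q)),
            }
        )
    return pd.DataFrame(rows)
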