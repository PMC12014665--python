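"""Group statistics: random-intercept mixed models, likelihood-ratio tests,
Welch's t on participant means, effect sizes and conditional R^2.

The central comparison is between nested maximum-likelihood mixed models for
a VEMP outcome (p1-n1 latency in ms, or p1-n1 amplitude in dB RL) with a
per-participant random intercept:

    null:  outcome ~ 1 [+ stimulus_level] + (1 | participant)
    alt:   outcome ~ 1 [+ stimulus_level] + sex + (1 | participant)

The p-value is the chi-squared upper tail of 2 * (logLik_alt - logLik_null).
Models are fitted by ML (not REML) because the compared models differ in
their fixed effects. An equivalent, simpler route averages the repeated
measures per participant and applies Welch's unequal-variances t-test; both
are provided because the power layer builds on the Welch route.

Sex is coded 0 = female, 1 = male, so a positive sex coefficient means a
longer latency (or larger amplitude) in men.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .exceptions import CvempError, ConfigurationError

__all__ = [
    "LMMFit",
    "WelchResult",
    "fit_lmm",
    "likelihood_ratio_test",
    "chi2_upper_tail",
    "participant_means",
    "welch_from_summary",
    "welch_from_samples",
    "welch_test",
    "cohens_d",
    "cohens_d_pooled",
    "conditional_r2",
    "sex_difference_lrt",
]

_log = logging.getLogger(__name__)

RESPONSES = {
    "p1n1_latency": "p1n1_latency",
    "p1_latency": "p1_latency",
    "n1_latency": "n1_latency",
    "p1n1_amplitude": "db_rl",
}


@dataclass
class LMMFit:
    """Summary of one ML random-intercept fit."""

    formula: str
    fixed_effects: pd.DataFrame  # index term, columns estimate / se
    random_intercepts: pd.Series  # per-participant BLUP deviations
    residual_variance: float
    random_intercept_variance: float
    log_likelihood: float
    n_obs: int
    n_groups: int
    n_fixed_params: int
    fitted_fixed: np.ndarray  # fixed-effect predictions, for conditional R^2
    singular: bool


def _prepare(data: pd.DataFrame, response: str) -> tuple[pd.DataFrame, str]:
    if response not in RESPONSES:
        raise ConfigurationError(f"unknown response {response!r}; "
                                 f"one of {sorted(RESPONSES)}")
    col = RESPONSES[response]
    df = data.copy()
    if "sex_male" not in df:
        df["sex_male"] = (df["sex"].astype(str).str.upper()
                          .map({"M": 1.0, "MALE": 1.0, "F": 0.0, "FEMALE": 0.0}))
    df = df.dropna(subset=[col])
    return df, col


def fit_lmm(data: pd.DataFrame, response: str = "p1n1_latency",
            include_sex: bool = True, include_stimulus: bool = False) -> LMMFit:
    """ML fit of ``response ~ [stimulus_level] [sex] + (1 | participant)``.

    ``data`` is the long-format latency dataset (one row per non-null pick).
    Singular fits (random-intercept variance collapsing to zero) are flagged
    on the result, not raised.
    """
    df, col = _prepare(data, response)
    per_sex = df.groupby("sex_male")["participant_id"].nunique()
    if include_sex and (len(per_sex) < 2 or per_sex.min() < 2):
        raise ConfigurationError("need at least 2 participants per sex")
    terms = ["1"]
    if include_stimulus:
        terms.append("stimulus_level")
    if include_sex:
        terms.append("sex_male")
    formula = f"{col} ~ {' + '.join(terms)}"
    model = smf.mixedlm(formula, df, groups=df["participant_id"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        result = model.fit(reml=False)
    var_re = float(result.cov_re.iloc[0, 0])
    singular = bool(var_re < 1e-8 * max(result.scale, 1e-12)) or not result.converged
    fixed = pd.DataFrame({
        "estimate": result.fe_params,
        "se": result.bse_fe,
    })
    re_blups = pd.Series({g: float(v.iloc[0]) for g, v in result.random_effects.items()})
    exog = result.model.exog
    fitted_fixed = exog @ result.fe_params.to_numpy()
    return LMMFit(
        formula=formula,
        fixed_effects=fixed,
        random_intercepts=re_blups,
        residual_variance=float(result.scale),
        random_intercept_variance=var_re,
        log_likelihood=float(result.llf),
        n_obs=int(result.nobs),
        n_groups=int(df["participant_id"].nunique()),
        n_fixed_params=len(result.fe_params),
        fitted_fixed=np.asarray(fitted_fixed, dtype=float),
        singular=singular,
    )


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail (survival) probability of the chi-squared distribution."""
    if x < 0:
        raise ConfigurationError("chi-squared statistic must be >= 0")
    if df < 1:
        raise ConfigurationError("df must be >= 1")
    return float(stats.chi2.sf(x, df))


def likelihood_ratio_test(null_fit: LMMFit, alt_fit: LMMFit
                          ) -> tuple[float, int, float]:
    """LRT of nested ML mixed models: (chi2, df, p).

    chi2 = 2 * (logLik_alt - logLik_null); df is the fixed-parameter count
    difference; p is the chi-squared upper tail.
    """
    if null_fit.n_obs != alt_fit.n_obs:
        raise ConfigurationError("models were fitted on different rows")
    df = alt_fit.n_fixed_params - null_fit.n_fixed_params
    if df < 0:
        raise ConfigurationError("null model must be nested in the alternative")
    chi2 = max(0.0, 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood))
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, chi2_upper_tail(chi2, df)


def sex_difference_lrt(data: pd.DataFrame, response: str = "p1n1_latency",
                       include_stimulus: bool = False) -> dict:
    """Convenience: fit the nested pair and test the sex effect.

    Returns a dict with the sex coefficient (men minus women), its SE, chi2,
    df, p and both fits.
    """
    null_fit = fit_lmm(data, response, include_sex=False,
                       include_stimulus=include_stimulus)
    alt_fit = fit_lmm(data, response, include_sex=True,
                      include_stimulus=include_stimulus)
    chi2, df, p = likelihood_ratio_test(null_fit, alt_fit)
    coef = float(alt_fit.fixed_effects.loc["sex_male", "estimate"])
    se = float(alt_fit.fixed_effects.loc["sex_male", "se"])
    return {"coef": coef, "se": se, "ci_low": coef - 1.96 * se,
            "ci_high": coef + 1.96 * se, "chi2": chi2, "df": df, "p": p,
            "null_fit": null_fit, "alt_fit": alt_fit}


def participant_means(data: pd.DataFrame, response: str = "p1n1_latency"
                      ) -> pd.DataFrame:
    """Mean outcome per participant (one row each), preserving sex.

    Participants contributing no non-null picks are excluded with a logged
    warning (they have no measurable outcome to average).
    """
    df, col = _prepare(data, response)
    if "is_null" in data.columns:
        ok = set(df.loc[~df["is_null"].astype(bool), "participant_id"])
        dropped = sorted(set(data["participant_id"]) - ok)
        if dropped:
            _log.warning("excluding all-null participants: %s", ", ".join(dropped))
        df = df[~df["is_null"].astype(bool)]
    out = (df.groupby(["participant_id", "sex"], as_index=False)[col]
           .mean().rename(columns={col: "mean"}))
    return out.sort_values("participant_id", ignore_index=True)


@dataclass
class WelchResult:
    mean_f: float
    mean_m: float
    sd_f: float
    sd_m: float
    n_f: int
    n_m: int
    difference: float  # men minus women
    t_statistic: float
    df: float  # Welch-Satterthwaite, fractional
    p_value: float
    ci_low: float
    ci_high: float


def welch_from_summary(mean_f: float, sd_f: float, n_f: int,
                       mean_m: float, sd_m: float, n_m: int,
                       conf_level: float = 0.95) -> WelchResult:
    """Welch's unequal-variances t-test from printed group summaries.

    The difference is men minus women; df is the fractional
    Welch-Satterthwaite value (round only for display).
    """
    if n_f < 2 or n_m < 2:
        raise ConfigurationError("each group needs n >= 2")
    if sd_f <= 0 or sd_m <= 0:
        raise ConfigurationError("group SDs must be positive")
    vf, vm = sd_f**2 / n_f, sd_m**2 / n_m
    diff = mean_m - mean_f
    se = np.sqrt(vf + vm)
    t = diff / se
    df = (vf + vm) ** 2 / (vf**2 / (n_f - 1) + vm**2 / (n_m - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, df)
    return WelchResult(mean_f=mean_f, mean_m=mean_m, sd_f=sd_f, sd_m=sd_m,
                       n_f=n_f, n_m=n_m, difference=diff, t_statistic=float(t),
                       df=float(df), p_value=float(p),
                       ci_low=float(diff - tcrit * se),
                       ci_high=float(diff + tcrit * se))


def welch_from_samples(samples_f, samples_m, conf_level: float = 0.95) -> WelchResult:
    """Welch's t-test from raw per-participant values (delegates to the
    summary form, so the two entry points agree exactly)."""
    f = np.asarray(samples_f, dtype=float)
    m = np.asarray(samples_m, dtype=float)
    return welch_from_summary(f.mean(), f.std(ddof=1), f.size,
                              m.mean(), m.std(ddof=1), m.size, conf_level)


def welch_test(means: pd.DataFrame, conf_level: float = 0.95) -> WelchResult:
    """Welch's t-test on a participant-means table (columns sex, mean)."""
    f = means.loc[means["sex"].astype(str).str.upper().str.startswith("F"), "mean"]
    m = means.loc[means["sex"].astype(str).str.upper().str.startswith("M"), "mean"]
    return welch_from_samples(f.to_numpy(), m.to_numpy(), conf_level)


def cohens_d(t: float, df: float) -> float:
    """Effect size from a (mixed-model or two-sample) t statistic: 2t/sqrt(df)."""
    if df <= 0:
        raise ConfigurationError("df must be positive")
    return 2.0 * t / np.sqrt(df)


def cohens_d_pooled(mean_f: float, mean_m: float, sd_f: float, sd_m: float) -> float:
    """Two-sample Cohen's d with the equal-n pooled SD sqrt((sd_f^2+sd_m^2)/2)."""
    pooled = np.sqrt((sd_f**2 + sd_m**2) / 2.0)
    return (mean_m - mean_f) / pooled


def conditional_r2(fit: LMMFit) -> float:
    """Conditional R^2 of a random-intercept fit (Nakagawa-Schielzeth form):

    (var_fixed + var_random) / (var_fixed + var_random + var_residual),
    with var_fixed the variance of the fixed-effect predictions over the
    data.
    """
    var_fixed = float(np.var(fit.fitted_fixed))
    total = var_fixed + fit.random_intercept_variance + fit.residual_variance
    if total <= 0:
        raise CvempError("conditional R^2 undefined: zero total variance")
    return (var_fixed + fit.random_intercept_variance) / total
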