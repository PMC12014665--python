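"""Random-effects meta-analysis of sex differences in p1-n1 latency, with
moderator meta-regression on stimulus presentation count.

Studies enter as summary rows (group means, SDs, counts). Each study's
effect is the raw mean difference md = mean_m - mean_f (positive = longer
latency in men) with variance sd_f^2/n_f + sd_m^2/n_m. Pooling uses
inverse-variance weights with a DerSimonian-Laird between-study variance
tau^2 (REML available as an option) and Wald confidence intervals.
Meta-regression fits md on a continuous study-level moderator by weighted
least squares with a method-of-moments residual tau^2, as the standard
mixed-effects meta-regression does; studies missing the moderator are
excluded.

Repeated-measure rows (both ears, multiple stimuli) enter as separate
studies without a correlation adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError

__all__ = [
    "StudySummary",
    "MetaResult",
    "study_effect",
    "pool_random_effects",
    "meta_regression",
    "read_studies",
    "forest_table",
]


@dataclass(frozen=True)
class StudySummary:
    """Per-study group summaries of p1-n1 latency (ms) by sex."""

    study_label: str
    n_f: int
    n_m: int
    mean_f: float
    mean_m: float
    sd_f: float
    sd_m: float
    presentations: float | None = None  # stimulus count; None when unreported
    stimulus_group: str = "other"  # air-conducted / body-conducted / other

    def __post_init__(self) -> None:
        if self.n_f < 2 or self.n_m < 2:
            raise ConfigurationError(f"{self.study_label}: group counts must be >= 2")
        if self.sd_f <= 0 or self.sd_m <= 0:
            raise ConfigurationError(f"{self.study_label}: group SDs must be > 0")


@dataclass
class MetaResult:
    pooled_md: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float
    weights: pd.Series  # normalized to sum 1
    k: int
    subgroups: dict = field(default_factory=dict)
    moderator: str | None = None
    moderator_slope: float | None = None
    moderator_se: float | None = None
    moderator_p: float | None = None
    intercept: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = self.weights.to_dict()
        d["subgroups"] = {k: {kk: vv for kk, vv in v.items() if kk != "weights"}
                          for k, v in self.subgroups.items()}
        return d


def study_effect(study: StudySummary) -> tuple[float, float]:
    """(mean difference men - women, sampling variance) for one study."""
    md = study.mean_m - study.mean_f
    var = study.sd_f**2 / study.n_f + study.sd_m**2 / study.n_m
    return md, var


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """DerSimonian-Laird tau^2 and Cochran's Q for intercept-only pooling."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu_fe) ** 2))
    k = len(y)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / c) if k > 1 and c > 0 else 0.0
    return tau2, Q


def _reml_tau2(y: np.ndarray, v: np.ndarray, tol: float = 1e-10,
               max_iter: int = 200) -> float:
    """REML tau^2 for intercept-only pooling (fixed-point iteration)."""
    tau2 = _dl_tau2(y, v)[0]
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        new = (np.sum(w**2 * ((y - mu) ** 2 - v)) / np.sum(w**2)
               + 1.0 / np.sum(w))
        new = max(0.0, float(new))
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    return tau2


def _pool(y: np.ndarray, v: np.ndarray, tau2_method: str) -> dict:
    if tau2_method == "dl":
        tau2, Q = _dl_tau2(y, v)
    elif tau2_method == "reml":
        tau2 = _reml_tau2(y, v)
        Q = _dl_tau2(y, v)[1]
    elif tau2_method == "fe":  # fixed-effect: tau2 forced to zero
        tau2, Q = 0.0, _dl_tau2(y, v)[1]
    else:
        raise ConfigurationError(f"unknown tau2 method {tau2_method!r}")
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    k = len(y)
    I2 = float(max(0.0, (Q - (k - 1)) / Q)) if Q > 0 and k > 1 else 0.0
    return {"pooled_md": pooled, "se": se,
            "ci_low": pooled - 1.959963984540054 * se,
            "ci_high": pooled + 1.959963984540054 * se,
            "tau2": float(tau2), "Q": Q, "I2": I2, "k": k,
            "weights": w / np.sum(w)}


def pool_random_effects(studies: list[StudySummary], tau2_method: str = "dl",
                        by_stimulus_group: bool = False) -> MetaResult:
    """Random-effects pooling of study mean differences.

    A single study pools to itself with tau^2 = 0. With
    ``by_stimulus_group=True`` per-group poolings are reported alongside the
    overall one.
    """
    if not studies:
        raise ConfigurationError("need at least one study")
    y, v = map(np.asarray, zip(*(study_effect(s) for s in studies)))
    labels = [s.study_label for s in studies]
    res = _pool(y, v, tau2_method)
    weights = pd.Series(res.pop("weights"), index=labels)
    out = MetaResult(weights=weights, **res)
    if by_stimulus_group:
        for grp in sorted({s.stimulus_group for s in studies}):
            sub = [s for s in studies if s.stimulus_group == grp]
            ys, vs = map(np.asarray, zip(*(study_effect(s) for s in sub)))
            r = _pool(ys, vs, tau2_method)
            r.pop("weights")
            out.subgroups[grp] = r
    return out


def meta_regression(studies: list[StudySummary], moderator: str = "presentations",
                    tau2_method: str = "mm") -> MetaResult:
    """Mixed-effects meta-regression of the mean difference on a moderator.

    Weighted least squares with weights 1/(v_i + tau^2), where the residual
    tau^2 is the method-of-moments estimate from the weighted residual sum
    of squares (the DerSimonian-Laird generalisation to a design matrix).
    The slope is tested with a Wald z statistic. Studies with a missing
    moderator are excluded; at least three complete studies are required.
    """
    rows = [(s, getattr(s, moderator)) for s in studies]
    complete = [(s, x) for s, x in rows if x is not None and not (
        isinstance(x, float) and math.isnan(x))]
    if len(complete) < 3:
        raise ConfigurationError("meta-regression needs >= 3 studies with the moderator")
    y, v = map(np.asarray, zip(*(study_effect(s) for s, _ in complete)))
    x = np.asarray([float(m) for _, m in complete])
    if np.ptp(x) == 0:
        raise ConfigurationError("moderator is constant; slope undefined")
    labels = [s.study_label for s, _ in complete]
    X = np.column_stack([np.ones_like(x), x])
    k, p = X.shape

    # method-of-moments residual tau^2 from the fixed-effect WLS residuals
    W = np.diag(1.0 / v)
    XtWX_inv = np.linalg.inv(X.T @ W @ X)
    H = X @ XtWX_inv @ X.T @ W
    resid = y - H @ y
    QE = float(resid @ W @ resid)
    trace_term = np.trace(W) - np.trace(XtWX_inv @ X.T @ W @ W @ X)
    tau2 = max(0.0, (QE - (k - p)) / trace_term) if trace_term > 0 else 0.0

    wstar = 1.0 / (v + tau2)
    Ws = np.diag(wstar)
    cov = np.linalg.inv(X.T @ Ws @ X)
    beta = cov @ X.T @ Ws @ y
    se = np.sqrt(np.diag(cov))
    z = beta[1] / se[1]
    pval = float(2.0 * stats.norm.sf(abs(z)))

    fitted = X @ beta
    pooled_at_mean = float(np.average(fitted, weights=wstar))
    I2 = float(max(0.0, (QE - (k - p)) / QE)) if QE > 0 else 0.0
    return MetaResult(
        pooled_md=pooled_at_mean,
        se=float(np.sqrt(1.0 / np.sum(wstar))),
        ci_low=float(beta[1] - 1.959963984540054 * se[1]),
        ci_high=float(beta[1] + 1.959963984540054 * se[1]),
        tau2=float(tau2), Q=QE, I2=I2,
        weights=pd.Series(wstar / np.sum(wstar), index=labels),
        k=k, moderator=moderator,
        moderator_slope=float(beta[1]), moderator_se=float(se[1]),
        moderator_p=pval, intercept=float(beta[0]),
    )


_STUDY_COLUMNS = ["study_label", "n_f", "n_m", "mean_f", "mean_m", "sd_f", "sd_m"]


def read_studies(path) -> list[StudySummary]:
    """Read a study-summary CSV (columns as in :class:`StudySummary`)."""
    df = pd.read_csv(path)
    missing = [c for c in _STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"studies CSV missing columns: {missing}")
    out = []
    for _, r in df.iterrows():
        pres = r.get("presentations")
        if pres is not None and isinstance(pres, float) and math.isnan(pres):
            pres = None
        out.append(StudySummary(
            study_label=str(r["study_label"]),
            n_f=int(r["n_f"]), n_m=int(r["n_m"]),
            mean_f=float(r["mean_f"]), mean_m=float(r["mean_m"]),
            sd_f=float(r["sd_f"]), sd_m=float(r["sd_m"]),
            presentations=None if pres is None else float(pres),
            stimulus_group=str(r.get("stimulus_group", "other")),
        ))
    return out


def forest_table(studies: list[StudySummary], result: MetaResult) -> str:
    """Plain-text forest table of study effects and the pooled estimate."""
    lines = [f"{'study':<24}{'md (ms)':>9}{'95% CI':>20}{'weight':>9}"]
    for s in studies:
        md, var = study_effect(s)
        half = 1.959963984540054 * math.sqrt(var)
        w = result.weights.get(s.study_label, float("nan"))
        lines.append(f"{s.study_label:<24}{md:>9.2f}"
                     f"{f'[{md - half:.2f}, {md + half:.2f}]':>20}{w:>9.3f}")
    lines.append("-" * len(lines[0]))
    lines.append(f"{'RE pooled':<24}{result.pooled_md:>9.2f}"
                 f"{f'[{result.ci_low:.2f}, {result.ci_high:.2f}]':>20}"
                 f"{'':>9}")
    lines.append(f"tau^2 = {result.tau2:.3f}, Q = {result.Q:.2f}, "
                 f"I^2 = {100 * result.I2:.0f}%")
    return "\n".join(lines)
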