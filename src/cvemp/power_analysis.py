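"""Two-sample power from the noncentral t, and design-reduction simulation.

The analytic route follows the G*Power convention for a two-tailed
two-sample t-test: pooled-SD effect size d, df = 2n - 2 and noncentrality
delta = d * sqrt(n/2), power = P(|T'| > t_crit). The simulation route
re-runs the full synthetic pipeline (generate -> average -> normalize ->
score -> participant means -> Welch) on cohorts with reduced presentation
counts and/or participant counts, reporting the fraction of significant
cohorts as empirical power, mirroring a modelling table of "fewer stimuli
and/or fewer participants".

Also provides the ear-canal correction for dial SPL calibrated in a 2 cc
coupler: pressure scales inversely with cavity volume, so the correction is
20*log10(2 / volume_cc) dB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic_data as sd
from .containers import ParticipantRecord
from .exceptions import ConfigurationError
from .group_stats import welch_from_samples
from .pipeline import picks_to_frame, simulate_participant_picks

__all__ = [
    "PowerRow",
    "power_two_sample_t",
    "subsample_presentations",
    "power_grid",
    "ear_canal_correction",
    "plot_power_grid",
]

_log = logging.getLogger(__name__)


def power_two_sample_t(d: float, n_per_group: int, alpha: float = 0.05,
                       two_tailed: bool = True) -> float:
    """Power of a two-sample t-test for standardized effect d, balanced n.

    df = 2n - 2 and delta = d * sqrt(n/2) (the G*Power post-hoc convention,
    pooled SD even under unequal variances).
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2")
    if d < 0:
        raise ConfigurationError("d must be >= 0")
    df = 2 * n_per_group - 2
    delta = d * np.sqrt(n_per_group / 2.0)
    if two_tailed:
        tcrit = stats.t.ppf(1 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta))
    tcrit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(tcrit, df, delta))


def subsample_presentations(record: ParticipantRecord, n_presentations: int,
                            epochs_per_sequence: int = 300) -> ParticipantRecord:
    """Keep the first ``n_presentations / 300`` sequences in acquisition order.

    Requests beyond the available sequences fall back to all of them with a
    logged warning; requests below one sequence keep the initial sequence.
    """
    k = max(1, n_presentations // epochs_per_sequence)
    seqs = record.ordered()
    if k > len(seqs):
        _log.warning("requested %d sequences but only %d available; using all",
                     k, len(seqs))
        k = len(seqs)
    return ParticipantRecord(participant_id=record.participant_id,
                             sex=record.sex, sequences=seqs[:k],
                             age=record.age,
                             background_rms=record.background_rms)


@dataclass
class PowerRow:
    """One cell of the design-reduction grid (averages over cohorts)."""

    presentations_per_participant: int
    n_total: int
    mean_f: float
    sd_f: float
    mean_m: float
    sd_m: float
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    power: float  # empirical: fraction of significant cohorts
    n_cohorts: int

    def to_dict(self) -> dict:
        return asdict(self)


def _cohort_participant_means(config: sd.GeneratorConfig, rng: np.random.Generator,
                              k_sequences: int, fast: bool) -> pd.DataFrame:
    cohort = sd.make_cohort(config, rng)
    rows = []
    for truth in cohort:
        picks = simulate_participant_picks(truth, config, rng, fast=fast)
        picks = [p for p in picks if p.sequence_order < k_sequences]
        frame = picks_to_frame(picks, config.epochs_per_sequence)
        if len(frame):
            rows.append((truth.participant_id, truth.sex,
                         frame["p1n1_latency"].mean()))
    return pd.DataFrame(rows, columns=["participant_id", "sex", "mean"])


def power_grid(config: sd.GeneratorConfig,
               grid: list[tuple[int, int]],
               n_cohorts: int = 1000,
               rng: np.random.Generator | int | None = None,
               alpha: float = 0.05,
               fast: bool = True,
               balanced_first_k: bool = True) -> list[PowerRow]:
    """Empirical power over a (presentations, n_total) design grid.

    For every cell, ``n_cohorts`` cohorts are simulated; each is reduced to
    the first ``presentations/300`` sequences per participant and a balanced
    subset of participants (first k of each sex by default, random subset
    otherwise), then pushed through peak scoring, participant means and
    Welch's t-test. Reported means/SDs/CI/p are averages over cohorts; power
    is the fraction of cohorts with p < alpha.

    ``fast=True`` draws sequence averages directly from their exact sampling
    distribution; ``fast=False`` runs the epoch-level reference route.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[PowerRow] = []
    for presentations, n_total in grid:
        if n_total % 2:
            raise ConfigurationError("n_total must be even (balanced design)")
        k_seq = max(1, presentations // config.epochs_per_sequence)
        per_sex = n_total // 2
        acc = {"mean_f": [], "sd_f": [], "mean_m": [], "sd_m": [],
               "difference": [], "ci_low": [], "ci_high": [], "p_value": [],
               "sig": []}
        for _ in range(n_cohorts):
            means = _cohort_participant_means(config, rng, k_seq, fast)
            f = means.loc[means.sex == "F", "mean"].to_numpy()
            m = means.loc[means.sex == "M", "mean"].to_numpy()
            if balanced_first_k:
                f, m = f[:per_sex], m[:per_sex]
            else:
                f = rng.choice(f, size=per_sex, replace=False)
                m = rng.choice(m, size=per_sex, replace=False)
            res = welch_from_samples(f, m)
            acc["mean_f"].append(res.mean_f)
            acc["sd_f"].append(res.sd_f)
            acc["mean_m"].append(res.mean_m)
            acc["sd_m"].append(res.sd_m)
            acc["difference"].append(res.difference)
            acc["ci_low"].append(res.ci_low)
            acc["ci_high"].append(res.ci_high)
            acc["p_value"].append(res.p_value)
            acc["sig"].append(res.p_value < alpha)
        out.append(PowerRow(
            presentations_per_participant=presentations,
            n_total=n_total,
            mean_f=float(np.mean(acc["mean_f"])),
            sd_f=float(np.mean(acc["sd_f"])),
            mean_m=float(np.mean(acc["mean_m"])),
            sd_m=float(np.mean(acc["sd_m"])),
            difference=float(np.mean(acc["difference"])),
            ci_low=float(np.mean(acc["ci_low"])),
            ci_high=float(np.mean(acc["ci_high"])),
            p_value=float(np.mean(acc["p_value"])),
            power=float(np.mean(acc["sig"])),
            n_cohorts=n_cohorts,
        ))
    return out


def ear_canal_correction(volume_cc: float) -> float:
    """dB to add to dial SPL for an ear canal smaller than the 2 cc coupler.

    Pressure is inversely proportional to cavity volume, so the adjustment is
    20*log10(2 / volume): 0 dB at 2 cc, 6.02 dB at 1 cc, 9.1 dB at 0.7 cc.
    """
    if volume_cc <= 0:
        raise ConfigurationError("ear canal volume must be positive")
    return float(20.0 * np.log10(2.0 / volume_cc))


def plot_power_grid(rows: list[PowerRow], path) -> None:
    """Forest-style plot of the grid's mean differences with 95% CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{r.presentations_per_participant} pres / {r.n_total} ppts"
              for r in rows]
    y = np.arange(len(rows))[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(rows) + 1.5))
    for r, yi in zip(rows, y):
        sig = r.ci_low > 0 or r.ci_high < 0
        color = "tab:green" if sig else "tab:olive"
        ax.plot([r.ci_low, r.ci_high], [yi, yi], color=color, lw=2)
        ax.plot(r.difference, yi, "|", color="tab:orange", ms=14, mew=3)
    ax.axvline(0.0, color="k", lw=0.8, ls=":")
    ax.set_yticks(y, labels)
    ax.set_xlabel("men - women p1-n1 latency difference (ms, 95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
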