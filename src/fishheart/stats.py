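"""Cohort-level statistics: critical swimming speed, survival, group tests.

Critical swimming speed follows the stepwise swim-tunnel protocol (Brett
form): water speed starts at 9 cm/s and rises by 8.66 cm/s every 150 s until
exhaustion, giving

    Ucrit = Ui + dU * (t / T)

with ``Ui`` the speed of the last fully completed stage, ``dU`` the stage
increment, ``t`` the time swum into the final stage and ``T`` the stage
duration; the result is optionally normalised to body lengths per second.
Survival is compared with Kaplan-Meier curves and the log-rank test
(lifelines); two-group means with the unpaired two-tailed t-test and multiple
groups with one-way ANOVA plus Tukey's HSD (scipy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    ProtocolError,
    SurvivalDataError,
    ZeroVarianceError,
)

__all__ = [
    "UcritResult",
    "LogrankResult",
    "GroupComparison",
    "compute_ucrit",
    "compute_ucrit_table",
    "km_logrank",
    "compare_groups",
]

_BOUNDARY_TOL = 1e-9  # s; exhaustion within this of a stage end counts as the end


@dataclass
class UcritResult:
    """Critical swimming speed, absolute and body-length normalised."""

    ucrit: float  # cm/s
    ucrit_bl: float | None  # body lengths / s


@dataclass
class LogrankResult:
    """Kaplan-Meier curves per group plus the log-rank test."""

    chi2: float
    df: int
    p: float
    curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)

    def summary(self) -> str:
        lines = [f"Log-rank test: chi2 = {self.chi2:.4f}, df = {self.df}, p = {self.p:.4g}"]
        for g, c in self.curves.items():
            lines.append(f"  group {g}: {len(c)} curve points, S(end) = {c['survival'].iloc[-1]:.3f}")
        return "\n".join(lines)


@dataclass
class GroupComparison:
    """Two-group t-test or one-way ANOVA (+ Tukey HSD) result."""

    test: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    group_means: list[float]
    group_sems: list[float]
    tukey: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [f"{self.test}: statistic = {self.statistic:.4f}, df = {self.df}, p = {self.p:.4g}"]
        for i, (m, s) in enumerate(zip(self.group_means, self.group_sems)):
            lines.append(f"  group {i}: mean = {m:.4g} +/- {s:.4g} (s.e.m.)")
        if self.tukey is not None:
            lines.append(self.tukey.to_string(index=False))
        return "\n".join(lines)


def compute_ucrit(
    exhaustion_time: float,
    initial_speed: float = 9.0,
    speed_increment: float = 8.66,
    stage_duration: float = 150.0,
    body_length: float | None = None,
    n_stages: int | None = None,
) -> UcritResult:
    """Critical swimming speed from the exhaustion time of a stepwise trial.

    ``exhaustion_time`` is measured from the start of the first swimming
    stage (the acclimation period is excluded).  Exhaustion exactly at a
    stage boundary credits the completed stage with no time in the next.

    Raises
    ------
    ProtocolError
        If the fish did not complete the first stage, or the exhaustion time
        exceeds the recorded protocol (``n_stages`` stages, when given).
    """
    if initial_speed <= 0 or speed_increment <= 0 or stage_duration <= 0:
        raise InvalidParameterError("protocol speeds and duration must be positive")
    if exhaustion_time < stage_duration - _BOUNDARY_TOL:
        raise ProtocolError(
            "fish exhausted during the first stage; Ucrit undefined under this protocol"
        )
    if n_stages is not None and exhaustion_time > n_stages * stage_duration + _BOUNDARY_TOL:
        raise ProtocolError(
            f"exhaustion time {exhaustion_time} s exceeds the {n_stages} recorded stages"
        )
    n_full = int(np.floor((exhaustion_time + _BOUNDARY_TOL) / stage_duration))
    t_into = exhaustion_time - n_full * stage_duration
    if t_into < _BOUNDARY_TOL:
        t_into = 0.0
    u_i = initial_speed + (n_full - 1) * speed_increment
    ucrit = u_i + speed_increment * (t_into / stage_duration)
    ucrit_bl = None
    if body_length is not None:
        if body_length <= 0:
            raise InvalidParameterError("body length must be positive")
        ucrit_bl = ucrit / body_length
    return UcritResult(ucrit=ucrit, ucrit_bl=ucrit_bl)


def compute_ucrit_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`compute_ucrit` over a swim-trial table.

    Expects columns ``exhaustion_time``, ``initial_speed``, ``speed_increment``,
    ``stage_duration`` and optionally ``body_length``; returns the table with
    ``ucrit`` (cm/s) and, when body length is present, ``ucrit_bl`` appended.
    """
    out = trials.copy()
    res = [
        compute_ucrit(
            row.exhaustion_time,
            row.initial_speed,
            row.speed_increment,
            row.stage_duration,
            getattr(row, "body_length", None),
        )
        for row in trials.itertuples()
    ]
    out["ucrit"] = [r.ucrit for r in res]
    if "body_length" in trials.columns:
        out["ucrit_bl"] = [r.ucrit_bl for r in res]
    return out


def km_logrank(
    records: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    group_col: str = "group",
) -> LogrankResult:
    """Kaplan-Meier curves per group and the multivariate log-rank test.

    The product-limit estimator starts at S(0) = 1 and is non-increasing;
    the test statistic is the classic sum over distinct event times of
    (O - E)^2 weighted by the hypergeometric variance, chi-squared with
    (groups - 1) degrees of freedom.  Censored times tied with events are
    kept at risk through the event.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = records[group_col].unique()
    if len(groups) < 2:
        raise SurvivalDataError("log-rank needs at least two groups")
    if records[event_col].sum() == 0:
        raise SurvivalDataError("all records censored; log-rank statistic undefined")
    if (records[time_col] < 0).any():
        raise InvalidParameterError("survival times must be non-negative")

    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        sub = records[records[group_col] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    res = multivariate_logrank_test(records[time_col], records[group_col], records[event_col])
    return LogrankResult(
        chi2=float(res.test_statistic),
        df=len(groups) - 1,
        p=float(res.p_value),
        curves=curves,
    )


def compare_groups(groups: list[np.ndarray]) -> GroupComparison:
    """Compare group means: unpaired two-tailed t-test for two groups,
    one-way ANOVA with Tukey's HSD pairwise table for three or more."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise InsufficientDataError("need >= 2 groups with >= 2 values each")
    means = [float(a.mean()) for a in arrs]
    sems = [float(a.std(ddof=1) / np.sqrt(len(a))) for a in arrs]
    pooled_var = np.sum([(len(a) - 1) * a.var(ddof=1) for a in arrs])
    if pooled_var == 0:
        if len(set(means)) > 1:
            raise ZeroVarianceError("zero within-group variance with unequal means")
        df = (
            len(arrs[0]) + len(arrs[1]) - 2
            if len(arrs) == 2
            else (len(arrs) - 1, sum(map(len, arrs)) - len(arrs))
        )
        return GroupComparison(
            test="t-test" if len(arrs) == 2 else "one-way ANOVA",
            statistic=0.0, df=df, p=1.0, group_means=means, group_sems=sems,
        )
    if len(arrs) == 2:
        res = sps.ttest_ind(arrs[0], arrs[1], equal_var=True)
        return GroupComparison(
            test="t-test",
            statistic=float(res.statistic),
            df=float(res.df),
            p=float(res.pvalue),
            group_means=means,
            group_sems=sems,
        )
    f, p = sps.f_oneway(*arrs)
    hsd = sps.tukey_hsd(*arrs)
    pairs = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            pairs.append(
                {
                    "group_a": i, "group_b": j,
                    "mean_diff": means[i] - means[j],
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    df_between = len(arrs) - 1
    df_within = sum(map(len, arrs)) - len(arrs)
    return GroupComparison(
        test="one-way ANOVA",
        statistic=float(f),
        df=(float(df_between), float(df_within)),
        p=float(p),
        group_means=means,
        group_sems=sems,
        tukey=pd.DataFrame(pairs),
    )
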