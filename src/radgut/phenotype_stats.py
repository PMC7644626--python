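"""Small statistics around the screen: Smurf proportions, fold changes,
two-sample tests, Kaplan-Meier survival with log-rank, and 2^-ddCt qPCR
fold changes.

The vial — not the fly — is the unit of replication throughout: means, SDs
and t-tests are computed across vial proportions. The default two-sample
test is Welch's (unequal variances, Satterthwaite df); pooled-variance is a
flag. Survival uses the product-limit estimator with right-censoring;
flies alive at study end are censored at the last observation day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PhenotypeTable, SurvivalTable

__all__ = [
    "SmurfSummary",
    "SurvivalCurve",
    "QpcrMeasurement",
    "smurf_summary",
    "fold_change",
    "welch_t_test",
    "km_estimate",
    "logrank",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class SmurfSummary:
    """Per-vial Smurf proportions for one group, with their mean and SD
    across vials (SD is NaN, and flagged, for fewer than 2 vials)."""

    group: str
    proportions: tuple[float, ...]
    mean: float
    sd: float
    n_vials: int

    @property
    def sd_defined(self) -> bool:
        return self.n_vials >= 2


def smurf_summary(records: PhenotypeTable | pd.DataFrame, group: str = "") -> SmurfSummary:
    """Summarize one group's vial records (columns n_smurf, n_total)."""
    df = records.df if isinstance(records, PhenotypeTable) else records
    if len(df) == 0:
        raise ValueError("empty group: no vial records to summarize")
    props = (df["n_smurf"] / df["n_total"]).to_numpy(dtype=float)
    n = len(props)
    sd = float(np.std(props, ddof=1)) if n >= 2 else math.nan
    return SmurfSummary(
        group=group,
        proportions=tuple(float(p) for p in props),
        mean=float(props.mean()),
        sd=sd,
        n_vials=n,
    )


def fold_change(treated_mean: float, control_mean: float) -> float:
    """treated / control; a zero control mean is an error, not infinity."""
    if control_mean <= 0:
        raise ValueError("fold change undefined: control mean must be > 0")
    return float(treated_mean) / float(control_mean)


def welch_t_test(
    group_a, group_b, pooled: bool = False
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test on vial proportions.

    Welch (Satterthwaite df) by default; ``pooled=True`` switches to the
    equal-variance test. Returns (t, df, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate: S(t) at each distinct event time.

    ``median`` is the first time with S(t) <= 0.5, NaN when the curve never
    drops that far.
    """

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    median: float

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(table: SurvivalTable, group: str) -> SurvivalCurve:
    """Kaplan-Meier curve for one group.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); censored
    records shrink the risk set without producing a step. With no deaths
    the curve is identically 1 and the median undefined.
    """
    from lifelines import KaplanMeierFitter

    sub = table.df[table.df["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"no records for group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    et = kmf.event_table
    event_rows = et[et["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"]
    survival = np.array([float(surv.loc[t]) for t in times])
    median = float(kmf.median_survival_time_)
    if math.isinf(median):
        median = math.nan
    return SurvivalCurve(
        times=times,
        at_risk=event_rows["at_risk"].to_numpy(dtype=float),
        n_events=event_rows["observed"].to_numpy(dtype=float),
        survival=survival,
        median=median,
    )


def logrank(table: SurvivalTable, group_a: str, group_b: str) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two groups; returns
    (chi-square statistic, p). Requires at least one death overall."""
    from lifelines.statistics import logrank_test

    a = table.df[table.df["group"] == group_a]
    b = table.df[table.df["group"] == group_b]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must have at least one record")
    if int(a["event"].sum() + b["event"].sum()) == 0:
        raise ValueError("log-rank undefined: no deaths observed in either group")
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class QpcrMeasurement:
    """Mean Ct values (cycles) for a target and a reference gene (e.g. the
    ribosomal protein 49 housekeeping gene) in treated and control
    conditions."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for name in ("ct_target_treated", "ct_ref_treated", "ct_target_control", "ct_ref_control"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


def ddct_fold_change(m: QpcrMeasurement) -> float:
    """Relative quantification: fold = 2^-ddCt with
    ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control.

    Normalization to the reference gene makes the fold invariant to any
    shift applied to all Cts or to the reference in both conditions.
    """
    ddct = (m.ct_target_treated - m.ct_ref_treated) - (
        m.ct_target_control - m.ct_ref_control
    )
    return float(2.0 ** (-ddct))
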