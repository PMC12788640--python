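"""Median-split pseudo-labeling and survival stratification.

Patients are dichotomized into "high" and "low" groups at the median of an
estimated immune-cell fraction; prognostic separation is then tested with the
Kaplan–Meier product-limit estimator and the two-group log-rank test
(significance at p < 0.05, unadjusted).  A Benjamini–Hochberg correction
across cell types is available but off by default, matching the common
practice of reporting unadjusted log-rank p-values per cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "StratifiedLabels",
    "median_split",
    "km_estimate",
    "logrank_test",
    "accuracy_ci",
    "records_to_frame",
    "bh_adjust",
]


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time in months, event=1 if death observed."""

    patient_id: str
    time: float
    event: int
    group: str  # "high" | "low"

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"negative follow-up time for {self.patient_id}")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


@dataclass
class StratifiedLabels:
    """Median-split assignment for one cell type."""

    cell_type: str
    threshold: float
    label_of: dict[str, str] = field(default_factory=dict)

    @property
    def n_high(self) -> int:
        return sum(1 for v in self.label_of.values() if v == "high")

    @property
    def n_low(self) -> int:
        return sum(1 for v in self.label_of.values() if v == "low")


def median_split(fractions: dict[str, float], cell_type: str = "") -> StratifiedLabels:
    """Stratify patients into high/low at the median estimated fraction.

    A patient is "high" iff its value strictly exceeds the median; ties at the
    median go to "low", so the high group strictly exceeds the threshold.
    """
    if len(fractions) < 2:
        raise ValueError("median split needs at least two patients")
    values = np.asarray(list(fractions.values()), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite fraction values")
    if np.all(values == values[0]):
        raise ValueError("all values identical: no stratification possible")
    thr = float(np.median(values))
    labels = {pid: ("high" if v > thr else "low") for pid, v in fractions.items()}
    return StratifiedLabels(cell_type=cell_type, threshold=thr, label_of=labels)


def km_estimate(records: list[SurvivalRecord]) -> dict[str, pd.DataFrame]:
    """Kaplan–Meier product-limit estimate per group.

    Returns, per group, a DataFrame with columns ``time``, ``n_at_risk``,
    ``n_events`` and ``survival`` — the right-continuous step function
    S(t) = prod_{t_i <= t} (1 - d_i / n_i) evaluated at each distinct event
    time (tied events aggregated).  S(0) = 1 by construction.
    """
    if not records:
        raise ValueError("no records")
    out: dict[str, pd.DataFrame] = {}
    for group in sorted({r.group for r in records}):
        times = np.array([r.time for r in records if r.group == group])
        events = np.array([r.event for r in records if r.group == group])
        if np.any(times < 0):
            raise ValueError("negative times")
        order = np.argsort(times, kind="stable")
        times, events = times[order], events[order]
        event_times = np.unique(times[events == 1])
        rows = []
        surv = 1.0
        for t in event_times:
            n_at_risk = int(np.sum(times >= t))
            d = int(np.sum((times == t) & (events == 1)))
            surv *= 1.0 - d / n_at_risk
            rows.append((float(t), n_at_risk, d, surv))
        out[group] = pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])
    return out


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """Evaluate a km_estimate step function at time t (right-continuous)."""
    past = km[km["time"] <= t]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def logrank_test(records: list[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank chi-square test (1 df).

    Accumulates observed-minus-expected events for one group over the pooled
    distinct event times, with the hypergeometric variance at each time; the
    p-value is the upper tail of chi-square(1).
    """
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {groups}")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    is_g0 = np.array([r.group == groups[0] for r in records])
    if events[is_g0].sum() == 0 and events[~is_g0].sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & is_g0).sum()
        d = int(((times == t) & (events == 1)).sum())
        d0 = int(((times == t) & (events == 1) & is_g0).sum())
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    if var == 0:
        raise ValueError("zero variance: a group is never at risk at event times")
    stat = o_minus_e**2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def accuracy_ci(
    correct: int | None = None,
    total: int | None = None,
    per_run_accuracies: list[float] | None = None,
    level: float = 0.95,
) -> tuple[float, float | None, float | None]:
    """Mean accuracy with a t-distribution confidence interval over runs.

    The CI is mean +/- t_{1-(1-level)/2, n-1} * sd / sqrt(n) over the repeated
    run (or fold) accuracies; with a single run only the mean is defined.
    ``correct``/``total`` give the pooled point estimate when no per-run
    accuracies are supplied.
    """
    if per_run_accuracies:
        runs = np.asarray(per_run_accuracies, dtype=float)
        mean = float(runs.mean())
        if runs.size < 2:
            return mean, None, None
        se = runs.std(ddof=1) / np.sqrt(runs.size)
        tq = stats.t.ppf(1 - (1 - level) / 2, df=runs.size - 1)
        return mean, float(mean - tq * se), float(mean + tq * se)
    if total is None or total <= 0:
        raise ValueError("need total > 0 or per-run accuracies")
    return correct / total, None, None


def bh_adjust(p_values: dict[str, float]) -> dict[str, float]:
    """Benjamini–Hochberg adjusted p-values (optional, off by default upstream)."""
    from statsmodels.stats.multitest import multipletests

    keys = list(p_values)
    _, adj, _, _ = multipletests([p_values[k] for k in keys], method="fdr_bh")
    return dict(zip(keys, adj))


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
        }
    )
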