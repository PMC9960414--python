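"""Product-limit survival estimation, k-group log-rank test, cutpoint search.

Times are in months throughout. The product-limit and log-rank routines are
implemented directly (ties handled by the standard hypergeometric variance)
and cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from metabosub.data_io import ClinicalTable
from metabosub.errors import ValidationError


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate over the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


@dataclass
class CutpointResult:
    threshold: float
    max_statistic: float
    p_value: float
    group_sizes: tuple[int, int]


def filter_min_followup(clinical: ClinicalTable, min_months: float = 1.0) -> ClinicalTable:
    """Remove samples with overall survival strictly shorter than ``min_months``."""
    df = clinical.df
    return ClinicalTable(df[df["os_months"] >= min_months].copy())


def km_estimate(times: Sequence[float], events: Sequence[int]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with right censoring.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i). Subjects
    censored at a time leave the risk set after that time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValidationError("km_estimate requires at least one subject")
    if np.any(t < 0):
        raise ValidationError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise ValidationError("events must be 0 or 1")
    event_times = np.unique(t[e == 1])
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    n_events = np.array([((t == u) & (e == 1)).sum() for u in event_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - n_events / at_risk
    survival = np.cumprod(factors)
    return SurvivalCurve(event_times, survival, at_risk, n_events)


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> LogRankResult:
    """k-group log-rank test.

    At each distinct event time the expected event count per group is
    d_t * n_gt / n_t; the statistic is the quadratic form of (O - E) over the
    first k-1 groups with the hypergeometric covariance, chi-square with k-1
    degrees of freedom under the null.
    """
    if len(groups) < 2:
        raise ValidationError("logrank_test requires >= 2 groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValidationError(f"group {g} has no subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    t_all = np.concatenate(times)
    e_all = np.concatenate(events)
    g_all = np.concatenate(labels)
    if e_all.sum() == 0:
        raise ValidationError("no events in any group")
    k = len(groups)
    event_times = np.unique(t_all[e_all == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for u in event_times:
        at_risk_mask = t_all >= u
        n_t = at_risk_mask.sum()
        d_t = ((t_all == u) & (e_all == 1)).sum()
        n_gt = np.array([(at_risk_mask & (g_all == g)).sum() for g in range(k)],
                        dtype=float)
        d_gt = np.array([((t_all == u) & (e_all == 1) & (g_all == g)).sum()
                         for g in range(k)], dtype=float)
        observed += d_gt
        expected += d_t * n_gt / n_t
        if n_t > 1:
            frac = n_gt / n_t
            hyper = d_t * (n_t - d_t) / (n_t - 1)
            cov += hyper * (np.diag(frac) - np.outer(frac, frac))
    z = (observed - expected)[:-1]
    v = cov[:-1, :-1]
    statistic = float(z @ np.linalg.pinv(v) @ z)
    df = k - 1
    p_value = float(stats.chi2.sf(statistic, df))
    return LogRankResult(statistic, df, p_value, observed, expected)


def logrank_by_label(times: Mapping[str, float], events: Mapping[str, int],
                     labels: Mapping[str, str]) -> LogRankResult:
    """Convenience wrapper grouping per-sample times/events by a label map."""
    by_group: dict[str, tuple[list[float], list[int]]] = {}
    for sample, label in labels.items():
        if sample in times:
            by_group.setdefault(label, ([], []))
            by_group[label][0].append(times[sample])
            by_group[label][1].append(events[sample])
    return logrank_test([by_group[g] for g in sorted(by_group)])


def optimal_cutpoint(values: Mapping[str, float], clinical: ClinicalTable,
                     minprop: float = 0.1) -> CutpointResult:
    """Maximally selected two-group log-rank cutpoint over observed values.

    Candidate thresholds are the observed values with both resulting groups
    containing at least ``minprop`` of the samples; ties in the statistic go
    to the lower threshold. The scan maximizes the statistic without a
    selection-adjusted p-value, so the reported p is exploratory.
    """
    df = clinical.df[clinical.df["sample_id"].isin(values)]
    n = len(df)
    if n < 10:
        raise ValidationError("optimal_cutpoint requires >= 10 samples with follow-up")
    v = np.array([values[s] for s in df["sample_id"]])
    t = df["os_months"].to_numpy(dtype=float)
    e = df["os_event"].to_numpy(dtype=int)
    min_size = max(1, int(np.ceil(minprop * n)))
    best: CutpointResult | None = None
    for threshold in np.unique(v):
        low = v <= threshold
        n_low = int(low.sum())
        if n_low < min_size or n - n_low < min_size:
            continue
        if e[low].sum() + e[~low].sum() == 0:
            continue
        res = logrank_test([(t[low], e[low]), (t[~low], e[~low])])
        if best is None or res.statistic > best.max_statistic + 1e-12:
            best = CutpointResult(float(threshold), res.statistic, res.p_value,
                                  (n_low, n - n_low))
    if best is None:
        raise ValidationError("no admissible threshold (groups too small or constant values)")
    return best
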