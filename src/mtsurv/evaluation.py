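"""Evaluation statistics for censored outcomes: concordance index with
confidence intervals, Kaplan-Meier estimation, log-rank testing, and
median-threshold risk stratification.

The concordance index used throughout counts a usable pair as concordant
when the patient with the longer observed time received the *higher*
prediction.  With this single convention, hazard-type predictions (larger =
worse) score *below* 0.5 when the model discriminates — values close to
zero are optimal — while survival-probability predictions score above 0.5.
The ``orientation`` argument records which reading applies and sets the
direction of the high-risk group in median stratification; it does not
change the index formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines.statistics import logrank_test as _lifelines_logrank

from .survival import SurvivalRecord

__all__ = [
    "ConcordanceResult",
    "StratificationResult",
    "KaplanMeierEstimate",
    "concordance_index",
    "km_estimate",
    "logrank_test",
    "stratify_by_median",
]

ORIENTATIONS = ("hazard", "survival")


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    ci_low: float
    ci_high: float
    n_usable_pairs: int
    orientation: str

    def __post_init__(self):
        assert 0.0 <= self.c_index <= 1.0
        assert self.ci_low <= self.c_index <= self.ci_high


def _usable_pairs(times, events):
    """Indices (i, j) such that the pair is usable under right censoring:
    the shorter time is an event; ties in time are usable only between an
    event and a censored patient (the event counts as earlier)."""
    n = len(times)
    first, second = [], []
    for i in range(n):
        if events[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            if times[i] < times[j] or (times[i] == times[j] and events[j] == 0):
                first.append(i)
                second.append(j)
    return np.asarray(first, dtype=int), np.asarray(second, dtype=int)


def concordance_index(
    predictions, records: Sequence[SurvivalRecord], orientation: str = "hazard"
) -> ConcordanceResult:
    """Concordance over all usable pairs, with a Noether 95% CI.

    Pairs are usable when the earlier time is an event (Harrell's rule);
    concordant when the longer-surviving patient has the higher prediction;
    tied predictions count 1/2.  The confidence interval uses the normal
    approximation with the U-statistic variance (see :func:`_noether_se`).
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    preds = np.asarray(predictions, dtype=float)
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    if preds.shape[0] != len(records):
        raise ValueError("predictions and records differ in length")
    short_idx, long_idx = _usable_pairs(times, events)
    n_pairs = len(short_idx)
    if n_pairs == 0:
        raise ValueError("no usable pairs under censoring")
    diff = preds[long_idx] - preds[short_idx]
    weight = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    c = float(weight.sum() / n_pairs)
    se = _noether_se(len(records), short_idx, long_idx, weight, c)
    half = 1.959963984540054 * se
    return ConcordanceResult(
        c_index=c,
        ci_low=max(0.0, c - half),
        ci_high=min(1.0, c + half),
        n_usable_pairs=n_pairs,
        orientation=orientation,
    )


def _noether_se(n, short_idx, long_idx, weight, c) -> float:
    """Normal-approximation standard error of the concordance estimator.

    U-statistic variance (Noether 1967, as used for C-index confidence
    intervals by Pencina & D'Agostino): with pc / pd the probabilities that
    a random usable pair is concordant / discordant and pcc, pdd, pcd the
    corresponding joint probabilities for two pairs sharing a subject,

        var(c) = (4 / n) * (pd^2 pcc - 2 pc pd pcd + pc^2 pdd) / (pc + pd)^4.

    Prediction ties (weight 1/2) are split between the concordant and
    discordant tallies.
    """
    conc = np.zeros(n)
    disc = np.zeros(n)
    np.add.at(conc, short_idx, weight)
    np.add.at(conc, long_idx, weight)
    np.add.at(disc, short_idx, 1.0 - weight)
    np.add.at(disc, long_idx, 1.0 - weight)
    denom2 = n * (n - 1)
    pc = conc.sum() / denom2
    pd = disc.sum() / denom2
    if n < 3 or pc + pd == 0:
        return float(np.sqrt(max(c * (1 - c), 1e-12) / max(len(weight), 1)))
    denom3 = n * (n - 1) * (n - 2)
    pcc = (conc * (conc - 1)).sum() / denom3
    pdd = (disc * (disc - 1)).sum() / denom3
    pcd = (conc * disc).sum() / denom3
    var = (4.0 / n) * (pd**2 * pcc - 2 * pc * pd * pcd + pc**2 * pdd) / (pc + pd) ** 4
    return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit step function with Greenwood 95% bands."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord]) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimator.

    Steps occur at distinct event times; censored patients leave the risk
    set without a step.  Pointwise 95% bands use the Greenwood variance
    S(t)^2 * sum d / (n (n - d)) on the plain scale, clipped to [0, 1].
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv = 1.0
    greenwood = 0.0
    rows = []
    for t in event_times:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            greenwood += d / (n_at_risk * (n_at_risk - d))
        se = surv * np.sqrt(greenwood)
        rows.append((t, surv, n_at_risk, d, max(0.0, surv - 1.96 * se), min(1.0, surv + 1.96 * se)))
    if not rows:  # no events: flat at 1
        return KaplanMeierEstimate(
            np.array([]), np.array([]), np.array([]), np.array([]), np.array([]), np.array([])
        )
    cols = list(zip(*rows))
    return KaplanMeierEstimate(*(np.asarray(c) for c in cols))


def logrank_test(records: Sequence[SurvivalRecord], groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {labels}")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    mask = groups == labels[0]
    result = _lifelines_logrank(
        times[mask], times[~mask], event_observed_A=events[mask], event_observed_B=events[~mask]
    )
    return float(result.test_statistic), float(result.p_value)


@dataclass(frozen=True)
class StratificationResult:
    threshold: float
    groups: np.ndarray  # "low" / "high" per evaluation patient
    statistic: float
    p_value: float
    degenerate: bool = False


def stratify_by_median(
    train_predictions,
    eval_predictions,
    eval_records: Sequence[SurvivalRecord],
    orientation: str = "hazard",
) -> StratificationResult:
    """Split evaluation patients at the median training prediction.

    Under hazard orientation predictions above the threshold are high risk;
    under survival orientation predictions below it are.  Predictions
    exactly at the threshold go to the low-risk group.  If all evaluation
    patients land in one group the result is returned with
    ``degenerate=True`` and a NaN test.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    train_predictions = np.asarray(train_predictions, dtype=float)
    if train_predictions.size == 0:
        raise ValueError("no training predictions to derive the threshold from")
    threshold = float(np.median(train_predictions))
    preds = np.asarray(eval_predictions, dtype=float)
    if orientation == "hazard":
        high = preds > threshold
    else:
        high = preds < threshold
    groups = np.where(high, "high", "low")
    if len(np.unique(groups)) < 2:
        import warnings

        warnings.warn("degenerate stratification: all patients in one group", stacklevel=2)
        return StratificationResult(threshold, groups, np.nan, np.nan, degenerate=True)
    stat, p = logrank_test(eval_records, groups)
    return StratificationResult(threshold, groups, stat, p)
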