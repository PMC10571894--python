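"""Outcome-model mathematics: bounded Cox log-hazard likelihood, the
discrete-time conditional-survival model, interval encoding, and the
combined multitask loss.

Two survival heads are supported.  The Cox head emits a tanh-bounded
log-hazard gamma(x) in (-1, 1) that scales a (never estimated) baseline
hazard, h(t, x) = h0(t) * exp(gamma(x)); it is trained with the batchwise
negative partial log-likelihood

    L_Cox = - sum_i delta_i * [ gamma_i - ln sum_{j : t_j >= t_i} exp(gamma_j) ]

summed (not averaged) over the batch, with the risk set defined by
t_j >= t_i (Breslow handling of tied times).  The discrete-time head emits,
for each of ten predefined intervals over a 0-120 month horizon, the
conditional probability of surviving that interval given survival to its
start; its negative log-likelihood is a masked binary cross-entropy over the
intervals each patient was observed in.  Unconditional survival curves are
cumulative products of the conditional probabilities.

All losses are written against :class:`mtsurv.autodiff.Tensor` so the same
code path serves evaluation (floats in, float out) and network training
(gradients flow to the head outputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor

__all__ = [
    "SurvivalRecord",
    "IntervalGrid",
    "IntervalLabels",
    "DEFAULT_BOUNDARIES",
    "encode_intervals",
    "cox_loss",
    "gensheimer_loss",
    "survival_curve",
    "survival_at",
    "dice_loss",
    "bce_loss",
    "segmentation_loss",
    "combined_loss",
    "read_outcome_table",
    "write_outcome_table",
]

#: Month boundaries of the ten discrete survival intervals.
DEFAULT_BOUNDARIES = (0.0, 6.0, 12.0, 18.0, 24.0, 30.0, 36.0, 48.0, 60.0, 84.0, 120.0)

#: Probabilities are clamped to [EPS, 1 - EPS] before logs.
EPS = 1e-7


@dataclass(frozen=True)
class SurvivalRecord:
    """A right-censored outcome: follow-up time in months and event flag."""

    time: float
    event: int
    patient_id: str = ""

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"negative follow-up time: {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class IntervalGrid:
    """Strictly increasing interval boundaries, first one at zero.

    ``len(boundaries) - 1`` half-open intervals [b_k, b_{k+1}) are defined;
    an event exactly on a boundary belongs to the interval starting there.
    """

    boundaries: tuple = DEFAULT_BOUNDARIES

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b[0] != 0:
            raise ValueError("first interval boundary must be 0")
        if len(b) < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing with >= 2 entries")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) - 1

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.boundaries[1:])


@dataclass(frozen=True)
class IntervalLabels:
    """Per-interval supervision for the discrete-time head.

    ``observed_mask[k]`` flags intervals contributing to the likelihood (a
    prefix of the grid); ``survival_target[k]`` is 1 if the patient survived
    interval k, 0 if the event fell inside it (then k is the last observed
    interval).  Intervals entered but exited by censoring are unobserved: a
    patient censored mid-interval receives no credit for it.
    """

    observed_mask: np.ndarray
    survival_target: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "observed_mask", np.asarray(self.observed_mask, dtype=float))
        object.__setattr__(self, "survival_target", np.asarray(self.survival_target, dtype=float))


def encode_intervals(record: SurvivalRecord, grid: IntervalGrid = IntervalGrid()) -> IntervalLabels:
    """Map a censored outcome onto per-interval binary targets.

    For an event at time t every interval ending at or before t is observed
    with target 1 and the interval containing t is observed with target 0.
    For a censored patient only fully elapsed intervals are observed, all
    with target 1.  Times at or beyond the final boundary yield all-observed,
    all-survived labels regardless of the event flag (the event falls outside
    the modeled horizon).
    """
    upper = grid.upper
    n = grid.n_intervals
    observed = (upper <= record.time).astype(float)
    target = np.ones(n)
    if record.event == 1 and record.time < grid.boundaries[-1]:
        k = int(np.searchsorted(upper, record.time, side="right"))
        observed[k] = 1.0
        target[k] = 0.0
    return IntervalLabels(observed, target)


def _lift(values, dtype=np.float64) -> Tensor:
    if isinstance(values, Tensor):
        return values
    return Tensor(np.asarray(values, dtype=dtype))


def cox_loss(log_hazards, records: Sequence[SurvivalRecord], normalize: bool = False):
    """Negative Cox partial log-likelihood of a batch.

    Summed over the batch by default; ``normalize=True`` divides by the
    number of events for learning-rate transfer across batch sizes.  Returns
    a float for plain array input or a :class:`Tensor` inside a graph.
    Batches without events contribute zero.
    """
    gamma = _lift(log_hazards)
    if gamma.shape[0] != len(records):
        raise ValueError(
            f"length mismatch: {gamma.shape[0]} predictions vs {len(records)} records"
        )
    times = np.array([r.time for r in records])
    events = np.array([float(r.event) for r in records], dtype=gamma.dtype)
    n_events = events.sum()
    if n_events == 0:
        zero = gamma.sum() * 0.0
        return zero if isinstance(log_hazards, Tensor) else float(zero)
    # risk_matrix[i, j] = 1 when patient j is still at risk at time t_i
    risk_matrix = (times[None, :] >= times[:, None]).astype(gamma.dtype)
    shift = float(gamma.value.max())  # constant: stabilizes exp for unbounded inputs
    n = gamma.shape[0]
    exp_g = (gamma - shift).exp().reshape(n, 1)
    log_risk = (Tensor(risk_matrix) @ exp_g).reshape(n).log() + shift
    loss = -((gamma - log_risk) * Tensor(events)).sum()
    if normalize:
        loss = loss * (1.0 / float(n_events))
    return loss if isinstance(log_hazards, Tensor) else float(loss)


def gensheimer_loss(conditional_probs, labels: Sequence[IntervalLabels] | IntervalLabels):
    """Masked binary cross-entropy of the discrete-time head.

    ``conditional_probs`` is (n_patients, n_intervals) with entries in
    (0, 1); entries are clamped to [1e-7, 1 - 1e-7] before the logs so
    saturated sigmoids cannot produce non-finite loss.  Unobserved intervals
    contribute nothing.
    """
    probs = _lift(conditional_probs)
    if isinstance(labels, IntervalLabels):
        labels = [labels]
    mask = np.stack([lab.observed_mask for lab in labels]).astype(probs.dtype)
    target = np.stack([lab.survival_target for lab in labels]).astype(probs.dtype)
    if probs.shape != mask.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs labels {mask.shape}")
    p = probs.clamp(EPS, 1.0 - EPS)
    ll = Tensor(target) * p.log() + Tensor(1.0 - target) * (1.0 - p).log()
    loss = -(Tensor(mask) * ll).sum()
    return loss if isinstance(conditional_probs, Tensor) else float(loss)


def survival_curve(conditional_probs) -> np.ndarray:
    """Unconditional survival per interval end: cumulative products."""
    probs = np.asarray(
        conditional_probs.value if isinstance(conditional_probs, Tensor) else conditional_probs,
        dtype=float,
    )
    return np.cumprod(probs, axis=-1)


def survival_at(conditional_probs, grid: IntervalGrid, t: float) -> float | np.ndarray:
    """Survival probability at boundary ``t`` (no interpolation)."""
    upper = grid.upper
    matches = np.nonzero(np.isclose(upper, t))[0]
    if len(matches) == 0:
        raise ValueError(f"t={t} is not an interval boundary of {grid.boundaries}")
    curve = survival_curve(conditional_probs)
    return curve[..., int(matches[0])]


def dice_loss(pred, target, smooth: float = 1e-5):
    """Soft Dice loss over the whole volume, averaged over the batch."""
    p = _lift(pred)
    t = np.asarray(target.value if isinstance(target, Tensor) else target, dtype=p.dtype)
    axes = tuple(range(1, p.ndim))
    inter = (p * Tensor(t)).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=tuple(range(1, t.ndim)))
    dice = (inter * 2.0 + smooth) / (denom + smooth)
    loss = (1.0 - dice).mean()
    return loss if isinstance(pred, Tensor) else float(loss)


def bce_loss(pred, target):
    """Voxelwise binary cross-entropy, averaged over all voxels."""
    p = _lift(pred).clamp(EPS, 1.0 - EPS)
    t = np.asarray(target.value if isinstance(target, Tensor) else target, dtype=p.dtype)
    ll = Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log()
    loss = -ll.mean()
    return loss if isinstance(pred, Tensor) else float(loss)


def segmentation_loss(pred, target):
    """L_seg = 0.5 * L_Dice + L_BCE (the BCE term unweighted)."""
    return dice_loss(pred, target) * 0.5 + bce_loss(pred, target)


def combined_loss(cox_term=None, gh_term=None, seg_term=None, mode: str = "multi"):
    """Total training objective for the configured outcome mode.

    multi -> L_Cox + L_GH; single-cox / single-gh -> one term; a
    segmentation term, when present, is always added.
    """
    if mode == "multi":
        if cox_term is None or gh_term is None:
            raise ValueError("multi mode requires both outcome terms")
        total = cox_term + gh_term
    elif mode == "single-cox":
        if cox_term is None:
            raise ValueError("single-cox mode requires the Cox term")
        total = cox_term
    elif mode == "single-gh":
        if gh_term is None:
            raise ValueError("single-gh mode requires the discrete-time term")
        total = gh_term
    else:
        raise ValueError(f"unknown outcome mode: {mode!r}")
    if seg_term is not None:
        total = total + seg_term
    return total


# -- outcome-table I/O ---------------------------------------------------------


def read_outcome_table(path) -> list[SurvivalRecord]:
    """Read a patient outcome CSV with columns patient_id, time_months, event."""
    df = pd.read_csv(path)
    required = {"patient_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"outcome table misses columns: {sorted(missing)}")
    return [
        SurvivalRecord(time=float(r.time_months), event=int(r.event), patient_id=str(r.patient_id))
        for r in df.itertuples()
    ]


def write_outcome_table(records: Sequence[SurvivalRecord], path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "time_months": [r.time for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(path, index=False)
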