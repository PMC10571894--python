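"""Experimental protocol: stratified repeated cross-validation,
event-balanced batch sampling, the training loop with best-checkpoint
restoration, and 15/12/3-model ensemble bookkeeping.

The exploratory cohort is partitioned into ``n_folds`` folds stratified by
event status, repeated ``n_repetitions`` times (default 3 x 5 = 15 models).
Patients of an independent validation cohort receive ensemble predictions
averaged over all 15 models; each exploratory patient receives a
``training`` ensemble averaged over the 12 models whose training split
contained the patient and an ``internal_test`` ensemble over the 3 models
that held the patient out.  Per-head aggregation averages the Cox
log-hazard and each interval's conditional survival probability.

Seeding is hierarchical: a master seed deterministically derives per-
(repetition, fold) seeds for fold assignment, weight initialization, batch
sampling, and augmentation, so a full run is reproducible end to end.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .autodiff import Tensor
from .networks import Module, NetworkConfig, build_network
from .optim import AdamW
from .pipeline import (
    AugmentationPolicy,
    VolumeSample,
    center_of_mass_crop,
    multicrop_inference,
    training_crop,
)
from .survival import (
    IntervalGrid,
    SurvivalRecord,
    combined_loss,
    cox_loss,
    encode_intervals,
    gensheimer_loss,
    segmentation_loss,
    survival_at,
)
from .evaluation import concordance_index, stratify_by_median

__all__ = [
    "FoldAssignment",
    "TrainingSchedule",
    "EnsembleTable",
    "make_folds",
    "event_balanced_batches",
    "train_one_model",
    "aggregate_ensembles",
    "run_cross_validation",
    "ensemble_report",
    "paper_schedule",
    "tiny_schedule",
]


# -- fold assignment -----------------------------------------------------------


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified fold membership for every repetition."""

    n_folds: int
    n_repetitions: int
    seed: int
    patient_ids: tuple
    test_sets: dict  # (repetition, fold) -> frozenset of held-out patient ids

    def role(self, repetition: int, fold: int, patient_id: str) -> str:
        return "internal_test" if patient_id in self.test_sets[(repetition, fold)] else "train"

    def models(self):
        return sorted(self.test_sets.keys())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"repetition": rep, "fold": fold, "patient_id": pid, "role": self.role(rep, fold, pid)}
            for (rep, fold) in self.models()
            for pid in self.patient_ids
        ]
        return pd.DataFrame(rows)


def make_folds(
    records: Sequence[SurvivalRecord],
    n_folds: int = 5,
    n_repetitions: int = 3,
    seed: int = 0,
) -> FoldAssignment:
    """Event-stratified k-fold partitions, repeated with fresh shuffles."""
    if n_folds < 2:
        raise ValueError("cross-validation requires at least 2 folds")
    events = np.array([r.event for r in records])
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in cohort")
    for label, name in ((1, "events"), (0, "censored")):
        count = int((events == label).sum())
        if count < n_folds:
            raise ValueError(
                f"stratum '{name}' has only {count} patients, fewer than {n_folds} folds"
            )
    test_sets = {}
    for rep in range(1, n_repetitions + 1):
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + 1000 * rep)
        for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(ids)), events), start=1):
            test_sets[(rep, fold)] = frozenset(ids[i] for i in test_idx)
    return FoldAssignment(n_folds, n_repetitions, seed, tuple(ids), test_sets)


# -- event-balanced sampling ---------------------------------------------------


def event_balanced_batches(
    records: Sequence[SurvivalRecord],
    batch_size: int = 16,
    seed: int = 0,
    n_batches: int | None = None,
):
    """Yield index batches sampled with replacement, weighted so that the
    expected number of events per batch is about half the batch size.

    Weights are inversely proportional to event-class frequency.  If only
    one class is present, sampling falls back to uniform with a warning.
    """
    events = np.array([r.event for r in records])
    n = len(events)
    counts = np.bincount(events, minlength=2)
    if counts.min() == 0:
        warnings.warn("single-class training split: uniform sampling", stacklevel=2)
        weights = np.full(n, 1.0 / n)
    else:
        weights = np.where(events == 1, 1.0 / counts[1], 1.0 / counts[0])
        weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    produced = 0
    while n_batches is None or produced < n_batches:
        yield rng.choice(n, size=batch_size, replace=True, p=weights)
        produced += 1


# -- training loop -------------------------------------------------------------


@dataclass(frozen=True)
class TrainingSchedule:
    """Optimization settings for one model."""

    epochs: int = 400
    batch_size: int = 16
    learning_rate: float = 1e-4
    weight_decay: float = 0.1
    crop_size: tuple = (48, 64, 64)
    n_inference_crops: int = 8
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    normalize_cox: bool = False  # Eq.-style batch sum by default


def paper_schedule(**overrides) -> TrainingSchedule:
    return TrainingSchedule(**overrides)


def tiny_schedule(**overrides) -> TrainingSchedule:
    """Desk-scale schedule matched to the 16^3 tiny presets."""
    defaults = dict(
        epochs=10,
        batch_size=8,
        learning_rate=1e-3,
        weight_decay=0.01,
        crop_size=(16, 16, 16),
        n_inference_crops=4,
        augmentation=AugmentationPolicy(
            apply_probability=0.5,
            max_translation_voxels=2,
            noise_sd=0.05,
            intensity_shift_range=(-0.1, 0.1),
            contrast_gamma_range=(0.8, 1.25),
            smooth_variance_range=(0.25, 0.75),
            max_rotation_degrees=10.0,
        ),
    )
    defaults.update(overrides)
    return TrainingSchedule(**defaults)


def _batch_losses(network, images, masks, records, labels, schedule, grid):
    """Forward a batch and return the individual loss terms as Tensors."""
    out = network(Tensor(images))
    cfg = network.config
    terms = {}
    if "log_hazard" in out:
        terms["cox"] = cox_loss(out["log_hazard"], records, normalize=schedule.normalize_cox)
    if "conditional_probs" in out:
        terms["gh"] = gensheimer_loss(out["conditional_probs"], labels)
    if cfg.use_segmentation_loss:
        terms["seg"] = segmentation_loss(out["segmentation"], masks)
    total = combined_loss(
        terms.get("cox"), terms.get("gh"), terms.get("seg"), cfg.outcome_mode
    )
    return total, terms


def evaluate_loss(network, samples, schedule, grid) -> dict[str, float]:
    """Total configured loss on central crops, evaluation mode, no grad."""
    was_training = network.training
    network.eval()
    crops = [center_of_mass_crop(s, schedule.crop_size) for s in samples]
    images = np.stack([c.image for c in crops])
    masks = np.stack([(c.mask > 0).astype(np.float32)[None] for c in crops])
    records = [s.record for s in samples]
    labels = [encode_intervals(r, grid) for r in records]
    total, terms = _batch_losses(network, images, masks, records, labels, schedule, grid)
    network.train(was_training)
    result = {k: float(v) for k, v in terms.items()}
    result["total"] = float(total)
    return result


def train_one_model(
    network: Module,
    train_samples: Sequence[VolumeSample],
    test_samples: Sequence[VolumeSample],
    schedule: TrainingSchedule,
    grid: IntervalGrid = IntervalGrid(),
    seed: int = 0,
    log=None,
) -> tuple[Module, dict]:
    """Optimize the combined multitask loss; restore the best checkpoint.

    One epoch draws ceil(n_train / batch_size) event-balanced batches with
    replacement.  After every epoch the same total loss is evaluated on the
    internal test split (central crops, no augmentation); at the end the
    weights with the lowest internal-test total loss are restored.  A
    non-finite loss aborts with the offending term named.
    """
    records = [s.record for s in train_samples]
    labels = {id(s): encode_intervals(s.record, grid) for s in train_samples}
    n_batches = max(1, int(np.ceil(len(train_samples) / schedule.batch_size)))
    optimizer = AdamW(
        network.parameters(), lr=schedule.learning_rate, weight_decay=schedule.weight_decay
    )
    aug_rng = np.random.default_rng((seed, 1))
    history = {"train": [], "test": []}
    best = {"loss": np.inf, "state": copy.deepcopy(network.state_dict()), "epoch": -1}

    if schedule.epochs > 0 and test_samples:
        initial = evaluate_loss(network, test_samples, schedule, grid)
        best.update(loss=initial["total"], epoch=0)

    for epoch in range(1, schedule.epochs + 1):
        network.train()
        sampler = event_balanced_batches(
            records, schedule.batch_size, seed=(seed + 7919 * epoch) % 2**31, n_batches=n_batches
        )
        epoch_terms: dict[str, float] = {}
        for batch_idx in sampler:
            batch = [
                training_crop(train_samples[i], schedule.augmentation, schedule.crop_size, aug_rng)
                for i in batch_idx
            ]
            images = np.stack([b.image for b in batch])
            masks = np.stack([(b.mask > 0).astype(np.float32)[None] for b in batch])
            recs = [b.record for b in batch]
            labs = [labels[id(train_samples[i])] for i in batch_idx]
            total, terms = _batch_losses(network, images, masks, recs, labs, schedule, grid)
            for name, term in {**terms, "total": total}.items():
                value = float(term)
                if not np.isfinite(value):
                    raise RuntimeError(f"non-finite '{name}' loss in epoch {epoch}")
                epoch_terms[name] = epoch_terms.get(name, 0.0) + value
            network.zero_grad()
            total.backward()
            optimizer.step()
        train_losses = {k: v / n_batches for k, v in epoch_terms.items()}
        history["train"].append(train_losses)
        if test_samples:
            test_losses = evaluate_loss(network, test_samples, schedule, grid)
            history["test"].append(test_losses)
            if test_losses["total"] < best["loss"]:
                best.update(
                    loss=test_losses["total"], state=copy.deepcopy(network.state_dict()), epoch=epoch
                )
        if log:
            test_str = f" test {history['test'][-1]['total']:.4f}" if test_samples else ""
            print(f"epoch {epoch}: train {train_losses['total']:.4f}{test_str}", file=log)

    if schedule.epochs > 0 and test_samples:
        network.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    return network, history


# -- ensemble bookkeeping ------------------------------------------------------


class EnsembleTable:
    """Per-patient ensemble predictions with their roles.

    Wraps a DataFrame with one row per (patient, ensemble_role); columns
    are ``patient_id``, ``ensemble_role`` (training / internal_test /
    validation), ``n_models``, ``log_hazard`` and ``gh_1 .. gh_K`` where
    present.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)

    def predictions(self, role: str, head: str) -> pd.DataFrame:
        sub = self.table[self.table.ensemble_role == role]
        if head == "cox":
            return sub[["patient_id", "log_hazard"]]
        cols = [c for c in sub.columns if c.startswith("gh_")]
        return sub[["patient_id", *cols]]

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))


def aggregate_ensembles(
    per_model: pd.DataFrame,
    assignment: FoldAssignment,
    validation_ids: Sequence[str] = (),
) -> EnsembleTable:
    """Average per-model predictions into role-specific ensembles.

    ``per_model`` needs columns repetition, fold, patient_id plus the head
    outputs (``log_hazard`` and/or ``gh_*``).  Every model must supply a
    prediction for every exploratory and validation patient; a missing pair
    raises with the (model, patient) named.
    """
    head_cols = [c for c in per_model.columns if c == "log_hazard" or c.startswith("gh_")]
    if not head_cols:
        raise ValueError("per-model table contains no head output columns")
    models = assignment.models()
    indexed = per_model.set_index(["repetition", "fold", "patient_id"])
    if indexed.index.has_duplicates:
        raise ValueError("duplicate (model, patient) predictions")

    def fetch(rep, fold, pid):
        try:
            return indexed.loc[(rep, fold, pid), head_cols]
        except KeyError:
            raise ValueError(f"missing prediction of model (rep {rep}, fold {fold}) "
                             f"for patient {pid!r}") from None

    rows = []
    for pid in assignment.patient_ids:
        contributions = {"training": [], "internal_test": []}
        for rep, fold in models:
            role = assignment.role(rep, fold, pid)
            key = "internal_test" if role == "internal_test" else "training"
            contributions[key].append(fetch(rep, fold, pid))
        for role, parts in contributions.items():
            mean = pd.concat(parts, axis=1).mean(axis=1)
            rows.append({"patient_id": pid, "ensemble_role": role, "n_models": len(parts),
                         **mean.to_dict()})
    for pid in validation_ids:
        parts = [fetch(rep, fold, pid) for rep, fold in models]
        mean = pd.concat(parts, axis=1).mean(axis=1)
        rows.append({"patient_id": pid, "ensemble_role": "validation", "n_models": len(parts),
                     **mean.to_dict()})
    return EnsembleTable(pd.DataFrame(rows))


# -- full protocol -------------------------------------------------------------


def run_cross_validation(
    samples: Sequence[VolumeSample],
    config: NetworkConfig,
    schedule: TrainingSchedule,
    n_folds: int = 5,
    n_repetitions: int = 3,
    seed: int = 0,
    validation_samples: Sequence[VolumeSample] = (),
    grid: IntervalGrid = IntervalGrid(),
    log=None,
) -> tuple[EnsembleTable, pd.DataFrame, FoldAssignment, list[dict]]:
    """Train the full grid of CV models and assemble the ensemble table."""
    records = [s.record for s in samples]
    assignment = make_folds(records, n_folds, n_repetitions, seed)
    by_id = {s.patient_id: s for s in samples}
    pred_rows = []
    histories = []
    for model_idx, (rep, fold) in enumerate(assignment.models()):
        model_seed = (seed + 104729 * rep + 1299709 * fold) % 2**31
        test_ids = assignment.test_sets[(rep, fold)]
        train_split = [by_id[p] for p in assignment.patient_ids if p not in test_ids]
        test_split = [by_id[p] for p in assignment.patient_ids if p in test_ids]
        network = build_network(config, seed=model_seed)
        if log:
            print(f"[model {model_idx + 1}/{len(assignment.models())}] rep {rep} fold {fold}: "
                  f"{len(train_split)} train / {len(test_split)} internal test", file=log)
        network, history = train_one_model(
            network, train_split, test_split, schedule, grid, seed=model_seed, log=log
        )
        histories.append({"repetition": rep, "fold": fold, **history})
        for sample in list(samples) + list(validation_samples):
            out = multicrop_inference(
                network,
                sample,
                schedule.crop_size,
                n_crops=schedule.n_inference_crops,
                seed=model_seed,
            )
            row = {"repetition": rep, "fold": fold, "patient_id": sample.patient_id}
            if "log_hazard" in out:
                row["log_hazard"] = float(out["log_hazard"])
            if "conditional_probs" in out:
                for k, p in enumerate(out["conditional_probs"], start=1):
                    row[f"gh_{k}"] = float(p)
            pred_rows.append(row)
    per_model = pd.DataFrame(pred_rows)
    table = aggregate_ensembles(
        per_model, assignment, [s.patient_id for s in validation_samples]
    )
    return table, per_model, assignment, histories


def ensemble_report(
    table: EnsembleTable,
    records_by_id: dict[str, SurvivalRecord],
    grid: IntervalGrid = IntervalGrid(),
    t_months: float = 24.0,
) -> pd.DataFrame:
    """Discrimination and stratification summary per head and ensemble role.

    The Cox head is read as a hazard (small C-index = good discrimination);
    the discrete-time head is evaluated through the predicted survival
    probability at ``t_months`` (large C-index = good).  Stratification
    thresholds always come from the training-ensemble predictions.
    """
    df = table.table
    gh_cols = [c for c in df.columns if c.startswith("gh_")]
    heads = []
    if "log_hazard" in df.columns:
        heads.append(("cox", "hazard"))
    if gh_cols:
        heads.append(("gh", "survival"))
    rows = []
    for head, orientation in heads:
        def values(sub):
            if head == "cox":
                return sub["log_hazard"].to_numpy()
            return np.array([
                survival_at(r[gh_cols].to_numpy(dtype=float), grid, t_months)
                for _, r in sub.iterrows()
            ])

        train_sub = df[df.ensemble_role == "training"]
        train_values = values(train_sub)
        for role in ("training", "internal_test", "validation"):
            sub = df[df.ensemble_role == role]
            if sub.empty:
                continue
            preds = values(sub)
            recs = [records_by_id[p] for p in sub.patient_id]
            conc = concordance_index(preds, recs, orientation)
            strat = stratify_by_median(train_values, preds, recs, orientation)
            rows.append(
                {
                    "head": head,
                    "role": role,
                    "n_patients": len(sub),
                    "c_index": conc.c_index,
                    "ci_low": conc.ci_low,
                    "ci_high": conc.ci_high,
                    "logrank_statistic": strat.statistic,
                    "logrank_p": strat.p_value,
                }
            )
    return pd.DataFrame(rows)
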