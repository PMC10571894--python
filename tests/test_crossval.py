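"""Cross-validation protocol: folds, sampling, training loop, ensembles."""

import numpy as np
import pandas as pd
import pytest

import mtsurv.crossval as crossval
from mtsurv.crossval import (
    aggregate_ensembles,
    event_balanced_batches,
    make_folds,
    run_cross_validation,
    tiny_schedule,
    train_one_model,
)
from mtsurv.networks import build_network, tiny_cnn_config
from mtsurv.survival import IntervalGrid, SurvivalRecord
from conftest import random_records


def records_with_events(n, n_events, rng):
    times = rng.exponential(30, n)
    events = np.zeros(n, dtype=int)
    events[:n_events] = 1
    rng.shuffle(events)
    return [SurvivalRecord(float(t), int(e), f"P{i}") for i, (t, e) in enumerate(zip(times, events))]


# -- fold assignment -----------------------------------------------------------


def test_folds_stratify_events(rng):
    records = records_with_events(100, 40, rng)
    assignment = make_folds(records, n_folds=5, n_repetitions=3, seed=1)
    by_id = {r.patient_id: r.event for r in records}
    for (rep, fold), test_ids in assignment.test_sets.items():
        events_in_fold = sum(by_id[p] for p in test_ids)
        assert events_in_fold == pytest.approx(8, abs=1)


def test_folds_partition_cohort(rng):
    records = records_with_events(30, 12, rng)
    assignment = make_folds(records, n_folds=5, n_repetitions=2, seed=0)
    for rep in (1, 2):
        union = set()
        total = 0
        for fold in range(1, 6):
            ts = assignment.test_sets[(rep, fold)]
            assert not (union & ts), "folds overlap"
            union |= ts
            total += len(ts)
        assert union == set(assignment.patient_ids) and total == 30


def test_folds_deterministic_and_seed_sensitive(rng):
    records = records_with_events(40, 15, rng)
    a = make_folds(records, seed=5)
    b = make_folds(records, seed=5)
    c = make_folds(records, seed=6)
    assert a.test_sets == b.test_sets
    assert a.test_sets != c.test_sets


def test_folds_input_validation(rng):
    records = records_with_events(20, 8, rng)
    with pytest.raises(ValueError, match="at least 2"):
        make_folds(records, n_folds=1)
    few_events = records_with_events(20, 3, rng)
    with pytest.raises(ValueError, match="'events'"):
        make_folds(few_events, n_folds=5)
    few_censored = records_with_events(20, 18, rng)
    with pytest.raises(ValueError, match="'censored'"):
        make_folds(few_censored, n_folds=5)


# -- event-balanced sampling ---------------------------------------------------


def test_balanced_batches_half_events_on_imbalanced_cohort(rng):
    records = records_with_events(200, 20, rng)  # 90% censored
    batches = list(event_balanced_batches(records, batch_size=16, seed=0, n_batches=400))
    events = np.array([r.event for r in records])
    mean_events = np.mean([events[b].sum() for b in batches])
    assert mean_events == pytest.approx(8.0, abs=0.6)


def test_balanced_batches_uniform_on_balanced_cohort(rng):
    records = records_with_events(100, 50, rng)
    batches = list(event_balanced_batches(records, batch_size=16, seed=1, n_batches=300))
    events = np.array([r.event for r in records])
    mean_events = np.mean([events[b].sum() for b in batches])
    assert mean_events == pytest.approx(8.0, abs=0.6)


def test_balanced_batches_deterministic(rng):
    records = records_with_events(50, 20, rng)
    a = list(event_balanced_batches(records, 8, seed=3, n_batches=10))
    b = list(event_balanced_batches(records, 8, seed=3, n_batches=10))
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


def test_balanced_batches_single_class_falls_back_uniform(rng):
    records = [SurvivalRecord(float(i + 1), 0, f"C{i}") for i in range(10)]
    with pytest.warns(UserWarning, match="single-class"):
        batches = list(event_balanced_batches(records, 8, seed=0, n_batches=5))
    assert len(batches) == 5


# -- training loop -------------------------------------------------------------


def test_zero_epochs_returns_initialization(tiny_cohort):
    samples, _, _ = tiny_cohort
    net = build_network(tiny_cnn_config(), seed=0)
    before = {k: v.copy() for k, v in net.state_dict().items()}
    _, history = train_one_model(net, samples[:6], samples[6:10], tiny_schedule(epochs=0))
    after = net.state_dict()
    assert all(np.array_equal(before[k], after[k]) for k in before)
    assert history["train"] == [] and history["best_epoch"] == -1


def test_checkpoint_restores_lowest_internal_test_loss(tiny_cohort, monkeypatch):
    """With injected internal-test losses [3, 1, 2], epoch-2 weights return."""
    samples, _, _ = tiny_cohort
    injected = iter([9.0, 3.0, 1.0, 2.0])  # initial eval, then epochs 1..3
    snapshots = {}

    def fake_evaluate(network, samples_, schedule, grid):
        value = next(injected)
        snapshots[value] = {k: v.copy() for k, v in network.state_dict().items()}
        return {"total": value}

    monkeypatch.setattr(crossval, "evaluate_loss", fake_evaluate)
    net = build_network(tiny_cnn_config(), seed=1)
    _, history = train_one_model(net, samples[:6], samples[6:10], tiny_schedule(epochs=3))
    assert history["best_epoch"] == 2
    final = net.state_dict()
    assert all(np.array_equal(final[k], snapshots[1.0][k]) for k in final)


def test_training_reduces_internal_test_loss(tiny_cohort):
    """On a separable toy cohort the selected checkpoint improves on epoch 1."""
    samples, _, _ = tiny_cohort
    net = build_network(tiny_cnn_config(), seed=2)
    _, history = train_one_model(
        net, samples[:16], samples[16:], tiny_schedule(epochs=4), seed=0
    )
    totals = [h["total"] for h in history["test"]]
    assert min(totals) <= totals[0]
    assert len(history["train"]) == 4


def test_nonfinite_loss_aborts_with_term_name(tiny_cohort):
    samples, _, _ = tiny_cohort
    net = build_network(tiny_cnn_config(), seed=3)
    for p in net.parameters():
        p.value = p.value * np.nan
    with pytest.raises(RuntimeError, match="non-finite"):
        train_one_model(net, samples[:8], samples[8:12], tiny_schedule(epochs=1))


# -- ensemble aggregation ------------------------------------------------------


def constant_predictions(assignment, validation_ids, value=0.25):
    rows = []
    for rep, fold in assignment.models():
        for pid in list(assignment.patient_ids) + list(validation_ids):
            rows.append(
                {"repetition": rep, "fold": fold, "patient_id": pid,
                 "log_hazard": value, "gh_1": value, "gh_2": value}
            )
    return pd.DataFrame(rows)


def test_ensemble_sizes_15_12_3(rng):
    records = records_with_events(60, 24, rng)
    assignment = make_folds(records, n_folds=5, n_repetitions=3, seed=0)
    per_model = constant_predictions(assignment, ["V0", "V1"])
    table = aggregate_ensembles(per_model, assignment, ["V0", "V1"]).table
    assert set(table[table.ensemble_role == "training"].n_models) == {12}
    assert set(table[table.ensemble_role == "internal_test"].n_models) == {3}
    assert set(table[table.ensemble_role == "validation"].n_models) == {15}
    # training + internal-test models partition the full set of 15
    assert (table[table.ensemble_role != "validation"]
            .groupby("patient_id").n_models.sum() == 15).all()


def test_ensemble_sizes_single_repetition(rng):
    records = records_with_events(25, 10, rng)
    assignment = make_folds(records, n_folds=5, n_repetitions=1, seed=0)
    table = aggregate_ensembles(constant_predictions(assignment, []), assignment).table
    assert set(table[table.ensemble_role == "training"].n_models) == {4}
    assert set(table[table.ensemble_role == "internal_test"].n_models) == {1}


def test_constant_models_average_to_constant(rng):
    records = records_with_events(20, 8, rng)
    assignment = make_folds(records, n_folds=4, n_repetitions=2, seed=1)
    table = aggregate_ensembles(constant_predictions(assignment, [], 0.7), assignment).table
    np.testing.assert_allclose(table["log_hazard"], 0.7)
    np.testing.assert_allclose(table["gh_2"], 0.7)


def test_ensemble_mean_permutation_invariant(rng):
    records = records_with_events(20, 8, rng)
    assignment = make_folds(records, n_folds=4, n_repetitions=2, seed=1)
    per_model = constant_predictions(assignment, [])
    per_model["log_hazard"] = rng.normal(size=len(per_model))
    shuffled = per_model.sample(frac=1.0, random_state=0)
    a = aggregate_ensembles(per_model, assignment).table.sort_values(
        ["patient_id", "ensemble_role"]).reset_index(drop=True)
    b = aggregate_ensembles(shuffled, assignment).table.sort_values(
        ["patient_id", "ensemble_role"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_missing_prediction_names_model_and_patient(rng):
    records = records_with_events(20, 8, rng)
    assignment = make_folds(records, n_folds=4, n_repetitions=1, seed=1)
    per_model = constant_predictions(assignment, [])
    dropped = per_model.drop(per_model[(per_model.repetition == 1) & (per_model.fold == 2)
                                       & (per_model.patient_id == "P3")].index)
    with pytest.raises(ValueError, match=r"rep 1, fold 2.*'P3'"):
        aggregate_ensembles(dropped, assignment)


# -- full run determinism ------------------------------------------------------


def test_run_cross_validation_deterministic(tiny_cohort):
    samples, _, _ = tiny_cohort
    cfg = tiny_cnn_config()
    sched = tiny_schedule(epochs=1, n_inference_crops=2)
    results = [
        run_cross_validation(samples, cfg, sched, n_folds=2, n_repetitions=1, seed=4)
        for _ in range(2)
    ]
    pd.testing.assert_frame_equal(results[0][0].table, results[1][0].table)
    pd.testing.assert_frame_equal(results[0][1], results[1][1])
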