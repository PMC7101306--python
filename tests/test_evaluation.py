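"""Confusion matrix, report metrics, kappa, ablation, counterfactual probe."""

from fractions import Fraction

import numpy as np
import pytest
import sklearn.metrics
from hypothesis import given, settings
from hypothesis import strategies as st

import tdarx as T

TRUE_50 = ["RA"] * 10 + ["nonRA"] * 40
PRED_50 = ["RA"] * 10 + ["RA"] + ["nonRA"] * 39  # one false positive


def test_confusion_worked_example():
    m = T.confusion(TRUE_50, PRED_50)
    assert (m.tp, m.fn, m.fp, m.tn) == (10, 0, 1, 39)
    assert m.total == 50


def test_confusion_identical_and_empty_lists():
    m = T.confusion(TRUE_50, TRUE_50)
    assert (m.fn, m.fp) == (0, 0)
    empty = T.confusion([], [])
    assert empty.total == 0


def test_confusion_rejects_bad_input():
    with pytest.raises(ValueError, match="equal length"):
        T.confusion(["RA"], [])
    with pytest.raises(ValueError, match="unknown label"):
        T.confusion(["RA"], ["maybe"])


def test_report_metrics_worked_example():
    metrics = T.prf_accuracy(T.confusion(TRUE_50, PRED_50))
    assert metrics.precision_pct == 91
    assert metrics.recall_pct == 100
    assert metrics.accuracy_pct == 98
    assert metrics.precision == Fraction(10, 11)
    assert metrics.recall == Fraction(1, 1)
    assert metrics.accuracy == Fraction(49, 50)


def test_perfect_matrix_scores_hundreds():
    metrics = T.prf_accuracy(T.ConfusionMatrix(tp=10, fn=0, fp=0, tn=40))
    assert (metrics.precision_pct, metrics.recall_pct,
            metrics.accuracy_pct) == (100, 100, 100)


def test_zero_denominator_metrics_are_undefined_not_zero():
    metrics = T.prf_accuracy(T.ConfusionMatrix(tp=0, fn=0, fp=0, tn=5))
    assert metrics.precision is None and metrics.precision_pct is None
    assert metrics.recall is None
    assert metrics.accuracy == Fraction(1, 1)


def test_metric_identities_against_sklearn():
    rng = np.random.default_rng(0)
    for _ in range(20):
        true = rng.choice(["RA", "nonRA"], size=40)
        pred = rng.choice(["RA", "nonRA"], size=40)
        if len(set(true)) < 2:
            continue
        m = T.prf_accuracy(T.confusion(true, pred))
        assert float(m.accuracy) == pytest.approx(
            sklearn.metrics.accuracy_score(true, pred))
        if m.precision is not None:
            assert float(m.precision) == pytest.approx(
                sklearn.metrics.precision_score(true, pred, pos_label="RA"))
        if m.recall is not None:
            assert float(m.recall) == pytest.approx(
                sklearn.metrics.recall_score(true, pred, pos_label="RA"))


def test_kappa_perfect_agreement():
    assert T.cohens_kappa(TRUE_50, TRUE_50) == 1.0


def test_kappa_constructed_chance_case():
    assert T.cohens_kappa(("RA", "nonRA"), ("RA", "RA")) == 0.0


def test_kappa_matches_hand_formula_on_study_pattern():
    # agreement pattern with counts (10, 0, 1, 39):
    # p_o = 49/50, p_e = (11*10 + 39*40)/50^2
    p_o, p_e = 49 / 50, (11 * 10 + 39 * 40) / 2500
    expected = (p_o - p_e) / (1 - p_e)
    assert T.cohens_kappa(TRUE_50, PRED_50) == pytest.approx(expected,
                                                             abs=1e-9)
    assert expected == pytest.approx(0.940, abs=5e-4)


def test_kappa_rater_symmetry_and_sklearn_agreement():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a = rng.choice(["RA", "nonRA"], size=30)
        b = rng.choice(["RA", "nonRA"], size=30)
        k = T.cohens_kappa(a, b)
        assert k == pytest.approx(T.cohens_kappa(b, a))
        assert k == pytest.approx(sklearn.metrics.cohen_kappa_score(a, b))


def test_kappa_of_shuffled_rater_concentrates_near_zero():
    rng = np.random.default_rng(2)
    a = np.array(["RA"] * 30 + ["nonRA"] * 70)
    kappas = [T.cohens_kappa(a, rng.permutation(a)) for _ in range(1000)]
    assert abs(np.mean(kappas)) < 0.02
    assert np.std(kappas) < 0.15


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.sampled_from(["RA", "nonRA"]),
                          st.sampled_from(["RA", "nonRA"])),
                min_size=1, max_size=60))
def test_kappa_bounded_and_symmetric(pairs):
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    k = T.cohens_kappa(a, b)
    assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
    assert k == pytest.approx(T.cohens_kappa(b, a))
    if a == b:
        assert k == 1.0


def test_kappa_rejects_length_mismatch():
    with pytest.raises(ValueError):
        T.cohens_kappa(["RA"], ["RA", "RA"])


# ---------------------------------------------------------------------------
# Counterfactual probe
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def acpa_model(acpa_only_cohort):
    learning, test = acpa_only_cohort
    run = T.run_trials(learning, test, T.TrainingConfig(trials=1, base_seed=2))
    return run.selected_model, test


def test_probe_identity_value_changes_nothing(acpa_model):
    model, test = acpa_model
    record = test[0]
    result = T.counterfactual_probe(model, record, "acpa", record.acpa)
    assert not result.changed
    assert result.original_label == result.modified_label


def test_probe_does_not_mutate_the_record(acpa_model):
    model, test = acpa_model
    record = test[0]
    before = T.render_tda(record).array.copy()
    T.counterfactual_probe(model, record, "acpa", 500.0)
    assert np.array_equal(T.render_tda(record).array, before)


def test_probe_rejects_invalid_field_and_value(acpa_model):
    model, test = acpa_model
    with pytest.raises(KeyError):
        T.counterfactual_probe(model, test[0], "cholesterol", 1.0)
    with pytest.raises(ValueError):
        T.counterfactual_probe(model, test[0], "patient_vas", 400.0)


def test_probe_flips_predictions_when_field_is_the_signal(acpa_model):
    """On a model whose only informative block is ACPA, switching ACPA
    category flips the predicted label for most records."""
    model, test = acpa_model
    flipped = 0
    for record in test[:20]:
        new_value = 0.0 if record.acpa >= 4.5 else 100.0
        result = T.counterfactual_probe(model, record, "acpa", new_value)
        flipped += result.changed
    assert flipped > 10
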