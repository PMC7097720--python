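"""Error matrices, performance metrics, alert budgets, frequency table."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxmatch.matcher import Label, MatchOutcome, MatchStatus
from rxmatch.metrics import (
    ErrorMatrix,
    alert_budget,
    build_error_matrix,
    compute_metrics,
    dedupe_pairs,
    frequency_report,
)


def outcome(pid, label, rx="1", disp="2", status=None, scds=("100", "100")):
    status = status or (MatchStatus.MATCH if label == Label.TN else MatchStatus.MISMATCH)
    return MatchOutcome(
        pair_id=pid,
        status=status,
        label=label,
        rx_ndc=rx,
        disp_ndc=disp,
        rx_scds=frozenset({scds[0]}),
        disp_scds=frozenset({scds[1]}),
    )


def test_build_error_matrix_counts_labels():
    outs = [
        outcome("a", Label.TP),
        outcome("b", Label.FP),
        outcome("c", Label.TN),
        outcome("d", Label.TN),
    ]
    m = build_error_matrix(outs)
    assert (m.tp, m.fp, m.fn, m.tn) == (1, 1, 0, 2)
    assert build_error_matrix([]) == ErrorMatrix()


def test_unlabeled_outcomes_excluded_from_matrix():
    outs = [
        outcome("a", Label.TN),
        MatchOutcome(pair_id="m", status=MatchStatus.MISSING_RXCUI),
    ]
    assert build_error_matrix(outs).total == 1


def test_matrix_rejects_negative_counts():
    with pytest.raises(ValueError):
        ErrorMatrix(tp=-1)


def test_dedupe_keeps_first_of_each_ordered_ndc_pair():
    outs = [outcome(str(i), Label.TN, rx="A", disp="B") for i in range(5)]
    assert [o.pair_id for o in dedupe_pairs(outs)] == ["0"]
    both_orders = [
        outcome("x", Label.TN, rx="A", disp="B"),
        outcome("y", Label.TN, rx="B", disp="A"),
    ]
    assert len(dedupe_pairs(both_orders)) == 2  # ordered pairs are distinct


def test_published_total_pairs_metrics_to_5_decimals():
    m = ErrorMatrix(tp=4, fp=546, fn=0, tn=526_459)
    assert m.total == 527_009
    r = compute_metrics(m, mode="total").rounded()
    assert r == {
        "accuracy": 0.99896,
        "sensitivity": 1.0,
        "false_positive_rate": 0.00104,
        "specificity": 0.99896,
        "precision": 0.00727,
        "f1": 0.01444,
    }


def test_published_unique_pairs_metrics_to_5_decimals():
    m = ErrorMatrix(tp=4, fp=90, fn=0, tn=28_723)
    assert m.total == 28_817
    r = compute_metrics(m, mode="unique").rounded()
    assert r == {
        "accuracy": 0.99688,
        "sensitivity": 1.0,
        "false_positive_rate": 0.00312,
        "specificity": 0.99688,
        "precision": 0.04255,
        "f1": 0.08163,
    }


def test_degenerate_denominators_are_undefined_not_errors():
    r = compute_metrics(ErrorMatrix(tn=10))
    assert r.precision is None and r.sensitivity is None and r.f1 is None
    assert r.accuracy == 1.0


@pytest.mark.parametrize(
    "matrix,budget",
    [
        (ErrorMatrix(tp=4, fp=546, fn=0, tn=0), 138),  # 137.5 rounds half-up
        (ErrorMatrix(tp=4, fp=90, fn=0, tn=0), 24),  # 23.5 rounds half-up
        (ErrorMatrix(tp=1, fp=0, fn=0, tn=0), 1),
        (ErrorMatrix(tp=0, fp=9, fn=0, tn=0), None),
    ],
)
def test_alert_budget_half_up(matrix, budget):
    assert alert_budget(matrix) == budget


matrices = st.builds(
    ErrorMatrix,
    tp=st.integers(0, 1000),
    fp=st.integers(0, 1000),
    fn=st.integers(0, 1000),
    tn=st.integers(0, 10_000),
)


@settings(derandomize=True, max_examples=300)
@given(matrices)
def test_metric_identities(m):
    r = compute_metrics(m)
    if m.total:
        assert math.isclose(r.accuracy, (m.tp + m.tn) / m.total)
    if m.tp + m.fn:
        assert math.isclose(r.sensitivity, m.tp / (m.tp + m.fn))
    if m.fp + m.tn:
        assert math.isclose(r.false_positive_rate + r.specificity, 1.0)
    if m.tp + m.fp:
        assert math.isclose(r.precision, m.tp / (m.tp + m.fp))
    if r.f1 is not None:
        assert math.isclose(
            r.f1, 2 * r.precision * r.sensitivity / (r.precision + r.sensitivity)
        )
    for v in (r.accuracy, r.sensitivity, r.false_positive_rate, r.specificity, r.precision, r.f1):
        assert v is None or 0.0 <= v <= 1.0


@settings(derandomize=True, max_examples=100)
@given(matrices, st.integers(1, 50))
def test_monotonicity(m, k):
    base = compute_metrics(m)
    more_fp = compute_metrics(ErrorMatrix(m.tp, m.fp + k, m.fn, m.tn))
    if base.precision is not None:
        assert more_fp.precision <= base.precision  # adding FP never helps precision
    more_tp = compute_metrics(ErrorMatrix(m.tp + k, m.fp, m.fn, m.tn))
    if base.sensitivity is not None:
        assert more_tp.sensitivity >= base.sensitivity


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.integers(1, 8), min_size=0, max_size=30), st.randoms(use_true_random=False))
def test_unique_mode_invariant_under_duplication(multiplicities, rnd):
    """Metrics over unique pairs do not change when the stream duplicates
    NDC pairs arbitrarily."""
    labels = [Label.TP, Label.FP, Label.TN]
    base = [
        outcome(f"p{i}", labels[i % 3], rx=f"R{i}", disp=f"D{i}") for i in range(len(multiplicities))
    ]
    duplicated = [o for o, k in zip(base, multiplicities) for _ in range(k)]
    rnd.shuffle(duplicated)
    # keep first-occurrence order deterministic: dedupe keys only on NDC pair
    m_base = build_error_matrix(dedupe_pairs(base))
    m_dup = build_error_matrix(dedupe_pairs(duplicated))
    assert m_base == m_dup
    assert compute_metrics(m_base).rounded() == compute_metrics(m_dup).rounded()


class _NameStore:
    def concept(self, rxcui):
        class C:
            name = f"drug {rxcui}"

        return C


def test_frequency_report_percent_and_ties():
    outs = [outcome(str(i), Label.TN, rx=str(i), disp=str(i), scds=("100", "100")) for i in range(3)]
    outs.append(outcome("x", Label.FP, status=MatchStatus.MISMATCH, scds=("200", "300")))
    rows = frequency_report(outs, _NameStore())
    assert rows == [("100", "drug 100", 3, 75.0)]
    assert frequency_report([], _NameStore()) == []


def test_frequency_percent_printed_convention():
    # 7688 matches of one drug among 527,881 analyzed pairs prints as 1.46%
    outs = [outcome(str(i), Label.TN, rx=str(i), disp=str(i)) for i in range(7688)]
    rows = frequency_report(outs, _NameStore(), denominator=527_881)
    assert rows[0][2] == 7688 and rows[0][3] == 1.46
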