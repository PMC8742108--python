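"""Diagnostic evaluation: exact CIs, confusion, ROC/AUC, split hygiene."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats as sps

from panelforge.cohort import CohortConfig, MarkerSpec, generate_cohort, split_train_test
from panelforge.diagnostics import (
    Confusion,
    clopper_pearson_ci,
    confusion,
    empirical_roc,
    evaluate_split,
    logistic_combined_roc,
    summarize_diagnostics,
)
from panelforge.panel import CutoffRule, PanelBuildSpec, PanelDefinition, call_markers


def test_clopper_pearson_closed_form_at_boundaries():
    lower, upper = clopper_pearson_ci(151, 151)
    assert upper == 1.0
    assert lower == pytest.approx(0.025 ** (1 / 151), abs=1e-12)
    lower, upper = clopper_pearson_ci(0, 20)
    assert lower == 0.0
    assert upper == pytest.approx(1 - 0.025 ** (1 / 20), abs=1e-12)


def _cp_by_root_finding(x, n, level=0.95):
    """Oracle: solve the binomial tail-sum equalities numerically."""
    alpha = 1 - level
    lower = 0.0
    if x > 0:
        lower = optimize.brentq(
            lambda p: sum(sps.binom.pmf(k, n, p) for k in range(x, n + 1)) - alpha / 2,
            1e-12,
            1 - 1e-12,
        )
    upper = 1.0
    if x < n:
        upper = optimize.brentq(
            lambda p: sum(sps.binom.pmf(k, n, p) for k in range(0, x + 1)) - alpha / 2,
            1e-12,
            1 - 1e-12,
        )
    return lower, upper


@pytest.mark.parametrize("x,n", [(65, 73), (148, 151), (7, 20), (1, 10)])
def test_clopper_pearson_matches_tail_sum_oracle(x, n):
    got = clopper_pearson_ci(x, n)
    expected = _cp_by_root_finding(x, n)
    assert got[0] == pytest.approx(expected[0], abs=5e-5)
    assert got[1] == pytest.approx(expected[1], abs=5e-5)


def test_clopper_pearson_input_validation():
    with pytest.raises(ValueError):
        clopper_pearson_ci(5, 0)
    with pytest.raises(ValueError):
        clopper_pearson_ci(5, 3)


def _score_table(case_calls, control_calls):
    calls = list(case_calls) + list(control_calls)
    groups = ["invasive"] * len(case_calls) + ["control"] * len(control_calls)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(calls))],
            "group": groups,
            "panel_call": calls,
        }
    )


def test_confusion_counts_and_degenerate_inputs():
    table = _score_table([1, 1, 0], [0, 0, 1])
    assert confusion(table) == Confusion(tp=2, fp=1, tn=2, fn=1)
    perfect = _score_table([1, 1], [0, 0])
    c = confusion(perfect)
    assert c.fn == 0 and c.fp == 0
    with pytest.raises(ValueError, match="no cases"):
        confusion(_score_table([], [0, 1]))


def test_summary_metrics_and_display_rounding():
    s = summarize_diagnostics(Confusion(tp=151, fp=20, tn=146, fn=0))
    assert s.sensitivity == 1.0
    assert s.specificity == pytest.approx(146 / 166)
    row = s.display_row()
    assert row["sensitivity"].startswith("100% (")
    assert row["specificity"].startswith("88% (")
    even = summarize_diagnostics(Confusion(tp=1, fp=1, tn=1, fn=1))
    assert even.sensitivity == even.specificity == even.accuracy == 0.5
    with pytest.raises(ValueError):
        summarize_diagnostics(Confusion(tp=0, fp=0, tn=5, fn=0))


def _auc_pairs(cases, controls):
    return float(
        np.mean([(c > k) + 0.5 * (c == k) for c in cases for k in controls])
    )


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    cases=st.lists(st.integers(0, 5), min_size=1, max_size=10),
    controls=st.lists(st.integers(0, 5), min_size=1, max_size=10),
)
def test_auc_equals_concordant_pair_fraction(cases, controls):
    values = np.array(cases + controls, dtype=float)
    labels = np.array([True] * len(cases) + [False] * len(controls))
    roc = empirical_roc(values, labels)
    assert roc.auc == pytest.approx(_auc_pairs(cases, controls), abs=1e-12)


def test_roc_curve_endpoints_and_monotonicity():
    rng = np.random.default_rng(0)
    values = rng.normal(size=60)
    labels = np.array([True] * 30 + [False] * 30)
    roc = empirical_roc(values, labels)
    assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
    assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
    assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()


def test_perfect_separation_gives_auc_one_and_shuffle_gives_half():
    cases = np.arange(10, 20, dtype=float)
    controls = np.arange(0, 10, dtype=float)
    roc = empirical_roc(
        np.concatenate([cases, controls]),
        np.array([True] * 10 + [False] * 10),
    )
    assert roc.auc == 1.0
    rng = np.random.default_rng(1)
    values = rng.normal(size=2000)
    labels = rng.permutation([True] * 1000 + [False] * 1000)
    assert empirical_roc(values, labels).auc == pytest.approx(0.5, abs=0.05)
    with pytest.raises(ValueError):
        empirical_roc(values, np.array([True] * 2000))


def test_positive_below_direction_reverses_ranking():
    values = np.array([1.0, 2.0, 3.0, 4.0])
    labels = np.array([True, True, False, False])  # cases have LOW values
    assert empirical_roc(values, labels, "positive_below").auc == 1.0


def _logistic_table(n, seed, beta=(0.0, 1.2, -0.8)):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 2))
    lin = beta[0] + x @ np.array(beta[1:])
    y = rng.random(n) < 1 / (1 + np.exp(-lin))
    table = pd.DataFrame({"m1": x[:, 0], "m2": x[:, 1]})
    table["group"] = np.where(y, "invasive", "control")
    table["sample_id"] = [f"s{i}" for i in range(n)]
    return table, lin, y


def test_logistic_single_marker_matches_empirical_roc():
    table, _, y = _logistic_table(400, 2, beta=(0.0, 1.5, 0.0))
    fit = logistic_combined_roc(table, ["m1"])
    emp = empirical_roc(table["m1"].to_numpy(), y)
    assert fit.roc.auc == pytest.approx(emp.auc, abs=1e-12)


def test_logistic_recovers_signs_and_auc_of_true_model():
    table, lin, y = _logistic_table(5000, 7)
    fit = logistic_combined_roc(table, ["m1", "m2"])
    assert fit.converged and not fit.separation
    assert fit.coefficients["m1"] > 0 and fit.coefficients["m2"] < 0
    true_auc = empirical_roc(lin, y).auc
    assert abs(fit.roc.auc - true_auc) < 0.02


def test_logistic_flags_complete_separation():
    table = pd.DataFrame(
        {
            "m1": np.concatenate([np.linspace(2, 3, 20), np.linspace(0, 1, 20)]),
            "m2": np.concatenate([np.linspace(5, 6, 20), np.linspace(1, 2, 20)]),
            "group": ["invasive"] * 20 + ["control"] * 20,
            "sample_id": [f"s{i}" for i in range(40)],
        }
    )
    fit = logistic_combined_roc(table, ["m1", "m2"])
    assert fit.separation
    assert fit.roc.auc == 1.0


def _mu_cohort(seed, sizes=None):
    groups = ("control", "benign", "DCIS", "invasive")
    markers = [
        MarkerSpec(
            name=f"g{i}_meth",
            kind="mu_ratio",
            group_location=dict(zip(groups, (0.2, 0.25, 4.0, 5.0))),
            group_scale=0.4,
        )
        for i in range(3)
    ]
    cfg = CohortConfig(
        group_sizes=sizes or {"control": 80, "benign": 15, "DCIS": 8, "invasive": 80},
        markers=markers,
        seed=seed,
    )
    return generate_cohort(cfg), [m.name for m in markers]


def test_evaluate_split_train_equals_test_when_identical():
    table, markers = _mu_cohort(1)
    spec = PanelBuildSpec(markers=tuple(markers), rule="fixed_value", select=False)
    res = evaluate_split(table, table.copy(), spec)
    assert res.train_summary == res.test_summary


def test_evaluate_split_freezes_thresholds_against_test_data():
    table, markers = _mu_cohort(2)
    train, test = split_train_test(table, 0.7, seed=0)
    spec = PanelBuildSpec(markers=tuple(markers), rule="median_plus_k_mad", k=1.0)
    res1 = evaluate_split(train, test, spec, combined_roc=False)
    mutated = test.copy()
    mutated[markers] = mutated[markers] * 100.0
    res2 = evaluate_split(train, mutated, spec, combined_roc=False)
    assert res1.panel == res2.panel  # no test-set value touches any threshold


def test_evaluate_split_strong_separation_recovers_on_test_set():
    hits = []
    for seed in range(10):
        table, markers = _mu_cohort(seed)
        train, test = split_train_test(table, 0.7, seed=seed)
        spec = PanelBuildSpec(markers=tuple(markers), rule="fixed_value", select=False)
        res = evaluate_split(train, test, spec, combined_roc=False)
        hits.append(
            res.test_summary.sensitivity > 0.95 and res.test_summary.specificity > 0.95
        )
    assert all(hits)


def test_evaluate_split_without_controls_raises():
    table, markers = _mu_cohort(3)
    train, test = split_train_test(table, 0.7, seed=1)
    no_controls = test[test["group"].isin(["DCIS", "invasive"])].reset_index(drop=True)
    spec = PanelBuildSpec(markers=tuple(markers), rule="fixed_value", select=False)
    with pytest.raises(ValueError, match="no controls"):
        evaluate_split(train, no_controls, spec, combined_roc=False)
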