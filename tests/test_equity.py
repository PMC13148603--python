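"""Equity audit: groups, confusion metrics, DOR, CV, thresholds, deciles."""

import numpy as np
import pandas as pd
import pytest

from utiaudit.cohort import CohortConfig, DemographicCell, generate_cohort
from utiaudit.equity import (
    AuditConfig,
    GroupMetrics,
    IntersectionalGroup,
    build_intersectional_groups,
    coefficient_of_variation,
    confusion_at_threshold,
    cv_confidence_interval,
    decile_diagnosis_table,
    diagnostic_odds_ratio,
    run_full_audit,
    select_policy_constrained_threshold,
    youden_optimal_threshold,
)
from utiaudit.errors import ConfigurationError, InfeasibleThresholdError
from utiaudit.harmonize import harmonize_table
from utiaudit.labeling import label_table


# ------------------------------------------------------------- grouping ----

def _demo_df(cells):
    rows = []
    for i, (key, n) in enumerate(cells.items()):
        age, sex, race, eth = key
        rows += [{"age_bin": age, "sex": sex, "race": race, "ethnicity": eth}] * n
    return pd.DataFrame(rows)


def test_group_size_floor_excludes_small_cells():
    df = _demo_df({("18-44", "female", "white", "non-hispanic"): 2500,
                   ("18-44", "male", "white", "non-hispanic"): 1999})
    groups = build_intersectional_groups(df, AuditConfig(min_group_size=2000))
    assert [g.n for g in groups] == [2500]


def test_empty_cohort_yields_no_groups():
    df = _demo_df({("18-44", "female", "white", "non-hispanic"): 1}).iloc[:0]
    assert build_intersectional_groups(df, AuditConfig()) == []


def test_generator_mix_with_nineteen_heavy_cells_yields_nineteen_groups():
    """A demographic mix built with 19 heavy cells plus a light tail gives
    exactly 19 audit groups (the treemap structure, at demo scale)."""
    heavy, light = [], []
    races = ("white", "black", "other or not listed")
    ages = ("18-44", "45-64", "65-84", "85+")
    cells = [(a, s, r, e) for a in ages for s in ("female", "male")
             for r in races for e in ("non-hispanic", "hispanic")]
    for i, key in enumerate(cells):
        (heavy if i < 19 else light).append(
            DemographicCell(age_bin=key[0], sex=key[1], race=key[2],
                            ethnicity=key[3],
                            weight=0.045 if i < 19 else 0.145 / (len(cells) - 19))
        )
    cfg = CohortConfig(n_encounters=20_000, n_patients=19_000,
                       demographic_mix=heavy + light, seed=17)
    t = generate_cohort(cfg)
    groups = build_intersectional_groups(t, AuditConfig(min_group_size=500))
    assert len(groups) == 19
    # deterministic ordering: size descending
    sizes = [g.n for g in groups]
    assert sizes == sorted(sizes, reverse=True)


# ------------------------------------------------- confusion arithmetic ----

def test_paper_scale_physician_confusion_rates():
    """Counts at the scale of a large ED cohort reproduce the expected
    overdiagnosis (FP/(FP+TN)) and underdiagnosis (FN/(TP+FN)) rates."""
    decisions = np.r_[np.ones(12_735), np.zeros(7_345), np.ones(11_807), np.zeros(117_562)]
    truth = np.r_[np.ones(20_080), np.zeros(129_369)]
    m = confusion_at_threshold(decisions.astype(bool), truth.astype(bool))["overall"]
    assert m.tp == 12_735 and m.fn == 7_345 and m.fp == 11_807 and m.tn == 117_562
    assert m.overdiagnosis == pytest.approx(0.091, abs=5e-4)
    assert m.underdiagnosis == pytest.approx(0.366, abs=5e-4)


def test_all_correct_predictions():
    truth = np.r_[np.ones(5, bool), np.zeros(5, bool)]
    m = confusion_at_threshold(truth, truth)["overall"]
    assert m.overdiagnosis == 0 and m.underdiagnosis == 0 and m.accuracy == 1


def test_confusion_cells_reconcile_per_group(labeled_cohort, cohort_probs):
    groups = build_intersectional_groups(labeled_cohort, AuditConfig(min_group_size=150))
    truth = labeled_cohort["strict_uti"].to_numpy(bool)
    res = confusion_at_threshold(cohort_probs, truth, threshold=0.3, groups=groups)
    total = res["overall"]
    assert total.tp + total.fp + total.fn + total.tn == len(labeled_cohort)
    for g in groups:
        m = res["groups"][g.key]
        assert m.tp + m.fp + m.fn + m.tn == m.n == g.n
        # rates, accuracy and DOR must be consistent with the four cells
        assert m.accuracy == pytest.approx((m.tp + m.tn) / m.n)
        if min(m.tp, m.fp, m.fn, m.tn) > 0:
            assert m.dor == pytest.approx((m.tp / m.fn) / (m.fp / m.tn))
        assert m.overdiagnosis + (m.tn / (m.fp + m.tn)) == pytest.approx(1.0)
        assert m.underdiagnosis + (m.tp / (m.tp + m.fn)) == pytest.approx(1.0)


# ------------------------------------------------------------------ DOR ----

@pytest.mark.parametrize(
    "cells, expected",
    [((9, 1, 1, 9), 81.0), ((5, 5, 5, 5), 1.0), ((5, 2, 0, 3), (5.5 / 0.5) / (2.5 / 3.5))],
)
def test_diagnostic_odds_ratio_values(cells, expected):
    assert diagnostic_odds_ratio(*cells) == pytest.approx(expected)


def test_dor_zero_cell_flagged_and_all_zero_rejected():
    m = GroupMetrics.from_decisions(
        ("g",), np.r_[np.ones(7, bool), np.zeros(3, bool)],
        np.r_[np.ones(5, bool), np.zeros(2, bool), np.ones(0, bool), np.zeros(3, bool)],
    )
    assert m.fn == 0 and m.dor_corrected
    with pytest.raises(ConfigurationError):
        diagnostic_odds_ratio(0, 0, 0, 0)


# ----------------------------------------------------- threshold choice ----

def _toy_groups(sizes):
    groups, start = [], 0
    for i, n in enumerate(sizes):
        groups.append(IntersectionalGroup(key=(f"g{i}",), indices=np.arange(start, start + n), n=n))
        start += n
    return groups


def test_policy_scan_vacuous_constraint_returns_top():
    truth = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    probs = np.r_[np.full(10, 0.995), np.full(10, 0.001)]
    phys = np.zeros(20, bool)  # physician misses everything: FNR = 1
    t = select_policy_constrained_threshold(probs, truth, phys, _toy_groups([20]), AuditConfig())
    assert t == 99


def test_policy_scan_two_group_separated_scores():
    """Separated scores (positives >=0.8, negatives <=0.2) against physician
    FNRs {0.4, 0.3}: model FNR is 0 up to threshold 80 and 1 above."""
    rows = []
    for fnr, n_pos in ((0.4, 50), (0.3, 50)):
        truth = np.r_[np.ones(n_pos, bool), np.zeros(50, bool)]
        miss = np.zeros(n_pos, bool)
        miss[: int(fnr * n_pos)] = True
        phys = np.r_[~miss, np.zeros(50, bool)]
        probs = np.r_[np.full(n_pos, 0.8), np.full(50, 0.2)]
        rows.append((truth, phys, probs))
    truth = np.concatenate([r[0] for r in rows])
    phys = np.concatenate([r[1] for r in rows])
    probs = np.concatenate([r[2] for r in rows])
    t = select_policy_constrained_threshold(
        probs, truth, phys, _toy_groups([100, 100]), AuditConfig()
    )
    assert t == 80


def test_policy_scan_matches_brute_force_enumeration(rng):
    """Implementation agrees with an exhaustive scan over all candidates."""
    n = 400
    truth = rng.random(n) < 0.3
    probs = np.clip(rng.normal(0.3 + 0.3 * truth, 0.25), 0, 1)
    phys = np.where(truth, rng.random(n) < 0.7, rng.random(n) < 0.1)
    groups = _toy_groups([200, 200])
    cfg = AuditConfig()

    def fnr(dec, t_mask):
        return (~dec[t_mask]).mean()

    feasible = []
    for t in range(1, 100):
        dec = probs >= t / 100
        ok = True
        for g in groups:
            gt = truth[g.indices]
            if gt.any() and not fnr(dec[g.indices], gt) < fnr(phys[g.indices], gt):
                ok = False
        if ok:
            feasible.append(t)
    if feasible:
        assert select_policy_constrained_threshold(probs, truth, phys, groups, cfg) == max(feasible)
    else:
        with pytest.raises(InfeasibleThresholdError):
            select_policy_constrained_threshold(probs, truth, phys, groups, cfg)


def test_policy_scan_infeasible_lists_groups():
    truth = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    probs = np.zeros(20)  # model never detects anyone at any threshold
    phys = np.r_[np.ones(10, bool), np.zeros(10, bool)]  # physician FNR = 0
    with pytest.raises(InfeasibleThresholdError) as err:
        select_policy_constrained_threshold(probs, truth, phys, _toy_groups([20]), AuditConfig())
    assert err.value.violating_groups == [("g0",)]


def test_youden_separated_scores_tie_breaks_low():
    truth = np.r_[np.ones(30, bool), np.zeros(30, bool)]
    probs = np.r_[np.full(30, 0.85), np.full(30, 0.2)]
    assert youden_optimal_threshold(probs, truth, range(1, 100)) == 21


def test_youden_matches_brute_force(rng):
    truth = rng.random(500) < 0.25
    probs = np.clip(rng.normal(0.3 + 0.25 * truth, 0.2), 0, 1)
    best_j, best_t = -np.inf, None
    for t in range(1, 100):
        d = probs >= t / 100
        j = d[truth].mean() - d[~truth].mean()
        if j > best_j:
            best_j, best_t = j, t
    assert youden_optimal_threshold(probs, truth, range(1, 100)) == best_t


def test_youden_null_scores_and_single_candidate(rng):
    truth = rng.random(5000) < 0.3
    probs = rng.random(5000)
    t = youden_optimal_threshold(probs, truth, range(1, 100))
    d = probs >= t / 100
    assert abs(d[truth].mean() - d[~truth].mean()) < 0.06  # J stays near 0
    assert youden_optimal_threshold(probs, truth, [37]) == 37


def test_threshold_monotonicity(labeled_cohort, cohort_probs):
    """Lowering the threshold never increases underdiagnosis and never
    decreases overdiagnosis."""
    truth = labeled_cohort["strict_uti"].to_numpy(bool)
    unders, overs = [], []
    for t in range(1, 100, 7):
        m = confusion_at_threshold(cohort_probs, truth, threshold=t / 100)["overall"]
        unders.append(m.underdiagnosis)
        overs.append(m.overdiagnosis)
    assert all(a <= b for a, b in zip(unders, unders[1:]))  # rising t
    assert all(a >= b for a, b in zip(overs, overs[1:]))


# ------------------------------------------------------------------- CV ----

@pytest.mark.parametrize(
    "values, expected",
    [([1, 1, 1], 0.0), ([2, 4, 6], 0.5), ([10, 20], 7.0710678 / 15)],
)
def test_coefficient_of_variation_values(values, expected):
    assert coefficient_of_variation(values).cv == pytest.approx(expected, abs=1e-6)


def test_cv_requires_positive_mean_and_two_values():
    with pytest.raises(ConfigurationError):
        coefficient_of_variation([5.0])
    with pytest.raises(ConfigurationError):
        coefficient_of_variation([1.0, -3.0])


def test_cv_interval_formula():
    lo, hi = cv_confidence_interval(0.48, 19)
    assert lo == pytest.approx(0.48 - 1.96 / 6, abs=1e-9)
    assert hi == pytest.approx(0.48 + 1.96 / 6, abs=1e-9)
    lo, hi = cv_confidence_interval(0.039, 19)
    assert lo == 0.0  # floored
    big_lo, big_hi = cv_confidence_interval(0.5, 10_001)
    assert big_hi - big_lo < 0.03  # width shrinks as groups grow


# -------------------------------------------------------------- deciles ----

def test_decile_step_function_physician():
    probs = np.linspace(0, 1, 1000)
    phys = probs >= np.median(probs)
    table = decile_diagnosis_table(probs, phys)
    assert table["physician_dx_rate"].tolist() == [0] * 5 + [1] * 5
    assert (table["n"] == 100).all()


def test_decile_independent_physician_is_flat(rng):
    probs = rng.random(20_000)
    phys = rng.random(20_000) < 0.3
    table = decile_diagnosis_table(probs, phys)
    assert table["physician_dx_rate"].std() < 0.02


def test_decile_calibrated_truth_increases(rng):
    probs = rng.uniform(0, 1, 20_000)
    truth = rng.random(20_000) < probs
    table = decile_diagnosis_table(probs, truth < 2, truth=truth)
    rates = table["culture_positive_rate"].to_numpy()
    assert (np.diff(rates) > 0).all()


def test_decile_needs_ten_rows():
    with pytest.raises(ConfigurationError):
        decile_diagnosis_table(np.linspace(0, 1, 5), np.zeros(5, bool))


# ------------------------------------------------------------ full audit ----

def test_full_audit_report_structure(labeled_cohort, cohort_probs):
    cfg = AuditConfig(min_group_size=150)
    report = run_full_audit(labeled_cohort, cohort_probs, cfg)
    assert report["n_audit_groups"] >= 2
    for definition in ("strict", "liberal"):
        section = report["definitions"][definition]
        for source in ("model_policy", "model_fixed_clinician", "model_youden", "physician"):
            payload = section["sources"][source]
            assert len(payload["per_group"]) == report["n_audit_groups"]
            assert {"accuracy", "dor"} <= set(payload["cv"])
    assert len(report["decile_table"]) == 10


def test_identical_decisions_give_identical_metrics(labeled_cohort):
    """Thresholding the physician's own decisions as 'model probabilities'
    reproduces the physician's metrics and CVs exactly.  (A policy-constrained
    threshold is correctly infeasible then: the model's underdiagnosis can
    never be strictly below its own.)"""
    from utiaudit.equity import cv_with_ci

    cfg = AuditConfig(min_group_size=150)
    phys = labeled_cohort["physician_diagnosed"].to_numpy(bool)
    truth = labeled_cohort["liberal_uti"].to_numpy(bool)
    groups = build_intersectional_groups(labeled_cohort, cfg)
    as_model = confusion_at_threshold(phys.astype(float), truth, threshold=0.423, groups=groups)
    as_phys = confusion_at_threshold(phys, truth, groups=groups)
    assert as_model["overall"] == as_phys["overall"]
    for key in as_phys["groups"]:
        assert as_model["groups"][key].to_dict() == as_phys["groups"][key].to_dict()
    cv_a = cv_with_ci([m.accuracy for m in as_model["groups"].values()], "accuracy")
    cv_b = cv_with_ci([m.accuracy for m in as_phys["groups"].values()], "accuracy")
    assert cv_a == cv_b

    with pytest.raises(InfeasibleThresholdError):
        select_policy_constrained_threshold(phys.astype(float), truth, phys, groups, cfg)


def test_liberal_only_audit_omits_strict_and_says_so(labeled_cohort, cohort_probs):
    cfg = AuditConfig(min_group_size=150, definitions=("liberal",))
    report = run_full_audit(labeled_cohort, cohort_probs, cfg)
    assert "strict" not in report["definitions"]
    assert report["metadata"]["definitions_omitted"] == ["strict"]


def test_model_dominates_physician_when_generator_says_so():
    """With a weak simulated physician and informative urinalysis, the model
    beats the physician on both error rates in every audit group."""
    from utiaudit.classifier import TrainingProtocol, cross_fit_probabilities, tune_and_fit
    from utiaudit.cohort import PhysicianBehavior

    cfg = CohortConfig(
        n_encounters=6000, n_patients=5100, seed=23,
        physician_behavior=PhysicianBehavior(sensitivity=0.45, false_positive_rate=0.2),
    )
    t = label_table(harmonize_table(generate_cohort(cfg)))
    proto = TrainingProtocol(n_trials=1, search_space={"n_estimators": (60, 120), "max_depth": (3, 5)}, seed=2)
    model = tune_and_fit(t, proto)
    probs = cross_fit_probabilities(t, model.params, proto)
    audit_cfg = AuditConfig(min_group_size=300)
    report = run_full_audit(t, probs, audit_cfg)
    section = report["definitions"]["strict"]["sources"]
    phys_by_group = {g["group"]: g for g in section["physician"]["per_group"]}
    for g in section["model_policy"]["per_group"]:
        p = phys_by_group[g["group"]]
        assert g["underdiagnosis"] < p["underdiagnosis"]
        assert g["overdiagnosis"] < p["overdiagnosis"]
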