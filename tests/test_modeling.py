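"""Grouped cross-validation, metrics, Mann-Whitney comparisons."""

import numpy as np
import pandas as pd
import pytest

from svxresp.errors import ValidationError
from svxresp.features import feature_columns
from svxresp.labeling import PSP, TP
from svxresp.modeling import (
    RfConfig,
    classification_report,
    compare_percentile_features,
    cross_validate,
    grouped_folds,
    macro_auc_score,
    mann_whitney_u,
    significance_stars,
)


def _toy_table(n_patients=20, svx_per_patient=4, signal=10.0, seed=0):
    """Feature table with one informative column and noise elsewhere."""
    rng = np.random.default_rng(seed)
    rows = []
    cols = feature_columns()
    for p in range(n_patients):
        for s in range(svx_per_patient):
            label = TP if (p + s) % 2 == 0 else PSP
            rec = {c: rng.normal() for c in cols}
            rec["PET__firstorder__mean"] = (
                signal if label == TP else -signal
            ) + rng.normal()
            rows.append(
                {
                    "patient_id": f"P{p:03d}",
                    "case_id": f"P{p:03d}_c0",
                    "supervoxel_id": s + 1,
                    "label": label,
                    "n_voxels": 200,
                    **rec,
                }
            )
    return pd.DataFrame(rows)


def test_grouped_folds_every_patient_in_one_fold():
    table = _toy_table(n_patients=23)
    folds = grouped_folds(table, n_folds=10, seed=1)
    assert set(folds.mapping) == set(table["patient_id"])
    assert set(folds.mapping.values()) == set(range(10))
    per_svx = folds.fold_of(table["patient_id"])
    for pid, grp in table.groupby("patient_id"):
        assert len(np.unique(per_svx[grp.index])) == 1


def test_grouped_folds_balance_supervoxel_counts():
    table = _toy_table(n_patients=40)
    folds = grouped_folds(table, n_folds=10, seed=0)
    sizes = table.groupby(table["patient_id"].map(folds.mapping)).size()
    assert sizes.max() - sizes.min() <= 4  # 4 supervoxels per patient


def test_too_few_patients_raises():
    with pytest.raises(ValidationError):
        grouped_folds(_toy_table(n_patients=5), n_folds=10)


def test_repeat_cases_share_fold():
    table = _toy_table(n_patients=12)
    extra = table[table["patient_id"] == "P000"].copy()
    extra["case_id"] = "P000_c1"
    table = pd.concat([table, extra], ignore_index=True)
    folds = grouped_folds(table, n_folds=10, seed=0)
    per_case = table.groupby("case_id")["patient_id"].first().map(folds.mapping)
    assert per_case["P000_c0"] == per_case["P000_c1"]


def test_separable_table_gives_perfect_scores():
    table = _toy_table(signal=50.0)
    cv = cross_validate(table, rf=RfConfig(seed=0))
    assert cv.macro_auc == pytest.approx(1.0)
    assert cv.metrics["accuracy"] == pytest.approx(1.0)


def test_cv_result_invariants():
    table = _toy_table(signal=2.0, seed=3)
    cv = cross_validate(table, rf=RfConfig(seed=0))
    assert cv.importances.sum() == pytest.approx(1.0, abs=1e-9)
    assert (cv.importances >= 0).all()
    assert cv.predictions["prob_tp"].between(0, 1).all()
    assert len(cv.predictions) == len(table)
    # pooled accuracy equals the fold-size-weighted mean of fold accuracies
    preds = cv.predictions
    correct = (preds["pred_label"] == preds["label"]).astype(float)
    weighted = correct.groupby(preds["fold"]).mean() * preds.groupby("fold").size()
    assert weighted.sum() / len(preds) == pytest.approx(
        cv.metrics["accuracy"], abs=1e-12
    )


def test_no_patient_leakage_between_train_and_test():
    table = _toy_table()
    cv = cross_validate(table, rf=RfConfig(seed=1))
    fold_of_patient = cv.folds.mapping
    for _, row in cv.predictions.iterrows():
        assert row["fold"] == fold_of_patient[row["patient_id"]]


def test_classification_report_hand_cases():
    m = classification_report(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.2, 0.1]))
    assert m["accuracy"] == 1.0 and m["f1_tp"] == 1.0 and m["f1_psp"] == 1.0

    m = classification_report(np.array([1, 0, 1, 0]), np.array([0.6, 0.6, 0.4, 0.4]))
    assert m["accuracy"] == 0.5
    assert m["precision_tp"] == 0.5


def test_f1_is_harmonic_mean_identity():
    rng = np.random.default_rng(0)
    for _ in range(10):
        y = rng.integers(0, 2, 50)
        prob = rng.random(50)
        if len(np.unique(y)) < 2:
            continue
        m = classification_report(y, prob)
        for cls in ("tp", "psp"):
            p, r, f1 = m[f"precision_{cls}"], m[f"recall_{cls}"], m[f"f1_{cls}"]
            expect = 2 * p * r / (p + r) if p + r > 0 else 0.0
            assert f1 == pytest.approx(expect)


def test_macro_auc_equals_plain_auc_for_binary():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, 100)
    prob = np.clip(y * 0.3 + rng.random(100) * 0.7, 0, 1)
    from sklearn.metrics import roc_auc_score

    assert macro_auc_score(y, prob) == pytest.approx(roc_auc_score(y, prob))


def test_mann_whitney_enumerated_example():
    res = mann_whitney_u([1, 2], [3, 4])
    assert res.u_statistic == 0.0  # no pair with x > y
    assert res.n1 == res.n2 == 2
    assert res.direction == "less"


def test_mann_whitney_identical_samples():
    x = np.arange(10.0)
    res = mann_whitney_u(x, x.copy())
    assert res.u_statistic == pytest.approx(50.0)  # n^2 / 2
    assert res.p_value > 0.9
    assert res.direction == "equal"


def test_mann_whitney_pairing_identity():
    rng = np.random.default_rng(2)
    for _ in range(5):
        x = rng.normal(size=rng.integers(3, 30))
        y = rng.normal(size=rng.integers(3, 30))
        assert mann_whitney_u(x, y).u_statistic + mann_whitney_u(
            y, x
        ).u_statistic == pytest.approx(len(x) * len(y))


def test_mann_whitney_empty_rejected():
    with pytest.raises(ValidationError):
        mann_whitney_u([], [1.0])


@pytest.mark.parametrize(
    "p,stars", [(0.0004, "***"), (0.004, "**"), (0.04, "*"), (0.2, "")]
)
def test_significance_star_thresholds(p, stars):
    assert significance_stars(p) == stars


def test_compare_percentile_features_reports_seven_contrasts():
    table = _toy_table(signal=5.0)
    report = compare_percentile_features(table)
    assert len(report) == 7
    assert set(report["channel"]) == {"PET", "CBV", "T1c"}
    pet_mean_like = report[(report["channel"] == "PET")]
    assert (pet_mean_like["p_value"] <= 1).all()
    assert set(report.columns) >= {"u_statistic", "p_value", "stars", "tp_vs_psp"}


def test_single_class_training_split_raises():
    table = _toy_table(n_patients=12)
    table["label"] = TP  # degenerate: single class everywhere
    with pytest.raises(ValidationError):
        cross_validate(table, rf=RfConfig(seed=0))
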