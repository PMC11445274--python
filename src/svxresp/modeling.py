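"""Patient-grouped cross-validated Random Forest for TP vs PsP supervoxels.

A 100-tree entropy-criterion Random Forest predicts, per supervoxel, the
probability of true progression from its 126 radiomics features. Validation
is tenfold cross-validation with the constraint that all supervoxels of one
patient share a fold (no information leakage between training and held-out
data of the same patient). Pooled out-of-fold probabilities are binarized
at the pre-defined cutoff 0.5 for the classification metrics; ranking
quality is reported as the macro-average of the per-class one-vs-rest AUCs.
Group contrasts between TP and PsP supervoxel features use the two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score

from .errors import ValidationError
from .features import feature_columns
from .labeling import PSP, TP


@dataclass
class RfConfig:
    """Random Forest hyperparameters (fixed, no tuning)."""

    n_trees: int = 100
    split_criterion: str = "entropy"
    max_features: str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")

    def build(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion=self.split_criterion,
            max_features=self.max_features,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class FoldAssignment:
    """patient_id -> fold index (0-based), every patient in exactly one fold."""

    mapping: dict[str, int]
    n_folds: int

    def fold_of(self, patient_ids: pd.Series) -> np.ndarray:
        return patient_ids.map(self.mapping).to_numpy()


@dataclass
class MwuResult:
    """Two-sided Mann-Whitney U comparison of two samples."""

    u_statistic: float
    n1: int
    n2: int
    p_value: float
    direction: str  # 'greater', 'less' or 'equal' (by median difference)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Conventional significance marks: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CVResult:
    """Pooled grouped-CV predictions, metrics and feature importances."""

    predictions: pd.DataFrame  # per supervoxel: metadata, fold, prob_tp, pred
    fold_auc: list[float]
    macro_auc: float
    metrics: dict[str, float]
    importances: pd.Series  # indexed by feature name, sums to 1
    folds: FoldAssignment
    cutoff: float = 0.5


def grouped_folds(
    table: pd.DataFrame, n_folds: int = 10, seed: int = 0
) -> FoldAssignment:
    """Assign patients to folds, balancing supervoxel counts.

    Greedy largest-first: patients sorted by descending supervoxel count
    (ties broken by a seeded shuffle) each join the currently smallest fold.
    All supervoxels of a patient inherit its fold.
    """
    counts = table.groupby("patient_id").size()
    if len(counts) < n_folds:
        raise ValidationError(
            f"{len(counts)} patients < {n_folds} folds; grouped CV impossible"
        )
    rng = np.random.default_rng(seed)
    patients = counts.sample(frac=1.0, random_state=rng).sort_values(
        ascending=False, kind="stable"
    )
    totals = np.zeros(n_folds, int)
    mapping: dict[str, int] = {}
    for pid, n in patients.items():
        fold = int(np.argmin(totals))
        mapping[pid] = fold
        totals[fold] += n
    return FoldAssignment(mapping=mapping, n_folds=n_folds)


def _binary_labels(y: np.ndarray) -> np.ndarray:
    """Map label codes to {1: TP, 0: PsP}."""
    return (np.asarray(y) == TP).astype(int)


def macro_auc_score(y_true01: np.ndarray, prob_tp: np.ndarray) -> float:
    """Unweighted mean of the per-class one-vs-rest AUCs.

    For a binary problem with complementary scores both one-vs-rest AUCs
    coincide, so this equals the ordinary AUC for the TP class; the macro
    form is kept because it is the configured reading of a class-imbalance
    aware AUC.
    """
    auc_tp = roc_auc_score(y_true01, prob_tp)
    auc_psp = roc_auc_score(1 - y_true01, 1 - prob_tp)
    return float((auc_tp + auc_psp) / 2.0)


def classification_report(
    y_true: np.ndarray, prob_tp: np.ndarray, cutoff: float = 0.5
) -> dict[str, float]:
    """Threshold the TP probabilities and report standard metrics.

    ``y_true`` may be given as label codes (1=TP, 2=PsP) or already binary
    {0,1}. TP is the positive class; sensitivity = TP-class recall,
    specificity = PsP-class recall.
    """
    y = np.asarray(y_true)
    y01 = _binary_labels(y) if set(np.unique(y)) - {0, 1} else y.astype(int)
    prob = np.asarray(prob_tp, float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValidationError("probabilities must lie in [0, 1]")
    pred = (prob >= cutoff).astype(int)

    tn, fp, fn, tp = confusion_matrix(y01, pred, labels=[0, 1]).ravel()
    n = tn + fp + fn + tp

    def _safe(num, den):
        return float(num / den) if den > 0 else 0.0

    precision_tp = _safe(tp, tp + fp)
    recall_tp = _safe(tp, tp + fn)
    precision_psp = _safe(tn, tn + fn)
    recall_psp = _safe(tn, tn + fp)
    f1_tp = _safe(2 * precision_tp * recall_tp, precision_tp + recall_tp)
    f1_psp = _safe(2 * precision_psp * recall_psp, precision_psp + recall_psp)

    metrics = {
        "accuracy": _safe(tp + tn, n),
        "balanced_accuracy": (recall_tp + recall_psp) / 2.0,
        "sensitivity": recall_tp,
        "specificity": recall_psp,
        "precision_tp": precision_tp,
        "recall_tp": recall_tp,
        "f1_tp": f1_tp,
        "precision_psp": precision_psp,
        "recall_psp": recall_psp,
        "f1_psp": f1_psp,
        "n_tp": int(tp + fn),
        "n_psp": int(tn + fp),
    }
    if len(np.unique(y01)) < 2:
        warnings.warn("single-class truth: AUC undefined", stacklevel=2)
        metrics["macro_auc"] = float("nan")
    else:
        metrics["macro_auc"] = macro_auc_score(y01, prob)
    return metrics


def cross_validate(
    table: pd.DataFrame,
    folds: FoldAssignment | None = None,
    rf: RfConfig | None = None,
    n_folds: int = 10,
    cutoff: float = 0.5,
) -> CVResult:
    """Patient-grouped k-fold CV of the supervoxel Random Forest.

    Fits one forest per fold on the remaining folds, collects out-of-fold
    TP probabilities for every supervoxel, and computes pooled metrics at
    ``cutoff`` plus per-fold macro AUCs. Feature importances (impurity
    based, summing to 1) come from a final forest fitted on all data.
    """
    rf = rf or RfConfig()
    if folds is None:
        folds = grouped_folds(table, n_folds=n_folds, seed=rf.seed)

    feat_cols = feature_columns()
    missing = [c for c in feat_cols if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table is missing columns: {missing[:3]}...")

    X = table[feat_cols].to_numpy(float)
    y01 = _binary_labels(table["label"].to_numpy())
    fold_of = folds.fold_of(table["patient_id"])

    prob = np.full(len(table), np.nan)
    fold_auc: list[float] = []
    for k in range(folds.n_folds):
        test = fold_of == k
        train = ~test
        if not test.any():
            continue
        if len(np.unique(y01[train])) < 2:
            raise ValidationError(f"training split of fold {k} has a single class")
        # leakage guard: no shared patient between train and test
        shared = set(table.loc[train, "patient_id"]) & set(
            table.loc[test, "patient_id"]
        )
        assert not shared, f"patient leakage across fold {k}: {sorted(shared)[:3]}"
        model = rf.build()
        model.fit(X[train], y01[train])
        prob[test] = model.predict_proba(X[test])[:, list(model.classes_).index(1)]
        if len(np.unique(y01[test])) == 2:
            fold_auc.append(macro_auc_score(y01[test], prob[test]))
        else:
            fold_auc.append(float("nan"))

    assert not np.isnan(prob).any(), "some supervoxel has no out-of-fold probability"

    metrics = classification_report(y01, prob, cutoff)
    final = rf.build()
    final.fit(X, y01)
    importances = pd.Series(final.feature_importances_, index=feat_cols)

    predictions = table[
        ["patient_id", "case_id", "supervoxel_id", "label", "n_voxels"]
    ].copy()
    predictions["fold"] = fold_of
    predictions["prob_tp"] = prob
    predictions["pred_label"] = np.where(prob >= cutoff, TP, PSP)

    return CVResult(
        predictions=predictions,
        fold_auc=fold_auc,
        macro_auc=metrics["macro_auc"],
        metrics=metrics,
        importances=importances,
        folds=folds,
        cutoff=cutoff,
    )


def permute_labels_within_patients(
    table: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Null cohort: shuffle supervoxel labels within each patient.

    Destroys any feature-label association while preserving each patient's
    class mix; grouped CV on the result should score at chance level.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    for _, idx in out.groupby("patient_id").groups.items():
        vals = out.loc[idx, "label"].to_numpy()
        out.loc[idx, "label"] = rng.permutation(vals)
    return out


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> MwuResult:
    """Two-sided Mann-Whitney U with midranks, tie and continuity correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    mx, my = np.median(x), np.median(y)
    direction = "greater" if mx > my else ("less" if mx < my else "equal")
    return MwuResult(
        u_statistic=float(res.statistic),
        n1=int(x.size),
        n2=int(y.size),
        p_value=float(res.pvalue),
        direction=direction,
    )


#: the tangible percentile contrasts compared between TP and PsP supervoxels
PERCENTILE_CONTRASTS = (
    ("PET", "p10"),
    ("PET", "median"),
    ("PET", "p90"),
    ("CBV", "p10"),
    ("CBV", "p90"),
    ("T1c", "p10"),
    ("T1c", "p90"),
)


def compare_percentile_features(table: pd.DataFrame) -> pd.DataFrame:
    """TP-vs-PsP Mann-Whitney comparison of the tangible percentile features.

    For each (channel, percentile) contrast the first-order feature column
    is compared between TP- and PsP-labeled supervoxels; the report gives
    U, sample sizes, the direction of the median difference and
    significance stars at 0.05 / 0.01 / 0.001.
    """
    rows = []
    tp_rows = table["label"] == TP
    psp_rows = table["label"] == PSP
    if not tp_rows.any() or not psp_rows.any():
        raise ValidationError("need both TP and PsP supervoxels to compare")
    for chan, feat in PERCENTILE_CONTRASTS:
        col = f"{chan}__firstorder__{feat}"
        if col not in table.columns:
            raise ValidationError(f"missing feature column {col}")
        res = mann_whitney_u(table.loc[tp_rows, col], table.loc[psp_rows, col])
        rows.append(
            {
                "channel": chan,
                "feature": feat,
                "u_statistic": res.u_statistic,
                "n_tp": res.n1,
                "n_psp": res.n2,
                "p_value": res.p_value,
                "tp_vs_psp": res.direction,
                "stars": res.stars,
            }
        )
    return pd.DataFrame(rows)
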