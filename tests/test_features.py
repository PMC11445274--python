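"""First-order and GLCM radiomics: hand values, oracles, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from svxresp.errors import DegenerateInputError
from svxresp.features import (
    FIRSTORDER_NAMES,
    GLCM_NAMES,
    DiscretizationSpec,
    GlcmSpec,
    extract_feature_table,
    feature_columns,
    first_order_features,
    glcm_features,
)

from conftest import analyze_case
from oracles import naive_first_order, naive_glcm_features


def test_feature_roster_is_42_per_channel():
    cols = feature_columns()
    assert len(cols) == 126
    for chan in ("CBV", "PET", "T1c"):
        assert sum(c.startswith(chan + "__") for c in cols) == 42


def test_first_order_hand_computed_values():
    f = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]), voxel_volume_mm3=2.0)
    assert f["mean"] == pytest.approx(2.5)
    assert f["median"] == pytest.approx(2.5)
    assert f["range"] == pytest.approx(3.0)
    assert f["variance"] == pytest.approx(1.25)  # population convention
    assert f["energy"] == pytest.approx(30.0)
    assert f["total_energy"] == pytest.approx(60.0)
    assert f["rms"] == pytest.approx(np.sqrt(7.5))
    assert f["mad"] == pytest.approx(1.0)
    assert f["iqr"] == pytest.approx(1.5)
    assert f["minimum"] == 1.0 and f["maximum"] == 4.0
    assert f["skewness"] == pytest.approx(0.0)
    assert f["kurtosis"] == pytest.approx(1.64)
    # 4 distinct values, 32 bins -> four cells of probability 1/4
    assert f["entropy"] == pytest.approx(2.0)
    assert f["uniformity"] == pytest.approx(0.25)
    # robust MAD: values within [P10, P90] = {2, 3}
    assert f["rmad"] == pytest.approx(0.5)


def test_first_order_constant_region():
    f = first_order_features(np.full(50, 7.0))
    assert f["variance"] == 0.0
    assert f["range"] == 0.0
    assert f["entropy"] == 0.0
    assert f["uniformity"] == 1.0
    assert f["mean"] == pytest.approx(7.0)
    assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0


def test_first_order_empty_rejected():
    with pytest.raises(DegenerateInputError):
        first_order_features(np.array([]))


@settings(max_examples=30, deadline=None)
@given(
    arrays(
        float,
        st.integers(min_value=2, max_value=60),
        elements=st.floats(-100, 100, allow_nan=False),
    )
)
def test_order_statistics_are_ordered(values):
    f = first_order_features(values)
    assert (
        f["minimum"] <= f["p10"] <= f["median"] <= f["p90"] <= f["maximum"]
    )


def test_glcm_single_gray_level():
    vol = np.full((3, 3, 3), 2.0)
    member = np.ones((3, 3, 3), bool)
    f = glcm_features(vol, member)
    assert f["maximum_probability"] == 1.0
    assert f["joint_entropy"] == pytest.approx(0.0, abs=1e-12)
    assert f["contrast"] == 0.0
    assert f["mcc"] == 1.0


def test_glcm_two_by_two_hand_enumeration():
    """2x2x1 patch [[1,2],[1,2]], 2 bins: four in-plane directions with
    hand-enumerated co-occurrence tables."""
    vol = np.array([[[1.0], [2.0]], [[1.0], [2.0]]])  # shape (2,2,1)
    member = np.ones((2, 2, 1), bool)
    f = glcm_features(vol, member, DiscretizationSpec(bins=2))
    # direction (1,0,0): pairs (1,1),(2,2) -> contrast 0, corr 1
    # directions (0,1,0),(1,1,0),(1,-1,0): all pairs (1,2) -> contrast 1, corr -1
    assert f["contrast"] == pytest.approx(0.75)
    assert f["maximum_probability"] == pytest.approx(0.5)
    assert f["joint_entropy"] == pytest.approx(1.0)
    assert f["correlation"] == pytest.approx(-0.5)
    assert f["joint_average"] == pytest.approx(1.5)
    assert f["autocorrelation"] == pytest.approx((2.5 + 2.0 + 2.0 + 2.0) / 4)


def test_glcm_matches_bruteforce_oracle_random_patches():
    rng = np.random.default_rng(42)
    for _ in range(10):
        vol = rng.normal(size=(5, 5, 5))
        member = rng.random((5, 5, 5)) < 0.6
        if member.sum() < 4:
            continue
        ours = glcm_features(vol, member)
        ref = naive_glcm_features(vol, member)
        for name in GLCM_NAMES:
            assert ours[name] == pytest.approx(ref[name], abs=1e-9), name


def test_first_order_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        vals = rng.normal(size=rng.integers(5, 200))
        ours = first_order_features(vals)
        ref = naive_first_order(vals)
        for name in FIRSTORDER_NAMES:
            assert ours[name] == pytest.approx(ref[name], abs=1e-9), name


def test_glcm_matrices_normalize_to_one():
    from svxresp.features import _glcm_matrices

    rng = np.random.default_rng(1)
    vol = rng.integers(1, 6, size=(6, 6, 6))
    member = rng.random((6, 6, 6)) < 0.7
    gray = np.where(member, vol, 0)
    _, stack = _glcm_matrices(gray, member, GlcmSpec())
    totals = stack.sum(axis=(1, 2))
    for mat, tot in zip(stack, totals):
        if tot > 0:
            assert (mat / tot).sum() == pytest.approx(1.0, abs=1e-12)


def test_intensity_shift_invariance_under_fixed_bin_count():
    """Adding a constant leaves every GLCM feature and the histogram-based
    first-order features unchanged (fixed-bin-count discretization)."""
    rng = np.random.default_rng(3)
    vol = rng.normal(size=(6, 6, 6))
    member = rng.random((6, 6, 6)) < 0.8
    g0 = glcm_features(vol, member)
    g1 = glcm_features(vol + 100.0, member)
    for name in GLCM_NAMES:
        assert g0[name] == pytest.approx(g1[name], abs=1e-8), name
    f0 = first_order_features(vol[member])
    f1 = first_order_features(vol[member] + 100.0)
    for name in ("entropy", "uniformity", "variance", "iqr", "range"):
        assert f0[name] == pytest.approx(f1[name], abs=1e-8)


def test_glcm_too_small_supervoxel_is_nan():
    vol = np.ones((3, 3, 3))
    member = np.zeros((3, 3, 3), bool)
    member[0, 0, 0] = True
    f = glcm_features(vol, member)
    assert all(np.isnan(v) for v in f.values())


def test_feature_table_126_columns_and_deterministic(small_case):
    _, svx, ml = analyze_case(small_case)
    a = extract_feature_table(
        [small_case], {small_case.case_id: svx}, {small_case.case_id: ml}
    )
    b = extract_feature_table(
        [small_case], {small_case.case_id: svx}, {small_case.case_id: ml}
    )
    feat_cols = [c for c in a.columns if "__" in c]
    assert len(feat_cols) == 126
    assert np.isfinite(a[feat_cols].to_numpy()).all()
    assert a.equals(b)
    assert {"patient_id", "case_id", "supervoxel_id", "label", "n_voxels"} <= set(
        a.columns
    )


def test_record_count_tracks_partition_arithmetic(small_case):
    _, svx, ml = analyze_case(small_case)
    table = extract_feature_table(
        [small_case], {small_case.case_id: svx}, {small_case.case_id: ml}
    )
    expected = small_case.cet_mask.sum() / 200
    assert len(table) == pytest.approx(expected, rel=0.5)
    assert len(table) == svx.n_supervoxels  # nothing degenerate here
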