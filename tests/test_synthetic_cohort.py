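"""Phantom cohort generator: counts, determinism, planted structure."""

import numpy as np
import pytest
from scipy import ndimage

from svxresp.errors import SizingError, ValidationError
from svxresp.geometry import ImageGeometry
from svxresp.labeling import PSP, TP
from svxresp.synthetic import (
    ClassEffect,
    CohortConfig,
    generate_cohort,
    plant_response_regions,
)

from conftest import small_cohort_config


def test_cohort_size_and_patient_ids():
    cases = generate_cohort(small_cohort_config(n_patients=3))
    assert len(cases) == 3
    assert len({c.patient_id for c in cases}) == 3
    assert len({c.case_id for c in cases}) == 3


def test_repeat_patients_share_patient_id():
    cases = generate_cohort(small_cohort_config(n_patients=3, repeat_patients=2))
    assert len(cases) == 5
    pids = [c.patient_id for c in cases]
    assert sum(pids.count(p) == 2 for p in set(pids)) == 2


def test_determinism_same_seed():
    a = generate_cohort(small_cohort_config(seed=5))[0]
    b = generate_cohort(small_cohort_config(seed=5))[0]
    for name in a.channels:
        np.testing.assert_array_equal(a.channels[name], b.channels[name])
    np.testing.assert_array_equal(a.followup_T1c, b.followup_T1c)
    np.testing.assert_array_equal(a.truth_labels.labels, b.truth_labels.labels)
    c = generate_cohort(small_cohort_config(seed=6))[0]
    assert not np.array_equal(a.channels["T1c"], c.channels["T1c"])


def test_truth_labels_cover_cet_exactly():
    for bundle in generate_cohort(small_cohort_config(n_patients=2)):
        cet = bundle.cet_mask
        labels = bundle.truth_labels.labels
        assert (labels[cet] != 0).all()
        assert (labels[~cet] == 0).all()


def test_planted_tp_fraction_near_target():
    # ~5000-voxel CET at the default geometry, tp_fraction 0.5
    bundle = generate_cohort(CohortConfig(n_patients=1, tp_fraction=0.5, seed=2))[0]
    assert bundle.cet_mask.sum() > 4000
    assert bundle.truth_labels.tp_fraction() == pytest.approx(0.5, abs=0.05)


@pytest.mark.parametrize("frac,code", [(0.0, PSP), (1.0, TP)])
def test_plant_boundary_fractions(frac, code):
    rng = np.random.default_rng(0)
    mask = np.zeros((16, 16, 16), bool)
    mask[4:12, 4:12, 4:12] = True
    result = plant_response_regions(mask, frac, 4.0, rng)
    assert (result.labels[mask] == code).all()


def test_plant_fraction_direct_count():
    rng = np.random.default_rng(1)
    mask = np.zeros((30, 30, 30), bool)
    mask[4:26, 4:26, 4:26] = True  # 10648 voxels
    result = plant_response_regions(mask[:, :, :], 0.3, 4.0, rng)
    n_tp = int(result.tp_mask.sum())
    assert abs(n_tp - 0.3 * mask.sum()) <= 500


def test_tp_blobs_are_spatially_coherent():
    bundle = generate_cohort(CohortConfig(n_patients=1, seed=4))[0]
    comp, ncomp = ndimage.label(
        bundle.truth_labels.tp_mask, structure=np.ones((3, 3, 3))
    )
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, ncomp + 1))
    assert sizes.mean() >= 27


def test_tumor_too_large_raises_sizing_error():
    with pytest.raises(SizingError):
        generate_cohort(
            small_cohort_config(tumor_radius_mm=14.0, rim_thickness_mm=4.0)
        )


def test_invalid_tp_fraction_rejected():
    with pytest.raises(ValidationError):
        CohortConfig(tp_fraction=1.5)
    rng = np.random.default_rng(0)
    mask = np.ones((10, 10, 10), bool)
    with pytest.raises(ValidationError):
        plant_response_regions(mask, -0.1, 4.0, rng)


def test_class_conditional_tbr_means_match_config():
    """Per-class PET TBR sample means agree with the configured values
    within 3 cluster-robust standard errors (cases as clusters)."""
    cfg = small_cohort_config(n_patients=8, seed=7)
    cases = generate_cohort(cfg)
    eff = cfg.effects["PET_TBR"]
    for class_mask_name, target in (("tp_mask", eff.tp_mean), ("psp_mask", eff.psp_mean)):
        case_means = []
        for b in cases:
            mask = getattr(b.truth_labels, class_mask_name)
            tbr = b.channels["PET_raw"] / cfg.pet_background_uptake
            if mask.any():
                case_means.append(float(tbr[mask].mean()))
        case_means = np.array(case_means)
        se = case_means.std(ddof=1) / np.sqrt(len(case_means))
        assert abs(case_means.mean() - target) <= 3 * se + 0.02


def test_mwu_effect_grows_with_planted_tbr_gap():
    """Raising the TP-PsP TBR mean gap strictly increases the voxel-level
    rank effect (common-language U / n1 n2) at fixed seed."""
    from scipy.stats import mannwhitneyu

    effects = []
    for gap in (0.2, 0.6, 1.2):
        cfg = small_cohort_config(n_patients=2, seed=11)
        cfg.effects["PET_TBR"] = ClassEffect(1.8 + gap, 0.45, 1.8, 0.45)
        tp_vals, psp_vals = [], []
        for b in generate_cohort(cfg):
            tbr = b.channels["PET_raw"] / cfg.pet_background_uptake
            tp_vals.append(tbr[b.truth_labels.tp_mask])
            psp_vals.append(tbr[b.truth_labels.psp_mask])
        x = np.concatenate(tp_vals)
        y = np.concatenate(psp_vals)
        u = mannwhitneyu(x, y).statistic
        effects.append(u / (len(x) * len(y)))
    assert effects[0] < effects[1] < effects[2]


def test_followup_tracks_truth_direction():
    """Median follow-up enhancement rises over TP and falls over PsP."""
    bundle = generate_cohort(small_cohort_config(seed=9, n_patients=1))[0]
    bl = bundle.channels["T1c"]
    fu = bundle.followup_T1c
    tp = bundle.truth_labels.tp_mask
    psp = bundle.truth_labels.psp_mask
    assert np.median(fu[tp] - bl[tp]) > 0
    assert np.median(fu[psp] - bl[psp]) < 0


def test_masks_disjoint_and_nonempty():
    bundle = generate_cohort(small_cohort_config(seed=1, n_patients=1))[0]
    cet = bundle.masks["CET"]
    nec = bundle.masks["necrosis"]
    ede = bundle.masks["edema"]
    assert not (cet & nec).any() and not (cet & ede).any() and not (nec & ede).any()
    assert cet.any() and bundle.masks["WM"].any()
    geo = bundle.geometry
    assert isinstance(geo, ImageGeometry)
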