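"""SLIC supervoxel partition and majority-vote labeling."""

import numpy as np
import pytest
from scipy import ndimage

from svxresp.errors import ValidationError
from svxresp.labeling import PSP, TP, ResponseLabelMap
from svxresp.supervoxels import (
    SlicConfig,
    SupervoxelMap,
    majority_label,
    slic_supervoxels,
)

from conftest import analyze_case
from oracles import naive_majority_labels


def _cube_mask(shape=(16, 16, 16), size=10):
    mask = np.zeros(shape, bool)
    mask[3 : 3 + size, 3 : 3 + size, 3 : 3 + size] = True
    return mask


def _channels(mask, value=1.0):
    vol = np.full(mask.shape, value)
    return {"CBV": vol, "PET": vol.copy(), "T1c": vol.copy()}


def test_homogeneous_cube_yields_expected_count():
    mask = _cube_mask(size=10)  # 1000 voxels, target 200
    svx = slic_supervoxels(_channels(mask), mask, SlicConfig(target_size=200))
    assert 4 <= svx.n_supervoxels <= 6
    assert svx.voxel_counts.sum() == 1000


def test_partition_contract(small_case):
    _, svx, _ = analyze_case(small_case)
    cet = small_case.cet_mask
    assert ((svx.ids > 0) == cet).all()
    assert svx.voxel_counts.sum() == cet.sum()
    assert (svx.voxel_counts > 0).all()
    # every supervoxel is a single 26-connected component
    struct = np.ones((3, 3, 3))
    for i in range(1, svx.n_supervoxels + 1):
        assert ndimage.label(svx.ids == i, structure=struct)[1] == 1


def test_two_compartment_phantom_respects_boundary():
    """With a sharp two-level intensity boundary and zero noise, no
    supervoxel mixes the compartments by more than 5% of its voxels."""
    mask = _cube_mask(shape=(20, 20, 20), size=14)  # 2744 voxels
    pet = np.ones(mask.shape)
    right = np.zeros(mask.shape, bool)
    right[:, 10:, :] = True
    pet[right] = 3.0
    channels = {"CBV": np.ones(mask.shape), "PET": pet, "T1c": np.ones(mask.shape)}
    svx = slic_supervoxels(channels, mask, SlicConfig(target_size=200))
    for i in range(1, svx.n_supervoxels + 1):
        member = svx.ids == i
        minority = min(
            (member & right).sum(), (member & ~right).sum()
        )
        assert minority <= 0.05 * member.sum()


def test_small_mask_single_supervoxel_with_warning():
    mask = _cube_mask(size=4)  # 64 voxels < 200
    with pytest.warns(UserWarning, match="single supervoxel"):
        svx = slic_supervoxels(_channels(mask), mask, SlicConfig(target_size=200))
    assert svx.n_supervoxels == 1
    assert (svx.ids[mask] == 1).all()


def test_deterministic_and_canonically_numbered(small_case):
    _, svx_a, _ = analyze_case(small_case)
    _, svx_b, _ = analyze_case(small_case)
    np.testing.assert_array_equal(svx_a.ids, svx_b.ids)
    # ids ascend with centroid (z, y, x) order
    cents = np.array(
        ndimage.center_of_mass(
            svx_a.ids > 0, svx_a.ids, index=np.arange(1, svx_a.n_supervoxels + 1)
        )
    )
    order = np.lexsort((cents[:, 2], cents[:, 1], cents[:, 0]))
    assert (order == np.arange(svx_a.n_supervoxels)).all()


def test_config_validation():
    with pytest.raises(ValidationError):
        SlicConfig(target_size=4)
    with pytest.raises(ValidationError):
        SlicConfig(compactness=0.0)
    with pytest.raises(ValidationError):
        slic_supervoxels(_channels(np.zeros((16, 16, 16), bool)),
                         np.zeros((16, 16, 16), bool))


def _random_label_map(mask, rng):
    labels = np.zeros(mask.shape, np.uint8)
    labels[mask] = rng.choice([TP, PSP], size=int(mask.sum()))
    return ResponseLabelMap(labels=labels, cet_mask=mask, provenance="synthetic-truth")


def test_majority_label_matches_bruteforce_oracle(small_case):
    rng = np.random.default_rng(0)
    _, svx, _ = analyze_case(small_case)
    labels = _random_label_map(small_case.cet_mask, rng)
    table = majority_label(svx, labels).set_index("supervoxel_id")
    oracle = naive_majority_labels(svx.ids, labels.labels)
    assert set(table.index) == set(oracle)
    for sid, ref in oracle.items():
        assert table.loc[sid, "label"] == ref["label"]
        assert table.loc[sid, "majority_fraction"] == pytest.approx(
            ref["majority_fraction"]
        )
        assert table.loc[sid, "n_voxels"] == ref["n_voxels"]


def test_majority_tie_goes_to_tp():
    mask = _cube_mask(size=10)
    ids = np.zeros(mask.shape, np.int32)
    ids[mask] = 1
    svx = SupervoxelMap(ids=ids, n_supervoxels=1, voxel_counts=np.array([1000]))
    labels = np.zeros(mask.shape, np.uint8)
    flat = np.argwhere(mask)
    labels[tuple(flat[:500].T)] = TP
    labels[tuple(flat[500:].T)] = PSP
    rmap = ResponseLabelMap(labels=labels, cet_mask=mask)
    table = majority_label(svx, rmap)
    assert table.loc[0, "label"] == TP
    assert table.loc[0, "majority_fraction"] == pytest.approx(0.5)


def test_majority_unanimous_psp():
    mask = _cube_mask(size=10)
    ids = np.where(mask, 1, 0).astype(np.int32)
    svx = SupervoxelMap(ids=ids, n_supervoxels=1, voxel_counts=np.array([1000]))
    labels = np.where(mask, PSP, 0).astype(np.uint8)
    rmap = ResponseLabelMap(labels=labels, cet_mask=mask)
    table = majority_label(svx, rmap)
    assert table.loc[0, "label"] == PSP
    assert table.loc[0, "majority_fraction"] == 1.0


def test_majority_requires_label_coverage():
    mask = _cube_mask(size=10)
    ids = np.where(mask, 1, 0).astype(np.int32)
    svx = SupervoxelMap(ids=ids, n_supervoxels=1, voxel_counts=np.array([1000]))
    labels = np.where(mask, TP, 0).astype(np.uint8)
    labels[5, 5, 5] = 0  # hole in coverage
    rmap = ResponseLabelMap(labels=labels, cet_mask=mask)
    with pytest.raises(ValidationError):
        majority_label(svx, rmap)
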