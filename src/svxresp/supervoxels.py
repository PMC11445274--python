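"""SLIC supervoxel partition of the contrast-enhancing tumor.

Neighboring CET voxels with similar multi-channel intensities (CBV,
TBR-PET, T1c) are grouped into supervoxels of roughly ``target_size``
voxels by masked SLIC clustering, so that radiomics and classification
operate on semantically homogeneous regions rather than single noisy
voxels. Channels are z-scored over the CET voxels per case before
clustering (they live on incommensurate scales), spatial distances are
measured in mm, and the resulting partition is canonicalized: every
supervoxel is 26-connected and ids are renumbered in ascending centroid
order so identical inputs give an identical id volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import slic as _skimage_slic

from .errors import ValidationError
from .geometry import require_same_geometry
from .labeling import PSP, TP, ResponseLabelMap

_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass
class SlicConfig:
    """SLIC clustering parameters.

    ``target_size`` is the rough number of voxels per supervoxel (the number
    of clusters is |CET| / target_size). ``compactness`` trades spatial
    regularity against intensity homogeneity; the default 0.1 (on z-scored
    channels) favors intensity homogeneity.
    """

    target_size: int = 200
    compactness: float = 0.1
    max_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_size < 8:
            raise ValidationError("target_size must be >= 8 voxels")
        if self.compactness <= 0:
            raise ValidationError("compactness must be > 0")


@dataclass
class SupervoxelMap:
    """Integer partition of the CET mask: ids 1..n inside, 0 outside."""

    ids: np.ndarray
    n_supervoxels: int
    voxel_counts: np.ndarray  # index i-1 -> count of id i

    def __post_init__(self) -> None:
        if self.n_supervoxels < 1:
            raise ValidationError("empty supervoxel map")

    @property
    def mask(self) -> np.ndarray:
        return self.ids > 0

    def voxel_sets(self):
        """Yield (id, index-array) pairs in id order."""
        order = np.argsort(self.ids[self.mask], kind="stable")
        coords = np.argwhere(self.mask)[order]
        bounds = np.cumsum(self.voxel_counts)
        start = 0
        for i, stop in enumerate(bounds, start=1):
            yield i, coords[start:stop]
            start = stop


def _zscore_over_mask(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = np.asarray(volume, float)[mask]
    sd = vals.std()
    out = np.zeros(volume.shape)
    if sd > 0:
        out[mask] = (vals - vals.mean()) / sd
    return out


def _centroids(ids: np.ndarray, n: int) -> np.ndarray:
    return np.array(
        ndimage.center_of_mass(np.ones_like(ids), ids, index=np.arange(1, n + 1))
    )


def _merge_orphan_fragments(
    ids: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Keep each id's largest 26-connected component; attach the rest to the
    adjacent supervoxel with the nearest centroid (in mm)."""
    ids = ids.copy()
    for _ in range(10):
        present = np.unique(ids[ids > 0])
        cents = {
            i: c
            for i, c in zip(
                present,
                ndimage.center_of_mass(ids > 0, ids, index=present),
            )
        }
        fragments = []
        for i in present:
            comp, ncomp = ndimage.label(ids == i, structure=_STRUCT26)
            if ncomp <= 1:
                continue
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, np.arange(1, ncomp + 1))
            keep = int(np.argmax(sizes)) + 1
            for c in range(1, ncomp + 1):
                if c != keep:
                    fragments.append(comp == c)
        if not fragments:
            return ids
        spacing_arr = np.asarray(spacing)
        for frag in fragments:
            dilated = ndimage.binary_dilation(frag, structure=_STRUCT26)
            frag_ids = ids[frag]
            neighbors = np.unique(ids[dilated & ~frag])
            neighbors = neighbors[(neighbors > 0) & (neighbors != frag_ids[0])]
            if neighbors.size == 0:
                continue  # isolated mask island: keeps its own id
            fc = np.array(ndimage.center_of_mass(frag)) * spacing_arr
            dists = [
                np.linalg.norm(fc - np.asarray(cents[nb]) * spacing_arr)
                for nb in neighbors
            ]
            ids[frag] = neighbors[int(np.argmin(dists))]
    return ids


def _canonicalize(ids: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Renumber ids 1..n by ascending (z, y, x) centroid order."""
    present = np.unique(ids[ids > 0])
    cents = np.array(ndimage.center_of_mass(ids > 0, ids, index=present))
    order = np.lexsort((cents[:, 2], cents[:, 1], cents[:, 0]))
    remap = np.zeros(int(present.max()) + 1, int)
    remap[present[order]] = np.arange(1, len(present) + 1)
    new_ids = remap[ids]
    counts = np.bincount(new_ids[new_ids > 0], minlength=len(present) + 1)[1:]
    return new_ids, len(present), counts


def slic_supervoxels(
    channels: dict[str, np.ndarray],
    cet_mask: np.ndarray,
    config: SlicConfig | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SupervoxelMap:
    """Partition the CET mask into ~|CET|/target_size supervoxels.

    ``channels`` maps channel names to aligned 3D volumes (conventionally
    CBV, PET TBR and T1c). Returns a canonical :class:`SupervoxelMap`;
    deterministic for identical inputs and config.
    """
    config = config or SlicConfig()
    cet = np.asarray(cet_mask, bool)
    vols = list(channels.values())
    require_same_geometry(cet, *vols)
    n_cet = int(cet.sum())
    if n_cet == 0:
        raise ValidationError("CET mask is empty")

    if n_cet < config.target_size:
        warnings.warn(
            f"CET mask ({n_cet} voxels) smaller than target supervoxel size "
            f"({config.target_size}); emitting a single supervoxel",
            stacklevel=2,
        )
        ids = cet.astype(np.int32)
        return SupervoxelMap(ids=ids, n_supervoxels=1, voxel_counts=np.array([n_cet]))

    # all work happens on the CET bounding box (plus margin); ids are
    # embedded back into the full grid at the end
    idx = np.argwhere(cet)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, cet.shape)
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    cet_box = cet[box]

    img = np.stack(
        [_zscore_over_mask(np.asarray(v, float)[box], cet_box) for v in vols], axis=-1
    )
    n_segments = max(1, round(n_cet / config.target_size))
    ids_box = _skimage_slic(
        img,
        n_segments=n_segments,
        compactness=config.compactness,
        max_num_iter=config.max_iterations,
        spacing=spacing,
        mask=cet_box,
        channel_axis=-1,
        start_label=1,
        # skimage's own connectivity pass sizes its minimum segment against
        # the full image rather than the mask and collapses masked runs;
        # connectivity is instead restored by the orphan-merge pass below
        enforce_connectivity=False,
    ).astype(np.int32)

    # any CET voxel left unassigned joins its nearest assigned neighbor
    missing = cet_box & (ids_box == 0)
    if missing.any():
        _, nearest = ndimage.distance_transform_edt(
            ids_box == 0, sampling=spacing, return_indices=True
        )
        ids_box[missing] = ids_box[tuple(nearest[:, missing])]
    ids_box[~cet_box] = 0

    ids_box = _merge_orphan_fragments(ids_box, spacing)
    ids_box, n, counts = _canonicalize(ids_box)
    ids = np.zeros(cet.shape, np.int32)
    ids[box] = ids_box
    return SupervoxelMap(ids=ids, n_supervoxels=n, voxel_counts=counts)


def majority_label(
    svx: SupervoxelMap, labels: ResponseLabelMap
) -> pd.DataFrame:
    """Majority-vote TP/PsP label per supervoxel.

    Returns a table (supervoxel_id, label, majority_fraction, n_voxels,
    n_tp, n_psp). Exact ties go to TP — conservative toward not missing
    progression.
    """
    require_same_geometry(svx.ids, labels.labels)
    in_mask = svx.mask
    if np.any(in_mask & (labels.labels == 0)):
        raise ValidationError("response labels do not cover the supervoxel mask")

    n = svx.n_supervoxels
    n_tp = np.bincount(svx.ids[in_mask & (labels.labels == TP)], minlength=n + 1)[1:]
    n_psp = np.bincount(svx.ids[in_mask & (labels.labels == PSP)], minlength=n + 1)[1:]
    total = n_tp + n_psp
    assert (total > 0).all(), "empty supervoxel — violates partition invariants"
    label = np.where(n_tp >= n_psp, TP, PSP)
    majority = np.maximum(n_tp, n_psp) / total
    return pd.DataFrame(
        {
            "supervoxel_id": np.arange(1, n + 1),
            "label": label,
            "majority_fraction": majority,
            "n_voxels": total,
            "n_tp": n_tp,
            "n_psp": n_psp,
        }
    )
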