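"""Tumor-to-background normalization of FET-PET uptake.

Amino-acid PET uptake in arbitrary units is converted to the unitless
tumor-to-background ratio (TBR) by dividing the whole volume by the mean
uptake of healthy-appearing white matter, the conventional reference tissue
for O-(2-[18F]fluoroethyl)-L-tyrosine quantification. Lesion voxels
(enhancing tumor, necrosis, edema) are excluded from the reference region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ValidationError
from .geometry import require_same_geometry

MIN_REFERENCE_VOXELS = 100


@dataclass
class TbrMap:
    """Unitless tumor-to-background ratio map with its reference statistics."""

    tbr: np.ndarray
    background_value: float
    reference_voxel_count: int
    reference_mask: np.ndarray | None = None


def tbr_normalize(
    pet_raw: np.ndarray,
    wm_mask: np.ndarray,
    exclusion_masks: Iterable[np.ndarray] = (),
    min_reference_voxels: int = MIN_REFERENCE_VOXELS,
) -> TbrMap:
    """Divide raw PET uptake by the mean over (WM minus exclusions).

    Raises :class:`ValidationError` if the reference region falls below
    ``min_reference_voxels`` voxels or its mean uptake is non-positive.
    TBR is scale-invariant: ``tbr_normalize(a * pet) == tbr_normalize(pet)``
    for any a > 0.
    """
    exclusions = list(exclusion_masks)
    require_same_geometry(pet_raw, wm_mask, *exclusions)
    reference = np.asarray(wm_mask, bool).copy()
    for mask in exclusions:
        reference &= ~np.asarray(mask, bool)

    n_ref = int(reference.sum())
    if n_ref < min_reference_voxels:
        raise ValidationError(
            f"reference region has {n_ref} voxels, need >= {min_reference_voxels}"
        )
    background = float(np.asarray(pet_raw, float)[reference].mean())
    if background <= 0:
        raise ValidationError(f"non-positive background uptake ({background})")

    return TbrMap(
        tbr=np.asarray(pet_raw, float) / background,
        background_value=background,
        reference_voxel_count=n_ref,
        reference_mask=reference,
    )
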