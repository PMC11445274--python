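"""Voxel-level TP/PsP labeling of the baseline contrast-enhancing tumor.

The ground truth of the study design is defined on the baseline CET mask:
a CET voxel is *true progression* (TP) if its contrast enhancement further
progresses in the registered follow-up scan, and *pseudoprogression* (PsP)
if enhancement is stable or decreasing. Clinically this judgement is made
per mRANO by a reader; here an explicit per-voxel relative-change rule makes
the step reproducible, and externally drawn label maps can be ingested
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .geometry import require_same_geometry

# label codes
BACKGROUND = 0
TP = 1
PSP = 2

DEFAULT_PROGRESSION_THRESHOLD = 0.10


@dataclass
class ResponseLabelMap:
    """Per-voxel response labels on the baseline CET mask.

    ``labels`` holds 0 (background), 1 (TP) or 2 (PsP); nonzero labels occur
    only inside the CET mask and every CET voxel carries one.
    """

    labels: np.ndarray
    cet_mask: np.ndarray
    provenance: str = "automatic"  # manual | automatic | synthetic-truth
    flagged_voxels: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))

    def __post_init__(self) -> None:
        require_same_geometry(self.labels, self.cet_mask)
        labels = np.asarray(self.labels)
        cet = np.asarray(self.cet_mask, bool)
        codes = np.unique(labels)
        if not np.isin(codes, [BACKGROUND, TP, PSP]).all():
            raise ValidationError(f"label codes outside {{0,1,2}}: {codes}")
        n_outside = int(np.count_nonzero(labels[~cet]))
        if n_outside:
            raise ValidationError(
                f"{n_outside} labeled voxel(s) fall outside the CET mask"
            )
        self.labels = labels.astype(np.uint8)
        self.cet_mask = cet

    @property
    def tp_mask(self) -> np.ndarray:
        return self.labels == TP

    @property
    def psp_mask(self) -> np.ndarray:
        return self.labels == PSP

    @property
    def n_unlabeled_cet(self) -> int:
        return int(np.count_nonzero(self.cet_mask & (self.labels == BACKGROUND)))

    def tp_fraction(self) -> float:
        n_cet = int(np.count_nonzero(self.cet_mask))
        return float(np.count_nonzero(self.tp_mask)) / n_cet


def znormalize_to_reference(
    volume: np.ndarray, reference_mask: np.ndarray
) -> np.ndarray:
    """Z-score a volume against the mean/SD over ``reference_mask``.

    Used to bring the baseline and follow-up T1c onto a common intensity
    scale before the relative-change rule (raw T1w units are arbitrary and
    scanner-dependent). The reference is typically nonenhancing brain.
    """
    ref = np.asarray(volume, float)[np.asarray(reference_mask, bool)]
    if ref.size == 0:
        raise ValidationError("empty reference mask for z-normalization")
    sd = float(ref.std())
    if sd <= 0:
        raise ValidationError("zero-variance reference region")
    return (np.asarray(volume, float) - float(ref.mean())) / sd


def label_voxels(
    t1c_baseline_norm: np.ndarray,
    t1c_followup_norm: np.ndarray,
    cet_mask: np.ndarray,
    progression_threshold: float = DEFAULT_PROGRESSION_THRESHOLD,
) -> ResponseLabelMap:
    """Label every baseline CET voxel TP or PsP from the follow-up scan.

    A voxel is TP iff its relative enhancement change
    ``(followup - baseline) / baseline`` exceeds ``progression_threshold``;
    otherwise (stable or decreasing enhancement) it is PsP. Both volumes
    must arrive co-registered and normalized to a common intensity scale
    (see :func:`znormalize_to_reference`).

    Voxels with non-positive baseline intensity (where a relative change is
    undefined) are flagged and filled by iterative 26-neighborhood majority
    vote, defaulting to PsP if isolated.
    """
    require_same_geometry(t1c_baseline_norm, t1c_followup_norm, cet_mask)
    cet = np.asarray(cet_mask, bool)
    if not cet.any():
        raise ValidationError("CET mask is empty")

    bl = np.asarray(t1c_baseline_norm, float)
    fu = np.asarray(t1c_followup_norm, float)

    labels = np.zeros(cet.shape, np.uint8)
    valid = cet & (bl > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_change = (fu - bl) / bl
    labels[valid] = np.where(rel_change[valid] > progression_threshold, TP, PSP)

    flagged = cet & ~valid
    flagged_idx = np.argwhere(flagged)
    # fill undefined voxels from their labeled 26-neighborhood, repeatedly
    # so that interior holes propagate from the flag-region boundary
    struct = np.ones((3, 3, 3), bool)
    remaining = flagged.copy()
    while remaining.any():
        tp_votes = ndimage.convolve(
            (labels == TP).astype(np.int32), struct.astype(np.int32), mode="constant"
        )
        psp_votes = ndimage.convolve(
            (labels == PSP).astype(np.int32), struct.astype(np.int32), mode="constant"
        )
        decidable = remaining & ((tp_votes + psp_votes) > 0)
        if not decidable.any():
            labels[remaining] = PSP  # isolated undefined region: conservative PsP? no —
            # no labeled neighbors anywhere means the whole CET was flagged;
            # fall back to PsP (no evidence of further progression).
            break
        labels[decidable] = np.where(
            tp_votes[decidable] >= psp_votes[decidable], TP, PSP
        )
        remaining &= ~decidable

    return ResponseLabelMap(
        labels=labels,
        cet_mask=cet,
        provenance="automatic",
        flagged_voxels=flagged_idx,
    )


def accept_external_labels(
    label_volume: np.ndarray, cet_mask: np.ndarray
) -> ResponseLabelMap:
    """Validate an externally produced (e.g. manually drawn) label volume.

    Raises if any label lies outside the CET mask; warns (with a count) if
    CET voxels are left unlabeled.
    """
    require_same_geometry(label_volume, cet_mask)
    labels = np.asarray(label_volume)
    codes = np.unique(labels)
    if not np.isin(codes, [BACKGROUND, TP, PSP]).all():
        raise ValidationError(f"label codes outside {{0,1,2}}: {codes}")
    cet = np.asarray(cet_mask, bool)
    n_outside = int(np.count_nonzero(labels[~cet]))
    if n_outside:
        raise ValidationError(
            f"{n_outside} labeled voxel(s) fall outside the CET mask"
        )
    result = ResponseLabelMap(labels=labels, cet_mask=cet, provenance="manual")
    if result.n_unlabeled_cet:
        warnings.warn(
            f"{result.n_unlabeled_cet} CET voxel(s) left unlabeled",
            stacklevel=2,
        )
    return result
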