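"""Multimodal phantom cohort with planted TP/PsP spatial structure.

Each phantom case emulates the imaging bundle of one suspected-recurrence
glioblastoma exam: a spherical brain with WM/GM/CSF tissue shells, a tumor
consisting of a necrotic core, a contrast-enhancing rim (CET) and an edema
margin, and three co-registered channels (contrast-enhanced T1w, raw FET-PET
uptake, CBV). Inside the CET rim, spatially contiguous true-progression (TP)
and pseudoprogression (PsP) territories are planted by thresholding a
smoothed random field, and a registered follow-up T1c is constructed in
which TP territory grows and brightens while PsP territory fades.

Class-conditional channel statistics are configurable; the defaults plant
higher tumor-to-background FET uptake and higher CBV in TP than in PsP,
with only a weak T1c contrast — the direction of the group differences the
classifier is expected to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import SizingError, ValidationError
from .geometry import ImageGeometry
from .labeling import PSP, TP, ResponseLabelMap

CHANNELS = ("T1c", "PET_raw", "CBV")


@dataclass(frozen=True)
class ClassEffect:
    """Per-channel class-conditional mean/SD for TP and PsP voxels."""

    tp_mean: float
    tp_sd: float
    psp_mean: float
    psp_sd: float

    def __post_init__(self) -> None:
        if self.tp_sd < 0 or self.psp_sd < 0:
            raise ValidationError("class SDs must be >= 0")


def _default_effects() -> dict[str, ClassEffect]:
    # TBR-PET: strong TP>PsP separation; CBV: moderate; T1c: weak
    # (both classes enhance — that is what makes the problem hard).
    return {
        "PET_TBR": ClassEffect(2.8, 0.45, 1.9, 0.45),
        "CBV": ClassEffect(3.0, 0.70, 2.0, 0.70),
        "T1c": ClassEffect(2.6, 0.55, 2.3, 0.55),
    }


def _default_noise() -> dict[str, float]:
    return {"PET_TBR": 0.10, "CBV": 0.20, "T1c": 0.12}


@dataclass
class CohortConfig:
    """Parameters of the phantom cohort generator.

    ``effects`` maps channel name (PET_TBR, CBV, T1c) to the TP/PsP
    class-conditional (mean, SD) pairs in that channel's natural units
    (unitless ratio for TBR, arbitrary perfusion units for CBV, z-score-like
    units for T1c). ``repeat_patients`` gives that many patients a second
    case, mirroring repeat inclusion in longitudinal cohorts and exercising
    patient-grouped cross-validation.
    """

    n_patients: int = 30
    cases_per_patient: int = 1
    repeat_patients: int = 0
    geometry: ImageGeometry = field(
        default_factory=lambda: ImageGeometry((64, 64, 64), (1.0, 1.0, 1.0))
    )
    tumor_radius_mm: float = 12.0
    rim_thickness_mm: float = 4.0
    edema_margin_mm: float = 5.0
    tp_fraction: float = 0.5
    effects: dict[str, ClassEffect] = field(default_factory=_default_effects)
    noise_sd: dict[str, float] = field(default_factory=_default_noise)
    spatial_correlation_mm: float = 1.5
    blob_scale_mm: float = 4.0
    followup_growth_mm: float = 2.0
    followup_tp_boost: float = 1.6
    followup_psp_fade: float = 0.7
    pet_background_uptake: float = 100.0
    center_jitter_mm: float = 2.0
    include_dsc: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.cases_per_patient < 1:
            raise ValidationError("n_patients and cases_per_patient must be >= 1")
        if not 0.0 <= self.tp_fraction <= 1.0:
            raise ValidationError("tp_fraction must lie in [0, 1]")
        if self.repeat_patients > self.n_patients:
            raise ValidationError("repeat_patients cannot exceed n_patients")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValidationError("noise SDs must be >= 0")
        if self.rim_thickness_mm <= 0 or self.rim_thickness_mm >= self.tumor_radius_mm:
            raise ValidationError("need 0 < rim_thickness_mm < tumor_radius_mm")


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """The standard study-scale phantom cohort: 30 patients, 3 of them with
    a repeat case, 50% planted TP, default effect sizes."""
    cfg = CohortConfig(n_patients=30, repeat_patients=3, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


# background tissue values per channel (WM, GM, CSF)
_TISSUE_VALUES = {
    "PET_TBR": {"WM": 1.0, "GM": 1.3, "CSF": 0.3},
    "CBV": {"WM": 1.0, "GM": 2.0, "CSF": 0.3},
    "T1c": {"WM": 0.0, "GM": 0.2, "CSF": -0.8},
}


@dataclass
class CaseBundle:
    """All co-registered volumes and identifiers of one imaging case."""

    case_id: str
    patient_id: str
    geometry: ImageGeometry
    channels: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    followup_T1c: np.ndarray | None = None
    truth_labels: ResponseLabelMap | None = None
    dsc: "object | None" = None  # optional DscSeries when simulated

    def __post_init__(self) -> None:
        for name, vol in {**self.channels, **self.masks}.items():
            self.geometry.check_volume(np.asarray(vol), name)
        if self.followup_T1c is not None:
            self.geometry.check_volume(self.followup_T1c, "followup_T1c")
        cet = self.masks.get("CET")
        if cet is None or not np.asarray(cet, bool).any():
            raise ValidationError("CET mask missing or empty")
        wm = self.masks.get("WM")
        if wm is None or not np.asarray(wm, bool).any():
            raise ValidationError("WM mask missing or empty")
        for a, b in (("CET", "necrosis"), ("CET", "edema"), ("necrosis", "edema")):
            if a in self.masks and b in self.masks:
                if np.any(
                    np.asarray(self.masks[a], bool) & np.asarray(self.masks[b], bool)
                ):
                    raise ValidationError(f"masks {a} and {b} overlap")

    @property
    def cet_mask(self) -> np.ndarray:
        return np.asarray(self.masks["CET"], bool)

    def nonenhancing_brain_mask(self) -> np.ndarray:
        """Brain minus CET, necrosis and edema — the reference tissue used
        for perfusion leakage fitting and intensity normalization."""
        ref = np.asarray(self.masks["brain"], bool).copy()
        for name in ("CET", "necrosis", "edema"):
            if name in self.masks:
                ref &= ~np.asarray(self.masks[name], bool)
        return ref


def plant_response_regions(
    cet_mask: np.ndarray,
    tp_fraction: float,
    blob_scale_mm: float,
    rng: np.random.Generator,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ResponseLabelMap:
    """Partition the CET mask into contiguous TP and PsP territories.

    A Gaussian random field smoothed at ``blob_scale_mm`` is thresholded at
    the within-mask quantile matching ``tp_fraction``, so the TP territory
    consists of coherent blobs (mixed-response geography) rather than
    salt-and-pepper voxels, while the planted TP share is honored to within
    quantile rounding.
    """
    cet = np.asarray(cet_mask, bool)
    if not cet.any():
        raise ValidationError("CET mask is empty")
    if not 0.0 <= tp_fraction <= 1.0:
        raise ValidationError("tp_fraction must lie in [0, 1]")

    labels = np.zeros(cet.shape, np.uint8)
    if tp_fraction == 0.0:
        labels[cet] = PSP
    elif tp_fraction == 1.0:
        labels[cet] = TP
    else:
        sigma = [blob_scale_mm / s for s in spacing]
        fld = ndimage.gaussian_filter(rng.standard_normal(cet.shape), sigma)
        thr = np.quantile(fld[cet], 1.0 - tp_fraction)
        labels[cet] = np.where(fld[cet] >= thr, TP, PSP)
    return ResponseLabelMap(labels=labels, cet_mask=cet, provenance="synthetic-truth")


def _radial_distance_mm(geometry: ImageGeometry, center_vox: np.ndarray) -> np.ndarray:
    coords = [
        (np.arange(n) - c) * s
        for n, c, s in zip(geometry.shape, center_vox, geometry.spacing)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    return np.sqrt(zz**2 + yy**2 + xx**2)


def _smooth_noise(
    shape: tuple[int, ...],
    sd: float,
    correlation_mm: float,
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean Gaussian field with the requested marginal SD, spatially
    correlated at ``correlation_mm`` (smoothing renormalized to preserve SD)."""
    if sd == 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    if correlation_mm > 0:
        sigma = [correlation_mm / s for s in spacing]
        raw = ndimage.gaussian_filter(raw, sigma)
        rsd = raw.std()
        if rsd > 0:
            raw /= rsd
    return sd * raw


def _dilate_mm(
    mask: np.ndarray, radius_mm: float, spacing: tuple[float, float, float]
) -> np.ndarray:
    if radius_mm <= 0:
        return np.asarray(mask, bool)
    dist = ndimage.distance_transform_edt(~np.asarray(mask, bool), sampling=spacing)
    return dist <= radius_mm


def _build_case(
    config: CohortConfig, case_id: str, patient_id: str, rng: np.random.Generator
) -> CaseBundle:
    geo = config.geometry
    extent = np.array(geo.shape) * np.array(geo.spacing)
    brain_radius = float(extent.min()) / 2.0 - 2.0

    tumor_extent = config.tumor_radius_mm + config.edema_margin_mm
    max_jitter = config.center_jitter_mm
    if tumor_extent + max_jitter + config.followup_growth_mm >= brain_radius:
        raise SizingError(
            f"tumor (radius+edema+growth+jitter = "
            f"{tumor_extent + max_jitter + config.followup_growth_mm:.1f} mm) "
            f"does not fit inside the brain (radius {brain_radius:.1f} mm)"
        )

    center_mm = extent / 2.0 + rng.uniform(-max_jitter, max_jitter, size=3)
    center_vox = center_mm / np.array(geo.spacing)
    brain_center_vox = (np.array(geo.shape) - 1) / 2.0

    r_tumor = _radial_distance_mm(geo, center_vox)
    r_brain = _radial_distance_mm(geo, brain_center_vox)

    brain = r_brain <= brain_radius
    necrosis = r_tumor < (config.tumor_radius_mm - config.rim_thickness_mm)
    cet = (r_tumor < config.tumor_radius_mm) & ~necrosis
    edema = (r_tumor < config.tumor_radius_mm + config.edema_margin_mm) & ~necrosis & ~cet
    necrosis &= brain
    cet &= brain
    edema &= brain

    tumor = necrosis | cet | edema
    csf = brain & ~tumor & (r_brain > 0.92 * brain_radius)
    gm = brain & ~tumor & ~csf & (r_brain > 0.72 * brain_radius)
    wm = brain & ~tumor & ~csf & ~gm

    truth = plant_response_regions(
        cet, config.tp_fraction, config.blob_scale_mm, rng, geo.spacing
    )

    channels: dict[str, np.ndarray] = {}
    fields: dict[str, np.ndarray] = {}
    noiseless: dict[str, np.ndarray] = {}
    for chan in ("PET_TBR", "CBV", "T1c"):
        eff = config.effects[chan]
        base = np.zeros(geo.shape)
        tissue = _TISSUE_VALUES[chan]
        base[wm] = tissue["WM"]
        base[gm] = tissue["GM"]
        base[csf] = tissue["CSF"]
        # edema/necrosis: perturbed tissue values
        base[edema] = tissue["WM"] * (1.15 if chan == "PET_TBR" else 0.8)
        base[necrosis] = tissue["CSF"]
        base[truth.tp_mask] = eff.tp_mean
        base[truth.psp_mask] = eff.psp_mean
        # class/texture heterogeneity: spatially correlated, zero-mean
        texture = np.zeros(geo.shape)
        texture[cet] = _smooth_noise(
            geo.shape, 1.0, config.spatial_correlation_mm, geo.spacing, rng
        )[cet]
        texture[truth.tp_mask] *= eff.tp_sd
        texture[truth.psp_mask] *= eff.psp_sd
        noise = config.noise_sd.get(chan, 0.0) * rng.standard_normal(geo.shape)
        noiseless[chan] = base + texture
        fields[chan] = base + texture + noise

    channels["T1c"] = fields["T1c"].astype(np.float32)
    channels["CBV"] = np.clip(fields["CBV"], 0, None).astype(np.float32)
    channels["PET_raw"] = (
        config.pet_background_uptake * np.clip(fields["PET_TBR"], 0, None)
    ).astype(np.float32)

    # follow-up T1c: same underlying anatomy, with TP enhancement boosted
    # (and grown outward beyond the baseline CET), PsP enhancement faded.
    # Growth never overwrites PsP territory inside the baseline CET —
    # response labels live on the baseline CET and must track the truth.
    tp_grown = _dilate_mm(truth.tp_mask, config.followup_growth_mm, geo.spacing) & brain
    tp_fu = truth.tp_mask | (tp_grown & ~cet)
    eff_t1c = config.effects["T1c"]
    factor = np.ones(geo.shape)
    factor[truth.psp_mask] = config.followup_psp_fade
    factor[truth.tp_mask] = config.followup_tp_boost
    fu_field = noiseless["T1c"] * factor
    new_growth = tp_fu & ~cet
    fu_field[new_growth] = eff_t1c.tp_mean * config.followup_tp_boost
    fu = fu_field + config.noise_sd.get("T1c", 0.0) * rng.standard_normal(geo.shape)

    bundle = CaseBundle(
        case_id=case_id,
        patient_id=patient_id,
        geometry=geo,
        channels=channels,
        masks={
            "CET": cet,
            "necrosis": necrosis,
            "edema": edema,
            "WM": wm,
            "GM": gm,
            "CSF": csf,
            "brain": brain,
        },
        followup_T1c=fu.astype(np.float32),
        truth_labels=truth,
    )

    if config.include_dsc:
        from .perfusion import make_dsc_series

        k2 = np.zeros(geo.shape)
        k2[cet] = rng.uniform(0.02, 0.08, size=int(cet.sum()))
        bundle.dsc = make_dsc_series(
            channels["CBV"], brain, k2_map=k2, rng=rng
        )
    return bundle


def generate_cohort(config: CohortConfig) -> list[CaseBundle]:
    """Generate the phantom cohort; deterministic given ``config.seed``.

    Returns one :class:`CaseBundle` per case, each carrying its ground-truth
    :class:`~svxresp.labeling.ResponseLabelMap` on the CET mask.
    """
    case_specs: list[tuple[str, str]] = []
    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        for c in range(config.cases_per_patient):
            case_specs.append((f"{pid}_c{c}", pid))
    for p in range(config.repeat_patients):
        pid = f"P{p:03d}"
        case_specs.append((f"{pid}_c{config.cases_per_patient}", pid))

    root = np.random.SeedSequence([config.seed, len(case_specs)])
    children = root.spawn(len(case_specs))
    return [
        _build_case(config, case_id, pid, np.random.default_rng(child))
        for (case_id, pid), child in zip(case_specs, children)
    ]
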