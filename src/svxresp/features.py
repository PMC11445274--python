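"""First-order and GLCM radiomics per supervoxel, IBSI-style.

Each supervoxel yields 42 features per channel — 18 first-order statistics
of the raw intensity multiset plus 24 gray-level co-occurrence matrix
(GLCM) texture features on intensities discretized to a fixed bin count —
for 126 features total over the three channels (CBV, PET TBR, T1c).

GLCM conventions: distance-1 offsets along the 13 unique 3D directions,
symmetric accumulation, co-occurrences counted only between voxel pairs
that are both inside the supervoxel, per-direction matrices normalized to
sum 1, features averaged over directions. Gray levels are the discretized
bin values actually present in the supervoxel (empty levels dropped).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .labeling import znormalize_to_reference
from .pet import tbr_normalize
from .supervoxels import SupervoxelMap, majority_label

logger = logging.getLogger(__name__)

_EPS = np.spacing(1.0)

FIRSTORDER_NAMES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "p10",
    "p90",
    "maximum",
    "mean",
    "median",
    "iqr",
    "range",
    "mad",
    "rmad",
    "rms",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)

GLCM_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "idm",
    "idmn",
    "id",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_squares",
    "mcc",
)

FEATURE_CHANNELS = ("CBV", "PET", "T1c")

assert len(FIRSTORDER_NAMES) == 18 and len(GLCM_NAMES) == 24


def feature_columns() -> list[str]:
    """The 126 feature column names: ``<channel>__<family>__<feature>``."""
    cols = []
    for chan in FEATURE_CHANNELS:
        cols += [f"{chan}__firstorder__{n}" for n in FIRSTORDER_NAMES]
        cols += [f"{chan}__glcm__{n}" for n in GLCM_NAMES]
    return cols


@dataclass(frozen=True)
class DiscretizationSpec:
    """Gray-level discretization applied per supervoxel per channel."""

    mode: str = "fixed-bin-count"  # or "fixed-bin-width"
    bins: int = 32
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed-bin-count", "fixed-bin-width"):
            raise ValidationError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed-bin-count" and self.bins < 2:
            raise ValidationError("need >= 2 bins")
        if self.mode == "fixed-bin-width" and self.width <= 0:
            raise ValidationError("bin width must be > 0")

    def discretize(self, values: np.ndarray) -> np.ndarray:
        """Map values to integer gray levels starting at 1."""
        v = np.asarray(values, float)
        if self.mode == "fixed-bin-count":
            lo, hi = v.min(), v.max()
            if hi <= lo:
                return np.ones(v.shape, np.int64)
            g = np.floor(self.bins * (v - lo) / (hi - lo)).astype(np.int64) + 1
            return np.clip(g, 1, self.bins)
        g = np.floor(v / self.width).astype(np.int64)
        return g - g.min() + 1


def _unique_3d_directions() -> tuple[tuple[int, int, int], ...]:
    """The 13 distance-1 3D offsets, unique up to sign."""
    dirs = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        first_nonzero = next(x for x in off if x != 0)
        if first_nonzero > 0:
            dirs.append(off)
    return tuple(dirs)


@dataclass(frozen=True)
class GlcmSpec:
    """Co-occurrence accumulation parameters."""

    distance: int = 1
    directions: tuple[tuple[int, int, int], ...] = _unique_3d_directions()
    symmetric: bool = True

    def offsets(self) -> list[tuple[int, int, int]]:
        return [tuple(self.distance * d for d in off) for off in self.directions]


def first_order_features(
    values: np.ndarray,
    disc: DiscretizationSpec | None = None,
    voxel_volume_mm3: float = 1.0,
) -> dict[str, float]:
    """The 18 first-order statistics of one supervoxel/channel multiset.

    Entropy and uniformity are computed on the discretized histogram; all
    moment-based features use the population convention.
    """
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise DegenerateInputError("empty value multiset")
    disc = disc or DiscretizationSpec()

    mean = v.mean()
    var = v.var()  # population
    p10, p25, median, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    energy = float((v**2).sum())

    robust = v[(v >= p10) & (v <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if var > 0:
        m = v - mean
        skew = float((m**3).mean() / var**1.5)
        kurt = float((m**4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0

    counts = np.bincount(disc.discretize(v))
    p = counts[counts > 0] / v.size
    return {
        "energy": energy,
        "total_energy": voxel_volume_mm3 * energy,
        "entropy": float(-(p * np.log2(p)).sum()),
        "minimum": float(v.min()),
        "p10": float(p10),
        "p90": float(p90),
        "maximum": float(v.max()),
        "mean": float(mean),
        "median": float(median),
        "iqr": float(p75 - p25),
        "range": float(v.max() - v.min()),
        "mad": float(np.abs(v - mean).mean()),
        "rmad": rmad,
        "rms": float(np.sqrt((v**2).mean())),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": float(var),
        "uniformity": float((p**2).sum()),
    }


def _glcm_matrices(
    gray: np.ndarray, member: np.ndarray, spec: GlcmSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-direction co-occurrence matrices over the levels present.

    Returns ``(levels, stack)`` where ``stack`` has one unnormalized
    symmetric count matrix per direction (directions with no valid pair
    yield an all-zero matrix).
    """
    levels = np.unique(gray[member])
    index = np.full(int(levels.max()) + 1, -1)
    index[levels] = np.arange(levels.size)

    ndir = len(spec.directions)
    stack = np.zeros((ndir, levels.size, levels.size))
    shape = gray.shape
    for d, off in enumerate(spec.offsets()):
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)
        )
        valid = member[src] & member[dst]
        if not valid.any():
            continue
        gi = index[gray[src][valid]]
        gj = index[gray[dst][valid]]
        np.add.at(stack[d], (gi, gj), 1.0)
        if spec.symmetric:
            np.add.at(stack[d], (gj, gi), 1.0)
    return levels, stack


def _glcm_features_one(P: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """The 24 texture features of one normalized co-occurrence matrix."""
    i = levels[:, None].astype(float)
    j = levels[None, :].astype(float)
    ng = levels.size

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((px * levels).sum())
    mu_y = float((py * levels).sum())
    sig_x = float(np.sqrt((px * (levels - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (levels - mu_y) ** 2).sum()))

    # difference and sum distributions over k = |i-j| and k = i+j
    diff_k = np.abs(i - j).astype(int)
    sum_k = (i + j).astype(int)
    p_diff = np.zeros(diff_k.max() + 1)
    np.add.at(p_diff, diff_k.ravel(), P.ravel())
    p_sum = np.zeros(sum_k.max() + 1)
    np.add.at(p_sum, sum_k.ravel(), P.ravel())
    kd = np.arange(p_diff.size)
    ks = np.arange(p_sum.size)

    diff_avg = float((kd * p_diff).sum())
    sum_avg = float((ks * p_sum).sum())

    hxy = float(-(P * np.log2(P + _EPS)).sum())
    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    pxy_indep = px[:, None] * py[None, :]
    hxy1 = float(-(P * np.log2(pxy_indep + _EPS)).sum())
    hxy2 = float(-(pxy_indep * np.log2(pxy_indep + _EPS)).sum())

    max_h = max(hx, hy)
    imc1 = (hxy - hxy1) / max_h if max_h > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig_x > 0 and sig_y > 0:
        corr = (float((P * i * j).sum()) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        corr = 1.0

    off_diag = diff_k > 0
    inv_var = float((P[off_diag] / (i - j)[off_diag] ** 2).sum()) if off_diag.any() else 0.0

    if ng > 1:
        # Q(a,b) = sum_k P(a,k) P(b,k) / (px(a) py(k)); MCC is the square
        # root of its second-largest eigenvalue
        Q = np.zeros((ng, ng))
        for k in range(ng):
            if py[k] <= 0:
                continue
            Q += np.outer(
                np.where(px > 0, P[:, k] / np.where(px > 0, px, 1.0), 0.0),
                P[:, k] / py[k],
            )
        eig = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    cp = i + j - mu_x - mu_y
    return {
        "autocorrelation": float((P * i * j).sum()),
        "joint_average": mu_x,
        "cluster_prominence": float((P * cp**4).sum()),
        "cluster_shade": float((P * cp**3).sum()),
        "cluster_tendency": float((P * cp**2).sum()),
        "contrast": float((P * (i - j) ** 2).sum()),
        "correlation": float(corr),
        "difference_average": diff_avg,
        "difference_entropy": float(-(p_diff * np.log2(p_diff + _EPS)).sum()),
        "difference_variance": float(((kd - diff_avg) ** 2 * p_diff).sum()),
        "joint_energy": float((P**2).sum()),
        "joint_entropy": hxy,
        "imc1": float(imc1),
        "imc2": imc2,
        "idm": float((P / (1.0 + (i - j) ** 2)).sum()),
        "idmn": float((P / (1.0 + ((i - j) ** 2) / ng**2)).sum()),
        "id": float((P / (1.0 + np.abs(i - j))).sum()),
        "idn": float((P / (1.0 + np.abs(i - j) / ng)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(P.max()),
        "sum_average": sum_avg,
        "sum_entropy": float(-(p_sum * np.log2(p_sum + _EPS)).sum()),
        "sum_squares": float((P * (i - mu_x) ** 2).sum()),
        "mcc": mcc,
    }


def glcm_features(
    volume: np.ndarray,
    member_mask: np.ndarray,
    disc: DiscretizationSpec | None = None,
    spec: GlcmSpec | None = None,
) -> dict[str, float]:
    """The 24 GLCM features of one supervoxel on one channel.

    Discretization happens over the member voxels only; co-occurrences are
    restricted to pairs with both voxels in ``member_mask``; per-direction
    feature values are averaged over the directions that have at least one
    valid pair. If no direction has any valid pair, all features are NaN.
    """
    disc = disc or DiscretizationSpec()
    spec = spec or GlcmSpec()
    member = np.asarray(member_mask, bool)
    n_member = int(member.sum())
    if n_member < 2:
        return {name: float("nan") for name in GLCM_NAMES}

    # work on the bounding box for speed
    idx = np.argwhere(member)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_member = member[box]
    sub_vol = np.asarray(volume, float)[box]

    gray = np.zeros(sub_member.shape, np.int64)
    gray[sub_member] = disc.discretize(sub_vol[sub_member])

    levels, stack = _glcm_matrices(gray, sub_member, spec)
    totals = stack.sum(axis=(1, 2))
    valid = totals > 0
    if not valid.any():
        return {name: float("nan") for name in GLCM_NAMES}

    acc: dict[str, float] = {name: 0.0 for name in GLCM_NAMES}
    for d in np.flatnonzero(valid):
        feats = _glcm_features_one(stack[d] / totals[d], levels)
        for name in GLCM_NAMES:
            acc[name] += feats[name]
    nvalid = int(valid.sum())
    return {name: acc[name] / nvalid for name in GLCM_NAMES}


def prepare_channels(bundle, t1c_mode: str = "zscore") -> dict[str, np.ndarray]:
    """Derive the three analysis channels of a case bundle.

    PET: tumor-to-background ratio (raw uptake normalized to nonlesional
    white matter). CBV: as carried by the bundle (leakage-corrected upstream
    if a DSC series was supplied). T1c: z-scored against nonenhancing brain
    by default (arbitrary units otherwise), ``t1c_mode='raw'`` disables it.
    """
    exclusions = [
        bundle.masks[m] for m in ("CET", "necrosis", "edema") if m in bundle.masks
    ]
    pet = tbr_normalize(bundle.channels["PET_raw"], bundle.masks["WM"], exclusions).tbr
    if "CBV" not in bundle.channels:
        raise ValidationError("bundle is missing the CBV channel")
    t1c = np.asarray(bundle.channels["T1c"], float)
    if t1c_mode == "zscore":
        t1c = znormalize_to_reference(t1c, bundle.nonenhancing_brain_mask())
    elif t1c_mode != "raw":
        raise ValidationError(f"unknown t1c_mode {t1c_mode!r}")
    return {
        "CBV": np.asarray(bundle.channels["CBV"], float),
        "PET": pet,
        "T1c": t1c,
    }


def extract_features_for_case(
    channels: dict[str, np.ndarray],
    svx: SupervoxelMap,
    svx_labels: pd.DataFrame,
    disc: DiscretizationSpec | None = None,
    glcm_spec: GlcmSpec | None = None,
    voxel_volume_mm3: float = 1.0,
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Feature records for every supervoxel of one case.

    Returns ``(table, excluded)`` where ``excluded`` lists
    (supervoxel_id, reason) for degenerate supervoxels left out of the
    table (single gray level on some channel, or no co-occurrence pairs).
    """
    disc = disc or DiscretizationSpec()
    glcm_spec = glcm_spec or GlcmSpec()
    missing = [c for c in FEATURE_CHANNELS if c not in channels]
    if missing:
        raise ValidationError(f"missing channel(s): {', '.join(missing)}")

    label_by_id = svx_labels.set_index("supervoxel_id")
    rows = []
    excluded: list[tuple[int, str]] = []
    for sid, coords in svx.voxel_sets():
        member = np.zeros(svx.ids.shape, bool)
        member[tuple(coords.T)] = True
        rec: dict[str, float] = {}
        reason = None
        for chan in FEATURE_CHANNELS:
            vals = channels[chan][member]
            if np.unique(vals).size < 2:
                reason = f"single gray level on {chan}"
                break
            fo = first_order_features(vals, disc, voxel_volume_mm3)
            gl = glcm_features(channels[chan], member, disc, glcm_spec)
            if any(np.isnan(v) for v in gl.values()):
                reason = f"no valid co-occurrence pairs on {chan}"
                break
            rec.update({f"{chan}__firstorder__{k}": v for k, v in fo.items()})
            rec.update({f"{chan}__glcm__{k}": v for k, v in gl.items()})
        if reason is not None:
            excluded.append((sid, reason))
            logger.info("excluding supervoxel %d: %s", sid, reason)
            continue
        meta = label_by_id.loc[sid]
        rows.append(
            {
                "supervoxel_id": sid,
                "label": int(meta["label"]),
                "majority_fraction": float(meta["majority_fraction"]),
                "n_voxels": int(meta["n_voxels"]),
                **rec,
            }
        )
    return pd.DataFrame(rows), excluded


def extract_feature_table(
    cases,
    svx_maps: dict[str, SupervoxelMap],
    svx_labels: dict[str, pd.DataFrame] | None = None,
    response_maps: dict | None = None,
    disc: DiscretizationSpec | None = None,
    glcm_spec: GlcmSpec | None = None,
    t1c_mode: str = "zscore",
) -> pd.DataFrame:
    """One 126-feature record per supervoxel across a cohort.

    ``svx_labels`` maps case_id to a majority-label table; alternatively
    ``response_maps`` maps case_id to a voxel ResponseLabelMap from which
    majority labels are computed here. The result carries patient_id,
    case_id, supervoxel_id, label, majority_fraction and n_voxels metadata
    columns followed by the 126 feature columns.
    """
    frames = []
    for bundle in cases:
        svx = svx_maps[bundle.case_id]
        if svx_labels is not None and bundle.case_id in svx_labels:
            labels = svx_labels[bundle.case_id]
        elif response_maps is not None:
            labels = majority_label(svx, response_maps[bundle.case_id])
        else:
            raise ValidationError(f"no labels provided for case {bundle.case_id}")
        channels = prepare_channels(bundle, t1c_mode=t1c_mode)
        table, excluded = extract_features_for_case(
            channels,
            svx,
            labels,
            disc,
            glcm_spec,
            voxel_volume_mm3=bundle.geometry.voxel_volume_mm3,
        )
        for sid, reason in excluded:
            logger.warning(
                "case %s: supervoxel %d excluded (%s)", bundle.case_id, sid, reason
            )
        table.insert(0, "case_id", bundle.case_id)
        table.insert(0, "patient_id", bundle.patient_id)
        frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    feat_cols = [c for c in out.columns if "__" in c]
    assert len(feat_cols) == 126, f"expected 126 feature columns, got {len(feat_cols)}"
    return out
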