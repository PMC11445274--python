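"""Leakage-corrected cerebral blood volume from DSC perfusion series.

Dynamic susceptibility contrast (DSC) MRI tracks the T2*-signal drop during
a gadolinium bolus. The transverse relaxation change is

    dR2*(t) = -(1/TE) * ln(S(t) / S0),

with S0 the pre-bolus baseline signal, and CBV is (up to a global constant)
the integral of dR2* over the bolus passage. In enhancing tumor the agent
extravasates, which biases the integral; the standard linear correction
models each voxel curve against the average curve of nonenhancing brain:

    dR2*_voxel(t) ~= K1 * R(t) - K2 * int_0^t R(tau) dtau

where R is the reference curve. The corrected CBV adds back the leakage
term: CBV_corr = int dR2* + K2 * iint R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ValidationError

DEFAULT_TE_MS = 30.0
DEFAULT_TR_MS = 1500.0


@dataclass
class DscSeries:
    """4D DSC signal S(x, t) with acquisition timing.

    ``signal`` has time on the last axis; ``baseline_window`` is the
    (start, stop) index slice of pre-bolus time points used for S0.
    """

    signal: np.ndarray
    te_ms: float = DEFAULT_TE_MS
    tr_ms: float = DEFAULT_TR_MS
    baseline_window: tuple[int, int] = (0, 8)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, float)
        if sig.ndim != 4:
            raise ValidationError("DSC signal must be 4D (x, y, z, t)")
        if sig.shape[-1] < 10:
            raise ValidationError("DSC series needs >= 10 time points")
        b0, b1 = self.baseline_window
        if not (0 <= b0 < b1 <= sig.shape[-1]):
            raise ValidationError("baseline_window must be a nonempty index range")
        if self.te_ms <= 0 or self.tr_ms <= 0:
            raise ValidationError("TE and TR must be positive")
        self.signal = sig

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[-1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr_ms / 1000.0


@dataclass
class CbvResult:
    """Leakage-corrected CBV plus the per-voxel leakage-model coefficients."""

    cbv: np.ndarray
    cbv_uncorrected: np.ndarray
    k1_map: np.ndarray
    k2_map: np.ndarray
    flagged: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), int))


def signal_to_delta_r2(
    series: DscSeries, brain_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convert the DSC signal into the dR2*(t) concentration proxy.

    Returns ``(delta_r2, flagged)`` where ``delta_r2`` is 4D and ``flagged``
    is an (n, 3) array of voxel indices inside the mask with non-positive
    S0 or signal, whose curves are zeroed and must be excluded from fits.
    """
    mask = np.asarray(brain_mask, bool)
    if series.signal.shape[:3] != mask.shape:
        _geom_err(series, mask)
    b0, b1 = series.baseline_window
    s0 = series.signal[..., b0:b1].mean(axis=-1)

    bad = mask & ((s0 <= 0) | (series.signal <= 0).any(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        dr2 = -np.log(series.signal / s0[..., None]) / series.te_ms
    dr2[~mask] = 0.0
    dr2[bad] = 0.0
    dr2[~np.isfinite(dr2)] = 0.0
    return dr2, np.argwhere(bad)


def _geom_err(series: DscSeries, mask: np.ndarray):
    from .errors import GeometryError

    raise GeometryError(
        f"mask shape {mask.shape} does not match DSC grid {series.signal.shape[:3]}"
    )


def gamma_variate(
    t: np.ndarray, t0: float = 12.0, alpha: float = 3.0, beta: float = 1.5
) -> np.ndarray:
    """Gamma-variate bolus shape, zero before arrival time ``t0`` (seconds)."""
    out = np.zeros_like(np.asarray(t, float))
    late = t > t0
    dt = t[late] - t0
    out[late] = (dt**alpha) * np.exp(-dt / beta)
    peak = out.max()
    return out / peak if peak > 0 else out


def leakage_corrected_cbv(
    delta_r2: np.ndarray,
    reference_mask: np.ndarray,
    times_s: np.ndarray,
    integration_window: tuple[int, int] | None = None,
    fit_mask: np.ndarray | None = None,
    min_reference_voxels: int = 100,
) -> CbvResult:
    """Per-voxel linear leakage fit against the reference-tissue curve.

    The reference curve R(t) is the mean dR2* over ``reference_mask``
    (nonenhancing brain). Each voxel curve is least-squares fitted as
    K1*R(t) - K2*cumint(R)(t) over ``integration_window`` (default: all
    time points); uncorrected CBV is the trapezoidal integral of the voxel
    curve and the corrected CBV adds K2 times the double integral of R.
    """
    dr2 = np.asarray(delta_r2, float)
    ref_mask = np.asarray(reference_mask, bool)
    if int(ref_mask.sum()) < min_reference_voxels:
        raise ValidationError(
            f"reference mask has {int(ref_mask.sum())} voxels, "
            f"need >= {min_reference_voxels}"
        )
    t = np.asarray(times_s, float)
    if integration_window is None:
        integration_window = (0, dr2.shape[-1])
    w0, w1 = integration_window

    ref = dr2[ref_mask].mean(axis=0)
    if not np.any(ref != 0):
        raise DegenerateInputError("reference curve is identically zero")

    ref_cum = _cumtrapz(ref, t)
    win = slice(w0, w1)
    tw, refw, cumw = t[win], ref[win], ref_cum[win]

    # 2x2 normal equations, solved for every voxel at once
    a11 = float(refw @ refw)
    a12 = float(refw @ -cumw)
    a22 = float(cumw @ cumw)
    det = a11 * a22 - a12 * a12
    if det <= 0:
        raise DegenerateInputError("degenerate leakage design (collinear regressors)")

    vox = dr2[..., win]
    b1 = vox @ refw
    b2 = vox @ -cumw
    k1 = (a22 * b1 - a12 * b2) / det
    k2 = (a11 * b2 - a12 * b1) / det  # second regressor is -cumint(R)

    cbv_unc = np.trapezoid(vox, tw, axis=-1)
    ref_double_int = np.trapezoid(cumw, tw)
    cbv = cbv_unc + k2 * ref_double_int

    if fit_mask is not None:
        keep = np.asarray(fit_mask, bool)
        k1 = np.where(keep, k1, 0.0)
        k2 = np.where(keep, k2, 0.0)
        cbv = np.where(keep, cbv, cbv_unc)

    return CbvResult(
        cbv=cbv, cbv_uncorrected=cbv_unc, k1_map=k1, k2_map=k2
    )


def _cumtrapz(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(t))
    return out


def compute_cbv(
    series: DscSeries,
    brain_mask: np.ndarray,
    reference_mask: np.ndarray,
    **kwargs,
) -> CbvResult:
    """Convenience wrapper: signal -> dR2* -> leakage-corrected CBV."""
    dr2, flagged = signal_to_delta_r2(series, brain_mask)
    result = leakage_corrected_cbv(
        dr2, reference_mask & np.asarray(brain_mask, bool), series.times_s, **kwargs
    )
    result.flagged = flagged
    return result


def normalize_to_wm(cbv: np.ndarray, wm_mask: np.ndarray) -> np.ndarray:
    """Optional variant: CBV relative to mean white-matter CBV (rCBV)."""
    wm_mean = float(cbv[np.asarray(wm_mask, bool)].mean())
    if wm_mean <= 0:
        raise ValidationError("non-positive mean WM CBV; cannot normalize")
    return cbv / wm_mean


def make_dsc_series(
    cbv_volume: np.ndarray,
    brain_mask: np.ndarray,
    k2_map: np.ndarray | None = None,
    te_ms: float = DEFAULT_TE_MS,
    tr_ms: float = DEFAULT_TR_MS,
    n_timepoints: int = 60,
    baseline_window: tuple[int, int] = (0, 8),
    s0: float = 1000.0,
    signal_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DscSeries:
    """Forward-simulate a DSC series whose leakage-corrected CBV is known.

    Every brain voxel follows the linear leakage model with a shared
    gamma-variate reference shape scaled to unit integral, K1 set so the
    corrected CBV equals ``cbv_volume``, and K2 from ``k2_map`` (default 0).
    Used by the phantom generator and by parameter-recovery tests.
    """
    mask = np.asarray(brain_mask, bool)
    t = np.arange(n_timepoints) * tr_ms / 1000.0
    shape_curve = gamma_variate(t)
    integral = np.trapezoid(shape_curve, t)
    ref = shape_curve / integral  # unit-integral reference curve

    k1 = np.where(mask, np.asarray(cbv_volume, float), 0.0)
    k2 = np.zeros(mask.shape) if k2_map is None else np.asarray(k2_map, float)

    ref_cum = _cumtrapz(ref, t)
    dr2 = k1[..., None] * ref[None, None, None, :] - k2[..., None] * ref_cum
    signal = s0 * np.exp(-te_ms * dr2)
    if signal_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        signal = signal + signal_noise_sd * rng.standard_normal(signal.shape)
    signal[~mask] = s0
    return DscSeries(
        signal=signal.astype(np.float32),
        te_ms=te_ms,
        tr_ms=tr_ms,
        baseline_window=baseline_window,
    )
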