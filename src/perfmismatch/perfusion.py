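"""DSC-MRI perfusion quantification by block-circulant SVD deconvolution.

The dynamic signal is converted to contrast-agent concentration,
C(t) = -ln(S/S0)/(k*TE), and the indicator-dilution convolution

    C(t) = CBF * (AIF (*) R)(t)

is inverted per voxel for the flow-scaled residue function
k(t) = CBF*R(t).  The convolution matrix is made circulant from the
zero-padded AIF (padding factor 2), which renders the inversion
insensitive to bolus delay: a delayed tissue curve yields the same
amplitude with the residue peak shifted.  Regularization is truncated
SVD — singular values below a fixed fraction (default 0.15) of the
largest are zeroed.

Summary parameters per voxel:

    CBF  = max_t k(t)
    Tmax = TR * argmax_t k(t)        (delay surrogate)
    CBV  = area(C) / area(AIF)       (trapezoid rule)
    MTT  = CBV / CBF                 (central volume theorem)

Proportionality constants (hematocrit, tissue density, k) are set to 1:
only contralateral-normalized relative maps are reported downstream,
where they cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .phantom import AcquisitionParams, ConcentrationCurve, DynamicSeries
from .volumes import BinaryMask, ScalarVolume

__all__ = [
    "DeconvConfig",
    "PerfusionMaps",
    "signal_to_concentration",
    "circulant_matrix",
    "truncated_svd_pinv",
    "deconvolve_svd_circulant",
    "perfusion_parameters",
    "compute_perfusion_maps",
]


@dataclass(frozen=True)
class DeconvConfig:
    """Deconvolution settings.

    svd_threshold : singular values below this fraction of the largest
        are discarded (0.15 default).
    pad_factor : zero-padding multiple for the circulant embedding
        (>= 2 for delay insensitivity).
    cbv_area_rule : numerical integration rule for the area ratio.
    mtt_rule : 'central_volume' (CBV/CBF) or 'first_moment' of k(t).
    """

    svd_threshold: float = 0.15
    pad_factor: int = 2
    cbv_area_rule: Literal["trapezoid"] = "trapezoid"
    mtt_rule: Literal["central_volume", "first_moment"] = "central_volume"

    def __post_init__(self) -> None:
        if not 0 < self.svd_threshold < 1:
            raise ValueError("svd_threshold must lie in (0, 1)")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be >= 2")


@dataclass
class PerfusionMaps:
    """CBF/CBV/MTT/Tmax bundle for one timepoint, on the ADC grid."""

    cbf: ScalarVolume
    cbv: ScalarVolume
    mtt: ScalarVolume
    tmax: ScalarVolume


def signal_to_concentration(series: DynamicSeries, n_baseline_frames: int = 8) -> np.ndarray:
    """Convert a 4D DSC signal series to concentration.

    S0 is estimated per voxel as the mean of the first
    ``n_baseline_frames`` (pre-bolus) frames; then
    C = -ln(S/S0) / (k*TE).  Voxels with nonpositive S or S0 are
    invalid (NaN over the full time course).
    """
    if n_baseline_frames < 3:
        raise ValueError("need at least 3 pre-bolus frames for the S0 estimate")
    p = series.params
    sig = series.signal
    s0 = sig[..., :n_baseline_frames].mean(axis=-1)
    bad = (s0 <= 0) | ~np.isfinite(s0) | np.any(sig <= 0, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = -np.log(sig / s0[..., None]) / (p.k_conversion * p.te_s)
    c[bad] = np.nan
    return c


def circulant_matrix(aif: ConcentrationCurve, n: int, cfg: DeconvConfig) -> np.ndarray:
    """Block-circulant convolution matrix of the zero-padded AIF.

    A[i, j] = TR * a[(i - j) mod L] with L = pad_factor * n, so that
    A @ k_pad reproduces the circular convolution TR * (a (*) k).
    """
    length = cfg.pad_factor * n
    a = np.zeros(length)
    a[: len(aif.values)] = aif.values
    idx = (np.arange(length)[:, None] - np.arange(length)[None, :]) % length
    return aif.tr_s * a[idx]


def truncated_svd_pinv(aif: ConcentrationCurve, n: int, cfg: DeconvConfig) -> np.ndarray:
    """Truncated-SVD pseudoinverse of the circulant AIF matrix.

    Singular values below ``cfg.svd_threshold`` times the largest are
    zeroed before inversion.  Raises if every singular value falls
    below the cutoff (degenerate AIF).
    """
    a_mat = circulant_matrix(aif, n, cfg)
    u, s, vt = np.linalg.svd(a_mat)
    cutoff = cfg.svd_threshold * s[0]
    keep = s >= cutoff
    if not keep.any():
        raise ValueError("all singular values below the truncation threshold")
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    return (vt.T * s_inv) @ u.T


def deconvolve_svd_circulant(
    c_voxel: np.ndarray, aif: ConcentrationCurve, cfg: DeconvConfig = DeconvConfig()
) -> np.ndarray:
    """Deconvolve one tissue curve: k(t) = CBF * R(t), length pad_factor*n."""
    c_voxel = np.asarray(c_voxel, dtype=np.float64).ravel()
    n = len(c_voxel)
    pinv = truncated_svd_pinv(aif, n, cfg)
    c_pad = np.zeros(cfg.pad_factor * n)
    c_pad[:n] = c_voxel
    return pinv @ c_pad


def perfusion_parameters(
    k: np.ndarray,
    c: np.ndarray,
    aif: ConcentrationCurve,
    cfg: DeconvConfig = DeconvConfig(),
    tr: float | None = None,
) -> tuple[float, float, float, float]:
    """Summary parameters (cbf, cbv, mtt, tmax) of one voxel.

    CBF is the residue-function maximum (negative truncation
    oscillations are kept for the argmax but CBF is floored at 0);
    Tmax is the time of that maximum; CBV the concentration/AIF area
    ratio; MTT follows from the central volume theorem and is NaN
    where CBF vanishes.
    """
    tr = aif.tr_s if tr is None else tr
    aif_area = aif.area()
    if aif_area <= 0:
        raise ValueError("zero AIF area")
    k = np.asarray(k, dtype=np.float64)
    imax = int(np.argmax(k))
    cbf = max(float(k[imax]), 0.0)
    tmax = tr * imax
    cbv = float(np.trapezoid(np.asarray(c, dtype=np.float64), dx=tr)) / aif_area
    if cfg.mtt_rule == "central_volume":
        mtt = cbv / cbf if cbf > 0 else float("nan")
    else:
        kp = np.clip(k, 0.0, None)
        area = kp.sum() * tr
        mtt = float((np.arange(len(k)) * tr * kp).sum() * tr / area) if area > 0 else float("nan")
    return cbf, cbv, mtt, tmax


def compute_perfusion_maps(
    series: DynamicSeries,
    aif: ConcentrationCurve,
    brain: BinaryMask,
    cfg: DeconvConfig = DeconvConfig(),
    n_baseline_frames: int = 8,
) -> PerfusionMaps:
    """Voxelwise perfusion quantification over a brain mask.

    The truncated pseudoinverse of the circulant AIF matrix is built
    once and applied to every voxel's concentration curve.  Voxels
    whose signal conversion fails are flagged invalid in every map;
    per-voxel failures never abort the volume.
    """
    p = series.params
    n = p.n_timepoints
    conc = signal_to_concentration(series, n_baseline_frames)
    bmask = brain.values
    curves = conc[bmask]  # (nvox, n)
    valid = np.all(np.isfinite(curves), axis=1)

    pinv = truncated_svd_pinv(aif, n, cfg)
    c_pad = np.zeros((curves.shape[0], cfg.pad_factor * n))
    c_pad[valid, :n] = curves[valid]
    k = c_pad @ pinv.T  # (nvox, L)

    imax = np.argmax(k, axis=1)
    cbf = np.maximum(k[np.arange(len(k)), imax], 0.0)
    tmax = p.tr_s * imax.astype(np.float64)
    aif_area = aif.area()
    cbv = np.trapezoid(np.where(valid[:, None], curves, 0.0), dx=p.tr_s, axis=1) / aif_area
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(cbf > 0, cbv / cbf, np.nan)

    def fill(vec: np.ndarray, units: str) -> ScalarVolume:
        vol = np.full(brain.shape, np.nan)
        v = vec.copy()
        v[~valid] = np.nan
        vol[bmask] = v
        return ScalarVolume(vol, brain.spacing_mm, units)

    return PerfusionMaps(
        cbf=fill(cbf, "a.u."),
        cbv=fill(cbv, "dimensionless"),
        mtt=fill(mtt, "s"),
        tmax=fill(tmax, "s"),
    )
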