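"""ADC mapping, CSF exclusion, and volume-growing infarct-core segmentation.

The apparent diffusion coefficient is computed from a two-point
diffusion experiment, ADC = ln(S_b0 / S_b1000) / b, and thresholded to
delineate the irreversibly injured infarct core: voxels at or below
550e-6 mm^2/s (a deliberately conservative cutoff that keeps penumbral
tissue out of the core) are grown into connected components.  CSF,
whose free-water diffusion sits far above parenchymal values, is
segmented separately and excluded from reference regions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, ScalarVolume

__all__ = [
    "SegmentationConfig",
    "compute_adc",
    "segment_csf",
    "grow_region",
    "segment_core",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and connectivity of the ADC-based segmentations.

    adc_core_upper : infarct-core upper ADC bound (mm^2/s).
    adc_csf_lower : CSF lower ADC bound (mm^2/s); the physiologic gap
        between parenchyma (~800e-6) and free water (~3000e-6) makes
        2000e-6 a safe default.
    connectivity : 6- (faces) or 26- (faces+edges+corners) neighborhood
        used by the region growing.
    min_component_voxels : connected components smaller than this are
        discarded as noise.
    """

    adc_core_upper: float = 550e-6
    adc_csf_lower: float = 2000e-6
    connectivity: Literal[6, 26] = 26
    min_component_voxels: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.adc_core_upper < self.adc_csf_lower:
            raise ValueError("require 0 < adc_core_upper < adc_csf_lower")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, 1 if self.connectivity == 6 else 3)


def compute_adc(b0: ScalarVolume, b1000: ScalarVolume, b: float = 1000.0) -> ScalarVolume:
    """ADC map from a b0/b1000 DWI pair: ln(b0/b1000)/b voxelwise.

    Voxels where the diffusion-weighted signal meets or exceeds the
    unweighted signal (only possible through noise) are clamped to
    ADC 0; background voxels (non-positive b0) are flagged invalid.
    """
    if b0.shape != b1000.shape:
        raise ValueError(f"grid mismatch: {b0.shape} vs {b1000.shape}")
    if b <= 0:
        raise ValueError("b-value must be positive")
    s0, s1 = b0.values, b1000.values
    adc = np.full(b0.shape, np.nan)
    fg = np.isfinite(s0) & (s0 > 0) & np.isfinite(s1)
    pos = fg & (s1 > 0) & (s1 < s0)
    adc[pos] = np.log(s0[pos] / s1[pos]) / b
    adc[fg & ~pos] = 0.0  # clamp b1000 >= b0 (and nonphysical zeros)
    return ScalarVolume(adc, b0.spacing_mm, "mm^2/s")


def segment_csf(adc: ScalarVolume, cfg: SegmentationConfig = SegmentationConfig()) -> BinaryMask:
    """CSF mask: voxels with ADC above the free-water threshold."""
    vals = adc.values
    return BinaryMask(np.isfinite(vals) & (vals > cfg.adc_csf_lower), adc.spacing_mm)


def grow_region(
    volume: ScalarVolume,
    predicate: np.ndarray,
    seeds: Sequence[tuple[int, int, int]] | None,
    cfg: SegmentationConfig = SegmentationConfig(),
) -> BinaryMask:
    """Volume growing: connected expansion of seeds through a predicate set.

    ``predicate`` is the boolean set of candidate voxels (e.g. ADC at
    or below the core threshold).  With explicit ``seeds``, only
    components containing a seed are kept, mirroring the interactive
    workflow; with ``seeds=None`` every qualifying voxel seeds itself
    (fully automatic).  Components smaller than
    ``cfg.min_component_voxels`` are dropped.
    """
    predicate = np.asarray(predicate, dtype=bool)
    if predicate.shape != volume.shape:
        raise ValueError("predicate grid does not match volume")
    if seeds is not None:
        for s in seeds:
            if not predicate[tuple(s)]:
                raise ValueError(f"seed {tuple(s)} does not satisfy the growing predicate")
    labels, n = ndimage.label(predicate, structure=cfg.structure)
    if n == 0:
        return BinaryMask(np.zeros(volume.shape, dtype=bool), volume.spacing_mm)
    counts = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    if seeds is None:
        keep[1:] = True
    else:
        for s in seeds:
            keep[labels[tuple(s)]] = True
    keep &= counts >= cfg.min_component_voxels
    keep[0] = False
    return BinaryMask(keep[labels], volume.spacing_mm)


def segment_core(
    adc: ScalarVolume,
    brain: BinaryMask,
    cfg: SegmentationConfig = SegmentationConfig(),
    seeds: Sequence[tuple[int, int, int]] | None = None,
) -> BinaryMask:
    """Infarct-core segmentation by thresholded volume growing.

    Candidate voxels are brain voxels with 0 < ADC <= the core upper
    threshold; growing proceeds per :func:`grow_region`.  By default
    every qualifying voxel acts as a seed (automatic mode); pass
    explicit seeds to reproduce an interactive seeded segmentation.
    An empty core is a valid result.
    """
    vals = adc.values
    predicate = brain.values & np.isfinite(vals) & (vals > 0) & (vals <= cfg.adc_core_upper)
    return grow_region(adc, predicate, seeds, cfg)
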