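"""Relative maps, mismatch ROI construction, and longitudinal features.

Perfusion parameters are normalized to the healthy (contralateral)
hemisphere: flow and volume maps by division by the contralateral mean
(rCBF, rCBV), temporal maps by subtraction of it (rMTT, rTmax), with
CSF excluded from the reference region.  Hypoperfused tissue is then
segmented on the rTmax map at a 6 s threshold; the penumbra is the
perfusion-diffusion mismatch — hypoperfusion minus the ADC-defined
infarct core — and the remaining affected-hemisphere brain (minus CSF)
is the unaffected-tissue ROI.  Per-ROI means are extracted at both
timepoints using the *baseline* ROIs throughout, so follow-up changes
measure perfusion evolution in fixed tissue, not ROI drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .diffusion import SegmentationConfig, grow_region
from .perfusion import PerfusionMaps
from .volumes import BinaryMask, HemispherePartition, ScalarVolume

__all__ = [
    "RoiConfig",
    "RelativeMaps",
    "TissueROIs",
    "SubjectFeatures",
    "contralateral_reference",
    "relative_map",
    "compute_relative_maps",
    "segment_hypoperfusion",
    "derive_rois",
    "roi_mean",
    "extract_subject_features",
]

#: normalization mode per perfusion parameter: ratio for flow/volume,
#: difference for temporal parameters.
NORMALIZATION_MODE: dict[str, str] = {
    "cbf": "divide",
    "cbv": "divide",
    "mtt": "subtract",
    "tmax": "subtract",
}


@dataclass(frozen=True)
class RoiConfig:
    """Mismatch segmentation switches.

    tmax_threshold_s : lower bound of hypoperfused tissue (inclusive).
    use_relative_tmax : threshold the contralateral-subtracted rTmax
        map (default) rather than absolute Tmax.
    """

    tmax_threshold_s: float = 6.0
    use_relative_tmax: bool = True
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)


@dataclass
class RelativeMaps:
    """Contralateral-normalized parameter bundle (one timepoint)."""

    rcbf: ScalarVolume
    rcbv: ScalarVolume
    rmtt: ScalarVolume
    rtmax: ScalarVolume


@dataclass
class TissueROIs:
    """Disjoint tissue classes of the affected hemisphere.

    penumbra = hypoperfusion minus core;
    unaffected = affected-hemisphere brain minus core, penumbra, CSF.
    """

    core: BinaryMask
    penumbra: BinaryMask
    unaffected: BinaryMask
    hypoperfusion: BinaryMask

    def as_dict(self) -> dict[str, BinaryMask]:
        return {"core": self.core, "penumbra": self.penumbra, "unaffected": self.unaffected}


def contralateral_reference(
    vol: ScalarVolume, hemis: HemispherePartition, csf: BinaryMask
) -> float:
    """Mean over contralateral brain tissue, CSF excluded."""
    region = hemis.contralateral.values & ~csf.values & vol.valid()
    if not region.any():
        raise ValueError("empty contralateral reference region")
    return float(vol.values[region].mean())


def relative_map(
    vol: ScalarVolume, reference: float, mode: Literal["divide", "subtract"]
) -> ScalarVolume:
    """Normalize a map to a scalar reference, by ratio or difference."""
    if mode == "divide":
        if reference <= 0:
            raise ValueError(f"division requires a positive reference, got {reference}")
        return vol.like(vol.values / reference, units="dimensionless")
    if mode == "subtract":
        return vol.like(vol.values - reference)
    raise ValueError(f"unknown normalization mode {mode!r}")


def compute_relative_maps(
    maps: PerfusionMaps, hemis: HemispherePartition, csf: BinaryMask
) -> RelativeMaps:
    """Normalize all four perfusion maps against the contralateral mean."""
    out = {}
    for name in ("cbf", "cbv", "mtt", "tmax"):
        vol: ScalarVolume = getattr(maps, name)
        ref = contralateral_reference(vol, hemis, csf)
        out["r" + name] = relative_map(vol, ref, NORMALIZATION_MODE[name])  # type: ignore[arg-type]
    return RelativeMaps(**out)


def segment_hypoperfusion(
    rtmax: ScalarVolume, brain: BinaryMask, cfg: RoiConfig = RoiConfig()
) -> BinaryMask:
    """Hypoperfused tissue: volume growing on rTmax >= threshold.

    The threshold is inclusive at exactly 6.0 s; an empty mask is a
    valid result (no perfusion deficit).
    """
    vals = rtmax.values
    predicate = brain.values & np.isfinite(vals) & (vals >= cfg.tmax_threshold_s)
    return grow_region(rtmax, predicate, seeds=None, cfg=cfg.segmentation)


def derive_rois(
    core: BinaryMask,
    hypoperfusion: BinaryMask,
    hemis: HemispherePartition,
    csf: BinaryMask,
) -> TissueROIs:
    """Build the disjoint core / penumbra / unaffected partition.

    Core voxels falling outside the affected hemisphere are clipped
    (with a warning); the penumbra is the mismatch set, and unaffected
    tissue the affected-hemisphere remainder excluding CSF.
    """
    affected = hemis.affected
    if np.any(core.values & ~affected.values):
        import warnings

        warnings.warn("core voxels outside the affected hemisphere were clipped", stacklevel=2)
        core = core & affected
    hypoperfusion = hypoperfusion & affected
    penumbra = hypoperfusion - core
    unaffected = ((affected - core) - penumbra) - csf
    return TissueROIs(core=core, penumbra=penumbra, unaffected=unaffected, hypoperfusion=hypoperfusion)


def roi_mean(vol: ScalarVolume, roi: BinaryMask) -> float:
    """Arithmetic mean over an ROI; invalid voxels excluded.

    An empty ROI (or one with no valid voxels) yields NaN — reported
    as missing rather than aborting the subject.
    """
    sel = roi.values & vol.valid()
    if not sel.any():
        return float("nan")
    return float(vol.values[sel].mean())


@dataclass
class SubjectFeatures:
    """Per-ROI parameter means at both timepoints, deltas and volumes.

    ``means[(roi, param, timepoint)]`` with roi in {core, penumbra,
    unaffected}, param in {rcbf, rcbv, rmtt, adc} and timepoint in
    {baseline, followup}; ``deltas[(roi, param)]`` = followup -
    baseline; ``volumes_ml[roi]`` from the baseline ROI voxel counts.
    ADC means are stored in 1e-6 mm^2/s to match clinical convention.
    """

    subject_id: str
    means: dict[tuple[str, str, str], float]
    deltas: dict[tuple[str, str], float]
    volumes_ml: dict[str, float]

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"subject_id": self.subject_id}
        for (roi, param, tp), v in self.means.items():
            row[f"{roi}_{param}_{tp}"] = v
        for (roi, param), v in self.deltas.items():
            row[f"{roi}_{param}_delta"] = v
        for roi, v in self.volumes_ml.items():
            row[f"{roi}_volume_ml"] = v
        return row


FEATURE_PARAMS = ("rcbf", "rcbv", "rmtt", "adc")


def extract_subject_features(
    subject_id: str,
    rois: TissueROIs,
    baseline_maps: RelativeMaps,
    followup_maps: RelativeMaps,
    adc_baseline: ScalarVolume,
    adc_followup: ScalarVolume,
) -> SubjectFeatures:
    """Longitudinal per-ROI means using the baseline ROIs at both timepoints.

    The follow-up maps must share the baseline grid (inter-timepoint
    registration is the identity for phantom data); ROIs are *never*
    re-segmented at follow-up.  ADC means are rescaled to 1e-6 mm^2/s.
    """
    for vol in (followup_maps.rcbf, adc_followup):
        if vol.shape != adc_baseline.shape:
            raise ValueError("follow-up maps must live on the baseline grid")
    means: dict[tuple[str, str, str], float] = {}
    deltas: dict[tuple[str, str], float] = {}
    volumes = {roi: mask.volume_ml() for roi, mask in rois.as_dict().items()}

    def param_vol(maps: RelativeMaps, adc: ScalarVolume, param: str) -> ScalarVolume:
        if param == "adc":
            return adc.like(adc.values * 1e6, units="1e-6 mm^2/s")
        return getattr(maps, param)

    for roi, mask in rois.as_dict().items():
        for param in FEATURE_PARAMS:
            b = roi_mean(param_vol(baseline_maps, adc_baseline, param), mask)
            f = roi_mean(param_vol(followup_maps, adc_followup, param), mask)
            means[(roi, param, "baseline")] = b
            means[(roi, param, "followup")] = f
            deltas[(roi, param)] = f - b
    return SubjectFeatures(subject_id=subject_id, means=means, deltas=deltas, volumes_ml=volumes)


def features_to_frame(features: list[SubjectFeatures]) -> pd.DataFrame:
    """Stack per-subject features into a tidy one-row-per-subject table."""
    return pd.DataFrame([f.to_row() for f in features])
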