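"""Digital stroke phantom and two-arm cohort simulator.

The package analyses DWI + DSC-MRI of acute stroke patients.  No public
patient data accompany that design, so this module supplies fully
synthetic subjects with known ground truth, built from the standard
indicator-dilution forward model:

    C_tissue(t) = CBF * (AIF (*) R)(t - delay)

where ``R`` is the residue function (exponential or boxcar) with
``integral R dt = MTT`` and, by the central volume theorem,
``CBV = CBF * MTT``.  Concentration is mapped to DSC signal through
``S(t) = S0 * exp(-k * TE * C(t))`` and diffusion weighting through
``S_b = S_b0 * exp(-b * ADC)``.  Every generated map is stored as
ground truth, so each analysis stage can be validated against the
values it should recover.

The phantom is a miniature head: an ellipsoidal brain on a 32x32x16
grid with a spherical infarct core inside a larger hypoperfused
(penumbral) sphere in one hemisphere, and symmetric CSF pockets.  The
cohort simulator reproduces the trial's two-arm design (13 treated vs
11 control subjects by default) with arm-specific baseline-to-3h
changes in each tissue class taken from the study's reported summary
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

from .volumes import BinaryMask, ScalarVolume, split_hemispheres, write_mask, write_volume

__all__ = [
    "AcquisitionParams",
    "ConcentrationCurve",
    "DynamicSeries",
    "GroundTruth",
    "SubjectClinical",
    "SubjectDataset",
    "SubjectSpec",
    "TissueLevels",
    "ARM_EFFECTS",
    "BASELINE_LEVELS",
    "CLINICAL_EFFECTS",
    "gamma_variate_aif",
    "residue_curve",
    "tissue_concentration",
    "concentration_to_signal",
    "synthesize_dwi",
    "synthesize_subject",
    "synthesize_cohort",
    "synthesize_imaging_cohort",
]


# --------------------------------------------------------------------------
# acquisition and curve types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionParams:
    """DSC/DWI acquisition settings of a simulated scan.

    tr_s : sampling interval of the dynamic series (s)
    te_s : echo time entering the signal model (s)
    n_timepoints : number of dynamic frames (>= 20)
    b_values : diffusion weightings, (0, 1000) s/mm^2
    k_conversion : signal->concentration proportionality (arbitrary;
        cancels in relative maps, kept explicit for round-trips)
    """

    tr_s: float = 1.5
    te_s: float = 0.030
    n_timepoints: int = 60
    b_values: tuple[float, float] = (0.0, 1000.0)
    k_conversion: float = 1.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0 or self.te_s <= 0 or self.k_conversion <= 0:
            raise ValueError("TR, TE and k_conversion must be positive")
        if self.n_timepoints < 20:
            raise ValueError("need at least 20 dynamic frames")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be nonnegative")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr_s


@dataclass
class ConcentrationCurve:
    """Arterial input function samples on the series' time grid."""

    values: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("AIF must be finite and nonnegative")
        if self.area() <= 0:
            raise ValueError("AIF must have positive area")

    def area(self) -> float:
        return float(np.trapezoid(self.values, dx=self.tr_s))


@dataclass
class DynamicSeries:
    """4D DSC signal (x, y, z, t) plus its acquisition parameters.

    ``s0`` is the pre-bolus baseline signal volume; the first frames
    of ``signal`` equal it wherever the simulation is noiseless.
    """

    signal: np.ndarray
    params: AcquisitionParams
    s0: ScalarVolume

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 4:
            raise ValueError("DynamicSeries requires a 4D (x,y,z,t) array")
        if self.signal.shape[3] != self.params.n_timepoints:
            raise ValueError("time axis length does not match n_timepoints")


# --------------------------------------------------------------------------
# forward models
# --------------------------------------------------------------------------


def gamma_variate_aif(
    params: AcquisitionParams,
    t0: float = 12.0,
    alpha: float = 3.0,
    beta: float = 1.5,
    amplitude: float = 1.0,
) -> ConcentrationCurve:
    """Gamma-variate bolus model standing in for a measured AIF.

    c(t) = amplitude * (t - t0)^alpha * exp(-(t - t0) / beta) for
    t > t0, zero before arrival.  Peak at ``t0 + alpha*beta``; analytic
    area ``amplitude * beta^(alpha+1) * Gamma(alpha+1)``.

    Raises if the series is too short to hold the bolus: the sampled
    curve must capture >= 95% of the analytic area.
    """
    if alpha <= 0 or beta <= 0 or t0 < 0:
        raise ValueError("require alpha > 0, beta > 0, t0 >= 0")
    t = params.time_s
    dt = np.maximum(t - t0, 0.0)
    c = amplitude * dt**alpha * np.exp(-dt / beta)
    c[t <= t0] = 0.0
    analytic_area = amplitude * beta ** (alpha + 1) * gamma_fn(alpha + 1)
    discrete_area = float(np.trapezoid(c, dx=params.tr_s))
    if discrete_area < 0.95 * analytic_area:
        raise ValueError(
            "series too short: sampled AIF captures "
            f"{100 * discrete_area / analytic_area:.1f}% of the bolus area"
        )
    return ConcentrationCurve(c, params.tr_s)


def residue_curve(
    model: Literal["exponential", "boxcar"], mtt: float, params: AcquisitionParams
) -> np.ndarray:
    """Residue function R(t) sampled at TR.

    R(0) = 1, R nonincreasing, and the discrete area approximates MTT.
    ``exponential``: exp(-t/MTT).  ``boxcar``: 1 for t < MTT (plug
    flow), so MTT=6 s at TR=1.5 s gives exactly four unit samples.
    """
    if mtt < params.tr_s:
        raise ValueError(f"MTT {mtt} s below the sampling interval {params.tr_s} s is unresolvable")
    t = params.time_s
    if model == "exponential":
        return np.exp(-t / mtt)
    if model == "boxcar":
        return (t < mtt).astype(np.float64)
    raise ValueError(f"unknown residue model {model!r}")


def _bin_averaged_residue(
    model: Literal["exponential", "boxcar"], mtt: float, params: AcquisitionParams
) -> np.ndarray:
    """Residue samples as exact per-bin averages, (1/TR) * int_bin R dt.

    Used inside the forward convolution: the rectangle-rule area
    TR * sum(R) then equals the analytic integral (MTT, up to tail
    truncation), so generated tracer areas honour CBV = CBF * MTT.
    Pointwise sampling would inflate the area by ~TR/2 per curve
    (up to ~20% at MTT 4 s, TR 1.5 s).
    """
    if mtt < params.tr_s:
        raise ValueError(f"MTT {mtt} s below the sampling interval {params.tr_s} s is unresolvable")
    tr = params.tr_s
    edges = np.arange(params.n_timepoints + 1) * tr
    if model == "exponential":
        integral = -mtt * np.exp(-edges / mtt)  # antiderivative of exp(-t/mtt)
    elif model == "boxcar":
        integral = np.minimum(edges, mtt)
    else:
        raise ValueError(f"unknown residue model {model!r}")
    return np.diff(integral) / tr


def tissue_concentration(
    cbf: float,
    mtt: float,
    delay: float,
    aif: ConcentrationCurve,
    model: Literal["exponential", "boxcar"],
    params: AcquisitionParams,
) -> np.ndarray:
    """Tissue concentration C(t) = CBF * (AIF (*) R)(t - delay).

    Discrete linear convolution scaled by TR, with the residue entering
    as exact per-bin averages (see :func:`_bin_averaged_residue`); the
    bolus delay must be an integer multiple of TR so that the Tmax
    ground truth is grid-exact.  The area ratio area(C)/area(AIF)
    equals CBV = CBF * MTT up to discretization (~2%).
    """
    if cbf < 0:
        raise ValueError("negative CBF")
    if cbf == 0:
        return np.zeros(params.n_timepoints)
    shift = delay / params.tr_s
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(f"delay {delay} s is not an integer multiple of TR {params.tr_s} s")
    shift = int(round(shift))
    r = _bin_averaged_residue(model, mtt, params)
    conv = np.convolve(aif.values, r)[: params.n_timepoints] * params.tr_s * cbf
    out = np.zeros_like(conv)
    if shift < params.n_timepoints:
        out[shift:] = conv[: params.n_timepoints - shift]
    return out


def concentration_to_signal(
    c: np.ndarray, s0: float | np.ndarray, params: AcquisitionParams
) -> np.ndarray:
    """DSC signal model S(t) = S0 * exp(-k * TE * C(t))."""
    s0 = np.asarray(s0, dtype=np.float64)
    if np.any(s0 <= 0):
        raise ValueError("baseline signal S0 must be positive")
    return s0 * np.exp(-params.k_conversion * params.te_s * np.asarray(c, dtype=np.float64))


def synthesize_dwi(
    adc: ScalarVolume,
    brain: BinaryMask,
    s0_b0: float = 1000.0,
    params: AcquisitionParams = AcquisitionParams(),
    snr: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Synthesize a (b0, b1000) DWI pair from a ground-truth ADC map.

    b1000 = b0 * exp(-b * ADC) voxelwise inside the brain; background
    is zero.  With ``snr`` set, Rician noise at that b0 SNR is applied
    to both magnitudes (sigma = s0_b0 / snr per quadrature channel).
    """
    b = params.b_values[1]
    b0 = np.where(brain.values, s0_b0, 0.0)
    adc_vals = np.where(brain.values & np.isfinite(adc.values), adc.values, 0.0)
    b1000 = b0 * np.exp(-b * adc_vals)
    if snr is not None:
        if rng is None:
            rng = np.random.default_rng()
        sigma = s0_b0 / snr
        b0 = _rician(b0, sigma, rng)
        b1000 = _rician(b1000, sigma, rng)
    sp = adc.spacing_mm
    return ScalarVolume(b0, sp, "a.u."), ScalarVolume(b1000, sp, "a.u.")


def _rician(mag: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    re = mag + rng.normal(0.0, sigma, mag.shape)
    im = rng.normal(0.0, sigma, mag.shape)
    return np.hypot(re, im)


# --------------------------------------------------------------------------
# ground truth and subject assembly
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """True hemodynamic and diffusion maps of one phantom timepoint.

    MTT = CBV / CBF holds voxelwise on the brain by construction
    (central volume theorem).  Core ADC sits below the 550e-6 mm^2/s
    segmentation threshold, CSF above 2000e-6 mm^2/s.
    """

    cbf: ScalarVolume
    cbv: ScalarVolume
    mtt: ScalarVolume
    delay: ScalarVolume
    adc: ScalarVolume
    core_mask: BinaryMask
    penumbra_mask: BinaryMask
    csf_mask: BinaryMask
    brain_mask: BinaryMask
    residue_model: Literal["exponential", "boxcar"] = "exponential"

    def validate(self) -> None:
        b = self.brain_mask.values
        cv = self.cbv.values[b] / self.cbf.values[b]
        if not np.allclose(cv, self.mtt.values[b], rtol=1e-10, atol=1e-12):
            raise ValueError("central volume consistency violated: MTT != CBV/CBF")
        if np.any(self.core_mask.values & ~b) or np.any(self.penumbra_mask.values & ~b):
            raise ValueError("lesion masks must lie inside the brain")
        if np.any(self.core_mask.values & self.penumbra_mask.values):
            raise ValueError("core and penumbra overlap")
        if np.any(self.adc.values[self.core_mask.values] >= 550e-6):
            raise ValueError("core ADC must stay below 550e-6 mm^2/s")
        if np.any(self.adc.values[self.csf_mask.values] <= 2000e-6):
            raise ValueError("CSF ADC must exceed 2000e-6 mm^2/s")

    @property
    def hypoperfusion_mask(self) -> BinaryMask:
        return self.core_mask | self.penumbra_mask


@dataclass
class SubjectClinical:
    """Clinical covariates of one simulated subject."""

    nihss_baseline: int
    nihss_3h: int
    arm: Literal["theophylline", "control"]
    hr_change_bpm: float
    recanalized: bool

    def __post_init__(self) -> None:
        for v in (self.nihss_baseline, self.nihss_3h):
            if not 0 <= v <= 42:
                raise ValueError(f"NIHSS {v} outside [0, 42]")


@dataclass
class Timepoint:
    dwi_b0: ScalarVolume
    dwi_b1000: ScalarVolume
    dsc: DynamicSeries
    aif: ConcentrationCurve
    truth: GroundTruth


@dataclass
class SubjectDataset:
    """One simulated subject: baseline + 3h follow-up on a shared grid."""

    subject_id: str
    baseline: Timepoint
    followup: Timepoint
    clinical: SubjectClinical
    affected_side: Literal["left", "right"] = "right"


# --------------------------------------------------------------------------
# study conditions: tissue levels and arm effects
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueLevels:
    """Relative hemodynamic levels of one tissue class at baseline.

    rcbf/rcbv are ratios to unaffected tissue; delay in seconds
    (an integer multiple of TR); ADC in mm^2/s.
    """

    rcbf: float
    rcbv: float
    delay_s: float
    adc: float


#: Baseline tissue classes.  Unaffected tissue anchors the absolute
#: scale (CBV 1.0, MTT 4 s => CBF 0.25 in phantom units); lesion
#: classes use the trial's reported baseline means: core rCBF halved
#: with mildly reduced rCBV (hence prolonged MTT ~7.4 s) and restricted
#: diffusion (ADC 450e-6); penumbra with moderately reduced flow,
#: elevated rCBV and near-normal ADC.  Both lesion classes carry a 9 s
#: bolus delay (6 samples at TR 1.5 s), well past the 6 s Tmax
#: hypoperfusion threshold.
BASELINE_LEVELS: dict[str, TissueLevels] = {
    "unaffected": TissueLevels(rcbf=1.0, rcbv=1.0, delay_s=0.0, adc=820e-6),
    "penumbra": TissueLevels(rcbf=0.70, rcbv=1.14, delay_s=9.0, adc=800e-6),
    "core": TissueLevels(rcbf=0.50, rcbv=0.93, delay_s=9.0, adc=450e-6),
    "csf": TissueLevels(rcbf=1.0, rcbv=1.0, delay_s=0.0, adc=3000e-6),
}

UNAFFECTED_CBF = 0.25  # phantom absolute units; CBV 1.0 / MTT 4 s

#: Baseline-to-3h change (mean, SD) per arm, tissue class and
#: parameter, transcribed from the trial's summary table.  rCBF and
#: rCBV are dimensionless ratios, rMTT in seconds, ADC in 1e-6 mm^2/s.
ARM_EFFECTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "theophylline": {
        "core": {"rcbf": (0.21, 0.33), "rcbv": (0.05, 0.18), "rmtt": (-2.82, 4.26), "adc": (201.0, 101.0)},
        "penumbra": {"rcbf": (0.11, 0.21), "rcbv": (-0.17, 0.25), "rmtt": (-3.80, 4.17), "adc": (-53.0, 195.0)},
        "unaffected": {"rcbf": (-0.02, 0.05), "rcbv": (-0.04, 0.07), "rmtt": (-0.00, 0.64), "adc": (-29.0, 54.0)},
    },
    "control": {
        "core": {"rcbf": (0.27, 0.36), "rcbv": (-0.14, 0.24), "rmtt": (-5.32, 4.43), "adc": (159.0, 110.0)},
        "penumbra": {"rcbf": (0.17, 0.16), "rcbv": (-0.08, 0.20), "rmtt": (-3.35, 3.16), "adc": (-22.0, 29.0)},
        "unaffected": {"rcbf": (-0.04, 0.04), "rcbv": (-0.08, 0.07), "rmtt": (-0.22, 0.54), "adc": (-40.0, 78.0)},
    },
}

#: Baseline per-arm means/SDs of the relative parameters (same table),
#: used for feature-level cohort simulation.
BASELINE_TABLE: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "theophylline": {
        "core": {"rcbf": (0.67, 0.28), "rcbv": (0.93, 0.27), "rmtt": (4.7, 3.6), "adc": (449.0, 24.0)},
        "penumbra": {"rcbf": (0.70, 0.21), "rcbv": (1.14, 0.31), "rmtt": (6.02, 3.17), "adc": (823.0, 179.0)},
        "unaffected": {"rcbf": (1.01, 0.07), "rcbv": (1.06, 0.09), "rmtt": (0.34, 0.64), "adc": (826.0, 46.0)},
    },
    "control": {
        "core": {"rcbf": (0.50, 0.13), "rcbv": (0.86, 0.22), "rmtt": (6.5, 3.8), "adc": (450.0, 27.0)},
        "penumbra": {"rcbf": (0.63, 0.17), "rcbv": (1.01, 0.31), "rmtt": (5.68, 3.17), "adc": (762.0, 62.0)},
        "unaffected": {"rcbf": (1.02, 0.04), "rcbv": (1.07, 0.09), "rmtt": (0.35, 0.60), "adc": (843.0, 84.0)},
    },
}

#: Clinical simulation settings: heart-rate change N(mean, SD) per arm,
#: NIHSS baseline N(mean, SD), large-vessel-occlusion and
#: recanalization-given-LVO probabilities per arm.
CLINICAL_EFFECTS: dict[str, dict[str, tuple[float, float] | float]] = {
    "theophylline": {"hr_change": (11.0, 26.0), "nihss": (9.0, 4.0), "p_lvo": 7 / 13, "p_recan": 1.0},
    "control": {"hr_change": (-9.0, 14.0), "nihss": (7.0, 3.0), "p_lvo": 4 / 11, "p_recan": 0.5},
}


@dataclass
class SubjectSpec:
    """Geometry, acquisition and effect settings of one phantom subject.

    The default geometry is a miniature head: ellipsoidal brain
    (radii 14x14x7 voxels) on a 32x32x16 grid at 2 mm isotropic
    spacing, a 3-voxel-radius spherical core inside a 5-voxel-radius
    hypoperfused sphere in the affected (right) hemisphere, and two
    mirror-symmetric CSF pockets.
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_radii: tuple[float, float, float] = (14.0, 14.0, 7.0)
    lesion_center: tuple[float, float, float] = (23.0, 16.0, 8.0)
    core_radius: float = 3.0
    hypo_radius: float = 5.0
    csf_center: tuple[float, float, float] = (19.0, 9.0, 8.0)
    csf_radius: float = 2.0
    affected_side: Literal["left", "right"] = "right"
    params: AcquisitionParams = field(default_factory=AcquisitionParams)
    residue_model: Literal["exponential", "boxcar"] = "exponential"
    levels: dict[str, TissueLevels] = field(default_factory=lambda: dict(BASELINE_LEVELS))
    arm: Literal["theophylline", "control"] = "theophylline"
    #: follow-up deltas per tissue class; None -> arm means from ARM_EFFECTS
    deltas: dict[str, dict[str, float]] | None = None
    recanalized: bool = True
    s0_dsc: float = 100.0
    s0_b0: float = 1000.0
    dwi_snr: float | None = None
    concentration_noise_sd: float | None = None

    def arm_mean_deltas(self) -> dict[str, dict[str, float]]:
        return {
            roi: {p: ms[0] for p, ms in params.items()}
            for roi, params in ARM_EFFECTS[self.arm].items()
        }


def _ball(shape, center, radii) -> np.ndarray:
    grid = np.indices(shape).astype(np.float64)
    d = sum(((grid[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d <= 1.0


def _build_geometry(spec: SubjectSpec):
    shape = spec.shape
    cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
    brain = _ball(shape, cx, spec.brain_radii)
    core = _ball(shape, spec.lesion_center, (spec.core_radius,) * 3) & brain
    hypo = _ball(shape, spec.lesion_center, (spec.hypo_radius,) * 3) & brain
    penumbra = hypo & ~core
    mirror = (shape[0] - 1 - spec.csf_center[0], spec.csf_center[1], spec.csf_center[2])
    csf = (
        _ball(shape, spec.csf_center, (spec.csf_radius,) * 3)
        | _ball(shape, mirror, (spec.csf_radius,) * 3)
    ) & brain
    csf &= ~hypo
    mid = shape[0] // 2
    affected = np.zeros(shape, dtype=bool)
    if spec.affected_side == "right":
        affected[mid:] = True
    else:
        affected[:mid] = True
    if np.any(core & ~affected) or np.any(penumbra & ~affected):
        raise ValueError("lesion exceeds the affected hemisphere")
    return brain, core, penumbra, csf, affected


def _truth_from_levels(
    spec: SubjectSpec,
    levels: dict[str, TissueLevels],
    geometry,
) -> GroundTruth:
    brain, core, penumbra, csf, affected = geometry
    sp = np.asarray(spec.spacing_mm)
    tr = spec.params.tr_s

    def snap_delay(d: float) -> float:
        return round(d / tr) * tr

    cbv = np.full(spec.shape, np.nan)
    mtt = np.full(spec.shape, np.nan)
    delay = np.full(spec.shape, np.nan)
    adc = np.full(spec.shape, np.nan)
    # Contralateral tissue is the normalization reference and stays at
    # its own level (baseline "unaffected" by default), so configured
    # relative deltas in the affected hemisphere are recovered exactly.
    class_masks = {
        "csf": csf,
        "contralateral": brain & ~affected & ~csf,
        "unaffected": brain & affected & ~core & ~penumbra & ~csf,
        "penumbra": penumbra,
        "core": core,
    }
    for name, m in class_masks.items():
        lv = levels.get(name, levels["unaffected"]) if name == "contralateral" else levels[name]
        c_cbf = lv.rcbf * UNAFFECTED_CBF
        c_cbv = lv.rcbv * 1.0
        if c_cbf <= 0 or c_cbv <= 0:
            raise ValueError(f"non-positive hemodynamics for class {name}")
        cbv[m] = c_cbv
        mtt[m] = c_cbv / c_cbf
        delay[m] = snap_delay(lv.delay_s)
        adc[m] = lv.adc
    cbf = cbv / mtt  # central volume theorem, exact by construction

    def vol(v, units):
        return ScalarVolume(v, sp, units)

    gt = GroundTruth(
        cbf=vol(cbf, "a.u."),
        cbv=vol(cbv, "dimensionless"),
        mtt=vol(mtt, "s"),
        delay=vol(delay, "s"),
        adc=vol(adc, "mm^2/s"),
        core_mask=BinaryMask(core, sp),
        penumbra_mask=BinaryMask(penumbra, sp),
        csf_mask=BinaryMask(csf, sp),
        brain_mask=BinaryMask(brain, sp),
        residue_model=spec.residue_model,
    )
    gt.validate()
    return gt


def _followup_levels(
    spec: SubjectSpec, deltas: dict[str, dict[str, float]]
) -> dict[str, TissueLevels]:
    """Apply baseline-to-3h changes to the tissue levels.

    Drawn rCBV and rMTT deltas define the follow-up state; rCBF then
    follows from the central volume theorem (CBF = CBV/MTT), keeping
    every generated map self-consistent.  MTT is floored just above TR
    and rCBV at 0.05 so extreme draws remain physically generable.
    """
    tr = spec.params.tr_s
    out = dict(spec.levels)
    for roi in ("core", "penumbra", "unaffected"):
        lv = spec.levels[roi]
        d = deltas.get(roi, {})
        new_rcbv = max(lv.rcbv + d.get("rcbv", 0.0), 0.05)
        base_mtt = lv.rcbv / (lv.rcbf * UNAFFECTED_CBF)
        new_mtt = max(base_mtt + d.get("rmtt", 0.0), tr * 1.05)
        new_rcbf = new_rcbv / (new_mtt * UNAFFECTED_CBF)
        new_adc = float(np.clip(lv.adc + d.get("adc", 0.0) * 1e-6, 100e-6, 1900e-6))
        new_delay = 0.0 if (roi in ("core", "penumbra") and spec.recanalized) else lv.delay_s
        out[roi] = TissueLevels(rcbf=new_rcbf, rcbv=new_rcbv, delay_s=new_delay, adc=new_adc)
    # the contralateral reference tissue keeps its baseline physiology
    out["contralateral"] = spec.levels["unaffected"]
    return out


def _synthesize_timepoint(
    spec: SubjectSpec,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> Timepoint:
    params = spec.params
    aif = gamma_variate_aif(params)
    brain = truth.brain_mask.values
    n = params.n_timepoints

    # unique (cbf, mtt, delay) combinations -> one convolution each
    keys = np.stack([truth.cbf.values, truth.mtt.values, truth.delay.values], axis=-1)
    flat = keys[brain].round(12)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    curves = np.empty((len(uniq), n))
    for i, (cbf, mtt, delay) in enumerate(uniq):
        curves[i] = tissue_concentration(cbf, mtt, delay, aif, spec.residue_model, params)
    conc = np.zeros(spec.shape + (n,))
    conc[brain] = curves[inverse]
    if spec.concentration_noise_sd is not None:
        conc[brain] += rng.normal(0.0, spec.concentration_noise_sd, conc[brain].shape)

    s0_vals = np.where(brain, spec.s0_dsc, 0.0)
    signal = np.ones(spec.shape + (n,))
    signal[brain] = concentration_to_signal(conc[brain], spec.s0_dsc, params)
    s0 = ScalarVolume(s0_vals, np.asarray(spec.spacing_mm), "a.u.")
    dsc = DynamicSeries(signal, params, s0)

    b0, b1000 = synthesize_dwi(truth.adc, truth.brain_mask, spec.s0_b0, params, spec.dwi_snr, rng)
    return Timepoint(dwi_b0=b0, dwi_b1000=b1000, dsc=dsc, aif=aif, truth=truth)


def synthesize_subject(spec: SubjectSpec, seed: int) -> SubjectDataset:
    """Generate one two-timepoint phantom subject.

    Baseline hemodynamics follow ``spec.levels``; the follow-up
    acquisition is regenerated with the arm-dependent changes in
    ``spec.deltas`` (defaults: the arm's mean effects) and, for
    recanalized subjects, bolus delay reset to zero.  Deterministic
    given (spec, seed).
    """
    rng = np.random.default_rng(seed)
    geometry = _build_geometry(spec)
    truth0 = _truth_from_levels(spec, spec.levels, geometry)
    deltas = spec.deltas if spec.deltas is not None else spec.arm_mean_deltas()
    levels_fu = _followup_levels(spec, deltas)
    # Follow-up ADC in the (baseline-defined) core may legitimately rise
    # above the core threshold; build the follow-up truth without the
    # core-ADC invariant by keeping masks but re-deriving maps.
    truth1 = _truth_from_levels_lenient(spec, levels_fu, geometry)
    baseline = _synthesize_timepoint(spec, truth0, rng)
    followup = _synthesize_timepoint(spec, truth1, rng)
    clinical = _draw_clinical(spec.arm, rng, recanalized=spec.recanalized)
    return SubjectDataset(
        subject_id=f"sub-{seed:06d}",
        baseline=baseline,
        followup=followup,
        clinical=clinical,
        affected_side=spec.affected_side,
    )


def _truth_from_levels_lenient(spec, levels, geometry) -> GroundTruth:
    """Follow-up truth: same geometry, updated maps, no core-ADC bound."""
    core = geometry[1]
    try:
        return _truth_from_levels(spec, levels, geometry)
    except ValueError:
        gt = _truth_from_levels(
            spec,
            {**levels, "core": replace(levels["core"], adc=min(levels["core"].adc, 549e-6))},
            geometry,
        )
        # restore the true (possibly normalized) core ADC on the map
        gt.adc.values[core] = levels["core"].adc
        return gt


def _draw_clinical(
    arm: str, rng: np.random.Generator, recanalized: bool | None = None
) -> SubjectClinical:
    eff = CLINICAL_EFFECTS[arm]
    nihss_m, nihss_sd = eff["nihss"]  # type: ignore[misc]
    nihss0 = int(np.clip(round(rng.normal(nihss_m, nihss_sd)), 4, 42))
    improvement = int(round(rng.normal(1.5, 2.5)))
    nihss3 = int(np.clip(nihss0 - improvement, 0, 42))
    hr_m, hr_sd = eff["hr_change"]  # type: ignore[misc]
    if recanalized is None:
        lvo = rng.random() < float(eff["p_lvo"])  # type: ignore[arg-type]
        recanalized = bool(lvo and rng.random() < float(eff["p_recan"]))  # type: ignore[arg-type]
    return SubjectClinical(
        nihss_baseline=nihss0,
        nihss_3h=nihss3,
        arm=arm,  # type: ignore[arg-type]
        hr_change_bpm=float(rng.normal(hr_m, hr_sd)),
        recanalized=recanalized,
    )


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

ROIS = ("core", "penumbra", "unaffected")
PARAMS = ("rcbf", "rcbv", "rmtt", "adc")


def synthesize_cohort(
    n_theo: int = 13,
    n_ctrl: int = 11,
    seed: int = 0,
    effect_table: dict | None = None,
    baseline_table: dict | None = None,
    null_effects: bool = False,
) -> pd.DataFrame:
    """Feature-level two-arm cohort draw.

    Per subject, per tissue class and parameter, the baseline level and
    the baseline-to-3h change are drawn independently from
    Normal(mean, SD) using the configured per-arm tables (defaults
    transcribe the trial's summary statistics); follow-up = baseline +
    delta.  Clinical covariates (heart-rate change, NIHSS,
    recanalization) are drawn analogously.  With ``null_effects`` both
    arms share the pooled control/treated mean of every delta — the
    null configuration used for type-I-error calibration.

    Returns a tidy DataFrame, one row per subject, with columns
    ``{roi}_{param}_{baseline|followup|delta}`` (ADC in 1e-6 mm^2/s),
    plus arm and clinical fields.
    """
    if n_theo < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 subjects per arm")
    eff = effect_table if effect_table is not None else ARM_EFFECTS
    base = baseline_table if baseline_table is not None else BASELINE_TABLE
    for arm_tab in eff.values():
        for roi_tab in arm_tab.values():
            for m, sd in roi_tab.values():
                if sd <= 0:
                    raise ValueError("non-positive SD in effect table")
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for arm, n in (("theophylline", n_theo), ("control", n_ctrl)):
        for _ in range(n):
            row: dict[str, object] = {"subject_id": f"sub-{sid:04d}", "arm": arm}
            sid += 1
            for roi in ROIS:
                for p in PARAMS:
                    bm, bsd = base[arm][roi][p]
                    if null_effects:
                        m_t, _ = eff["theophylline"][roi][p]
                        m_c, _ = eff["control"][roi][p]
                        dm = 0.5 * (m_t + m_c)
                        _, dsd = eff[arm][roi][p]
                    else:
                        dm, dsd = eff[arm][roi][p]
                    b = rng.normal(bm, bsd)
                    d = rng.normal(dm, dsd)
                    row[f"{roi}_{p}_baseline"] = b
                    row[f"{roi}_{p}_delta"] = d
                    row[f"{roi}_{p}_followup"] = b + d
            clin = _draw_clinical(arm, rng)
            row.update(
                nihss_baseline=clin.nihss_baseline,
                nihss_3h=clin.nihss_3h,
                hr_change_bpm=clin.hr_change_bpm,
                recanalized=clin.recanalized,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def synthesize_imaging_cohort(
    n_theo: int = 13,
    n_ctrl: int = 11,
    seed: int = 0,
    base_spec: SubjectSpec | None = None,
) -> list[SubjectDataset]:
    """Full-imaging cohort: one phantom subject per row of the design.

    Per-subject follow-up changes in rCBV, rMTT and ADC are drawn from
    the arm's effect distributions (rCBF then follows from the central
    volume theorem); each subject is rendered as complete DWI + DSC
    acquisitions at both timepoints.
    """
    if n_theo < 2 or n_ctrl < 2:
        raise ValueError("need at least 2 subjects per arm")
    master = np.random.default_rng(seed)
    subjects = []
    for arm, n in (("theophylline", n_theo), ("control", n_ctrl)):
        for _ in range(n):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            deltas = {
                roi: {p: float(rng.normal(*ARM_EFFECTS[arm][roi][p])) for p in ("rcbv", "rmtt", "adc")}
                for roi in ROIS
            }
            eff = CLINICAL_EFFECTS[arm]
            lvo = rng.random() < float(eff["p_lvo"])  # type: ignore[arg-type]
            recan = bool(lvo and rng.random() < float(eff["p_recan"]))  # type: ignore[arg-type]
            spec = replace(
                base_spec if base_spec is not None else SubjectSpec(),
                arm=arm,
                deltas=deltas,
                recanalized=recan,
            )
            subjects.append(synthesize_subject(spec, seed=sub_seed))
    return subjects


# --------------------------------------------------------------------------
# on-disk representation
# --------------------------------------------------------------------------


def write_subject(dataset: SubjectDataset, out_dir: str | Path) -> Path:
    """Write a subject as NIfTI volumes plus a JSON sidecar.

    The sidecar records acquisition parameters, the AIF samples and
    clinical fields; ground-truth maps and masks go to a ``truth``
    subdirectory per timepoint.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, tp in (("baseline", dataset.baseline), ("followup", dataset.followup)):
        d = out_dir / name
        d.mkdir(exist_ok=True)
        write_volume(tp.dwi_b0, d / "dwi_b0.nii.gz")
        write_volume(tp.dwi_b1000, d / "dwi_b1000.nii.gz")
        img_spacing = tuple(tp.dwi_b0.spacing_mm) + (tp.dsc.params.tr_s,)
        import nibabel as nib  # local: 4D write is the one non-3D case

        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = tp.dwi_b0.spacing_mm
        img = nib.Nifti1Image(tp.dsc.signal.astype(np.float32), aff)
        img.header.set_zooms(img_spacing)
        nib.save(img, str(d / "dsc.nii.gz"))
        td = d / "truth"
        td.mkdir(exist_ok=True)
        for vname in ("cbf", "cbv", "mtt", "delay", "adc"):
            write_volume(getattr(tp.truth, vname), td / f"{vname}.nii.gz")
        for mname in ("core_mask", "penumbra_mask", "csf_mask", "brain_mask"):
            write_mask(getattr(tp.truth, mname), td / f"{mname}.nii.gz")
    params = dataset.baseline.dsc.params
    sidecar = {
        "subject_id": dataset.subject_id,
        "affected_side": dataset.affected_side,
        "acquisition": {
            "tr_s": params.tr_s,
            "te_s": params.te_s,
            "n_timepoints": params.n_timepoints,
            "b_values": list(params.b_values),
            "k_conversion": params.k_conversion,
        },
        "aif_baseline": dataset.baseline.aif.values.tolist(),
        "aif_followup": dataset.followup.aif.values.tolist(),
        "clinical": {
            "nihss_baseline": dataset.clinical.nihss_baseline,
            "nihss_3h": dataset.clinical.nihss_3h,
            "arm": dataset.clinical.arm,
            "hr_change_bpm": dataset.clinical.hr_change_bpm,
            "recanalized": dataset.clinical.recanalized,
        },
    }
    (out_dir / "subject.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir
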