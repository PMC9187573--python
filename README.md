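# perfmismatch

Perfusion–diffusion mismatch analysis for acute stroke MRI, built for
studies that track how a treatment changes cerebral perfusion between a
baseline scan and an early follow-up. The package implements the full
multiparametric analysis chain used in two-arm stroke perfusion trials —
from raw DWI/DSC volumes to a group comparison table — together with a
digital phantom generator that supplies ground-truth inputs, so every
stage is verifiable without patient data.

## What it computes

**Diffusion.** From a b0/b1000 DWI pair, the apparent diffusion
coefficient ADC = ln(S_b0 / S_b1000)/b. The infarct core is segmented by
volume growing at a conservative upper threshold of 550 × 10⁻⁶ mm²/s
(chosen so no penumbral tissue enters the core); CSF is excluded above
2000 × 10⁻⁶ mm²/s.

**Perfusion.** DSC signal is converted to contrast concentration,
C(t) = −ln(S/S₀)/(k·TE), and the indicator-dilution model
C = CBF · (AIF ⊛ R) is inverted per voxel by block-circulant
deconvolution: the convolution matrix of the zero-padded AIF is
diagonalized by SVD and singular values below 0.15 of the largest are
truncated, giving a delay-insensitive estimate of the flow-scaled
residue function k(t) = CBF·R(t). Summary maps: CBF = max k, Tmax =
argmax k, CBV = area(C)/area(AIF), MTT = CBV/CBF (central volume
theorem).

**Mismatch.** Relative maps normalize to the contralateral hemisphere
(CSF excluded): division for rCBF/rCBV, subtraction for rMTT/rTmax.
Hypoperfused tissue is grown on the rTmax map at ≥ 6 s; the penumbra is
the perfusion–diffusion mismatch (hypoperfusion minus core); unaffected
tissue is the remaining affected-hemisphere brain. Per-ROI means are
extracted at both timepoints using the *baseline* ROIs.

**Statistics.** Between-arm comparison of parameter levels (Wilcoxon
rank-sum, exact for small tie-free samples) and baseline-to-follow-up
changes (pooled equal-variance t-test), Fisher's exact test for
categorical outcomes, and a ≥ 4-point NIHSS drop as the early clinical
response rule — two-sided α = 0.05, deliberately uncorrected
(exploratory design). The pooled t-test can also be recomputed straight
from printed summary statistics (mean, SD, n).

**Phantom.** A miniature digital head (ellipsoidal brain, spherical
core inside a hypoperfused sphere, mirror-symmetric CSF) with
ground-truth CBF/CBV/MTT/delay/ADC maps, forward-modeled DWI and DSC
acquisitions, and a two-arm cohort simulator whose arm-specific
baseline-to-3 h effects transcribe a published theophylline add-on
trial (13 treated vs 11 control subjects).

## Worked example

```bash
python examples/02_perfusion_deconvolution.py
```

```
true : CBF 0.250  CBV 1.500  MTT 6.00 s  Tmax 4.5 s
est. : CBF 0.177  CBV 1.500  MTT 8.49 s  Tmax 6.0 s
CBV error 0.00% | Tmax error 1 samples | CBF bias -29% (SVD truncation)
```

A tissue curve generated with known flow parameters is inverted by the
truncated-SVD deconvolution: the area-based CBV is recovered almost
exactly and Tmax to within one sample, while absolute CBF carries the
well-known truncation underestimation — which cancels in the
contralateral-normalized relative maps the analysis actually reports.

```bash
python examples/04_cohort_statistics.py
```

```
recomputed from printed summaries:
  core delta-rCBV 0.05(0.18) vs -0.14(0.24): t = 2.21, p = 0.037
  recanalization 7/7 vs 2/4: Fisher two-sided p = 0.11
```

The headline inference of the source trial — infarct-core rCBV rising
by 0.05 under treatment while falling by 0.14 under placebo — is
significant at p ≈ 0.037 when recomputed from the printed group
summaries, and the recanalization contrast reproduces the reported
p = 0.11.

The other examples generate a phantom subject
(`01_phantom_subject.py`) and run the full single-subject mismatch
chain (`03_mismatch_rois.py`). A thin CLI mirrors the stages:
`perfmismatch simulate | adc | core | run-subject | run-cohort`.

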