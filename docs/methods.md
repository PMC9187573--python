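# Methods

This note documents the models, numerical choices and limitations of
`perfmismatch`: what each stage assumes, which parameters matter, what
the phantom does and does not emulate, and where the design was
genuinely open.

## Forward model of the phantom

Tissue concentration follows the indicator-dilution convolution

    C(t) = CBF · (AIF ⊛ R)(t − δ),

with R the residue function (exponential `exp(−t/MTT)` by default, or
boxcar plug flow), δ the bolus delay, and CBV = CBF·MTT by the central
volume theorem — enforced voxelwise at generation, so MTT = CBV/CBF is
exact in every ground-truth object. The arterial input is a
gamma-variate bolus c(t) = A·(t−t₀)^α·e^{−(t−t₀)/β} (defaults t₀ = 12 s,
α = 3, β = 1.5 s), rejected if the sampled series captures less than
95 % of its analytic area. Signal models are the standard
exponentials: S = S₀·e^{−k·TE·C} for DSC and S_b = S_b0·e^{−b·ADC} for
diffusion; both are exactly invertible, so noiseless round-trips are
machine-precision tests.

Two discretization rules matter:

- **Bolus delays are integer multiples of TR**, making Tmax ground
  truth grid-exact and recovery assertable to ±1 sample.
- **The residue enters the forward convolution as exact per-bin
  averages** ((1/TR)∫ R over each TR bin) rather than pointwise
  samples. Rectangle-rule convolution of pointwise samples inflates
  the discrete tracer area by ≈ TR/2 per curve — a 20 % CBV error at
  MTT 4 s, TR 1.5 s — whereas bin averaging preserves
  area(C)/area(AIF) = CBV to well under 1 % and renders the
  single-bin boxcar an exact impulse. The public `residue_curve`
  remains the pointwise R with R(0) = 1.

### Geometry and tissue classes

The default subject is a miniature head on a 32×32×16 grid at 2 mm
isotropic spacing: an ellipsoidal brain (radii 14×14×7 voxels), a
3-voxel-radius spherical core inside a 5-voxel-radius hypoperfused
sphere in the right hemisphere, and two mirror-symmetric CSF pockets.
Problem sizes throughout (grid, 60-frame series, cohort and sweep
counts) are chosen so the full suite and the acceptance run complete in
minutes on one CPU while keeping every estimate's sampling error well
inside its tolerance.

Baseline tissue levels anchor unaffected tissue at CBV 1.0, MTT 4 s
(CBF 0.25 in phantom units) and use the trial's reported baseline
means for the lesion: core at half the unaffected rCBF with rCBV 0.93
(hence MTT ≈ 7.4 s) and ADC 450×10⁻⁶ mm²/s; penumbra at rCBF 0.70,
rCBV 1.14, near-normal ADC 800×10⁻⁶; CSF at ADC 3000×10⁻⁶. Both lesion
classes carry a 9 s delay (6 samples), comfortably past the 6 s Tmax
threshold. Noise — Gaussian on concentration curves, Rician on DWI
magnitudes — is optional and off by default, as the target workflow is
ground-truth verification.

### Follow-up and arm effects

Follow-up volumes are regenerated with arm-specific changes whose
defaults transcribe the trial's baseline-to-3 h summary table (e.g.
core ΔrCBV +0.05 treated, −0.14 control; heart-rate change N(+11, 26)
vs N(−9, 14) bpm). For imaging subjects, drawn ΔrCBV and ΔrMTT define
the follow-up state and rCBF follows from CBV/MTT, keeping the central
volume identity intact (the feature-level cohort simulator draws all
four parameters independently, exactly as tabulated). MTT is floored
just above TR and rCBV at 0.05 so extreme draws remain generable; in
recanalized subjects the lesion delay resets to zero, mirroring the
Tmax normalization the trial observed at 3 h.

Two deliberate idealizations: contralateral tissue keeps its baseline
physiology between timepoints, so configured relative deltas are
recovered exactly (relative parameters are defined against that
reference); and follow-up shares the baseline grid, so inter-timepoint
registration is the identity (a rigid-registration hook is the natural
extension point for real data). The phantom makes no attempt at
realistic anatomy, partial-volume effects, arterial dispersion, or
motion — passing tests demonstrate correctness of the estimators under
the stated model, not robustness to those real-data effects.

## Diffusion analysis

ADC = ln(b0/b1000)/b with b = 1000 s/mm²; voxels where noise pushes
b1000 ≥ b0 clamp to 0, background is NaN ("invalid"), and invalid
voxels are excluded from every downstream mean. Core segmentation
grows connected components of 0 < ADC ≤ 550×10⁻⁶ mm²/s. The
interactive seeding of the original semi-automatic workflow is
replaced by automatic all-qualifying-voxel seeding with a minimum
component size of 5 voxels (explicit seeds remain available);
connectivity defaults to the 26-neighborhood. The CSF bound
(2000×10⁻⁶) and brain-mask physiologic range (1–3500×10⁻⁶) exploit the
wide gap between parenchymal (~800×10⁻⁶) and free-water (~3000×10⁻⁶)
diffusion.

The ADC-range brain mask is noiseless-path plumbing, standing in for a
dedicated brain segmentation: under Rician noise, background voxels
fall inside the physiologic ADC window, so noisy-sweep validations use
the phantom's reference brain mask as the segmentation input — which
is also how a clinical pipeline is structured (brain extraction is a
separate tool).

## Perfusion analysis

S₀ is the mean of the first 8 pre-bolus frames (the default AIF
arrives at 12 s = frame 8). The deconvolution builds the circulant
matrix A[i,j] = TR·a[(i−j) mod L] from the AIF zero-padded to
L = 2N, takes its SVD, zeroes singular values below 0.15·σ_max, and
applies the truncated pseudo-inverse to every voxel's padded curve —
computed once per AIF, so a volume costs one L×L SVD plus a matrix
multiply. The circulant embedding makes the estimate delay-insensitive:
a shifted curve returns the same amplitudes with the residue peak
moved, which is what makes Tmax = TR·argmax k a clean delay surrogate.

Numerical behavior, quantified on noiseless phantom curves (MTT
4–12 s): CBV (pure area ratio, independent of the inversion) is exact
to < 1 %; Tmax lands within one sample (a consistent +1 shift from the
bin-averaged residue asymmetry, which cancels in rTmax); reconvolution
residuals stay under 4 % and shrink monotonically as the threshold is
lowered; absolute CBF is underestimated 16–40 %, worst at short MTT —
the classic truncated-SVD bias. Rank order of CBF across voxels is
preserved (Spearman ρ ≈ 0.97), and the bias cancels to first order in
the contralateral ratio maps that the study design actually reports.
MTT uses the central volume theorem (CBV/CBF) rather than the first
moment of k(t), which is fragile under truncation oscillations; both
rules are config switches. Negative k samples are retained for the
argmax, but CBF floors at 0. Proportionality constants (hematocrit,
density, k·TE) are set to 1 since they cancel in relative maps. No
smoothing is applied to the residue before the Tmax argmax.

## Mismatch construction

Relative maps divide (rCBF, rCBV) or subtract (rMTT, rTmax) the mean
over contralateral brain minus CSF — so by construction the
contralateral non-CSF mean of rCBF is exactly 1 and of rMTT exactly 0.
The 6 s hypoperfusion threshold is applied to the *relative* Tmax map,
inclusive at exactly 6.0 s; with contralateral Tmax near bolus arrival
this coincides with the conventional absolute Tmax > 6 s rule, and
both the absolute/relative switch and the inclusivity are config
options. Penumbra = hypoperfusion ∖ core; unaffected =
affected-hemisphere brain ∖ (core ∪ penumbra ∪ CSF). The hemispheres
are split at the grid midpoint of the left–right axis — phantoms are
generated head-centered, so no midline estimation is needed. Feature
extraction applies the baseline ROIs at both timepoints (lesion ROIs
are never re-segmented at follow-up); an empty ROI yields a missing
value, not a failed subject. ADC features are reported in 10⁻⁶ mm²/s
to match clinical convention.

## Statistics

Levels at each timepoint use the two-sample Wilcoxon rank-sum test
(exact enumeration when n₁+n₂ ≤ 16 without ties; otherwise the normal
approximation with tie and continuity corrections; fully tied data
return p = 1), while baseline-to-follow-up changes use the pooled
equal-variance t-test — the split follows the source table's footnote
markers, since the trial text leaves the assignment ambiguous, and is
an explicit config. Fisher's two-sided p sums hypergeometric
probabilities ≤ that of the observed table (the convention that
reproduces the trial's printed 0.11). No multiplicity correction is
applied by default, mirroring the exploratory design; Holm is
available but off. The clinical response rule is a ≥ 4-point NIHSS
improvement, boundary inclusive.

Calibration note: the pooled t-test is exact under the equal-variance
null (type-I error ≈ 0.05); under variance heterogeneity with unequal
group sizes it is mildly anticonservative, which is a property of the
published analysis choice, not of this implementation. Analytic power
at the trial's core ΔrCBV effect (noncentral-t with pooled SD) is
≈ 0.56 at n = 13 vs 11, matched by simulation.

## Pipeline

Per-subject failures are captured as machine-readable errors and never
abort a cohort (incomplete imaging is the norm in acute stroke — the
source trial analyzed 24 of 64 enrolled patients). All thresholds
(550×10⁻⁶ mm²/s, 0.15, 6 s, α = 0.05, NIHSS ≥ 4) live in one
`RunConfig`; outputs embed its SHA-256 hash, which changes iff a
setting changes. A cohort run can restart from a cached features table,
skipping the imaging stages.

## Known limitations

- Absolute CBF/MTT are biased by SVD truncation (by design of the
  fixed 0.15 threshold); only relative maps should be interpreted.
- The mid-sagittal split and identity registration presume centered,
  aligned volumes; real data need prior reorientation/registration.
- The ADC-range brain mask is not a skull stripper.
- The phantom's piecewise-constant tissue classes make segmentation
  recovery sharper than on real, heterogeneous lesions; the SNR-20
  Dice sweep (mean ≈ 0.9) is the more realistic indicator.
- AIF selection, leakage/dispersion correction and motion correction
  are out of scope; the AIF is an input.
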