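# Methods

This note documents the models, parameter choices and known limitations of
the package. It covers the synthetic phantom, the CVR estimator, the
asymmetry/classification rules and the statistical layer; nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design emulated by the phantom

Three groups are generated: chronic stroke (default n = 17), acute/subacute
stroke (n = 13) and healthy controls (n = 17). Chronic subjects may carry
Wallerian degeneration (WD, ipsilateral cerebral-peduncle atrophy; default
8/17), ipsilateral thalamic diaschisis (ITD; 9/17, with 7 among the WD⁺ and
2 among the WD⁻) and crossed cerebellar diaschisis (CCD; 7/17). Acute and
healthy subjects never carry WD — the acute group exists precisely to show
that the masking/volumetry chain does not produce spurious threshold
crossings early after stroke.

**Count-based assignment.** Membership counts are `round(p · n)` with
seed-shuffled placement, not independent Bernoulli draws. A fixture whose
composition wobbles with the seed cannot serve as a regression target for
the classification chain; the seed still permutes which subject gets which
values, the imaging noise, lesion sizes and demographics.

**Moment-matched reference sets.** Indices whose healthy-cohort mean/SD are
the quantities of interest (peduncular volume AI 1.0 ± 5.0 %, thalamic CVR
AI 4.1 ± 8.0 %, cerebellar CVR AI 1.0 ± 5.5 %) are generated as normal
quantile sets rescaled to those exact sample moments. The derived 2SD
thresholds (11 %, 20.1 %, 12.0 % before measurement noise) are then
reproducible to rasterization/regression precision for any seed. A
consequence worth knowing: quantile sets bound the extremes at roughly
±2 SD, so the healthy cohort never produces an outlier beyond ~2.2 SD —
real cohorts occasionally would.

**Separation margins.** Group-specific index distributions are truncated so
every subject clears (or stays clear of) the runtime-derived cutoff by a
margin of at least ~3 measurement-noise SDs: WD⁺ peduncular AI in
[−36, −13.5] %, WD⁻ in [−9.5, +5.5] %; ITD⁺ thalamic CVR AI in [31, 58] %,
ITD⁻ in [−9, 10] %; CCD⁺ cerebellar CVR AI in [16, 33] %, CCD⁻ in [−8, 8] %.
This makes classification deterministic by construction. The cost is that
subgroup means sit somewhat wide of a purely observational cohort (e.g. the
ITD⁺ thalamic CVR AI mean is ≈ 38 % rather than ≈ 33 %); the phantom's
contract is the composition and the thresholds, not the subgroup means.

**Atrophy coupling.** The thalamic volume AI is a linear Gaussian function
of the (standardized) peduncular volume AI,
`thal = −19.2 + 16.6·(ρ·z_ped + √(1−ρ²)·ε)`, with ε orthogonalized against
`z_ped` within-sample and unit-standardized, so the sample Pearson
correlation equals ρ (default 0.77) exactly at any cohort size ≥ 3. WD⁺
ipsilateral peduncle volumes are a quantile set with exact mean 1.51 cm³.

**Geometry.** Two co-registered grids per subject: 1 mm isotropic
192×192×105 ("anatomical", used for volumetry) and 3 mm isotropic 64×64×35
("BOLD", used for simulation and CVR extraction). Regions are ellipsoids
(structure-specific aspect ratios) rasterized by *exact voxel-count
selection*: the N = round(V_target / V_voxel) voxels nearest the centroid in
ellipsoid-normalized distance, guaranteeing volume fidelity within one voxel
volume on any grid. Labels never overlap; the stroke lesion is a separate
binary mask that may overlap the hemisphere labels and the corticospinal
ROI. Lesions are supratentorial only and never touch peduncle, thalamus or
cerebellum; corticospinal-tract involvement is encoded by placing the lesion
over the motor-cortex ROI (all WD⁺ subjects by default, configurable).

One deliberately preserved oddity: the healthy thalamic volumes default to
0.74/0.67 cm³, an order of magnitude below anatomical reality (~7 cm³).
These values are kept as the calibration defaults of the packaged fixture;
the practical consequence is a very small thalamic ROI on the BOLD grid
(~27 voxels), which the noise calibration below takes into account.

## Signal model and noise

A voxel of a region with reactivity c (%BOLD/mmHg) follows

    S(t) = S0 · (1 + c/100 · (x(t) − x̄)) + d·t + ε,   ε ~ N(0, σ)

with x(t) the rendered CO₂ trace (block protocol: 120 s baseline, 120 s
hypercapnia, 120 s baseline; baseline 37.8 mmHg, step 9.4 mmHg, 2 s
sampling; optional first-order exponential transition smoothing, default
ideal steps). The trace is centered at its temporal mean so that S0 *is* the
temporal-mean signal; percent-of-mean OLS then recovers c exactly in the
noiseless case (the recovery contract is 1e-6 %/mmHg). Referencing the
baseline level instead would make the temporal mean c-dependent and bias the
estimator by ~0.6 % relative — the centering is a definition of S0, not an
approximation.

Defaults: S0 = 1000, σ = 10 (temporal SNR ≈ 100, typical of 3 T EPI), drift
d = 0. Under the default protocol this gives a single-voxel CVR standard
error of ≈ 0.017 %/mmHg, hence ≈ 0.003 for a 27-voxel thalamic ROI and
≈ 0.001 for a cerebellar ROI — small against the between-subject AI spread,
which is the regime the classification margins above assume. Noise is drawn
per subject from a seed spawned off the cohort seed; identical spec + seed
reproduces the series bit-for-bit. Noisy series are synthesized in float32
(quantization ≈ 1e-4 signal units, three orders below the noise floor);
noiseless series in float64 to honor the exact-recovery contract.

Perfusion maps are region-constant ground truth (relative units: thalamus
55, cerebellum 50, hemispheres 45, peduncles 28; post-acetazolamide ≈ 1.3×
baseline) plus N(0, 1) noise and Gaussian smoothing (default FWHM 6 mm,
emulating PET's lower resolution). Smoothing mixes regions with background,
so recovered PET AIs are biased versions of the generative ones —
acceptable, since only relative difference indices are ever reported and no
classification uses PET.

## CVR estimation

`compute_cvr_map` fits, per voxel, the OLS slope of the raw signal on the
CO₂ regressor and normalizes by the voxel's whole-series temporal mean
(×100). Whole-series-mean normalization is protocol-independent; a
baseline-epoch mean is available via the configuration. The regressor is the
CO₂ trace shifted by a fixed user-supplied delay (default 0 s) and linearly
interpolated at volume-acquisition midpoints; no hemodynamic lag
optimization is performed (a known limitation — lag fitting is deliberately
out of scope). Voxels with temporal-mean signal below 10 % of the robust
(99th-percentile) maximum of the mean image are masked invalid, which
removes air/background voxels where percent normalization would explode.
Estimates are gain-invariant (rescaling the raw signal leaves CVR unchanged)
and agree with a per-voxel normal-equations solve to 1e-10 relative.

## Asymmetry indices and classification

Volume AI = 100·(ipsi − contra)/contra (atrophy negative). Hemodynamic
(CVR/PET) AI defaults to 100·(contra − ipsi)/contra so an ipsilateral
deficit is positive; the signed volume-style convention is available via
configuration. The two conventions are kept distinct because the reported
deficit-positive diaschisis indices and the atrophy-negative volume indices
otherwise disagree in sign. "Ipsilateral" resolves through the subject's
stroke side; healthy subjects use left-as-ipsilateral, keeping the reference
distribution symmetric in expectation.

Thresholds are always derived at run time from the supplied healthy cohort
(sample mean, sample SD with n−1): WD requires a *negative* peduncular
volume AI whose magnitude strictly exceeds |mean| + 2·SD (the sign
requirement is added because a 2SD exceedance with the larger peduncle on
the stroke side is not degeneration; a magnitude-only mode exists);
diaschisis requires the regional CVR AI to strictly exceed mean + 2·SD.
Boundary values classify negative.

## Statistics

Each variable is screened with Shapiro-Wilk (α = 0.05). Continuous variables
normal in both groups: independent two-tailed Student's t-test
(equal-variance by default, Welch configurable), summarized mean ± SD.
Everything else: Mann-Whitney U (two-sided), summarized median (IQR,
type-7/linear-interpolation quartiles) or frequency (%). Dichotomous
variables additionally report Fisher's exact p (the more appropriate 2×2
test; Mann-Whitney remains the primary for fidelity to the emulated
workflow). Correlations: Pearson when both variables pass the gate, Spearman
otherwise; r² is always reported with r. No multiple-testing correction is
applied anywhere, by design. Degenerate inputs (constant vectors, n < 3,
single-subject subgroups) raise typed errors or flag the table cell as
not-computable rather than silently passing.

## Problem sizes used in tests and the acceptance script

The packaged default cohort (47 subjects at full geometry) runs in well
under a minute on one CPU and is exercised once per test session and once in
the acceptance script. Unit and property tests use a 36×36×24 grid at 2 mm
with ~0.4 cm³ regions (≥ 50 voxels per ROI), 50-replicate seeds for the
bias check, and 2,000 null replicates for the type-I-error band — sizes
chosen so each check's sampling error is small against the tolerance it
asserts.

## What passing tests do and do not show

The phantom exercises the full numerical chain — rasterization, simulation,
regression, volumetry, thresholds, classification, statistics — against
known ground truth, including noise, voxel quantization and PET smoothing.
It does not emulate hemodynamic response delays or lag dispersion, motion,
physiological (cardiac/respiratory) noise, partial-volume anatomy,
registration error, field inhomogeneity, or manual-masking variability. The
real-data regional CVR values the generator uses as defaults (e.g.
whole-brain 0.19 %/mmHg) are generative inputs, not reproduced
measurements: passing tests certify the pipeline's correctness and
calibration on phantom data, not agreement with any particular scanner
cohort.
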