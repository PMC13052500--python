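# Methods

## Problem setting

Keratoconus (KC) is a progressive ectatic corneal disease; the clinically
hard problem is the *subclinical* form (SKC), where topography is subtle and
eyes are routinely cleared for refractive surgery. Polarization-sensitive
OCT (PS-OCT) adds a functional signal — stromal birefringence, observed as
phase retardation (PR) — plus ultrahigh-resolution sublayer thickness maps
(epithelium, Bowman's layer). This package implements, end to end and on
synthetic data, a three-device comparison: a PS-OCT feature set against two
clinical tomographers (a rotating-Scheimpflug device and a hybrid
Placido/OCT device), each feeding an identically configured random-forest
classifier evaluated by leave-one-out cross-validation (LOOCV), followed by
cross-device agreement and reclassification analysis.

## Signal model

For a two-channel PS-OCT A-scan with orthogonal-polarization amplitude
profiles A1(z), A2(z):

* reflectivity  R(z) = A1(z)² + A2(z)²  (any positive scale factor is
  admissible; only relative reflectivity is used);
* phase retardation  PR(z) = arctan(A2(z)/A1(z)), reported in degrees in
  [0°, 90°]. A1 = 0 with A2 > 0 is exactly 90°; a sample with both
  amplitudes zero carries no polarization information and is masked, never
  silently zeroed.

En-face PR maps sample each A-scan at the posterior stromal surface (a
single depth sample; the acquisition protocol does not average a
neighborhood). Maps are smoothed with a floating average over a physical
1×1 mm window — converted to the nearest odd pixel count covering the
window, shrinking at map borders so no padding values are invented — and
cropped centered to the analysis field (10×8 mm for PR, 8×8 mm for
thickness).

## Synthetic cohort generator

The generator is first-class, tested code; it defines the study conditions
under which everything downstream is validated.

**Spatial model.** Maps live on a 0.25 mm grid. Phase retardation is a
radial profile (low central retardance, rising quadratically to the
periphery, reflecting near-normal incidence on orthogonally stacked central
lamellae and circumferential peripheral lamellae) plus a fourfold angular
("rhombus") modulation, an optional Gaussian cone bump, and smooth spatial
noise (Gaussian-filtered white noise, σ = 2 px). The epithelium is uniform
with an annular ("doughnut") depression around the cone; Bowman's layer is
uniform with focal Gaussian thinning at the cone. Cone center defaults to
(0.8, −0.8) mm (inferotemporal) with ±0.5 mm per-eye jitter, radius 1.5 mm.

**Levels and indices.** Class-conditional means/SDs for the screening
indices and the published tomography parameters follow the reported cohort
statistics (e.g. healthy IS 0.3 ± 0.5, KISA% 8 ± 11, BAD-D 1.0 ± 0.4; KC
Kmax 55.0 ± 4.9 D; KISA% in KC drawn log-normally, moment-matched to
912 ± 1290, because that distribution is heavily right-skewed and
positive). Central PR levels are 26.0 ± 3.2° (healthy), 30.0 ± 3.7° (SKC),
38.0 ± 4.5° plus a 15° cone bump (KC); epithelium ≈ 52 μm, Bowman
16.0 ± 1.0 μm in health, consistent with the 15–17 μm healthy range.
Keratometry, derived indices (ISV, IVA, KI, CKI, IHA, IHD) and wavefront
summaries not published per group were fixed once at clinic-plausible
values with SKC intermediate but closer to healthy (SKC ISV ≈ 20.5 and IVA
≈ 0.14 anchor to reported SKC subgroup values). KMean and astigmatism are
derived from K1/K2; axes are uniform on [0°, 180°).

**Label consistency.** The screening triple (KISA%, IS, BAD-D) is redrawn
by rejection (bounded at 1000 attempts, then an error signalling
inconsistent parameters) until it satisfies the eye's group box, so every
generated cohort passes the labeling audit exactly. Whether the clinical
distributions are truly truncated normals is unknowable from summary
statistics; truncation is a modeling decision here.

**Correlation structure.** Two mechanisms give the cohort realistic
structure without changing any marginal mean or SD:

1. a per-eye latent severity factor z ~ N(0,1) loads with weight ρ = 0.5 on
   every index (signed by the healthy→KC direction of that index) and on
   the map levels (PR +, thickness −), via
   x = μ + σ(ρ·dir·z + √(1−ρ²)·ε). Real tomography indices are strongly
   inter-correlated; independent draws would hand the classifier an
   unrealistically informative stack of weak independent separators.
2. fellow eyes of highly asymmetric KC (33 of 109 SKC eyes by default) draw
   from a phenotype blended 60% of the way toward healthy. Clinically these
   eyes show no signs of disease; this subpopulation is what makes SKC the
   hardest class and drives SKC→healthy reclassification.

**Reproducibility.** Per-eye seeds derive from
`SeedSequence([base_seed, eye_index])`, masked to 31 bits — a splittable
scheme that is stable under parallel generation. Identical seeds give
byte-identical cohorts.

**What the generator does not emulate.** No speckle or light-propagation
physics, no Scheimpflug/Placido raytracing, no segmentation errors, no
age/sex covariates, no within-subject correlation between fellow eyes of
one patient, and no cross-device correlation beyond the shared severity
factor (the two devices' keratometry draws are conditionally independent
given severity). Passing tests therefore demonstrate the correctness and
internal consistency of the analysis machinery under these assumptions, not
clinical performance on real corneas.

## Zernike features

Maps are fitted with Zernike polynomials through radial order 6 (28 terms)
by least squares over valid pixels inside a centered circular pupil,
coordinates normalized to the unit disk. The basis uses OSA/ANSI
single-index ordering with unit-RMS (orthonormal) normalization — the
ophthalmic-optics standard; the source protocol does not state its
convention, so coefficient values are convention-dependent while the fitted
surface is not. The fit pupil is the inscribed 8 mm disk for both the
thickness fields and the 10×8 mm PR field (the vertical extent limits the
common disk). Rank deficiency raises an error rather than returning a
pseudo-inverse solution. The three 28-coefficient blocks (PR, epithelium,
Bowman) concatenate into the 84-feature PS-OCT vector; the Scheimpflug
schema is 32 named indices and the hybrid-device schema 23, including five
epithelial-map summaries (LO/HO/coma RMS, defocus, spherical aberration)
computed from an order-6 fit of the epithelium map by the standard
RMS-grouping formulas.

## Labeling

Strict inequalities implement the screening boxes (healthy: KISA% < 60,
IS < 1.4, BAD-D < 1.65; SKC: < 60 / < 1.6 / < 2.6; KC: > 60 / > 3.0 /
> 3.0). The healthy box is a subset of the SKC box; a `clinical_suspect`
flag (fellow-eye or bilateral-suspect context) separates the two, mirroring
clinical practice where the distinction is contextual, not numeric. Eyes in
no applicable box — including exact threshold equality and the gap zones,
e.g. IS in [1.6, 3.0] — are `indeterminate`, never silently assigned; the
generator never produces them, but real-data users should expect them.

## Classification and metrics

One `RandomForestClassifier` per LOOCV fold with the fixed hyperparameters
(100 trees, Gini, unbounded depth, min_samples_split 2, min_samples_leaf 1
— scikit-learn defaults). Each fold's forest is seeded from
`(base_seed, eye_id)` (CRC-32 based) and training rows are put in canonical
eye-id order, which makes per-eye predictions exactly invariant to input
ordering. Multiclass AUC is one-vs-rest per class, macro-averaged — the
protocol says only "average AUC", so the scheme is documented here. Ties in
predicted probability resolve to the earlier class in (healthy, skc, kc). A
never-predicted class gets precision 0 with a warning. Model-vs-model AUC
differences use the DeLong correlated-ROC test (midrank implementation),
the standard choice for paired probability scores from the same eyes; the
source protocol names only "the ROC curve", so this is an interpretation.

## Agreement analysis

The Venn partition classifies each eye's three predictions as all-equal,
exactly-one-pair-equal (attributed to that pair), or all-distinct — an
exact partition by construction. Proportions are compared by Pearson
chi-square on the 2×2 table without continuity correction (a Yates flag
exists, default off). Subgroup contrasts use Welch's unequal-variance
t-test; subgroups under 2 eyes or zero-variance parameters are summarized
without a test and flagged.

## Problem sizes and numerical choices

The default simulated cohort is 120/109/130 (359 eyes, 33 fellow eyes),
matching the study scale; the acceptance script runs at this scale. The
test suite exercises most properties on smaller cohorts (e.g. 12/11/13 for
unit checks; 60/55/65 over five seeds for the cross-device accuracy-ordering
check; 30/30/30 for the perfect-separation check), sizes chosen to keep the
default `pytest` run at desk scale while preserving class proportions.
Zernike fits use `numpy.linalg.lstsq`; recovery of known order-6 fields is
verified to 1e-6 relative error. Phase retardation uses `arctan2`, so the
A1 = 0 limit is exact. Smoothing windows are odd pixel counts covering at
least the requested physical size; 1 mm at 0.25 mm spacing is a 5-pixel
window.

## Known limitations

* Absolute per-eye predictions of the original clinical study are not
  reproducible: its RF seeds are unpublished and its data are clinical; the
  published headline metrics serve only as a qualitative pattern (KC nearly
  perfect, healthy high, SKC lowest and device-dependent), which the
  synthetic pipeline reproduces.
* Coefficient values depend on the chosen Zernike convention; compare runs
  only within one convention.
* The chi-square and Welch defaults are interpretations of an
  underspecified statistical protocol; both alternatives (Yates correction,
  pooled-variance t) are one flag away but unused by default.
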