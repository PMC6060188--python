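# Methods

`flucipet` reimplements a semiquantitative analysis chain for dynamic
fluciclovine (anti-[18F]FACBC) brain PET in glioma: background-normalized
threshold segmentation, SUV / tumor-to-background (TB) metrics per time
frame, time-activity-curve (TAC) equilibrium assessment, ROC-based cutoff
derivation for high-grade (HGG, WHO III–IV) versus low-grade (LGG, WHO II)
glioma, and correlation of uptake with the Ki-67 proliferation index.
Because no patient images are available, every stage is driven by a
synthetic 4D phantom generator that carries full ground truth, so each
operation can be validated exactly and the statistical procedures can be
calibrated by Monte Carlo.

## Phantom model

**Geometry.** A phantom is an axis-aligned ellipsoid of normal parenchyma
containing spherical lesions and a spherical venous-confluence region,
voxelized on an isotropic grid (default 3 mm in the demo pipeline; the
clinical reference grid is 1.2 mm). A voxel belongs to a region iff its
center lies inside (center-in convention), applied uniformly to spheres and
ellipsoids. World coordinates are mm; voxel indices are 0-based.

**Kinetics.** Each tissue follows

S(t) = S_eq · g(t) + m · max(0, t − t_d),

where g(t) is the response of a mono-exponential uptake (rate k per minute)
to a constant-rate infusion of duration T_inf (default 4 min, the pump
infusion used clinically):

g(t) = (1/T_inf) ∫₀^min(t,T_inf) (1 − e^{−k(t−u)}) du,

evaluated in closed form (bolus limit g = 1 − e^{−kt} when T_inf = 0). g
rises monotonically from 0 to 1, so S_eq is the equilibrium SUV; the
optional linear drift m (SUV/min after t_d) breaks the plateau and is the
alternative hypothesis for the equilibrium tests. This curve family is an
emulation of the observed TAC shape (rise, then flattening from ≈30 min);
it is not a compartmental model of fluciclovine pharmacokinetics, and decay
correction is assumed (no decay term).

**Frames.** The default schedule is the clinical histogramming: 6 × 30 s,
4 × 180 s, 5 × 600 s — 15 contiguous frames ending at 65 min, with the last
four frame mid-times at 30/40/50/60 min (the equilibrium window). A frame's
voxel value is the *time-average* of its tissue TAC over the frame interval
(16-point Gauss–Legendre per smooth piece, split at the infusion-end and
drift-onset kinks), matching how histogrammed list-mode data behaves and
making frame values exactly testable.

**Degradation.** After painting, each frame is blurred with an isotropic
Gaussian PSF and degraded with additive i.i.d. Gaussian noise (SD in SUV,
seeded). The PSF default is 4.6 mm FWHM — the scanner's stated final
isotropic resolution. The acquisition description also mentions a 24 mm
FWHM post-reconstruction smoothing kernel, which cannot be literal
alongside a 4.6 mm final resolution; both values are exposed
(`DEFAULT_PSF_FWHM_MM`, `SMOOTHING_FWHM_MM`) and the default favors the
final resolution. Additive Gaussian noise is a deliberate simplification:
post-reconstruction PET images are approximately Gaussian, and projection
(Poisson) noise, attenuation/scatter and reconstruction (OP-OSEM) are out
of scope. Phantoms are generated directly in SUV units; injected dose and
body weight are not simulated.

**Ground truth.** Rendering returns the pre-blur, pre-noise tissue label
volume, per-lesion noiseless frame-averaged TACs, and the true
tumor-to-background ratio S_eq(lesion)/S_eq(brain) — used by the exact
segmentation and TAC-recovery tests.

## Synthetic study cohort

`synthesize_cohort` draws the study conditions the pipeline operates under:
12 HGG lesions (one WHO III, the rest WHO IV) and 6 LGG (WHO II) by
default, mirroring the reference cohort of 18 lesions from 16 patients.
Chosen once and fixed:

- Normal parenchyma equilibrates at SUV 1.5 and the venous confluence at
  1.6 (no material difference between blood pool and parenchyma, as
  observed clinically). Uptake rates (0.35/min brain, 0.9/min venous) put
  both tissues fully at equilibrium before 30 min.
- Lesion equilibrium SUVs: HGG ~ N(5.4, 1.1) truncated at 2.2, LGG ~
  N(2.7, 0.45) truncated at 1.6, i.e. generative TB ratios of 3.6 ± 0.73
  vs 1.8 ± 0.30. This reproduces the qualitative regime of the clinical
  scatter: strong but imperfect separation with every lesion hotter than
  parenchyma, and the LGG distribution straddling the 1.3×/1.6×/1.9×
  segmentation thresholds. Lesion uptake rates are drawn U(0.18, 0.32)/min,
  so a small residual climb can remain inside the window — faithfully, the
  clinical analysis also saw one significant late HGG time-pair.
- Ki-67 is generated as −16 + 11·TB + N(0, 6), clipped to [0.5, 95]
  percent, giving LGG values of a few percent and HGG values of tens of
  percent and an induced uptake–Ki-67 correlation near 0.85; 5/18 lesions
  have Ki-67 missing, as in the reference table.
- Attrition: a scan completes the full 65 min with probability 6/10 (HGG)
  or 5/6 (LGG); non-completers lack the 60-min frame. Missing frames are
  represented as missing values, never imputed.

What the phantom does *not* emulate: anatomical texture (gray/white
contrast inside the background sphere collapses to one tissue class),
lesion heterogeneity and infiltrative margins, motion, reconstruction
artifacts, partial-volume recovery coefficients. Passing tests therefore
demonstrate correctness of the measurement and statistics chain under
idealized imaging physics, not clinical performance on real data.

## ROI constructions and metrics

The background is a 15-mm-diameter sphere (the conventional reading of a
"15-mm spherical ROI") placed by mirroring the lesion center across the
midsagittal plane; it is fixed across frames, and each frame's ratios are
normalized by that same frame's background mean. Metabolically active tumor
at threshold k ∈ {1.3, 1.6, 1.9} is the set of search-ROI voxels with value
≥ k × background mean (≥ because a *minimum* threshold includes the
boundary), minus an optional exclusion mask (blood pool / choroid plexus).
SUV_max is the hottest single voxel in the search region (SUV_peak is a
non-goal); TB_max = SUV_max / background mean; TB_mean_k = (mean SUV over
the threshold-k voxels) / background mean. An empty threshold mask yields
*missing* TB/SUV_mean values with zero segmented volume, never zeros — at
3-mm voxels with blur, a low-grade lesion frequently has no voxel at 1.9×
background, and downstream statistics must see that as absence, not as
signal. Early frames whose background mean is not yet positive (infusion
barely begun, noise-dominated) likewise yield missing ratios.

## Equilibrium analysis

Observations (lesion × frame values of a statistic, long format) with frame
mid-times ≥ 30 min enter an unbalanced two-way ANOVA (time, group) with
type-II sums of squares — appropriate when attrition unbalances the design
— followed by Tukey HSD across time points within each group. A group is
*plateaued* when no within-group time-pair is significant at α = 0.05. The
per-pair adjusted p-values are always reported so callers can apply their
own reading (the clinical analysis itself treated HGGs as plateaued despite
one significant 30-vs-50-min pair). Groups contributing a single lesion
have no residual degrees of freedom; their Tukey table and plateau flag are
returned as unavailable rather than fabricated. With one group present the
group factor is dropped (one-way in time). TAC plots start at 4.5 min for
display only; data structures keep all frames.

Calibration (recomputed by `scripts/acceptance.py` and the test suite):
under drift-free kinetics with 10 lesions and SUV noise 0.1, the plateau
flag rejects in ≈5–7% of 500 replicates (the nominal α), and rejection
power grows to ≈1 by drift slope 0.02 SUV/min.

## Discrimination statistics

**Pooling.** One observation per lesion × equilibrium frame (missing values
dropped and counted). Pooled observations are treated as independent for
ROC construction — the clinical denominators imply lesion × time pooling —
with a per-lesion (lesion-mean) alternative available. WHO III lesions are
HGG for ROC and TAC purposes but excluded from the WHO II-vs-IV Welch
t-tests, exactly as in the source analysis.

**ROC.** HGG is the positive class; higher metric = more malignant; a case
is called positive when its value ≥ threshold. Candidate thresholds are
midpoints between consecutive sorted unique values plus ∓∞ sentinels, so
every achievable operating point appears once. AUC is the trapezoidal area
over the polygon traversed in lexicographic (FPR, sensitivity) order, which
equals the Mann–Whitney concordance probability with ties counted ½ (an
exact identity asserted against a brute-force pair count). The optimal
cutoff maximizes Youden J = sens + spec − 1; exact ties prefer the
higher-sensitivity point ("prioritizing sensitivity followed by
specificity" alone is degenerate — it always picks the minimum threshold —
so Youden is the operative rule).

**Ki-67 correlation.** Pearson r with the two-sided zero-slope p from the
least-squares line, at a single time point (default 30 min), n ≥ 3
evaluable pairs. "<1" table entries parse to 0.5 (the interval midpoint),
"N/A" rows are dropped; both behaviors configurable. A zero-variance input
is flagged degenerate rather than silently reported as r = 0. No
multiple-testing correction is applied across metrics (raw p-values are
reported, as in the source analysis).

**Lasso relevance.** The four metrics (SUV_max, SUV_mean, TB_max, TB_mean)
are standardized and entered into an L1-penalized logistic regression of
grade class; the coefficient path is traced over a descending penalty grid,
and the operating penalty is chosen by seeded stratified 5-fold
cross-validation under the 1-SE rule on *classification error* — the
parsimony-oriented measure for variable selection. Because CV-selected
penalties are known to overselect under a global null (a chance correlation
of ±1/√n survives in held-out folds), a null-model guard is applied: the
selected model must beat the intercept-only model on cross-validated
deviance by a paired one-sided t-test over folds at α = 0.05, otherwise no
metric is flagged relevant. This two-part design was calibrated by
simulation: with two strong and two null predictors at n = 400 it recovers
the exact informative support in ≈96–98% of replicates, and under an
all-null design it flags nothing in ≈93–95% — a deviance-based 1-SE choice
alone reached only ≈70% support recovery, and a classification-error choice
without the guard kept spurious support in ≈40% of null replicates.
Entry order along the path is reported, and constant predictors are
excluded with a warning.

## Numerical choices and degenerate inputs

- Frame averaging: Gauss–Legendre order 16 per smooth piece (exact to
  machine precision for these kinetics; validated against adaptive
  quadrature at 1e-8).
- PSF: σ = FWHM/(2√(2 ln 2)) in mm converted to voxels; reflective
  boundaries conserve interior-supported activity to 0.1%; FWHM 0 is the
  identity.
- Zero-variance ANOVA input: F undefined, all p = 1, plateau true.
- Welch t with both samples constant: t = 0, p = 1 if means agree, else
  p = 0 with an infinite statistic.
- Thresholded means over empty masks: NaN (missing), volume 0.
- Seeds: every stochastic stage takes an explicit seed; the pipeline spawns
  per-stage seeds from one master seed via `numpy.random.SeedSequence`, so
  a run is byte-reproducible from (config, seed).

## Problem sizes

The demo pipeline renders one 40 × 40 × 34-voxel (3 mm) phantom per lesion,
18 lesions, 15 frames — about 4 s end to end on one core. Monte-Carlo
calibrations use 100–500 replicates as stated above; the whole acceptance
script completes in about 3 minutes. These sizes were chosen so that the
full validation cycle stays interactive while keeping every statistical
check adequately powered.

## Known limitations

- The phantom's idealized physics mean recovered TB ratios carry
  partial-volume bias at realistic blur (segmented edges dilute the mean);
  tests that need exactness run with blur off.
- The per-lesion SUV values behind the published cutoffs (4.32 SUV_max,
  2.15/2.56/2.58 TB_mean) and correlations (R = 0.81) are not recoverable
  from printed tables, so the package validates its statistical machinery
  by construction and calibration rather than by matching those numbers;
  the synthetic cohort lands in the same qualitative regime but its
  cutoffs are its own.
- The equilibrium analysis ignores the repeated-measures structure
  (lesions appear at every time point), exactly as a two-way ANOVA + Tukey
  treatment does; with homogeneous within-group kinetics this is the
  stated procedure, but it is conservative/anticonservative trade-offs of
  that classical choice, not a mixed-model analysis.
- Mean patient age in the packaged table recomputes to 52.5 years per
  patient; the published text prints 49.6. The summary reports the
  recomputed value and no test asserts it.
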