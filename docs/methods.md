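# Methods

`dmnfc` implements a seed-based resting-state functional-connectivity
analysis of the brain default mode network (DMN) for three-group cirrhosis
studies — healthy controls (HC), cirrhotic patients without hepatic
encephalopathy (nonHE), and minimal hepatic encephalopathy (MHE) patients —
together with a synthetic-cohort generator that makes every stage testable
without access to clinical data.

## Analysis model

**Per-subject connectivity.** After preprocessing, the mean time series of
each of three spherical seeds — medial prefrontal cortex (MPFC; MNI −1, 47,
−4), posterior cingulate cortex (PCC; −5, −49, 40) and left lateral parietal
cortex (LP; −45, −67, 36), radius 6 mm by default — is correlated with every
voxel (lag-zero Pearson r). r maps are variance-stabilized with Fisher's
transform, z = atanh(r), and the three z maps are averaged into the
subject's DMN map. Seed placement is done in mm and mapped through the
inverse affine, so seeds are grid-independent; radius 0 degenerates to the
single voxel containing the seed center.

**Preprocessing.** Order: discard the first 10 volumes (T1 equilibration);
exclude subjects whose motion exceeds 1.0 mm translation or 1.0° rotation
(strict inequality — boundary-equal subjects are retained); smooth with an
isotropic Gaussian (8 mm FWHM, specified in mm, converted to voxels per
axis); regress an intercept, the six motion parameters, and mean CSF / white
matter / whole-brain signals by voxelwise OLS; band-pass the residuals to
0.01–0.08 Hz. The filter is a zero-phase frequency-domain window with
raised-cosine transitions of 0.005 Hz; zero phase matters because phase
shifts would bias lag-zero correlations. Nuisance regression precedes
filtering, matching the narrative order of the standard pipeline; this
ordering is a known sensitivity point in the field. Rotation screening uses
the reported degree values directly rather than converting to displacement
at a head radius. Motion-parameter files are 6-column whitespace text,
translations (mm) before rotations (degrees); radian input is never
auto-detected — units are part of the contract.

**Conjunction DMN mask.** For the mask-defining group (the healthy
controls, so patient data never shape the domain on which groups are
compared), a voxelwise one-sample t-test of z against zero is run per seed
across subjects, two-sided p, Benjamini–Hochberg FDR at q = 0.05. A voxel
enters a seed's significance mask when it survives FDR *and* has positive
mean z: the mask encodes membership in a positively coupled network, and
global-signal regression shifts background correlations slightly negative,
so a sign-blind mask would admit that bias wholesale. The combined DMN mask
keeps voxels significant for at least 2 of the 3 seeds.

**Group inference.** Within the DMN mask, each voxel is tested with a
covariate-adjusted one-way ANOVA: F compares the linear model
[1, group indicators, age, gender] to the model without the group
indicators, with HC as the reference level so post hoc signs read
patient-minus-control. Post hoc two-group t contrasts (same covariates) are
evaluated only inside the significant ANOVA clusters. Gender is coded 0/1;
the design must be full rank or the offending columns are reported.

**Cluster-extent correction.** Voxelwise thresholding at the
cluster-forming p (default 0.01, deliberately stricter than the family
alpha since the underlying software convention leaves it unreported) is
followed by connected-component extraction (26-neighbor connectivity by
default; 6 and 18 available). The minimum cluster extent k is estimated by
Monte Carlo: Gaussian white fields on the grid, smoothed to the estimated
residual smoothness, standardized within the mask, thresholded two-sided at
the forming p; k is the smallest extent whose null exceedance probability
is ≤ alpha (default 0.05, 1000 iterations, seeded). Residual smoothness is
estimated per axis from the variance of spatial first differences of the
group-model residuals: for a Gaussian autocorrelation field,
FWHM = d·sqrt(−2 ln 2 / ln ρ) with ρ = 1 − var(diff)/(2 var), clipped below
at the voxel size; constant residual fields raise an error rather than
returning a sentinel. On 200 simulated null cohorts (12³ grid, 8 subjects
per group) the measured family-wise error rate of this chain sits inside
the 95% binomial envelope of alpha (the acceptance suite re-runs this
check).

**Diagnostics.** A cirrhotic patient is labeled MHE when at least one of
two psychometric tests is abnormal: number connection test A (NCT-A,
longer time = worse) above the control mean + 2 SD, or digit symbol test
(DST, lower score = worse) below the control mean − 2 SD. The 2-SD
multiplier follows the convention of the psychometric-criterion literature
and is configurable; the labeling is monotone in severity. Regional mean z
values (over the significant ANOVA clusters) are correlated with NCT-A and
DST across all patients (MHE and nonHE pooled) by Pearson's r with the
t-transformation p value. ROC analysis discriminates MHE from nonHE per
region with the orientation "lower connectivity indicates disease"
(reversible by flag); AUC is computed by the trapezoidal rule and equals
pairwise case–control concordance with ties counted ½. The reported cutoff
maximizes Youden's J = sensitivity + specificity − 1, breaking ties toward
higher specificity and then toward the lower threshold, so output is
deterministic.

## Synthetic cohort

The generator emulates a 250-volume acquisition at TR = 2 s (the first 10
volumes later discarded) on a 3 mm isotropic grid. Six spherical DMN nodes
(radius 6 mm) sit at the three seed coordinates plus surrogates for left
superior frontal gyrus and bilateral middle temporal gyri — the regions
where group differences are expected. The default grid is 40×46×26 voxels,
auto-centered on the node bounding box: large enough to hold all nodes at
their true MNI coordinates, small enough that a 60-subject cohort simulates
and analyzes in a few minutes on one core. Any grid/node combination is
accepted provided the spheres fit.

Per subject, one latent network signal n(t) and voxel-unique signals u_v(t)
are drawn as band-limited (0.01–0.08 Hz) Gaussian processes; node voxels
receive sqrt(ρ)·n + sqrt(1−ρ)·u_v, which has unit variance and pairwise
inter-node correlation ρ. Band-limited construction is deliberate: the
planted correlation passes the pipeline's own band-pass filter unchanged.
A consequence worth noting is that 240 retained volumes carry only ~34
independent Fourier modes in the band, so single-pair sample correlations
scatter around ρ with SE ≈ 0.12; recovery checks therefore average over
node-voxel pairs. ρ defaults to 0.60 / 0.45 / 0.30 for HC / nonHE / MHE
with per-subject Gaussian jitter (SD 0.04) so neuropsychological coupling
is a genuine per-subject correlation. On top of the network signal every
voxel receives white noise (SD 0.5), a random linear drift (amplitude 0.3),
a shared global nuisance signal (amplitude 0.3), motion-coupled artifacts
(random-walk motion, SD 0.05 mm/deg, coupling 0.1), a constant baseline of
100, and — inside small corner CSF/WM surrogate boxes — tissue-specific
nuisance signals that make the tissue-mean regressors meaningful.

NCT-A is drawn as 92 − 80·ρ + N(0, 8) seconds (floored at 15 s) and DST as
18 + 42·ρ + N(0, 4) points, so connectivity loss worsens both scores in the
correct directions at control values typical of psychometric norms. Ages
come from one N(48, 10²) distribution for all groups (matched cohorts);
gender is 75% male, mirroring the cirrhosis demographic. Everything is
deterministic given (master_seed, subject_seed).

What the generator does **not** emulate: hemodynamic response shape,
cardiac/respiratory cycles, susceptibility artifacts, realistic tissue
geometry, spatial normalization error, or site effects. Passing tests
therefore demonstrate that the statistical machinery is correct and
calibrated under the declared signal model — not that the pipeline is
robust to every artifact of real acquisitions.

## Numerical choices

- Missing values are NaN throughout; a voxel missing in any subject is
  excluded from that group test, and |r| = 1 maps to missing z with a
  logged warning.
- Zero-variance detection in correlation maps uses a dtype-aware threshold
  (demeaning a constant series leaves round-off of order eps·‖series‖).
- Exact-fit voxels in ANOVA / t (residuals at round-off scale) return
  F = 0 / t = 0 when the effect is also at round-off scale, ±inf otherwise.
- Smoothing uses a truncated (4 SD), discretely normalized separable
  kernel; constant volumes are unchanged and interior-supported mass is
  conserved to the stated 1e-6.
- Simulated BOLD is stored float32 (halves memory traffic); all group
  statistics are computed in float64.
- Problem sizes in the validation suite (12³ grids for the null-calibration
  study, 20 subjects per group for recovery) are chosen so the full suite
  runs in minutes on one core while keeping every check at the statistical
  scale it needs.

## Known limitations

- The Monte-Carlo extent correction simulates Gaussian fields but is
  applied to F maps; this is the standard convention of the original
  software and is empirically well calibrated here, but it is an
  approximation.
- Whether nuisance regression should precede or follow filtering is
  unresolved in the field; only the regression-then-filter order is
  implemented.
- Slice-timing correction, realignment estimation and spatial normalization
  are out of scope: inputs must already live in a common space with motion
  parameters supplied as files.
- The conjunction threshold is applied at the group level (one-sample t
  across subjects) rather than to subject-level correlation p values; both
  readings exist, and the group-level one was chosen because the mask's
  purpose is to gate group maps.
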