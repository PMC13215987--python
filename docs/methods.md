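# Methods

`slicefat` quantifies abdominal adipose tissue from a single axial
opposed-phase T1 MRI slice. On such images fat is hyperintense, lean
tissue intermediate, and background dark, and the signal cancellation at
fat/water interfaces sharpens compartment boundaries. The pipeline is
fully automated: preprocessing, binary adipose segmentation, arm removal,
VAT/SAT delineation, surface quantification, and regression calibration of
the systematic area underestimation that intensity thresholding incurs.

## Pipeline

**Preprocessing.** An adaptive Wiener filter (default 6×6 window)
suppresses noise: each pixel becomes
`mu + max(var − nv, 0)/max(var, nv) · (x − mu)` with `mu`, `var` the local
window moments and `nv` the noise variance, estimated as the mean of the
local variances when not supplied. Contrast is then enhanced
morphologically: `clip(img + tophat − bottomhat)`, where the white top-hat
(image minus opening) lifts bright structures smaller than the structuring
element and the black bottom-hat (closing minus image) deepens dark ones.
The structuring element is a disk of radius 5 px by default — on the order
of the subcutaneous ring thickness at the intended export resolution — and
is configurable (`selem_shape`, `selem_radius_px`). All local filters use
reflect padding so the image border does not seed artificial components.
The enhancement weights the two hat images equally; no weighting scheme is
exposed because none proved necessary on phantoms.

**Segmentation.** Three interchangeable backends produce a binary
adipose-vs-rest mask, with the brighter class always mapped to adipose
(mapping is by center/threshold intensity, never by label index):

* *Otsu*: threshold maximizing between-class variance over a 256-bin
  histogram; ties resolve to the lowest maximizing threshold so results
  are reproducible. Constant images are rejected as degenerate.
* *k-means* (k = 2): Lloyd iterations on the flattened intensities with
  k-means++ seeding from the run seed; an emptied cluster is re-seeded at
  the sample farthest from its center (logged). The within-cluster sum of
  squares is recorded per iteration and is non-increasing.
* *fuzzy c-means* (c = 2, fuzziness m = 2.0, tol 1e-5, max 300
  iterations): alternating membership/center updates
  `u_ij = 1/Σ_k (d_ij/d_ik)^(2/(m−1))`; a sample exactly at a center gets
  membership 1 for that center (no division by zero). Pixels are hardened
  by maximum membership. The m = 2 default is the literature's standard
  choice; the objective is recorded and non-increasing.

**Arm removal.** Upper-extremity fat would otherwise contaminate the SAT
compartment. An abdominal mask is built from the raw slice: Otsu
foreground, morphological closing (disk radius 10 px), hole filling, then
the 8-connected component containing (or nearest to) the image center is
kept. Hole filling happens *before* component selection: on fat-bright
slices the threshold may retain only the subcutaneous ring, and filling
turns that ring into the solid trunk so the center falls inside it. A
manually drawn mask can always be supplied instead. The adipose mask is
intersected (logical AND) with the abdominal mask.

**VAT/SAT delineation.** The arm-free adipose mask is decomposed into
8-connected regions with per-region area, centroid and
centroid-to-image-center Euclidean distance (image center
`((rows−1)/2, (cols−1)/2)`, (row, col) 0-based, origin top-left —
one convention everywhere). Of the two largest regions, the one whose
centroid lies farther from the center is SAT (the peripheral ring); the
nearer one, and every smaller fragment, is VAT (the fragmented central
compartment). Degenerate situations warn rather than fail silently: a
single region becomes SAT with empty VAT (suggesting SAT–VAT bridging,
an exclusion situation in practice), and an exact distance tie (≤1e-9)
is broken by area. The number of compared regions (`k_largest`) is
configurable but defaults to two.

**Quantification.** Area = foreground pixel count × pixel area, with
pixel area = (FOV_row/rows)·(FOV_col/cols)/100 in cm². The geometry must
describe the grid the masks live on — when a scanner export interpolates
(e.g. a 256×176 acquisition exported at 512×352), total area is conserved
only if the FOV is divided by the export grid. Distribution indices are
VAT/TAT (%) and VAT/SAT; undefined ratios (zero denominator) are carried
as NaN, never as infinity. Multi-slice volumes are
`V = (t + h)·ΣA_i` with slice thickness `t` and inter-slice gap `h`
(cm): each slice area represents a slab of extent `t + h`. The additive
form `t + h·ΣA` is dimensionally inconsistent (lengths plus length×area)
and is rejected.

**Evaluation.** Confusion counts, Dice `2TP/(2TP+FP+FN)` (primary — it is
robust to the heavy adipose/background class imbalance) and the symmetric
Hausdorff distance over full foreground pixel coordinate sets, Euclidean,
in pixel units. Conventions: both-empty Dice = 1, one-empty Dice = 0;
Hausdorff on an empty mask is an error. A 95th-percentile Hausdorff
variant is available behind a flag; boundary-only Hausdorff is not
implemented.

## Calibration models

Threshold segmentation loses partial-volume pixels at tissue interfaces
and therefore underestimates areas by a roughly linear, predictable
amount. The shipped corrections (cm²) are

    VAT_ref = 7.224 + 1.112 · VAT_auto + 7.583 · I_obesity
    SAT_ref = 0.670 + 1.037 · SAT_auto + 3.337 · I_adult

with dummy coding female/child/normal-weight as reference levels. These
coefficients are cohort- and protocol-specific; the module's purpose is
to let users refit them. Fitting is weighted least squares with
inverse-frequency Sex × Age weights (each record weighted by the
reciprocal of its subgroup count, so every subgroup carries equal total
weight); both weighted and unweighted fits are available since for the
shipped models the two coincide at the printed precision.

Supporting machinery:

* **Model selection** — exhaustive enumeration of candidate demographic
  terms and area interactions (intercept and area predictor always
  retained), scored by an information criterion. BIC is the default: its
  ln(n) penalty keeps the false-inclusion probability of a spurious term
  small at any realistic cohort size, whereas AIC's fixed penalty of 2
  admits a spurious term with probability ≈0.16 each regardless of n.
  AIC remains selectable. Ties prefer fewer terms, then lexicographic
  order, so selection is deterministic.
* **Multicollinearity** — VIF_j = 1/(1−R²_j) from regressing each column
  on the rest; infinite VIF flags exact collinearity. For interaction
  screening, binary predictors can be mean-centered before products are
  formed.
* **Agreement** — Bland–Altman limits: mean difference ± 1.96·SD (ddof=1);
  the 1.96 multiplier is configurable.
* **Uncertainty** — BCa bootstrap CIs (default 10,000 resamples, bias
  correction from the bootstrap distribution, acceleration from the
  jackknife), deterministic given a seed. A zero-variance statistic
  yields a zero-width interval with a warning.
* **Internal validation** — leave-one-out and repeated k-fold CV
  (default 10-fold × 100 repeats). Every training fold refits from
  scratch, *including recomputing the inverse-frequency weights from the
  training records only*; held-out predictions are pooled into R², RMSE,
  MAE and mean bias. Rank-deficient folds are skipped with a warning and
  counted.

## Synthetic data

**Slice phantoms** emulate the geometry and intensity ordering of an
axial abdominal slice: an elliptical body (default semi-axes 52×42 px on
a 128×192 grid), a subcutaneous fat ring with per-quadrant thickness,
circular visceral fat deposits in the lean interior, optional fat-rimmed
arm cross-sections lateral to the trunk, three intensity levels
(background 0.10, lean 0.30, fat 0.90 — the lean–fat gap exceeds the
background–lean gap, as it does for hyperintense fat), and additive
Gaussian noise clipped to [0, 1] (Rician magnitude noise is available as
an option). Generation is a pure function of the spec including its seed.

Two geometric choices keep the delineation rule exercisable, and are
deliberate idealizations: the ring is thicker posteriorly (default
thickness (5, 5, 25, 5) px for anterior/right/posterior/left, giving a
ring centroid ≈14 px off-center — a perfectly concentric ring would make
the centroid-distance rule degenerate, and real subcutaneous fat is
dorsally accentuated), and VAT blob centers are confined to a 9.5 px
scatter disk around the body center, so the largest blob's centroid is
always nearer the center than the ring centroid. Arms sit 26 px lateral
to the trunk so the abdominal-mask closing cannot bridge them.

What phantoms do **not** model: MR physics (chemical shift, bias fields,
the India-ink boundary artifact as a signal phenomenon), organ texture,
SAT–VAT bridging, realistic VAT fractions (the default phantom's VAT/TAT
is a few percent, far below typical adult values — the blobs are kept
small and central for rule well-posedness), or anatomical variation
beyond ellipse parameters. Passing phantom tests therefore demonstrates
correctness of the pipeline's logic under its stated assumptions, not
clinical accuracy on patient images.

**Cohort simulation** draws automated-area predictors (uniform or evenly
spaced over a configurable range), independent sex/age/obesity strata
(defaults mirror a realistic pediatric-plus-adult cohort structure: n=68,
30/68 male, 47/68 adult), and computes the reference area from the linear
bias model plus Gaussian residuals (default SD 11.5 cm², the VAT model's
cross-validated RMSE). With zero residual SD the response is exactly the
linear predictor, which is what the coefficient-recovery tests and the
acceptance script exploit: any strictly positive weighting must then
return the generating coefficients to numerical precision.

## Numerical choices and degenerate inputs

* Otsu tie-break: lowest maximizing threshold. Histogram: 256 bins over
  the observed range.
* k-means/FCM initialization: k-means++ from `numpy.random.default_rng(seed)`;
  one seed governs all stochastic stages of a pipeline run and is
  recorded in the run manifest (which contains no timestamps, so
  identical config + seed reproduces byte-identical artifacts).
* FCM zero-distance convention: membership 1 at the coincident center
  (split equally if several coincide). Note the large-m limit
  (memberships → 1/c) holds only away from centers; at a data point equal
  to a center the membership stays pinned.
* Masks are uint8 over {0, 1}; images float64 in [0, 1]; 16-bit rasters
  rescaled by 65535, RGB collapsed by BT.709 luminance with a warning.
* Empty adipose mask → error; single adipose region or distance tie →
  warning, not silence.
* Batch runs isolate per-case failures: one malformed slice does not
  abort the cohort.

## Problem sizes

Default phantoms are 128×192 px — large enough for a multi-pixel ring,
distinct blobs and arms, while keeping the full three-backend test
matrix fast. Statistical property tests use the cohort sizes stated in
their docstrings (n = 60–2000, 100–200 simulation repeats, bootstrap
resamples 2,000–10,000), chosen so each check has adequate power against
the property it asserts.

## Known limitations

* The delineation rule assumes the SAT ring is the largest or
  second-largest adipose region and measurably off-center; slices where
  SAT and VAT bridge, or the ring fragments into several arcs, only
  trigger warnings and should be reviewed.
* The shipped correction equations transfer only to acquisitions matching
  their source protocol; refit before use elsewhere.
* Hausdorff is computed over full foreground point sets, which for
  fragmented VAT can be dominated by a single spurious blob; the
  95th-percentile variant mitigates but does not remove this.
* Only 2-class segmentation is supported; no spatial regularization, no
  bias-field correction, no DICOM I/O.
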