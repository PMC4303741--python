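# Methods

`clinmri` is a desk-scale re-implementation of the infrastructure needed to
turn routinely acquired clinical brain MRI into quantitative volumetric
biomarkers: cohort selection from radiology reports, DICOM
de-identification and defacing, header/image quality assurance, multi-atlas
kNN tissue segmentation, and the cohort-level linear models.  This note
records the models, the defaults and the design choices, and what the
synthetic validation does and does not show.

## Synthetic phantoms

Every stage is validated against synthetic head phantoms with analytic
ground truth.  A phantom is a family of nested axis-aligned ellipsoids —
white matter inside grey matter inside CSF inside skull inside scalp — with
a face lobe attached anteriorly.  Ellipsoid nesting keeps tissue volumes in
closed form (4/3 π abc, scaled by the cube of the pose scale), so volumetric
recovery can be scored against exact truth without any reference dataset.

* Default grid 64×64×48 at 3 mm isotropic (configurable upward); the volume
  centre is the patient-space origin.
* Default class mean intensities (arbitrary units): air 0, skull 100,
  scalp/face 300, CSF 450, GM 620, WM 800.  Default noise SD 8.5 — 5 % of
  the smallest tissue separation (CSF↔GM, 170 units) — which is the regime
  all recovery experiments are run in.
* A subject's pose (rotation, translation, uniform scale) is applied
  analytically to the geometry: voxel coordinates are pulled back through
  the inverse pose before the ellipsoid membership test, so posed ground
  truth involves no resampling.
* The optional bias field is a quadratic polynomial in normalised
  coordinates, scaled so its maximum deviation from 1 equals the requested
  amplitude.
* Intensities are rounded to integers and written as 16-bit unsigned DICOM
  (explicit VR little endian, one file per slice, rescale slope/intercept
  1/0), which makes write→read round trips bit-lossless.
* Header profiles emulate a multi-vendor archive (GE Discovery/Signa,
  Siemens Sonata, Philips NT Intera with their typical TR/TE/TI/flip/field
  strength), including private-tag payloads and contrast-agent flags.

Atlas sets are pose- and intensity-jittered phantoms (default: ±5° rotation,
±5 mm translation, ±3 % scale, ±5 % class means).  Shape is deliberately
shared: ellipsoid families are exactly affinely alignable, which isolates
the label-fusion machinery from shape-model error.  The non-rigid stage is
exercised separately with fixtures whose inner shells are displaced relative
to the outer ones — a configuration no global affine can express.  Atlas
masks derive from the ground-truth labels: intracranial = CSF∪GM∪WM,
cerebrum = GM∪WM, and the face-exclusion mask is the complement of the face
region dilated by one voxel so sub-voxel registration error cannot leave a
facial shell behind.

What the phantoms do **not** emulate: realistic MR physics (no k-space, no
partial volume beyond voxelization), gyral/sulcal geometry, pathology, or
real inter-subject shape variation.  Passing tests therefore demonstrate the
correctness of the pipeline mechanics (privacy, geometry, label fusion,
classification, accounting), not clinical segmentation accuracy.

## De-identification

Header scrubbing blanks a declared list of identity fields (names,
identifiers, locations, dates — a subset of the DICOM PS3.15 basic
confidentiality profile), removes every private (odd-group) element, resets
birth dates to January 1 of the birth year, and truncates study dates to the
year (ages at scan and acquisition years feed the analysis stage, so the
years are retained).  Scrubbing is idempotent and audited; audit lines name
the modified element but never record the removed value.  UIDs are remapped
with a keyed hash so referential integrity across the files of a series
survives the scrub.  Age at scan is computed (floor of whole years) before
scrubbing destroys the birth day/month.

Defacing registers an atlas to the subject (affine, mutual information) and
multiplies the image by the transformed binary keep-mask: voxels outside the
facial region are bit-identical to the input, facial voxels become 0.  No
blurring is applied.

## Registration

Registration maximises Mattes mutual information with dense (every-voxel)
metric sampling, which makes results fully deterministic — there is no
random sampling to seed.  The affine search runs in three stages:

1. a 6-DOF rigid search at the coarse pyramid levels (shrink 4 and 2,
   smoothing 2 and 1 voxels, 32 histogram bins) — rotations are poorly
   conditioned in the full 12-DOF space and benefit from a rigid warm
   start;
2. the 12-DOF affine search at the same coarse levels;
3. a full-resolution polish with a 64-bin histogram.  The finer histogram
   matters because phantom intensities concentrate on a few discrete
   levels; 32 bins blur the boundary information the gradient needs for
   the last fraction of a degree.

Each stage uses regular-step gradient descent (learning rate 2.0, minimum
step 1e-4, 100 iterations/level, relaxation 0.6) with parameter scales
estimated from physical shift.  Initialisation is centre-of-mass (moments)
alignment with identity rotation.  The final mutual information is
recomputed with the package's own joint-histogram implementation —
independent of the optimisation engine — and if the optimised transform
fails to improve on the initialisation, the initialisation is returned, so
"final MI ≥ initial MI" holds by construction.

The non-rigid refinement is a coarse cubic B-spline (3×3×3 control mesh)
fitted by LBFGSB at a single quarter-resolution level (10 iterations) on
top of the affine pre-alignment.  Control-point displacements are clipped
to the configured cap (default 15 mm) after optimisation — the LBFGSB
wrapper exposes no box constraints — and if the warp does not improve MI
over the affine alone, the zero field is returned.  Transforms map fixed
(target) coordinates to moving coordinates, the resampling convention;
intensities are resampled linearly, labels and masks nearest-neighbour
only.

On phantoms, known translations up to 10 mm are recovered within half a
voxel and rotations up to 10° within 1°.  A residual of this size is
expected: the head ellipsoids are nearly circular in the x–z plane, so
rotation about y is the worst-conditioned direction.

## Quality assurance

Sequence classification is a decision table over the header physics.  The
published record of this class of pipeline does not state numeric
thresholds, so the table is an explicit, overridable declaration of
textbook ranges (times in ms):

| rule | class |
| --- | --- |
| diffusion b-value present | DWI |
| EP with ≥ 10 temporal positions | fMRI |
| GR with TI > 0 | T1w (inversion-prepared gradient echo) |
| GR, TI = 0, TE < 10, flip ≥ 8° | T1w (spoiled gradient echo) |
| SE, TR < 1000, TE < 30 | T1w |
| SE, TR ≥ 2000, TE ≥ 80 | T2w |
| SE, TR ≥ 2000, TE < 30 | PDw |
| otherwise | unknown |

Rules fire top to bottom; a missing echo time means no numeric rule can
fire and the class is `unknown` (a value, not an error).  Per contrast
class the highest-resolution series wins (smallest voxel volume, ties to
the larger in-plane matrix, then the lowest series number), and the
preference order for segmentation input is T1w, else PDw+T2w.  Series with
a recorded contrast agent are excluded (whitespace normalises to "none").

The field-of-view check registers an atlas affinely to the subject, carries
the brain mask over nearest-neighbour, and measures the brain-voxel
fraction on the six outer planes of the grid; a fraction **strictly**
greater than 0.20 on any plane excludes the scan (exactly 20 % passes).

## Tissue segmentation and volumetry

1. **Bias correction.**  A low-order (quadratic, 10-term) polynomial field
   is fitted in log-intensity space over the foreground (Otsu threshold
   halved), alternating for 3 iterations with a deterministic 1-D k-means
   (k = 5, quantile-initialised) over corrected intensities so tissue
   structure is not absorbed into the field.  Five clusters cover the
   foreground intensity levels present in a head image (skull, scalp, CSF,
   GM, WM); fewer lets anatomy leak into the field estimate.  The field is
   strictly positive with unit geometric mean over the foreground, and the
   corrected image is rescaled to preserve the foreground mean.
2. **Probability map.**  Each atlas is registered (affine + non-rigid) to
   the bias-corrected subject; transformed expert labels are averaged, so
   with n atlases every class probability is a multiple of 1/n.  A failing
   atlas is dropped with a warning; losing all of them is an error.
3. **Masks.**  Transformed intracranial and cerebrum masks are combined by
   majority voting with threshold 0.8 (5 of 6 atlases suffice, 4 do not).
   The 0.8 vote is stated for the brain mask in the source methodology;
   applying the same rule to the intracranial mask is this package's
   declared choice.
4. **Training.**  Voxels where the atlases vote unanimously (probability
   1.0) for CSF, GM or WM supply training intensities, subsampled (seeded)
   to 2000 per class.  If a class has fewer than k candidates the
   threshold steps down by 1/n per warning, with a floor of one atlas
   vote; a class that stays short raises an error naming the class.
   Because training samples come from the subject's own image, the
   classifier inherits the subject's contrast, and global linear intensity
   rescaling provably cannot change the segmentation.
5. **Classification.**  k-nearest-neighbour with k = 45 on the
   bias-corrected intensity (two intensity channels when segmenting from a
   PDw+T2w pair).  The decision is defined over the *inclusive shell*:
   every training sample whose distance does not exceed the k-th smallest
   distance votes.  With quantised intensities the k-th distance is
   massively tied and "the k nearest" is not a well-defined set; the
   inclusive shell is its unique order-independent completion, exactly
   reproducible by a brute-force scan (which the tests perform).  Class
   ties break by smaller mean neighbour distance, then CSF < GM < WM.
   Voxels outside the intracranial mask are background; inside it,
   background is not a class — every intracranial voxel is forced into a
   tissue.
6. **Volumes.**  Tissue volume = voxel count × voxel volume / 1000 (ml);
   brain = GM + WM and ICV = CSF + GM + WM are computed as those exact
   sums, so the identities hold to the last bit.  Whether the cerebellum
   belongs in "brain volume" is ambiguous in the source methodology; the
   package reports brain volume within the ICV mask and the
   cerebrum-mask-restricted volume separately.

On ten seeded phantoms at 5 % noise and ±10 % bias with poses up to ±8 mm /
±8° / ±5 % scale, ICV is recovered within ~4 % and brain volume within
~0.5 % of the analytic truth (the acceptance bound is 7 %).  The ICV error
is dominated by the conservative 0.8 majority vote at the mask boundary,
not by the classifier.

## Cohort statistics

Selection queries radiology report text with case-insensitive regular
expressions.  The analysis cohort keeps ages ≥ 45 at scan (inclusive) and
applies a Tukey IQR rule to the ICV-corrected brain volume (brain/ICV):
records strictly outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are excluded,
quartiles by linear interpolation between order statistics, applied within
each disease group by default (a pooled option exists; the source is silent
on which was used).  Fewer than four records exclude nothing, with a
warning.

The models are ordinary least squares:

    ICV   = β0 + β1·gender + β2·age + Σᵢ β3ᵢ·groupᵢ + β4·seq + Σⱼ β5ⱼ·typeⱼ + β6·fs + ε
    brain = same terms + β7·ICV + ε

with gender coded 0/1 (female reference), the open-question group and the
Philips NT Intera scanner as dummy reference levels, and field strength
entered linearly.  Factors with a single observed level are dropped with a
warning; a rank-deficient design is an error naming the aliased terms.
Adjusted group means are model predictions at an *absolute* evaluation
point — age 60.5 years, ICV 1150 ml, GR sequence on the NT Intera at the
cohort's modal field strength — so they are invariant to re-coding the
dummy references (only the coefficients change).  Pairwise group contrasts
carry Bonferroni-corrected p-values.

The statistics are validated against the models themselves: a synthetic
cohort generator draws covariates shaped like a mixed clinical archive and
computes the response from a known coefficient vector, so zero-noise fits
must interpolate exactly (recovered to 1e-8) and 95 % confidence intervals
must cover the true age effect at their nominal rate (93–97 % over 200
replicates at n = 650).

## Pipeline

Each examination runs read → scrub/deface → QA → segment → volumes
independently; every stage error is captured into the result, never
crashing the batch.  Outputs are keyed by pseudo-ID (a guarded bijective
mapping table with an exclusion list stands between hospital IDs and
research IDs) and headers are scrubbed before any artefact is written, so
no input identity string can appear in the output tree — a property the
tests verify by byte-sweeping the tree for planted canaries.  Retrieval is
abstracted behind a small interface: the filesystem implementation reads
DICOM directories; the DICOM-network variant is a stub that raises until
configured.  Step-wise accounting (selected → retrieved → QA-passed →
biomarker-extracted) is reported as percentages of the selected count and
must be monotone non-increasing.

## Problem sizes and numerical choices

Validation runs use the 64×64×48 / 3 mm phantom, six atlases, and the
seeded conditions above; the acceptance script scales the volumetric
recovery to five phantoms and the coverage simulation to 200 replicates.
All randomness flows through explicit seeds (NumPy `default_rng`);
registration is deterministic by construction.  Degenerate inputs are
contracts, not surprises: all-zero images, empty mask lists, empty batches,
unreadable series and excluded patients each have a defined error or
captured-failure path, exercised by the tests.

## Known limitations

* Ellipsoid phantoms cannot detect shape-model failure on real anatomy;
  the atlas set shares its shape family with the subjects.
* The simplified polynomial bias model handles smooth low-order fields
  only; clinical-grade correction would use a finer spline field.
* The kNN feature set is intensity (optionally two channels); no spatial
  coordinates are included by default.
* Multi-frame (enhanced) DICOM and compressed transfer syntaxes are out of
  scope; classic single-frame little-endian only.
* The sequence decision table is a declared stand-in for unpublished
  thresholds and should be re-derived per archive before clinical use.
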