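# Methods

`hemlabel` transfers molecular labels from an immunohistochemistry (IHC)
slide onto its matched H&E slide and uses the transferred labels to train
a tile-level cancer classifier and estimate tumor purity. This note
documents the models, the parameters that matter, the synthetic data the
package validates itself against, and the numerical choices made where
the design was open.

## Stain model and color normalization

Transmitted light through stained tissue follows the Beer–Lambert law:
optical density `OD = -log10(I / I0)` adds linearly over stains,

    OD = C · S,

where the rows of the stain matrix `S` are unit color vectors in OD space
(hematoxylin and eosin for an H&E slide; hematoxylin, eosin and DAB for
the IHC slide) and `C` holds the per-pixel stain concentrations. The OD
transform uses `I0 = 255` after luminosity standardization and clamps
intensities to ≥ 1 before the log, so white maps exactly to OD 0 and the
transform inverts to within 8-bit rounding.

**Luminosity standardization** divides the LAB lightness channel by its
95th percentile (clipping at white). On a slide image the 95th percentile
sits in the empty-glass background, so background becomes white while
chroma is untouched. The operation is idempotent to within one intensity
unit.

**Stain-matrix estimation** runs on "tissue pixels", defined as pixels
whose *maximum* OD channel exceeds β = 0.15. The maximum matters: eosin
barely absorbs red light (red-channel OD component ≈ 0.07), so a
minimum-channel criterion would discard exactly the near-pure eosin
pixels that anchor the fit. Two estimators are available:

- `vahadane` (default): sparse non-negative dictionary learning with two
  atoms (sklearn `DictionaryLearning`, positive code and dictionary,
  sparsity weight λ = 0.1), on a seeded subsample of at most
  `max_fit_pixels = 10 000` tissue pixels, followed by five alternating
  non-negative least-squares sweeps. The polish is needed because the L1
  code penalty biases the learned atoms into the interior of the data
  cone; with it, stain vectors of a well-separated synthetic mix are
  recovered to ~0.015 rad (the SVD method below reaches ~0.002 rad).
- `macenko`: project tissue OD onto the top-two SVD plane and take the
  directions at the 1st/99th percentile angles.

Rows are rescaled to unit norm and ordered hematoxylin-first, identified
as the vector with the larger red-channel component (hematoxylin absorbs
red strongly, eosin transmits it — 0.65 vs 0.07 for the published
reference vectors; a blue/red-ratio rule would misorder them).

**Concentrations** solve `OD ≈ C · S` per pixel by exact non-negative
least squares (active-set enumeration, vectorized across pixels; exact
for k ≤ 3 stains).

**Normalization** re-mixes the source concentrations through the
template's stain matrix, `OD_norm = C_source · S_template`, after
rescaling each concentration channel so its 99th percentile matches the
template's (prevents saturation when source staining is weak or strong).
The template is the cancer-status slide whose mean (R, G, B) vector is
closest to the componentwise median over the cohort; ties break to the
lowest index. A pure-background image is returned unchanged — there is
nothing to re-color. Reinhard normalization (per-channel mean/std
matching in LAB) is included as the simpler alternative; identifiability
of the stain model is not required for it.

## Registration

The IHC image is aligned onto the H&E image; the H&E image is never
resampled. Both images are converted to grayscale (ITU-R 601 luminance
weights 0.299/0.587/0.114) and downscaled by `downscale` (default 5×,
anti-aliased) before fitting. The objective is mutual information of the
joint grayscale histogram,

    I(IHC, H&E) = Σ p(ihc, h&e) · log[ p(ihc, h&e) / (p(ihc) p(h&e)) ],

reported in nats from a 50-bin joint histogram. The fit itself runs
through SimpleITK with Mattes mutual information and a
RegularStepGradientDescent optimizer (learning rate 1.0, minimum step
1e-4, ≤ 200 iterations per level) in an 8/4/2/1 shrink pyramid with
3/2/1/0-px Gaussian smoothing. Plain (non-regular-step) gradient descent
stalled far from the optimum on smooth slide images and is not used.

The linear phase fits a rigid transform first and refines it with a full
affine; a direct 6-DOF affine fit was markedly less reliable (scale/shear
let the optimizer leave the correct basin), while rigid capture followed
by affine refinement recovers seeded rigid misalignments of up to 10° /
20 px to ~0.1° / 0.2 px. The refinement — and likewise the subsequent
B-spline phase — is kept only if it increases the measured mutual
information; otherwise the simpler transform stands. The B-spline phase
uses a control-point grid at 64-px spacing (refined once, 2× scale), 100
iterations, and seeded random sampling of 25% of pixels per metric
evaluation (dense sampling is ~6× slower with no accuracy gain on the
reference experiments). Resampling applies the same transform to each
RGB channel with linear interpolation; out-of-field pixels become white,
the color of empty glass.

## Stain separation and masks

Registered IHC images are unmixed with the published Ruifrok–Johnston
H/E/DAB unit vectors (config-overridable) by inverting the 3×3 stain
matrix — exact, and channels are returned unclipped so remixing is an
identity. Two Otsu stages produce the masks:

1. **Tissue**: hematoxylin OD over the whole image; the faint counterstain
   everywhere in tissue sits well above the glass background, making this
   split reliable. Otsu uses 256 bins over the observed range, maximizes
   between-class variance, and breaks ties toward the lower edge.
2. **DAB-positive**: a second Otsu on the DAB OD of tissue pixels only,
   computed independently per slide.

Otsu always splits its input, so a slide with *no* genuine DAB deposits
would otherwise have ~half of its tissue marked positive from background
noise. The guard: if the mean DAB OD of the putative positive class is
below `min_dab_od = 0.1`, the slide is declared to have no distinct
positive staining and the mask is left empty (with a warning). A genuine
chromogen deposit has OD far above this floor. The guard tests the class
mean rather than the threshold because on discrete noise-free data the
between-class variance is flat over a range of cuts and the tie rule
parks the threshold at the edge of the negative mode.

Per-tile tissue fractions reuse the slide-level hematoxylin-Otsu mask.
Otsu on a single tile is meaningless — it splits whatever it is given,
returning ~50% "tissue" even on pure background.

## Label transfer

The H&E image is cut into non-overlapping, fully contained 224 × 224-px
tiles (partial edge tiles are dropped, not padded — they would distort
per-tile fractions). Masks live on the registered IHC image at the
registration downscale, so each tile corresponds to a
`round(224 / 5) = 45`-px label tile there. Rules, in order of precedence:

1. **Tissue presence**: a tile where exactly one of the H&E/IHC pair has
   tissue (fraction ≥ `tissue_presence_min = 0.05`) is discarded as a
   probable registration artifact (`tissue_mismatch`); a tile where
   neither has tissue is background (`no_tissue`).
2. **Uncertainty band**: if the mean DAB OD over the tile's tissue pixels
   falls in `[dab_uncertain_low, dab_uncertain_high]` (defaults 0.05 and
   0.45), the tile is `uncertain` regardless of its positive fraction.
   With chromogen deposits near OD 1, a tile's mean DAB OD approximates
   its positive-area fraction, so the default band spans "clearly above
   faint background staining" to "majority positive": tiles in between
   are ambiguous cellular mixtures and are excluded from training and
   testing. Both bounds are user-selectable.
3. **The 2% rule**: otherwise the tile is `cancer` iff more than 2% of
   its label-tile pixels are DAB-positive (the fraction counts all
   pixels of the tile, not tissue pixels only), else `normal`.
4. **Slide filter** (training only): a cancer slide contributes only its
   cancer tiles, a non-cancer slide only its normal tiles; everything
   else is re-labeled uncertain with a recorded reason. This protects
   training from p53's known failure modes (positive staining in damaged
   normal cells, absent staining in deleted-TP53 tumors).

For evaluation against a pathologist annotation mask, a tile is cancer
when ≥ 50% of its area lies inside the annotation (config-exposed; "tile
enclosed by the annotation" is ambiguous at boundaries).

## Classifier

Transfer learning with a frozen feature extractor and a trainable head:
a 256-unit fully connected layer (ReLU) and a single sigmoid output,
trained with binary cross-entropy and Adam (lr 1e-3, batch 64) for 100
epochs, no early stopping. ImageNet CNN backbones (vgg16 — 512-d pooled
features — vgg19, resnet50, inceptionv3, xception) plug in when
tensorflow is available; the built-in `tiny` backbone is a deterministic
32-dimensional bank of pooled color, stain-channel (including nuclear-
density statistics from the hematoxylin channel) and texture features,
so the whole pipeline runs on a plain CPU without pretrained weights.
The head is a small numpy MLP; training is seeded and bit-reproducible.

Training tiles are augmented with their eight rotation/flip (dihedral)
variants, which inherit the tile's label — tumor content does not depend
on orientation. Classes are balanced before training by subsampling the
dominant class (seeded), the same strategy applied before evaluation
metrics, which keeps the sigmoid's operating point near 0.5 under equal
priors. Prediction warns when the input tiles' mean color is far from
the training tiles' (likely un-normalized input).

## Evaluation and purity

Accuracy, a confusion matrix (rows = truth, columns = prediction,
classes ordered normal/cancer) and ROC AUC are computed after balancing;
AUC equals the probability that a random positive outranks a random
negative, ties counted half (verified against a brute-force pairwise
oracle in the tests). Slide-level tumor purity is the tissue-area-
weighted cancer fraction

    purity = Σ 1[p_cancer > 0.5] · tissue_fraction / Σ tissue_fraction

over tiles with positive tissue fraction — a half-background tile
contributes half a tile of area. Tile calls are binarized at 0.5 by
default; probabilistic weighting is available behind a flag.

## Synthetic data: what it emulates, and what it does not

The generator renders adjacent-section pairs from a known forward model
so every stage has exact ground truth:

- **Geometry**: tissue and cancer regions are thresholded smooth Gaussian
  random fields. Region correlation length is 110 px — tumor regions in a
  colorectal section span millimeters, i.e. many 224-px tiles at ×10 —
  against a default 1024 × 1024 desk-scale image. Thresholds are set at
  the quantile matching the requested tissue fraction (0.55) and
  cancer-area fraction, so requested purity is hit to rasterization
  tolerance.
- **Stains**: a nuclear-density field at 9-px (cellular) scale drives
  hematoxylin, with eosin anti-correlated (nuclei vs stroma/cytoplasm)
  and nuclei covering roughly a quarter of the tissue area; baseline
  hematoxylin in stroma stays well above glass background so Otsu tissue
  detection has a clean gap. Mean concentrations: hematoxylin 0.6, eosin
  0.35, DAB 1.0 OD in cancer regions plus 0.02 faint background within
  tissue. Cancer regions get +0.35 nuclear density (hypercellularity).
  The elevation is in *density*, not per-nucleus stain strength: a global
  stain boost would be cancelled by the per-slide 99th-percentile
  concentration rescaling during normalization, whereas hypercellularity
  — like real tumor morphology — survives it.
- **Optics**: concentrations are blurred by a 1.5-px Gaussian PSF
  (microscope resolution / section thickness), images rendered through
  Beer–Lambert mixing with additive Gaussian OD noise (sd 0.02,
  multiplicative in intensity), background white.
- **Misalignment**: rotation about the image center plus translation
  (defaults 2°, (8, −6) px), optional isotropic scale and a smooth
  sinusoidal displacement field; applied to the IHC image with white
  fill. The truth object carries the aligning transform.
- **Cohorts**: per-slide stain matrices are randomly perturbed to
  exercise normalization; training cohorts use five cancer + five normal
  pairs.

What the generator does **not** emulate: nucleus-level morphology and
chromatin texture, glandular architecture, staining artifacts (folds,
bubbles, pen marks), out-of-focus regions, true biological differences
between adjacent sections, and p53's biological failure modes
(TP53-deleted tumors, stressed normal cells). Passing the end-to-end
tests therefore demonstrates that the pipeline machinery — normalization,
registration, mask extraction, the labeling rules, training and the
purity estimator — is correct and internally consistent under a faithful
forward model; it does not certify classifier performance on real
histology, which depends on morphological signal far richer than the
tiny backbone's statistics.

## Reference experiment sizes

The validation experiments are sized for minutes on one CPU: rigid
recovery on twenty 256-px pairs at fitting resolution; variance reduction
on a ten-slide 512-px cohort; the end-to-end study on 1120-px slides
(5 × 5 tile grid) with a ten-slide training cohort and ten held-out
slides spanning purities 0.1–0.8; oracle purity recovery on 2240-px
slides (10 × 10 grid), three per target fraction, where tile quantization
error is small against the ±0.05 criterion.

## Known limitations

- The rigid-first linear phase assumes misalignments within roughly ±15°;
  gross rotations (slide mounted sideways) need a manual initialization.
- Vahadane fitting assumes both stains are well represented; a slide that
  is essentially single-stain raises a rank error rather than returning a
  degenerate matrix.
- The uncertainty band defaults assume DAB deposits near OD 1; markedly
  weaker chromogens need the user-selectable bounds adjusted.
- GrabCut tissue segmentation (a selectable alternative for the
  presence check) requires OpenCV, which is an optional dependency; the
  deterministic hematoxylin-Otsu default is used throughout.
- SVS/pyramidal reading goes through tifffile; vendor-specific SVS
  metadata (MPP, magnification) is not parsed.
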