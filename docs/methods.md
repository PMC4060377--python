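# Methods

This note documents the models, parameters and design decisions behind
`clift_cad`, in the order the pipeline runs.

## Problem and data model

A CLIFT slide carries one well per serum. Because a single microscope field
does not cover the well, each well is acquired as several images (default
emulation: 5), each showing several *Crithidia luciliae* cells (mean 8).
Serum status is a property of the well, so every image of a well inherits
the well's ground-truth label — an image of a positive well whose visible
cells happen to lack a stained kinetoplast is still labeled positive. Cell
labels are independent of this: a cell is positive iff its kinetoplast is
stained. This mismatch between levels is deliberate; it is exactly what the
majority-voting hierarchy has to absorb.

Two magnification scales are supported, expressed as a single
`magnification_scale` (1.0 = reference 50-fold optics, 0.5 = 25-fold).
Every length parameter downstream is multiplied by this scale, and every
texture feature is computed on crops resampled to a fixed physical size, so
the pipeline is nominally magnification-free.

## Synthetic data generator

The generator emulates the statistical structure of a CLIFT acquisition,
not its optics (no PSF, no vignetting, single channel). Per image:

| quantity | model | default |
|---|---|---|
| cells per image | Poisson truncated at ≥ 1 | mean 8 |
| cell body | filled rotated ellipse, aspect 2.5 | length ~ N(40·s, 6·s) px |
| cytoplasm intensity | Uniform | 0.15–0.30 |
| kinetoplast | Gaussian spot at 0.35·length from center along the major axis | σ = 2.5·s px, peak 0.9 |
| nucleus (distractor) | Gaussian at cell center, prob. 0.6 | σ = 10·s, peak U(0.35, 0.50) |
| basal body (distractor) | Gaussian spot 3σ_k from the kinetoplast site, prob. 0.3 | σ = 1.5·s, peak U(0.5, 0.7) |
| artifacts (distractor) | Poisson-many speckles outside all cells | mean 1/image, σ U(1, 3), peak U(0.6, 1.0) |
| background, noise | constant + i.i.d. Gaussian, clipped to [0, 1] | 0.05, σ = 0.02 |

(`s` = magnification scale.) In a positive well each cell carries a
kinetoplast with probability 0.9. Rendering is additive with a final clip
at 1.0; images are written as 8-bit grayscale PNG. All randomness flows
from one `numpy` Generator seeded by `SynthConfig.seed`, so a dataset is
reproducible byte-for-byte.

Cells are placed by rejection sampling with a minimum boundary gap of
`max(5, 4.8·σ_k·s)` px between body ellipses (≤ 100 retries, then overlap
is accepted). The gap matters: the nucleus halo fluoresces beyond the body
ellipse, and bodies closer than the halo width fuse during downstream
segmentation, which would silently turn two annotated cells into one crop.
Artifacts are placed outside all cell bodies on purpose, so the
"extracellular candidate" rejection path is exercised.

What passing tests on this generator do **not** show: robustness to uneven
illumination, focus drift, touching/overlapping cells, chromatic noise, or
staining-intensity variation between laboratories. The generator's
separability is also kinder than patient data — cell-level accuracy near
99 % here versus ~94 % reported on real material is expected, and the
meaningful checks are the invariants (zero screening false negatives,
hierarchical error recovery, magnification robustness), not the absolute
accuracy.

## Screening (candidate kinetoplast detection)

1. Subtract the per-image median (ambient background) and clip at 0.
2. Subtract a Gaussian-blurred copy (σ_bg = 2 × 2.5·s px = twice the
   nominal kinetoplast σ) and clip at 0. This removes the cytoplasm
   pedestal and most of the broad nucleus blob; without it no global
   threshold separates a spot riding on a bright cell body from the body
   itself.
3. Threshold at `max(μ + 4σ, 0.15)`, statistics of the corrected image.
   The adaptive part tracks exposure and clutter; the absolute floor
   (intensities are calibrated to [0, 1]) keeps near-empty fields from
   collapsing the threshold below the faint cell-edge residue of step 2.
4. 8-connected components, kept when area ∈ [0.25, 6] × π(2.5·s)² and
   compactness 4πA/P² ≥ 0.4. The upper area gate is 6 (not ~4) because a
   Gaussian spot of scale σ thresholded at 1/8 of its peak covers
   2πσ²·ln 8 ≈ 4.2 πσ²; 6 leaves margin while still rejecting whole cell
   bodies (~25 πσ²). The compactness gate rejects elongated streaks.

Candidates are sorted by peak intensity (ties by centroid) so downstream
order is deterministic. A constant image returns no candidates. An image
with no candidates is *presumed negative* and never reaches the
classifier; candidates only make an image "presumed positive" — the
classifier decides whether they are kinetoplasts.

## Cell localization and crops

Around each candidate a window of 3 × expected cell length (40·s px) is
segmented: 3-class multi-Otsu on the median-subtracted window, lowest
boundary, then morphological closing (disk radius 2). Plain Otsu fails
here — the window histogram is tri-modal (background / cytoplasm / bright
spot) and Otsu often splits cytoplasm from spot instead of background from
cell. The connected component containing (or within 5 px of) the candidate
is the body; candidates farther than that are discarded as extracellular
artifacts (a kinetoplast is an organelle). Bodies whose major axis is
outside [0.4, 2] × expected cell length are rejected too: below, the
"body" is an artifact speckle; above, it is a sprawling noise blob from a
cell-free window. A body claimed by several candidates yields **one** crop
holding all of them, so multi-spot cells are judged once.

Each crop is resampled (bilinear; nearest for masks) so the body major
axis is ≈ 64 px. All texture parameters below therefore see a fixed
physical scale regardless of magnification.

Specialist annotations (one point per cell at its centroid) label a crop
when the point falls inside the body mask; overlap ties go to the nearest
body centroid, and unmatched annotations are counted and logged.

## Features (60 per cell, fixed order)

* **Histogram (5)** — fraction of body pixels > θ_hf = 0.7, max, mean, std,
  entropy of a 32-bin histogram (bits). θ_hf targets the kinetoplast's
  near-saturating brightness; nucleus peaks sit well below it, basal
  bodies straddle it (by design — they are the hard distractor).
* **GLCM (10)** — contrast, correlation, energy, homogeneity, entropy at
  distances {1, 2}, averaged over the four axial/diagonal directions,
  32 gray levels, pixel pairs restricted to the body mask, symmetric and
  normalized. Degenerate cases: a single-level matrix has correlation 1,
  energy 1; a distance with no valid pair yields zeros (logged).
* **Fourier (9)** — energy fractions in 8 equal radial annuli (radius 1–32)
  of the centered 64×64 power spectrum, DC excluded, plus the spectral
  centroid radius. More fluorescent objects in a cell push energy to
  higher spatial frequency. An all-zero crop reports nine zeros.
* **Circular LBP (28)** — rotation-invariant uniform LBP at (P=8, R=1)
  → 10 bins and (P=16, R=2) → 18 bins, computed on the 8-bit quantized
  crop, histogrammed over the body interior (2-px erosion) and normalized
  to sum 1. Rotation invariance removes cell-orientation nuisance and is
  exact under right-angle rotations.
* **Morphology (8)** — on the brightest candidate: area / body area,
  eccentricity, solidity, compactness, mean-intensity ratio vs body
  (denominator guarded at 1e-6), peak intensity, centroid offset / body
  major axis, candidate count.

Scale-dependent quantities are ratios or fractions throughout, which is
what makes the 25×/50× accuracies land within a couple of points of each
other.

## Cell classifier

`CellClassifier` is a scikit-learn estimator: standardization (z-scores
from training data only; zero-variance features keep scale 1 and are
flagged) followed by an RBF-kernel SVM with class weights inversely
proportional to class frequency (cell classes are imbalanced, ~62/38 in
the reference material). Hyperparameters are chosen by inner stratified
5-fold CV maximizing balanced accuracy over C ∈ {0.1, 1, 10, 100} and
γ ∈ {0.25, 0.5, 1, 2, 4}/n_features; ties resolve to the smallest C, then
the smallest γ (the grid iterates C-major). Everything is deterministic
given the seed.

Evaluation is one-well-out CV: the fold testing well *k* trains on all
other wells, so cells of one serum never straddle the train/test split;
scaling and hyperparameter search are refit per fold. Folds whose training
set collapses below the contract (two classes, ≥ 10 cells each) are
skipped with a warning rather than silently mis-trained.

## Voting and suspension

Image = majority of its cell labels; an exact tie resolves **positive** —
screening is already biased against false negatives, a positive tie-break
keeps that orientation, and the well vote can still recover it. An image
pre-screened negative is negative without classification, and an image
whose every candidate proved extracellular is negative (nothing
intracellular fluoresced). Well = majority of its image labels; an exact
tie **suspends** the decision, which is emitted as its own outcome and
never silently resolved — the operator decides.

## Metrics

Confusion counts are tabulated with suspended decisions kept out of the
binary cells: a suspension counts in the denominator of accuracy and of
its true class's rate (sensitivity for a suspended positive, specificity
for a suspended negative) but never in precision. With no suspensions all
four metrics reduce to their textbook forms. Percentages are computed from
integer counts and rounded half-up to one decimal; rounded values are
never chained.

## Problem sizes used in the checks

The end-to-end evaluation runs one-well-out CV on a 30-well generated
dataset (150 images, ~900–1000 labeled cells) and the magnification
comparison on two 12-well datasets; both finish in a few minutes on one
CPU. Larger runs change nothing qualitatively — accuracy on this generator
saturates near the ceiling well before 30 wells.

## Known limitations

* The cell-localization procedure is a reconstruction; alternative
  segmentations (e.g. watershed on touching cells) are out of scope.
* Serum titer / dilution estimation is not addressed.
* The screening floor (0.15) presumes the [0, 1] intensity calibration of
  8/16-bit input; heavily under-exposed material would need the floor
  lowered via `ScreeningParams`.
* Suspended wells are counted against accuracy and sensitivity; other
  scoring conventions exist and would change the reported numbers.
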