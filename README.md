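# clift-cad

Computer-aided classification of **Crithidia luciliae immunofluorescence
test (CLIFT)** wells.

CLIFT is the indirect immunofluorescence assay used to detect anti-dsDNA
antibodies, a serological marker of systemic lupus erythematosus. The
antigen is the **kinetoplast** of the hemoflagellate *C. luciliae* — a
mitochondrial organelle packed with naked circular dsDNA. In a positive
serum the kinetoplast lights up as a small, very bright, compact spot near
one pole of the elongated cell body; the cell nucleus, the basal body and
slide artifacts can also fluoresce and mislead a reader. This package is
for laboratory-automation and medical-image-analysis work: it implements a
full multi-step recognition system for CLIFT wells, plus a synthetic image
generator so the system can be trained and evaluated with no patient data.

## Method

A well (one serum) is photographed as several non-overlapping fields
("images"), each showing a handful of cells. Classification is hierarchical:

1. **Screening** — candidate kinetoplast regions are detected by
   thresholding a background- and pedestal-corrected image at
   μ + k·σ (k = 4) with area and compactness gates
   (compactness = 4πA/P²). An image with no candidate is labeled negative
   outright; this step is designed never to lose a true positive.
2. **Cell classification** — each candidate's host cell is localized,
   segmented and resampled to a fixed physical scale (64-px major axis).
   A 60-dimensional feature vector is computed per cell: intensity
   histogram (5), gray-level co-occurrence texture (10), radial Fourier
   energy (9), rotation-invariant uniform circular LBP (28), and
   morphology of the brightest candidate (8). An RBF-kernel SVM with
   class weights inverse to class frequency assigns *positive* /
   *negative* per cell; C and γ are chosen by inner stratified 5-fold CV
   maximizing balanced accuracy.
3. **Voting** — each image takes the majority label of its cells; each
   well takes the majority label of its images, and **suspends** the
   decision (defers to the physician) when the image votes tie exactly.

Evaluation uses **one-well-out cross-validation** (cells of one well = test
set) and reports accuracy, sensitivity, specificity and precision at cell,
image and well level, with suspended wells counted in the denominators of
accuracy and of their own class's rate but never as correct calls.

## Worked example

```sh
clift-cad generate --seed 11 --wells 12 --out demo
clift-cad crossval --manifest demo/manifest.json --seed 11
```

which prints (one-well-out CV over 12 synthetic wells, ~340 labeled cells):

```
level,accuracy,sensitivity,specificity,precision
cell,99.5,100.0,98.6,99.2
image,100.0,100.0,100.0,100.0
well,100.0,100.0,100.0,100.0
```

Reading: 99.5 % of individual candidate-bearing cells were labeled
correctly; majority voting absorbed the remaining cell-level errors, so
every image and every well was classified correctly — the hierarchical
error recovery the architecture is built for. Other verbs: `screen`
(per-image candidate counts), `features` (per-cell CSV), `train` /
`predict` (fit a model, classify new wells with a full per-cell /
per-image / per-well audit trail), `evaluate` (score predictions).

Library use mirrors the CLI; the cell classifier is a scikit-learn
compatible estimator:

```python
from clift_cad import CellClassifier, generate_dataset, SynthConfig, hierarchical_cv

manifest = generate_dataset(SynthConfig(seed=11, n_wells=12), "demo")
result = hierarchical_cv(manifest, seed=11)
print(result.cell_accuracy, result.image_accuracy, result.well_accuracy)
```

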