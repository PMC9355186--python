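# Methods

## The screening model

The package treats strabismus screening as binary classification of a
frontal photograph into *normal* vs *strabismic*, driven by two kinds of
evidence:

* **geometric position features** read directly off the image — the
  position-similarity ratio S and the Hirschberg corneal-light-reflex
  (CLR) ratio — which encode ocular alignment explicitly; and
* **learned embedding features** of the eye-region raster, reduced by
  PCA, which capture appearance structure the geometry misses.

Both are fused into a 7-dimensional vector (five principal components,
S, CLR ratio), standardized, and classified by a linear support vector
machine. Because clinical cohorts in this setting are tiny (tens of
images), evaluation uses a repeated-split protocol: each experiment
draws 15 training and 15 test subjects per class without replacement,
refits everything on the training half, and scores the held-out half;
the reported metrics are means over many such splits with
normal-approximation 95% confidence intervals (mean ± 1.96·SE).

### Position similarity

With R₁, R₂ the Euclidean distances from the right pupil centre to the
medial and lateral canthus and L₁, L₂ the analogous left-eye distances,

S = max(R₁/R₂, L₁/L₂) / min(R₁/R₂, L₁/L₂).

S ≥ 1 always; S = 1 for perfectly symmetric fixation. The ratio of
ratios cancels global scale and is invariant under rigid motion of the
landmark set, so no camera calibration is required. Index convention:
the first distance of each pair is to the medial canthus. Distances are
Euclidean (not horizontal-only), matching the drawn geometry of the
measurement.

### CLR ratio and imputation

Each eye's medial corneal limbus is taken one iris radius from the pupil
centre along the horizontal axis toward the nose. With D₁, D₃ the
distances from the detected reflex centroids to the medial limbus and
D₂, D₄ the iris diameters, the ratio is (D₁+D₃)/(D₂+D₄): exactly 0.5
for centred reflexes, 0.448–0.488 in orthotropic eyes by the published
reference bands (abnormal below 0.440 or above 0.497).

Subjects photographed without a pen torch have no reflex. Training
images are imputed from their labels: 0.468 (the normal-band midpoint)
for normal, 0 for strabismic. Test images must be imputed label-free:
the criterion is the midpoint between the largest training-normal S and
the smallest training-strabismic S, and a test image with S at or below
the criterion receives 0.468, otherwise 0. The boundary is inclusive
(S = criterion → 0.468). Reading "the median value between the maximum
… and the minimum …" of two scalars as their midpoint is the only
sensible interpretation and is fixed here.

### Iris segmentation and circle fitting

The per-eye chain: luma grayscale (0.299, 0.587, 0.114 weights); an
Otsu dark-foreground mask (threshold by explicit search over all 255
split points of the 256-bin histogram, maximizing between-class
variance, smallest argmax on ties); an HSV gate [0,0,0]–[180,255,v]
with v the rounded mean gray of the crop, inclusive upper bound, which
for the H and S bounds used reduces to value ≤ v; the two masks ANDed;
connected components below 1% of the crop area removed (eyelash/noise
cleanup — a pragmatic choice, not part of the core measurement);
per-column bottom-to-top first-hit sampling of the lower limbus arc; and
a Kåsa algebraic least-squares circle fit minimizing
Σ(x²+y²+Dx+Ey+F)², closed-form and deterministic, with RMS radial
deviation reported. A Gauss–Newton geometric refinement
(`refine_circle_geometric`) is available but not default: on rasterized
limbus arcs the algebraic fit is within a few hundredths of a pixel of
the geometric optimum.

Only the lower arc is sampled because the upper limbus is routinely
covered by the eyelid; the fitted circle is insensitive to occlusion
fractions up to at least 0.4 of the iris height.

Reflex detection searches for bright pixels *enclosed by* the dark iris
mask (hole-filling the mask, intersecting with the fitted disc) and
applies Otsu with bright polarity there. Enclosure matters: eyelid skin
overhanging the limbus and sclera admitted by a slightly-too-large
fitted circle are connected to the image background and are excluded,
where a purely geometric disc test would sweep them in and either fake
a reflex or drown the real one. A bright class is accepted as a reflex
only if it covers ≥ 2 px and ≤ 10% of the disc; otherwise the reflex is
reported absent (a value, not an error).

### Embedding and PCA

The embedding provider maps an 84×84 RGB raster to a feature vector.
The interface mirrors a ResNet-12 few-shot embedding network (12,800-d
output, declared as `RESNET12_OUTPUT_DIM`); training such a network is
prior work at GPU scale and out of scope, so the default provider is a
seeded Gaussian random projection of the centred gray pixels —
deterministic across processes, and sufficient to carry the
iris-position signal into the classifier. External providers register
by name; nothing downstream assumes any particular dimension beyond
k + 1 samples of it.

PCA is mean-centred, computed by full SVD, keeping k = 5 components by
default. Sign ambiguity is fixed by requiring each component's
largest-magnitude entry to be non-negative, making fits bit-for-bit
reproducible. PCA is refit per experiment on the 30 training embeddings
only — never globally — to keep test information out of the fitted
basis. `choose_k_by_eigenvalue` implements the Kaiser rule (components
with eigenvalue > 1 on column-standardized data) as a diagnostic; k = 5
is the default because five components exceed the Kaiser bound on the
embedding scree, and the diagnostic is not on the default path.

### Classifier and protocol

Linear kernel, C = 1 (the reference protocol never states kernel or
regularization; both are exposed). A decision score of exactly 0 is
classified strabismic — the sensitivity-favoring tie rule, since a
missed strabismic costs more than a false referral in screening.
Per-experiment seeds derive from the base seed as
`SeedSequence(base_seed, spawn_key=(i,))`, so experiment i is re-runnable
in isolation and the whole evaluation is reproducible bit-for-bit.
Under the balanced 15/15 test split, per-experiment accuracy equals
(sensitivity + specificity)/2 exactly. With a single experiment the CI
degenerates to a zero-width interval at the point estimate.

## The synthetic-data generator

`synthetic_eye` renders what the screening photographs contain, reduced
to what the measurements actually touch: uniform skin (gray 200), two
palpebral ellipses of sclera (180) with half-axes 0.14·W × 0.24·H at
rest centres (0.25·W, 0.5·H) and (0.75·W, 0.5·H), a dark iris disc
(60, radius 18 px at the default 360×140 geometry), an optional reflex
dot (250, radius 2 px), optional eyelid occlusion of the upper limbus,
and optional additive Gaussian noise. Rendering is a pure function of
the scene spec (seed included) and is not anti-aliased by default, so
the set of pixels darker than the sclera is *exactly* the iris disc and
segmentation oracles are pixel-exact; a smoothing flag exists for
robustness experiments. Sides are anatomical: the subject's right eye
is on the image's left.

A scene is labelled strabismic when the larger per-eye deviation
magnitude exceeds 5 px — a declared threshold standing in for an
ophthalmologist's judgement. Cohort defaults mirror the reference study
conditions: 30 + 30 subjects; normal scenes draw per-component fixation
jitter uniform in ±1.2 px (magnitude ≤ 1.7 px); strabismic scenes
deviate one eye by a magnitude uniform in 7–14 px along a direction
within 35° of horizontal (eso-/exotropia with a small vertical
component — the cone also guarantees the iris stays inside the
palpebral opening at every sampled magnitude); the deviated eye's
reflex is displaced by −0.4× the deviation (the reflection tracks the
torch, not the rotated globe), clipped to keep ≥ 2.5 px of limbus
clearance; eyelid occlusion 0.15; and the missing-reflex mix is
realised exactly per class (8 of 30 normal, 13 of 30 strabismic in the
reference composition).

What the generator does **not** model: iris texture, skin-tone and
illumination variability, eyelashes, head pose, camera optics, and the
biological relation between deviation angle and reflex displacement in
millimetres. Passing tests therefore demonstrate that the measurement
chain recovers known geometry and that the protocol machinery is
correct and leak-free — not that the classifier's accuracy on these
scenes transfers to clinical photographs, whose headline numbers depend
on a private clinical dataset and a pretrained embedding and are out of
scope here.

## Numerical choices and degenerate inputs

* Otsu on a constant image raises (no valid threshold); reflex
  detection on a constant disc returns "absent".
* Circle fitting requires ≥ 3 non-collinear points; collinear input
  raises a singular-system error; fewer than 3 sampled limbus columns
  raises before fitting.
* Standardization uses population (ddof = 0) statistics so transformed
  training columns have sd exactly 1; a constant column is detected via
  `ptp == 0` as well as `sd == 0`, because identical float values can
  leave sd ≈ 1e-17 after mean subtraction; the offending dimension is
  named in the error.
* `fit_pca` rejects k above the centred-data rank; eigenvalues are
  sample variances (ddof = 1) so their sum equals total variance.
* Crop boxes are landmark bounding boxes expanded 25% per side, clipped
  to the image; resizing to 84×84 is direct bilinear without aspect
  preservation; an already-84×84 crop passes through unchanged.
* The 500-experiment default in tests and the acceptance script (vs the
  reference 5,000) keeps Monte-Carlo error on mean accuracy below ~0.01
  while the full protocol remains available via `n_experiments`.
* The label-randomization null averages over ten independent shuffles
  of 50 experiments each: a single shuffle retains chance feature–label
  association across every split and can sit several points from 0.5.

## Known limitations

* The heuristic landmark detector is built for synthetic-style
  intensity structure (dark iris, sclera/skin contrast) and is not a
  face detector for photographs; real images should use an external
  landmark provider behind the same interface.
* The renderer's reflex-displacement model (−0.4× deviation, clipped)
  is a geometric convenience, not Hirschberg millimetre calibration.
* The CLR criterion assumes training normal/strabismic S ranges
  overlap at most mildly; heavily overlapping cohorts make test-phase
  imputation noisy (by design — the rule is label-free).
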