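# Methods

## Problem and model

`somroi` delineates data-driven regions of interest (ROIs) in co-registered
structural brain tissue maps and scores their relevance for separating two
subject groups (e.g. controls vs Alzheimer's disease). Inputs are
per-subject grey-matter (GM) and white-matter (WM) probability maps on a
common voxel grid, values in [0, 1], plus a binary label per subject. The
method never consults an anatomical atlas: ROIs emerge from vector
quantization of the data themselves.

The pipeline, per tissue:

1. **Voxel statistics.** Per-class mean images μ_c and variance images
   σ²_c (population convention, divide by N_c; configurable to sample
   variance), and the voxel-wise Fisher Discriminant Ratio

       FDR = (μ₁ − μ₂)² / (σ₁² + σ₂² + ε),

   the classical two-class separability score (unrelated to the
   false-discovery rate). ε = 1e−12 keeps zero-variance voxels finite;
   FDR is defined as 0 when the numerator is 0.

2. **Feature space.** The difference image D = μ_control − μ_patient is
   computed, and every in-brain voxel contributes a 4-D vector
   (x, y, z, d): its grid coordinates and its difference intensity.
   Coordinates are scaled to [0, 1] per axis (divide by grid_dim − 1);
   d is min–max scaled to [0, 1] over the mask and multiplied by
   `d_weight` (default 1.0), the knob balancing spatial compactness
   against intensity homogeneity of the ROIs. A constant D is a documented
   degenerate case (d ≡ 0). The in-brain mask keeps voxels whose pooled
   mean tissue probability ≥ `p_min` (default 0.05), emulating
   skull-stripped input. The signed difference is the default; an
   absolute-value mode exists.

3. **Self-organizing map.** A 3-D-lattice SOM (default 6×6×3 = 108 units,
   cylindrical topology — the first lattice axis wraps) quantizes the
   feature vectors. Online training: for each sample x, the best matching
   unit (BMU) c = argmin_i ‖x − w_i‖ is found (ties to the lowest index)
   and every prototype moves by

       w_i ← w_i + α(t) · exp(−d_lat(c,i)² / 2σ(t)²) · (x − w_i),

   with reciprocally decreasing learning rate α(t) = α₀ / (1 + t/T).
   Two phases: rough ordering (α₀ = 0.1, σ₀ = max(lattice)/2 decaying
   linearly to 1.0, 10 epochs) then fine-tuning (α₀ = 0.01,
   σ₀ = max(lattice)/8 decaying to 0.5, 20 epochs). Initialization is
   "linear" by default: lattice coordinates mapped affinely onto the
   spatial bounding box, d channel at mid-range; a seeded "random" mode
   draws uniformly in the bounding box. Samples are presented in a seeded
   shuffled order each epoch; `subsample` caps the vectors drawn per epoch.
   Every update is a convex pull, so prototypes stay in the bounding box of
   initialization and data, and training is bit-reproducible from the seed.

4. **ROIs and relevance.** The receptive field of unit i — the voxels whose
   BMU is i — is ROI i; receptive fields partition the mask, and empty ones
   are legal (size 0), keeping the feature dimensionality fixed at M.
   ROI relevance combines intensity and discriminative power:

       r_i = Σ_{v ∈ RF_i} weight(v) · FDR(v)      [ / |RF_i| ]

   At training time `weight` is the difference image; for per-subject
   projection it is the subject's own tissue map, giving an M-vector of
   features per subject per tissue. Size normalization (the bracketed
   division) is on by default so scores are comparable across unequal
   receptive fields; both modes are exposed because the exact combination
   of cluster size and significance is a design choice here. ROI maps can
   be restricted to voxels whose FDR exceeds a fraction (e.g. 0.9) of the
   FDR maximum; the comparison is strictly greater-than, making
   fraction = 1.0 a well-defined empty restriction.

5. **Classification.** Per subject, GM and WM projection vectors are
   concatenated (2M features) and fed to an RBF-kernel SVM. Evaluation is
   stratified 10-fold cross-validation; within each fold all learned
   objects — statistics, FDR, difference image, mask, SOM, ROI map, feature
   scaling, SVM hyperparameters — are fitted on the training portion only.
   (C, γ) are chosen by stratified 5-fold inner grid search
   (C ∈ {0.1, 1, 10, 100}, γ ∈ {0.1, 1, 10}/n_features). Metrics are
   accuracy, sensitivity and specificity (positive class = disease),
   reported mean ± sd across folds; pooled decision scores give the ROC
   curve and a Mann–Whitney rank AUC (ties counted ½). Baselines:
   voxels-as-features (VAF; all in-mask intensities, optionally
   block-averaged, no selection) and PCA (per-voxel standardization, then
   projection onto the components explaining ≥ 95% of training variance).

### Feature scaling for the SVM: a deliberate deviation from z-scoring

The SVM pipeline scales the feature matrix by a *single* training
statistic — the pooled standard deviation of all entries — rather than
standardizing each feature to unit variance. The relevance features carry
the method's voxel selection in their *magnitudes*: ROIs overlapping
discriminative voxels have FDR-inflated values orders of magnitude above
irrelevant ROIs. Per-feature z-scoring equalizes those variances and
erases exactly this selection, after which the few informative ROIs drown
among the many noise ROIs in the RBF distance (on phantoms this collapses
cross-validated accuracy to chance). One global factor conditions the
kernel's length scale without touching relative magnitudes, and keeps the
classifier invariant to duplicating feature columns or rescaling all
features by a constant. The PCA baseline retains per-voxel
standardization, which is part of that method's definition.

## Phantom generator

The phantom emulates what the pipeline assumes of segmented, co-registered
data — not anatomy:

- a seeded low-frequency Gaussian random field (length scale
  `baseline_smoothness`, default 4 voxels), min–max rescaled to
  [0.2, 0.9], serves as the tissue baseline, shared by both classes and
  keeping masks and FDR denominators well conditioned;
- class-1 ("disease") subjects lose `effect_size` probability units inside
  each planted sphere of the matching tissue, so the control-minus-patient
  difference image is positive there;
- independent Gaussian noise (sd `noise_sd`) is added per subject after
  the effect, then values are clipped to [0, 1].

Default study condition: 32³ grid, 40 subjects per class, one GM sphere of
radius 4 voxels and effect 0.4, noise sd 0.05. These sizes make a full
10-fold evaluation run in tens of seconds on one core while leaving the
lesion-to-noise geometry qualitatively comparable to group-level atrophy
mapping. Features of real data the phantom does not emulate: anatomy and
tissue covariance structure, registration error, partial-volume effects,
spatially correlated noise, diffuse or bilateral atrophy, site effects.
Passing tests therefore demonstrate the machinery's correctness and its
ability to recover compact planted effects — not clinical performance.

## Numerical and design choices

- **Variance convention**: population (1/N); the conventional form for the
  discriminant ratio. `ddof=1` available.
- **BMU ties**: lowest unit index, exactly (first-minimum argmin); the
  vectorized assignment path uses the same arithmetic as the scalar path.
- **σ(t)**: linear decay within each phase from σ₀ to a floor (1.0 rough,
  0.5 fine); α(t) reciprocal with T = steps in the phase.
- **qe_history**: entry 0 is the quantization error of the initial
  prototypes over the full feature space; entry e ≥ 1 is the error over
  the vectors presented in epoch e, after that epoch's updates (cheap
  under subsampling, and an unbiased per-epoch sample of the full error).
- **`subsample = 1024`** vectors/epoch is the classification pipeline's
  default, decoupling SOM cost from grid size; `None` uses every vector.
- **Seeds**: every entry point takes one seed; internal consumers (per-fold
  SOMs, inner CV) derive children via `numpy.random.SeedSequence`, so runs
  are bit-reproducible end to end.
- **Degenerate inputs**: empty mask, empty class, single-class labels,
  grid mismatches and scaling mismatches raise informative errors;
  constant difference images and empty receptive fields are handled as
  documented above.
- **NIfTI affines** are carried through unchanged but never interpreted;
  all geometry is 0-based voxel indices on the common grid.

## Calibration behaviour under the null

On effect-free phantoms the cross-validated accuracy of the full pipeline
averages slightly *below* 0.5 (≈ 0.48 over 20 cohorts of 80 subjects).
Mildly below-chance accuracy is a documented property of small-sample
cross-validation when feature extraction is refit within each training
fold: held-out subjects are anti-correlated with training-fold statistics.
The deviation stays well inside the binomial fluctuation band of the
pooled decisions and should be kept in mind when interpreting accuracies
near chance on small cohorts.

## Known limitations

- Two classes only; the multi-class extension of the discriminant ratio is
  out of scope, as is multiple-testing correction of FDR maps.
- One intensity channel per feature space: GM and WM are modelled
  separately and only combined at the classifier.
- Online (per-sample) SOM training only; no batch or growing variants.
- The phantom's planted effects are spheres with sharp boundaries; smooth
  or anisotropic lesions are not generated.
- No preprocessing of any kind (registration, segmentation, bias
  correction, skull stripping): the package consumes already-segmented,
  co-registered probability maps.
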