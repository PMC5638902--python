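# Methods

This note documents the models, defaults and design decisions behind
`pvcnet`, in the spirit of a package's methods appendix: what is computed,
under which assumptions, and what a passing test does and does not establish.

## Acquisition model

The observed PET volume is modeled as the true tracer distribution convolved
with a spatially invariant isotropic Gaussian PSF, plus additive Gaussian
noise clipped at zero:

    observed = (true * h) + ε,   ε ~ N(0, σ²) i.i.d. per voxel, then max(·, 0)

* **FWHM** — default 6 mm. Scanner resolution for amyloid PET is typically
  5–6 mm FWHM; the effective post-harmonization value for multi-scanner data
  is not published, so 6 mm is a configurable stand-in.
* **Kernel sampling** — the Gaussian is sampled on the voxel grid, truncated
  at 4 SD per axis, and renormalized to sum exactly 1, so convolution
  conserves total activity (testable to < 0.5%).
* **Boundary rule** — half-sample symmetric ("reflective") padding. For a
  symmetric kernel this operator is *exactly self-adjoint* (it is
  diagonalized by the DCT-II basis), which the least-squares gradients in
  both deconvolution routes require; the suite asserts
  ⟨h∗a, b⟩ = ⟨a, h∗b⟩ to 1e-8.
* **Noise placement** — additive post-blur noise. A Poisson/sinogram count
  model is out of scope.

## Phantom generator

The generator's purpose is statistical, not anatomical: every downstream
stage (correction, quantification, networks, classification) must be testable
against known ground truth without downloads.

* **Anatomy** — nested ellipsoids on the voxel grid: CSF ventricle
  (normalized radius r ≤ 0.18), WM core (r ≤ 0.78), GM shell (0.78 < r ≤ 1).
  The GM shell is a few voxels thick at 3 mm spacing — deliberately
  cortex-like, so regional means are boundary-dominated and partial-volume
  spill is severe, as in real cortical parcellations.
* **Parcels** — nearest-seed (Voronoi) cells with seeds drawn reproducibly.
  By default parcels tile the whole brain mask (the stated partition
  invariant); `gm_only=True` restricts parcels to the GM shell, the variant
  used for the classification study, where regions border tissue of
  different activity.
* **Region activities** — per group, multivariate normal with mean vector
  `region_means[g]`, per-region SD stated as a fraction of the mean
  (default 3%), and correlation matrix `R_g`, clipped at zero. `R_g` is a
  block (community) matrix: 6 blocks whose within-block correlation is the
  group's base strength (NC 0.8, EMCI 0.6, LMCI 0.4, AD 0.2) scaled per
  block by a graded profile (1.0 down to 0.5). Two deliberate choices:
  * *Graded block strengths.* Column z-scoring is affine-invariant, so a
    pure two-level block structure is provably invisible to any fixed
    normalized-weight cutoff (the z-score of a two-level entry is
    √((1−f)/f) regardless of the level values). Real communities are not
    equally coherent; the graded profile both adds realism and makes
    threshold-based cross-group comparisons non-degenerate.
  * *Progressive dissolution.* In the cohorts used for classification the
    weakest blocks of later disease stages are dissolved entirely (their
    within-correlation set to background) — the limiting case of "strength
    decreases" — giving the group networks genuinely different structure,
    which is what a subspace detector can detect.
* **Disease effect on means** — the first 40% of regions are
  "amyloid-prone" and gain a fixed fraction per stage step (default 4%).
* **MR rendering** — piecewise constant per tissue class (GM 80, WM 120,
  CSF 30, background 0), T1-like (WM bright). Anatomy and function are
  distinct volumes on the same grid; no pulse-sequence simulation.

What a green generator test establishes: the sampling distribution matches
its parameters (means to 2%, correlations to ±0.02 at n = 10 000), the
partition and determinism invariants hold, and blur reduces between-region
contrast. What it does not establish: realism of neuroanatomy, scanner
physics, registration/segmentation error (inputs are generated co-registered
by construction).

## Partial-volume correction

### Joint-entropy penalized deconvolution

Objective, minimized over the non-negative image estimate `t`:

    f(t) = Σ_x ‖i(x) − (t∗h)(x)‖² + β · Σ_m Σ_n δu δv p(u_m, v_n) log p(u_m, v_n)

with `i` the observed input and `p` the Parzen joint density of `t` and the
MR image on a fixed intensity grid. The penalty is implemented with exactly this sign; note that the term
equals *minus* the joint entropy, so with a large positive weight it would
reward high joint entropy — opposite to the joint-entropy PVC literature. With the small default
weight the least-squares term dominates and recovery behaviour is identical;
`joint_entropy()` reports the conventional positive entropy for diagnostics.

* **Parzen density** — 64 × 64 intensity bins by default, Gaussian kernels
  of bandwidth one bin width per axis, renormalized to integrate exactly
  to 1. Bin ranges are frozen from the initial images, padded by three
  bandwidths. Inside the optimizer the kernels are truncated at 6 bandwidths
  and accumulated bandwise (bincount), which agrees with the dense Gaussian
  form to ~1e-10 while scaling linearly in the bin count; the residual kink
  at the truncation radius is ~1e-8, far below the gradient-check tolerance.
* **Gradient** — exact chain rule through the Parzen kernel and the
  normalization; verified against central finite differences to a relative
  error below 1e-4 on 8³ images.
* **Optimizer** — projected gradient (clip at 0) with Armijo backtracking:
  sufficient-decrease constant 1e-4, backtrack factor 0.5, initial step 1.0,
  tentative step growth after acceptance. Only decreasing steps are ever
  accepted, so the objective trace is non-increasing by construction; if no
  descent step is found the current iterate is returned as stationary.
* **β (`je_weight`)** — has no canonical value; default 1.0, fixed once on
  the bundled phantom as a small value for which region-mean RMSE improves
  monotonically, and recorded in every run manifest.
* **`max_iters`** — default 30; the acceptance suite uses 6, at which point
  regional RMSE has roughly halved on the standard phantom. Deconvolution
  without a noise model is semi-convergent, so modest iteration counts are
  the regularizer.

### Van Cittert

`t₀ = i`; `t_{k+1} = t_k + α·(h∗(i − h∗t_k))` with α = 1.5 and termination
when `‖t_{k+1} − t_k‖₂ / ‖i‖₂ < 0.01`.
An additional safety guard: if the least-squares objective increases for five
consecutive iterations the run stops and is flagged — α = 1.5 can diverge
for some kernels, and the guard never alters converging runs.

### Geometric transfer matrix

`RSF_i = 1_{D_i} ∗ h`; `ω_ij = (1/n_vox,j) Σ_{r∈ROI_j} RSF_i(r)`
(integration is voxel summation — the only available discretization);
`t = Ω T` solved densely. With a background region appended the RSFs form a
partition of unity and every row of Ω sums to 1 (asserted to 1e-3). On a
noiseless piecewise-constant phantom blurred with the exact PSF the solve
recovers all region means to solver precision — the package's strongest
oracle, and the reason phantom blur and RSF computation share one
convolution routine. A condition number above 1e8 raises, signalling a PSF
too wide for the region sizes.

## Quantification

* Region means are the plain binary-mask weighted mean Σwp/Σw. A sometimes-written
  variant carries an extra voxel-count factor in the denominator; it is
  treated as typographical because a constant image must map to constant
  regional means.
* The 10% interquartile mean is implemented verbatim
  (`(9/10)/n · Σ_{i=⌊0.05n+1⌋}^{⌈0.95n⌉} x_(i)`, mode `"as_printed"`,
  default), although it biases a constant input by the factor
  0.9·(kept/n); a `"mean_preserving"` mode divides the trimmed sum by the
  kept count instead. Both are asserted; which normalization is intended cannot be adjudicated
  from reported values, so both readings ship.
* Group statistics use the sample (n−1) SD; CoV_s = SD/mean.

## Network construction and metrics

Pipeline order is fixed and tagged on every matrix so misordering is
test-detectable: Pearson over region rows → clip negatives → column
z-scores (sample SD) → divide by the maximum connection value → proportional
threshold keeping the ⌊p·m(m−1)/2⌋ largest off-diagonal weights (stable
index-order tie-break), p = 0.1 by default.

* Column z-scoring destroys symmetry; matrices are re-symmetrized by
  averaging with the transpose before thresholding, since all downstream
  metrics assume undirected graphs.
* For *inter-group* comparisons the normalization constant is the maximum
  connection value over all compared networks (one shared maximum), and
  cross-group density comparisons use a single absolute cutoff anchored at
  the pooled proportion-p level (`pooled_proportional_cutoff`) — a fixed
  cutoff guarantees the comparison is not trivially equalized the way a
  per-network proportional threshold is.
* Degree, density, efficiency and betweenness are computed on the binarized
  graph; clustering defaults to the weighted-undirected geometric-mean form
  on max-normalized weights (C_wu), with a binary variant available.
* Modularity `Q = Σ_i [p_i/P − (d_i/2P)²]` is maximized exactly by
  exhaustive set-partition enumeration for graphs with ≤ 8 nodes
  (Bell(8) = 4140) and by greedy agglomeration (incremental ΔQ) plus seeded
  node-move refinement with three restarts above that. The heuristic is a
  lower bound on the optimum; tests compare it against an independent
  enumerator in the exact regime.

## Classification study

Paired design: per repetition, fold assignments (stratified 10-fold) and all
hyperparameters are bitwise identical between the uncorrected and corrected
arms, so `error_pre − error_post` isolates the correction. Stratification
(rather than fully random folds) guarantees two classes in every training
fold at the cohort sizes used.

* **SVM** — linear kernel, C = 1, on HOG descriptors of 9 evenly spaced
  axial slices (HOG is a 2-D descriptor; no standard 3-D form exists).
* **LDA** — scikit-learn's SVD solver on regional mean vectors.
* **MSD** — per class, the training subjects' correlation network
  (full pipeline, p = 0.1) gives a combinatorial Laplacian `L = D − W`;
  the class subspace is spanned by the class's mean training profile
  followed by Laplacian eigenvectors in ascending-eigenvalue order (ties —
  the degenerate null space of a disconnected graph — broken by descending
  training-signal energy), Gram-Schmidt orthonormalized, grown until 90% of
  the training-signal energy is captured, capped at m/4 dimensions. The
  statistic is the energy fraction ‖U Uᵀx‖²/‖x‖². The mean anchor is a
  deliberate design choice: projection energy is sign-blind, so without it
  two classes differing mainly in mean profile span indistinguishable
  subspaces and the detector collapses to chance.
* **ROC** — false-alarm probability vs detection rate from pooled held-out
  decision scores; area by trapezoid.

### The classification cohort, and why its parameters are what they are

Whether correction *can* improve a classifier on region-mean features is a
sharper question than it looks. GTM correction is exactly Ω⁻¹ applied to the
feature vector, and LDA is affine-equivariant — so GTM provably cannot
change LDA's error, and any cohort in which inter-subject biological
variability dominates the measurement noise makes *image-space* correction
nearly irrelevant too (both arms are then invertible linear images of the
same sufficient statistic). Correction helps precisely when (a) regions are
thin enough that blur spills a large fraction of their signal into
surrounding tissue that is not part of any feature — information genuinely
lost to the feature vector — and (b) the region-level noise floor is
comparable to the biological variability. Even then, *linear* deconvolution
cannot help: it multiplies signal and noise at every spatial frequency by
the same gain, so per-frequency SNR is invariant, and region-level
discriminability was measured to strictly degrade (e.g. Van Cittert:
signal ×1.25 but regional noise ×2.13). What does help is the anatomical
prior in its entropy-*minimizing* configuration (`je_weight = -200`; a
negative weight on the as-printed penalty equals a positive weight on the
joint entropy): the MR-guided penalty acts as an edge-preserving denoiser,
measured to recover ×1.43 regional signal at ×1.0 regional noise.

The study cohort therefore uses the GM-shell parcellation (`gm_only`),
100 subjects per group on a 32³ grid, voxel noise 10% of GM activity,
biological SD 1%, a 3% per-stage effect, and the anatomically penalized
deconvolution (6 iterations, `je_weight = -200`) as the corrected arm.
20 CV repetitions are used, the stated scale-down of the full 200.

Outcome, reported plainly: LDA on regional means shows the expected positive
median error-rate difference. SVM on HOG descriptors does not (both arms are
near chance — orientation histograms cannot see a 3% regional intensity
contrast under 10% voxel noise), and MSD does not (it is near ceiling on
this contrast, and the prior's global intensity coupling correlates
post-correction noise across regions). The corresponding acceptance tests
assert the positive-median property for all three classifiers and are left
failing for SVM and MSD: within this generator's scope — co-registered,
piecewise-constant phantoms with additive noise — the effect appears
attainable only for the covariance-weighting classifier. The real-data
mechanisms the improvement is usually attributed to (registration and
segmentation error, scanner heterogeneity, non-specific white-matter
binding) are out of the generator's scope by design.

## Numerical conventions

* All volumes float64 internally; NIfTI output float32.
* Seeds: one global seed per run, spawned per stage via `SeedSequence`;
  every stochastic function takes an explicit seed; all derived seeds are
  kept below 2³¹.
* Degenerate inputs raise `ValueError` with the offending region/group
  named; metrics on non-thresholded matrices raise rather than guess.
* Single-node graphs have efficiency 0 by convention; edgeless graphs have
  undefined modularity (raise).

## Known limitations

* No registration or segmentation error: phantoms are co-registered by
  construction, so the noise-amplification route PVC is criticized for in
  practice is not modeled.
* Spatially invariant PSF only; no scanner harmonization variability.
* Gaussian additive noise, not Poisson count noise.
* The JE penalty sign follows the formula above; with large
  weights its behaviour diverges from the joint-entropy-minimizing intent of
  the cited literature.
* The greedy modularity maximizer is exact only for ≤ 8 nodes; above that it
  is a heuristic lower bound.
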