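# pvcnet

Partial-volume correction (PVC) for amyloid-PET quantification, and its impact
on brain correlation networks and group classification — a complete, tested,
download-free pipeline exercised on synthetic phantom cohorts.

## The problem

PET scanners resolve 5–6 mm at best. The measured image is, to good
approximation, the true tracer distribution convolved with a Gaussian
point-spread function (PSF): a voxel's value mixes signal from its
neighbourhood (the *partial volume effect*). For amyloid tracers this biases
regional SUVR quantification and, less obviously, everything built on top of
it: inter-regional correlation networks, their graph metrics, and classifiers
trained on the images. This package implements three correction routes and the
full downstream comparison, so the effect of correction can be measured
end-to-end on data with known ground truth:

* **JE deconvolution** — image-space deconvolution minimizing
  `Σ_x ‖i(x) − (t∗h)(x)‖² + β · Σ_m Σ_n δu δv p(u_m,v_n) log p(u_m,v_n)`
  over `t ≥ 0`, where `p` is the Parzen joint density of the PET estimate and
  a co-registered MR image; solved by projected gradient descent with Armijo
  backtracking.
* **Van Cittert (VC)** — `t_{k+1} = t_k + α·(h ∗ (i − h∗t_k))` with `α = 1.5`,
  stopped when `‖t_{k+1} − t_k‖ / ‖i‖ < 0.01`.
* **GTM** — the geometric transfer matrix: region means only, via
  `t = Ω T` with `ω_ij = (1/n_vox,j) Σ_{r∈ROI_j} RSF_i(r)` and
  `RSF_i = 1_{D_i} ∗ h`; exact on noiseless piecewise-constant phantoms.

Downstream: region-mean intensity matrices `I_{m×n}`, SUVR normalization by a
reference region, 10% interquartile means, Pearson correlation networks
(negatives clipped → column z-scores → max-normalization → proportional
threshold `p = 0.1`), graph metrics (density `d = 2K/(N²−N)`, global
efficiency, weighted clustering `C_wu`, maximum modularity
`Q = Σ_i [p_i/P − (d_i/2P)²]`, betweenness hubs), and a paired
corrected-vs-uncorrected classification study (HOG+SVM, LDA, and graph
matched-subspace detection under repeated stratified 10-fold CV).

## Worked example

```python
import numpy as np
from pvcnet import (PSFModel, build_parcellation, default_cohort_spec,
                    sample_cohort_activities, render_subject,
                    simulate_acquisition, gtm_matrix, gtm_correct)
from pvcnet.quantify import region_means

parc = build_parcellation((48, 48, 48), (3.0, 3.0, 3.0), n_regions=10, seed=3)
rng = np.random.default_rng(4)
truth = rng.uniform(0.5, 3.0, 10)
pet, mr = render_subject(parc, truth)
psf = PSFModel(fwhm_mm=6.0)
observed = simulate_acquisition(pet, psf, noise_sd=0.0)

blurred = region_means(observed, parc)
recovered = gtm_correct(blurred, gtm_matrix(parc, psf))
print("max blur bias      :", float(np.abs(blurred - truth).max()))
print("max GTM residual   :", float(np.abs(recovered - truth).max()))
```

prints

```
max blur bias      : 0.23256360229346829
max GTM residual   : 2.353672812205332e-14
```

i.e. a 6 mm PSF biases regional means by up to ~0.23 activity units on this
phantom, and the GTM solve removes the bias to solver precision — the
package's strongest internal oracle.

A full end-to-end run (phantom cohort → blur → all corrections → SUVR stats →
network metrics → classification) is one call:

```sh
pvcnet run-all --out demo_run --seed 7
```

which writes `suvr_stats.tsv`, `network_metrics.tsv`, `betweenness_hubs.tsv`
and `classification_report.tsv`, each stamped with the configuration hash.

## Acceptance script

`scripts/acceptance.py` recomputes the pipeline-parameter targets from
scratch by running the package (no stored results): the maximum absolute
column mean after the z-scoring stage of the network pipeline on a seeded
random 90-node correlation matrix, and the maximum modularity returned by the
maximizer over a 100-network randomized suite. Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
|---|---|
| `pvcnet.core` | volumetric containers, parcellation, PSF sampling, convolution |
| `pvcnet.phantom` | synthetic cohorts: anatomy, activities, acquisition model |
| `pvcnet.pvc` | JE deconvolution, Van Cittert, RSF/GTM |
| `pvcnet.quantify` | region means, SUVR, interquartile means, group stats |
| `pvcnet.network` | correlation-network pipeline, graph metrics, modularity |
| `pvcnet.classify` | HOG/SVM, LDA, matched-subspace detection, paired CV, ROC |
| `pvcnet.io`, `pvcnet.pipeline`, `pvcnet.cli` | NIfTI/TSV I/O, orchestration, CLI |

See `docs/methods.md` for the model assumptions, parameter defaults, and known
limitations.
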