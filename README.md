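# hemoseg

Hemodynamic segmentation of dynamic-susceptibility-contrast (DSC) MR brain
perfusion series, with perfusion quantification and a Monte Carlo phantom
simulator for delay/dispersion validation.

## The problem

A DSC acquisition records the T2\* signal drop of every brain voxel while a
gadolinium bolus passes through (typically 60–70 frames at 1 s resolution).
Voxels of one perfusion compartment — artery, gray matter, white matter,
veins and sinuses, CSF — share a characteristic bolus-transit profile, and
cerebrovascular disease (carotid stenosis, moyamoya) produces *delayed and
dispersed* variants of these profiles in the affected territory.  Automatic
segmentation of the compartments lets the arterial input function (AIF) be
taken from the right cluster — including a local, delayed AIF for impaired
tissue — and turns the series into per-tissue hemodynamic numbers.  The
package is aimed at perfusion-MRI researchers who want a transparent,
scriptable implementation of this clustering pipeline and of the simulation
machinery used to validate it.

## The method

Tissue classes are modeled as a mixture of multivariate Gaussians (MoMG)
over reduced voxel features,

```
p(x) = Σᵢ αᵢ N(x; μᵢ, Σᵢ),   i = 1..K,
```

fitted by EM.  The pipeline: Otsu brain masking → M×N observation matrix →
zero-mean normalization → PCA retaining ≥99% variance → whitening (so
cov(Y)=I and squared-Euclidean distances weight all components equally) →
Ward-linkage hierarchical clustering, whose K-cluster cut supplies the
initial (αᵢ, μᵢ, Σᵢ) → EM → maximum-posterior labels.  The number of
classes minimizes the description length −LL + (P_K/2)·ln N.  From the
labeled classes the package computes C(t) = −(1/TE)·ln(S/S₀), the
gamma-variate AIF, and per-voxel rCBV (first-pass area ratio), rCBF
(truncated-SVD deconvolution of C = rCBF·Δt·(AIF ⊛ R)), MTT = rCBV/rCBF
and TTP, optionally with per-class local AIFs.

The phantom simulator draws each class from a multivariate Gaussian whose
mean curve comes from the bolus forward model with the effective residue
`R(t) = exp(−(t−t_delay)/MTT)` convolved with an exponential dispersion
kernel, and whose covariance mimics real EPI heterogeneity
(baseline/amplitude/arrival jitter plus an AR(1) floor).  Benchmark
drivers score matched per-cluster classification rates over seeded Monte
Carlo repetitions.  See `docs/methods.md` for assumptions and parameter
rationale.

## Worked example

Segment a simulated 7-compartment phantom and pick K by MDL:

```python
import numpy as np
from hemoseg import (PhantomConfig, extended_tissue_library,
                     generate_phantom, segment_select_k, classification_rate)

specs = extended_tissue_library(7, scale=0.25)       # 1301 voxels
values, truth = generate_phantom(PhantomConfig(tissues=specs, snr=70),
                                 np.random.default_rng(42))
best, fits = segment_select_k(values, (5, 9), seed=0)
res = fits[best - 5]
print(res.summary())
print(f"classification rate vs truth: "
      f"{classification_rate(truth, res.labels).overall_rate:.1f}%")
```

prints

```
Gaussian mixture segmentation (EM)
============================================
components (K):      7   features (w): 3
observations:     1301
log-likelihood:        -605.97
MDL score:              853.37
iterations:          7   converged: True
--------------------------------------------
class   weight   n_map   |mean|
    0   0.1061     138    2.368
    1   0.3144     409    1.340
    2   0.0338      44    4.649
    3   0.3344     435    0.434
    4   0.1174     152    1.532
    5   0.0786     103    1.543
    6   0.0154      20    5.402
classification rate vs truth: 99.8%
```

MDL is minimal at the generating class count (K = 7), and the matched
per-cluster classification rate against the ground-truth labels is 99.8%.
The class weights recover the design proportions (GM 0.31, WM 0.33,
artery 0.11, ...).

The same pipeline is available from the shell:

```
hemoseg simulate  --out phantom/ --n-classes 7 --seed 42 --scale 0.25
hemoseg segment   --input phantom/phantom.nii.gz --out seg/ --k-min 5 --k-max 9
hemoseg hemo      --input phantom/phantom.nii.gz --labels seg/labels.nii.gz \
                  --out maps/ --aif-mode local
hemoseg benchmark --mode delay --reps 50 --snr 70 --out grid.csv
```

`segment` writes a label NIfTI, per-class mean curves and the MDL-vs-K
table; `hemo` writes rCBV/rCBF/MTT/TTP maps and per-class mean ± SD
statistics; every command writes a JSON manifest with its seed and
configuration.

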