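# mccsd

Crossing-fiber orientation estimation in edematous brain tissue from
clinically feasible diffusion MRI, by cascaded multi-compartment modeling and
constrained spherical deconvolution (CSD).

## The problem

Peritumoral edema floods white matter with isotropic water. The extra
isotropic signal — a fast, CSF-like free-water pool plus a slower hindered
pool — swamps the angular contrast that fiber-tracking methods rely on, so
tractography through the peritumoral region misses or distorts exactly the
tracts a neurosurgeon needs to see. `mccsd` separates the isotropic pools
from the anisotropic white-matter signal voxel by voxel, then deconvolves a
voxel-specific single-fiber response from what remains, recovering a fiber
orientation distribution (FOD) whose lobes resolve crossing bundles even at
high edema fractions.

## The model

Each voxel's normalized signal is a four-compartment mixture

```
E(b, n) = f_b [ f_csf e^(-b λ_csf) + (1 − f_csf) e^(-b λ_iso) ]
        + (1 − f_b) [ f_r e^(-b λ∥ (nᵀμ)²)
                     + (1 − f_r) e^(-b [λ⊥ + (λ∥−λ⊥)(nᵀμ)²]) ]
```

an isotropic bundle (free water at λ_csf = 3×10⁻⁹ m²/s plus hindered water
at λ_iso) and an anisotropic bundle (intra-axonal stick plus extra-axonal
zeppelin sharing one parallel diffusivity λ∥, with the tortuosity constraint
λ⊥ = (1 − f_r) λ∥). Fitting proceeds as a cascade: a single-ball prefit
estimates λ_iso ∈ [0.1, 3]×10⁻⁹ m²/s, a brute-force grid plus bounded
L-BFGS-B refinement fits the fractions and axis, and if the refined λ_iso
does not exceed λ∥ the isotropic bundle collapses to pure free water
(f_csf ≡ 1). The fitted mixture, axis aligned to z, becomes the convolution
kernel of a multi-shell CSD:

```
E = FOD(c) ⊛ E_MC(f*),   subject to FOD ≥ 0 (soft),
```

solved per voxel by iteratively re-weighted least squares with
regularization weight λ = 1 and threshold τ = 10% of the mean initial FOD
amplitude. Super-resolved CSD re-solves at l_max = 12 — beyond what the
sampled directions alone support — with the non-negativity rows
regularizing the extra harmonic orders. Because the isotropic compartments
are rotation invariant they contribute only to l = 0: free and hindered
water are eliminated from the FOD's angular structure by construction.

## Worked example

Simulate one condition of the evaluation study — two fibers crossing at 90°
under 40% isotropic contamination, multi-shell protocol P3 (b = 300/800/2000
s/mm² with 15/30/64 directions), Rician noise at SNR 30 — and score peak
recovery over 25 repetitions:

```python
import numpy as np
from mccsd import PhantomSpec, run_condition

spec = PhantomSpec(n_fibers=2, crossing_angles=(90.0,), iso_vf=0.4,
                   snr=30.0, protocol="P3", n_reps=25, seed=1)
row = run_condition(spec, lmax=12, super_csd=True)
print(f"peak separation rate: {row['rate']:.2f}")
print(f"median crossing-angle error: {row['error_median']:.2f} deg")
```

```
peak separation rate: 1.00
median crossing-angle error: 0.65 deg
```

Every repetition recovered exactly two FOD peaks (rate 1.00), and the angle
between the two recovered peaks was typically within ~1° of the true 90°.

The same pipeline runs on images from the shell:

```
mccsd fit --dwi dwi.nii.gz --bval dwi.bval --bvec dwi.bvec \
          --mask mask.nii.gz --lmax 12 --super-csd \
          --lambda-par auto --out-dir out/ --seed 0
mccsd simulate --config study.yaml --out-dir study_out/
mccsd report --results study_out/results.csv --out report.md
```

`fit` writes fraction maps (fb, fcsf, fr), λ_iso, the FOD
spherical-harmonic image, peak directions, peak counts, the anisotropic
index, and a JSON manifest reproducing the run.

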