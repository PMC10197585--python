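# Methods

## Signal model

A voxel's diffusion-attenuated signal, normalized by its mean b=0 value, is
modeled as a convex mixture of four Gaussian compartments grouped into two
bundles:

- **Isotropic bundle** (fraction `fb`): free water, a ball with fixed
  diffusivity λ_csf = 3×10⁻⁹ m²/s, holding fraction `fcsf` of the bundle;
  and hindered water, a ball with estimated diffusivity λ_iso, holding the
  remainder. Free water models CSF-like fluid; hindered water models the
  slower isotropic pool characteristic of vasogenic edema.
- **Anisotropic bundle** (fraction `1 − fb`): a stick (zero-radius
  cylinder) for restricted intra-axonal diffusion, fraction `fr`, and a
  zeppelin (axially symmetric tensor) for hindered extra-axonal diffusion,
  fraction `1 − fr`. Both share one axis μ and one parallel diffusivity λ∥;
  the zeppelin's perpendicular diffusivity is tied to the intra-axonal
  fraction by the tortuosity relation λ⊥ = (1 − fr)·λ∥.

All compartments are Gaussian and diffusion-time independent, so pulse
timings (δ, Δ) are carried as acquisition metadata only. b-values are
user-facing in s/mm² and converted to s/m² internally so that every
exponent b·λ is dimensionless. Gradient directions are axial throughout
(n ≡ −n); the canonical representative has non-negative z.

Assumptions worth keeping in mind: Gaussian compartments are adequate up to
b ≈ 1500–2000 s/mm² but ignore kurtosis at stronger weighting; a single
anisotropic bundle per voxel means crossings are resolved by the
deconvolution stage, not by multiple sticks; fitted fractions are effective
model parameters, not literal tissue volume fractions.

## Cascaded fit

1. **Isotropic prefit.** λ_iso is estimated by least-squares fitting a
   single ball to the whole signal over the bounded interval
   [0.1, 3]×10⁻⁹ m²/s (1-D bounded Brent, endpoints checked). On mixed
   voxels this estimate is biased toward the anisotropic bundle's mean
   diffusivity; it serves as the initializer of the full fit.
2. **Full fit.** The least-squares cost is evaluated on the full Cartesian
   grid of fractions (5 points per fraction by default) times a 30-point
   axial orientation grid, at the prefit λ_iso. The best 3 grid points each
   seed a bounded L-BFGS-B refinement over (fb, fcsf, fr, λ_iso, θ, φ),
   with λ_iso scaled to units of 10⁻⁹ m²/s so all variables are O(1), and
   tight tolerances (ftol 1e-16, gtol 1e-12). Multi-start matters: the cost
   surface has shallow secondary basins where a single start occasionally
   strands, visible as noiseless-recovery failures.
3. **Free-water collapse.** If the refined λ_iso does not exceed λ∥, slow
   hindered water is indistinguishable from tissue and the isotropic bundle
   cannot be split: the voxel is refit with `fcsf = 1` (isotropic bundle =
   one free-water ball), warm-started from the free solution. The rule is
   exactly binary: `fcsf` is either the fitted value (λ_iso > λ∥) or
   literally 1.0. Keeping λ_iso free in the refinement, rather than frozen
   at the prefit value, is what makes the fractions of noiseless
   matched-model voxels recoverable (median errors ≲ 1e-4 instead of ~0.3
   for fcsf); the prefit-frozen variant spuriously collapses mixed voxels
   because its λ_iso estimate absorbs anisotropic signal.

Identifiability notes: when `fb ≈ 0` the isotropic parameters (fcsf,
λ_iso) are unconstrained, and when λ_iso approaches λ_csf = 3×10⁻⁹ the
free/hindered split degenerates — both are intrinsic to the model, not
optimizer artifacts.

**λ∥ for in vivo data** is estimated from high-FA voxels: a weighted linear
least-squares tensor fit on shells ≤ 1000 s/mm² (limiting kurtosis bias),
FA computed per voxel, the top 300 voxels with FA > 0.7 selected (fallback:
top 300 by FA), and their mean largest eigenvalue returned. The FA
threshold, voxel count and shell cutoff are exposed as arguments.
Simulations fix λ∥ = 1.7×10⁻⁹ m²/s, the value used for all simulated white
matter.

## Deconvolution

FODs are expanded in a real, orthonormal, even-order symmetric
spherical-harmonic basis (l ascending, m from −l to l). The voxel-specific
convolution kernel is the full fitted mixture signal with μ along z,
projected per shell onto the m = 0 harmonics by 96-node Gauss–Legendre
quadrature over cos θ. Isotropic compartments are rotation invariant and
contribute only to l = 0, so the free- and hindered-water signal cannot
generate angular FOD structure — this is how isotropic elimination is
realized. (An alternative reading — subtracting the isotropic signal before
deconvolving with the anisotropic kernel alone — changes only the l = 0
coefficient scaling, not the lobes; it is not implemented.)

Convolution in coefficient space is `c'_lm = c_lm · r_l · sqrt(4π/(2l+1))`.
The data system stacks all shells, b=0 rows included with the kernel's mean
value. CSD solves it by iteratively re-weighted least squares: initialize
unconstrained at l_max = 8; find constraint directions on a 724-point
axial sphere where the current FOD falls below τ = 10% of the mean initial
FOD amplitude; append those amplitude rows as soft zero-targets weighted by
`reg_lambda · ‖A‖_F / ‖B‖_F` (reg_lambda = 1 by default); re-solve;
iterate to a constraint-set fixed point (cap 50). Super-resolved CSD
re-solves at l_max = 12 (default) with the same data rows; the dense
constraint rows are what determine the harmonic orders the 109 acquired
directions alone cannot support.

Numerical behavior of the soft constraint: negative FOD lobes are
suppressed to roughly 1–2% of the peak amplitude, not eliminated. This is
structural — raising the constraint weight with a fixed active set
plateaus near −0.7% of the peak, and hard-zeroing the (typically > 91)
sub-threshold directions annihilates the FOD since the constraint matrix
has full column rank. Residual negativity at this scale sits far below the
25% peak-selection rule and does not affect peak metrics. The constraint
sphere size (724) and the fixed-point stopping rule are implementation
choices; the weight and threshold defaults are the standard CSD operating
point. A singular system returns an isotropic FOD flagged unconverged.

## Peaks and metrics

Peaks are strict local maxima of the FOD over a 1281-point axial mesh
(8-neighbour test, antipodally aware across the hemisphere seam), each
refined by Nelder–Mead ascent on the continuous SH amplitude, merged
within 15° (the merge radius prevents mesh-resolution duplicates at
l_max = 12), and thresholded: non-positive peaks are dropped, and secondary
peaks must reach 25% of the strongest. The **peak separation rate** of a
condition is the fraction of repetitions recovering exactly the true number
of fibers. The **crossing-angle error** (2-fiber conditions only) matches
the two largest peaks to the true axes by minimal total axial angle and
reports |estimated − true| crossing angle; repetitions with fewer than two
peaks are excluded from error distributions, since the rate already counts
them. The **anisotropic index** AI = sqrt(Σ_{l≥2} c² / Σ_{l≥0} c²) is the
fraction of FOD power outside the isotropic order — 0 for a uniform FOD, 1
when isotropic power vanishes; this power-fraction definition is this
package's declared formula for the FOD-anisotropy summary.

## Synthetic data

The phantom module emulates edema-contaminated crossing voxels: signal =
iso_vf · ball(λ_iso) + (1 − iso_vf) · equal-weight fiber bundles, each a
stick+zeppelin with fr = 0.6 and λ∥ = 1.7×10⁻⁹ m²/s (matched to the
fitted model; an alternative geometry is a prolate-tensor fiber for
mismatched-model robustness checks). λ_iso is drawn uniformly per
repetition from [1.7, 2.95]×10⁻⁹ m²/s — the hindered-water range of
edema — unless pinned. Fibers are laid out in a canonical plane at the
requested crossing angles and given a fresh uniform random rotation per
repetition to avoid grid alignment artifacts. Rician noise forms the
magnitude of a complex Gaussian perturbation with σ = 1/SNR relative to
the unit b=0 signal; SNR levels 20/30/40 are the study's conditions and
∞ means noiseless. Simulation protocols: P1 = b=800 (30 directions), P2 =
b=2000 (64), P3 = multi-shell b=300/800/2000 (15/30/64), each plus one b=0
volume; per-shell direction sets are seeded electrostatic-repulsion point
sets, since the original simulated tables are not published.

What the phantoms do **not** emulate: spatially curved fiber geometry and
partial-volume mixing along tube boundaries, exchange between pools,
non-Gaussian (kurtosis) effects at high b, gradient nonlinearities, and
noise correlations from parallel imaging. Passing the simulation study
therefore demonstrates correct model inversion and angular resolution under
the model's own generative assumptions with realistic noise — not in vivo
validity, which requires patient data outside this package's scope. A small
labeled grid phantom (CSF / GM / WM / edema-crossing slabs) exercises the
volume pipeline end to end.

## Study conditions and problem sizes

The bundled evaluation (tests and `scripts/acceptance.py`) uses the study's
operating point: protocol P3, SNR 30, crossing angles 45/60/90°, isotropic
volume fractions 0.2–0.8, super-CSD l_max = 12, and 100 repetitions per
condition for the headline 90° sweep and the 45° detection check. Ordering
comparisons (protocols P1/P2/P3, CSD l_max=8 vs super-CSD l_max=12, SNR
20/30/40) use 25 repetitions per condition, pooled across angle and volume
fraction where a single rate is compared, which keeps Monte-Carlo
variability below the effect sizes being ordered.

## Known limitations

- Fractions lose identifiability at the fb → 0 and λ_iso → λ_csf corners
  (see above); fitted values there are fit artifacts by construction.
- In grey matter, where isotropic diffusivity can exceed λ∥ without true
  free water, the collapse rule misattributes signal and FODs develop
  spurious peaks; restrict fitting to white matter and the peritumoral
  region.
- Soft-constrained FODs retain small negative lobes (~1% of peak).
- The λ∥ voxel-selection recipe (FA > 0.7, top 300) is a declared,
  config-exposed stand-in for automated reference-region selection, not a
  reproduction of any specific published pipeline.
- Single-diffusion-encoding only; no spatial regularization across voxels.
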