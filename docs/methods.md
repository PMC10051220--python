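# Methods

`diffray` solves four X-ray imaging inverse problems with one recipe: write
the acquisition as a composition of differentiable operators, define a
data-fidelity-plus-regularization loss, and minimize it with gradients
obtained by reverse-mode automatic differentiation. This note documents the
models, the numerical choices, the synthetic-data generators, and the known
limitations.

## The differentiation engine

The AD backend (`diffray.autodiff`) is a small reverse-mode engine over
NumPy arrays. Every operation records, per differentiable input, a
vector-Jacobian-product closure; `Tensor.backward()` traverses the graph in
reverse topological order and accumulates cotangents. All numerics are
double precision. Complex quantities are carried as explicit
(real, imaginary) duplets, so differentiating through complex-valued models
(ptychography) reduces to ordinary real differentiation of the paired
coordinates — the real-coordinate realization of Wirtinger derivatives.

Hand-derived VJPs back the non-elementwise primitives:

* orthonormal DCT-II and centered orthonormal FFT are unitary, so the
  adjoint (the VJP of a linear map) is the inverse transform;
* multi-level biorthogonal-4.4 wavelet synthesis (symmetric extension,
  3 levels by default) is materialized once per image shape as an explicit
  matrix built column-by-column from PyWavelets, giving an exact adjoint;
  the coefficient layout follows PyWavelets' packed-array bookkeeping;
* same-size zero-padded correlation (blur) has convolution as its image
  adjoint and a padded valid-mode correlation as its kernel adjoint;
* bilinear resampling (affine warps, subpixel crops) scatters the four
  corner weights for the image adjoint and uses the analytic bilinear
  derivative for the coordinate adjoint;
* factor-binning (detector pixel integration) back-distributes uniformly.

Every VJP is validated against central finite differences (the independent
oracle, scale-normalized steps of 1e-5) at 1e-4 relative tolerance; the
linear operators additionally pass adjoint dot-product tests at 1e-6.

## Optimization

`solver.minimize` exposes two methods behind one closure interface (clear
gradients, simulate, differentiate, update):

* limited-memory BFGS with strong-Wolfe line search (scipy's L-BFGS-B driven
  by AD gradients) for real-valued, moderately sized problems;
* Adam, a first-order adaptive method, for the large non-convex
  ptychographic problems.

Convergence is declared when the relative loss change stays below `tol`
(default 1e-8) for five consecutive iterations. Both methods are
deterministic: identical inputs give bitwise-identical traces. A non-finite
loss aborts the run and returns the best state reached.

Plain simultaneous descent is *not* the right protocol for the two
bilinear-in-the-unknowns problems, and the model classes encode the
protocols that work:

* **Blind super-resolution** (image x kernel): simultaneous MAP descent
  drifts toward the classic blurred-image/sharp-kernel degeneracy of blind
  deconvolution. `SuperResolutionModel.fit` minimizes the same loss by
  block-coordinate descent — an image sweep with the kernel frozen, then a
  kernel sweep with the image frozen — and stops when a full round improves
  the loss by less than 0.5% (12 rounds maximum). A near-correct initial
  kernel converges in 2–3 rounds; a badly wrong one (motion blur started
  from a Gaussian) keeps earning its rounds and reorients correctly.
* **Tomographic alignment** (volume x geometry): a cold start lets the
  volume absorb the misalignment. `TomographyModel.fit` first estimates the
  2N+1 alignment parameters from projection-consistency moments — the
  column sums of corrected projections are the per-slice mass and must be
  angle-invariant, and the horizontal center of mass must follow a
  first-harmonic sinusoid of the angle — and only then alternates volume
  sweeps with alignment sweeps of the full loss.
* **Ptychography** (object x probe): object-only and probe-only
  quasi-Newton sweeps are each well conditioned and carry the blind probe
  into the right basin; a joint Adam polish (learning rate 0.005) over all
  enabled parameter groups finishes the job. The propagation distance is
  refined as a dimensionless multiple of the nominal value so the optimizer
  sees an O(1) coordinate. Scan positions equilibrate slowly against the
  co-evolving object (greedy positions-only sweeps against a partially
  converged object demonstrably bias the estimates), so the
  position-refinement study simply runs the joint stage long (7000
  iterations); sub-0.3-px recovery then holds with margins that vary with
  the draw.

## Forward models and losses

**Compressive sensing.** The latent unknown is the coefficient array of the
image in an orthonormal 2D DCT (wavelet optional); the loss is the L2
misfit on the sampled pixels plus `lambda1 * ||x||_1`. Defaults:
`lambda1 = 1e-3 max|y|`, `lambda2 = 1e-2 max|y|`. The background-corrected
variant multiplies the measured data by a co-estimated field `w` (so `w`
approximates the reciprocal beam gain) with a 1D total-variation penalty on
its raster serialization; `w` is kept positive by a softplus
reparameterization, and the joint scale ambiguity is resolved for reporting
by normalizing `median(w) = 1`. A model-side variant (the field multiplies
the simulation instead of the data) is available behind a flag.

**Super-resolution.** Degradation is blur by an odd 13x13 kernel followed
by 4x mean binning. The loss is a Huber data term (knee delta = 1; the
standard symmetric form) plus isotropic TV on the image and L1 on the
kernel. TV uses `sqrt(eps + dr^2 + dc^2) - sqrt(eps)` with `eps = 1e-8`, so
flat regions have finite gradients and constants score exactly zero; a
printed variant with a column *sum* instead of a difference exists behind a
switch for comparison. Weights default to `lambda1 = 3e-5 max|y|` (TV) and
`lambda2 = 1e-4 max|y|` (kernel L1): with sum reductions, the Huber term
runs over 16x fewer LR pixels than the TV term, and larger TV weights
reward the degenerate blur-transfer solution. Resolution gain is assessed
by Fourier Ring Correlation with the standard one-bit information threshold
`(0.5 + 2.4142/sqrt(n)) / (1.5 + 1.4142/sqrt(n))` per ring.

**Tomography.** The latent unknown is per-slice wavelet coefficients; the
forward model synthesizes the volume, rotates it in-plane about the
vertical axis and Riemann-sums along the beam. Because the angle list is
fixed geometry, the rotate-and-project composition is materialized once as
a sparse matrix (four bilinear weights per sample) with an exact adjoint;
the fully differentiable warp path remains in `tomo_forward` and in the
data-side alignment corrections. The aligned loss replaces each projection
`y_i` by `C_i y_i` with per-projection shifts and one global detector tilt.
Two exact gauge freedoms — a constant vertical shift and a first-harmonic
horizontal shift component, both equivalent to rigidly translating the
volume — are removed by convention from both the reported estimates and the
generator's injected truth ("jitter has no net drift").

**Ptychography.** The object and the (optionally multimode) probe are
complex duplets; the measured intensity is the incoherent mode sum of the
propagated exit waves, with far-field (single centered FFT) and
angular-spectrum (cached transfer-function) propagators. Cropping at
real-valued scan positions is a translation-family bilinear resampler, so
position gradients exist; integer slicing would not be differentiable. The
magnitude-excess regularizer penalizes the moduli of exactly those object
pixels above 1 (a transmission function cannot amplify), with the selection
set held fixed during differentiation. The probe/object multiplicative
split is resolved for reporting by renormalizing the total probe power to
the mean measured total intensity. Estimates are compared to ground truth
after removing the global phase *and* the exact linear phase-ramp
ambiguity (object ramp, conjugate probe ramp), over the illuminated region;
position errors are scored after removing the global-translation gauge.

## Synthetic data

The generator module defines the reference study conditions; every draw
takes an explicit seed and is bitwise reproducible.

* `make_phantom`: exactly-K-sparse DCT images (optionally with a bright DC
  term, modelling a transmission scan with mean ~1), piecewise-constant
  ellipse phantoms (<= 8 grey levels), and smooth cell-like blob fields.
* `simulate_cs_scan`: sparse raster scan with an optional multiplicative
  beam drift: a bounded random walk over scan rows, constant within a row —
  smooth along the raster serialization, striped in 2D, with
  `max|gain - 1|` equal to the requested amplitude.
* `simulate_lr`: blur + binning degradation with optional additive noise.
* `make_volume_phantom` / `simulate_sinogram`: smooth 3D blobs plus bright
  fiducial beads ringing the specimen rim at the top/bottom surfaces (the
  gold-nanobead practice that makes alignment well determined), embedded in
  empty margins so shifted/tilted acquisitions never clip mass at the field
  edge. Misaligned acquisitions are rendered in a *single* trilinear
  sampling pass per projection, as a physical detector would sample them;
  warping ideal projections after the fact smooths the data twice and
  demonstrably biases the alignment objective toward absorbing the tilt
  into the volume.
* `simulate_ptycho`: raster scan with uniform stage jitter; by default the
  dataset stores the nominal positions (unrecorded mechanical error, the
  position-refinement study), with `record_positions=True` for
  encoder-recorded jitter — which also breaks the raster-grid pathology of
  perfectly periodic scans that otherwise admits spurious low-loss
  solutions.

Noise defaults to none: the losses are plain L2/Huber fits, so the
reference studies are noiseless forward simulations, with additive-Gaussian
and Poisson noise available as robustness controls.

What the generators do **not** emulate: detector point-spread functions,
partial coherence beyond the plain incoherent mode sum, scattering beyond
the projection approximation, zone-plate wavefronts beyond a smooth
(optionally defocused) disk, and counting statistics matched to real dose.
Passing the recovery studies therefore demonstrates the correctness and
joint identifiability of the differentiable models at desk scale, not
beamline-grade image quality.

## Reference study sizes

Chosen as the package's desk-scale defaults: CS 64x64 at 30% sampling
(40-sparse); super-resolution 104x104 from 26x26 (x4, 13x13 kernel);
tomography 64x64 single slice with 60 angles over 120 degrees, and a
16x48x48 bead phantom with 40 angles for alignment; ptychography 100x100
object, 5x5 scan at 12 px step with a 48 px probe (75% overlap). The
ptychographic field is 100 px rather than the minimal 96 px so every scan
position keeps the interpolation margin the resampler requires.

## Known limitations

* The affine resampler is bilinear everywhere; its interpolation error is
  the accuracy floor of the geometric refinements (visible as the ~0.1 px
  scale of residuals at sharp features).
* The L1 terms are genuinely nonsmooth; the line-search quasi-Newton stalls
  at the kinks around 1e-3 relative loss, which bounds how sharply two runs
  of the convex CS objective agree.
* Detector tilt in the aligned tomography model is identifiable only when
  the specimen carries sharp features far from the rotation center
  (fiducials); smooth phantoms leave it degenerate with a volume rotation.
* With a freely refined probe the ptychographic propagation distance is
  nearly degenerate (the probe absorbs propagation); distance refinement
  assumes a characterized illumination.
* Wavelet coefficient vectors follow PyWavelets' packed layout, which pads
  odd shapes; padded coordinates are inert (zero columns in the synthesis
  matrix) and harmlessly L1-penalized to zero.
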