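# Methods

## The reconstruction problem

A low-magnification Bessel light-sheet acquisition records a volume `Y`
whose resolution is limited by two factors: the effective system PSF (the
swept, slit-synchronized Bessel sheet axially, the detection optics
laterally) and the coarse voxelization of the camera and z-stepping
(2 μm in the ×3.2 mode, versus the ~0.9 μm diffraction limit of the
0.28-NA detection). The package recovers a high-resolution volume `X` on a
grid `s`× finer (default `s = 4`, 0.5-μm iso-voxels) by solving, for each
block `i` of the tiled volume,

    minimize_x  ‖A x_i − y_i‖₂² + λ_i ‖x_i‖₁                      (per-block objective)

over the DFT coefficients `x_i` of the high-resolution block. The
measurement operator is

    A x = Bin_s( Re( IDFT( OTF · x ) ) )

— multiplication by the optical transfer function (DFT of the centered,
unit-sum PSF), inverse transform, and reduction of every `s×s×s` cell to
one camera voxel. `‖x‖₁` is the sum of complex moduli over the full
spectrum, DC included.

### Conventions and their consequences

* DFT: forward unnormalized, inverse carries `1/N`. The exact adjoint is
  then `Aᴴy = conj(OTF)·DFT(BinTy)/N` with `BinT` replication/`s³`; for an
  identity OTF at `s = 1` this gives `AᴴA = I/N`. The `1/N` cancels out of
  everything observable (step sizes and λ are expressed relative to
  `λmax = 2·max|Aᴴy|`, computed with the same adjoint).
* Binning: boxcar mean by default — camera pixels integrate photons.
  Plain decimation is retained as an ablation option.
* Boundary handling: each block is reflect-padded by the PSF half-support
  (in LR voxels, at least 2) before the solve; the apron is cropped
  afterwards. This suppresses circular-convolution wrap-around, which the
  periodic DFT model would otherwise introduce.
* Coordinates: arrays are (z, y, x) with z the scan axis; voxel centers at
  `(i + 0.5)·pitch`; all physical quantities in μm.

## Content-aware regularization

One global λ cannot serve a volume whose content ranges from empty
background through isolated somata to dense dendrite bundles: a λ tuned
for sparse blocks over-constrains complicated signals (loss of structure),
one tuned for dense blocks under-regularizes sparse ones (noise
amplification and artefacts). Each content block therefore receives

    λ_i = λ0 · α_i · β_i · λmax_i ,   clipped to [λ_min, λ_max]·λmax_i

* `β_i = 1/(ε + H_i)` with `H_i` the normalized Shannon entropy (256-bin
  histogram of the min–max-normalized block, natural log, divided by
  ln 256; constant blocks → 0) and `ε = 0.05`. β is inversely proportional
  to the entropy: disordered, information-rich content must not be
  over-constrained. The entropy may alternatively be computed on the
  spectral magnitudes (`entropy_domain="fourier"`); the spatial histogram
  is the default as the more robust of the two.
* `α_i = ρ_i + 0.1` with `ρ_i` the fraction of voxels above
  `μ_bg + 3σ_bg` — α tracks the signal density. The direction matters and
  was a genuinely open design point. The increasing form is used because
  the opposite choice (α large for sparse blocks) hands the volume's
  strongest regularization to exactly the blocks that contain isolated
  point sources, and measurably erodes them: with α decreasing, the
  converged bead response under default calibration widens back toward the
  raw-sampling limit, and the resolution recovery that is the method's
  central claim is lost. Sparse blocks are already stabilized by positivity
  and need the least shrinkage; dense blocks can absorb more. The λ-map
  direction across content classes is still governed by β: a dense,
  disordered filament-crossing block always receives a weight no larger
  than a sparse single-bead block.
* `λmax_i = 2·max|Aᴴy_i|` is the smallest λ that zeroes the block's
  solution; scaling by it makes one dimensionless `λ0` transfer across
  intensity scales and exposure settings.
* Background statistics come from the lowest-decile voxels of the whole
  volume. The decile subset samples the lower tail of the background
  distribution, so its mean and SD are corrected for the truncation under
  a Gaussian model (the correction constants come from the truncated
  normal); this keeps the 3σ/5σ thresholds meaningful even though the
  subset is biased. When the lower tail is degenerate — count data are
  clipped at zero, so a zero-photon background makes more than a decile of
  the voxels exactly 0 — the spread is taken from the upper side instead
  (`q84 − median`, one σ for a Gaussian).
* Blocks whose maximum does not exceed `μ_bg + 5σ_bg` (strictly) are
  classified empty, bypass the solver, and are tricubic-upsampled. The
  maximum of ~10⁵ background voxels sits near 4.5σ, so the 5σ rule leaves
  pure-noise blocks on the cheap path while a single genuine bead
  (tens of σ) flips the block to content.
* `mode="constant"` sets `α = β = 1` and replaces `λmax_i` by the median
  content-block `λmax` of the volume, reproducing conventional compressed
  sensing with one fixed λ — the baseline the adaptive map is compared
  against.

**Calibration of λ0.** The remaining free constant was fixed by a fidelity
sweep (λ0 from 10⁻³ down to 3·10⁻⁵) on bead, filament and nuclei phantoms
under the default ×3.2 conditions, scoring NRMSE and SSIM of the
reconstruction against the generating truth. The sweep has an interior
optimum — the largest value over-regularizes the filament phantom, the
smallest under-regularizes filaments and nuclei alike — and the aggregate
(mean normalized NRMSE, equivalently mean SSIM, across the three phantom
classes) is minimized at `λ0 = 10⁻⁴`, the default.

## Solver

**FISTA** (accelerated proximal gradient) is the default: gradient steps
`1/L` with `L = 2·‖A‖²` from power iteration on `AᴴA` (seeded,
deterministic, shared across same-shaped blocks), complex soft-thresholding
as the prox, adaptive restart on objective increase, and λ-continuation
(the threshold starts at `0.1·λmax` and decays geometrically to the target
over the first 150 iterations — the standard homotopy warm start; all
stopping and certification happens at the target λ). Iterates live in the
half-spectrum (rfftn) layout — the coefficients of a real image are
hermitian-symmetric, and the per-coefficient FISTA update commutes with
that symmetry, so the half array is simply the stored representative.
Objectives are accumulated in float64 regardless of the working dtype
(float32 in the pipeline, float64 for small certified solves).

Optimality of the convex objective is certified through the KKT residual

    x_j = 0:  |2Aᴴ(Ax−y)_j| ≤ λ(1 + tol)
    x_j ≠ 0:  |2Aᴴ(Ax−y)_j + λ x_j/|x_j|| ≤ λ·tol

with `tol = 10⁻³` relative to λ. `λ ≥ λmax` short-circuits to the exact
zero solution (the KKT threshold condition). Non-convergence within
`max_iter` is reported through a flag, never an exception; the pipeline
lists such blocks and returns a `partial` status.

**Interior point.** An independent route to the same minimizer, for
cross-validation on small blocks: the problem is written as a second-order
cone program over stacked real/imaginary parts (`|x_j| ≤ u_j`), and the
log-barrier `−Σ log(u_j² − |x_j|²)` is followed down the central path
(μ = 20 per step), each barrier problem solved by damped Newton with
conjugate-gradient (truncated-Newton) inner iterations, matrix-free
through the operator. On random 8³ instances the two routes agree to
~10⁻⁹ relative in objective value; the suite asserts 10⁻⁴.

**Positivity.** Fluorescence intensity is non-negative, and for signals
sampled below their Nyquist rate (2-μm voxels against 0.9-μm lateral
optics) positivity is the prior that actually disambiguates aliases: the
plain Fourier-L1 minimizer provably concentrates every aliasing class of
coefficients on its largest-transfer (lowest-frequency) member, so its
output is band-limited to the raw sampling — a point source can never come
out narrower than the ~2.3 μm sinc main lobe of the 2-μm grid, for any λ.
With the positivity constraint active during the iteration (projection
onto the non-negative orthant in the spatial domain each step), point-like
and line-like structures are recovered well below that limit. The solver
exposes three modes:

* `nonneg="none"` — the plain convex problem, exactly as written;
* `nonneg="clip"` — same solve, spatial output clipped at zero (all KKT
  certification and solver-agreement checks run in these two modes);
* `nonneg="constraint"` — projected FISTA on the constrained problem;
  the pipeline default, and the mode under which the resolution-recovery
  results are obtained.

## Pipeline

The LR volume is tiled into `block³` blocks (default 50³ desk-scale;
100³ matches the production setting) overlapping by 16 LR voxels. The
overlap is set by the solve's effective nonlocality, not the PSF support:
the spectral penalty couples every voxel of a block, so two blocks
reconstructing the same voxels from different windows agree only gradually
as their shared context grows. Sixteen LR voxels keep the residual
disagreement between a feather-stitched pair of blocks and an unsplit
solve below 2% of the local dynamic range on dense filament content. Every
block has the full shape; far-edge blocks extend past the volume and are
reflect-padded, with the valid extent recorded. Stitching blends overlaps
axis-by-axis with linear feather weights `t_k = (k+1)/(v+1)` applied in
lerp form `prev + t·(cur − prev)`, which is an exact partition of unity:
equal inputs reproduce bit-exactly, so reassembling unmodified blocks
returns the input unchanged, and processing order cannot affect any output
voxel. The stitched result is cropped to `lr_shape × s`; output pitch is
input pitch / s.

The run is deterministic given (volume, configuration, seed): the seed
reaches every stochastic component (the power-iteration start vector;
phantom generation and noise in simulation). The report carries the
per-block λ/α/β/entropy/density maps on the block grid, per-block
convergence records (iterations, final objective, KKT residual), timings,
and global intensity statistics.

## Synthetic specimens and the acquisition model

The phantoms emulate the statistical structure of the real samples:

* **beads** — sub-resolution point sources (trilinear-splatted at random
  subvoxel positions, minimum separation enforced by dart throwing), with
  near-uniform brightness (0.9–1.0 by default) as for the monodisperse
  polystyrene microspheres used to characterize instrument PSFs; the
  resolution probe.
* **filaments** — persistent-random-walk centerlines rasterized as tubes
  with Gaussian cross-section (radius 0.75 μm default, matching fine
  dendrites), optional short spine protrusions; the dense/disordered
  content class.
* **nuclei** — soft-edged spheres (radius 3 μm) at Poisson-disc positions;
  the count is exactly `round(density × volume)` (240 at
  2.4·10⁵ mm⁻³ in a (100 μm)³ extent), so counting accuracy is measured
  against construction.
* **nmj** — a curved postsynaptic shell plus a presynaptic polar cap
  covering exactly the requested voxel fraction (occupancy within 1%),
  in two channels.

Acquisition simulation applies the same forward physics the
reconstruction inverts — PSF blur, `s³` boxcar binning — then scales to
photon counts (default peak 400 photons ⇒ peak SNR ≈ 20), applies Poisson
shot noise, Gaussian read noise (σ = 2 counts), and 16-bit quantization.
The default ×3.2-mode emulation uses a Gaussian effective PSF of 2.0 μm
lateral / 1.6 μm axial FWHM on a 0.5-μm grid with `s = 4`, reproducing the
~4–5 μm apparent bead size of the raw 2-μm stacks. Using the identical
operator for simulation and reconstruction is deliberate for unit testing;
`AcquisitionSpec` accepts any PSF, so an inverse-crime-free check simply
passes a ±10%-perturbed PSF to the reconstruction.

What the phantoms do **not** model: tissue scattering and depth-dependent
aberrations, autofluorescence, vasculature-like extended structures,
spatially varying PSFs, and sample motion. Passing tests therefore
demonstrate the correctness and the resolution/fidelity behavior of the
computation under its own physics assumptions, not performance inside
deep cleared tissue.

## Optics model

The Bessel beam cross-section is the ideal annular-aperture profile
`I(r) = J₀²(k·NA·r)`. The swept sheet's axial profile is the slit-windowed
sweep integral `S(z) ∝ ∫_{|y|≤w} J₀²(k·NA·√(y²+z²)) dy`; the confocal slit
is a hard top-hat window of half-width `w` (the rolling-shutter rows), and
the unsynchronized sweep is represented by a wide window of 200
central-lobe radii — the integral grows only logarithmically in the
window, so this stands for the camera-FOV-limited integral while keeping
the side-lobe tails that synchronization exists to remove. With
λ = 488 nm, NA 0.14 and a slit of about one central-lobe radius, the
modeled sheet FWHM falls in the 1–2 μm range, consistent with the
instrument-class sheet thickness; only interval consistency is asserted,
since the analytic slit-windowed profile is a modeling choice. Detection
blur is a lateral Gaussian of FWHM `0.51·λ/NA_det`. System PSFs (any
construction path) are truncated at 10⁻⁴ of peak — discarded mass far
below quantization — and renormalized to unit sum.

## Quality metrics

* `NRMSE = RMS(x − ref)/(max(ref) − min(ref))`.
* SSIM with a 3D Gaussian window (σ = 1.5 voxels, 11-voxel support,
  `C1 = (0.01L)²`, `C2 = (0.03L)²`), averaged over voxels whose window
  lies fully inside the volume; cross-checked in the suite against
  scikit-image's independent implementation.
* FWHM: 1D profile through the (refined) object centroid,
  tails-median background subtraction, half-maximum crossings by linear
  interpolation — the same procedure applied to instrument linecuts.
* Counting: local-maxima detection with an anisotropy-aware ellipsoidal
  footprint; flat-topped objects yield plateau maxima, which are reduced
  to plateau centroids before greedy minimum-distance suppression;
  detections are matched to truth by mutual nearest neighbor.
* NMJ occupancy = 100 × (presynaptic voxels)/(postsynaptic voxels),
  following the printed formula (all presynaptic voxels count);
  `clip_to_post=True` implements the stricter intersection reading.
  Masks default to per-channel Otsu thresholds.

## Problem sizes and defaults

Desk-scale defaults keep every validation run on a single CPU core:
48³–50³-LR volumes (≈200³ HR after ×4), one 50³ block per solve. FISTA
iteration counts are matched to the quantity being measured: resolution
metrics (bead FWHM) are taken at ≈450–550 iterations, where they are
converged to well under the measurement precision; object counting and
fidelity metrics stabilize far earlier (≈120–150 iterations). The
objective is recorded every 10 iterations in pipeline runs. The block
contract (no shared state, order-free stitching) is what makes the
production-scale setting — thousands of 100³ blocks processed in
parallel — a pure orchestration exercise outside this package's scope.

## Known limitations

* The α/β functional forms are one reasonable monotone choice; only their
  directions (both decreasing λ for dense, high-entropy content) and the
  product structure are constrained by the method's design. All four
  constants are config-exposed.
* The positivity-constrained mode has no closed-form optimality
  certificate (the projected prox is inexact for the combined
  L1-plus-indicator term); its convergence is monitored through the
  objective, and the exactly-certified modes are retained alongside.
* Production-scale λ between overlapping blocks can differ, so seams are
  feathered rather than exactly consistent; the suite bounds the residual
  seam error at 2% of local dynamic range.
* The sheet model is profile-level; no vectorial diffraction, no
  propagation through scattering media.
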