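# cacs — content-aware compressed-sensing reconstruction for light-sheet microscopy

Whole-organ light-sheet imaging trades resolution for speed: a ×3.2
Bessel-sheet acquisition covers a 4-mm field with 2-μm voxels in minutes,
but fine neurites, densely packed nuclei and synaptic structure blur into
a ~4–5 μm point response. `cacs` recovers a 0.5-μm iso-voxel,
high-SNR volume from that single low-resolution stack by solving a
block-wise, Fourier-domain, L1-regularized inverse problem whose
regularization adapts to the local image content.

For each block `i` of the tiled raw volume `Y`, the package solves

```
minimize_x  ‖A xᵢ − yᵢ‖₂² + λᵢ ‖xᵢ‖₁
```

over the DFT coefficients `xᵢ` of the high-resolution block, where
`A = Bin_s ∘ IDFT ∘ OTF` blurs with the system PSF and bins `s×s×s` cells
to camera voxels, and

```
λᵢ = λ₀ · αᵢ · βᵢ · λmaxᵢ,   βᵢ = 1/(ε + Hᵢ),   αᵢ = ρᵢ + 0.1
```

with `Hᵢ` the block's normalized histogram entropy and `ρᵢ` its
signal-voxel fraction: disordered, information-rich blocks get weak
regularization (no over-constraining), near-empty blocks holding isolated
point sources get the least shrinkage (positivity already stabilizes
them), and λ scales with each block's own λmax so one λ₀ serves the whole
dynamic range. Solves are FISTA with adaptive restart and
λ-continuation (an interior-point route is included for certification);
positivity of fluorescence is enforced during the iteration by default,
which is what carries recovery below the raw Nyquist limit for point- and
line-like structures. Recovered blocks are feather-stitched into the final
volume `X`.

The package is self-contained: a phantom generator (beads, neuronal
filaments, stained nuclei, dual-channel neuromuscular junctions) plus a
camera-physics acquisition simulator produce every input needed to
validate the pipeline end to end, with exact truth records.

## Worked example

Simulate a ×3.2-mode bead acquisition and reconstruct it:

```python
import numpy as np
from cacs import (PhantomSpec, AcquisitionSpec, generate_phantom,
                  simulate_acquisition, make_system_psf, RunConfig,
                  run_cacs, fwhm_profile)
from cacs.solver import SolveConfig

psf = make_system_psf("gaussian", {"fwhm_xy": 2.0, "fwhm_z": 1.6}, (0.5,) * 3)
ph = generate_phantom(PhantomSpec(kind="beads", extent=48.0, pitch=0.5,
                                  n_beads=3, bead_min_sep=15.0, seed=7))
raw = simulate_acquisition(ph.volume, AcquisitionSpec(psf=psf, factor=4,
                                                      photon_scale=400, read_noise=2, seed=7))
X, report = run_cacs(raw, RunConfig(psf=psf, factor=4, block=24,
                                    solver=SolveConfig(dtype="float32", max_iter=450,
                                                       trace_every=10), seed=1))
for pos in ph.truth["positions_um"]:
    ax = fwhm_profile(X, pos, axis=0)
    lat = fwhm_profile(X, pos, axis=2)
    print(f"bead at {np.round(pos, 1)} um:  axial FWHM {ax:.2f} um, lateral {lat:.2f} um")
print(f"status={report['status']}  content blocks={report['n_content']}/{report['n_blocks']}")
```

Output:

```
bead at [29.4 41.2 35.9] um:  axial FWHM 1.31 um, lateral 1.95 um
bead at [12.1 15.4 40.1] um:  axial FWHM 1.90 um, lateral 1.78 um
bead at [ 2.6 37.9 36.8] um:  axial FWHM 1.14 um, lateral 1.29 um
status=clean  content blocks=1/1
```

On the raw 2-μm stack the same beads measure ~2.5–3 μm apparent FWHM
(tricubic-upsampled, noise-free optics; in cleared tissue the raw figure
runs wider still); the reconstruction resolves them at ~1.1–2.0 μm on a
0.5-μm grid. Those axial/lateral FWHM numbers are what the resolution
claims of the method rest on. The report carries the per-block
λ/α/β/entropy/density maps and convergence records.

The same operations are available from the shell:

```
cacs simulate --kind nuclei --extent 100 --pitch 0.5 --density 2.4e5 \
              --factor 4 --seed 7 --out-gt gt.tif --out-raw raw.tif --out-truth truth.csv
cacs run --input raw.tif --psf-model gaussian:fwhm_xy=2.0,fwhm_z=1.6 \
         --factor 4 --block 50 --overlap 16 --output out.tif --report report.json
cacs metrics --test out.tif --ref gt.tif --report metrics.json
```

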