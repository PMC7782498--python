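"""Synthetic specimens and simulated Bessel-sheet acquisitions.

Ground-truth high-resolution volumes with the statistical structure of the
real samples the instrument images — sub-resolution beads, neuronal
filaments with optional spines, densely packed stained nuclei, and
dual-channel neuromuscular junctions (a postsynaptic endplate shell partly
covered by presynaptic terminals).  Every phantom carries an exact truth
record (positions, centerlines, masks) so that downstream accuracy is
always measured against construction, never against a reconstruction.

``simulate_acquisition`` degrades a ground-truth volume through the same
physics the reconstruction inverts: blur by the system PSF, s-fold boxcar
binning (camera pixels integrate), scaling to expected photon counts,
Poisson shot noise, additive Gaussian read noise, and quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .operators import make_operator
from .optics import PSFModel
from .volume import ImageVolume

__all__ = [
    "PhantomSpec",
    "AcquisitionSpec",
    "Phantom",
    "generate_phantom",
    "simulate_acquisition",
]


class GenerationError(RuntimeError):
    """Raised when a feasible phantom cannot be packed."""


@dataclass
class PhantomSpec:
    """Specification of a synthetic specimen.

    kind : "beads" | "filaments" | "nuclei" | "nmj".
    extent : physical size (z, y, x) in um (scalar = cube).
    pitch : HR voxel pitch in um (isotropic).
    seed : RNG seed; generation is deterministic given the spec.

    Bead parameters: n_beads point sources with intensities in
    ``bead_intensity_range`` and minimum pairwise separation
    ``bead_min_sep`` (um).

    Filament parameters: ``n_filaments`` smoothed random-walk centerlines
    rasterized as tubes of Gaussian cross-section ``tube_radius`` (um),
    with ``spine_rate`` short protrusions per um of centerline.

    Nuclei parameters: spherical blobs of radius ``nucleus_radius`` at
    Poisson-disc positions with density ``nuclei_density`` per mm^3 and
    minimum separation ``nuclei_min_sep``; the truth count is exactly
    round(density x volume).

    NMJ parameters: a curved postsynaptic shell plus a presynaptic partial
    cover whose voxel-volume ratio equals ``occupancy`` within 1%.
    """

    kind: str
    extent: tuple[float, float, float] = (50.0, 50.0, 50.0)
    pitch: float = 0.5
    seed: int = 0
    # beads
    n_beads: int = 8
    bead_intensity_range: tuple[float, float] = (0.9, 1.0)
    bead_min_sep: float = 20.0
    # filaments
    n_filaments: int = 5
    tube_radius: float = 0.75
    filament_intensity: float = 1.0
    spine_rate: float = 0.0
    spine_length: float = 2.0
    # nuclei
    nuclei_density: float = 2.4e5
    nucleus_radius: float = 3.0
    nuclei_min_sep: float = 8.0
    # nmj
    occupancy: float = 0.5
    shell_radius: float = 12.0
    shell_thickness: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("beads", "filaments", "nuclei", "nmj"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if np.isscalar(self.extent):
            self.extent = (float(self.extent),) * 3
        self.extent = tuple(float(e) for e in self.extent)
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        for e in self.extent:
            n = e / self.pitch
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"extent {e} is not an integer number of voxels at pitch {self.pitch}")
        if not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy must be within [0, 1]")
        if self.nuclei_density < 0:
            raise ValueError("density must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / self.pitch)) for e in self.extent)


@dataclass
class Phantom:
    """A generated specimen: main volume, named channels, and truth record."""

    volume: ImageVolume
    truth: dict
    channels: dict = field(default_factory=dict)


def _dart_throw(rng, extent, n, min_sep, margin, max_tries_factor=2000):
    """Uniform positions with enforced minimum separation (dart throwing)."""
    positions: list[np.ndarray] = []
    lo = np.full(3, margin)
    hi = np.asarray(extent) - margin
    if np.any(hi <= lo):
        raise GenerationError("margin leaves no room for object centers")
    tries = 0
    max_tries = max_tries_factor * max(n, 1)
    while len(positions) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not pack {n} objects at min separation {min_sep} um "
                f"in extent {tuple(extent)} um ({len(positions)} placed)"
            )
        p = lo + rng.random(3) * (hi - lo)
        if all(np.linalg.norm(p - q) >= min_sep for q in positions):
            positions.append(p)
    return np.array(positions).reshape(n, 3)


def _splat_trilinear(vol, pos_vox, amplitude):
    """Deposit a point source at a fractional voxel position."""
    base = np.floor(pos_vox).astype(int)
    frac = pos_vox - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[0] if dz else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dx else 1 - frac[2])
                )
                idx = base + (dz, dy, dx)
                if np.all(idx >= 0) and np.all(idx < vol.shape):
                    vol[tuple(idx)] += amplitude * w


def _beads(spec: PhantomSpec, rng):
    shape = spec.shape
    vol = np.zeros(shape)
    margin = max(2 * spec.pitch, 0.05 * min(spec.extent))
    pos = _dart_throw(rng, spec.extent, spec.n_beads, spec.bead_min_sep, margin)
    lo, hi = spec.bead_intensity_range
    inten = lo + rng.random(spec.n_beads) * (hi - lo)
    for p, a in zip(pos, inten):
        _splat_trilinear(vol, p / spec.pitch - 0.5, a)
    return vol, {"positions_um": pos, "intensities": inten}


def _filaments(spec: PhantomSpec, rng):
    shape = spec.shape
    density = np.zeros(shape)
    extent = np.asarray(spec.extent)
    step = 0.5 * spec.pitch
    centerlines = []
    spines = []
    for _ in range(spec.n_filaments):
        p = extent * (0.1 + 0.8 * rng.random(3))
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        n_steps = int(1.5 * extent.max() / step)
        pts = []
        dist_since_spine = 0.0
        for _ in range(n_steps):
            pts.append(p.copy())
            _splat_trilinear(density, p / spec.pitch - 0.5, 1.0)
            # spines: short lateral protrusions at the requested rate
            dist_since_spine += step
            if spec.spine_rate > 0 and dist_since_spine * spec.spine_rate >= 1.0:
                dist_since_spine = 0.0
                sdir = np.cross(d, rng.standard_normal(3))
                nrm = np.linalg.norm(sdir)
                if nrm > 0:
                    sdir /= nrm
                    spines.append((p.copy(), sdir))
                    for t in np.arange(step, spec.spine_length, step):
                        q = p + t * sdir
                        if np.all(q > 0) and np.all(q < extent):
                            _splat_trilinear(density, q / spec.pitch - 0.5, 0.7)
            # persistent random walk, reflected at the boundary
            d = d + 0.25 * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            p = p + step * d
            for ax in range(3):
                if p[ax] < 0 or p[ax] > extent[ax]:
                    d[ax] = -d[ax]
                    p[ax] = np.clip(p[ax], 0, extent[ax])
        centerlines.append(np.array(pts))
    sigma_vox = spec.tube_radius / spec.pitch
    vol = ndimage.gaussian_filter(density, sigma_vox)
    peak = vol.max()
    if peak > 0:
        vol *= spec.filament_intensity / peak
    return vol, {"centerlines_um": centerlines, "spines": spines}


def _nuclei(spec: PhantomSpec, rng):
    shape = spec.shape
    vol_mm3 = float(np.prod(spec.extent)) * 1e-9
    n = int(round(spec.nuclei_density * vol_mm3))
    margin = spec.nucleus_radius
    pos = _dart_throw(rng, spec.extent, n, spec.nuclei_min_sep, margin)
    vol = np.zeros(shape)
    r_vox = spec.nucleus_radius / spec.pitch
    half = int(math.ceil(r_vox + 2))
    zz, yy, xx = np.mgrid[-half : half + 1, -half : half + 1, -half : half + 1]
    rr = np.sqrt(zz * zz + yy * yy + xx * xx)
    # soft-edged sphere: flat core, ~1-voxel cosine rolloff at the surface
    edge = 1.0
    blob = np.clip(0.5 * (1 + np.cos(np.pi * np.clip((rr - r_vox + edge) / (2 * edge), 0, 1))), 0, 1)
    inten = 0.7 + 0.3 * rng.random(n)
    for p, a in zip(pos, inten):
        c = np.round(p / spec.pitch - 0.5).astype(int)
        sl_v, sl_b = [], []
        ok = True
        for ax in range(3):
            lo = c[ax] - half
            hi = c[ax] + half + 1
            blo = max(0, -lo)
            bhi = (2 * half + 1) - max(0, hi - shape[ax])
            lo = max(lo, 0)
            hi = min(hi, shape[ax])
            if hi <= lo:
                ok = False
                break
            sl_v.append(slice(lo, hi))
            sl_b.append(slice(blo, bhi))
        if ok:
            region = vol[tuple(sl_v)]
            np.maximum(region, a * blob[tuple(sl_b)], out=region)
    return vol, {"positions_um": pos, "count": n, "intensities": inten}


def _nmj(spec: PhantomSpec, rng):
    shape = spec.shape
    extent = np.asarray(spec.extent)
    center = extent / 2.0
    zc, yc, xc = [
        (np.arange(n) + 0.5) * spec.pitch - c for n, c in zip(shape, center)
    ]
    rr = np.sqrt(
        zc[:, None, None] ** 2 + yc[None, :, None] ** 2 + xc[None, None, :] ** 2
    )
    # curved cup: spherical shell restricted to a polar cap
    costheta = np.where(rr > 0, zc[:, None, None] / np.where(rr > 0, rr, 1.0), 1.0)
    shell = (np.abs(rr - spec.shell_radius) <= spec.shell_thickness / 2.0) & (
        costheta >= -0.2
    )
    n_post = int(shell.sum())
    if n_post == 0:
        raise GenerationError("shell radius too large for the extent")
    # presynaptic cover: the top-k shell voxels by polar angle
    k = int(round(spec.occupancy * n_post))
    pre = np.zeros(shape, bool)
    if k > 0:
        idx = np.argwhere(shell)
        ct = costheta[shell]
        order = np.argsort(-ct, kind="stable")
        chosen = idx[order[:k]]
        pre[tuple(chosen.T)] = True
    post_vol = ndimage.gaussian_filter(shell.astype(float), 1.0)
    pre_vol = ndimage.gaussian_filter(pre.astype(float), 1.0)
    truth = {
        "post_mask": shell,
        "pre_mask": pre,
        "occupancy_pct": 100.0 * k / n_post,
    }
    return post_vol, pre_vol, truth


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate a ground-truth HR volume plus its exact truth record."""
    rng = np.random.default_rng(spec.seed)
    pitch3 = (spec.pitch,) * 3
    if spec.kind == "beads":
        vol, truth = _beads(spec, rng)
    elif spec.kind == "filaments":
        vol, truth = _filaments(spec, rng)
    elif spec.kind == "nuclei":
        vol, truth = _nuclei(spec, rng)
    else:
        post, pre, truth = _nmj(spec, rng)
        return Phantom(
            ImageVolume(post, pitch3),
            truth,
            channels={
                "post": ImageVolume(post, pitch3),
                "pre": ImageVolume(pre, pitch3),
            },
        )
    return Phantom(ImageVolume(vol, pitch3), truth)


@dataclass
class AcquisitionSpec:
    """Camera/optics model of one acquisition.

    psf : system PSF sampled at the ground-truth (HR) pitch.
    factor : binning factor s per axis (HR -> LR).
    photon_scale : expected photon count at the brightest LR voxel
        (peak SNR ~ sqrt(photon_scale) for shot-noise-limited data);
        None or inf disables shot noise.
    read_noise : Gaussian read noise SD in counts.
    bit_depth : quantization depth of the camera output.
    seed : RNG seed for the noise.
    """

    psf: PSFModel
    factor: int = 4
    photon_scale: float | None = 400.0
    read_noise: float = 2.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photon_scale is not None and not self.photon_scale > 0:
            raise ValueError("photon_scale must be > 0 (or None)")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")


def simulate_acquisition(gt: ImageVolume, acq: AcquisitionSpec) -> ImageVolume:
    """Forward-simulate the raw LR stack from an HR ground truth.

    Blur with the PSF, boxcar-bin by s, scale to photon counts, apply
    Poisson shot noise then Gaussian read noise, and quantize.  The
    intensity gain (counts per ground-truth unit) and the saturated-voxel
    fraction are recorded in ``meta``.
    """
    for pg, pp in zip(gt.pitch, acq.psf.pitch):
        if abs(pg - pp) > 1e-9:
            raise ValueError(f"ground-truth pitch {gt.pitch} != PSF pitch {acq.psf.pitch}")
    s = int(acq.factor)
    hr_shape = gt.shape
    if any(n % s for n in hr_shape):
        raise ValueError(f"volume shape {hr_shape} not divisible by factor {s}")
    op = make_operator(acq.psf, hr_shape, factor=s, binning="boxcar")
    blurred = op.forward_spatial(np.asarray(gt.data, dtype=float))
    peak = blurred.max()
    rng = np.random.default_rng(acq.seed)
    if acq.photon_scale is None or not np.isfinite(acq.photon_scale):
        gain = 1.0 if peak <= 0 else (2 ** acq.bit_depth - 1) * 0.5 / peak
        counts = blurred * gain
    else:
        gain = 1.0 if peak <= 0 else acq.photon_scale / peak
        counts = rng.poisson(np.clip(blurred * gain, 0, None)).astype(float)
    if acq.read_noise > 0:
        counts = counts + rng.normal(0.0, acq.read_noise, counts.shape)
    qmax = 2 ** acq.bit_depth - 1
    counts = np.clip(np.round(counts), 0, qmax)
    saturated = float((counts >= qmax).mean())
    lr_pitch = tuple(p * s for p in gt.pitch)
    out = ImageVolume(counts.astype(np.float64), lr_pitch, value_range=(0.0, float(qmax)))
    out.meta.update(
        {"gain": gain, "saturated_fraction": saturated, "read_noise": acq.read_noise}
    )
    if saturated > 0.01:
        out.meta["warning"] = f"saturation fraction {saturated:.1%} exceeds 1%"
    return out
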