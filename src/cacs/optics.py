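"""Profile-level optics of a confocally scanned Bessel light-sheet.

A Bessel beam produced by an annular pupil has the transverse intensity
profile I(r) = J0(k * NA * r)**2: a narrow non-diverging central lobe
surrounded by side lobes that decay only as 1/r.  Sweeping the beam
laterally (y) builds a virtual sheet; without synchronization every side
lobe contributes to every camera row and the sheet cross-section acquires
broad axial tails.  Synchronizing a narrow band of active camera rows (a
confocal slit) with the sweeping beam restricts the integration window and
rejects most of the side-lobe fluorescence.

This module models exactly that: the radial beam profile, the slit-windowed
sweep integral S(z), and an effective three-dimensional system PSF used by
the forward model.  Full vectorial diffraction and propagation through
scattering tissue are out of scope; the reconstruction only ever consumes
the effective kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import j0

from .volume import ImageVolume, read_tiff, write_tiff

__all__ = [
    "BeamSpec",
    "PSFModel",
    "bessel_cross_section",
    "sheet_axial_profile",
    "make_system_psf",
    "read_psf_tiff",
    "write_psf_tiff",
]

#: Half-window (in central-lobe radii) used to emulate an unsynchronized
#: sweep: the slit integral grows only logarithmically with the window, so a
#: wide finite window stands for the full camera FOV.
UNSYNC_WINDOW_LOBES = 200.0

#: Relative intensity below which PSF support is truncated before
#: renormalization.  The discarded mass is far below camera quantization.
PSF_TRUNCATION = 1e-4


class InvalidSpecError(ValueError):
    """Raised for non-physical beam or PSF parameters."""


@dataclass(frozen=True)
class BeamSpec:
    """Illumination/detection parameters of the Bessel sheet.

    wavelength : excitation wavelength in um.
    na_ill : numerical aperture of the (annular) illumination.
    na_det : numerical aperture of the detection objective.
    slit_halfwidth : confocal-slit half-width in um, or ``None``/inf for the
        unsynchronized swept sheet.
    """

    wavelength: float = 0.488
    na_ill: float = 0.14
    na_det: float = 0.28
    slit_halfwidth: float | None = None

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise InvalidSpecError(f"wavelength must be > 0, got {self.wavelength}")
        for name in ("na_ill", "na_det"):
            na = getattr(self, name)
            if not 0 < na < 1:
                raise InvalidSpecError(f"{name} must be in (0, 1), got {na}")
        w = self.slit_halfwidth
        if w is not None and not (w > 0):
            raise InvalidSpecError(f"slit_halfwidth must be > 0 or None, got {w}")

    @property
    def k(self) -> float:
        """Vacuum wavenumber 2*pi/lambda (1/um)."""
        return 2.0 * math.pi / self.wavelength

    @property
    def central_lobe_radius(self) -> float:
        """First zero of J0(k*NA*r): r = 2.4048.../(k*NA), in um."""
        return 2.404825557695773 / (self.k * self.na_ill)

    def effective_window(self) -> float:
        """Slit half-width used in the sweep integral (um)."""
        w = self.slit_halfwidth
        if w is None or math.isinf(w):
            return UNSYNC_WINDOW_LOBES * self.central_lobe_radius
        return float(w)


def bessel_cross_section(r, spec: BeamSpec):
    """Radial intensity I(r) = J0(k*NA_ill*r)^2 of the ideal Bessel beam.

    Normalized so I(0) = 1.  ``r`` in um; scalar or array.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be >= 0")
    return j0(spec.k * spec.na_ill * r) ** 2


def sheet_axial_profile(z, spec: BeamSpec, n_quad: int = 4096):
    """Axial cross-section S(z) of the swept (slit-windowed) sheet.

    S(z) = integral over |y| <= w of J0(k*NA*sqrt(y^2+z^2))^2 dy, normalized
    to S(0) = 1.  A finite slit half-width w models row-synchronized
    acquisition; w = inf (unsynchronized) is represented by a wide window of
    ``UNSYNC_WINDOW_LOBES`` central-lobe radii and exhibits the broad
    side-lobe tails.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    w = spec.effective_window()
    # even integrand: integrate y in [0, w] and double; trapezoid on a dense
    # grid (integrand is smooth and bounded)
    y = np.linspace(0.0, w, n_quad)
    kna = spec.k * spec.na_ill

    def integral(zv):
        rr = np.sqrt(y * y + zv * zv)
        f = j0(kna * rr) ** 2
        return 2.0 * np.trapezoid(f, y)

    s = np.vectorize(integral)(z)
    s0 = integral(0.0)
    if not np.isfinite(s0) or s0 <= 0:
        raise ArithmeticError(
            f"sheet integral failed to converge: S(0)={s0} (w={w}, n_quad={n_quad})"
        )
    return s / s0


def profile_fwhm(f, xmax: float = 50.0, tol: float = 1e-6) -> float:
    """FWHM of an even, peak-at-zero profile ``f`` by bisection on f(x)=f(0)/2."""
    half = f(0.0) / 2.0
    lo, hi = 0.0, None
    x = 1e-3
    while x < xmax:
        if f(x) < half:
            hi = x
            break
        lo = x
        x *= 1.5
    if hi is None:
        raise ValueError("no half-maximum crossing found")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < half:
            hi = mid
        else:
            lo = mid
    return 2.0 * 0.5 * (lo + hi)


def tail_mass_fraction(spec: BeamSpec, n_fwhm: float = 3.0, zmax_fwhm: float = 40.0) -> float:
    """Fraction of the axial profile's mass beyond ``n_fwhm`` FWHMs.

    Quantifies how much excitation the side lobes deposit out of focus; the
    confocal slit exists to reduce precisely this number.
    """
    fwhm = profile_fwhm(lambda zz: float(sheet_axial_profile(zz, spec)))
    z = np.linspace(0.0, zmax_fwhm * fwhm, 6000)
    s = sheet_axial_profile(z, spec)
    total = np.trapezoid(s, z)
    tail = np.trapezoid(np.where(z > n_fwhm * fwhm, s, 0.0), z)
    return float(tail / total)


@dataclass
class PSFModel:
    """Normalized 3D blur kernel of the system on the HR grid.

    kernel : ndarray (z, y, x), non-negative, sums to 1.
    pitch : voxel pitch (z, y, x) in um.
    provenance : "parametric-gaussian" | "bessel-sheet" | "measured".
    """

    kernel: np.ndarray
    pitch: tuple[float, float, float]
    provenance: str = "measured"

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.ndim != 3:
            raise InvalidSpecError("PSF kernel must be 3D")
        if np.any(self.kernel < 0):
            raise InvalidSpecError("PSF kernel must be non-negative")
        s = self.kernel.sum()
        if s <= 0:
            raise InvalidSpecError("PSF kernel is all zero (degenerate)")
        self.kernel = self.kernel / s
        self.pitch = tuple(float(p) for p in self.pitch)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.kernel.shape

    def centroid_offset(self) -> np.ndarray:
        """Centroid minus geometric center, in voxels per axis."""
        idx = np.indices(self.kernel.shape)
        c = np.array([(i * self.kernel).sum() for i in idx])
        geo = (np.array(self.kernel.shape) - 1) / 2.0
        return c - geo

    def half_support(self) -> tuple[int, int, int]:
        """Half extent of the kernel in voxels per axis (floor of shape/2)."""
        return tuple(n // 2 for n in self.kernel.shape)


def _gaussian_1d(n: int, sigma_vox: float) -> np.ndarray:
    x = np.arange(n) - (n - 1) / 2.0
    if sigma_vox == 0:
        g = (x == 0).astype(float)
    else:
        g = np.exp(-0.5 * (x / sigma_vox) ** 2)
    return g


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _truncate(kernel: np.ndarray, rel: float = PSF_TRUNCATION) -> np.ndarray:
    """Crop the bounding box where kernel >= rel * peak, keeping odd shape
    symmetric about the center voxel."""
    peak = kernel.max()
    mask = kernel >= rel * peak
    center = tuple((n - 1) // 2 for n in kernel.shape)
    slices = []
    for ax, c in enumerate(center):
        proj = mask.any(axis=tuple(i for i in range(3) if i != ax))
        nz = np.nonzero(proj)[0]
        half = max(c - nz[0], nz[-1] - c, 0)
        half = min(half, c, kernel.shape[ax] - 1 - c)
        slices.append(slice(c - half, c + half + 1))
    return kernel[tuple(slices)]


def make_system_psf(kind: str, params: dict, pitch) -> PSFModel:
    """Build a normalized system PSF on the HR grid.

    kind = "gaussian": separable Gaussian; params carry ``fwhm_xy`` and
    ``fwhm_z`` in um (or ``sigma_xy``/``sigma_z``).

    kind = "bessel-sheet": axial profile from :func:`sheet_axial_profile`
    (confocal-slit sweep of the Bessel beam) composed with a lateral
    detection Gaussian of FWHM 0.51*lambda/NA_det; params carry a
    :class:`BeamSpec` under key ``spec``.

    kind = "measured": params carry ``kernel`` (3D array).

    The kernel is truncated where intensity falls below ``PSF_TRUNCATION`` of
    the peak, then renormalized to unit sum.
    """
    pitch = tuple(float(p) for p in (pitch if np.iterable(pitch) else (pitch,) * 3))
    if any(p <= 0 for p in pitch):
        raise InvalidSpecError(f"pitch must be positive, got {pitch}")
    pz, py, px = pitch

    if kind in ("gaussian", "parametric-gaussian"):
        if "sigma_xy" in params:
            sx = sy = float(params["sigma_xy"])
        else:
            sx = sy = float(params["fwhm_xy"]) * _FWHM_TO_SIGMA
        if "sigma_z" in params:
            sz = float(params["sigma_z"])
        else:
            sz = float(params["fwhm_z"]) * _FWHM_TO_SIGMA
        if sx <= 0 or sz <= 0:
            raise InvalidSpecError("Gaussian PSF widths must be > 0")
        # size to cover the truncation radius: exp(-r^2/2s^2) = 1e-4 at
        # r = 4.29 sigma
        r_trunc = math.sqrt(-2.0 * math.log(PSF_TRUNCATION))
        half = [int(math.ceil(r_trunc * s / p)) for s, p in ((sz, pz), (sy, py), (sx, px))]
        gz = _gaussian_1d(2 * half[0] + 1, sz / pz)
        gy = _gaussian_1d(2 * half[1] + 1, sy / py)
        gx = _gaussian_1d(2 * half[2] + 1, sx / px)
        kernel = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        provenance = "parametric-gaussian"
    elif kind == "bessel-sheet":
        spec: BeamSpec = params["spec"]
        fwhm_det = 0.51 * spec.wavelength / spec.na_det
        sx = sy = fwhm_det * _FWHM_TO_SIGMA
        # axial: slit-windowed sweep profile, tabulated then sampled
        axial_fwhm = profile_fwhm(lambda zz: float(sheet_axial_profile(zz, spec)))
        half_z = int(math.ceil(4.0 * axial_fwhm / pz))
        zs = np.arange(-half_z, half_z + 1) * pz
        prof_z = sheet_axial_profile(np.abs(zs), spec)
        r_trunc = math.sqrt(-2.0 * math.log(PSF_TRUNCATION))
        half_l = [int(math.ceil(r_trunc * sy / py)), int(math.ceil(r_trunc * sx / px))]
        gy = _gaussian_1d(2 * half_l[0] + 1, sy / py)
        gx = _gaussian_1d(2 * half_l[1] + 1, sx / px)
        kernel = prof_z[:, None, None] * gy[None, :, None] * gx[None, None, :]
        provenance = "bessel-sheet"
    elif kind == "measured":
        kernel = np.asarray(params["kernel"], dtype=float)
        if kernel.ndim != 3:
            raise InvalidSpecError("measured PSF kernel must be 3D")
        provenance = "measured"
    else:
        raise InvalidSpecError(f"unknown PSF kind {kind!r}")

    if kernel.max() <= 0:
        raise InvalidSpecError("PSF kernel is all zero (degenerate)")
    kernel = _truncate(kernel)
    return PSFModel(kernel=kernel, pitch=pitch, provenance=provenance)


def read_psf_tiff(path, pitch=None) -> PSFModel:
    vol = read_tiff(path, pitch=pitch)
    return make_system_psf("measured", {"kernel": vol.data}, vol.pitch)


def write_psf_tiff(path, psf: PSFModel) -> None:
    write_tiff(path, ImageVolume(psf.kernel.astype(np.float32), psf.pitch))


def export_profile(path, position_um: np.ndarray, intensity: np.ndarray) -> None:
    """Write a 2-column delimited text profile (position um, intensity)."""
    np.savetxt(path, np.column_stack([position_um, intensity]), fmt="%.6g", delimiter="\t")
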