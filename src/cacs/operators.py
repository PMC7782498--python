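"""The measurement operator A of the block-wise inverse problem.

The unknown of each block solve is the set of DFT coefficients x of the
high-resolution (HR) image; the measurement is the low-resolution (LR)
spatial block y.  A maps coefficients to LR samples in three steps:

    A x = Bin_s( Re( IDFT( OTF * x ) ) )

i.e. multiplication by the optical transfer function (DFT of the centered
system PSF), inverse transform to the HR spatial grid, and reduction of
each s x s x s cell to one LR voxel, either by its mean (boxcar; camera
pixels integrate photons) or by taking its first sample (decimate).

DFT convention: forward transform unnormalized, inverse carries 1/N.  The
exact adjoint under the standard inner products is then

    Aᴴ y = conj(OTF) * DFT( BinT_s(y) ) / N

with BinT the adjoint of the binning (replication / s^3 for boxcar mean).
Note that with this convention AᴴA = I/N for the identity OTF at s = 1;
the 1/N is the price of the asymmetric DFT normalization and cancels
everywhere it matters (step sizes, lambda scales are all expressed
relative to quantities computed with the same adjoint).

Internally the hermitian-symmetric coefficients of a real image are stored
in the half-spectrum (rfftn) layout; the public ``apply_forward`` /
``apply_adjoint`` accept and return full complex DFT arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as spfft

from .optics import PSFModel

__all__ = [
    "ForwardOperator",
    "CoefficientVector",
    "make_operator",
    "apply_forward",
    "apply_adjoint",
    "lambda_max",
    "operator_norm_sq",
    "spectrum_weights",
]


class ShapeError(ValueError):
    pass


def _as_factor(factor, ndim=3) -> tuple[int, ...]:
    if np.isscalar(factor):
        factor = (int(factor),) * ndim
    factor = tuple(int(f) for f in factor)
    if any(f < 1 for f in factor):
        raise ValueError(f"decimation factor must be >= 1, got {factor}")
    return factor


def bin_boxcar(hr: np.ndarray, factor) -> np.ndarray:
    s0, s1, s2 = factor
    n0, n1, n2 = hr.shape
    return hr.reshape(n0 // s0, s0, n1 // s1, s1, n2 // s2, s2).mean(axis=(1, 3, 5))


def bin_decimate(hr: np.ndarray, factor) -> np.ndarray:
    s0, s1, s2 = factor
    return hr[::s0, ::s1, ::s2]


def bin_boxcar_adjoint(lr: np.ndarray, factor) -> np.ndarray:
    s0, s1, s2 = factor
    out = lr
    for ax, s in enumerate((s0, s1, s2)):
        out = np.repeat(out, s, axis=ax)
    return out / (s0 * s1 * s2)


def bin_decimate_adjoint(lr: np.ndarray, factor, hr_shape) -> np.ndarray:
    out = np.zeros(hr_shape, dtype=lr.dtype)
    s0, s1, s2 = factor
    out[::s0, ::s1, ::s2] = lr
    return out


def spectrum_weights(hr_shape) -> np.ndarray:
    """Multiplicity of each half-spectrum bin in the full spectrum.

    2 for bins whose conjugate partner is not stored, 1 for the
    self-represented planes (last-axis index 0 and, for even sizes, n/2).
    Σ_full f(|x|) = Σ_half w * f(|x_half|) for any even f.
    """
    n_last = hr_shape[-1]
    m = n_last // 2 + 1
    w = np.full(hr_shape[:-1] + (m,), 2.0)
    w[..., 0] = 1.0
    if n_last % 2 == 0:
        w[..., m - 1] = 1.0
    return w


@dataclass
class CoefficientVector:
    """Hermitian-symmetric DFT coefficients of a real HR block.

    Stored in half-spectrum (rfftn) layout; ``full()`` synthesizes the
    redundant full spectrum, ``spatial()`` the real-space image.
    """

    half: np.ndarray
    shape: tuple[int, int, int]

    def full(self) -> np.ndarray:
        return spfft.fftn(self.spatial())

    def spatial(self) -> np.ndarray:
        return spfft.irfftn(self.half, s=self.shape)

    def l1(self) -> float:
        """L1 norm over the full spectrum (complex moduli, DC included)."""
        w = spectrum_weights(self.shape)
        return float(np.sum(w * np.abs(self.half)))

    @classmethod
    def from_full(cls, values: np.ndarray, rtol: float = 1e-10) -> "CoefficientVector":
        values = np.asarray(values)
        spatial = spfft.ifftn(values)
        scale = np.abs(values).max()
        if scale > 0 and np.abs(spatial.imag).max() > rtol * scale:
            raise ValueError("coefficients are not hermitian-symmetric (inverse transform not real)")
        return cls(spfft.rfftn(spatial.real), values.shape)

    @classmethod
    def from_spatial(cls, image: np.ndarray) -> "CoefficientVector":
        image = np.asarray(image)
        return cls(spfft.rfftn(image), image.shape)


@dataclass
class ForwardOperator:
    """A = Bin_s ∘ Re ∘ IDFT ∘ OTF on an HR grid.

    otf_half : DFT of the centered PSF in half-spectrum layout; unit at
        zero frequency for a unit-sum PSF.
    """

    hr_shape: tuple[int, int, int]
    factor: tuple[int, int, int]
    otf_half: np.ndarray
    binning: str = "boxcar"
    workers: int = 1
    _norm_sq: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.hr_shape = tuple(int(n) for n in self.hr_shape)
        self.factor = _as_factor(self.factor)
        if self.binning not in ("boxcar", "decimate"):
            raise ValueError(f"unknown binning mode {self.binning!r}")
        for n, s in zip(self.hr_shape, self.factor):
            if n % s:
                raise ShapeError(f"hr dimension {n} not divisible by factor {s}")

    @property
    def lr_shape(self) -> tuple[int, int, int]:
        return tuple(n // s for n, s in zip(self.hr_shape, self.factor))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.hr_shape))

    # -- half-spectrum fast path (hermitian coefficients of real images) --

    def forward_half(self, x_half: np.ndarray) -> np.ndarray:
        hr = spfft.irfftn(self.otf_half * x_half, s=self.hr_shape, workers=self.workers)
        if self.binning == "boxcar":
            return bin_boxcar(hr, self.factor)
        return bin_decimate(hr, self.factor)

    def adjoint_half(self, y_lr: np.ndarray) -> np.ndarray:
        if self.binning == "boxcar":
            up = bin_boxcar_adjoint(y_lr, self.factor)
        else:
            up = bin_decimate_adjoint(y_lr, self.factor, self.hr_shape)
        return np.conj(self.otf_half) * spfft.rfftn(up, workers=self.workers) / self.n_voxels

    def forward_spatial(self, hr_image: np.ndarray) -> np.ndarray:
        """Blur-and-bin a real HR image (A applied to its DFT)."""
        return self.forward_half(spfft.rfftn(hr_image, workers=self.workers))

    # -- full-spectrum interface --

    def otf_full(self) -> np.ndarray:
        return spfft.fftn(spfft.irfftn(self.otf_half, s=self.hr_shape))

    def norm_sq(self, seed: int = 0, n_iter: int = 40, safety: float = 1.02) -> float:
        """Power-iteration estimate of ||A||^2 (largest eigenvalue of AᴴA).

        Iterates over coefficients of real images (the hermitian subspace,
        where the solver lives; by conjugation symmetry the operator norm
        is attained there).  Slightly inflated by ``safety`` so that it
        upper-bounds Rayleigh quotients.
        """
        if self._norm_sq is None:
            rng = np.random.default_rng(seed)
            v = spfft.rfftn(rng.standard_normal(self.hr_shape))
            w = spectrum_weights(self.hr_shape)
            lam = 0.0
            for _ in range(n_iter):
                mv = self.adjoint_half(self.forward_half(v))
                lam = float(np.sum(w * (np.conj(v) * mv).real) / np.sum(w * np.abs(v) ** 2))
                nv = np.sqrt(np.sum(w * np.abs(mv) ** 2))
                if nv == 0:
                    lam = 0.0
                    break
                v = mv / nv
            self._norm_sq = lam * safety
        return self._norm_sq


def make_operator(
    psf: PSFModel,
    hr_shape,
    factor=4,
    binning: str = "boxcar",
    workers: int = 1,
) -> ForwardOperator:
    """Build the operator for a given HR grid from a normalized PSF.

    The PSF kernel is embedded centered on the grid and circularly shifted
    so its center sits at the zero-phase origin; the OTF is its DFT.
    """
    hr_shape = tuple(int(n) for n in hr_shape)
    factor = _as_factor(factor)
    kernel = psf.kernel
    if any(k > n for k, n in zip(kernel.shape, hr_shape)):
        raise ShapeError(
            f"PSF kernel {kernel.shape} larger than target grid {hr_shape}"
        )
    embed = np.zeros(hr_shape)
    ctr = tuple(n // 2 for n in hr_shape)
    sl = tuple(
        slice(c - k // 2, c - k // 2 + k) for c, k in zip(ctr, kernel.shape)
    )
    embed[sl] = kernel
    otf_half = spfft.rfftn(np.fft.ifftshift(embed))
    return ForwardOperator(hr_shape, factor, otf_half, binning, workers)


def apply_forward(x, op: ForwardOperator) -> np.ndarray:
    """Apply A to full-spectrum coefficients (or a CoefficientVector)."""
    if isinstance(x, CoefficientVector):
        if x.shape != op.hr_shape:
            raise ShapeError(f"coefficient shape {x.shape} != operator {op.hr_shape}")
        return op.forward_half(x.half)
    x = np.asarray(x)
    if x.shape != op.hr_shape:
        raise ShapeError(f"coefficient shape {x.shape} != operator {op.hr_shape}")
    hr = spfft.ifftn(op.otf_full() * x).real
    if op.binning == "boxcar":
        return bin_boxcar(hr, op.factor)
    return bin_decimate(hr, op.factor)


def apply_adjoint(y_lr: np.ndarray, op: ForwardOperator, full: bool = True):
    """Apply the exact adjoint Aᴴ to an LR spatial block.

    Returns the full complex spectrum by default, or a
    :class:`CoefficientVector` (half layout) with ``full=False``.
    """
    y_lr = np.asarray(y_lr)
    if y_lr.shape != op.lr_shape:
        raise ShapeError(f"LR shape {y_lr.shape} != operator {op.lr_shape}")
    half = op.adjoint_half(y_lr.astype(float))
    cv = CoefficientVector(half, op.hr_shape)
    return cv.full() if full else cv


def lambda_max(y_lr: np.ndarray, op: ForwardOperator) -> float:
    """Smallest λ for which x = 0 minimizes ‖Ax−y‖² + λ‖x‖₁.

    Equals 2·max|Aᴴy| over coefficients (the KKT threshold: at x = 0 the
    subgradient condition is |2Aᴴy|_j ≤ λ for every j).
    """
    y_lr = np.asarray(y_lr, dtype=float)
    if y_lr.shape != op.lr_shape:
        raise ShapeError(f"LR shape {y_lr.shape} != operator {op.lr_shape}")
    return 2.0 * float(np.abs(op.adjoint_half(y_lr)).max())


def operator_norm_sq(op: ForwardOperator, seed: int = 0, n_iter: int = 60) -> float:
    return op.norm_sq(seed=seed, n_iter=n_iter)
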