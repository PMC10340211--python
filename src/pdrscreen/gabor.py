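"""2D continuous Gabor wavelet transform, computed in the frequency domain.

The Gabor wavelet is a complex exponential with carrier k0 under an
anisotropic Gaussian envelope,

    psi(x) = exp(j k0.x) exp(-|A x|^2 / 2),   A = diag(eps^(-1/2), 1),

whose Fourier transform is a Gaussian in frequency centered at k0,

    psi_hat(k) = det(B)^(1/2) exp(-|B (k - k0)|^2 / 2),   B = A^(-1).

The elongation eps >= 1 stretches the spatial envelope along x, making the
wavelet an oriented line detector; eps = 1 is isotropic.  The transform at
position b, angle theta and scale a is evaluated for every b at once as an
inverse FFT of g_hat(k) * psi_hat(a r_{-theta} k), scaled by a.  The
admissibility constant C_psi only rescales magnitudes globally and is fixed
to 1; the kernel's DC bin is zeroed so that flat regions give exactly zero
response.  Orientation is swept over a grid (default 0..170 deg in 10 deg
steps; line detection is 180 deg periodic) and the per-pixel maximum modulus
is the vessel-enhancement map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GaborPathConfig

__all__ = [
    "GaborBankParams",
    "ResponseMap",
    "gabor_kernel_spatial",
    "gabor_kernel_freq",
    "cwt_response",
    "orientation_max",
]

_DEFAULT_THETAS = tuple(float(t) for t in range(0, 180, 10))


@dataclass(frozen=True)
class GaborBankParams:
    """Parameters of one Gabor filter bank.

    ``k0`` is the carrier frequency vector (kx, ky) in radians/pixel before
    rotation; the bracketed magnitudes quoted for fundus work correspond to
    k0 = (0, |k0|).
    """

    dilation: float
    elongation: float
    k0: tuple[float, float]
    thetas: tuple[float, ...] = _DEFAULT_THETAS

    def __post_init__(self) -> None:
        if self.elongation < 1:
            raise ValueError(f"elongation must be >= 1, got {self.elongation}")
        if len(self.thetas) == 0:
            raise ValueError("theta grid must be non-empty")
        if np.hypot(*self.k0) <= 0:
            raise ValueError("|k0| must be > 0")

    @classmethod
    def from_path_config(cls, path: GaborPathConfig,
                         thetas: tuple[float, ...] = _DEFAULT_THETAS,
                         ) -> "GaborBankParams":
        return cls(dilation=path.dilation, elongation=path.elongation,
                   k0=(0.0, path.k0_mag), thetas=thetas)


@dataclass(frozen=True)
class ResponseMap:
    """Per-pixel orientation-maximum modulus of the Gabor transform."""

    m_psi: np.ndarray           # float64, >= 0
    scale_a: float
    params: GaborBankParams = field(repr=False)


def gabor_kernel_spatial(params: GaborBankParams, shape: tuple[int, int],
                         theta: float = 0.0, scale_a: float = 1.0) -> np.ndarray:
    """Sample the spatial-domain wavelet on a centered grid (for duality checks).

    Returns psi((r_{-theta} x) / a) on integer coordinates centered at
    shape//2, without the 1/a normalization (absorbed into the transform).
    """
    eps = params.elongation
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    x -= w // 2
    y -= h // 2
    t = np.deg2rad(theta)
    # rotate coordinates by -theta, then divide by the dilation
    xr = (np.cos(t) * x + np.sin(t) * y) / scale_a
    yr = (-np.sin(t) * x + np.cos(t) * y) / scale_a
    k0x, k0y = params.k0
    carrier = np.exp(1j * (k0x * xr + k0y * yr))
    envelope = np.exp(-0.5 * (xr * xr / eps + yr * yr))
    return carrier * envelope


def _freq_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    ky = 2 * np.pi * np.fft.fftfreq(h)[:, None]
    kx = 2 * np.pi * np.fft.fftfreq(w)[None, :]
    return kx, ky


def gabor_kernel_freq(params: GaborBankParams, theta: float, scale_a: float,
                      shape: tuple[int, int], remove_dc: bool = False) -> np.ndarray:
    """Evaluate psi_hat(a r_{-theta} k) on the FFT frequency grid of ``shape``.

    The result is real and non-negative (a Gaussian in frequency) with peak
    value det(B)^(1/2) = eps^(1/4) near k = r_theta(k0)/a.  With
    ``remove_dc`` the k = 0 bin is zeroed so a constant image yields zero
    transform.
    """
    eps = params.elongation
    kx, ky = _freq_grid(shape)
    t = np.deg2rad(theta)
    # u = a * r_{-theta} k
    ux = scale_a * (np.cos(t) * kx + np.sin(t) * ky)
    uy = scale_a * (-np.sin(t) * kx + np.cos(t) * ky)
    k0x, k0y = params.k0
    # |B (u - k0)|^2 with B = diag(eps^(1/2), 1)
    quad = eps * (ux - k0x) ** 2 + (uy - k0y) ** 2
    kern = eps**0.25 * np.exp(-0.5 * quad)
    if remove_dc:
        kern = kern.copy()
        kern[0, 0] = 0.0
    return kern


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def cwt_response(img: np.ndarray, params: GaborBankParams, theta: float,
                 scale_a: float | None = None, pad: bool = True) -> np.ndarray:
    """Gabor transform T_psi(b, theta, a) for all positions b.

    Computed as a * IFFT[ g_hat(k) psi_hat(a r_{-theta} k) ] with the DC bin
    removed.  With ``pad`` the image is mirror-padded to the next power of
    two per axis before filtering and cropped afterwards, suppressing
    wrap-around ridge artifacts at the field edge; padding preserves
    linearity.
    """
    img = np.asarray(img, dtype=np.float64)
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite pixels")
    a = params.dilation if scale_a is None else scale_a
    h, w = img.shape
    if pad:
        ph, pw = _next_pow2(h), _next_pow2(w)
        work = np.pad(img, ((0, ph - h), (0, pw - w)), mode="symmetric")
    else:
        work = img
    kern = gabor_kernel_freq(params, theta, a, work.shape, remove_dc=True)
    resp = np.fft.ifft2(np.fft.fft2(work) * kern) * a
    return resp[:h, :w]


def orientation_max(img: np.ndarray, params: GaborBankParams,
                    scale_a: float | None = None, pad: bool = True) -> ResponseMap:
    """Maximum modulus of the Gabor transform over the orientation grid."""
    a = params.dilation if scale_a is None else scale_a
    m = None
    for theta in params.thetas:
        mod = np.abs(cwt_response(img, params, theta, a, pad=pad))
        m = mod if m is None else np.maximum(m, mod)
    return ResponseMap(m_psi=m, scale_a=a, params=params)
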