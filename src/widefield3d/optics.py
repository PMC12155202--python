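"""Depth-variant theoretical widefield PSFs and sampling utilities.

The point spread function is computed from a scalar-diffraction pupil
integral of Gibson–Lanni type.  Exactly three optical quantities beyond the
objective itself control the depth dependence: the immersion refractive index
``n_i``, the sample (embedding) refractive index ``n_s``, and the nominal
depth of the plane below the coverslip.  The refractive-index mismatch adds
an optical-path-difference term that accumulates linearly with depth,

    OPD(rho; d) = d * (n_s cos(theta_s) - n_i cos(theta_i)),

with sin(theta_i) = NA rho / n_i and sin(theta_s) = NA rho / n_s for the
normalized pupil radius rho in [0, 1].  When ``n_s == n_i`` the term vanishes
identically and the PSF is depth-invariant.  The amplitude PSF at defocus
``z`` and lateral radius ``r`` is

    U(z, r) = int_0^1 J0(k0 NA r rho) exp(i k0 (z n_i cos(theta_i) + OPD)) rho drho

with ``k0 = 2 pi / lambda_em``; the intensity PSF is |U|^2, normalized to
unit sum over its support.  The integral is evaluated by Gauss–Legendre
quadrature (>= 200 nodes over the pupil radius) on a fine radial grid and
interpolated onto the voxel lattice, which makes the kernel radially
symmetric up to grid discretization by construction.

A widefield PSF conserves energy per defocus plane (no optical sectioning),
so no finite box captures "all" of it: support selection is an explicit
truncation policy (see :func:`default_support`) and kernels are renormalized
to unit sum after truncation; a warning is emitted when the border shell
still carries a non-negligible energy fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j0

from ._util import as_odd

__all__ = [
    "OpticalConfig",
    "DepthVariantPSFBank",
    "nyquist_axial_um",
    "generate_psf",
    "build_psf_bank",
    "default_support",
    "psf_lateral_extent_um",
    "psf_axial_fwhm_um",
]

#: Default hard cap on kernel support (z, y, x) in voxels.
DEFAULT_MAX_SUPPORT = (161, 61, 61)

_N_PUPIL_NODES = 256


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the acquisition.

    Attributes
    ----------
    na
        Numerical aperture; must satisfy ``0 < na < n_immersion``.
    n_immersion
        Refractive index of the lens immersion medium (water: 1.33).
    n_sample
        Refractive index of the sample embedding medium (cleared tissue: 1.50).
    coverslip_distance_um
        Distance from the coverslip to the first acquired plane, in um.
    em_wavelength_nm
        Emission wavelength of the active channel, in nm.
    voxel_size
        (dz, dy, dx) in um.
    imaging_direction
        "downward": z index 0 is the plane nearest the coverslip.
    """

    na: float
    n_immersion: float = 1.33
    n_sample: float = 1.50
    coverslip_distance_um: float = 0.0
    em_wavelength_nm: float = 520.0
    voxel_size: tuple[float, float, float] = (0.8, 0.34, 0.34)
    imaging_direction: str = "downward"

    def __post_init__(self) -> None:
        if not 0.0 < self.na < self.n_immersion:
            raise ValueError(
                f"need 0 < NA < n_immersion for a well-defined half-angle; "
                f"got NA={self.na}, n_immersion={self.n_immersion}"
            )
        for label, n in (("n_immersion", self.n_immersion), ("n_sample", self.n_sample)):
            if not 1.0 <= n <= 2.0:
                raise ValueError(f"{label}={n} outside the physical range [1, 2]")
        if self.coverslip_distance_um < 0:
            raise ValueError("coverslip_distance_um must be >= 0")
        if self.em_wavelength_nm <= 0:
            raise ValueError("em_wavelength_nm must be positive")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive values (dz, dy, dx)")
        if self.imaging_direction not in ("downward", "upward"):
            raise ValueError(f"unknown imaging direction {self.imaging_direction!r}")

    def with_wavelength(self, em_wavelength_nm: float) -> "OpticalConfig":
        return replace(self, em_wavelength_nm=em_wavelength_nm)

    def plane_depth_um(self, z_index: float) -> float:
        """Nominal depth below the coverslip of plane ``z_index``."""
        return self.coverslip_distance_um + z_index * self.voxel_size[0]


@dataclass
class DepthVariantPSFBank:
    """PSF kernels sampled at strictly increasing nominal depths, shared support."""

    kernels: list[np.ndarray]
    nominal_depths_um: list[float]
    support: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("PSF bank must hold at least one kernel")
        if len(self.kernels) != len(self.nominal_depths_um):
            raise ValueError("one nominal depth per kernel required")
        d = np.asarray(self.nominal_depths_um, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise ValueError("nominal depths must be strictly increasing")
        for k in self.kernels:
            if tuple(k.shape) != tuple(self.support):
                raise ValueError("all kernels must share the bank support")
            if k.min() < 0 or abs(k.sum() - 1.0) > 1e-6:
                raise ValueError("kernels must be non-negative and unit-sum")

    def kernel_for_depth(self, depth_um: float) -> np.ndarray:
        """Kernel whose nominal depth is nearest the requested depth."""
        i = int(np.argmin(np.abs(np.asarray(self.nominal_depths_um) - depth_um)))
        return self.kernels[i]


def nyquist_axial_um(cfg: OpticalConfig) -> float:
    """Axial Nyquist sampling interval in micrometers.

    lambda_em / (4 n_i (1 - cos(asin(NA / n_i)))) — the largest z-step that
    samples the widefield optical transfer function without axial aliasing.
    """
    lam_um = cfg.em_wavelength_nm * 1e-3
    cos_t = math.cos(math.asin(cfg.na / cfg.n_immersion))
    return lam_um / (4.0 * cfg.n_immersion * (1.0 - cos_t))


def _pupil_nodes(n: int = _N_PUPIL_NODES) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def _radial_intensity(
    cfg: OpticalConfig, depth_um: float, z_um: np.ndarray, r_um: np.ndarray
) -> np.ndarray:
    """Intensity PSF sampled on a (defocus, lateral-radius) grid."""
    rho, w = _pupil_nodes()
    k0 = 2.0 * math.pi / (cfg.em_wavelength_nm * 1e-3)
    sin_i = cfg.na * rho / cfg.n_immersion
    cos_i = np.sqrt(np.clip(1.0 - sin_i**2, 0.0, None))
    sin_s = cfg.na * rho / cfg.n_sample
    cos_s = np.sqrt(np.clip(1.0 - sin_s**2, 0.0, None))
    opd = depth_um * (cfg.n_sample * cos_s - cfg.n_immersion * cos_i)
    opd = opd - opd[0]  # remove piston; |U|^2 is unaffected but keeps phases small
    bessel = j0(k0 * cfg.na * np.outer(r_um, rho))  # (nr, nrho)
    phase = k0 * (np.outer(z_um, cfg.n_immersion * cos_i) + opd[None, :])  # (nz, nrho)
    amp = (w * rho)[None, :] * np.exp(1j * phase)
    field = amp @ bessel.T
    return np.ascontiguousarray(np.abs(field) ** 2)


def _focal_shift_um(cfg: OpticalConfig, depth_um: float) -> float:
    """Defocus position of the peak on-axis intensity (spherical-aberration focal shift)."""
    if depth_um == 0 or cfg.n_sample == cfg.n_immersion:
        return 0.0
    span = 0.2 * depth_um + 10.0
    z = np.linspace(-span, span, 801)
    prof = _radial_intensity(cfg, depth_um, z, np.array([0.0]))[:, 0]
    return float(z[int(np.argmax(prof))])


def _onaxis_fwhm_um(cfg: OpticalConfig, depth_um: float) -> float:
    shift = _focal_shift_um(cfg, depth_um)
    span = 20.0 + 0.05 * depth_um
    z = np.linspace(shift - span, shift + span, 4001)
    prof = _radial_intensity(cfg, depth_um, z, np.array([0.0]))[:, 0]
    return _fwhm_from_profile(z, prof)


def _fwhm_from_profile(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum around the global peak, linear interpolation."""
    pk = int(np.argmax(y))
    half = y[pk] / 2.0
    i = pk
    while i > 0 and y[i - 1] >= half:
        i -= 1
    lo = x[i] if i == 0 else np.interp(half, [y[i - 1], y[i]], [x[i - 1], x[i]])
    j = pk
    while j < len(y) - 1 and y[j + 1] >= half:
        j += 1
    hi = x[j] if j == len(y) - 1 else np.interp(half, [y[j + 1], y[j]], [x[j + 1], x[j]])
    return float(hi - lo)


def default_support(
    cfg: OpticalConfig,
    nominal_depth_um: float,
    max_support: tuple[int, int, int] = DEFAULT_MAX_SUPPORT,
) -> tuple[int, int, int]:
    """Choose an odd kernel support for the given depth.

    Lateral half-width: three times the 99%-energy radius of the in-focus
    plane.  Axial half-width: the spherical-aberration focal shift plus four
    axial FWHMs — wide enough to hold the displaced, depth-broadened main
    lobe.  Both are capped by ``max_support``; the residual out-of-box energy
    of the (non-convergent) widefield PSF is accepted as the truncation
    policy and flagged by :func:`generate_psf` when large.
    """
    dz, dy, dx = cfg.voxel_size
    dr = min(dy, dx)
    lam_um = cfg.em_wavelength_nm * 1e-3
    shift = abs(_focal_shift_um(cfg, nominal_depth_um))
    r = np.linspace(0.0, 60.0 * lam_um / cfg.na, 2048)
    plane = _radial_intensity(cfg, nominal_depth_um, np.array([shift]), r)[0]
    cum = np.cumsum(plane * r)
    cum /= cum[-1]
    r99 = float(r[int(np.searchsorted(cum, 0.99))])
    half_xy = max(3, int(math.ceil(3.0 * r99 / dr)))
    fwhm = _onaxis_fwhm_um(cfg, nominal_depth_um)
    half_z = max(4, int(math.ceil((shift + 4.0 * fwhm) / dz)))
    caps = [m if m % 2 == 1 else m - 1 for m in max_support]
    return (
        min(as_odd(2 * half_z + 1), caps[0]),
        min(as_odd(2 * half_xy + 1), caps[1]),
        min(as_odd(2 * half_xy + 1), caps[2]),
    )


def generate_psf(
    cfg: OpticalConfig,
    nominal_depth_um: float,
    support: tuple[int, int, int] | None = None,
    warn_energy: bool = True,
) -> np.ndarray:
    """Theoretical widefield PSF kernel at the given nominal depth.

    Returns a non-negative, unit-sum (z, y, x) kernel on an odd support.
    Warns if the outermost voxel shell of the chosen support still carries
    more than 1% of the in-box energy (truncation of the non-convergent
    widefield PSF).
    """
    if nominal_depth_um < 0:
        raise ValueError("nominal_depth_um must be >= 0")
    if support is None:
        support = default_support(cfg, nominal_depth_um)
    sz, sy, sx = (int(s) for s in support)
    if sy % 2 == 0 or sx % 2 == 0:
        raise ValueError("kernel support must be odd in y and x")
    if sz % 2 == 0:
        raise ValueError("kernel support must be odd in z")
    dz, dy, dx = cfg.voxel_size

    # Kernel index convention: (iz - center) = detection plane index minus
    # emitter plane index.  With n_sample > n_immersion the true focus lies
    # deeper than the nominal plane, so an emitter's in-focus image appears at
    # a *shallower* nominal index: the defocus coordinate runs opposite to the
    # stack index, hence the sign flip.
    z = -(np.arange(sz) - sz // 2) * dz
    yy = (np.arange(sy) - sy // 2) * dy
    xx = (np.arange(sx) - sx // 2) * dx
    rad = np.hypot(yy[:, None], xx[None, :])
    rmax = float(rad.max())
    nr = max(256, 4 * max(sy, sx))
    r_grid = np.linspace(0.0, rmax, nr)
    prof = _radial_intensity(cfg, nominal_depth_um, z, r_grid)  # (sz, nr)

    kernel = np.empty((sz, sy, sx))
    flat_r = rad.ravel()
    for iz in range(sz):
        kernel[iz] = np.interp(flat_r, r_grid, prof[iz]).reshape(sy, sx)
    np.clip(kernel, 0.0, None, out=kernel)
    total = kernel.sum()
    if total <= 0:
        raise ValueError("degenerate PSF (all-zero on the requested support)")

    if warn_energy:
        inner = kernel[1:-1, 1:-1, 1:-1].sum() if min(sz, sy, sx) > 2 else 0.0
        shell_frac = 1.0 - inner / total
        if shell_frac > 0.01:
            warnings.warn(
                f"PSF support {support} captures <99% of in-box energy "
                f"(border shell holds {shell_frac:.1%}); consider a larger support",
                RuntimeWarning,
                stacklevel=2,
            )
    kernel /= total
    return kernel


def build_psf_bank(
    cfg: OpticalConfig,
    depths_um,
    support: tuple[int, int, int] | None = None,
    max_support: tuple[int, int, int] = DEFAULT_MAX_SUPPORT,
    warn_energy: bool = True,
) -> DepthVariantPSFBank:
    """One kernel per nominal depth, all on a shared support.

    The shared support is the per-axis maximum of the per-depth default
    supports unless given explicitly.
    """
    depths = [float(d) for d in depths_um]
    if not depths:
        raise ValueError("depth list must not be empty")
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    if support is None:
        sup = np.array([default_support(cfg, d, max_support) for d in depths])
        support = tuple(int(s) for s in sup.max(axis=0))
    kernels = [generate_psf(cfg, d, support=support, warn_energy=warn_energy)
               for d in depths]
    return DepthVariantPSFBank(kernels=kernels, nominal_depths_um=depths, support=tuple(support))


def psf_lateral_extent_um(kernel: np.ndarray, voxel_size) -> float:
    """Radius enclosing 95% of the in-focus plane's energy, in micrometers.

    The in-focus plane is taken as the z-plane of maximum energy; a
    single-voxel (delta-like) plane has extent 0.
    """
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 3:
        raise ValueError("kernel must be 3D (z, y, x)")
    total = kernel.sum()
    if total <= 0:
        raise ValueError("degenerate all-zero kernel")
    _, dy, dx = voxel_size
    plane = kernel[int(np.argmax(kernel.sum(axis=(1, 2))))]
    sy, sx = plane.shape
    yy = (np.arange(sy) - sy // 2) * dy
    xx = (np.arange(sx) - sx // 2) * dx
    rad = np.hypot(yy[:, None], xx[None, :]).ravel()
    vals = plane.ravel()
    order = np.argsort(rad)
    cum = np.cumsum(vals[order])
    psum = cum[-1]
    if psum <= 0:
        raise ValueError("in-focus plane carries no energy")
    idx = int(np.searchsorted(cum, 0.95 * psum))
    return float(rad[order][min(idx, len(order) - 1)])


def psf_axial_fwhm_um(kernel: np.ndarray, dz_um: float) -> float:
    """FWHM of the kernel's central axial column, linearly interpolated."""
    kernel = np.asarray(kernel, dtype=float)
    sz, sy, sx = kernel.shape
    col = kernel[:, sy // 2, sx // 2]
    z = (np.arange(sz) - sz // 2) * dz_um
    return _fwhm_from_profile(z, col)
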