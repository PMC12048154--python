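"""Optical-characterization fitting.

Tools to turn measured (or simulated) intensity profiles into resolution
numbers: single/double Gaussian fits of bead profiles, the axial-resolution
rule (FWHM of a single Gaussian; for a double Gaussian the sum of the two
half-widths at half maximum plus the peak separation), and least-squares
quartic fits of resolution/magnification versus radial distance. Also
generates bead-phantom z-profiles directly from an optics model so the
simulator's PSF behaviour can be re-measured and compared with its own
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .optics import OpticsModel, psf_axes

__all__ = [
    "ProfileFit",
    "fit_gaussian_fwhm",
    "fit_double_gaussian",
    "axial_resolution_from_profile",
    "fit_quartic",
    "bead_axial_profile",
    "bead_profile_from_stack",
    "psf_model_from_measurements",
    "GAUSS_FWHM_FACTOR",
]

GAUSS_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = factor * sigma


@dataclass
class ProfileFit:
    model: str  # 'gaussian' | 'double_gaussian' | 'quartic' | 'quartic_linear'
    params: np.ndarray
    fwhm: float | None
    resolution: float | None
    residual_norm: float
    converged: bool


def _gauss(x, amp, mu, sigma, off):
    return off + amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _double_gauss(x, a1, m1, s1, a2, m2, s2, off):
    return (
        off
        + a1 * np.exp(-((x - m1) ** 2) / (2.0 * s1**2))
        + a2 * np.exp(-((x - m2) ** 2) / (2.0 * s2**2))
    )


def fit_gaussian_fwhm(position: np.ndarray, intensity: np.ndarray) -> ProfileFit:
    """Least-squares single-Gaussian fit; FWHM = 2*sqrt(2 ln 2) * sigma."""
    x = np.asarray(position, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples")
    if y.max() <= y.min():
        return ProfileFit("gaussian", np.full(4, np.nan), None, None, np.inf, False)
    amp0 = y.max() - y.min()
    mu0 = x[np.argmax(y)]
    s0 = max((x.max() - x.min()) / 6.0, 1e-6)
    try:
        p, _ = curve_fit(
            _gauss, x, y, p0=(amp0, mu0, s0, y.min()), maxfev=10_000
        )
    except RuntimeError:
        return ProfileFit("gaussian", np.full(4, np.nan), None, None, np.inf, False)
    sigma = abs(p[2])
    resid = float(np.linalg.norm(y - _gauss(x, *p)))
    fwhm = GAUSS_FWHM_FACTOR * sigma
    return ProfileFit("gaussian", p, float(fwhm), float(fwhm), resid, True)


def fit_double_gaussian(position: np.ndarray, intensity: np.ndarray) -> ProfileFit:
    """Two-Gaussian fit; resolution = HWHM1 + HWHM2 + |peak separation|."""
    x = np.asarray(position, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.size < 7:
        raise ValueError("need at least 7 samples")
    amp0 = y.max() - y.min()
    mu0 = x[np.argmax(y)]
    span = x.max() - x.min()
    s0 = max(span / 8.0, 1e-6)
    try:
        p, _ = curve_fit(
            _double_gauss,
            x,
            y,
            p0=(amp0, mu0 - span / 8.0, s0, amp0, mu0 + span / 8.0, s0, y.min()),
            maxfev=20_000,
        )
    except RuntimeError:
        return ProfileFit(
            "double_gaussian", np.full(7, np.nan), None, None, np.inf, False
        )
    s1, s2 = abs(p[2]), abs(p[5])
    res = 0.5 * GAUSS_FWHM_FACTOR * s1 + 0.5 * GAUSS_FWHM_FACTOR * s2 + abs(p[4] - p[1])
    resid = float(np.linalg.norm(y - _double_gauss(x, *p)))
    return ProfileFit("double_gaussian", p, None, float(res), resid, True)


def axial_resolution_from_profile(
    position: np.ndarray,
    intensity: np.ndarray,
    double_improvement: float = 0.2,
) -> ProfileFit:
    """Axial resolution with single/double Gaussian model selection.

    The double-Gaussian model is preferred only when it reduces the
    residual sum of squares by more than ``double_improvement`` (fraction);
    for the single model the resolution is the FWHM, for the double model
    the sum of the two HWHMs plus the distance between the peaks.
    """
    single = fit_gaussian_fwhm(position, intensity)
    if not single.converged:
        return single
    y = np.asarray(intensity, dtype=float)
    scale = np.linalg.norm(y - y.mean())
    if scale == 0 or single.residual_norm / scale < 1e-3:
        return single  # single Gaussian already fits to numerical precision
    try:
        double = fit_double_gaussian(position, intensity)
    except ValueError:
        return single
    if (
        double.converged
        and double.residual_norm**2 < (1.0 - double_improvement) * single.residual_norm**2
    ):
        return double
    return single


def fit_quartic(x, y, with_linear_term: bool = False) -> np.ndarray:
    """Least squares on the quartic basis.

    ``with_linear_term=False``: f(x) = a x^4 + b x^2 + c, returns (a, b, c).
    ``with_linear_term=True``: g(x) = d x^4 + e x^2 + f x + h, returns
    (d, e, f, h).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if with_linear_term:
        design = np.column_stack([x**4, x**2, x, np.ones_like(x)])
    else:
        design = np.column_stack([x**4, x**2, np.ones_like(x)])
    if x.size < design.shape[1]:
        raise ValueError("not enough samples for the basis")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient quartic design")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def bead_profile_from_stack(
    stack_or_path, dz_um: float, roi_halfwidth_px: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Axial intensity profile of one bead from a (z, y, x) stack.

    ``stack_or_path`` is an array or a TIFF path. The bead is located at
    the brightest pixel of the maximum projection; the profile is the mean
    over a small square ROI around it, background-subtracted by the stack
    median. Returns (z positions µm, intensity).
    """
    if isinstance(stack_or_path, (str, bytes)) or hasattr(stack_or_path, "__fspath__"):
        import tifffile

        stack = tifffile.imread(stack_or_path)
    else:
        stack = np.asarray(stack_or_path)
    if stack.ndim != 3:
        raise ValueError("expected a (z, y, x) stack")
    proj = stack.max(axis=0)
    cy, cx = np.unravel_index(np.argmax(proj), proj.shape)
    h = roi_halfwidth_px
    sub = stack[
        :,
        max(0, cy - h) : cy + h + 1,
        max(0, cx - h) : cx + h + 1,
    ]
    profile = sub.mean(axis=(1, 2)) - np.median(stack)
    z = np.arange(stack.shape[0]) * dz_um
    return z, profile


def psf_model_from_measurements(
    radii_um, axial_um, lateral_um, **caps
) -> "object":
    """Fit the quartic radial PSF model to measured resolutions.

    Returns a ready-to-use optics PSF block fitted with the even quartic
    basis at the supplied radii.
    """
    from .optics import PSFSizeModel

    ax = fit_quartic(np.asarray(radii_um, float), np.asarray(axial_um, float))
    lat = fit_quartic(np.asarray(radii_um, float), np.asarray(lateral_um, float))
    return PSFSizeModel(axial=tuple(ax), lateral=tuple(lat), **caps)


def bead_axial_profile(
    optics: OpticsModel,
    radius_um: float,
    z_range_um: float = 40.0,
    dz_um: float = 0.25,
    surface: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial intensity profile of a subresolved bead at a given radius.

    Emulates stepping the focus through a point-like bead sitting on the
    focal surface at radial distance ``radius_um``, with the scan following
    the excitation-volume axis (orthogonal to the focal surface, i.e. the
    local propagation direction). The profile is the Gaussian-weighted
    excitation along that axis, so re-fitting it isolates the configured
    axial FWHM at that radius; a scan constrained to the laboratory z axis
    would instead mix in the (much tighter) lateral confinement wherever
    the focal surface is tilted. Returns (axis offsets µm, intensity).
    """
    _, ax = psf_axes(radius_um, optics.psf)
    z = np.arange(-z_range_um, z_range_um + dz_um / 2.0, dz_um)
    s_ax = ax / GAUSS_FWHM_FACTOR
    intensity = np.exp(-(z**2) / (2 * s_ax**2))
    return z, intensity
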