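"""Geometric-optics models of GRIN microendoscopes.

Everything here is rotationally symmetric about the optical axis: the
asphere sag of the corrective lens profile, the imaging focal surface
(a fifth-order polynomial of radial distance for corrected probes, one or
two spherical shells — astigmatism — for uncorrected probes), quartic
radial models of the lateral/axial PSF FWHM, the magnification/distance
distortion calibration, and the radial excitation-intensity profile.

Default model coefficients for the four probe types (corrected/uncorrected
x 6.4 mm/8.8 mm) are reconstructions chosen to reproduce the published
summary quantities (effective FOV radii of 46/100 µm and 34/52 µm at the
10 µm axial-resolution threshold), not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "AsphereProfile",
    "FocalSurfaceModel",
    "PSFSizeModel",
    "MagnificationModel",
    "RadialIntensityProfile",
    "OpticsModel",
    "asphere_sag",
    "focal_surface_height",
    "surface_normal",
    "psf_axes",
    "magnification_factor",
    "real_distance",
    "nominal_distance",
    "effective_fov_radius",
    "fov_fold_report",
    "default_optics",
    "PROBE_TYPES",
    "AXIAL_RESOLUTION_THRESHOLD",
]

#: axial-resolution threshold (µm) defining the effective FOV radius
AXIAL_RESOLUTION_THRESHOLD = 10.0

PROBE_TYPES = (
    "corrected-6.4",
    "uncorrected-6.4",
    "corrected-8.8",
    "uncorrected-8.8",
)


@dataclass
class AsphereProfile:
    """Aspheric surface sag parameters: curvature c=1/R (µm^-1), conic
    constant k, and even asphericity coefficients alpha_n (n = 1..4)."""

    c: float
    k: float = 0.0
    alpha: tuple[float, ...] = ()


def asphere_sag(r, profile: AsphereProfile):
    """Surface sag Z(r) = c r^2 / (1 + sqrt(1 - (1+k) c^2 r^2)) + sum a_n r^2n.

    Raises a domain error (naming the largest admissible radius) where the
    square-root argument would go negative.
    """
    r = np.asarray(r, dtype=float)
    c, k = profile.c, profile.k
    arg = 1.0 - (1.0 + k) * c**2 * r**2
    if np.any(arg < -1e-12):
        r_max = np.inf if (1.0 + k) * c**2 <= 0 else 1.0 / np.sqrt((1.0 + k) * c**2)
        raise ValueError(f"asphere sag undefined beyond r = {r_max:.6g} µm")
    arg = np.clip(arg, 0.0, None)
    z = c * r**2 / (1.0 + np.sqrt(arg))
    for n, a in enumerate(profile.alpha, start=1):
        z = z + a * r ** (2 * n)
    return z if z.ndim else float(z)


def _sphere_sag(r, radius: float):
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= radius):
        raise ValueError(f"radius {radius} µm shell undefined at r >= {radius} µm")
    return radius - np.sqrt(radius**2 - r**2)


@dataclass
class FocalSurfaceModel:
    """Imaging focal surface(s), rotationally symmetric about the axis.

    ``kind='polynomial'``: sag(r) = sum_i poly_coeffs[i] * r^i (i = 0..5).
    ``kind='spherical_shells'``: one sag per shell, R - sqrt(R^2 - r^2).
    ``center_depth`` (µm) anchors the surface at the axis inside the tissue
    volume; ``sign=-1`` (default) curves the surface toward the probe front
    end at the FOV margin, matching the observation that off-axis cells sit
    closer to the probe. Depth of the surface at radius r is
    ``center_depth + sign * sag(r)``.
    """

    kind: str
    poly_coeffs: tuple[float, ...] = ()
    shell_radii: tuple[float, ...] = ()
    center_depth: float = 0.0
    sign: float = -1.0

    def __post_init__(self):
        if self.kind not in ("polynomial", "spherical_shells"):
            raise ValueError("kind must be 'polynomial' or 'spherical_shells'")

    @property
    def n_surfaces(self) -> int:
        return 1 if self.kind == "polynomial" else len(self.shell_radii)


def focal_surface_height(r, model: FocalSurfaceModel) -> np.ndarray:
    """Sag(s) of the focal surface(s) at radius r, anchored to 0 on axis.

    Polynomial models return shape ``r.shape``; shell models return one sag
    per shell stacked on a leading axis.
    """
    r = np.asarray(r, dtype=float)
    if model.kind == "polynomial":
        z = np.zeros_like(r)
        for i, cfs in enumerate(model.poly_coeffs):
            z = z + cfs * r**i
        z = z - (model.poly_coeffs[0] if model.poly_coeffs else 0.0)  # anchor Z(0)=0
        return z
    return np.stack([_sphere_sag(r, R) for R in model.shell_radii])


def surface_depth(r, model: FocalSurfaceModel) -> np.ndarray:
    """Absolute depth(s) (µm) of the focal surface(s) at radius r."""
    return model.center_depth + model.sign * focal_surface_height(r, model)


def _surface_slope(r, model: FocalSurfaceModel, surface: int = 0):
    """d(sag)/dr of one surface."""
    r = np.asarray(r, dtype=float)
    if model.kind == "polynomial":
        s = np.zeros_like(r)
        for i, cfs in enumerate(model.poly_coeffs):
            if i >= 1:
                s = s + i * cfs * r ** (i - 1)
        return s
    R = model.shell_radii[surface]
    return r / np.sqrt(R**2 - r**2)


def surface_normal(r, model: FocalSurfaceModel, surface: int = 0) -> np.ndarray:
    """Unit normal of the rotationally symmetric surface at radius ``r``.

    Returned in the (radial, axial-depth) plane as a 3-vector
    ``(n_r, 0, n_z)`` with ``n_z > 0``; the depth component accounts for the
    surface orientation ``sign``.
    """
    r = float(r)
    slope = float(_surface_slope(abs(r), model, surface)) * model.sign
    n = np.array([-slope, 0.0, 1.0])
    return n / np.linalg.norm(n)


@dataclass
class PSFSizeModel:
    """Quartic radial models of the excitation-volume FWHM (µm).

    ``axial`` and ``lateral`` are (a, b, c) with f(r) = a r^4 + b r^2 + c.
    The quartics are fits over a finite measured range; ``axial_cap_um`` and
    ``lateral_cap_um`` clip the extrapolation at large radii where a quartic
    diverges unphysically.
    """

    axial: tuple[float, float, float]
    lateral: tuple[float, float, float]
    axial_cap_um: float = 40.0
    lateral_cap_um: float = 10.0


def _quartic(r, coeffs):
    a, b, c = coeffs
    return a * r**4 + b * r**2 + c


def psf_axes(r, model: PSFSizeModel) -> tuple[np.ndarray, np.ndarray]:
    """(lateral FWHM, axial FWHM) in µm at radius r, extrapolation-capped."""
    r = np.asarray(r, dtype=float)
    lat = np.minimum(_quartic(r, model.lateral), model.lateral_cap_um)
    ax = np.minimum(_quartic(r, model.axial), model.axial_cap_um)
    if np.any(lat <= 0) or np.any(ax <= 0):
        raise ValueError("PSF size model must be positive over the FOV")
    return lat, ax


def effective_fov_radius(
    model: PSFSizeModel,
    threshold: float = AXIAL_RESOLUTION_THRESHOLD,
    r_max: float = 250.0,
) -> float:
    """Smallest radius at which the axial FWHM reaches ``threshold`` µm.

    Found by bisection on the (uncapped) axial quartic; returns ``r_max``
    when the quartic stays below threshold everywhere in [0, r_max].
    """
    f = lambda r: _quartic(r, model.axial) - threshold
    if f(0.0) >= 0:
        return 0.0
    if f(r_max) < 0:
        return r_max
    # bracket the first crossing with a coarse scan, then refine
    rs = np.linspace(0.0, r_max, 512)
    vals = f(rs)
    idx = int(np.argmax(vals >= 0))
    return float(brentq(f, rs[idx - 1], rs[idx], xtol=1e-9))


def fov_fold_report(radius_uncorrected: float, radius_corrected: float) -> dict:
    """Fold change in effective FOV radius and area, rounded as printed
    (radius folds to 2 decimals, area folds to 1)."""
    rf = radius_corrected / radius_uncorrected
    return {
        "radius_fold": round(rf, 2),
        "area_fold": round(rf**2, 1),
    }


@dataclass
class MagnificationModel:
    """FOV distortion calibration.

    ``mag`` = (a, b, c): local magnification factor f(x) = a x^4 + b x^2 + c
    (nominal/local pixel size) versus nominal radial distance x (µm).
    ``dist`` = (d, e, f, h): g(x) = d x^4 + e x^2 + f x + h mapping *real*
    radial distance to *nominal* radial distance (µm). ``nominal_pixel_size``
    is the undistorted µm/pixel of the acquisition.
    """

    mag: tuple[float, float, float] = (0.0, 0.0, 1.0)
    dist: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 0.0)
    nominal_pixel_size: float = 1.0
    r_range: float = 300.0  # calibrated radial range, µm

    def __post_init__(self):
        if self.mag[2] <= 0:
            raise ValueError("on-axis magnification factor must be positive")
        # monotonicity of g over the calibrated range
        x = np.linspace(0.0, self.r_range, 256)
        g = self._g(x)
        if np.any(np.diff(g) <= 0):
            raise ValueError("distance calibration g must be monotone increasing")

    def _g(self, x):
        d, e, f, h = self.dist
        x = np.asarray(x, dtype=float)
        return d * x**4 + e * x**2 + f * x + h


def magnification_factor(r_nominal, model: MagnificationModel):
    """Local magnification factor at nominal radius ``r_nominal`` (µm)."""
    r = np.asarray(r_nominal, dtype=float)
    out = _quartic(r, model.mag)
    return out if out.ndim else float(out)


def nominal_distance(r_real, model: MagnificationModel):
    """Real -> nominal radial distance via the quartic g."""
    out = model._g(r_real)
    return out if np.ndim(out) else float(out)


def real_distance(r_nominal, model: MagnificationModel):
    """Nominal -> real radial distance: numerical inverse of monotone g."""
    scalar = np.ndim(r_nominal) == 0
    r_nom = np.atleast_1d(np.asarray(r_nominal, dtype=float))
    out = np.empty_like(r_nom)
    # largest radius up to which g keeps increasing (quartics may turn over
    # far outside the calibrated range); inversion is clamped there
    b_max = model.r_range
    while True:
        b_next = b_max * 1.25
        if b_next > 1e6 or model._g(b_next) <= model._g(b_max):
            break
        b_max = b_next
    g_top = model._g(b_max)
    clamped = False
    for i, x in enumerate(r_nom):
        if x <= model._g(0.0):
            out[i] = 0.0
        elif x >= g_top:
            out[i] = b_max
            clamped = True
        else:
            out[i] = brentq(lambda t: model._g(t) - x, 0.0, b_max, xtol=1e-9)
    if clamped:
        import warnings

        warnings.warn(
            "nominal distance beyond the invertible range of g; clamped",
            stacklevel=2,
        )
    return float(out[0]) if scalar else out


@dataclass
class RadialIntensityProfile:
    """Relative excitation efficiency vs radial distance, 1 on axis.

    Even polynomial I(r) = 1 + a2 r^2 + a4 r^4, clipped to [0, 1]; the
    decay emulates the fluorescence fall-off measured on subresolved
    fluorescent films at the FOV margins.
    """

    a2: float = 0.0
    a4: float = 0.0

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        out = np.clip(1.0 + self.a2 * r**2 + self.a4 * r**4, 0.0, 1.0)
        return out if out.ndim else float(out)


@dataclass
class OpticsModel:
    """Full optical description of one probe type."""

    probe_type: str
    focal_surface: FocalSurfaceModel
    psf: PSFSizeModel
    magnification: MagnificationModel
    intensity: RadialIntensityProfile
    fov_um: float  # lateral FOV side length, µm
    edge_radius_um: float  # circular FOV radius (edge-noise boundary), µm
    shell_weights: tuple[float, ...] = (1.0,)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsModel":
        d = dict(d)
        d["focal_surface"] = FocalSurfaceModel(**_tupled(d["focal_surface"]))
        d["psf"] = PSFSizeModel(**_tupled(d["psf"]))
        d["magnification"] = MagnificationModel(**_tupled(d["magnification"]))
        d["intensity"] = RadialIntensityProfile(**d["intensity"])
        d["shell_weights"] = tuple(d.get("shell_weights", (1.0,)))
        return cls(**d)

    @classmethod
    def load(cls, path) -> "OpticsModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


# ---------------------------------------------------------------------------
# Default (reconstructed) probe configurations.
#
# The axial quartics are anchored to an on-axis axial FWHM of 5 µm and to the
# published effective FOV radii at the 10 µm threshold: corrected-6.4 crosses
# at 100 µm, uncorrected-6.4 at 46 µm, corrected-8.8 at 52 µm and
# uncorrected-8.8 at 34 µm. Shell curvature radii of uncorrected probes are
# the published estimates (273 & 2000 µm for 6.4 mm, 992 & 2000 µm for
# 8.8 mm). FOV sizes: 400 µm (6.4 mm) and 360 µm (8.8 mm); edge radii 200 and
# 180 µm.
# ---------------------------------------------------------------------------


def _axial_quartic(r_cross: float, c0: float = 5.0, quartic_share: float = 0.5):
    """(a, b, c) with f(0)=c0 and f(r_cross)=threshold, mixing r^2/r^4."""
    gap = AXIAL_RESOLUTION_THRESHOLD - c0
    a = quartic_share * gap / r_cross**4
    b = (1.0 - quartic_share) * gap / r_cross**2
    return (a, b, c0)


_DEFAULTS: dict[str, dict] = {
    "corrected-6.4": dict(
        focal_surface=FocalSurfaceModel(
            "polynomial", poly_coeffs=(0.0, 0.0, 1.0 / 1600.0, 0.0, 0.0, 0.0),
            center_depth=110.0,
        ),
        psf=PSFSizeModel(axial=_axial_quartic(100.0), lateral=(0.0, 4e-5, 0.8)),
        magnification=MagnificationModel(
            mag=(0.0, 2.0e-6, 1.0), dist=(-4.0e-9, 0.0, 1.0, 0.0),
            nominal_pixel_size=1.0,
        ),
        intensity=RadialIntensityProfile(a2=-6.0e-6, a4=-6.0e-12),
        fov_um=400.0,
        edge_radius_um=200.0,
        shell_weights=(1.0,),
    ),
    "uncorrected-6.4": dict(
        focal_surface=FocalSurfaceModel(
            "spherical_shells", shell_radii=(273.0, 2000.0), center_depth=110.0,
        ),
        psf=PSFSizeModel(
            axial=_axial_quartic(46.0), lateral=(0.0, 8e-4, 0.8), axial_cap_um=100.0
        ),
        magnification=MagnificationModel(nominal_pixel_size=1.0),
        intensity=RadialIntensityProfile(a2=-5.5e-5, a4=0.0),
        fov_um=400.0,
        edge_radius_um=200.0,
        shell_weights=(0.5, 0.5),
    ),
    "corrected-8.8": dict(
        focal_surface=FocalSurfaceModel(
            # stronger field curvature than the uncorrected 8.8 mm probe:
            # the centre of the corrected surface sits deeper in the sample
            "polynomial", poly_coeffs=(0.0, 0.0, 1.0 / 900.0, 0.0, 0.0, 0.0),
            center_depth=140.0,
        ),
        psf=PSFSizeModel(axial=_axial_quartic(52.0), lateral=(0.0, 1.2e-4, 0.8)),
        magnification=MagnificationModel(
            mag=(0.0, 3.0e-6, 1.0), dist=(-6.0e-9, 0.0, 1.0, 0.0),
            nominal_pixel_size=1.0,
        ),
        intensity=RadialIntensityProfile(a2=-9.0e-6, a4=-9.0e-12),
        fov_um=360.0,
        edge_radius_um=180.0,
        shell_weights=(1.0,),
    ),
    "uncorrected-8.8": dict(
        focal_surface=FocalSurfaceModel(
            "spherical_shells", shell_radii=(992.0, 2000.0), center_depth=110.0,
        ),
        psf=PSFSizeModel(
            axial=_axial_quartic(34.0), lateral=(0.0, 1.2e-3, 0.8), axial_cap_um=100.0
        ),
        magnification=MagnificationModel(nominal_pixel_size=1.0),
        intensity=RadialIntensityProfile(a2=-9.0e-5, a4=0.0),
        fov_um=360.0,
        edge_radius_um=180.0,
        shell_weights=(0.5, 0.5),
    ),
}


def default_optics(probe_type: str) -> OpticsModel:
    """Reconstructed default optics model for one of :data:`PROBE_TYPES`."""
    if probe_type not in _DEFAULTS:
        raise ValueError(f"unknown probe type {probe_type!r}; options: {PROBE_TYPES}")
    d = _DEFAULTS[probe_type]
    return OpticsModel(probe_type=probe_type, **{k: v for k, v in d.items()})
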