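"""Analytic small-angle scattering models for lipid self-assemblies.

Orientationally averaged form factors for the particle shapes that occur in
ganglioside--phospholipid dispersions: globular core--shell micelles (sphere
and ellipsoid of revolution), unilamellar vesicles (solvent-filled shells),
finite cylinders covering the disc regime, multilamellar Bragg patterns, and
weight-linear mixtures of any of these for samples in which several particle
populations co-exist.

Conventions
-----------
* Lengths are Ångström and the scattering vector ``q`` is Å⁻¹ throughout the
  package core; nanometre values are converted at the interface layer only.
* Scattering length densities (SLDs) are relative, in any consistent unit:
  measured intensities here carry an arbitrary scale, so only contrasts
  (SLD differences) matter and a free ``scale`` factor absorbs the rest.
* Every model returns ``scale * |amplitude|**2 + background`` with the
  amplitude carrying the contrast-weighted volumes, so the forward limit is
  ``I(0) - background = scale * (sum_i Δρ_i V_i)**2``.
* Orientational averages use fixed-order Gauss--Legendre quadrature on the
  tilt angle α ∈ [0, π/2] with the measure sin α dα (which integrates to 1),
  default order 76; an optional convergence check doubles the order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
from typing import Sequence, Union

import numpy as np
from scipy.special import j1 as _bessel_j1

__all__ = [
    "SphereCoreShellParams",
    "EllipsoidCoreShellParams",
    "VesicleParams",
    "CylinderParams",
    "LamellarPatternParams",
    "MixtureModel",
    "QuadratureError",
    "sphere_amplitude",
    "core_shell_sphere_intensity",
    "core_shell_ellipsoid_intensity",
    "vesicle_intensity",
    "cylinder_intensity",
    "lamellar_pattern",
    "mixture_intensity",
    "evaluate",
    "forward_intensity",
    "params_to_dict",
    "params_from_dict",
    "preset",
    "PRESET_NAMES",
    "DEFAULT_QUAD_ORDER",
]

DEFAULT_QUAD_ORDER = 76

# Relative X-ray SLDs (electron-density scale) used by the shipped presets.
SLD_WATER = 0.334
SLD_BILAYER = 0.360


class QuadratureError(RuntimeError):
    """Raised when the orientational average fails its convergence check."""

    def __init__(self, achieved: float, requested: float):
        self.achieved = achieved
        self.requested = requested
        super().__init__(
            f"orientational quadrature not converged: achieved relative "
            f"change {achieved:.3e} on order doubling, requested {requested:.3e}"
        )


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class SphereCoreShellParams:
    """Concentric sphere with a core of one SLD inside a shell of another."""

    core_radius: float
    shell_thickness: float
    sld_core: float
    sld_shell: float
    sld_solvent: float
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        _require(self.core_radius >= 0, "core_radius must be >= 0")
        _require(self.shell_thickness >= 0, "shell_thickness must be >= 0")
        _require(self.scale >= 0, "scale must be >= 0")
        _require(self.background >= 0, "background must be >= 0")

    @property
    def total_radius(self) -> float:
        return self.core_radius + self.shell_thickness


@dataclass
class EllipsoidCoreShellParams:
    """Core--shell ellipsoid of revolution with a uniform shell thickness.

    The axial ratio (polar/equatorial) is derived, never stored: a ratio
    below 1 is an oblate spheroid, the shape inferred for GM1 micelles.
    """

    core_polar_radius: float
    core_equatorial_radius: float
    shell_thickness: float
    sld_core: float
    sld_shell: float
    sld_solvent: float
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        _require(self.core_polar_radius >= 0, "core_polar_radius must be >= 0")
        _require(self.core_equatorial_radius >= 0,
                 "core_equatorial_radius must be >= 0")
        _require(self.shell_thickness >= 0, "shell_thickness must be >= 0")
        _require(self.scale >= 0, "scale must be >= 0")
        _require(self.background >= 0, "background must be >= 0")

    @property
    def axial_ratio(self) -> float:
        """Core polar over equatorial radius (< 1 means oblate)."""
        return self.core_polar_radius / self.core_equatorial_radius

    @property
    def total_polar_radius(self) -> float:
        return self.core_polar_radius + self.shell_thickness

    @property
    def total_equatorial_radius(self) -> float:
        return self.core_equatorial_radius + self.shell_thickness

    @property
    def total_polar_diameter(self) -> float:
        return 2.0 * self.total_polar_radius

    @property
    def total_equatorial_diameter(self) -> float:
        return 2.0 * self.total_equatorial_radius


@dataclass
class VesicleParams:
    """Unilamellar vesicle: a bilayer shell around a solvent-filled lumen."""

    core_radius: float
    shell_thickness: float
    sld_shell: float
    sld_solvent: float
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        _require(self.core_radius > 0, "core_radius must be > 0")
        _require(self.shell_thickness > 0, "shell_thickness must be > 0")
        _require(self.scale >= 0, "scale must be >= 0")
        _require(self.background >= 0, "background must be >= 0")

    @property
    def total_radius(self) -> float:
        return self.core_radius + self.shell_thickness


@dataclass
class CylinderParams:
    """Homogeneous finite cylinder; length < 2*radius is the disc regime."""

    radius: float
    length: float
    sld_cyl: float
    sld_solvent: float
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        _require(self.radius > 0, "radius must be > 0")
        _require(self.length > 0, "length must be > 0")
        _require(self.scale >= 0, "scale must be >= 0")
        _require(self.background >= 0, "background must be >= 0")

    @property
    def is_disc(self) -> bool:
        return self.length < 2.0 * self.radius


@dataclass
class LamellarPatternParams:
    """Multilamellar Bragg pattern: Lorentzian orders on a power-law base.

    Order ``n`` is centred at ``q_n = 2*pi*n/d``.  The lineshape is a
    documented package choice (symmetric Lorentzian with a common HWHM);
    the baseline is ``baseline_amplitude * q**(-baseline_exponent)``.
    """

    repeat_distance: float
    n_orders: int = 2
    peak_width: float = 0.004
    order_amplitudes: Sequence[float] = field(default_factory=lambda: [1.0, 0.35])
    baseline_amplitude: float = 0.0
    baseline_exponent: float = 2.0

    def __post_init__(self) -> None:
        _require(self.repeat_distance > 0, "repeat_distance must be > 0")
        _require(self.n_orders >= 1, "n_orders must be >= 1")
        _require(self.peak_width > 0, "peak_width must be > 0")
        self.order_amplitudes = list(self.order_amplitudes)
        _require(len(self.order_amplitudes) == self.n_orders,
                 "order_amplitudes must have n_orders entries")
        _require(all(a >= 0 for a in self.order_amplitudes),
                 "order amplitudes must be >= 0")
        _require(self.baseline_amplitude >= 0, "baseline_amplitude must be >= 0")

    def peak_centers(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(1, self.n_orders + 1) / self.repeat_distance


ShapeParams = Union[
    SphereCoreShellParams,
    EllipsoidCoreShellParams,
    VesicleParams,
    CylinderParams,
    LamellarPatternParams,
]


@dataclass
class MixtureModel:
    """Weight-linear combination of component models.

    The intensity is exactly ``sum_i w_i I_i(q)``; weights need not sum to
    one because the absolute scale of a measured curve is arbitrary.
    """

    components: Sequence[ShapeParams]
    weights: Sequence[float]

    def __post_init__(self) -> None:
        self.components = list(self.components)
        self.weights = [float(w) for w in self.weights]
        _require(len(self.components) == len(self.weights),
                 "components and weights must have equal length")
        _require(len(self.components) >= 1, "mixture needs >= 1 component")
        if any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be >= 0")


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

def sphere_amplitude(x):
    """Normalized sphere scattering amplitude F(x) = 3(sin x − x cos x)/x³.

    ``x = qR``; F(0) = 1 exactly, evaluated by Taylor series near zero so
    the limit never goes through 0/0 division.

    Parameters
    ----------
    x : float or array_like, dimensionless, >= 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("sphere_amplitude requires x >= 0")
    out = np.empty_like(x)
    small = x < 1e-2
    xs = x[small]
    # F(x) = 1 - x^2/10 + x^4/280 - x^6/15120 + ...
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    if out.ndim == 0:
        return float(out)
    return out


def _sphere_volume(r):
    return 4.0 * np.pi / 3.0 * np.asarray(r, dtype=float) ** 3


@lru_cache(maxsize=32)
def _tilt_nodes(order: int):
    """Gauss–Legendre nodes/weights for ∫₀^{π/2} f(α) sin α dα."""
    x, w = np.polynomial.legendre.leggauss(order)
    alpha = 0.25 * np.pi * (x + 1.0)
    weight = 0.25 * np.pi * w * np.sin(alpha)
    return alpha, weight


def core_shell_sphere_intensity(p: SphereCoreShellParams, q) -> np.ndarray:
    """Closed-form core--shell sphere intensity on a q grid (Å⁻¹)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0 elementwise")
    rc = p.core_radius
    rt = p.total_radius
    amp = (_sphere_volume(rc) * (p.sld_core - p.sld_shell) * sphere_amplitude(q * rc)
           + _sphere_volume(rt) * (p.sld_shell - p.sld_solvent) * sphere_amplitude(q * rt))
    return p.scale * np.square(amp) + p.background


def vesicle_intensity(p: VesicleParams, q) -> np.ndarray:
    """Vesicle intensity: a core--shell sphere whose core is solvent."""
    eq = SphereCoreShellParams(
        core_radius=p.core_radius,
        shell_thickness=p.shell_thickness,
        sld_core=p.sld_solvent,
        sld_shell=p.sld_shell,
        sld_solvent=p.sld_solvent,
        scale=p.scale,
        background=p.background,
    )
    return core_shell_sphere_intensity(eq, q)


def _ellipsoid_mean_sq_amplitude(p: EllipsoidCoreShellParams, q: np.ndarray,
                                 order: int) -> np.ndarray:
    alpha, w = _tilt_nodes(order)
    sin2 = np.sin(alpha) ** 2
    cos2 = np.cos(alpha) ** 2
    # effective spherical radii of core and outer surfaces at each tilt
    r_core = np.sqrt(p.core_equatorial_radius**2 * sin2
                     + p.core_polar_radius**2 * cos2)
    r_tot = np.sqrt(p.total_equatorial_radius**2 * sin2
                    + p.total_polar_radius**2 * cos2)
    v_core = 4.0 * np.pi / 3.0 * p.core_polar_radius * p.core_equatorial_radius**2
    v_tot = (4.0 * np.pi / 3.0 * p.total_polar_radius
             * p.total_equatorial_radius**2)
    qg = q[:, None]
    amp = (v_core * (p.sld_core - p.sld_shell) * sphere_amplitude(qg * r_core[None, :])
           + v_tot * (p.sld_shell - p.sld_solvent) * sphere_amplitude(qg * r_tot[None, :]))
    return np.square(amp) @ w


def core_shell_ellipsoid_intensity(p: EllipsoidCoreShellParams, q, *,
                                   order: int = DEFAULT_QUAD_ORDER,
                                   convergence_rtol: float | None = None,
                                   ) -> np.ndarray:
    """Orientationally averaged core--shell ellipsoid intensity.

    The amplitude at tilt α uses the sphere kernel at the effective radii
    r(α) = sqrt(R_eq² sin²α + R_pol² cos²α) of the core and outer surfaces.

    Parameters
    ----------
    order : Gauss--Legendre order for the tilt average.
    convergence_rtol : if given, re-evaluate at 2×order and raise
        :class:`QuadratureError` when the maximum relative change of the
        form factor exceeds this tolerance.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0 elementwise")
    pq = _ellipsoid_mean_sq_amplitude(p, q, order)
    if convergence_rtol is not None:
        pq2 = _ellipsoid_mean_sq_amplitude(p, q, 2 * order)
        achieved = float(np.max(np.abs(pq - pq2) / np.maximum(np.abs(pq2), 1e-300)))
        if achieved > convergence_rtol:
            raise QuadratureError(achieved, convergence_rtol)
        pq = pq2
    return p.scale * pq + p.background


def _cylinder_mean_sq_amplitude(p: CylinderParams, q: np.ndarray,
                                order: int) -> np.ndarray:
    alpha, w = _tilt_nodes(order)
    sa = np.sin(alpha)
    ca = np.cos(alpha)
    v = np.pi * p.radius**2 * p.length
    qg = q[:, None]
    xr = qg * p.radius * sa[None, :]
    xl = qg * (p.length / 2.0) * ca[None, :]
    # 2 J1(x)/x -> 1 and sin(x)/x -> 1 as x -> 0
    radial = np.where(xr > 1e-8, 2.0 * _bessel_j1(np.maximum(xr, 1e-300)) / np.maximum(xr, 1e-300),
                      1.0 - xr**2 / 8.0)
    axial = np.sinc(xl / np.pi)
    amp = v * (p.sld_cyl - p.sld_solvent) * radial * axial
    return np.square(amp) @ w


def cylinder_intensity(p: CylinderParams, q, *, order: int = DEFAULT_QUAD_ORDER,
                       convergence_rtol: float | None = None) -> np.ndarray:
    """Orientationally averaged finite-cylinder (disc) intensity."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0 elementwise")
    pq = _cylinder_mean_sq_amplitude(p, q, order)
    if convergence_rtol is not None:
        pq2 = _cylinder_mean_sq_amplitude(p, q, 2 * order)
        achieved = float(np.max(np.abs(pq - pq2) / np.maximum(np.abs(pq2), 1e-300)))
        if achieved > convergence_rtol:
            raise QuadratureError(achieved, convergence_rtol)
        pq = pq2
    return p.scale * pq + p.background


def lamellar_pattern(p: LamellarPatternParams, q) -> np.ndarray:
    """Sum of Lorentzian Bragg orders at q_n = 2πn/d plus power-law base."""
    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q)
    for n, amp in zip(range(1, p.n_orders + 1), p.order_amplitudes):
        qn = 2.0 * np.pi * n / p.repeat_distance
        out += amp / (1.0 + ((q - qn) / p.peak_width) ** 2)
    if p.baseline_amplitude > 0:
        with np.errstate(divide="ignore"):
            out += p.baseline_amplitude * np.power(np.maximum(q, 1e-12),
                                                   -p.baseline_exponent)
    return out


def mixture_intensity(m: MixtureModel, q, **kwargs) -> np.ndarray:
    """Exact weighted sum of component intensities; no renormalization."""
    q = np.asarray(q, dtype=float)
    out = np.zeros_like(q)
    for w, comp in zip(m.weights, m.components):
        out += w * evaluate(comp, q, **kwargs)
    return out


_DISPATCH = {
    SphereCoreShellParams: core_shell_sphere_intensity,
    EllipsoidCoreShellParams: core_shell_ellipsoid_intensity,
    VesicleParams: vesicle_intensity,
    CylinderParams: cylinder_intensity,
    LamellarPatternParams: lamellar_pattern,
}


def evaluate(model, q, **kwargs) -> np.ndarray:
    """Evaluate any shape-parameter set or mixture on a q grid (Å⁻¹)."""
    if isinstance(model, MixtureModel):
        return mixture_intensity(model, q, **kwargs)
    fn = _DISPATCH.get(type(model))
    if fn is None:
        raise TypeError(f"unknown model type {type(model).__name__}")
    if fn in (core_shell_sphere_intensity, vesicle_intensity, lamellar_pattern):
        kwargs = {}  # closed forms take no quadrature options
    return fn(model, q, **kwargs)


def forward_intensity(model) -> float:
    """Closed-form forward limit I(0) = scale·(Σ Δρᵢ Vᵢ)² + background."""
    if isinstance(model, SphereCoreShellParams):
        a = (_sphere_volume(model.core_radius) * (model.sld_core - model.sld_shell)
             + _sphere_volume(model.total_radius) * (model.sld_shell - model.sld_solvent))
        return model.scale * a * a + model.background
    if isinstance(model, VesicleParams):
        a = (_sphere_volume(model.total_radius) - _sphere_volume(model.core_radius)
             ) * (model.sld_shell - model.sld_solvent)
        return model.scale * a * a + model.background
    if isinstance(model, EllipsoidCoreShellParams):
        vc = (4.0 * np.pi / 3.0 * model.core_polar_radius
              * model.core_equatorial_radius**2)
        vt = (4.0 * np.pi / 3.0 * model.total_polar_radius
              * model.total_equatorial_radius**2)
        a = vc * (model.sld_core - model.sld_shell) + vt * (model.sld_shell - model.sld_solvent)
        return model.scale * a * a + model.background
    if isinstance(model, CylinderParams):
        a = np.pi * model.radius**2 * model.length * (model.sld_cyl - model.sld_solvent)
        return model.scale * a * a + model.background
    raise TypeError(f"no forward limit for {type(model).__name__}")


# --------------------------------------------------------------------------
# serialization and presets
# --------------------------------------------------------------------------

_TYPE_TAGS = {
    "sphere_core_shell": SphereCoreShellParams,
    "ellipsoid_core_shell": EllipsoidCoreShellParams,
    "vesicle": VesicleParams,
    "cylinder": CylinderParams,
    "lamellar": LamellarPatternParams,
    "mixture": MixtureModel,
}
_TAG_BY_TYPE = {v: k for k, v in _TYPE_TAGS.items()}


def params_to_dict(model) -> dict:
    """Flat key-value form (YAML/JSON friendly) with a ``model`` tag."""
    if isinstance(model, MixtureModel):
        return {
            "model": "mixture",
            "weights": list(model.weights),
            "components": [params_to_dict(c) for c in model.components],
        }
    d = {"model": _TAG_BY_TYPE[type(model)]}
    for f in fields(model):
        v = getattr(model, f.name)
        d[f.name] = list(v) if isinstance(v, (list, tuple)) else v
    return d


def params_from_dict(d: dict):
    """Inverse of :func:`params_to_dict`."""
    d = dict(d)
    tag = d.pop("model")
    cls = _TYPE_TAGS.get(tag)
    if cls is None:
        raise ValueError(f"unknown model tag {tag!r}; known: {sorted(_TYPE_TAGS)}")
    if cls is MixtureModel:
        comps = [params_from_dict(c) for c in d.pop("components")]
        return MixtureModel(components=comps, weights=d.pop("weights"))
    return cls(**d)


def _gm1_micelle() -> EllipsoidCoreShellParams:
    # Slightly oblate micelle, total polar/equatorial diameters 9 and 10 nm
    # (read as outer dimensions; core radii follow from a 22 Å hydrated
    # oligosaccharide shell).  Relative SLDs chosen so the simulated curve
    # shows the micelle signature of this system: a minimum near
    # q ≈ 0.06 Å⁻¹ followed by a broad peak above 0.1 Å⁻¹.
    return EllipsoidCoreShellParams(
        core_polar_radius=23.0,
        core_equatorial_radius=28.0,
        shell_thickness=22.0,
        sld_core=0.240,
        sld_shell=0.380,
        sld_solvent=SLD_WATER,
        scale=1e-6,
        background=1e-3,
    )


def _dopc_vesicle() -> VesicleParams:
    # Sonicated unilamellar vesicle, ~60 nm outer diameter, ~40 Å bilayer.
    return VesicleParams(
        core_radius=260.0,
        shell_thickness=40.0,
        sld_shell=SLD_BILAYER,
        sld_solvent=SLD_WATER,
        scale=1e-6,
        background=1e-3,
    )


def _gm1_dopc_disc() -> CylinderParams:
    # Disc-like object ~16 nm across and one bilayer (~40 Å) thick.
    return CylinderParams(
        radius=80.0,
        length=40.0,
        sld_cyl=SLD_BILAYER,
        sld_solvent=SLD_WATER,
        scale=1e-6,
        background=1e-3,
    )


def _lamellar(d: float) -> LamellarPatternParams:
    return LamellarPatternParams(
        repeat_distance=d,
        n_orders=2,
        peak_width=0.004,
        order_amplitudes=[1.0, 0.35],
        baseline_amplitude=2e-5,
        baseline_exponent=2.0,
    )


_PRESETS = {
    "gm1_micelle": _gm1_micelle,
    "dopc_vesicle": _dopc_vesicle,
    "gm1_dopc_disc": _gm1_dopc_disc,
    "dopc_lamellar_60A": lambda: _lamellar(60.0),
    "dopc_gm1_lamellar_64A": lambda: _lamellar(64.0),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str):
    """Return a fresh parameter set for a named shipped preset."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
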