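"""PFG-STE diffusion NMR: Stejskal–Tanner fitting and hydrodynamic sizing.

A pulsed-field-gradient stimulated-echo experiment attenuates the signal of
a species diffusing with coefficient ``D`` as ``I(b) = I0 exp(-b D)`` with
the diffusion weighting ``b = gamma^2 G^2 delta^2 (Delta - delta/3)``.
This module builds ``b`` from the pulse-sequence parameters, fits the
monoexponential decay, converts ``D`` to a hydrodynamic radius through the
Stokes–Einstein relation ``D = kT / (6 pi eta R)``, and applies the
fast-exchange population average relevant when free monomers co-exist with
micelles below/above the critical micelle concentration (CMC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GAMMA_1H",
    "K_BOLTZMANN",
    "PulseSequence",
    "EchoDecay",
    "DiffusionFit",
    "HydroContext",
    "bvalue",
    "fit_stejskal_tanner",
    "fit_decay",
    "water_viscosity",
    "stokes_einstein_radius",
    "stokes_einstein_diffusion",
    "fast_exchange_average_D",
    "free_monomer_fraction",
    "load_decay",
    "diffusion_report",
]

#: ¹H gyromagnetic ratio, rad s⁻¹ T⁻¹ (CODATA).
GAMMA_1H = 2.6752218744e8
#: Boltzmann constant, J/K (exact, 2019 SI).
K_BOLTZMANN = 1.380649e-23


@dataclass
class PulseSequence:
    """PFG-STE timing constants and the gradient ramp.

    delta is the gradient-pulse duration (s), Delta the diffusion delay (s)
    and gradients the linearly (or otherwise) incremented strengths (T/m).
    """

    gamma: float = GAMMA_1H
    delta: float = 2e-3
    Delta: float = 150e-3
    gradients: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 0.5, 32))

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=float)
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.Delta <= self.delta / 3.0:
            raise ValueError("Delta must exceed delta/3")
        if self.gradients.size < 4:
            raise ValueError("need >= 4 gradient steps for fitting")
        if np.any(self.gradients < 0) or np.any(np.diff(self.gradients) <= 0):
            raise ValueError("gradients must be strictly increasing and >= 0")

    def bvalues(self) -> np.ndarray:
        return bvalue(self, self.gradients)


@dataclass
class EchoDecay:
    """Measured peak areas along the gradient ramp of a PulseSequence."""

    sequence: PulseSequence
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != self.sequence.gradients.shape:
            raise ValueError("areas must match gradients in length")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")
        # sanity: a decay starts at its maximum; tolerate noise-level
        # inversions but reject grossly non-decaying series
        if self.areas[0] < np.max(self.areas) * 0.8:
            raise ValueError("first area must be the maximum (decay)")


@dataclass
class DiffusionFit:
    """Monoexponential fit outcome: D (m²/s), I0, rms residual, status."""

    D: float
    I0: float
    residual_rms: float
    convergence_flag: bool

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")


@dataclass
class HydroContext:
    """Temperature/viscosity context for Stokes–Einstein conversions."""

    temperature: float = 310.15  # K; 37 °C stored exactly
    viscosity: float | None = None  # Pa·s; None -> pure water at T

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.viscosity is None:
            self.viscosity = water_viscosity(self.temperature)
        if self.viscosity <= 0:
            raise ValueError("viscosity must be > 0")


def bvalue(seq: PulseSequence, G) -> np.ndarray | float:
    """Diffusion weighting b = γ²G²δ²(Δ − δ/3) in s/m²."""
    G = np.asarray(G, dtype=float)
    b = seq.gamma**2 * G**2 * seq.delta**2 * (seq.Delta - seq.delta / 3.0)
    return float(b) if b.ndim == 0 else b


def fit_decay(b, areas) -> DiffusionFit:
    """Fit I(b) = I0 exp(−b D) to (b, area) pairs.

    A log-linear regression provides the starting point; a nonlinear
    least-squares refinement in linear space gives the reported values.
    Two points reduce to the closed form D = ln(I1/I2)/(b2−b1).
    Non-decaying data yield D clamped at 0 with ``convergence_flag`` False
    and a warning.
    """
    b = np.asarray(b, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if b.shape != areas.shape or b.ndim != 1:
        raise ValueError("b and areas must be equal-length 1-D arrays")
    if b.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")

    # log-linear initialization: ln I = ln I0 - b D
    slope, intercept = np.polyfit(b, np.log(areas), 1)
    d0, i0 = -slope, math.exp(intercept)

    if d0 <= 0:
        warnings.warn("echo decay is non-decaying; clamping D at 0",
                      RuntimeWarning, stacklevel=2)
        i0_hat = float(np.mean(areas))
        rms = float(np.sqrt(np.mean((areas - i0_hat) ** 2)))
        flat = np.allclose(areas, areas[0], rtol=1e-12, atol=0.0)
        return DiffusionFit(D=0.0, I0=i0_hat, residual_rms=rms,
                            convergence_flag=flat)

    if b.size == 2:
        d_exact = math.log(areas[0] / areas[1]) / (b[1] - b[0])
        return DiffusionFit(D=d_exact, I0=float(areas[0] * math.exp(b[0] * d_exact)),
                            residual_rms=0.0, convergence_flag=True)

    def model(bb, i0_, d_):
        return i0_ * np.exp(-bb * d_)

    try:
        popt, _ = curve_fit(model, b, areas, p0=(i0, d0), maxfev=10000)
        i0_hat, d_hat = float(popt[0]), float(popt[1])
        ok = d_hat >= 0 and i0_hat > 0
    except RuntimeError:
        i0_hat, d_hat, ok = i0, d0, False
    resid = areas - model(b, i0_hat, d_hat)
    return DiffusionFit(D=max(d_hat, 0.0), I0=i0_hat,
                        residual_rms=float(np.sqrt(np.mean(resid**2))),
                        convergence_flag=ok)


def fit_stejskal_tanner(d: EchoDecay) -> DiffusionFit:
    """Fit the Stejskal–Tanner decay of an :class:`EchoDecay`.

    b-values are computed internally from the gradient ramp so the pulse
    parameters remain the single source of truth; use :func:`fit_decay`
    for externally supplied b columns.
    """
    return fit_decay(d.sequence.bvalues(), d.areas)


def water_viscosity(T: float) -> float:
    """Dynamic viscosity of pure water (Pa·s) for 273.15 K ≤ T ≤ 373.15 K.

    Vogel-type empirical correlation
    ``eta = 2.414e-5 * 10**(247.8/(T - 140))``, accurate to about 1% over
    the liquid range (1.002e-3 Pa·s at 20 °C, 6.91e-4 Pa·s at 37 °C).
    """
    if not (273.15 <= T <= 373.15):
        raise ValueError("temperature outside 273.15-373.15 K")
    return 2.414e-5 * 10.0 ** (247.8 / (T - 140.0))


def stokes_einstein_radius(D: float, ctx: HydroContext) -> float:
    """Hydrodynamic radius R = kT/(6πηD) in metres."""
    if D <= 0:
        raise ValueError("D must be > 0")
    return K_BOLTZMANN * ctx.temperature / (6.0 * math.pi * ctx.viscosity * D)


def stokes_einstein_diffusion(R: float, ctx: HydroContext) -> float:
    """Diffusion coefficient of a sphere of hydrodynamic radius R (m)."""
    if R <= 0:
        raise ValueError("R must be > 0")
    return K_BOLTZMANN * ctx.temperature / (6.0 * math.pi * ctx.viscosity * R)


def free_monomer_fraction(c_total: float, cmc: float) -> float:
    """Fraction of amphiphile free in solution: min(CMC/c_total, 1)."""
    if c_total <= 0 or cmc < 0:
        raise ValueError("concentrations must be positive")
    return min(cmc / c_total, 1.0)


def fast_exchange_average_D(f_free: float, D_free: float,
                            D_aggregate: float) -> float:
    """Population-weighted observed D under fast monomer/micelle exchange."""
    if not (0.0 <= f_free <= 1.0):
        raise ValueError("f_free must be in [0, 1]")
    if D_free <= 0 or D_aggregate <= 0:
        raise ValueError("diffusion coefficients must be > 0")
    return f_free * D_free + (1.0 - f_free) * D_aggregate


def load_decay(path_or_buf, gamma: float = GAMMA_1H, delta: float = 2e-3,
               Delta: float = 150e-3):
    """Read an echo-decay CSV with a header row.

    Columns: ``gradient_T_per_m`` (or ``b_s_per_m2``) and ``area``.  With a
    gradient column an :class:`EchoDecay` is returned (b built from the
    pulse parameters); with a b column a ``(b, areas)`` tuple is returned
    for :func:`fit_decay`.
    """
    df = pd.read_csv(path_or_buf, comment="#")
    cols = {c.strip(): c for c in df.columns}
    if "area" not in cols:
        raise ValueError("decay CSV must have an 'area' column")
    areas = df[cols["area"]].to_numpy(dtype=float)
    if "gradient_T_per_m" in cols:
        seq = PulseSequence(gamma=gamma, delta=delta, Delta=Delta,
                            gradients=df[cols["gradient_T_per_m"]].to_numpy(dtype=float))
        return EchoDecay(sequence=seq, areas=areas)
    if "b_s_per_m2" in cols:
        return df[cols["b_s_per_m2"]].to_numpy(dtype=float), areas
    raise ValueError("decay CSV needs 'gradient_T_per_m' or 'b_s_per_m2'")


def diffusion_report(fit: DiffusionFit, ctx: HydroContext) -> dict:
    """Sizing report: D, I0, hydrodynamic radius/diameter, conditions."""
    r = stokes_einstein_radius(fit.D, ctx) if fit.D > 0 else None
    return {
        "D_m2_per_s": fit.D,
        "I0": fit.I0,
        "residual_rms": fit.residual_rms,
        "converged": fit.convergence_flag,
        "hydrodynamic_radius_nm": None if r is None else r * 1e9,
        "hydrodynamic_diameter_nm": None if r is None else 2.0 * r * 1e9,
        "temperature_K": ctx.temperature,
        "viscosity_Pa_s": ctx.viscosity,
    }
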