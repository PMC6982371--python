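"""Analysis of reduced 1-D SAXS profiles.

Covers the workflow used to characterise lipid dispersions from azimuthally
averaged scattering curves: reading two/three-column ASCII profiles,
converting between scattering angle, scattering vector and real-space
distance, detecting Bragg peaks, indexing them to a lamellar repeat
distance, and fitting analytic form-factor models by weighted least
squares.

Angle convention: ``q = 4 pi sin(theta) / lambda`` with ``theta`` HALF the
total scattering angle ``2 theta``; :class:`BeamConfig` names the field
``half_angle`` to make the convention impossible to miss.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Sequence

import numpy as np
import lmfit
from scipy.signal import find_peaks

from . import scattering_models as sm

__all__ = [
    "ScatterProfile",
    "BeamConfig",
    "PeakSet",
    "LamellarIndexing",
    "FitResult",
    "q_from_angle",
    "angle_from_q",
    "dspacing_from_q",
    "detect_peaks",
    "index_lamellar",
    "fit_model",
    "load_profile",
    "save_profile",
    "fit_report_dict",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class ScatterProfile:
    """A reduced 1-D scattering curve I(q), optionally with uncertainties."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive everywhere")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class BeamConfig:
    """X-ray wavelength and half scattering angle (theta, not 2-theta)."""

    wavelength: float  # Å
    half_angle: float  # rad

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if not (0 <= self.half_angle < math.pi / 2):
            raise ValueError("half_angle must be in [0, pi/2)")


@dataclass
class PeakSet:
    """Detected peak positions (Å⁻¹) with prominences, sorted ascending."""

    positions: np.ndarray
    prominences: np.ndarray
    assigned_orders: list[int] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.prominences = np.asarray(self.prominences, dtype=float)
        if self.positions.shape != self.prominences.shape:
            raise ValueError("positions and prominences must match in length")
        if self.positions.size > 1 and np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted ascending")

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class LamellarIndexing:
    """Lamellar repeat distance with the Bragg-order assignment used."""

    repeat_distance: float  # Å
    order_assignment: dict[float, int]
    rms_residual: float  # Å⁻¹

    def __post_init__(self) -> None:
        if self.repeat_distance <= 0:
            raise ValueError("repeat_distance must be > 0")


@dataclass
class FitResult:
    """Least-squares estimates with 1σ uncertainties and fit diagnostics.

    ``uncertainties`` maps a parameter to ``None`` (and
    ``has_uncertainties`` is False) when the covariance could not be
    estimated; uncertainties are never silently zero-filled.
    """

    parameters: dict[str, float]
    uncertainties: dict[str, float | None]
    chi2_reduced: float
    convergence_flag: bool
    n_evaluations: int
    model: object | None = None
    fit_space: str = "linear"

    @property
    def has_uncertainties(self) -> bool:
        return all(v is not None for v in self.uncertainties.values())


# --------------------------------------------------------------------------
# scalar conversions
# --------------------------------------------------------------------------

def q_from_angle(b: BeamConfig) -> float:
    """Scattering vector q = 4π sin(θ)/λ in Å⁻¹ (θ is the half angle)."""
    return 4.0 * math.pi * math.sin(b.half_angle) / b.wavelength


def angle_from_q(q: float, wavelength: float) -> float:
    """Half scattering angle θ (rad) giving the supplied q at wavelength λ."""
    s = q * wavelength / (4.0 * math.pi)
    if not (0 <= s < 1):
        raise ValueError("q out of range for this wavelength")
    return math.asin(s)


def dspacing_from_q(q: float, round_to: float | None = None) -> float:
    """Real-space repeat distance d = 2π/q in Å.

    ``round_to`` rounds the result to the nearest multiple (e.g. 10 Å for a
    "ca." value quoted to one significant figure past the decade).
    """
    if q <= 0:
        raise ValueError("q must be > 0")
    d = 2.0 * math.pi / q
    if round_to is not None:
        if round_to <= 0:
            raise ValueError("round_to must be > 0")
        d = round(d / round_to) * round_to
    return d


# --------------------------------------------------------------------------
# peak detection and lamellar indexing
# --------------------------------------------------------------------------

def _parabolic_refine(x: np.ndarray, logy: np.ndarray, i: int) -> float:
    """Vertex of the parabola through three points around index i."""
    if i == 0 or i == x.size - 1:
        return x[i]
    y0, y1, y2 = logy[i - 1], logy[i], logy[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return x[i]
    # offset in index units, then map to (possibly non-uniform) x
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    if delta >= 0:
        return x[i] + delta * (x[i + 1] - x[i])
    return x[i] + delta * (x[i] - x[i - 1])


def detect_peaks(p: ScatterProfile, min_prominence: float = 0.05,
                 smoothing_window: int = 1) -> PeakSet:
    """Find local intensity maxima above a prominence threshold.

    ``min_prominence`` is a fraction of the maximum intensity; an optional
    centred moving average (``smoothing_window`` points) is applied first.
    Positions are refined to sub-grid precision by a 3-point parabolic fit
    on log-intensity.  No peaks is a valid outcome (empty
    :class:`PeakSet`), not an error.
    """
    if len(p) < 5:
        raise ValueError("profile needs at least 5 points")
    y = p.intensity
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        y = np.convolve(y, kernel, mode="same")
    prominence = min_prominence * float(np.max(y))
    idx, props = find_peaks(y, prominence=prominence)
    logy = np.log(np.maximum(y, 1e-300))
    positions = np.array([_parabolic_refine(p.q, logy, i) for i in idx])
    return PeakSet(positions=positions, prominences=props.get(
        "prominences", np.zeros(len(idx))))


def index_lamellar(peaks: PeakSet, max_order: int = 4) -> LamellarIndexing:
    """Assign integer Bragg orders and fit the lamellar repeat distance.

    Searches assignments in which the lowest-q peak takes order
    ``n1 = 1..max_order`` and every other peak the nearest harmonic, then
    least-squares fits ``q_n = 2 pi n / d`` and keeps the assignment with
    the smallest rms residual (ties go to the lowest orders).  A single
    peak is indexed as first order.
    """
    if len(peaks) == 0:
        raise ValueError("nothing to index: empty PeakSet")
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    qs = peaks.positions
    if len(qs) == 1:
        d = 2.0 * math.pi / qs[0]
        return LamellarIndexing(d, {float(qs[0]): 1}, 0.0)

    best: tuple[float, float, np.ndarray] | None = None
    for n1 in range(1, max_order + 1):
        x1 = qs[0] / n1  # candidate fundamental spacing in q
        orders = np.rint(qs / x1).astype(int)
        orders[0] = n1
        if np.any(orders < 1) or np.any(orders > max(max_order, orders[0])) \
                or np.any(np.diff(orders) <= 0):
            continue
        # least squares for x = 2*pi/d given q_i ~ n_i * x
        x = float(np.dot(orders, qs) / np.dot(orders, orders))
        resid = qs - orders * x
        rms = float(np.sqrt(np.mean(resid**2)))
        if best is None or rms < best[0] - 1e-15:
            best = (rms, x, orders.copy())
    if best is None:
        raise ValueError("no consistent order assignment up to max_order")
    rms, x, orders = best
    d = 2.0 * math.pi / x
    assignment = {float(q): int(n) for q, n in zip(qs, orders)}
    return LamellarIndexing(d, assignment, rms)


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

_NONNEG_FIELDS = {
    "core_radius", "shell_thickness", "core_polar_radius",
    "core_equatorial_radius", "radius", "length", "repeat_distance",
    "peak_width", "scale", "background", "baseline_amplitude",
}


def _flatten_model(model) -> dict[str, float]:
    """Flat parameter-name -> value map for any model, mixtures included."""
    if isinstance(model, sm.MixtureModel):
        flat: dict[str, float] = {}
        for i, w in enumerate(model.weights):
            flat[f"c{i}_weight"] = float(w)
        for i, comp in enumerate(model.components):
            for name, val in _flatten_model(comp).items():
                flat[f"c{i}_{name}"] = val
        return flat
    out = {}
    for f in dc_fields(model):
        v = getattr(model, f.name)
        if isinstance(v, (int, float)):
            out[f.name] = float(v)
        elif isinstance(v, (list, tuple, np.ndarray)):
            for j, vj in enumerate(v):
                out[f"{f.name}_{j}"] = float(vj)
    return out


def _rebuild_model(template, values: Mapping[str, float]):
    """Rebuild a model of the template's type from a flat value map."""
    if isinstance(template, sm.MixtureModel):
        comps = []
        weights = []
        for i, comp in enumerate(template.components):
            weights.append(values[f"c{i}_weight"])
            sub = {k[len(f"c{i}_"):]: v for k, v in values.items()
                   if k.startswith(f"c{i}_") and k != f"c{i}_weight"}
            comps.append(_rebuild_model(comp, sub))
        return sm.MixtureModel(components=comps, weights=weights)
    kwargs = {}
    for f in dc_fields(template):
        v = getattr(template, f.name)
        if isinstance(v, (int, float)):
            kwargs[f.name] = values[f.name]
        elif isinstance(v, (list, tuple, np.ndarray)):
            kwargs[f.name] = [values[f"{f.name}_{j}"] for j in range(len(v))]
        else:
            kwargs[f.name] = v
    return type(template)(**kwargs)


def fit_model(p: ScatterProfile, model, free_params: Sequence[str],
              bounds: Mapping[str, tuple[float, float]] | None = None,
              init: Mapping[str, float] | None = None,
              max_nfev: int = 5000) -> FitResult:
    """Weighted least-squares fit of a scattering model to a profile.

    Parameters
    ----------
    model : any shape-parameter set or :class:`MixtureModel`; its current
        values are the defaults for fixed parameters and starting points.
    free_params : flat parameter names to vary (mixture components are
        addressed as ``c0_core_radius``, weights as ``c0_weight``).
    bounds : optional per-name (lo, hi); physically non-negative lengths,
        scales and weights default to a lower bound of 0.
    init : optional starting values overriding the model's values.

    Weights are ``1/sigma**2`` when the profile carries uncertainties.
    Without uncertainties, profiles spanning more than two decades are fit
    in log-intensity space (SAXS dynamic range would otherwise let low q
    dominate); flat profiles are fit unweighted in linear space.
    Non-convergence is reported through ``convergence_flag``, never as a
    silent success.
    """
    flat = _flatten_model(model)
    unknown = [n for n in free_params if n not in flat]
    if unknown:
        raise ValueError(f"unknown free parameters: {unknown}; "
                         f"available: {sorted(flat)}")
    bounds = dict(bounds or {})
    init = dict(init or {})
    bad = [n for n, v in init.items()
           if n in bounds and not (bounds[n][0] <= v <= bounds[n][1])]
    if bad:
        raise ValueError(f"init outside bounds for: {bad}")

    span = (np.max(p.intensity[p.intensity > 0])
            / max(np.min(p.intensity[p.intensity > 0]), 1e-300))
    use_log = p.sigma is None and span > 100.0
    fit_space = "log" if use_log else "linear"

    params = lmfit.Parameters()
    for name, value in flat.items():
        v = float(init.get(name, value))
        lo, hi = bounds.get(
            name,
            (0.0, np.inf) if name.split("_", 1)[-1] in _NONNEG_FIELDS
            or name in _NONNEG_FIELDS or name.endswith("weight")
            else (-np.inf, np.inf))
        params.add(name, value=v, vary=name in free_params, min=lo, max=hi)

    weights = 1.0 / p.sigma if p.sigma is not None else None

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        vals = {k: pars[k].value for k in pars}
        m = _rebuild_model(model, vals)
        imod = sm.evaluate(m, p.q)
        if use_log:
            return (np.log(np.maximum(imod, 1e-300))
                    - np.log(np.maximum(p.intensity, 1e-300)))
        r = imod - p.intensity
        return r * weights if weights is not None else r

    def run(start: lmfit.Parameters):
        minimizer = lmfit.Minimizer(residual, start, nan_policy="raise")
        try:
            out = minimizer.least_squares(max_nfev=max_nfev)
            return out, bool(out.success)
        except Exception:
            return None, False

    res, converged = run(params)

    # The orientationally averaged ellipsoid has a near-degenerate twin
    # with polar and equatorial radii exchanged (prolate <-> oblate); a
    # deterministic restart from the swapped starting point avoids being
    # trapped in the wrong basin.
    swap = ("core_polar_radius", "core_equatorial_radius")
    if (isinstance(model, sm.EllipsoidCoreShellParams)
            and all(n in free_params for n in swap) and res is not None):
        swapped = params.copy()
        swapped[swap[0]].value, swapped[swap[1]].value = (
            params[swap[1]].value, params[swap[0]].value)
        res2, conv2 = run(swapped)
        if res2 is not None and (
                np.sum(np.asarray(res2.residual) ** 2)
                < np.sum(np.asarray(res.residual) ** 2)):
            res, converged = res2, conv2

    if res is None:
        return FitResult(parameters=dict(flat),
                         uncertainties={n: None for n in free_params},
                         chi2_reduced=math.nan, convergence_flag=False,
                         n_evaluations=0, model=model, fit_space=fit_space)

    values = {k: float(res.params[k].value) for k in res.params}
    errors = {n: (float(res.params[n].stderr)
                  if res.params[n].stderr is not None else None)
              for n in free_params}
    nfree = max(len(p) - len(free_params), 1)
    chi2_red = float(np.sum(np.asarray(res.residual) ** 2) / nfree)
    fitted = _rebuild_model(model, values)
    return FitResult(parameters=values, uncertainties=errors,
                     chi2_reduced=chi2_red, convergence_flag=converged,
                     n_evaluations=int(res.nfev), model=fitted,
                     fit_space=fit_space)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def load_profile(path_or_buf, q_unit: str = "1/A",
                 metadata: str = "") -> ScatterProfile:
    """Read a 2- or 3-column ASCII/CSV profile (q, I[, sigma]).

    Lines starting with ``#`` are comments; columns may be separated by
    whitespace or commas.  ``q_unit`` is ``"1/A"`` (default) or ``"1/nm"``;
    nm⁻¹ input is converted to Å⁻¹ on ingestion.
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [tok for tok in line.replace(",", " ").split() if tok]
        rows.append([float(tok) for tok in parts])
    if not rows:
        raise ValueError("no data rows found")
    ncol = len(rows[0])
    if ncol not in (2, 3) or any(len(r) != ncol for r in rows):
        raise ValueError("expected 2 or 3 numeric columns throughout")
    arr = np.asarray(rows, dtype=float)
    q = arr[:, 0]
    if q_unit == "1/nm":
        q = q / 10.0
    elif q_unit != "1/A":
        raise ValueError("q_unit must be '1/A' or '1/nm'")
    sigma = arr[:, 2] if ncol == 3 else None
    return ScatterProfile(q=q, intensity=arr[:, 1], sigma=sigma,
                          metadata=metadata)


def save_profile(profile: ScatterProfile, path_or_buf) -> None:
    """Write a profile in the same dialect :func:`load_profile` accepts."""
    buf = io.StringIO()
    if profile.metadata:
        for line in profile.metadata.splitlines():
            buf.write(f"# {line}\n")
    buf.write("# q_1/A intensity" + (" sigma\n" if profile.sigma is not None
                                     else "\n"))
    cols = [profile.q, profile.intensity]
    if profile.sigma is not None:
        cols.append(profile.sigma)
    for row in zip(*cols):
        buf.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def fit_report_dict(result: FitResult,
                    indexing: LamellarIndexing | None = None,
                    peaks: PeakSet | None = None) -> dict:
    """Machine-readable fit report (JSON-serializable key-value dump)."""
    out: dict = {
        "parameters": result.parameters,
        "uncertainties": result.uncertainties,
        "chi2_reduced": result.chi2_reduced,
        "converged": result.convergence_flag,
        "n_evaluations": result.n_evaluations,
        "fit_space": result.fit_space,
    }
    if peaks is not None:
        out["peaks"] = {
            "positions_1/A": [float(v) for v in peaks.positions],
            "prominences": [float(v) for v in peaks.prominences],
        }
    if indexing is not None:
        out["lamellar"] = {
            "repeat_distance_A": indexing.repeat_distance,
            "orders": {f"{q:.6g}": n
                       for q, n in indexing.order_assignment.items()},
            "rms_residual_1/A": indexing.rms_residual,
        }
    return json.loads(json.dumps(out))  # ensure plain JSON types
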