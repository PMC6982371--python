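"""Seeded synthetic inputs for every pipeline stage.

Generates SAXS curves from any scattering model or mixture, multilamellar
Bragg patterns, and PFG-STE echo decays, each with a declared noise model
and the full generating truth attached, so parameter-recovery studies and
round-trip tests need no external data.

Shipped presets mirror the sample set of a DOPC/GM1 co-existence study:
GM1 micelles (slightly oblate core--shell ellipsoid, 9/10 nm outer
diameters), DOPC multilamellar stacks (repeat distance 60 Å), a
DOPC-GM1 97.5:2.5 stack (64 Å), vesicle-dominated micelle/vesicle(/disc)
mixtures, and a GM1 echo decay with D = 1.04e-10 m²/s.

The noise level is a package choice (instrument counting statistics are
not knowable from a reduced curve); the default is 2% multiplicative
Gaussian.  Randomness is fully determined by integer seeds: replicate
``i`` of master seed ``s`` draws from ``numpy.random.SeedSequence([s, i])``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import scattering_models as sm
from .nmr_diffusion import EchoDecay, PulseSequence
from .saxs_analysis import ScatterProfile

__all__ = [
    "NoiseSpec",
    "SimulatedDataset",
    "Scenario",
    "default_q_grid",
    "child_seed",
    "spawn_seeds",
    "apply_noise",
    "simulate_saxs",
    "simulate_lamellar",
    "simulate_echo_decay",
    "simulate_scenario",
    "preset",
    "PRESET_NAMES",
]

_NOISE_KINDS = ("none", "multiplicative-gaussian", "poisson-like")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: kind, level (fraction or count scale) and seed."""

    kind: str = "multiplicative-gaussian"
    level: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"kind must be one of {_NOISE_KINDS}")
        if self.level < 0:
            raise ValueError("level must be >= 0")


@dataclass
class SimulatedDataset:
    """Generated data plus an immutable copy of the generating truth."""

    truth: object
    data: ScatterProfile | EchoDecay
    noise: NoiseSpec


def default_q_grid(n: int = 200, q_min: float = 0.01, q_max: float = 0.5,
                   ) -> np.ndarray:
    """Default SAXS grid: log-spaced Å⁻¹ covering the usual 1-D range."""
    return np.geomspace(q_min, q_max, n)


def child_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Documented splitting rule: replicate streams from [master, index]."""
    return np.random.SeedSequence([int(master_seed), int(index)])


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """n independent integer seeds (< 2**31) derived from a master seed."""
    return [int(child_seed(master_seed, i).generate_state(1)[0] % (2**31))
            for i in range(n)]


def apply_noise(values: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Apply a NoiseSpec to noiseless values; level 0 or kind none is exact."""
    values = np.asarray(values, dtype=float)
    if noise.kind == "none" or noise.level == 0.0:
        return values.copy()
    rng = np.random.default_rng(np.random.SeedSequence(noise.seed))
    if noise.kind == "multiplicative-gaussian":
        out = values * (1.0 + noise.level * rng.standard_normal(values.shape))
    else:  # poisson-like: counts at an effective scale, then rescaled
        out = rng.poisson(np.maximum(values, 0.0) * noise.level) / noise.level
    # intensities/areas are physically non-negative
    return np.maximum(out, 1e-12 * np.max(values))


def _noise_sigma(values: np.ndarray, noise: NoiseSpec) -> np.ndarray | None:
    if noise.kind == "none" or noise.level == 0.0:
        return None
    if noise.kind == "multiplicative-gaussian":
        return np.maximum(noise.level * values, 1e-300)
    return np.maximum(np.sqrt(np.maximum(values, 0.0) / noise.level), 1e-300)


def simulate_saxs(model, q_grid: np.ndarray | None = None,
                  noise: NoiseSpec = NoiseSpec("none", 0.0, 0)) -> SimulatedDataset:
    """Evaluate a scattering model on a grid and apply noise.

    The returned profile carries per-point sigmas matching the declared
    noise model (none for noiseless data), and the truth is a deep copy of
    the generating parameter set.
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    ideal = sm.evaluate(model, q_grid)
    data = apply_noise(ideal, noise)
    profile = ScatterProfile(q=q_grid, intensity=data,
                             sigma=_noise_sigma(ideal, noise),
                             metadata=f"simulated: {type(model).__name__}, "
                                      f"noise={noise.kind}@{noise.level}, "
                                      f"seed={noise.seed}")
    return SimulatedDataset(truth=copy.deepcopy(model), data=profile,
                            noise=noise)


def simulate_lamellar(params: sm.LamellarPatternParams,
                      q_grid: np.ndarray | None = None,
                      noise: NoiseSpec = NoiseSpec("none", 0.0, 0),
                      ) -> SimulatedDataset:
    """Multilamellar Bragg pattern; same contract as :func:`simulate_saxs`."""
    return simulate_saxs(params, q_grid, noise)


def simulate_echo_decay(D: float, I0: float,
                        seq: PulseSequence | None = None,
                        noise: NoiseSpec = NoiseSpec("none", 0.0, 0),
                        ) -> SimulatedDataset:
    """PFG-STE echo decay I0*exp(-b(G) D) along the gradient ramp.

    The default sequence is the ¹H experiment the presets assume: δ = 2 ms,
    Δ = 150 ms, 32 linearly incremented gradient steps.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if I0 <= 0:
        raise ValueError("I0 must be > 0")
    if seq is None:
        seq = PulseSequence()
    ideal = I0 * np.exp(-seq.bvalues() * D)
    areas = apply_noise(ideal, noise)
    decay = EchoDecay(sequence=seq, areas=areas)
    truth = {"D": D, "I0": I0, "sequence": copy.deepcopy(seq)}
    return SimulatedDataset(truth=truth, data=decay, noise=noise)


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A fully specified generating condition for one synthetic dataset."""

    name: str
    kind: str  # "saxs" | "lamellar" | "decay"
    model: object | None = None
    D: float | None = None
    I0: float | None = None
    sequence: PulseSequence | None = None
    noise: NoiseSpec = NoiseSpec("multiplicative-gaussian", 0.02, 0)

    def simulate(self, seed: int | None = None) -> SimulatedDataset:
        return simulate_scenario(self, seed)

    @property
    def repeat_distance(self) -> float:
        if isinstance(self.model, sm.LamellarPatternParams):
            return self.model.repeat_distance
        raise AttributeError("scenario has no lamellar repeat distance")

    @property
    def Delta(self) -> float:
        if self.sequence is None:
            raise AttributeError("scenario has no pulse sequence")
        return self.sequence.Delta


def simulate_scenario(sc: Scenario, seed: int | None = None) -> SimulatedDataset:
    """Run a preset scenario, optionally re-seeding its noise stream."""
    noise = sc.noise if seed is None else NoiseSpec(sc.noise.kind,
                                                    sc.noise.level, seed)
    if sc.kind in ("saxs", "lamellar"):
        return simulate_saxs(sc.model, None, noise)
    return simulate_echo_decay(sc.D, sc.I0, sc.sequence, noise)


def _mixture_90_10() -> sm.MixtureModel:
    # vesicle-dominated: the bilayer shell out-scatters the micelles by far
    return sm.MixtureModel(
        components=[sm.preset("dopc_vesicle"), sm.preset("gm1_micelle")],
        weights=[1.0, 0.15],
    )


def _mixture_65_35() -> sm.MixtureModel:
    return sm.MixtureModel(
        components=[sm.preset("dopc_vesicle"), sm.preset("gm1_micelle"),
                    sm.preset("gm1_dopc_disc")],
        weights=[1.0, 0.5, 0.3],
    )


def _scenarios() -> dict[str, Scenario]:
    return {
        "gm1_micelle": Scenario("gm1_micelle", "saxs",
                                model=sm.preset("gm1_micelle")),
        "dopc_lamellar": Scenario("dopc_lamellar", "lamellar",
                                  model=sm.preset("dopc_lamellar_60A"),
                                  noise=NoiseSpec("multiplicative-gaussian",
                                                  0.01, 0)),
        "dopc_gm1_2.5_lamellar": Scenario(
            "dopc_gm1_2.5_lamellar", "lamellar",
            model=sm.preset("dopc_gm1_lamellar_64A"),
            noise=NoiseSpec("multiplicative-gaussian", 0.01, 0)),
        "dopc_gm1_90_10_mixture": Scenario("dopc_gm1_90_10_mixture", "saxs",
                                           model=_mixture_90_10()),
        "dopc_gm1_65_35_mixture": Scenario("dopc_gm1_65_35_mixture", "saxs",
                                           model=_mixture_65_35()),
        "gm1_diffusion": Scenario("gm1_diffusion", "decay",
                                  D=1.04e-10, I0=1.0,
                                  sequence=PulseSequence()),
    }


PRESET_NAMES = tuple(sorted(_scenarios()))


def preset(name: str) -> Scenario:
    """Return the named generating scenario (a fresh, fully specified copy)."""
    table = _scenarios()
    try:
        return table[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(PRESET_NAMES)}") from None
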