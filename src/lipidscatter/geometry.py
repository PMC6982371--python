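"""Packing geometry of amphiphiles and cross-technique size consistency.

Tanford-type estimates of molecular dimensions — the fully extended length
of an n-carbon acyl chain, the oligosaccharide headgroup contribution, and
the resulting micelle diameter (roughly twice the molecular length) — plus
a small aggregator that tabulates size observations from different
techniques (cryo-TEM, DLS, diffusion NMR, SAXS fitting, geometric
prediction) and flags inconsistencies.

All lengths here are nanometres, the natural unit at this scale; the
scattering core of the package works in Å and converts at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

__all__ = [
    "MoleculeGeometry",
    "SizeObservation",
    "ConsistencyReport",
    "tanford_chain_length",
    "headgroup_length",
    "micelle_size_estimate",
    "consistency_report",
]


def tanford_chain_length(nc: int) -> float:
    """Fully extended acyl-chain length l = 0.15 + 0.12*nc in nm."""
    if nc < 0:
        raise ValueError("carbon count must be >= 0")
    return 0.15 + 0.12 * nc


def headgroup_length(residues_along_axis: int, per_residue: float = 0.8) -> float:
    """Headgroup extension as residue count x per-residue length (nm)."""
    if residues_along_axis < 0 or per_residue < 0:
        raise ValueError("inputs must be >= 0")
    return residues_along_axis * per_residue


@dataclass
class MoleculeGeometry:
    """Chain/headgroup descriptors of an amphiphile and derived lengths.

    The headgroup contribution is taken as a direct length interval
    (``headgroup_range``): for branched oligosaccharides the effective
    extension along the micelle radius is shorter than the summed residue
    lengths, so no single multiplication is hard-coded;
    :func:`headgroup_length` is available as an explicit helper.
    """

    n_carbons: int
    headgroup_residues: int = 0
    per_residue_length: float = 0.8
    chain_length: float | None = None  # nm override of the Tanford estimate
    headgroup_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_carbons < 0 or self.headgroup_residues < 0:
            raise ValueError("counts must be >= 0")
        if self.chain_length is None:
            self.chain_length = tanford_chain_length(self.n_carbons)
        if self.chain_length < 0:
            raise ValueError("chain_length must be >= 0")
        lo, hi = self.headgroup_range
        if lo < 0 or lo > hi:
            raise ValueError("headgroup_range must satisfy 0 <= lo <= hi")

    @property
    def molecule_length_range(self) -> tuple[float, float]:
        lo, hi = self.headgroup_range
        return (self.chain_length + lo, self.chain_length + hi)


def micelle_size_estimate(chain: float, head_low: float, head_high: float,
                          ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Molecule-length and micelle-diameter ranges from packing lengths.

    The micelle diameter is taken as twice the fully stretched molecular
    length (chain + headgroup), endpoint-wise over the headgroup interval.

    Returns ``(molecule_length_range_nm, micelle_diameter_range_nm)``.
    """
    if chain < 0 or head_low < 0 or head_high < 0:
        raise ValueError("lengths must be >= 0")
    if head_low > head_high:
        raise ValueError("head_low must be <= head_high")
    mol = (chain + head_low, chain + head_high)
    return mol, (2.0 * mol[0], 2.0 * mol[1])


@dataclass
class SizeObservation:
    """One technique's size measurement as an interval in nm."""

    technique: str
    quantity: str
    value_range: tuple[float, float]
    source_note: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.value_range
        if not (lo <= hi) or hi <= 0:
            raise ValueError("value_range must satisfy lo <= hi and hi > 0")


@dataclass
class ConsistencyReport:
    """Pairwise interval-overlap summary of a set of size observations."""

    observations: list[SizeObservation]
    overlaps: dict[tuple[str, str], bool]
    gaps: dict[tuple[str, str], float]
    max_gap: float
    flagged_pairs: list[tuple[str, str]]

    def all_consistent(self) -> bool:
        return not self.flagged_pairs


def _interval_gap(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Distance between two closed intervals; 0 when they overlap."""
    return max(0.0, max(a[0], b[0]) - min(a[1], b[1]))


def consistency_report(observations: Sequence[SizeObservation]) -> ConsistencyReport:
    """Tabulate observations and flag non-overlapping technique pairs.

    Pairs are keyed by sorted technique labels so the report is invariant
    to the input order.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("need at least one observation")
    overlaps: dict[tuple[str, str], bool] = {}
    gaps: dict[tuple[str, str], float] = {}
    flagged: list[tuple[str, str]] = []
    for a, b in combinations(sorted(obs, key=lambda o: o.technique), 2):
        key = tuple(sorted((a.technique, b.technique)))
        gap = _interval_gap(a.value_range, b.value_range)
        # several observations per technique pair: keep the worst gap
        if key in gaps and gaps[key] >= gap:
            continue
        gaps[key] = gap
        overlaps[key] = gap == 0.0
        if gap > 0 and key not in flagged:
            flagged.append(key)
    flagged.sort()
    max_gap = max(gaps.values()) if gaps else 0.0
    return ConsistencyReport(observations=obs, overlaps=overlaps, gaps=gaps,
                             max_gap=max_gap, flagged_pairs=flagged)
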