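"""Normalization of adsorption isotherms into comparable coordinates.

Raw per-gram isotherms of different nucleotides, or of the same nucleotide on
differently ground powders of one mineral, cannot be compared directly.  Two
transformations make them commensurable:

* the equilibrium concentration is divided by the solute's molar solubility
  (reduced concentration x = Ceq / S), which superimposes the curves of
  homologous molecules adsorbing by a common mechanism;
* the per-gram uptake is divided by a specific surface area (total, basal, or
  edge, m^2/g), turning it into an adsorption density (mol/m^2).  Only the
  area that actually carries the adsorbate collapses curves across samples —
  for nucleotides on phyllosilicates, the lateral (edge) area.

The degree of superposition is quantified by a collapse score: the mean
coefficient of variation across curves evaluated on a shared log-spaced grid.
The score is dimensionless and invariant to a common scaling of all curves,
so scores measured in different units are comparable; lower means more
collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .isotherm import Isotherm

__all__ = [
    "NormPoint",
    "NormalizedIsotherm",
    "CollapseReport",
    "PlateauEstimate",
    "as_normalized",
    "reduce_concentration",
    "to_density",
    "collapse_score",
    "collapse_report",
    "plateau_density",
]

BASES = ("total", "basal", "edge", "none")


@dataclass(frozen=True)
class NormPoint:
    x: float  # concentration coordinate (mol/L raw, or dimensionless reduced)
    d: float  # density (mol/m^2) or per-gram uptake if basis == "none"
    sd_d: float = 0.0


@dataclass(frozen=True)
class NormalizedIsotherm:
    """An isotherm in normalized coordinates.

    ``basis`` records which specific surface area divided the uptake
    ("none" while still per-gram); ``concentration_mode`` is "raw" (mol/L)
    or "reduced" (Ceq / solubility, dimensionless).
    """

    points: tuple[NormPoint, ...]
    basis: str
    concentration_mode: str
    nucleotide: str
    mineral: str

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValueError(f"basis must be one of {BASES}")
        if self.concentration_mode not in ("raw", "reduced"):
            raise ValueError("concentration_mode must be 'raw' or 'reduced'")
        if any(p.x < 0 for p in self.points):
            raise ValueError("concentration coordinate must be >= 0")

    @property
    def x(self) -> np.ndarray:
        return np.array([p.x for p in self.points])

    @property
    def d(self) -> np.ndarray:
        return np.array([p.d for p in self.points])

    @property
    def sd_d(self) -> np.ndarray:
        return np.array([p.sd_d for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CollapseReport:
    """Superposition quality of a curve family before and after normalization."""

    score_before: float
    score_after: float
    grid: tuple[float, ...]
    n_curves: int


@dataclass(frozen=True)
class PlateauEstimate:
    value: float  # mean density over the tail window
    sd: float
    no_plateau: bool  # True when sd/mean exceeds the flatness threshold


Curve = Union[Isotherm, NormalizedIsotherm]


def as_normalized(iso: Curve) -> NormalizedIsotherm:
    """View an :class:`Isotherm` in raw per-gram coordinates (identity on
    :class:`NormalizedIsotherm`)."""
    if isinstance(iso, NormalizedIsotherm):
        return iso
    pts = tuple(NormPoint(p.c_eq, p.q_ads, p.sd_q) for p in iso.points)
    return NormalizedIsotherm(pts, "none", "raw", iso.nucleotide.name, iso.mineral.name)


def reduce_concentration(iso: Curve, solubility: float | None = None) -> NormalizedIsotherm:
    """Divide the concentration axis by the nucleotide's molar solubility.

    For an :class:`Isotherm` the solubility is taken from its nucleotide spec;
    for an already-normalized curve it must be passed explicitly (the curve
    only carries the nucleotide's name).  The density axis is untouched, so
    this commutes with :func:`to_density`.
    """
    if isinstance(iso, Isotherm):
        s = iso.nucleotide.solubility if solubility is None else solubility
        name = iso.nucleotide.name
        norm = as_normalized(iso)
    else:
        if iso.concentration_mode == "reduced":
            raise ValueError("curve is already on the reduced axis")
        if solubility is None:
            raise ValueError(
                f"solubility unknown for nucleotide {iso.nucleotide!r}; pass it explicitly"
            )
        s, name, norm = solubility, iso.nucleotide, iso
    if s is None or s <= 0:
        raise ValueError(f"missing or non-positive solubility for nucleotide {name!r}")
    pts = tuple(NormPoint(p.x / s, p.d, p.sd_d) for p in norm.points)
    return NormalizedIsotherm(pts, norm.basis, "reduced", norm.nucleotide, norm.mineral)


def to_density(iso: Curve, basis: str, ssa: float | None = None) -> NormalizedIsotherm:
    """Divide the uptake axis by a specific surface area (mol/g -> mol/m^2).

    ``basis`` is one of "total", "basal", "edge".  For an :class:`Isotherm`
    the area comes from its mineral spec; for a normalized curve pass ``ssa``
    (m^2/g) explicitly.  Uncertainties are propagated linearly.
    """
    if basis not in ("total", "basal", "edge"):
        raise ValueError("basis must be 'total', 'basal' or 'edge'")
    if isinstance(iso, Isotherm):
        area = iso.mineral.ssa(basis) if ssa is None else ssa
        norm = as_normalized(iso)
    else:
        if iso.basis != "none":
            raise ValueError(f"curve is already densitized on basis {iso.basis!r}")
        if ssa is None:
            raise ValueError(f"pass ssa explicitly for mineral {iso.mineral!r}")
        area, norm = ssa, iso
    if area is None or area <= 0:
        raise ValueError(f"basis area unavailable: {basis} SSA is zero or missing")
    pts = tuple(NormPoint(p.x, p.d / area, p.sd_d / area) for p in norm.points)
    return NormalizedIsotherm(pts, basis, norm.concentration_mode, norm.nucleotide, norm.mineral)


def _common_grid(curves: Sequence[NormalizedIsotherm], n_grid: int) -> np.ndarray:
    los, his = [], []
    for c in curves:
        x = c.x
        pos = x[x > 0]
        if pos.size == 0:
            raise ValueError("curve has no positive abscissa values")
        los.append(pos.min())
        his.append(x.max())
    lo, hi = max(los), min(his)
    if not lo < hi:
        raise ValueError("curves have disjoint abscissa supports")
    return np.geomspace(lo, hi, n_grid)


def collapse_score(curves: Iterable[Curve], n_grid: int = 50) -> float:
    """Mean cross-curve coefficient of variation on a shared log grid.

    Each curve is interpolated (monotone piecewise-linear, no extrapolation)
    onto a log-spaced grid restricted to the common support; the score is the
    mean over grid points of sd/mean across curves (sample sd, ddof=1).
    Identical curves score 0; multiplying every curve by a common constant
    leaves the score unchanged.
    """
    normed = [as_normalized(c) for c in curves]
    if len(normed) < 2:
        raise ValueError("collapse_score needs >= 2 curves")
    grid = _common_grid(normed, n_grid)
    values = np.empty((len(normed), grid.size))
    for i, c in enumerate(normed):
        order = np.argsort(c.x)
        values[i] = np.interp(grid, c.x[order], c.d[order])
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), 0.0)
    return float(np.mean(cv))


def collapse_report(
    before: Iterable[Curve], after: Iterable[Curve], n_grid: int = 50
) -> CollapseReport:
    """Score the same curve family in two coordinate systems (e.g. raw vs
    solubility-reduced) and report both, with the grid used for `after`."""
    before = [as_normalized(c) for c in before]
    after = [as_normalized(c) for c in after]
    if len(before) != len(after):
        raise ValueError("before/after families must have the same number of curves")
    report_grid = _common_grid(after, n_grid)
    return CollapseReport(
        score_before=collapse_score(before, n_grid),
        score_after=collapse_score(after, n_grid),
        grid=tuple(report_grid),
        n_curves=len(after),
    )


def plateau_density(
    curve: Curve, tail_fraction: float = 0.25, flatness_threshold: float = 0.1
) -> PlateauEstimate:
    """Saturation-plateau density from the tail of an isotherm.

    Averages the densities whose abscissa lies in the top `tail_fraction` of
    the abscissa range.  A relative spread sd/mean above `flatness_threshold`
    flags the curve as having no plateau (still rising or too noisy).
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    c = as_normalized(curve)
    x, d = c.x, c.d
    cut = x.max() - tail_fraction * (x.max() - x.min())
    tail = d[x >= cut]
    if tail.size < 3:
        raise ValueError(
            f"only {tail.size} points in the tail window; need >= 3 for a plateau estimate"
        )
    mean = float(np.mean(tail))
    sd = float(np.std(tail, ddof=1))
    no_plateau = bool(mean == 0 or sd / abs(mean) > flatness_threshold)
    return PlateauEstimate(mean, sd, no_plateau)
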