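"""Batch-adsorption processing at the solid/liquid interface.

A batch (immersion) experiment mixes a nucleotide solution of known initial
concentration with a weighed mass of mineral powder; after equilibration the
supernatant concentration is measured by UV/vis spectrophotometry.  The
depletion of the bulk solution gives, by mass balance, the adsorbed quantity
in mol of adsorbate per gram of mineral.  This module converts raw batch
measurements (absorbances or concentrations) into quality-checked adsorption
isotherms: ordered (equilibrium concentration, adsorbed quantity) curves with
replicate statistics and full provenance of the nucleotide, the mineral, and
the solution conditions.

Internal units are fixed: mol/L for concentrations, L for volumes, g for
masses, mol/g for adsorbed quantities.  All unit conversion happens at the
I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NucleotideSpec",
    "MineralSpec",
    "BatchSample",
    "IsothermPoint",
    "Isotherm",
    "Conditions",
    "CalibrationError",
    "NegativeAdsorptionWarning",
    "concentration_from_absorbance",
    "fit_extinction_coefficient",
    "adsorbed_quantity",
    "build_isotherm",
]

#: Default C0 schema range (mol/L); values outside trigger a warning, not a failure.
C0_SCHEMA_RANGE = (0.0, 3.5e-3)


class CalibrationError(ValueError):
    """Raised when a spectrophotometric reading cannot be converted to a concentration."""


class NegativeAdsorptionWarning(UserWarning):
    """Equilibrium concentration exceeded the initial one (desorption or measurement error)."""


@dataclass(frozen=True)
class NucleotideSpec:
    """Physico-chemical constants of a nucleotide (NMP or dNMP).

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"dGMP"``.
    molecular_weight : float
        g/mol.
    solubility : float
        Molar solubility (mol/L) at the reference temperature; used to build
        the solubility-reduced concentration axis.
    pka_values : tuple of float
        Acid dissociation constants, sorted ascending.
    extinction_coefficient : float
        Molar extinction coefficient (L mol^-1 cm^-1) at `wavelength`.
    wavelength : float
        Detection wavelength in nm.
    """

    name: str
    molecular_weight: float
    solubility: float
    pka_values: tuple[float, ...] = ()
    extinction_coefficient: float = 1.0e4
    wavelength: float = 260.0

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular_weight must be > 0")
        if self.solubility <= 0:
            raise ValueError(f"{self.name}: solubility must be > 0")
        if self.extinction_coefficient <= 0:
            raise ValueError(f"{self.name}: extinction_coefficient must be > 0")
        if list(self.pka_values) != sorted(self.pka_values):
            raise ValueError(f"{self.name}: pka_values must be sorted ascending")


@dataclass(frozen=True)
class MineralSpec:
    """A phyllosilicate sample with its partitioned specific surface areas.

    Clay particles expose large basal (siloxane) faces and small lateral
    (broken-edge) faces carrying pH-dependent metal hydroxyls; swelling clays
    additionally have an interlayer space.  Areas are in m^2/g.
    """

    name: str
    swelling: bool
    ssa_total: float
    ssa_basal: float
    ssa_edge: float
    point_of_zero_charge: float | None = None
    #: relative slack allowed on ssa_basal + ssa_edge <= ssa_total
    area_tolerance: float = 0.05

    def __post_init__(self) -> None:
        for label, area in (
            ("ssa_total", self.ssa_total),
            ("ssa_basal", self.ssa_basal),
            ("ssa_edge", self.ssa_edge),
        ):
            if area < 0:
                raise ValueError(f"{self.name}: {label} must be >= 0")
        if self.ssa_basal + self.ssa_edge > self.ssa_total * (1.0 + self.area_tolerance):
            raise ValueError(
                f"{self.name}: ssa_basal + ssa_edge exceeds ssa_total beyond tolerance"
            )

    def ssa(self, basis: str) -> float:
        """Specific surface area (m^2/g) for a normalization basis."""
        try:
            return {"total": self.ssa_total, "basal": self.ssa_basal, "edge": self.ssa_edge}[basis]
        except KeyError:
            raise ValueError(f"unknown surface basis {basis!r}") from None


@dataclass(frozen=True)
class Conditions:
    """Solution conditions shared by all samples of one isotherm."""

    ph: float
    temperature: float  # degrees C
    composition: tuple[tuple[str, float], ...] = ()  # (salt, mol/L), sorted by salt

    @staticmethod
    def from_mapping(ph: float, temperature: float, composition: Mapping[str, float]) -> "Conditions":
        return Conditions(ph, temperature, tuple(sorted(composition.items())))


@dataclass
class BatchSample:
    """One batch-adsorption measurement (one tube)."""

    initial_concentration: float  # C0, mol/L
    equilibrium_concentration: float  # Ceq, mol/L
    solution_volume: float  # V, L
    mineral_mass: float  # m, g
    ph: float = 7.0
    temperature: float = 25.0
    solution_composition: Mapping[str, float] = field(default_factory=dict)
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.solution_volume <= 0:
            raise ValueError("solution_volume must be > 0")
        if self.mineral_mass <= 0:
            raise ValueError("mineral_mass must be > 0")
        if self.initial_concentration < 0 or self.equilibrium_concentration < 0:
            raise ValueError("concentrations must be >= 0")
        lo, hi = C0_SCHEMA_RANGE
        if not (lo <= self.initial_concentration <= hi):
            warnings.warn(
                f"C0 = {self.initial_concentration:g} mol/L outside the usual "
                f"experimental range [{lo:g}, {hi:g}] mol/L",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class IsothermPoint:
    c_eq: float  # mol/L
    q_ads: float  # mol/g
    sd_q: float = 0.0  # mol/g; replicate spread, 0 if single

    def __post_init__(self) -> None:
        if self.c_eq < 0:
            raise ValueError("c_eq must be >= 0")
        if self.sd_q < 0:
            raise ValueError("sd_q must be >= 0")


@dataclass(frozen=True)
class Isotherm:
    """Equilibrium adsorption curve: adsorbed quantity vs equilibrium concentration."""

    points: tuple[IsothermPoint, ...]
    nucleotide: NucleotideSpec
    mineral: MineralSpec
    conditions: Conditions

    def __post_init__(self) -> None:
        c = [p.c_eq for p in self.points]
        if any(b <= a for a, b in zip(c, c[1:])):
            raise ValueError("isotherm points must be strictly ordered by increasing c_eq")

    @property
    def c_eq(self) -> np.ndarray:
        return np.array([p.c_eq for p in self.points])

    @property
    def q_ads(self) -> np.ndarray:
        return np.array([p.q_ads for p in self.points])

    @property
    def sd_q(self) -> np.ndarray:
        return np.array([p.sd_q for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


def concentration_from_absorbance(
    absorbance: float, spec: NucleotideSpec, path_length: float = 1.0
) -> float:
    """Convert a UV/vis absorbance to a molar concentration (Beer-Lambert).

    C = A / (epsilon * l).  Linearity is assumed over the working range.

    Raises
    ------
    CalibrationError
        If the absorbance is negative (impossible reading) or the path length
        is not positive.
    """
    if path_length <= 0:
        raise CalibrationError("path_length must be > 0 cm")
    if absorbance < 0:
        raise CalibrationError(f"negative absorbance {absorbance:g} rejected")
    return absorbance / (spec.extinction_coefficient * path_length)


def fit_extinction_coefficient(
    concentrations: Sequence[float], absorbances: Sequence[float], path_length: float = 1.0
) -> float:
    """Least-squares extinction coefficient from a multi-point standard curve.

    Fits A = epsilon * l * C as a line through the origin (closed form:
    epsilon = sum(A*C) / (l * sum(C^2))), the standard calibration for a
    Beer-Lambert-linear instrument.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.shape != a.shape or c.size < 2:
        raise CalibrationError("need >= 2 matched (concentration, absorbance) standards")
    if path_length <= 0:
        raise CalibrationError("path_length must be > 0 cm")
    denom = path_length * float(np.dot(c, c))
    if denom == 0:
        raise CalibrationError("all standard concentrations are zero")
    return float(np.dot(a, c)) / denom


def adsorbed_quantity(sample: BatchSample) -> float:
    """Adsorbed quantity q = (C0 - Ceq) * V / m in mol/g, by mass balance.

    The conservation identity q*m + Ceq*V = C0*V holds to machine precision.
    A negative result (Ceq > C0) is returned as-is and flagged with a
    :class:`NegativeAdsorptionWarning`; it is never clipped, so downstream QC
    can catch desorption or measurement errors.
    """
    q = (
        (sample.initial_concentration - sample.equilibrium_concentration)
        * sample.solution_volume
        / sample.mineral_mass
    )
    if q < 0:
        warnings.warn(
            f"negative adsorption: Ceq = {sample.equilibrium_concentration:g} > "
            f"C0 = {sample.initial_concentration:g} mol/L",
            NegativeAdsorptionWarning,
            stacklevel=2,
        )
    return q


def _conditions_match(a: BatchSample, b: BatchSample, rel_tol: float) -> str | None:
    """Return the name of the first mismatching condition field, or None."""
    if not math.isclose(a.ph, b.ph, rel_tol=rel_tol, abs_tol=1e-9):
        return "ph"
    if not math.isclose(a.temperature, b.temperature, rel_tol=rel_tol, abs_tol=1e-9):
        return "temperature"
    ca, cb = dict(a.solution_composition), dict(b.solution_composition)
    if set(ca) != set(cb):
        return "solution_composition"
    for salt in ca:
        if not math.isclose(ca[salt], cb[salt], rel_tol=rel_tol, abs_tol=0.0):
            return "solution_composition"
    return None


def build_isotherm(
    samples: Iterable[BatchSample],
    nucleotide: NucleotideSpec,
    mineral: MineralSpec,
    *,
    rel_tol: float = 1e-9,
) -> Isotherm:
    """Assemble an :class:`Isotherm` from batch samples.

    Replicates (samples sharing C0 and conditions within `rel_tol` relative
    tolerance) are aggregated to mean c_eq and mean q with the sample standard
    deviation of q; points are sorted by increasing c_eq.  The result is
    invariant to input order and idempotent on already-aggregated data.

    Raises
    ------
    ValueError
        If samples disagree on pH, temperature, or solution composition beyond
        tolerance (the offending field is named), or if no samples are given.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples given")
    ref = samples[0]
    for s in samples[1:]:
        bad = _conditions_match(ref, s, rel_tol)
        if bad is not None:
            raise ValueError(f"samples mix incompatible conditions: field {bad!r} differs")

    # Group replicates on C0 within relative tolerance (sorted sweep).
    ordered = sorted(samples, key=lambda s: s.initial_concentration)
    groups: list[list[BatchSample]] = []
    for s in ordered:
        if groups and math.isclose(
            groups[-1][0].initial_concentration,
            s.initial_concentration,
            rel_tol=rel_tol,
            abs_tol=0.0,
        ):
            groups[-1].append(s)
        else:
            groups.append([s])

    points = []
    for grp in groups:
        qs = np.array([adsorbed_quantity(s) for s in grp])
        ceqs = np.array([s.equilibrium_concentration for s in grp])
        sd = float(np.std(qs, ddof=1)) if len(qs) > 1 else 0.0
        points.append(IsothermPoint(float(np.mean(ceqs)), float(np.mean(qs)), sd))
    points.sort(key=lambda p: p.c_eq)
    c = [p.c_eq for p in points]
    if any(b <= a for a, b in zip(c, c[1:])):
        raise ValueError("duplicated c_eq after replicate aggregation")

    conditions = Conditions.from_mapping(ref.ph, ref.temperature, dict(ref.solution_composition))
    return Isotherm(tuple(points), nucleotide, mineral, conditions)
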