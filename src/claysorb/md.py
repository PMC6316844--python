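"""Adsorption-state and complex-charge analysis of MD trajectories.

Post-processes trajectories of a nucleotide near a clay slab (orthorhombic
periodic box).  Per frame, the minimum-image distance between any molecule
atom and any surface atom decides adsorption: the molecule is adsorbed when
that distance is <= 4 A (inclusive).  Adsorbed frames are split by the tilt
of the nucleobase ring plane relative to the surface plane into a parallel
(state 2) and a non-parallel (state 1) configuration; state 0 is free.  From
the classified series the module derives dwell segments, the duration ratio
of adsorbed to free time, and the complexed-molecule ("global") charge: the
molecule's net charge plus the formal charges of ions within a cutoff of it,
averaged per state.  Cation bridging shows up as a higher global charge and
longer residence in divalent-salt systems.

Only orthorhombic boxes are supported; clay-slab systems have the slab
normal along the longest box axis, which is the default surface orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "CHARGE_CONVENTION",
    "TrajectoryFrame",
    "StateSeries",
    "ChargeSeries",
    "min_surface_distance",
    "ring_tilt_angle",
    "classify_state",
    "state_series",
    "complex_charge",
    "charge_series",
    "per_state_charge",
    "combine_replicate_tables",
]

ROLES = ("molecule", "surface", "cation", "anion", "solvent")

#: Bookkeeping convention recorded with every charge output.
CHARGE_CONVENTION = (
    "sum of molecule partial charges plus formal charges of cations and anions "
    "with any atom within ion_cutoff (minimum image) of any molecule atom"
)


@dataclass(frozen=True)
class TrajectoryFrame:
    """One frame: coordinates (A), orthorhombic box edges (A), per-atom roles
    and charges (e), and the index subset defining the nucleobase ring."""

    time: float  # ns
    box: tuple[float, float, float]
    coordinates: np.ndarray  # (n_atoms, 3)
    roles: tuple[str, ...]
    charges: np.ndarray  # (n_atoms,)
    ring_atoms: tuple[int, ...]
    elements: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "charges", np.asarray(self.charges, dtype=float))
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ValueError("box must be three positive orthorhombic edge lengths")
        n = coords.shape[0]
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if len(self.roles) != n or self.charges.shape[0] != n:
            raise ValueError("roles and charges must match the atom count")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown atom roles: {sorted(bad)}")
        mol = set(self.indices("molecule"))
        if len(self.ring_atoms) < 3:
            raise ValueError("ring_atoms must contain >= 3 atoms")
        if not set(self.ring_atoms) <= mol:
            raise ValueError("ring_atoms must be a subset of molecule atoms")

    def indices(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role], dtype=int)


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _pair_min_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum over all a-b pairs of the minimum-image Euclidean distance."""
    delta = _min_image(a[:, None, :] - b[None, :, :], box)
    return float(np.sqrt((delta**2).sum(axis=2).min()))


def min_surface_distance(frame: TrajectoryFrame) -> float:
    """Minimum molecule-surface atom distance (A), orthorhombic minimum image."""
    mol = frame.indices("molecule")
    surf = frame.indices("surface")
    if mol.size == 0 or surf.size == 0:
        raise ValueError("frame lacks molecule or surface atoms")
    box = np.asarray(frame.box)
    return _pair_min_distance(frame.coordinates[mol], frame.coordinates[surf], box)


def _surface_axis(frame: TrajectoryFrame, surface_axis: int | None) -> int:
    return int(np.argmax(frame.box)) if surface_axis is None else surface_axis


def ring_tilt_angle(frame: TrajectoryFrame, surface_axis: int | None = None) -> float:
    """Angle (degrees, in [0, 90]) between the nucleobase ring plane and the
    surface plane.

    The ring plane is the least-squares plane through ``ring_atoms`` (smallest
    principal axis of the centered coordinates); the surface plane is normal
    to `surface_axis` (default: the longest box edge, the slab normal).
    """
    axis = _surface_axis(frame, surface_axis)
    ring = frame.coordinates[list(frame.ring_atoms)]
    centered = ring - ring.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("ring_atoms are collinear; no plane is defined")
    normal = vt[2]
    surf_normal = np.zeros(3)
    surf_normal[axis] = 1.0
    cosang = np.clip(abs(float(normal @ surf_normal)), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def classify_state(
    frame: TrajectoryFrame,
    cutoff: float = 4.0,
    parallel_max_tilt: float = 30.0,
    surface_axis: int | None = None,
) -> int:
    """Three-state classification of one frame.

    state 0: min molecule-surface distance > `cutoff` (free);
    state 2: adsorbed (distance <= cutoff, inclusive) with ring tilt
    <= `parallel_max_tilt` (parallel); state 1: adsorbed, non-parallel.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if min_surface_distance(frame) > cutoff:
        return 0
    tilt = ring_tilt_angle(frame, surface_axis)
    return 2 if tilt <= parallel_max_tilt else 1


@dataclass(frozen=True)
class StateSeries:
    """Classified trajectory: per-frame states with distances and tilts,
    dwell segments (state, start_frame, end_frame exclusive), and the
    adsorbed/free duration ratio (np.inf with ``ratio_infinite`` set when no
    frame is free)."""

    states: np.ndarray
    min_distance: np.ndarray
    tilt_angle: np.ndarray
    times: np.ndarray
    dwell_segments: tuple[tuple[int, int, int], ...]
    duration_ratio: float
    ratio_infinite: bool


def _run_segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    segs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segs.append((int(labels[start]), start, i))
            start = i
    return segs


def _relabel_short_runs(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Merge runs shorter than min_len into the flanking state (previous run
    when it exists, else the following one), repeating until stable."""
    labels = labels.copy()
    if min_len <= 1:
        return labels
    changed = True
    while changed:
        changed = False
        segs = _run_segments(labels)
        for k, (state, a, b) in enumerate(segs):
            if b - a < min_len and len(segs) > 1:
                flank = segs[k - 1][0] if k > 0 else segs[k + 1][0]
                labels[a:b] = flank
                changed = True
                break
    return labels


def state_series(
    frames: Sequence[TrajectoryFrame],
    cutoff: float = 4.0,
    parallel_max_tilt: float = 30.0,
    min_dwell_frames: int = 1,
    surface_axis: int | None = None,
) -> StateSeries:
    """Classify every frame and derive dwell statistics.

    With ``min_dwell_frames > 1`` dwell segments shorter than the threshold
    are relabelled to the flanking state — first on the adsorbed/free
    dichotomy, then within the adsorbed sub-states — suppressing fleeting
    recrossings.  duration_ratio = (frames in states 1 or 2)/(frames in 0).
    """
    if len(frames) < 2:
        raise ValueError("need >= 2 frames")
    dists = np.array([min_surface_distance(f) for f in frames])
    tilts = np.array([ring_tilt_angle(f, surface_axis) for f in frames])
    adsorbed = dists <= cutoff
    states = np.where(adsorbed, np.where(tilts <= parallel_max_tilt, 2, 1), 0)

    if min_dwell_frames > 1:
        dichotomy = _relabel_short_runs(adsorbed.astype(int), min_dwell_frames)
        adsorbed = dichotomy.astype(bool)
        sub = np.where(tilts <= parallel_max_tilt, 2, 1)
        sub = _relabel_short_runs(sub, min_dwell_frames)
        states = np.where(adsorbed, sub, 0)

    n_free = int(np.sum(states == 0))
    n_ads = int(np.sum(states > 0))
    if n_free == 0:
        ratio, infinite = float("inf"), True
        warnings.warn("no free frames: duration ratio is infinite", UserWarning, stacklevel=2)
    else:
        ratio, infinite = n_ads / n_free, False
    times = np.array([f.time for f in frames])
    return StateSeries(
        states, dists, tilts, times, tuple(_run_segments(states)), ratio, infinite
    )


def complex_charge(frame: TrajectoryFrame, ion_cutoff: float = 4.0) -> float:
    """Global charge of the complexed molecule (elementary units).

    Default convention (recorded as :data:`CHARGE_CONVENTION`): the sum of
    the molecule's partial charges plus the charge of every cation and anion
    having any atom within `ion_cutoff` of any molecule atom (minimum image).
    """
    mol = frame.indices("molecule")
    if mol.size == 0:
        raise ValueError("frame lacks molecule atoms")
    if not np.all(np.isfinite(frame.charges)):
        raise ValueError("missing (non-finite) charges")
    box = np.asarray(frame.box)
    total = float(frame.charges[mol].sum())
    mol_xyz = frame.coordinates[mol]
    ions = np.concatenate([frame.indices("cation"), frame.indices("anion")])
    if ions.size:
        delta = _min_image(frame.coordinates[ions][:, None, :] - mol_xyz[None, :, :], box)
        dmin = np.sqrt((delta**2).sum(axis=2)).min(axis=1)
        total += float(frame.charges[ions[dmin <= ion_cutoff]].sum())
    return total


@dataclass(frozen=True)
class ChargeSeries:
    values: np.ndarray  # per-frame complex charge
    convention: str = CHARGE_CONVENTION


def charge_series(frames: Sequence[TrajectoryFrame], ion_cutoff: float = 4.0) -> ChargeSeries:
    return ChargeSeries(np.array([complex_charge(f, ion_cutoff) for f in frames]))


def per_state_charge(series: StateSeries, charges: ChargeSeries) -> pd.DataFrame:
    """Frame-weighted mean and sd of the complex charge per state.

    Returns a DataFrame indexed by state (0, 1, 2) with columns mean, sd, n;
    unvisited states get n = 0 and NaN statistics.
    """
    if len(series.states) != len(charges.values):
        raise ValueError("state and charge series must be frame-aligned")
    rows = []
    for state in (0, 1, 2):
        vals = charges.values[series.states == state]
        if vals.size == 0:
            rows.append({"state": state, "mean": np.nan, "sd": np.nan, "n": 0})
        else:
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            rows.append({"state": state, "mean": float(np.mean(vals)), "sd": sd, "n": int(vals.size)})
    return pd.DataFrame(rows).set_index("state")


def combine_replicate_tables(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Frame-count-weighted average of per-state charge tables across
    replicate simulations."""
    tables = list(tables)
    if not tables:
        raise ValueError("no tables given")
    rows = []
    for state in (0, 1, 2):
        ns = np.array([t.loc[state, "n"] for t in tables], dtype=float)
        means = np.array([t.loc[state, "mean"] for t in tables], dtype=float)
        n_tot = ns.sum()
        if n_tot == 0:
            rows.append({"state": state, "mean": np.nan, "n": 0})
        else:
            ok = ns > 0
            rows.append(
                {"state": state, "mean": float((means[ok] * ns[ok]).sum() / n_tot), "n": int(n_tot)}
            )
    return pd.DataFrame(rows).set_index("state")
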