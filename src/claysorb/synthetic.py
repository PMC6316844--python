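"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here with the statistical
structure the analysis assumes, and with the generating parameters stored
alongside, so that every downstream statistic has a closed-form expectation:

* batch samples whose equilibrium concentrations solve the chosen Langmuir
  model jointly with mass balance (instrument-like multiplicative noise);
* families of "homologous" nucleotide isotherms sharing one reduced-axis
  shape, so collapse on the solubility-reduced axis is true by construction;
* coarse/fine grain pairs of one mineral whose uptake is proportional to the
  edge area, so only the edge-basis density collapses;
* multi-domain low-pressure argon isotherms built from Bragg-Williams local
  isotherms, including an "edge-blocked" variant emulating a surface whose
  high-energy sites have been covered by an adsorbate;
* two-state Markov toy trajectories of a rigid molecule (planar 5-ring, net
  charge -2) over a static slab, with state-dependent distance and tilt
  sampling and scenario-dependent ion complexation (monovalent Na-like vs
  divalent Ca-like).

All randomness flows from ``numpy.random.default_rng(seed)``; the same
(seed, parameters) pair reproduces identical output bit for bit.

The shipped nucleotide/mineral constants (solubilities, extinction
coefficients, surface areas) are synthetic placeholders for testing, not
literature values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import brentq

from .dis import GasIsotherm, LocalDomain, theta_local
from .isotherm import (
    BatchSample,
    Isotherm,
    IsothermPoint,
    MineralSpec,
    NucleotideSpec,
    Conditions,
)
from .md import TrajectoryFrame

__all__ = [
    "SyntheticScenario",
    "SYNTHETIC_SEAWATER",
    "isotherm_scenario",
    "homologous_family_scenario",
    "grain_pair_scenario",
    "gas_isotherm_scenario",
    "trajectory_scenario",
    "gen_isotherm",
    "gen_homologous_family",
    "gen_grain_pair",
    "gen_gas_isotherm",
    "gen_trajectory",
]

#: Seawater-analog composition used as the default solution, mol/L.
SYNTHETIC_SEAWATER = {"NaCl": 0.5, "MgCl2": 0.05}

KINDS = ("isotherm", "homologous_family", "grain_pair", "gas_isotherm", "trajectory")


@dataclass(frozen=True)
class SyntheticScenario:
    """Seeded ground-truth parameter bundle for one generator run."""

    seed: int
    kind: str
    truth: dict[str, Any] = field(default_factory=dict)
    noise: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _require(scenario: SyntheticScenario, kind: str) -> None:
    if scenario.kind != kind:
        raise ValueError(f"scenario kind is {scenario.kind!r}, expected {kind!r}")


# ---------------------------------------------------------------------------
# batch isotherms

def isotherm_scenario(
    seed: int,
    *,
    model: str = "classic",
    q_max: float = 1.0e-4,  # mol/g
    k: float = 5.0e3,  # L/mol (classic)
    k_ml: float = 100.0,  # dimensionless (modified)
    solubility: float = 0.02,  # mol/L, synthetic placeholder
    c0_max: float = 3.5e-3,  # stock-solution range upper end, mol/L
    n_points: int = 20,
    replicates: int = 1,
    noise: float = 0.02,  # relative sd of the multiplicative Ceq noise
    volume_L: float = 1.0e-3,
    mass_g: float = 0.01,
) -> SyntheticScenario:
    """Scenario for a single batch-adsorption isotherm with Langmuir truth."""
    if model not in ("classic", "modified"):
        raise ValueError("model must be 'classic' or 'modified'")
    truth = dict(
        model=model, q_max=q_max, k=k, k_ml=k_ml, solubility=solubility,
        c0_max=c0_max, n_points=n_points, replicates=replicates,
        volume_L=volume_L, mass_g=mass_g,
    )
    return SyntheticScenario(seed, "isotherm", truth, {"ceq": noise})


def _truth_q(truth: dict[str, Any], ceq: float) -> float:
    if truth["model"] == "classic":
        return truth["q_max"] * truth["k"] * ceq / (1.0 + truth["k"] * ceq)
    c_s, k_ml = truth["solubility"], truth["k_ml"]
    return truth["q_max"] * k_ml * ceq / (c_s - ceq + k_ml * ceq)


def gen_isotherm(scenario: SyntheticScenario) -> list[BatchSample]:
    """Batch samples whose Ceq solves the truth model plus mass balance.

    For each C0 on a uniform grid, Ceq is the root of
    Ceq + q(Ceq) * m / V - C0 = 0 (bracketed bisection/Brent to ~1e-14), so
    mass balance closes exactly before noise.  Multiplicative Gaussian noise
    is then applied to Ceq; draws that would go negative are resampled (with
    a warning count).
    """
    _require(scenario, "isotherm")
    t = scenario.truth
    rng = scenario.rng()
    sigma = scenario.noise.get("ceq", 0.0)
    c0_grid = np.linspace(0.0, t["c0_max"], t["n_points"] + 1)[1:]
    ratio = t["mass_g"] / t["volume_L"]
    samples, n_resampled = [], 0
    for c0 in c0_grid:
        f = lambda ceq: ceq + _truth_q(t, ceq) * ratio - c0  # noqa: E731
        ceq_true = brentq(f, 0.0, c0, xtol=1e-16, rtol=8.9e-16)
        for rep in range(t["replicates"]):
            ceq = ceq_true * (1.0 + sigma * rng.standard_normal()) if sigma else ceq_true
            while ceq < 0:
                n_resampled += 1
                ceq = ceq_true * (1.0 + sigma * rng.standard_normal())
            samples.append(
                BatchSample(
                    initial_concentration=float(c0),
                    equilibrium_concentration=float(ceq),
                    solution_volume=t["volume_L"],
                    mineral_mass=t["mass_g"],
                    ph=7.0,
                    temperature=25.0,
                    solution_composition=dict(SYNTHETIC_SEAWATER),
                    replicate_id=rep,
                )
            )
    if n_resampled:
        warnings.warn(f"resampled {n_resampled} negative Ceq draws", UserWarning, stacklevel=2)
    return samples


# ---------------------------------------------------------------------------
# homologous families and grain pairs

_SHARED_MINERAL = MineralSpec("syn-nontronite", swelling=True, ssa_total=60.0,
                              ssa_basal=50.0, ssa_edge=10.0)


def _shape(x: np.ndarray, d_max: float, k_x: float) -> np.ndarray:
    """Shared reduced-axis Langmuir shape d(x) = d_max * k_x x / (1 + k_x x)."""
    return d_max * k_x * x / (1.0 + k_x * x)


def homologous_family_scenario(
    seed: int,
    *,
    solubilities: Sequence[float] = (0.005, 0.010, 0.025),  # 5-fold spread, mol/L
    q_scale: float = 1.0e-4,  # mol/g at full coverage
    k_x: float = 50.0,  # affinity on the reduced axis
    x_range: tuple[float, float] = (1e-3, 0.5),
    n_points: int = 15,
    noise: float = 0.02,
) -> SyntheticScenario:
    """Family of nucleotides sharing one reduced-axis shape, solubilities apart."""
    if len(solubilities) < 2:
        raise ValueError("need >= 2 nucleotides with distinct solubilities")
    if len(set(solubilities)) != len(solubilities):
        warnings.warn("solubilities are not all distinct", UserWarning, stacklevel=2)
    truth = dict(solubilities=tuple(solubilities), q_scale=q_scale, k_x=k_x,
                 x_range=x_range, n_points=n_points)
    return SyntheticScenario(seed, "homologous_family", truth, {"q": noise})


def gen_homologous_family(scenario: SyntheticScenario) -> list[Isotherm]:
    """One isotherm per synthetic nucleotide, materialized at c_eq = x * S_i."""
    _require(scenario, "homologous_family")
    t = scenario.truth
    rng = scenario.rng()
    sigma = scenario.noise.get("q", 0.0)
    x = np.geomspace(*t["x_range"], t["n_points"])
    q_clean = _shape(x, t["q_scale"], t["k_x"])
    conditions = Conditions.from_mapping(7.0, 25.0, SYNTHETIC_SEAWATER)
    isotherms = []
    for i, s in enumerate(t["solubilities"]):
        nuc = NucleotideSpec(f"synNMP{i}", molecular_weight=320.0, solubility=float(s))
        q = q_clean * (1.0 + sigma * rng.standard_normal(x.size)) if sigma else q_clean
        pts = tuple(IsothermPoint(float(xi * s), float(max(qi, 0.0))) for xi, qi in zip(x, q))
        isotherms.append(Isotherm(pts, nuc, _SHARED_MINERAL, conditions))
    return isotherms


def grain_pair_scenario(
    seed: int,
    *,
    edge_ssas: tuple[float, float] = (10.0, 30.0),  # coarse, fine (m^2/g)
    basal_ssas: tuple[float, float] = (20.0, 40.0),  # chosen NOT proportional to edge
    d_edge_max: float = 3.0e-6,  # mol/m^2 of edge surface at full coverage
    k_x: float = 50.0,
    solubility: float = 0.02,
    x_range: tuple[float, float] = (1e-3, 0.5),
    n_points: int = 15,
    noise: float = 0.02,
) -> SyntheticScenario:
    """Coarse vs fine grains of one mineral, uptake proportional to edge area.

    The basal (and hence total) areas are deliberately not proportional to the
    edge areas, so per-gram, basal-basis and total-basis curves differ between
    the grains while the edge-basis densities coincide.
    """
    truth = dict(edge_ssas=edge_ssas, basal_ssas=basal_ssas, d_edge_max=d_edge_max,
                 k_x=k_x, solubility=solubility, x_range=x_range, n_points=n_points)
    return SyntheticScenario(seed, "grain_pair", truth, {"q": noise})


def gen_grain_pair(scenario: SyntheticScenario) -> tuple[list[Isotherm], list[MineralSpec]]:
    _require(scenario, "grain_pair")
    t = scenario.truth
    rng = scenario.rng()
    sigma = scenario.noise.get("q", 0.0)
    x = np.geomspace(*t["x_range"], t["n_points"])
    d_edge = _shape(x, t["d_edge_max"], t["k_x"])
    nuc = NucleotideSpec("syn-dGMP", molecular_weight=347.2, solubility=t["solubility"])
    conditions = Conditions.from_mapping(7.0, 25.0, SYNTHETIC_SEAWATER)
    isotherms, minerals = [], []
    for grain, (edge, basal) in zip(("coarse", "fine"), zip(t["edge_ssas"], t["basal_ssas"])):
        mineral = MineralSpec(f"syn-chlorite-{grain}", swelling=False,
                              ssa_total=edge + basal, ssa_basal=basal, ssa_edge=edge)
        q = d_edge * edge
        if sigma:
            q = q * (1.0 + sigma * rng.standard_normal(x.size))
        pts = tuple(
            IsothermPoint(float(xi * t["solubility"]), float(max(qi, 0.0)))
            for xi, qi in zip(x, q)
        )
        isotherms.append(Isotherm(pts, nuc, mineral, conditions))
        minerals.append(mineral)
    return isotherms, minerals


# ---------------------------------------------------------------------------
# gas isotherms

def gas_isotherm_scenario(
    seed: int,
    *,
    domains: Sequence[tuple[float, float, float]] = ((0.3, -12.0, 0.8), (0.7, -5.0, 2.0)),
    edge_blocked: bool = False,
    p_range: tuple[float, float] = (1e-7, 0.05),
    n_points: int = 300,
    noise: float = 0.01,
) -> SyntheticScenario:
    """Multi-domain argon isotherm scenario.

    ``domains`` lists (v_m, u_half, omega) triples, ordered by energy; the
    default is an edge domain at u_half = -12 holding 30% of the monolayer
    and a basal domain at -5 holding 70%.  ``edge_blocked=True`` zeroes the
    most energetic (lowest u_half) domain, emulating a surface whose
    high-energy edge sites are covered by an adsorbate.
    """
    if not 1 <= len(domains) <= 4:
        raise ValueError("need 1 to 4 domains")
    doms = [list(d) for d in sorted(domains, key=lambda d: d[1])]
    for v_m, u_half, omega in doms:
        LocalDomain(v_m, u_half, omega)  # validates, incl. omega < 4
    if edge_blocked:
        doms[0][0] = 0.0
    truth = dict(domains=tuple(tuple(d) for d in doms), edge_blocked=edge_blocked,
                 p_range=p_range, n_points=n_points)
    return SyntheticScenario(seed, "gas_isotherm", truth, {"v": noise})


def gen_gas_isotherm(scenario: SyntheticScenario) -> GasIsotherm:
    """v_ads(u) = sum of v_m,i * theta_i(u) on a log-spaced P/P0 grid, with
    multiplicative noise proportional to the local signal."""
    _require(scenario, "gas_isotherm")
    t = scenario.truth
    rng = scenario.rng()
    sigma = scenario.noise.get("v", 0.0)
    p = np.geomspace(*t["p_range"], t["n_points"])
    u = np.log(p)
    v = np.zeros_like(u)
    for v_m, u_half, omega in t["domains"]:
        if v_m > 0:
            v += v_m * theta_local(u, u_half, omega)
    if sigma:
        v = v * (1.0 + sigma * rng.standard_normal(u.size))
    return GasIsotherm(tuple(p), tuple(np.clip(v, 0.0, None)))


def truth_domains(scenario: SyntheticScenario) -> tuple[LocalDomain, ...]:
    """Ground-truth domains of a gas-isotherm scenario as LocalDomain objects."""
    _require(scenario, "gas_isotherm")
    return tuple(
        LocalDomain(v_m, u_half, omega) for v_m, u_half, omega in scenario.truth["domains"]
    )


# ---------------------------------------------------------------------------
# toy trajectories

# Rigid molecule template: planar 5-ring plus a short phosphate-bearing arm.
# Partial charges sum to exactly -2 e.
_MOL_TEMPLATE = np.array(
    [
        [1.35 * math.cos(2 * math.pi * k / 5), 1.35 * math.sin(2 * math.pi * k / 5), 0.0]
        for k in range(5)
    ]
    + [[2.45, 0.0, 0.55], [3.40, 0.75, 0.25], [3.55, -0.85, 0.45], [4.40, -0.10, 1.05]]
)
_MOL_CHARGES = np.array([0.10, 0.05, 0.05, 0.05, 0.03, 0.02, -0.60, -0.60, -1.10])
_MOL_ELEMENTS = ("C", "C", "N", "C", "N", "C", "O", "O", "P")
_RING_ATOMS = (0, 1, 2, 3, 4)

_SALT_DEFAULTS = {
    # transition probabilities per frame (free->adsorbed, adsorbed->free),
    # ion valence, box ion counts, state-dependent Poisson bound-ion means
    "na": dict(p_on=0.02, p_off=0.05, ion_charge=1.0, n_cations=28, n_anions=26,
               bound_mean_adsorbed=3.4, bound_mean_free=2.85),
    "ca": dict(p_on=0.06, p_off=0.02, ion_charge=2.0, n_cations=14, n_anions=26,
               bound_mean_adsorbed=2.8, bound_mean_free=2.46),
}


def trajectory_scenario(
    seed: int,
    *,
    salt: str = "na",
    n_frames: int = 2000,
    dt_ns: float = 0.05,
    box: tuple[float, float, float] = (41.44, 35.88, 62.5),
    parallel_prob: float = 0.5,
    parallel_max_tilt: float = 30.0,
    cutoff: float = 4.0,
    ion_cutoff: float = 4.0,
    adsorbed_distance: tuple[float, float] = (2.5, 4.0),
    free_distance: tuple[float, float] = (4.5, 20.0),
    jitter: float = 0.1,  # RMS atomic displacement magnitude, A
    **overrides: float,
) -> SyntheticScenario:
    """Two-state Markov trajectory scenario (Na-like or Ca-like salt).

    The defaults give the Na-like chain a stationary adsorbed fraction
    p_on/(p_on+p_off) = 2/7, i.e. an expected adsorbed/free duration ratio of
    0.4, and the Ca-like chain a fraction 3/4 (ratio 3).  State-dependent
    Poisson means for the number of complexed ions put the mean adsorbed-state
    global charge near +1.4 e (monovalent Na-like) and +3.6 e (divalent
    Ca-like).  ``overrides`` may replace any salt default (p_on, p_off,
    ion_charge, n_cations, n_anions, bound_mean_adsorbed, bound_mean_free).
    """
    if salt not in _SALT_DEFAULTS:
        raise ValueError("salt must be 'na' or 'ca'")
    params = dict(_SALT_DEFAULTS[salt])
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown overrides: {sorted(unknown)}")
    params.update(overrides)
    if adsorbed_distance[1] > cutoff:
        raise ValueError("adsorbed distance range extends beyond the adsorption cutoff")
    if free_distance[0] <= cutoff:
        raise ValueError("free distance range must start above the adsorption cutoff")
    pi = params["p_on"] / (params["p_on"] + params["p_off"])
    truth = dict(
        salt=salt, n_frames=n_frames, dt_ns=dt_ns, box=box,
        parallel_prob=parallel_prob, parallel_max_tilt=parallel_max_tilt,
        cutoff=cutoff, ion_cutoff=ion_cutoff,
        adsorbed_distance=adsorbed_distance, free_distance=free_distance,
        stationary_adsorbed_fraction=pi,
        expected_duration_ratio=pi / (1.0 - pi),
        molecule_net_charge=-2.0,
        expected_adsorbed_charge=-2.0 + params["ion_charge"] * params["bound_mean_adsorbed"],
        expected_free_charge=-2.0 + params["ion_charge"] * params["bound_mean_free"],
        **params,
    )
    return SyntheticScenario(seed, "trajectory", truth, {"jitter": jitter})


def _rotation(tilt_deg: float, azimuth: float) -> np.ndarray:
    """Rotate about y by the tilt, then about z by the azimuth."""
    t, a = math.radians(tilt_deg), azimuth
    ry = np.array([[math.cos(t), 0, math.sin(t)], [0, 1, 0], [-math.sin(t), 0, math.cos(t)]])
    rz = np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]])
    return rz @ ry


def _min_image_dist(points: np.ndarray, ref: np.ndarray, box: np.ndarray) -> float:
    delta = points - ref
    delta -= box * np.round(delta / box)
    return float(np.sqrt((delta**2).sum(axis=1)).min())


def gen_trajectory(
    scenario: SyntheticScenario,
) -> tuple[list[TrajectoryFrame], dict[str, Any]]:
    """Generate frames plus a truth record.

    Returns ``(frames, truth)`` where ``truth`` extends the scenario truth
    with per-frame ground-truth ``states`` (0/1/2) and ``bound_ions`` counts.
    The surface is a static grid slab normal to z; the molecule is placed so
    that its lowest atom sits exactly at the sampled minimum distance above a
    surface atom (adsorbed) or anywhere above the free-distance floor (free).
    Positional jitter (RMS magnitude ``noise['jitter']``) is applied to all
    atoms after placement; truth labels refer to the unjittered geometry.
    """
    _require(scenario, "trajectory")
    t = scenario.truth
    rng = scenario.rng()
    box = np.asarray(t["box"], dtype=float)
    jitter_sigma = scenario.noise.get("jitter", 0.0) / math.sqrt(3.0)

    # static surface slab: grid in the xy plane at z = 2 A
    z_surf = 2.0
    nx, ny = 13, 11
    gx = (np.arange(nx) + 0.5) * box[0] / nx
    gy = (np.arange(ny) + 0.5) * box[1] / ny
    surf = np.array([[x, y, z_surf] for x in gx for y in gy])
    n_surf = surf.shape[0]
    n_mol = _MOL_TEMPLATE.shape[0]
    n_cat, n_an = int(t["n_cations"]), int(t["n_anions"])

    roles = (
        ("molecule",) * n_mol + ("surface",) * n_surf
        + ("cation",) * n_cat + ("anion",) * n_an
    )
    elements = (
        _MOL_ELEMENTS + ("Si",) * n_surf
        + (("Na",) if t["ion_charge"] == 1.0 else ("Ca",)) * n_cat + ("Cl",) * n_an
    )
    base_charges = np.concatenate(
        [_MOL_CHARGES, np.zeros(n_surf), np.full(n_cat, t["ion_charge"]), np.full(n_an, -1.0)]
    )

    def place_far(n: int, mol_xyz: np.ndarray) -> np.ndarray:
        """Ion positions with min-image distance > ion_cutoff + 1 from the molecule."""
        out = np.empty((n, 3))
        placed = 0
        while placed < n:
            cand = rng.uniform(0.0, 1.0, 3) * box
            if _min_image_dist(mol_xyz, cand, box) > t["ion_cutoff"] + 1.0:
                out[placed] = cand
                placed += 1
        return out

    adsorbed = rng.random() < t["stationary_adsorbed_fraction"]  # start at stationarity
    frames: list[TrajectoryFrame] = []
    states: list[int] = []
    bound_counts: list[int] = []
    for i in range(int(t["n_frames"])):
        # Markov update of the adsorbed/free dichotomy
        if i > 0:
            p_flip = t["p_off"] if adsorbed else t["p_on"]
            if rng.random() < p_flip:
                adsorbed = not adsorbed
        if adsorbed:
            parallel = rng.random() < t["parallel_prob"]
            tilt = (
                rng.uniform(0.0, 0.8 * t["parallel_max_tilt"])
                if parallel
                else rng.uniform(t["parallel_max_tilt"] + 10.0, 90.0)
            )
            dz = rng.uniform(*t["adsorbed_distance"])
            state = 2 if parallel else 1
        else:
            tilt = rng.uniform(0.0, 90.0)
            dz = rng.uniform(*t["free_distance"])
            state = 0

        mol = _MOL_TEMPLATE @ _rotation(tilt, rng.uniform(0.0, 2 * math.pi)).T
        low = int(np.argmin(mol[:, 2]))
        if adsorbed:
            anchor = surf[rng.integers(n_surf)]  # lowest atom right above a surface atom
            target = anchor + np.array([0.0, 0.0, dz])
        else:
            target = np.array(
                [rng.uniform(0.0, box[0]), rng.uniform(0.0, box[1]), z_surf + dz]
            )
        mol = mol + (target - mol[low])

        mean = t["bound_mean_adsorbed"] if adsorbed else t["bound_mean_free"]
        k_bound = min(int(rng.poisson(mean)), n_cat)
        bound = np.empty((k_bound, 3))
        for j in range(k_bound):
            atom = mol[rng.integers(n_mol)]
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            bound[j] = atom + rng.uniform(2.0, 3.6) * direction
        free_ions = place_far(n_cat - k_bound, mol)
        anions = place_far(n_an, mol)

        coords = np.vstack([mol, surf, bound, free_ions, anions])
        if jitter_sigma:
            coords = coords + rng.normal(0.0, jitter_sigma, coords.shape)
        frames.append(
            TrajectoryFrame(
                time=i * t["dt_ns"],
                box=tuple(box),
                coordinates=coords,
                roles=roles,
                charges=base_charges.copy(),
                ring_atoms=_RING_ATOMS,
                elements=elements,
            )
        )
        states.append(state)
        bound_counts.append(k_bound)

    truth = dict(t)
    truth["states"] = states
    truth["bound_ions"] = bound_counts
    return frames, truth
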