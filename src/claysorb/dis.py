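"""Derivative Isotherm Summation (DIS) for low-pressure argon adsorption.

Quasi-equilibrium volumetric setups resolve argon adsorption at very low
relative pressure (P/P0 < 0.05), where monolayer filling is ordered by site
energy: the most energetic sites (on clays, the lateral/edge faces) fill at
the lowest pressures, basal faces at higher ones.  Plotting the isotherm as
dV_ads/d ln(P/P0) against u = ln(P/P0) puts it on a free-energy abscissa (in
kT units); surface heterogeneity then shows up as a superposition of peaks.

The DIS method models this experimental derivative as a sum of local-domain
derivative isotherms.  The local isotherm used here is a Langmuir isotherm
with Bragg-Williams (mean-field) lateral interactions, defined implicitly by

    u = u_half + ln(theta / (1 - theta)) - omega * (theta - 1/2),

where u_half locates half-coverage on the energy axis and omega (in kT) is
the lateral interaction strength.  For omega < 4 the map u(theta) is strictly
increasing (du/dtheta = 1/(theta(1-theta)) - omega > 0), so theta(u) is
single-valued and the local derivative is

    dv/du = v_m * dtheta/du = v_m / (1/(theta(1-theta)) - omega),

a unimodal peak of height v_m/(4 - omega) at u_half (v_m/4 for the pure
logistic omega = 0) whose integral over u is the monolayer capacity v_m.
Fitted domains are labelled edge or basal by their energy position, giving
the relative proportions of lateral and basal surfaces; monolayer capacities
convert to areas through the argon cross-section.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

__all__ = [
    "GasIsotherm",
    "DerivativeIsotherm",
    "LocalDomain",
    "DISDecomposition",
    "derivative_isotherm",
    "theta_local",
    "local_derivative",
    "fit_dis",
    "domain_area",
    "AVOGADRO",
    "MOLAR_VOLUME_STP",
    "ARGON_CROSS_SECTION_NM2",
    "DEFAULT_U_MAX",
]

AVOGADRO = 6.02214076e23  # molecules / mol
MOLAR_VOLUME_STP = 22414.0  # cm^3 STP / mol
ARGON_CROSS_SECTION_NM2 = 0.138  # conventional argon cross-section at 77 K
DEFAULT_U_MAX = math.log(0.05)  # monolayer regime boundary on the ln(P/P0) axis


@dataclass(frozen=True)
class GasIsotherm:
    """Quasi-equilibrium gas adsorption isotherm: V_ads(P/P0), STP cm^3/g."""

    p_over_p0: tuple[float, ...]
    v_ads: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.p_over_p0)
        if p.size != len(self.v_ads):
            raise ValueError("p_over_p0 and v_ads must have equal length")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("relative pressures must lie strictly in (0, 1)")
        if np.any(np.diff(p) <= 0):
            raise ValueError("relative pressures must be strictly increasing")

    @property
    def u(self) -> np.ndarray:
        return np.log(np.asarray(self.p_over_p0))

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self.v_ads, dtype=float)


@dataclass(frozen=True)
class DerivativeIsotherm:
    """dV_ads/d ln(P/P0) vs u = ln(P/P0); ``n_clamped`` counts negative
    derivative values clamped to zero after smoothing."""

    u: tuple[float, ...]
    dv_du: tuple[float, ...]
    n_clamped: int = 0

    def __post_init__(self) -> None:
        u = np.asarray(self.u)
        if np.any(np.diff(u) <= 0):
            raise ValueError("u must be strictly increasing")
        if np.any(u >= 0):
            raise ValueError("u = ln(P/P0) must be negative")

    @property
    def u_arr(self) -> np.ndarray:
        return np.asarray(self.u, dtype=float)

    @property
    def y_arr(self) -> np.ndarray:
        return np.asarray(self.dv_du, dtype=float)


@dataclass(frozen=True)
class LocalDomain:
    """One adsorption domain: monolayer capacity v_m (STP cm^3/g), energy
    position u_half = ln(P/P0) at half coverage, lateral interaction omega
    (kT), and an edge/basal/unassigned label."""

    v_m: float
    u_half: float
    omega: float = 0.0
    label: str = "unassigned"

    def __post_init__(self) -> None:
        if self.v_m < 0:
            raise ValueError("v_m must be >= 0")
        if self.u_half >= 0:
            raise ValueError("u_half must be < 0 (ln of a relative pressure)")
        if not 0 <= self.omega < 4:
            raise ValueError("omega must be in [0, 4) for a single-valued local isotherm")
        if self.label not in ("edge", "basal", "unassigned"):
            raise ValueError("label must be 'edge', 'basal' or 'unassigned'")


@dataclass(frozen=True)
class DISDecomposition:
    domains: tuple[LocalDomain, ...]
    residual_rms: float
    edge_fraction: float
    total_v_m: float
    split_u: float | None
    converged: bool
    areas: tuple[float, ...] | None = None  # m^2/g per domain, argon cross-section


def derivative_isotherm(gas: GasIsotherm, smoothing_window: int = 7) -> DerivativeIsotherm:
    """Numerical derivative dV/du by sliding local quadratic fits.

    The adsorbed volume is physically non-decreasing, so the series is first
    projected onto the monotone cone (isotonic regression); this suppresses
    negative-slope noise without the upward bias that pointwise truncation
    would introduce, and the derivative then integrates back to the net
    adsorbed volume.  At each point a local polynomial (cubic where the
    window allows, the Savitzky-Golay convention; quadratic/linear in
    shrunken end windows) is fitted over a centered window of
    `smoothing_window` points and its slope at the point is taken.  Residual
    negative values are clamped to zero and counted in ``n_clamped``.
    """
    from scipy.optimize import isotonic_regression

    u, v = gas.u, gas.v
    n = u.size
    if n < 10:
        raise ValueError("need >= 10 points for a derivative isotherm")
    if smoothing_window > n:
        raise ValueError("smoothing_window larger than the series")
    if smoothing_window < 3:
        raise ValueError("smoothing_window must be >= 3")
    v = isotonic_regression(v).x
    half = smoothing_window // 2
    dv = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if hi - lo < 3:  # pragma: no cover - guarded by n >= 10
            lo, hi = max(0, hi - 3), min(n, lo + 3)
        du = u[lo:hi] - u[i]
        # slope at du = 0 of a local polynomial (degree 3 when possible)
        coef = np.polynomial.polynomial.polyfit(du, v[lo:hi], deg=min(3, hi - lo - 1))
        dv[i] = coef[1]
    n_clamped = int(np.sum(dv < 0))
    return DerivativeIsotherm(tuple(u), tuple(np.clip(dv, 0.0, None)), n_clamped)


def theta_local(u: np.ndarray | float, u_half: float, omega: float) -> np.ndarray:
    """Coverage theta(u) of the Bragg-Williams local isotherm, by bisection.

    Solves u = u_half + ln(theta/(1-theta)) - omega*(theta - 1/2) for theta in
    (0, 1); unique for omega < 4 because u(theta) is strictly increasing.
    """
    if omega >= 4:
        raise ValueError("multivalued local isotherm: omega must be < 4")
    u = np.atleast_1d(np.asarray(u, dtype=float))
    lo = np.full_like(u, 1e-14)
    hi = np.full_like(u, 1.0 - 1e-14)
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        f = u_half + np.log(mid / (1.0 - mid)) - omega * (mid - 0.5) - u
        lo = np.where(f < 0, mid, lo)
        hi = np.where(f < 0, hi, mid)
    return 0.5 * (lo + hi)


def local_derivative(domain: LocalDomain, grid: np.ndarray | Sequence[float]) -> np.ndarray:
    """Local derivative isotherm dv/du = v_m / (1/(theta(1-theta)) - omega)."""
    grid = np.asarray(grid, dtype=float)
    th = theta_local(grid, domain.u_half, domain.omega)
    return domain.v_m / (1.0 / (th * (1.0 - th)) - domain.omega)


def _dis_model(params: np.ndarray, u: np.ndarray) -> np.ndarray:
    total = np.zeros_like(u)
    for v_m, u_half, omega in params.reshape(-1, 3):
        th = theta_local(u, u_half, omega)
        total += v_m / (1.0 / (th * (1.0 - th)) - omega)
    return total


def _peak_pick_init(u: np.ndarray, y: np.ndarray, n_domains: int) -> np.ndarray:
    """Initial (v_m, u_half, omega) per domain from peaks of the data.

    The derivative is pre-smoothed (moving average) before peak picking so
    that noise spikes riding on one physical peak are not mistaken for
    separate domains; peaks are ranked by prominence.
    """
    w = max(3, min(11, y.size // 20) | 1)
    smooth = np.convolve(y, np.ones(w) / w, mode="same")
    peaks, props = find_peaks(smooth, prominence=0.02 * max(smooth.max(), 1e-12))
    order = np.argsort(props["prominences"])[::-1] if peaks.size else np.array([], dtype=int)
    chosen = list(peaks[order][:n_domains])
    # pad with quantile-spaced positions when fewer peaks than domains
    while len(chosen) < n_domains:
        q = (len(chosen) + 1) / (n_domains + 1)
        chosen.append(int(np.clip(round(q * (u.size - 1)), 0, u.size - 1)))
    init = []
    for idx in sorted(chosen):
        height = max(smooth[idx], smooth.max() * 0.05, 1e-12)
        init.extend([3.0 * height, u[idx], 1.0])  # height ~ v_m/(4 - omega) at omega = 1
    return np.asarray(init)


def _auto_split(u: np.ndarray, y: np.ndarray, u_halfs: np.ndarray) -> float | None:
    """Deepest experimental minimum between the two most separated u_half clusters."""
    if u_halfs.size < 2:
        return None
    s = np.sort(u_halfs)
    gaps = np.diff(s)
    g = int(np.argmax(gaps))
    lo, hi = s[g], s[g + 1]
    mask = (u > lo) & (u < hi)
    if not np.any(mask):
        return 0.5 * (lo + hi)
    return float(u[mask][np.argmin(y[mask])])


def fit_dis(
    deriv: DerivativeIsotherm,
    n_domains: int,
    init: Sequence[LocalDomain] | None = None,
    *,
    split_u: float | None = None,
    u_max: float | None = DEFAULT_U_MAX,
    n_starts: int = 10,
    cross_section_nm2: float | None = None,
) -> DISDecomposition:
    """Fit the experimental derivative as a sum of `n_domains` local domains.

    Bounded trust-region least squares over (v_m, u_half, omega) per domain
    (v_m >= 0, u_half within the data range, omega in [0, 4)), multi-started
    deterministically from peak-picked initial guesses.  Fitting is restricted
    to the monolayer regime u <= `u_max` (default ln 0.05); pass ``u_max=None``
    to use the whole series.  Domains with u_half below the split threshold are
    labelled edge, the rest basal; the threshold defaults to the deepest
    experimental minimum between the two most separated fitted u_half values
    and can be overridden with `split_u`.  With `cross_section_nm2` set,
    per-domain areas are attached via :func:`domain_area`.

    Non-convergence of the optimizer returns the best-so-far decomposition
    with ``converged=False``.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    u, y = deriv.u_arr, deriv.y_arr
    if u_max is not None:
        mask = u <= u_max
        u, y = u[mask], y[mask]
    n_params = 3 * n_domains
    if u.size <= n_params:
        raise ValueError(
            f"over-parameterized: {n_params} parameters for {u.size} derivative points"
        )
    if u.size < 5 * n_params:
        warnings.warn(
            f"only {u.size} points for {n_domains} domains; recommend >= {5 * n_params}",
            UserWarning,
            stacklevel=2,
        )

    if init is not None:
        base = np.concatenate([[d.v_m, d.u_half, d.omega] for d in init])
        if base.size != n_params:
            raise ValueError("init must provide exactly n_domains domain guesses")
    else:
        base = _peak_pick_init(u, y, n_domains)

    span = u.max() - u.min()
    lower = np.tile([0.0, u.min() - 0.1 * span, 0.0], n_domains)
    upper = np.tile([np.inf, min(u.max() + 0.1 * span, -1e-9), 3.999], n_domains)

    def residuals(p):
        return _dis_model(p, u) - y

    rng = np.random.default_rng(0)
    best, converged, stall = None, False, 0
    for start in range(n_starts):
        p0 = base.copy()
        if start > 0:
            p0 = p0.reshape(-1, 3)
            p0[:, 0] *= np.exp(rng.normal(0.0, 0.4, n_domains))
            p0[:, 1] += rng.uniform(-0.15 * span, 0.15 * span, n_domains)
            p0[:, 2] = rng.uniform(0.0, 3.0, n_domains)
            p0 = p0.ravel()
        p0 = np.clip(p0, lower + 1e-12, np.where(np.isfinite(upper), upper - 1e-12, p0))
        try:
            sol = least_squares(residuals, p0, bounds=(lower, upper), method="trf", max_nfev=600)
        except Exception:
            continue
        if best is None or sol.cost < best.cost * (1.0 - 1e-2):
            best, stall = sol, 0
            converged = bool(sol.status > 0)
        else:
            stall += 1
            if stall >= 3:  # repeated restarts no longer improve the optimum
                break
    if best is None:
        raise RuntimeError("DIS fit failed from every start")

    fitted = best.x.reshape(-1, 3)
    fitted = fitted[np.argsort(fitted[:, 1])]  # order by energy position
    threshold = split_u if split_u is not None else _auto_split(u, y, fitted[:, 1])
    domains = []
    for v_m, u_half, omega in fitted:
        label = "unassigned" if threshold is None else ("edge" if u_half < threshold else "basal")
        domains.append(LocalDomain(float(v_m), float(min(u_half, -1e-12)), float(omega), label))

    total_v_m = float(sum(d.v_m for d in domains))
    edge_v_m = float(sum(d.v_m for d in domains if d.label == "edge"))
    edge_fraction = edge_v_m / total_v_m if total_v_m > 0 else 0.0
    residual_rms = math.sqrt(2 * best.cost / u.size)
    areas = (
        tuple(domain_area(d, cross_section_nm2) for d in domains)
        if cross_section_nm2 is not None
        else None
    )
    return DISDecomposition(
        tuple(domains), residual_rms, edge_fraction, total_v_m, threshold, converged, areas
    )


def domain_area(domain: LocalDomain, cross_section_nm2: float = ARGON_CROSS_SECTION_NM2) -> float:
    """Surface area (m^2/g) of a domain from its monolayer capacity.

    area = (v_m / 22414 cm^3 mol^-1) * N_A * sigma, with sigma the adsorbate
    cross-section (default 0.138 nm^2 for argon at 77 K).
    """
    if cross_section_nm2 <= 0:
        raise ValueError("cross_section must be > 0")
    moles = domain.v_m / MOLAR_VOLUME_STP
    return moles * AVOGADRO * cross_section_nm2 * 1e-18
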