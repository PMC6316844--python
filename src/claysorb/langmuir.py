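"""Classic and modified (solid/liquid) Langmuir models for adsorption isotherms.

The classic Langmuir model, q = q_max * K * C / (1 + K * C), was derived for
gas/solid adsorption; its affinity constant K carries units of L/mol, which
makes thermodynamic quantities derived from it convention-dependent.  For
solid/liquid systems a modified form rescales the concentration by the
solute's saturation concentration C_s (its solubility), giving

    q = q_max * K_ML * C / (C_s - C + K_ML * C),      0 <= C < C_s,

with a *dimensionless* equilibrium constant K_ML, so that the standard free
energy of adsorption is unambiguous: dG0 = -R T ln(K_ML).  In the dilute
limit C << C_s the modified model reduces to the classic one with effective
K = K_ML / C_s, and K_ML = 1 degenerates to the linear partition q =
q_max * C / C_s.

Fitted parameters are reported as descriptive quantities: a Langmuir-shaped
solution/solid isotherm does not by itself establish monolayer coverage on a
homogeneous surface, so q_max and K summarize the curve rather than prove a
mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.optimize import least_squares

from .isotherm import Isotherm
from .normalization import NormalizedIsotherm, as_normalized

__all__ = [
    "R_GAS",
    "LangmuirFitResult",
    "classic_langmuir",
    "modified_langmuir",
    "langmuir_eval",
    "delta_g_from_kml",
    "kml_from_delta_g",
    "fit_langmuir",
]

R_GAS = 8.314  # J mol^-1 K^-1

# deterministic multiplicative perturbations of the initial affinity guess
_MULTISTART_FACTORS = (1.0, 0.2, 5.0, 0.04, 25.0)


@dataclass(frozen=True)
class LangmuirFitResult:
    """Result of a weighted nonlinear Langmuir fit.

    ``q_max`` is in the units of the fitted uptake axis (mol/g or mol/m^2).
    ``k`` (L/mol) is set for the classic model, ``k_ml`` (dimensionless),
    ``c_s`` (mol/L) and ``delta_g`` (kJ/mol at `temperature` K) for the
    modified one.  ``parameter_sd`` holds curvature-based standard deviations
    keyed by parameter name; ``residual_rms`` is in fit units.
    """

    model: str
    q_max: float
    k: float | None
    k_ml: float | None
    c_s: float | None
    delta_g: float | None
    residual_rms: float
    parameter_sd: dict[str, float]
    n_points: int
    temperature: float


def classic_langmuir(c: np.ndarray | float, q_max: float, k: float):
    """q = q_max * K * C / (1 + K * C)."""
    c = np.asarray(c, dtype=float)
    out = q_max * k * c / (1.0 + k * c)
    return out if out.ndim else float(out)


def modified_langmuir(c: np.ndarray | float, q_max: float, k_ml: float, c_s: float):
    """q = q_max * K_ML * C / (C_s - C + K_ML * C); requires C < C_s."""
    c = np.asarray(c, dtype=float)
    if np.any(c >= c_s):
        raise ValueError("equilibrium concentration beyond solubility (C >= C_s)")
    out = q_max * k_ml * c / (c_s - c + k_ml * c)
    return out if out.ndim else float(out)


def langmuir_eval(model: str, c, *, q_max: float, k: float | None = None,
                  k_ml: float | None = None, c_s: float | None = None):
    """Evaluate either Langmuir variant from keyword parameters."""
    if model == "classic":
        if k is None:
            raise ValueError("classic model needs k")
        return classic_langmuir(c, q_max, k)
    if model == "modified":
        if k_ml is None or c_s is None:
            raise ValueError("modified model needs k_ml and c_s")
        return modified_langmuir(c, q_max, k_ml, c_s)
    raise ValueError(f"unknown model {model!r}")


def delta_g_from_kml(k_ml: float, temperature: float = 298.15) -> float:
    """Standard free energy of adsorption, dG0 = -R T ln(K_ML), in kJ/mol."""
    if k_ml <= 0:
        raise ValueError("k_ml must be > 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return -R_GAS * temperature * math.log(k_ml) / 1000.0


def kml_from_delta_g(delta_g: float, temperature: float = 298.15) -> float:
    """Inverse of :func:`delta_g_from_kml`."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return math.exp(-delta_g * 1000.0 / (R_GAS * temperature))


def _extract_xy(iso: Union[Isotherm, NormalizedIsotherm]):
    n = as_normalized(iso)
    return n.x, n.d, n.sd_d


def _linearized_guess(c, q, model, c_s):
    """Initial guess from the reciprocal (double-inverse) linearization.

    classic:  1/q = 1/q_max + (1/(q_max K)) * (1/C)
    modified: 1/q = 1/q_max + (1/(q_max K_ML)) * ((C_s - C)/C)
    """
    mask = (c > 0) & (q > 0)
    cc, qq = c[mask], q[mask]
    t = 1.0 / cc if model == "classic" else (c_s - cc) / cc
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, 1.0 / qq, rcond=None)
    intercept, slope = coef
    if intercept <= 0 or slope <= 0:
        # degenerate linearization (noise-dominated); fall back on scales
        q_max0 = float(qq.max()) * 1.2
        aff0 = 1.0 / float(np.median(cc)) if model == "classic" else 10.0
        return q_max0, aff0
    return 1.0 / intercept, intercept / slope


def fit_langmuir(
    iso: Union[Isotherm, NormalizedIsotherm],
    model: str = "classic",
    c_s: float | None = None,
    temperature: float = 298.15,
) -> LangmuirFitResult:
    """Weighted nonlinear least-squares Langmuir fit.

    Weights are 1/sd when replicate sds are available (all positive),
    otherwise uniform.  Positivity of (q_max, K) is enforced by optimizing
    their logarithms; the optimizer is started from the linearized reciprocal
    guess and from four deterministic multiplicative perturbations of the
    affinity to guard against local minima.  Parameter standard deviations
    come from the Jacobian at the optimum (local curvature, delta method back
    to natural parameters).

    Parameters
    ----------
    model : {"classic", "modified"}
    c_s : float, optional
        Saturation concentration (solubility, mol/L) for the modified model.
        Fixed, never fitted.  Defaults to the isotherm's nucleotide solubility
        when fitting an :class:`Isotherm`.
    temperature : float
        Temperature in K used for dG0 (modified model only).
    """
    if model not in ("classic", "modified"):
        raise ValueError(f"unknown model {model!r}")
    c, q, sd = _extract_xy(iso)
    keep = q >= 0
    c, q, sd = c[keep], q[keep], sd[keep]
    if np.unique(c).size < 4:
        raise ValueError("need >= 4 points with distinct c_eq to fit a Langmuir model")
    if model == "modified":
        if c_s is None and isinstance(iso, Isotherm):
            c_s = iso.nucleotide.solubility
        if c_s is None or c_s <= 0:
            raise ValueError("modified model needs a positive c_s (solubility)")
        if np.any(c >= c_s):
            raise ValueError("equilibrium concentration beyond solubility (C >= C_s)")

    w = 1.0 / sd if np.all(sd > 0) else np.ones_like(q)

    def residuals(logp):
        q_max, aff = np.exp(logp)
        if model == "classic":
            pred = classic_langmuir(c, q_max, aff)
        else:
            pred = modified_langmuir(c, q_max, aff, c_s)
        return (pred - q) * w

    q_max0, aff0 = _linearized_guess(c, q, model, c_s)
    best = None
    for factor in _MULTISTART_FACTORS:
        x0 = np.log([q_max0, aff0 * factor])
        try:
            sol = least_squares(residuals, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("Langmuir fit failed to converge from all starts")

    q_max, aff = np.exp(best.x)
    n = len(q)
    rss = float(2 * best.cost)
    residual_rms = math.sqrt(rss / n)

    # curvature-based parameter sds: cov(logp) = (J^T J)^-1 * s^2
    dof = max(n - 2, 1)
    s2 = rss / dof
    J = best.jac
    try:
        cov_log = np.linalg.inv(J.T @ J) * s2
        sd_log = np.sqrt(np.clip(np.diag(cov_log), 0, None))
    except np.linalg.LinAlgError:
        sd_log = np.array([np.nan, np.nan])
    aff_name = "k" if model == "classic" else "k_ml"
    parameter_sd = {"q_max": q_max * sd_log[0], aff_name: aff * sd_log[1]}

    if model == "classic":
        return LangmuirFitResult(
            model, float(q_max), float(aff), None, None, None,
            residual_rms, parameter_sd, n, temperature,
        )
    return LangmuirFitResult(
        model, float(q_max), None, float(aff), float(c_s),
        delta_g_from_kml(float(aff), temperature),
        residual_rms, parameter_sd, n, temperature,
    )
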