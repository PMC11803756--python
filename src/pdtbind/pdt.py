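"""Propagation of a p0 model along the alchemical path.

The potential distribution theorem determines every intermediate state from
the initial-state density:

    p_lam(u) = exp(-beta W_lam(u_sc(u))) p0(u) / K(lam),
    K(lam)   = int exp(-beta W_lam(u_sc(u))) p0(u) du,
    dG(lam)  = -kB T ln K(lam).

All quadratures are carried out in the soft-core variable u_sc, whose domain
is bounded above by u_max, using the change of measure

    p0(u_sc) = p0(u) / u_sc'(u)   at u = u_sc^{-1}(u_sc).

The raw-u upper tail of the collisional component is heavy (no finite mean),
but its image under the soft-core transform carries negligible mass near
u_max, so a composite trapezoid grid in u_sc converges quickly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .analytic import CouplingModel, p0_density
from .softcore import (
    ScheduleSpec,
    SchedulePoint,
    SoftCoreSpec,
    softcore,
    softcore_derivative,
    softcore_inverse,
    w_lambda,
)
from .thermo import ThermoSpec, DEFAULT_THERMO

__all__ = [
    "QuadratureSpec",
    "FreeEnergyProfile",
    "CoupledStateMean",
    "default_quadrature",
    "p0_softcore_density",
    "k_lambda",
    "p_lambda_density",
    "p_lambda_softcore_density",
    "free_energy_profile",
    "coupled_state_mean",
]


@dataclass(frozen=True)
class QuadratureSpec:
    """Composite-trapezoid grid in the u_sc variable."""

    lower: float
    upper: float
    n_nodes: int = 4001
    method: Literal["grid-trapezoid"] = "grid-trapezoid"

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError("upper must exceed lower")
        if self.n_nodes < 101:
            raise ValueError("n_nodes must be >= 101")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_nodes)


def default_quadrature(
    model: CouplingModel, sc: SoftCoreSpec, n_nodes: int = 4001
) -> QuadratureSpec:
    """Grid from 12 sigma below the lowest mode mean up to just under u_max."""
    lower = min(model.support_lower(12.0), sc.u_cut - 1.0)
    upper = sc.u_max - 1e-6 * (sc.u_max - sc.u_cut)
    return QuadratureSpec(lower=lower, upper=upper, n_nodes=n_nodes)


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Excess free energy profile dG(lam) = -kB T ln K(lam) in kcal/mol."""

    lam_grid: np.ndarray
    delta_g: np.ndarray
    excess_dg: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lambda": self.lam_grid,
                "K_lambda": np.exp(-self.delta_g / self._kt),
                "delta_g_kcal_mol": self.delta_g,
            }
        )

    _kt: float = 0.0  # set at construction for K reconstruction


# ---------------------------------------------------------------------------


def p0_softcore_density(
    u_sc, model: CouplingModel, sc: SoftCoreSpec, nodes: int = 19
) -> np.ndarray | float:
    """Density of the soft-core perturbation energy, p0(u)/u_sc'(u)."""
    arr = np.asarray(u_sc, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    u = softcore_inverse(arr, sc)
    with np.errstate(over="ignore"):
        dens = p0_density(u, model, nodes=nodes)
        deriv = softcore_derivative(u, sc)
    out = np.where(dens > 0.0, dens / np.where(deriv > 0.0, deriv, 1.0), 0.0)
    return float(out[0]) if scalar else out


def _log_integrand(
    grid: np.ndarray,
    model: CouplingModel,
    pt: SchedulePoint,
    sc: SoftCoreSpec,
    th: ThermoSpec,
    nodes: int,
) -> np.ndarray:
    dens = np.asarray(p0_softcore_density(grid, model, sc, nodes=nodes))
    w = np.asarray(w_lambda(grid, pt))
    with np.errstate(divide="ignore"):
        return np.where(dens > 0.0, np.log(np.maximum(dens, 1e-300)), -np.inf) - th.beta * w


def _trapz_exp(log_f: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoid integral of exp(log_f) with a max-shift for underflow safety."""
    m = np.max(log_f)
    if not np.isfinite(m):
        return 0.0
    return float(np.exp(m) * np.trapezoid(np.exp(log_f - m), grid))


def k_lambda(
    model: CouplingModel,
    pt: SchedulePoint,
    sc: SoftCoreSpec,
    th: ThermoSpec = DEFAULT_THERMO,
    q: QuadratureSpec | None = None,
    nodes: int = 19,
    check: bool = False,
    check_rtol: float = 1e-5,
) -> float:
    """Excess binding constant K(lam) = <exp(-beta W_lam)>_0, by u_sc quadrature."""
    if q is None:
        q = default_quadrature(model, sc)
    grid = q.grid
    val = _trapz_exp(_log_integrand(grid, model, pt, sc, th, nodes), grid)
    if check:
        fine = QuadratureSpec(q.lower, q.upper, 2 * q.n_nodes - 1)
        val2 = _trapz_exp(_log_integrand(fine.grid, model, pt, sc, th, nodes), fine.grid)
        if abs(val2 - val) > check_rtol * abs(val2):
            raise RuntimeError(
                f"K(lambda) quadrature did not converge: {val} vs {val2} "
                f"on {q.n_nodes} vs {fine.n_nodes} nodes (lam={pt.lam})"
            )
        val = val2
    if not val > 0.0:
        raise RuntimeError(f"K(lambda) evaluated to {val}; widen the quadrature grid")
    return val


def p_lambda_density(
    u,
    model: CouplingModel,
    pt: SchedulePoint,
    sc: SoftCoreSpec,
    th: ThermoSpec = DEFAULT_THERMO,
    q: QuadratureSpec | None = None,
    nodes: int = 19,
) -> np.ndarray | float:
    """Intermediate-state density p_lam(u) in the raw perturbation-energy variable."""
    arr = np.asarray(u, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    k = k_lambda(model, pt, sc, th, q=q, nodes=nodes)
    usc = softcore(arr, sc)
    out = np.exp(-th.beta * np.asarray(w_lambda(usc, pt))) * np.asarray(
        p0_density(arr, model, nodes=nodes)
    ) / k
    return float(out[0]) if scalar else out


def p_lambda_softcore_density(
    u_sc,
    model: CouplingModel,
    pt: SchedulePoint,
    sc: SoftCoreSpec,
    th: ThermoSpec = DEFAULT_THERMO,
    q: QuadratureSpec | None = None,
    nodes: int = 19,
) -> np.ndarray | float:
    """Intermediate-state density of the soft-core perturbation energy."""
    arr = np.asarray(u_sc, dtype=float)
    if np.any(arr >= sc.u_max):
        raise ValueError("u_sc must be below u_max")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    k = k_lambda(model, pt, sc, th, q=q, nodes=nodes)
    out = np.exp(-th.beta * np.asarray(w_lambda(arr, pt))) * np.asarray(
        p0_softcore_density(arr, model, sc, nodes=nodes)
    ) / k
    return float(out[0]) if scalar else out


def free_energy_profile(
    model: CouplingModel,
    schedule: ScheduleSpec,
    th: ThermoSpec = DEFAULT_THERMO,
    q: QuadratureSpec | None = None,
    nodes: int = 19,
) -> FreeEnergyProfile:
    """dG(lam) over the schedule grid; the last entry is the excess free energy."""
    sc = schedule.softcore
    if q is None:
        q = default_quadrature(model, sc)
    dg = np.array(
        [
            -th.kt * np.log(k_lambda(model, p, sc, th, q=q, nodes=nodes))
            for p in schedule.points
        ]
    )
    prof = FreeEnergyProfile(
        lam_grid=schedule.lam_values, delta_g=dg, excess_dg=float(dg[-1]), _kt=th.kt
    )
    return prof


@dataclass(frozen=True)
class CoupledStateMean:
    """Mean perturbation energy in the fully coupled (lam = 1) state."""

    per_mode: np.ndarray  # kcal/mol, one entry per mode
    overall: float        # kcal/mol, decoupled-weight average of per_mode
    mean_u_sc: float | None = None  # quadrature only: <u_sc> under p_1


def coupled_state_mean(
    model: CouplingModel,
    sc: SoftCoreSpec,
    th: ThermoSpec = DEFAULT_THERMO,
    method: Literal["linear-response", "quadrature"] = "linear-response",
    q: QuadratureSpec | None = None,
    nodes: int = 19,
) -> CoupledStateMean:
    """Average interaction energy in the coupled state.

    The linear-response closed form u1 = u0 - beta sigma^2 per mode neglects
    the collisional component, which is suppressed by exp(-beta u) in the
    coupled ensemble.  The quadrature method integrates u p_1(u) du over the
    (bounded) u_sc grid and also reports <u_sc>; because the raw collisional
    tail has no finite mean, the quadrature value is the grid-truncated
    integral and is meaningful only when the coupled state is clash-free.
    """
    if method == "linear-response":
        per_mode = np.array(
            [m.gaussian.mean_u0 - th.beta * m.gaussian.sigma**2 for m in model.modes]
        )
        overall = float(np.dot(model.weights, per_mode))
        return CoupledStateMean(per_mode=per_mode, overall=overall)
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    if q is None:
        q = default_quadrature(model, sc)
    pt = SchedulePoint(1.0, 1.0, 1.0)
    grid = q.grid
    log_f = _log_integrand(grid, model, pt, sc, th, nodes)
    k = _trapz_exp(log_f, grid)
    if not k > 0.0:
        raise RuntimeError("coupled-state quadrature diverged (K <= 0)")
    m = np.max(log_f)
    p1 = np.exp(log_f - m)
    u = softcore_inverse(grid, sc)
    mean_u = float(np.exp(m) * np.trapezoid(u * p1, grid) / k)
    mean_usc = float(np.exp(m) * np.trapezoid(grid * p1, grid) / k)
    per_mode = np.array(
        [m_.gaussian.mean_u0 - th.beta * m_.gaussian.sigma**2 for m_ in model.modes]
    )
    return CoupledStateMean(per_mode=per_mode, overall=mean_u, mean_u_sc=mean_usc)
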