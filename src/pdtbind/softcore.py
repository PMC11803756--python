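"""Soft-core perturbation energy and the softplus alchemical potential.

The soft-core transform caps large positive perturbation energies smoothly:

    u_sc(u) = u                                          for u <= u_cut
            = (u_max - u_cut) f_sc((u - u_cut)/(u_max - u_cut)) + u_cut
                                                         for u >  u_cut
    f_sc(y) = (z^a - 1)/(z^a + 1),   z(y) = 1 + 2 y/a + 2 (y/a)^2.

It is a strictly increasing C^1 bijection of the real line onto
(-inf, u_max), equal to the identity below u_cut.

The softplus alchemical perturbation function at schedule point
(lam1, lam2, alpha, u0) is

    W(u_sc) = ((lam2 - lam1)/alpha) ln(1 + exp(-alpha (u_sc - u0)))
              + lam2 u_sc,

which reduces to the linear form lam*u_sc when lam1 = lam2 = lam, and
satisfies W = 0 at lam1 = lam2 = 0 and W = u_sc at lam1 = lam2 = 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SoftCoreSpec",
    "SchedulePoint",
    "ScheduleSpec",
    "softcore",
    "softcore_inverse",
    "softcore_derivative",
    "w_lambda",
    "linear_schedule",
    "read_schedule",
    "write_schedule",
    "DEFAULT_COUPLING_SOFTCORE",
    "DEFAULT_TRANSFER_SOFTCORE",
]


@dataclass(frozen=True)
class SoftCoreSpec:
    """Soft-core capping parameters (u_cut, u_max in kcal/mol, a dimensionless)."""

    u_cut: float = 0.0
    u_max: float = 50.0
    a_exponent: float = 0.0625

    def __post_init__(self) -> None:
        if not self.u_max > self.u_cut:
            raise ValueError("u_max must exceed u_cut")
        if not self.a_exponent > 0:
            raise ValueError("a_exponent must be positive")


# parameters used for coupling/decoupling and for host-guest transfer runs
DEFAULT_COUPLING_SOFTCORE = SoftCoreSpec(u_cut=0.0, u_max=50.0, a_exponent=0.0625)
DEFAULT_TRANSFER_SOFTCORE = SoftCoreSpec(u_cut=100.0, u_max=200.0, a_exponent=0.0625)


@dataclass(frozen=True)
class SchedulePoint:
    """One alchemical state: progress lam and softplus parameters."""

    lam: float
    lam1: float
    lam2: float
    alpha: float = 1.0  # 1/(kcal/mol)
    u0_shift: float = 0.0  # kcal/mol

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class ScheduleSpec:
    """Ordered lambda schedule plus the governing soft-core settings."""

    points: tuple[SchedulePoint, ...]
    softcore: SoftCoreSpec

    def __init__(self, points: Iterable[SchedulePoint], softcore: SoftCoreSpec) -> None:
        points = tuple(points)
        if len(points) < 1:
            raise ValueError("schedule requires at least one point")
        lams = [p.lam for p in points]
        if any(b <= a for a, b in zip(lams, lams[1:])):
            raise ValueError("lam must be strictly increasing across schedule points")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "softcore", softcore)
        self.validate_endpoints()

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lam_values(self) -> np.ndarray:
        return np.array([p.lam for p in self.points])

    def validate_endpoints(self, rtol: float = 1e-9) -> None:
        """Endpoint contract: W == 0 at lam=0 and W == u_sc at lam=1, if present."""
        grid = np.linspace(self.softcore.u_cut - 60.0, self.softcore.u_max - 1e-6, 33)
        for p in self.points:
            if p.lam == 0.0:
                w = w_lambda(grid, p)
                if np.max(np.abs(w)) > 1e-9:
                    raise ValueError("schedule point at lam=0 must give W = 0 for all u_sc")
            if p.lam == 1.0:
                w = w_lambda(grid, p)
                if np.max(np.abs(w - grid)) > 1e-9 + rtol * np.max(np.abs(grid)):
                    raise ValueError("schedule point at lam=1 must give W = u_sc")


# ---------------------------------------------------------------------------
# soft-core transform


def _fsc(y: np.ndarray, a: float) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore"):
        z = 1.0 + 2.0 * y / a + 2.0 * (y / a) ** 2
        za = np.power(z, a)
        out = (za - 1.0) / (za + 1.0)
    return np.where(np.isfinite(za), out, 1.0)


def softcore(u, sc: SoftCoreSpec) -> np.ndarray | float:
    """Soft-core perturbation energy u_sc(u); identity for u <= u_cut."""
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("u must be finite")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = arr.copy()
    span = sc.u_max - sc.u_cut
    hi = arr > sc.u_cut
    if np.any(hi):
        y = (arr[hi] - sc.u_cut) / span
        out[hi] = span * _fsc(y, sc.a_exponent) + sc.u_cut
    return float(out[0]) if scalar else out


def softcore_inverse(u_sc, sc: SoftCoreSpec) -> np.ndarray | float:
    """Inverse of the soft-core transform, in closed form.

    Raises for u_sc >= u_max (outside the range of the transform).
    """
    arr = np.asarray(u_sc, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("u_sc must be finite")
    if np.any(arr >= sc.u_max):
        raise ValueError("u_sc must be below u_max")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = arr.copy()
    span = sc.u_max - sc.u_cut
    a = sc.a_exponent
    hi = arr > sc.u_cut
    if np.any(hi):
        f = (arr[hi] - sc.u_cut) / span
        z = np.power((1.0 + f) / (1.0 - f), 1.0 / a)
        y = 0.5 * a * (np.sqrt(2.0 * z - 1.0) - 1.0)
        out[hi] = sc.u_cut + span * y
    return float(out[0]) if scalar else out


def softcore_derivative(u, sc: SoftCoreSpec) -> np.ndarray | float:
    """du_sc/du: equals 1 below u_cut, positive, decays to 0 at large u."""
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("u must be finite")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.ones_like(arr)
    span = sc.u_max - sc.u_cut
    a = sc.a_exponent
    hi = arr > sc.u_cut
    if np.any(hi):
        y = (arr[hi] - sc.u_cut) / span
        with np.errstate(over="ignore", invalid="ignore"):
            z = 1.0 + 2.0 * y / a + 2.0 * (y / a) ** 2
            za = np.power(z, a)
            zp = 2.0 / a + 4.0 * y / (a * a)
            # d f_sc/dy = 2 a z^(a-1) z' / (z^a + 1)^2 ; chain rule cancels the span
            d = 2.0 * a * np.power(z, a - 1.0) * zp / (za + 1.0) ** 2
        out[hi] = np.where(np.isfinite(z), d, 0.0)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# softplus alchemical potential


def _softplus(x: np.ndarray) -> np.ndarray:
    # ln(1 + e^x) evaluated without overflow
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def w_lambda(u_sc, pt: SchedulePoint) -> np.ndarray | float:
    """Softplus alchemical perturbation energy W(u_sc) at one schedule point."""
    arr = np.asarray(u_sc, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = pt.lam2 * arr
    if pt.lam2 != pt.lam1:
        out = out + ((pt.lam2 - pt.lam1) / pt.alpha) * _softplus(
            -pt.alpha * (arr - pt.u0_shift)
        )
    return float(out[0]) if scalar else out


def linear_schedule(
    n_states: int,
    sc: SoftCoreSpec,
    lam_end: float = 1.0,
    alpha: float = 1.0,
    u0_shift: float = 0.0,
) -> ScheduleSpec:
    """Evenly spaced linear schedule with lam1 = lam2 = lam on [0, lam_end].

    lam_end = 0.5 gives one leg of an alchemical-transfer calculation.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    lams = np.linspace(0.0, lam_end, n_states)
    pts = [SchedulePoint(l, l, l, alpha, u0_shift) for l in lams]
    return ScheduleSpec(pts, sc)


# ---------------------------------------------------------------------------
# schedule files: TSV with columns lambda, lambda1, lambda2, alpha, u0

_SCHEDULE_COLS = ["lambda", "lambda1", "lambda2", "alpha", "u0"]


def read_schedule(path, sc: SoftCoreSpec) -> ScheduleSpec:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _SCHEDULE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"schedule file missing columns: {missing}")
    pts = [
        SchedulePoint(r["lambda"], r["lambda1"], r["lambda2"], r["alpha"], r["u0"])
        for _, r in df.iterrows()
    ]
    return ScheduleSpec(pts, sc)


def write_schedule(path, schedule: ScheduleSpec) -> None:
    df = pd.DataFrame(
        [
            {
                "lambda": p.lam,
                "lambda1": p.lam1,
                "lambda2": p.lam2,
                "alpha": p.alpha,
                "u0": p.u0_shift,
            }
            for p in schedule.points
        ],
        columns=_SCHEDULE_COLS,
    )
    df.to_csv(path, sep="\t", index=False)
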