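"""Analytical perturbation-energy density families.

The probability density of the perturbation energy u of a coupling process
in the decoupled ensemble is modelled as

    p0(u) = sum_i w_i [ b_i N_i(u) + (1 - b_i) (N_i * F_i)(u) ]

where N is a normal ("background") density capturing long-ranged, many-body
interactions through linear response / central-limit arguments, F is the
max-statistics density of the collisional (short-range repulsive) energy,
``*`` denotes convolution, and b is the probability that a configuration of
the decoupled ensemble is free of atomic clashes.  Multiple modes describe
distinct conformational populations.

The collisional density derives from Lennard-Jones max statistics.  With

    x(u)  = sqrt(1 + (u + u_tilde)/epsilon),   xc = sqrt(1 + u_tilde/epsilon)

the cumulative distribution of the largest collisional energy among n_l
statistically independent atomic groups is

    G(u) = [1 - sqrt((1 + xc)/(1 + x))]**n_l,   u >= 0,

and the density F(u) = dG/du is

    F(u) = n_l [1 - sqrt((1+xc)/(1+x))]**(n_l-1)
           * sqrt(1+xc) / (4 epsilon x (1+x)**(3/2)),   u >= 0.

G and F are exact antiderivative/derivative partners, G(0) = 0 and
G(u) -> 1 as u -> infinity, so F is normalized on [0, inf) by construction.
Note the tail is heavy: 1 - G(u) ~ n_l sqrt((1+xc)) u**(-1/4), so the raw
collisional energy has no finite mean; all downstream quadrature is done in
the (bounded) soft-core variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GaussianParams",
    "CollisionParams",
    "ModelMode",
    "CouplingModel",
    "gaussian_density",
    "collision_density",
    "collision_cdf",
    "collision_quantile",
    "convolved_collision_density",
    "p0_density",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)

# weight-sum tolerance for a valid mixture
WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class GaussianParams:
    """Background (linear-response) component: N(u; mean_u0, sigma)."""

    mean_u0: float  # kcal/mol
    sigma: float    # kcal/mol, > 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_u0):
            raise ValueError("mean_u0 must be finite")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class CollisionParams:
    """Collisional (max-statistics) component parameters.

    b_no_collision is the probability that no clash occurs in the decoupled
    ensemble; epsilon is the effective Lennard-Jones energy prefactor;
    u_tilde is the onset energy above which max statistics applies; n_l is
    the effective number of independently colliding atomic groups (may be
    fractional).
    """

    b_no_collision: float  # in [0, 1]
    epsilon: float         # kcal/mol, > 0
    u_tilde: float         # kcal/mol, >= 0
    n_l: float             # >= 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.b_no_collision <= 1.0):
            raise ValueError(f"b_no_collision must be in [0, 1], got {self.b_no_collision}")
        if not (np.isfinite(self.epsilon) and self.epsilon > 0):
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not (np.isfinite(self.u_tilde) and self.u_tilde >= 0):
            raise ValueError(f"u_tilde must be non-negative, got {self.u_tilde}")
        if not (np.isfinite(self.n_l) and self.n_l >= 1):
            raise ValueError(f"n_l must be >= 1, got {self.n_l}")

    @property
    def xc(self) -> float:
        return float(np.sqrt(1.0 + self.u_tilde / self.epsilon))


@dataclass(frozen=True)
class ModelMode:
    """One mixture mode: weight, background and collisional parameters."""

    weight: float
    gaussian: GaussianParams
    collision: CollisionParams

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"mode weight must be in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class CouplingModel:
    """Multimodal analytical density model of a coupling (or transfer) process."""

    modes: tuple[ModelMode, ...]
    label: str = ""

    def __init__(self, modes: Iterable[ModelMode], label: str = "") -> None:
        modes = tuple(modes)
        if len(modes) == 0:
            raise ValueError("CouplingModel requires at least one mode")
        total = sum(m.weight for m in modes)
        if abs(total - 1.0) > WEIGHT_TOL:
            raise ValueError(f"mode weights must sum to 1, got {total!r}")
        object.__setattr__(self, "modes", modes)
        object.__setattr__(self, "label", label)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def weights(self) -> np.ndarray:
        return np.array([m.weight for m in self.modes])

    def gaussian_mean(self) -> float:
        """Mixture mean of the background (no-collision) components only."""
        return float(sum(m.weight * m.gaussian.mean_u0 for m in self.modes))

    def support_lower(self, n_sigma: float = 12.0) -> float:
        """A practical lower bound of the density support for quadrature grids."""
        return min(m.gaussian.mean_u0 - n_sigma * m.gaussian.sigma for m in self.modes)


# ---------------------------------------------------------------------------
# densities


def _as_finite_array(u, name: str = "u") -> np.ndarray:
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def gaussian_density(u, g: GaussianParams) -> np.ndarray | float:
    """Normal density N(u; mean_u0, sigma) in 1/(kcal/mol)."""
    arr = _as_finite_array(u)
    z = (arr - g.mean_u0) / g.sigma
    out = np.exp(-0.5 * z * z) / (g.sigma * _SQRT2PI)
    return out if arr.ndim else float(out)


def _collision_s(u_coll: np.ndarray, c: CollisionParams) -> np.ndarray:
    """sqrt((1+xc)/(1+x)) for u_coll >= 0 (the single-contact survival kernel)."""
    x = np.sqrt(1.0 + (u_coll + c.u_tilde) / c.epsilon)
    return np.sqrt((1.0 + c.xc) / (1.0 + x))


def collision_density(u_coll, c: CollisionParams) -> np.ndarray | float:
    """Max-statistics density F(u_coll) of the collisional energy; 0 for u_coll < 0."""
    arr = _as_finite_array(u_coll, "u_coll")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.zeros_like(arr)
    pos = arr >= 0.0
    if np.any(pos):
        up = arr[pos]
        x = np.sqrt(1.0 + (up + c.u_tilde) / c.epsilon)
        s = np.sqrt((1.0 + c.xc) / (1.0 + x))
        base = 1.0 - s
        # (n_l - 1) exponent: base == 0 at the origin; 0**0 := 1 when n_l == 1
        if c.n_l == 1.0:
            pw = np.ones_like(base)
        else:
            pw = np.power(base, c.n_l - 1.0)
        out[pos] = c.n_l * pw * np.sqrt(1.0 + c.xc) / (
            4.0 * c.epsilon * x * np.power(1.0 + x, 1.5)
        )
    return float(out[0]) if scalar else out


def collision_cdf(u_coll, c: CollisionParams) -> np.ndarray | float:
    """Closed-form CDF G(u_coll) of the collisional energy (0 below 0, -> 1)."""
    arr = _as_finite_array(u_coll, "u_coll")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.zeros_like(arr)
    pos = arr > 0.0
    if np.any(pos):
        s = _collision_s(arr[pos], c)
        out[pos] = np.power(1.0 - s, c.n_l)
    return float(out[0]) if scalar else out


def collision_quantile(q, c: CollisionParams) -> np.ndarray | float:
    """Inverse of :func:`collision_cdf` on (0, 1), in closed form."""
    arr = np.asarray(q, dtype=float)
    if np.any((arr < 0.0) | (arr >= 1.0)):
        raise ValueError("quantile argument must be in [0, 1)")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    s = 1.0 - np.power(arr, 1.0 / c.n_l)          # sqrt((1+xc)/(1+x))
    x = (1.0 + c.xc) / (s * s) - 1.0
    u = c.epsilon * (x * x - 1.0) - c.u_tilde
    u = np.maximum(u, 0.0)
    return float(u[0]) if scalar else u


def convolved_collision_density(
    u,
    g: GaussianParams,
    c: CollisionParams,
    nodes: int = 19,
    method: str = "gauss-hermite",
) -> np.ndarray | float:
    """Convolution (N * F)(u) of the background and collisional densities.

    method="gauss-hermite" integrates over the Gaussian variable with
    ``nodes`` Gauss-Hermite nodes (the default, 19 nodes, follows common
    practice for this model family).  method="quantile" integrates over the
    collisional quantile q in (0, 1) with Gauss-Legendre nodes, which
    converges faster at high accuracy because the integrand is smooth there;
    it serves as the high-accuracy route.
    """
    if nodes < 5:
        raise ValueError("nodes must be >= 5")
    arr = _as_finite_array(u)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if method == "gauss-hermite":
        t, w = np.polynomial.hermite.hermgauss(nodes)
        # u_b = mean + sqrt(2) sigma t;  C(u) = E_b[ F(u - u_b) ]
        ub = g.mean_u0 + np.sqrt(2.0) * g.sigma * t
        fv = collision_density(arr[:, None] - ub[None, :], c)
        out = fv @ w / np.sqrt(np.pi)
    elif method == "quantile":
        t, w = np.polynomial.legendre.leggauss(nodes)
        q = 0.5 * (t + 1.0)
        uc = collision_quantile(q, c)
        nv = gaussian_density(arr[:, None] - uc[None, :], g)
        out = nv @ w * 0.5
    else:
        raise ValueError(f"unknown convolution method {method!r}")
    return float(out[0]) if scalar else out


def p0_density(u, model: CouplingModel, nodes: int = 19) -> np.ndarray | float:
    """Mixture density p0(u) = sum_i w_i [b_i N_i + (1-b_i)(N_i * F_i)](u)."""
    arr = _as_finite_array(u)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.zeros_like(arr)
    for m in model.modes:
        if m.weight == 0.0:
            continue
        b = m.collision.b_no_collision
        dens = b * gaussian_density(arr, m.gaussian)
        if b < 1.0:
            dens = dens + (1.0 - b) * convolved_collision_density(
                arr, m.gaussian, m.collision, nodes=nodes
            )
        out += m.weight * dens
    return float(out[0]) if scalar else out
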