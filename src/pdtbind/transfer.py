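"""Transfer models by convolution of coupling models, and binding bookkeeping.

The perturbation energy of transferring a ligand from solvent to a solvated
receptor is u_t = u_h - u_s: the gain of ligand-receptor interaction energy
minus the ligand-solvent interaction energy in the solvated state.  Its
initial-state density is the convolution of the receptor-coupling density
with the (sign-flipped) solvated-state solvent density, and — because the
solvated state is clash-free and Gaussian by linear response — the result
has the same Gaussian + collisional mixture form as a coupling model:

    per mode pair (i, j):
        weight   w_t = w_h,i * w_s,j
        mean     u0_t = u0_h,i - u1_s,j         (u1 = coupled-state mean)
        sigma_t  = sqrt(sigma_h,i^2 + sigma_s,j^2)
        (b, epsilon, u_tilde, n_l) inherited from the receptor mode i.

The unbinding direction exchanges the two roles: collisional parameters come
from the solvent-coupling model and the mean is u0_s,j - u1_h,i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal

import numpy as np

from .analytic import CouplingModel, GaussianParams, ModelMode
from .pdt import coupled_state_mean, default_quadrature
from .softcore import SoftCoreSpec
from .thermo import ThermoSpec, DEFAULT_THERMO

__all__ = [
    "TransferDirection",
    "SiteSpec",
    "build_transfer_model",
    "two_leg_free_energy",
    "ideal_binding_term",
    "cavity_free_energy",
    "standard_binding_free_energy",
    "STANDARD_VOLUME_A3",
]

#: Volume per molecule at the 1 M standard concentration, in cubic angstrom.
STANDARD_VOLUME_A3 = 1660.539


class TransferDirection(str, Enum):
    """Direction of the alchemical transfer process.

    BINDING ("+"): solvent -> receptor; collisional parameters are inherited
    from the receptor-coupling model.  UNBINDING ("-"): receptor -> solvent;
    collisional parameters are inherited from the solvent-coupling model.
    """

    BINDING = "binding"
    UNBINDING = "unbinding"


@dataclass(frozen=True)
class SiteSpec:
    """Spherical binding-site region (flat-bottom COM restraint radius)."""

    site_radius: float  # angstrom
    standard_volume: float = STANDARD_VOLUME_A3  # A^3 per molecule at 1 M

    def __post_init__(self) -> None:
        if not self.site_radius > 0:
            raise ValueError("site_radius must be positive")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.site_radius**3


def build_transfer_model(
    receptor: CouplingModel,
    solvent: CouplingModel,
    direction: TransferDirection | str = TransferDirection.BINDING,
    th: ThermoSpec = DEFAULT_THERMO,
    mean_method: Literal["linear-response", "quadrature"] = "linear-response",
    sc: SoftCoreSpec | None = None,
    label: str | None = None,
) -> CouplingModel:
    """Combine a receptor-coupling and a solvent-coupling model into a transfer model.

    mean_method selects how the coupled-state mean u1 of the initial (fully
    coupled) environment is evaluated; the linear-response closed form
    u1 = u0 - beta sigma^2 per mode is the default and matches the additive
    parameter-combination rules above.  ``sc`` is only needed for the
    quadrature mean.
    """
    direction = TransferDirection(direction)
    if direction is TransferDirection.BINDING:
        gaining, losing = receptor, solvent
    else:
        gaining, losing = solvent, receptor

    # coupled-state mean of each mode of the environment being left behind
    if mean_method == "linear-response":
        u1 = [m.gaussian.mean_u0 - th.beta * m.gaussian.sigma**2 for m in losing.modes]
    elif mean_method == "quadrature":
        if sc is None:
            raise ValueError("quadrature mean requires a SoftCoreSpec")
        # the coupled (solvated/bound) state is clash-free, so the capped
        # soft-core mean equals the physical mean there; the raw-u average is
        # tail-dominated and not usable
        u1_all = coupled_state_mean(losing, sc, th, method="quadrature").mean_u_sc
        u1 = [u1_all for _ in losing.modes]
    else:
        raise ValueError(f"unknown mean_method {mean_method!r}")

    modes = []
    for i, mg in enumerate(gaining.modes):
        for j, ml in enumerate(losing.modes):
            modes.append(
                ModelMode(
                    weight=mg.weight * ml.weight,
                    gaussian=GaussianParams(
                        mean_u0=mg.gaussian.mean_u0 - u1[j],
                        sigma=math.hypot(mg.gaussian.sigma, ml.gaussian.sigma),
                    ),
                    collision=mg.collision,
                )
            )
    if label is None:
        tag = "binding" if direction is TransferDirection.BINDING else "unbinding"
        label = f"{gaining.label or 'coupling'} / {losing.label or 'coupling'} transfer ({tag})"
    return CouplingModel(modes, label=label)


def two_leg_free_energy(dg_plus: float, dg_minus: float) -> float:
    """Excess binding free energy from the two transfer legs, dG+ - dG-."""
    if not (np.isfinite(dg_plus) and np.isfinite(dg_minus)):
        raise ValueError("leg free energies must be finite")
    return float(dg_plus - dg_minus)


def ideal_binding_term(site: SiteSpec, th: ThermoSpec = DEFAULT_THERMO) -> float:
    """Ideal component of the standard binding free energy, -kB T ln(C deg V_site)."""
    return -th.kt * math.log(site.volume / site.standard_volume)


def cavity_free_energy(b: float, th: ThermoSpec = DEFAULT_THERMO) -> float:
    """Cavity-formation free energy -kB T ln b from the no-collision probability."""
    if not (0.0 < b <= 1.0):
        raise ValueError(f"b must be in (0, 1], got {b}")
    return -th.kt * math.log(b)


def standard_binding_free_energy(excess_dg: float, ideal_dg: float) -> float:
    """Standard binding free energy dG_b = dG_ideal + dG_excess."""
    if not (np.isfinite(excess_dg) and np.isfinite(ideal_dg)):
        raise ValueError("free energy terms must be finite")
    return float(excess_dg + ideal_dg)
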