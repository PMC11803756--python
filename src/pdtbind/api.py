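"""Model/Results front end for fitting the analytical density to samples.

`AlchemicalDensityModel` bundles a multi-state sample set with the fitting
machinery; `fit()` returns an `AlchemicalDensityResults` carrying the
estimated mixture parameters, fit diagnostics, and derived quantities
(free-energy profiles, predicted state densities, kernel diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .analytic import CouplingModel
from .inference import (
    FitConfig,
    FitResult,
    ReweightingResult,
    fit_model,
    initialize_from_diagnostics,
    kernel_lambda_function,
    kernel_p0_estimate,
    negative_log_likelihood,
    uwham_weights,
)
from .pdt import FreeEnergyProfile, free_energy_profile, p_lambda_softcore_density
from .samples import SampleSet
from .softcore import SchedulePoint, SoftCoreSpec
from .thermo import ThermoSpec, DEFAULT_THERMO

__all__ = ["AlchemicalDensityModel", "AlchemicalDensityResults"]


class AlchemicalDensityModel:
    """Analytical perturbation-energy density model bound to a sample set.

    Parameters
    ----------
    samples : SampleSet
        Multi-state soft-core perturbation-energy samples.
    n_modes : int
        Number of mixture modes to fit.
    thermo : ThermoSpec
        Temperature convention (default 300 K).

    Examples
    --------
    >>> model = AlchemicalDensityModel(samples, n_modes=1)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        samples: SampleSet,
        n_modes: int = 1,
        thermo: ThermoSpec = DEFAULT_THERMO,
    ) -> None:
        self.samples = samples.drop_empty()
        self.n_modes = int(n_modes)
        self.thermo = thermo

    @classmethod
    def from_tsv(
        cls,
        path,
        softcore: SoftCoreSpec,
        n_modes: int = 1,
        discard_fraction: float = 0.0,
        thermo: ThermoSpec = DEFAULT_THERMO,
    ) -> "AlchemicalDensityModel":
        from .io import read_samples

        return cls(read_samples(path, softcore, discard_fraction), n_modes, thermo)

    @cached_property
    def uwham(self) -> ReweightingResult:
        """Multistate reweighting solution for this sample set."""
        return uwham_weights(self.samples, self.thermo)

    def initialize(self, bandwidth: float = 1.0, size_hint: float = 3.0) -> CouplingModel:
        """Diagnostics-based starting model (kernel density + lambda-function)."""
        return initialize_from_diagnostics(
            self.samples, self.uwham, bandwidth, self.n_modes, self.thermo, size_hint
        )

    def loglike(self, params: CouplingModel) -> float:
        return -negative_log_likelihood(params, self.samples, self.thermo)

    def fit(
        self,
        start: CouplingModel | None = None,
        config: FitConfig | None = None,
        **kwargs,
    ) -> "AlchemicalDensityResults":
        """Maximum-likelihood fit; extra keyword arguments update FitConfig."""
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            from dataclasses import replace

            config = replace(config, **kwargs)
        if start is None:
            start = self.initialize()
        if start.n_modes != self.n_modes:
            raise ValueError(
                f"starting model has {start.n_modes} modes, expected {self.n_modes}"
            )
        result = fit_model(start, self.samples, self.thermo, config)
        return AlchemicalDensityResults(self, result)


@dataclass
class AlchemicalDensityResults:
    """Fit results: estimated mixture parameters plus derived quantities."""

    model: AlchemicalDensityModel
    fit_result: FitResult

    @property
    def params(self) -> CouplingModel:
        """The fitted analytical model."""
        return self.fit_result.model

    @property
    def cost(self) -> float:
        return self.fit_result.cost

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    @property
    def nobs(self) -> int:
        return self.model.samples.n_total

    def free_energy_profile(self, **kwargs) -> FreeEnergyProfile:
        """PDT free-energy profile of the fitted model over the data's schedule."""
        return free_energy_profile(
            self.params, self.model.samples.schedule(), self.model.thermo, **kwargs
        )

    def predict_density(self, lam_point: SchedulePoint, u_sc: np.ndarray) -> np.ndarray:
        """Fitted p_lam(u_sc) at one schedule point."""
        return np.asarray(
            p_lambda_softcore_density(
                u_sc, self.params, lam_point, self.model.samples.softcore, self.model.thermo
            )
        )

    def kernel_diagnostics(self, bandwidth: float = 1.0):
        """(grid, kernel p0, kernel lambda-function) from the reweighted samples."""
        grid, dens = kernel_p0_estimate(self.model.samples, self.model.uwham, bandwidth)
        _, lam = kernel_lambda_function(
            self.model.samples, self.model.uwham, bandwidth, grid, self.model.thermo
        )
        return grid, dens, lam

    def summary(self) -> str:
        """Parameter table in the customary mode-per-row layout."""
        lines = [
            "Alchemical density maximum-likelihood fit",
            "=" * 78,
            f"observations: {self.nobs}   states: {self.model.samples.n_states}   "
            f"modes: {self.params.n_modes}",
            f"-log L: {self.cost:.4f}   converged: {self.converged}   "
            f"iterations: {self.fit_result.n_iter}",
            "-" * 78,
            f"{'mode':>4} {'w':>10} {'b':>10} {'u0bar':>9} {'sigma':>8} "
            f"{'epsilon':>8} {'u_tilde':>8} {'n_l':>7}",
        ]
        for i, m in enumerate(self.params.modes, start=1):
            c = m.collision
            lines.append(
                f"{i:>4} {m.weight:>10.3e} {c.b_no_collision:>10.3e} "
                f"{m.gaussian.mean_u0:>9.3f} {m.gaussian.sigma:>8.3f} "
                f"{c.epsilon:>8.3f} {c.u_tilde:>8.3f} {c.n_l:>7.2f}"
            )
        lines.append("=" * 78)
        lines.append("energies in kcal/mol; b, w dimensionless")
        return "\n".join(lines)
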