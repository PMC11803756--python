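"""Built-in parameter tables for the TEMOA host-guest and water systems.

These transcribe published maximum-likelihood fits of the analytical
coupling model: the water-in-water coupling model, host-coupling models of
water and the five SAMPL8 guests (G1-G5) to the tetramethyl octa-acid
(TEMOA) host, the corresponding hydration models, and reference transfer
models.  They serve as realistic inputs for the transfer builder, the PDT
engine and the synthetic sampler.
"""

from __future__ import annotations

import json
from importlib import resources

from .analytic import CouplingModel
from .io import read_model

__all__ = ["available", "load_model", "load_ddm_table"]

_MODELS = {
    "h2o-coupling": "h2o_coupling.json",
    "h2o-transfer-ref": "h2o_transfer_ref.json",
    "temoa-h2o-coupling": "temoa_h2o_coupling.json",
    "temoa-g1-coupling": "temoa_g1_coupling.json",
    "temoa-g2-coupling": "temoa_g2_coupling.json",
    "temoa-g3-coupling": "temoa_g3_coupling.json",
    "temoa-g4-coupling": "temoa_g4_coupling.json",
    "temoa-g5-coupling": "temoa_g5_coupling.json",
    "hydration-h2o": "hydration_h2o.json",
    "hydration-g1": "hydration_g1.json",
    "hydration-g2": "hydration_g2.json",
    "hydration-g3": "hydration_g3.json",
    "hydration-g4": "hydration_g4.json",
    "hydration-g5": "hydration_g5.json",
    "temoa-h2o-transfer-leg1-ref": "temoa_h2o_transfer_leg1_ref.json",
    "temoa-h2o-transfer-leg2-ref": "temoa_h2o_transfer_leg2_ref.json",
}


def available() -> list[str]:
    """Names accepted by :func:`load_model`."""
    return sorted(_MODELS)


def _data_path(filename: str):
    return resources.files("pdtbind.data").joinpath(filename)


def load_model(name: str) -> CouplingModel:
    """Load one of the built-in coupling/hydration/transfer models by name."""
    if name not in _MODELS:
        raise KeyError(f"unknown model {name!r}; available: {available()}")
    with resources.as_file(_data_path(_MODELS[name])) as p:
        return read_model(p)


def load_ddm_table() -> dict:
    """Published double-decoupling and transfer excess free energies (kcal/mol)."""
    with _data_path("ddm_free_energies.json").open() as fh:
        return json.load(fh)
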