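"""Model and sample file formats.

Models are JSON documents with a label, a role tag and one record per mode
carrying {weight, b, u0bar, sigma, epsilon, u_tilde, n_l} (energies in
kcal/mol).  Samples are TSV files with header columns
state_index, lambda, lambda1, lambda2, alpha, u0, u_sc_kcal_mol; extra
columns (e.g. replica-exchange provenance) are ignored.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .analytic import CollisionParams, CouplingModel, GaussianParams, ModelMode
from .samples import SampleSet, StateSamples
from .softcore import SchedulePoint, SoftCoreSpec

__all__ = ["read_model", "write_model", "read_samples", "write_samples", "MODEL_ROLES"]

MODEL_ROLES = (
    "host-coupling",
    "solvent-coupling",
    "transfer-binding",
    "transfer-unbinding",
)

_MODE_FIELDS = ("weight", "b", "u0bar", "sigma", "epsilon", "u_tilde", "n_l")

# printed parameter tables carry three significant figures; accept weight sums
# off by rounding, renormalize to machine precision, reject anything worse
_WEIGHT_SUM_TOL = 2e-3


def read_model(path) -> CouplingModel:
    """Read a model JSON file, validating schema and weight normalization."""
    with open(path) as fh:
        doc = json.load(fh)
    if "modes" not in doc or not isinstance(doc["modes"], list) or not doc["modes"]:
        raise ValueError(f"{path}: model file must carry a non-empty 'modes' list")
    role = doc.get("role")
    if role is not None and role not in MODEL_ROLES:
        raise ValueError(f"{path}: unknown role {role!r}; expected one of {MODEL_ROLES}")
    raw = []
    for k, m in enumerate(doc["modes"]):
        for f in _MODE_FIELDS:
            if f not in m:
                raise ValueError(f"{path}: mode {k} is missing field {f!r}")
            if not isinstance(m[f], (int, float)):
                raise ValueError(f"{path}: mode {k} field {f!r} is not numeric")
        raw.append({f: float(m[f]) for f in _MODE_FIELDS})
    total = sum(m["weight"] for m in raw)
    if abs(total - 1.0) > _WEIGHT_SUM_TOL:
        raise ValueError(f"{path}: mode weights sum to {total}, expected 1")
    if abs(total - 1.0) <= 1e-9:
        total = 1.0  # already normalized: keep the stored weights bit-exact
    modes = [
        ModelMode(
            weight=m["weight"] / total,
            gaussian=GaussianParams(mean_u0=m["u0bar"], sigma=m["sigma"]),
            collision=CollisionParams(
                b_no_collision=m["b"],
                epsilon=m["epsilon"],
                u_tilde=m["u_tilde"],
                n_l=m["n_l"],
            ),
        )
        for m in raw
    ]
    return CouplingModel(modes, label=doc.get("label", Path(path).stem))


def write_model(path, model: CouplingModel, role: str | None = None) -> None:
    doc = {
        "label": model.label,
        "modes": [
            {
                "weight": m.weight,
                "b": m.collision.b_no_collision,
                "u0bar": m.gaussian.mean_u0,
                "sigma": m.gaussian.sigma,
                "epsilon": m.collision.epsilon,
                "u_tilde": m.collision.u_tilde,
                "n_l": m.collision.n_l,
            }
            for m in model.modes
        ],
    }
    if role is not None:
        if role not in MODEL_ROLES:
            raise ValueError(f"unknown role {role!r}")
        doc["role"] = role
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


_SAMPLE_COLS = ("state_index", "lambda", "lambda1", "lambda2", "alpha", "u0", "u_sc_kcal_mol")


def read_samples(
    path,
    softcore: SoftCoreSpec,
    discard_fraction: float = 0.0,
) -> SampleSet:
    """Read a sample TSV file into a :class:`SampleSet`.

    discard_fraction drops the leading fraction of each state's rows in file
    order (equilibration trimming of trajectory output); 1/3 is the
    customary choice for replica-exchange data.
    """
    if not (0.0 <= discard_fraction < 1.0):
        raise ValueError("discard_fraction must be in [0, 1)")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SAMPLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in _SAMPLE_COLS:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if df[c].isna().any() or bad.any():
            line = int(np.argmax((df[c].isna() | bad).to_numpy())) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric or missing value in column {c!r} at line {line}")
    over = df["u_sc_kcal_mol"].to_numpy(dtype=float) >= softcore.u_max
    if over.any():
        line = int(np.argmax(over)) + 2
        raise ValueError(
            f"{path}: u_sc >= u_max ({softcore.u_max} kcal/mol) at line {line}; "
            "samples must lie below the soft-core cap"
        )
    states = []
    for idx, grp in df.groupby("state_index", sort=True):
        for c in ("lambda", "lambda1", "lambda2", "alpha", "u0"):
            if grp[c].nunique() > 1:
                raise ValueError(
                    f"{path}: state {idx} maps to more than one schedule point ({c} varies)"
                )
        first = grp.iloc[0]
        pt = SchedulePoint(
            float(first["lambda"]),
            float(first["lambda1"]),
            float(first["lambda2"]),
            float(first["alpha"]),
            float(first["u0"]),
        )
        u = grp["u_sc_kcal_mol"].to_numpy(dtype=float)
        n_drop = int(np.floor(discard_fraction * u.size))
        states.append(StateSamples(int(idx), pt, u[n_drop:]))
    return SampleSet(states, softcore, provenance={"path": str(path), "discard_fraction": discard_fraction})


def write_samples(path, samples: SampleSet) -> None:
    samples.to_frame().to_csv(path, sep="\t", index=False)
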