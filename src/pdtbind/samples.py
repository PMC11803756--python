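"""Multi-state perturbation-energy sample container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .softcore import SchedulePoint, ScheduleSpec, SoftCoreSpec

__all__ = ["StateSamples", "SampleSet"]


@dataclass(frozen=True)
class StateSamples:
    """Soft-core perturbation-energy samples of one alchemical state."""

    state_index: int
    point: SchedulePoint
    u_sc: np.ndarray  # kcal/mol

    def __post_init__(self) -> None:
        arr = np.asarray(self.u_sc, dtype=float)
        if arr.ndim != 1:
            raise ValueError("u_sc must be one-dimensional")
        object.__setattr__(self, "u_sc", arr)

    @property
    def n(self) -> int:
        return self.u_sc.size


@dataclass(frozen=True)
class SampleSet:
    """Per-state collections of soft-core perturbation-energy samples.

    The unit of inference: every record carries the schedule point it was
    generated at, and all energies lie strictly below the soft-core cap.
    """

    states: tuple[StateSamples, ...]
    softcore: SoftCoreSpec
    provenance: Mapping | None = None

    def __init__(
        self,
        states: Iterable[StateSamples],
        softcore: SoftCoreSpec,
        provenance: Mapping | None = None,
    ) -> None:
        states = tuple(states)
        if not states:
            raise ValueError("SampleSet requires at least one state")
        seen = {}
        for st in states:
            if st.state_index in seen:
                raise ValueError(f"duplicate state_index {st.state_index}")
            seen[st.state_index] = st.point
            if st.n and np.max(st.u_sc) >= softcore.u_max:
                raise ValueError(
                    f"state {st.state_index} contains u_sc >= u_max ({softcore.u_max})"
                )
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "softcore", softcore)
        object.__setattr__(self, "provenance", provenance)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_total(self) -> int:
        return int(sum(st.n for st in self.states))

    @property
    def counts(self) -> np.ndarray:
        return np.array([st.n for st in self.states])

    def all_u_sc(self) -> np.ndarray:
        return np.concatenate([st.u_sc for st in self.states])

    def schedule(self) -> ScheduleSpec:
        """The schedule implied by the states, ordered by lam."""
        pts = sorted((st.point for st in self.states), key=lambda p: p.lam)
        return ScheduleSpec(pts, self.softcore)

    def drop_empty(self) -> "SampleSet":
        kept = [st for st in self.states if st.n > 0]
        return SampleSet(kept, self.softcore, self.provenance)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.states:
            rows.append(
                pd.DataFrame(
                    {
                        "state_index": st.state_index,
                        "lambda": st.point.lam,
                        "lambda1": st.point.lam1,
                        "lambda2": st.point.lam2,
                        "alpha": st.point.alpha,
                        "u0": st.point.u0_shift,
                        "u_sc_kcal_mol": st.u_sc,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)
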