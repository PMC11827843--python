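"""Highest-single-agent (HSA) drug-synergy scoring of dose matrices.

Given % viability over a two-drug concentration grid (both dose vectors
include zero: the single-agent row/column and the untreated corner), each
combination cell's excess is its % inhibition minus the better of its two
single agents, and the synergy score is the mean excess in percentage
points.  Scores above +10 are called synergistic, below -10 antagonistic,
otherwise additive.  No baseline correction or response-surface smoothing
is applied; inhibition is left unclamped (viability above 100% gives a
negative inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError

__all__ = [
    "DoseMatrix",
    "SynergyResult",
    "inhibition_from_viability",
    "hsa_excess",
    "hsa_score",
    "read_dose_matrix",
]


@dataclass
class DoseMatrix:
    """% viability over a dose grid; ``viability[i, j]`` is (doses_a[i], doses_b[j])."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    drug_a: str = "drug_a"
    drug_b: str = "drug_b"
    units: str = "uM"

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if d.ndim != 1 or len(d) < 2:
                raise InvalidParameterError(f"{name} needs >= 2 doses (zero plus one)")
            if d[0] != 0:
                raise InvalidParameterError(f"{name} must start at dose 0")
            if not np.all(np.diff(d) > 0):
                raise InvalidParameterError(f"{name} must be strictly increasing")
        if self.viability.shape != (len(self.doses_a), len(self.doses_b)):
            raise InvalidParameterError(
                f"viability shape {self.viability.shape} does not match dose grid "
                f"({len(self.doses_a)}, {len(self.doses_b)})"
            )


@dataclass
class SynergyResult:
    excess: np.ndarray  # combination cells only, percentage points
    score: float
    classification: str  # synergistic | additive | antagonistic


def inhibition_from_viability(v):
    """% inhibition = 100 - % viability, unclamped."""
    return 100.0 - np.asarray(v, dtype=float)


def hsa_excess(m: DoseMatrix) -> np.ndarray:
    """Excess over the highest single agent for every combination cell.

    ``excess[i, j] = I(a_i, b_j) - max(I(a_i, 0), I(0, b_j))`` for
    ``i, j >= 1`` on the dose grid.
    """
    inh = inhibition_from_viability(m.viability)
    single_a = inh[1:, 0][:, None]  # drug A alone, per row
    single_b = inh[0, 1:][None, :]  # drug B alone, per column
    return inh[1:, 1:] - np.maximum(single_a, single_b)


def hsa_score(m: DoseMatrix) -> SynergyResult:
    """Mean HSA excess over the combination grid with the +/-10 bands."""
    excess = hsa_excess(m)
    if excess.size < 1:
        raise InvalidParameterError("dose matrix has no combination cells")
    score = float(excess.mean())
    if score > 10:
        classification = "synergistic"
    elif score < -10:
        classification = "antagonistic"
    else:
        classification = "additive"
    return SynergyResult(excess=excess, score=score, classification=classification)


def read_dose_matrix(
    path: str | Path,
    value: str = "viability",
    drug_a: str = "drug_a",
    drug_b: str = "drug_b",
) -> DoseMatrix:
    """Read a dose matrix CSV: first row/column are doses (0 first), body is %.

    ``value`` selects whether the body holds % viability or % inhibition
    (inhibition is converted on read).
    """
    if value not in ("viability", "inhibition"):
        raise InvalidParameterError("value must be 'viability' or 'inhibition'")
    frame = pd.read_csv(path, index_col=0)
    try:
        doses_a = frame.index.to_numpy(dtype=float)
        doses_b = frame.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"dose labels must be numeric: {exc}") from exc
    body = frame.to_numpy(dtype=float)
    if value == "inhibition":
        body = 100.0 - body
    return DoseMatrix(doses_a=doses_a, doses_b=doses_b, viability=body,
                      drug_a=drug_a, drug_b=drug_b)
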