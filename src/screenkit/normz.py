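"""The normZ scoring engine for one control/treated contrast.

The pipeline is the classic chemogenetic-interaction recipe: read counts
are depth-normalised with a pseudocount, guide-level log2 fold changes are
z-scored against an empirical-Bayes standard deviation estimated in a
sliding window over guides of similar control abundance (abundance, not
identity, drives fold-change variance), guide z-scores are summed per gene
and divided by the square root of the number of observations, and the
resulting raw gene scores are re-standardised across all scored units to
give normZ.  One-tailed p-values come from the standard normal (left tail
= depletion/sensitizer, right tail = enrichment/suppressor) and are
Benjamini-Hochberg corrected within each tail separately.

This module fixes every convention the algorithm needs (pseudocount 5,
normalisation to 1e7 reads, window ``min(500, max(50, n//4))``, sample sd
with denominator n-1, std floor 1e-6); exact numerical parity with any
external implementation is not a goal -- self-consistency and the test
oracle are the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, InvalidParameterError
from .library import GENE_COL, GUIDE_COL, CountTable

__all__ = [
    "ContrastSpec",
    "EngineParams",
    "normalize_counts",
    "guide_log2fc",
    "eb_std",
    "gene_scores",
    "run_contrast",
    "bh_adjust",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass(frozen=True)
class ContrastSpec:
    """One comparison: treated samples scored against control samples."""

    label: str
    control_samples: tuple[str, ...]
    treated_samples: tuple[str, ...]
    paired: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_samples", tuple(self.control_samples))
        object.__setattr__(self, "treated_samples", tuple(self.treated_samples))
        if not self.control_samples or not self.treated_samples:
            raise InvalidParameterError(f"{self.label}: sample lists must be non-empty")
        if set(self.control_samples) & set(self.treated_samples):
            raise InvalidParameterError(f"{self.label}: control and treated overlap")
        if self.paired and len(self.control_samples) != len(self.treated_samples):
            raise InvalidParameterError(f"{self.label}: paired contrast needs equal-length lists")

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        if self.paired:
            return tuple(zip(self.control_samples, self.treated_samples))
        return tuple((c, t) for c in self.control_samples for t in self.treated_samples)


@dataclass(frozen=True)
class EngineParams:
    pseudocount: float = 5.0
    scale: float = 1e7
    window: int | None = None  # None -> min(500, max(50, n//4))
    min_std: float = 1e-6

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise InvalidParameterError("pseudocount must be >= 0")
        if self.scale <= 0 or self.min_std <= 0:
            raise InvalidParameterError("scale and min_std must be > 0")
        if self.window is not None and self.window < 1:
            raise InvalidParameterError("window must be >= 1")

    def resolve_window(self, n_guides: int) -> int:
        if self.window is not None:
            if self.window > n_guides:
                raise InvalidParameterError(
                    f"window {self.window} exceeds {n_guides} guides"
                )
            return self.window
        return max(1, min(500, max(50, n_guides // 4)))


def normalize_counts(column, params: EngineParams = EngineParams()) -> np.ndarray:
    """``pseudocount + count * scale / column_total`` (reads-per-scale)."""
    col = np.asarray(column, dtype=float)
    total = col.sum()
    if total <= 0:
        raise InvalidParameterError("cannot normalize an all-zero column")
    return params.pseudocount + col * (params.scale / total)


def guide_log2fc(
    table: CountTable, contrast: ContrastSpec, params: EngineParams = EngineParams()
) -> pd.DataFrame:
    """Per (guide, control/treated pair) normalised control count and log2 FC."""
    missing = [s for s in contrast.control_samples + contrast.treated_samples
               if s not in table.samples]
    if missing:
        raise ConsistencyError(f"{contrast.label}: samples missing from table: {missing}")
    frames = []
    for ctrl, trt in contrast.pairs:
        nc = normalize_counts(table.data[ctrl].to_numpy(), params)
        nt = normalize_counts(table.data[trt].to_numpy(), params)
        frames.append(
            pd.DataFrame(
                {
                    GUIDE_COL: table.data[GUIDE_COL].to_numpy(),
                    GENE_COL: table.data[GENE_COL].to_numpy(),
                    "PAIR": f"{ctrl}|{trt}",
                    "NORM_CONTROL": nc,
                    "FC": np.log2(nt / nc),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def eb_std(stats: pd.DataFrame, params: EngineParams = EngineParams()) -> pd.DataFrame:
    """Empirical-Bayes std per guide: sample sd of FC in a rank window.

    Within each pair, guides are ranked by normalised control count
    (descending, ties broken by guide id); the std at rank ``r`` is the
    sample sd (ddof=1) of FC over ranks ``[r-w, r+w]`` clamped to the table,
    floored at ``min_std``.  Adds ``STD`` and ``Z = FC / STD``.
    """
    out = []
    for _, grp in stats.groupby("PAIR", sort=True):
        n = len(grp)
        if n < 2:
            raise InvalidParameterError("empirical-Bayes std needs at least 2 guides")
        w = params.resolve_window(n)
        order = np.lexsort((grp[GUIDE_COL].to_numpy(), -grp["NORM_CONTROL"].to_numpy()))
        grp = grp.iloc[order].reset_index(drop=True)
        rolled = (
            pd.Series(grp["FC"]).rolling(window=2 * w + 1, center=True, min_periods=2).std(ddof=1)
        )
        grp["STD"] = np.fmax(rolled.to_numpy(), params.min_std)
        grp["Z"] = grp["FC"] / grp["STD"]
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def gene_scores(
    stats: pd.DataFrame,
    gene_mapping: Mapping[str, str] | Callable[[str], str] | None = None,
) -> pd.DataFrame:
    """Aggregate guide z-scores into re-standardised per-unit normZ.

    ``gene_mapping`` overrides the table's gene labels (used to relabel NTC
    guides into pseudogenes); guides it does not cover are dropped with a
    warning.  Returns one row per unit sorted by normZ ascending with
    columns UNIT, NUMOBS, SUMZ, NORMZ, P_LEFT, P_RIGHT, FDR_LEFT,
    FDR_RIGHT, RANK.
    """
    stats = stats.copy()
    if gene_mapping is None:
        stats["UNIT"] = stats[GENE_COL]
    elif callable(gene_mapping):
        stats["UNIT"] = [gene_mapping(g) for g in stats[GUIDE_COL]]
    else:
        stats["UNIT"] = [gene_mapping.get(g) for g in stats[GUIDE_COL]]
    dropped = stats["UNIT"].isna()
    if dropped.any():
        warnings.warn(
            f"{int(dropped.sum())} guide observations have no unit and are excluded",
            stacklevel=2,
        )
        stats = stats.loc[~dropped]
    if stats.empty:
        raise InvalidParameterError("no scored units remain")

    grouped = stats.groupby("UNIT", sort=True)["Z"]
    sumz = grouped.sum()
    numobs = grouped.size()
    raw = sumz / np.sqrt(numobs)

    sd = float(raw.std(ddof=0))
    if sd == 0.0 or not np.isfinite(sd):
        # degenerate contrast (e.g. treated == control): no ordering information
        normz = pd.Series(0.0, index=raw.index)
        p_left = np.full(len(raw), 0.5)
        p_right = np.full(len(raw), 0.5)
    else:
        normz = (raw - float(raw.mean())) / sd
        p_left = np.clip(norm.cdf(normz), _P_FLOOR, _P_CEIL)
        p_right = np.clip(norm.sf(normz), _P_FLOOR, _P_CEIL)

    out = pd.DataFrame(
        {
            "UNIT": raw.index.to_numpy(),
            "NUMOBS": numobs.to_numpy(),
            "SUMZ": sumz.to_numpy(),
            "NORMZ": normz.to_numpy(),
            "P_LEFT": p_left,
            "P_RIGHT": p_right,
            "FDR_LEFT": bh_adjust(p_left),
            "FDR_RIGHT": bh_adjust(p_right),
        }
    )
    out = out.sort_values(["NORMZ", "UNIT"], kind="mergesort").reset_index(drop=True)
    out["RANK"] = np.arange(1, len(out) + 1)
    return out


def run_contrast(
    table: CountTable,
    contrast: ContrastSpec,
    params: EngineParams = EngineParams(),
    gene_mapping: Mapping[str, str] | Callable[[str], str] | None = None,
) -> pd.DataFrame:
    """Full engine for one contrast: normalise, fold-change, EB z, normZ."""
    stats = guide_log2fc(table, contrast, params)
    stats = eb_std(stats, params)
    return gene_scores(stats, gene_mapping=gene_mapping)
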