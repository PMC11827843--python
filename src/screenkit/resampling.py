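"""NTC-pseudogene resampling wrapper around the normZ engine.

Non-targeting controls have no gene-level structure, so to score them on
the same footing as genes they are randomly aggregated into pseudogenes of
``group_size`` guides.  Because the aggregation is arbitrary, the whole
scoring run is repeated ``n_rep`` times with fresh random partitions;
a gene's score is the arithmetic mean of its normZ over repetitions,
p-values come from the standard normal applied to the averaged score, and
Benjamini-Hochberg correction is applied per tail over real genes.

Essential-control guides are excluded from the count table before scoring
(they would otherwise dominate the fold-change variance windows of a
drug-vs-vehicle contrast); exclusion is a per-contrast switch because a
vehicle-vs-baseline fitness contrast may deliberately keep them.

Real genes' counts never change across repetitions: per-rep variation
arises only through the aggregated NTCs' influence on the empirical-Bayes
windows and the final re-standardisation.  NTC pseudogene scores are
reported per repetition as diagnostics; their membership changes every
repetition, so cross-rep averaging is undefined for them and they are kept
out of the averaged table and the BH family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._random import keyed_rng
from .errors import BudgetError, InvalidParameterError
from .library import CATEGORY_COL, GENE_COL, GUIDE_COL, CountTable
from .normz import ContrastSpec, EngineParams, bh_adjust, run_contrast

__all__ = [
    "NTC_PSEUDOGENE_PREFIX",
    "ResamplingParams",
    "AveragedScoreTable",
    "exclude_essentials",
    "aggregate_ntc",
    "build_rep_table",
    "resampled_scores",
]

NTC_PSEUDOGENE_PREFIX = "NTC_PG_"

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass(frozen=True)
class ResamplingParams:
    seed: int
    group_size: int = 4
    n_rep: int = 100
    excluded_categories: frozenset[str] = frozenset({"essential"})
    max_cells: int = 2_000_000_000  # n_rep * rows * sample columns budget

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidParameterError("seed is mandatory")
        if self.group_size < 1 or self.n_rep < 1:
            raise InvalidParameterError("group_size and n_rep must be >= 1")
        object.__setattr__(self, "excluded_categories", frozenset(self.excluded_categories))


@dataclass
class AveragedScoreTable:
    """Averaged gene scores plus per-repetition traces and NTC diagnostics."""

    label: str
    genes: pd.DataFrame  # GENE MEAN_NORMZ P_LEFT P_RIGHT FDR_LEFT FDR_RIGHT
    trace: pd.DataFrame  # index GENE, one column per repetition
    ntc_diagnostics: pd.DataFrame  # REP N_PSEUDOGENES MEAN_NORMZ SD_NORMZ FRAC_ABS_GT_1_645
    params: ResamplingParams | None = None


def exclude_essentials(table: CountTable, params: ResamplingParams) -> CountTable:
    """Drop guides of the excluded categories, preserving row order."""
    keep = ~table.data[CATEGORY_COL].isin(params.excluded_categories)
    if not keep.any():
        raise InvalidParameterError(
            f"excluding {sorted(params.excluded_categories)} removes every guide"
        )
    return table.subset(keep)


def aggregate_ntc(
    ntc_guide_ids, group_size: int, rng: np.random.Generator
) -> dict[str, str]:
    """Uniformly random partition of NTC guides into ``group_size`` blocks.

    Ids are shuffled and consecutive blocks become pseudogenes
    ``NTC_PG_0001``...; a remainder that cannot fill a block is dropped
    from this repetition with a warning.
    """
    ids = list(ntc_guide_ids)
    if len(ids) < group_size:
        raise InvalidParameterError(
            f"need at least {group_size} NTC guides, got {len(ids)}"
        )
    perm = rng.permutation(len(ids))
    remainder = len(ids) % group_size
    if remainder:
        warnings.warn(
            f"{remainder} NTC guides do not fill a group of {group_size} and are "
            "dropped from this repetition",
            stacklevel=2,
        )
    mapping: dict[str, str] = {}
    n_groups = len(ids) // group_size
    for g in range(n_groups):
        label = f"{NTC_PSEUDOGENE_PREFIX}{g + 1:04d}"
        for j in perm[g * group_size : (g + 1) * group_size]:
            mapping[ids[j]] = label
    return mapping


def build_rep_table(table: CountTable, params: ResamplingParams, rep: int) -> CountTable:
    """The count table scored in repetition ``rep`` (1-based).

    Essential categories are excluded, NTC guides are relabeled to the
    repetition's pseudogenes (remainder guides removed), and all other rows
    pass through untouched.  The repetition's partition comes from the
    fixed counter-based seed split, so any single repetition can be rebuilt
    independently.
    """
    base = exclude_essentials(table, params)
    ntc_mask = base.data[CATEGORY_COL] == "ntc"
    ntc_ids = base.data.loc[ntc_mask, GUIDE_COL].tolist()
    mapping = aggregate_ntc(ntc_ids, params.group_size, keyed_rng(params.seed, rep))
    data = base.data.copy()
    relabeled = data.loc[ntc_mask, GUIDE_COL].map(mapping)
    data.loc[ntc_mask, GENE_COL] = relabeled
    data = data.loc[~(ntc_mask & relabeled.isna())].reset_index(drop=True)
    return CountTable(data)


def resampled_scores(
    table: CountTable,
    contrast: ContrastSpec,
    engine: EngineParams = EngineParams(),
    params: ResamplingParams | None = None,
) -> AveragedScoreTable:
    """Score one contrast under ``n_rep`` random NTC aggregations and average."""
    if params is None:
        raise InvalidParameterError("ResamplingParams (with a seed) are required")
    if not (table.data[CATEGORY_COL] == "ntc").any():
        raise InvalidParameterError("table contains no NTC guides to aggregate")
    cells = params.n_rep * table.n_guides * max(1, len(table.samples))
    if cells > params.max_cells:
        raise BudgetError(
            f"{params.n_rep} repetitions x {table.n_guides} guides exceeds the "
            f"configured budget of {params.max_cells} cells"
        )

    traces: list[pd.Series] = []
    diagnostics: list[dict] = []
    for rep in range(1, params.n_rep + 1):
        rep_table = build_rep_table(table, params, rep)
        scores = run_contrast(rep_table, contrast, engine)
        is_pg = scores["UNIT"].str.startswith(NTC_PSEUDOGENE_PREFIX)
        pg_z = scores.loc[is_pg, "NORMZ"].to_numpy()
        diagnostics.append(
            {
                "REP": rep,
                "N_PSEUDOGENES": int(is_pg.sum()),
                "MEAN_NORMZ": float(pg_z.mean()) if len(pg_z) else np.nan,
                "SD_NORMZ": float(pg_z.std(ddof=1)) if len(pg_z) > 1 else np.nan,
                "P05_NORMZ": float(np.quantile(pg_z, 0.05)) if len(pg_z) else np.nan,
                "P95_NORMZ": float(np.quantile(pg_z, 0.95)) if len(pg_z) else np.nan,
                "FRAC_ABS_GT_1_645": float((np.abs(pg_z) > 1.645).mean()) if len(pg_z) else np.nan,
            }
        )
        gene_rows = scores.loc[~is_pg]
        traces.append(pd.Series(gene_rows["NORMZ"].to_numpy(), index=gene_rows["UNIT"], name=f"rep_{rep}"))

    trace = pd.concat(traces, axis=1).sort_index()
    if trace.isna().any().any():
        raise InvalidParameterError("gene universe changed across repetitions")
    mean_z = trace.mean(axis=1)
    p_left = np.clip(norm.cdf(mean_z), _P_FLOOR, _P_CEIL)
    p_right = np.clip(norm.sf(mean_z), _P_FLOOR, _P_CEIL)
    genes = pd.DataFrame(
        {
            "GENE": trace.index.to_numpy(),
            "MEAN_NORMZ": mean_z.to_numpy(),
            "P_LEFT": p_left,
            "P_RIGHT": p_right,
            "FDR_LEFT": bh_adjust(p_left),
            "FDR_RIGHT": bh_adjust(p_right),
        }
    ).sort_values(["MEAN_NORMZ", "GENE"], kind="mergesort").reset_index(drop=True)

    return AveragedScoreTable(
        label=contrast.label,
        genes=genes,
        trace=trace,
        ntc_diagnostics=pd.DataFrame(diagnostics),
        params=params,
    )
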