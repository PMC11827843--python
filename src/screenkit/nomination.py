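"""Sensitizer hit nomination across cell lines and drug contrasts.

A gene is nominated when (i) its fitness score (vehicle vs baseline normZ)
lies in the closed window [-1, +1] in every cell line where it was
measured -- the gene must be tolerated on its own -- and (ii) its drug
normZ (drug vs vehicle) is strictly below -1 in at least ``min_cell_lines``
cell lines.  An FDR < 0.1 clause is recorded as an annotation flag by
default and can be promoted to a hard gate (``require_fdr``); the original
selection combined the FDR with a visual per-guide consistency check,
which is quantified here as a guide-concordance fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConsistencyError, InvalidParameterError
from .library import GENE_COL, CountTable
from .normz import ContrastSpec, EngineParams, normalize_counts
from .resampling import AveragedScoreTable

__all__ = ["NominationCriteria", "nominate_hits", "guide_concordance", "annotate_known"]

KNOWN_PARPI_SENSITIZERS = frozenset({"CHD1L", "BRCA1", "MUS81", "RNASEH2A", "XRCC1"})


@dataclass(frozen=True)
class NominationCriteria:
    fitness_window: tuple[float, float] = (-1.0, 1.0)
    drug_threshold: float = -1.0
    min_cell_lines: int = 1
    fdr_max: float = 0.1
    require_fdr: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.fitness_window
        if not lo < hi:
            raise InvalidParameterError("fitness_window must have lower < upper")
        if not self.drug_threshold < hi:
            raise InvalidParameterError("drug_threshold must lie below the fitness window top")
        if self.min_cell_lines < 1:
            raise InvalidParameterError("min_cell_lines must be >= 1")


def _scores_frame(scores) -> pd.DataFrame:
    if isinstance(scores, AveragedScoreTable):
        return scores.genes
    return scores


def nominate_hits(
    scores: Mapping[tuple[str, str], AveragedScoreTable | pd.DataFrame],
    fitness_label: str,
    criteria: NominationCriteria = NominationCriteria(),
) -> pd.DataFrame:
    """Apply the two-contrast nomination rule.

    ``scores`` maps (cell_line, contrast_label) to an averaged score table
    (columns GENE, MEAN_NORMZ, FDR_LEFT).  ``fitness_label`` names the
    vehicle-vs-baseline contrast; every other label is a drug contrast.
    Genes with drug data but no fitness score in that cell line are listed
    as unevaluable and never nominated.
    """
    cell_lines = sorted({cl for cl, _ in scores})
    fitness: dict[str, pd.DataFrame] = {}
    for cl in cell_lines:
        if (cl, fitness_label) not in scores:
            raise InvalidParameterError(f"cell line {cl!r} lacks fitness contrast {fitness_label!r}")
        fitness[cl] = _scores_frame(scores[(cl, fitness_label)]).set_index("GENE")
    drug_keys = [(cl, lab) for cl, lab in scores if lab != fitness_label]
    if not drug_keys:
        raise InvalidParameterError("at least one drug contrast is required")
    drug: dict[tuple[str, str], pd.DataFrame] = {
        key: _scores_frame(scores[key]).set_index("GENE") for key in drug_keys
    }

    genes = sorted(set().union(*[set(t.index) for t in drug.values()]))
    lo, hi = criteria.fitness_window
    rows = []
    for gene in genes:
        row: dict = {"GENE": gene}
        met: list[str] = []
        unevaluable = False

        fit_vals: dict[str, float] = {}
        for cl in cell_lines:
            if gene in fitness[cl].index:
                v = float(fitness[cl].loc[gene, "MEAN_NORMZ"])
                fit_vals[cl] = v
                row[f"NORMZ_{cl}_{fitness_label}"] = v
            elif any(cl == dcl and gene in t.index for (dcl, _), t in drug.items()):
                unevaluable = True
        fitness_ok = bool(fit_vals) and all(lo <= v <= hi for v in fit_vals.values())
        if fitness_ok:
            met.append("fitness_window")

        passing_lines: set[str] = set()
        fdr_flag = False
        for (cl, lab), t in drug.items():
            if gene not in t.index:
                continue
            z = float(t.loc[gene, "MEAN_NORMZ"])
            fdr = float(t.loc[gene, "FDR_LEFT"])
            row[f"NORMZ_{cl}_{lab}"] = z
            row[f"FDR_{cl}_{lab}"] = fdr
            depleted = z < criteria.drug_threshold
            fdr_ok = fdr < criteria.fdr_max
            if depleted and fdr_ok:
                fdr_flag = True
                met.append(f"fdr:{cl}:{lab}")
            if depleted and (fdr_ok or not criteria.require_fdr):
                passing_lines.add(cl)
                met.append(f"drug_normz:{cl}:{lab}")
        drug_ok = len(passing_lines) >= criteria.min_cell_lines

        if unevaluable:
            met.append("unevaluable:missing_fitness")
        row["FITNESS_OK"] = fitness_ok
        row["DRUG_OK"] = drug_ok
        row["FDR_OK"] = fdr_flag
        row["NOMINATED"] = bool(fitness_ok and drug_ok and not unevaluable)
        row["CRITERIA_MET"] = ";".join(met)
        row["KNOWN"] = False
        rows.append(row)

    out = pd.DataFrame(rows)
    lead = ["GENE", "NOMINATED", "CRITERIA_MET", "FITNESS_OK", "DRUG_OK", "FDR_OK", "KNOWN"]
    return out[lead + [c for c in out.columns if c not in lead]]


def guide_concordance(
    table: CountTable,
    contrast: ContrastSpec,
    gene: str,
    params: EngineParams = EngineParams(),
) -> float:
    """Fraction of a gene's guides depleted under treatment.

    Quantitative stand-in for the visual per-guide consistency check: a
    guide counts as depleted when its mean normalised treated count is
    strictly below its mean normalised control count.
    """
    mask = (table.data[GENE_COL] == gene).to_numpy()
    if not mask.any():
        raise ConsistencyError(f"gene {gene!r} not present in the count table")
    norm_cols = {
        s: normalize_counts(table.data[s].to_numpy(), params)
        for s in set(contrast.control_samples) | set(contrast.treated_samples)
    }
    ctrl = sum(norm_cols[s][mask] for s in contrast.control_samples) / len(contrast.control_samples)
    trt = sum(norm_cols[s][mask] for s in contrast.treated_samples) / len(contrast.treated_samples)
    return float((trt < ctrl).mean())


def annotate_known(hits: pd.DataFrame, known_genes: Iterable[str]) -> pd.DataFrame:
    """Flag hits whose symbol matches a known-sensitizer list (case-insensitive)."""
    known = {g.upper() for g in known_genes}
    out = hits.copy()
    out["KNOWN"] = [str(g).upper() in known for g in out["GENE"]]
    return out
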