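"""Synthetic pooled-screen generator with known ground truth.

The generator emulates the statistical structure of a genotoxic dropout
screen rather than its mechanics: lentiviral infection and selection are
summarised by a lognormal skew of initial guide abundance and a Beta-
distributed per-guide knockout efficiency, growth over ``D`` population
doublings multiplies each guide's abundance by ``2**(D * u * effect)``,
proportions are renormalised (compositional closure, so essential dropout
inflates the rest of the library as in a real screen), and sequencing reads
are drawn per guide from a gamma-Poisson (negative binomial) with mean
``depth * proportion`` and dispersion ``theta``.

Effects are log2 abundance changes per doubling: ``fitness`` applies in
every grown arm, ``sensitization`` additionally in its drug arm only.
Guides of a gene share the gene effect attenuated by their own efficiency
``u ~ Beta(alpha, beta)``.  NTC guides have no effect by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._random import keyed_rng
from .errors import ConsistencyError, InvalidParameterError
from .library import CATEGORY_COL, GENE_COL, CountTable, LibraryDesign, SampleEntry, SampleSheet

__all__ = [
    "EffectModel",
    "SimulatedScreen",
    "simulate_screen",
    "expected_log2fc",
    "expected_proportions",
    "truth_labels",
    "build_effect_model",
]

T0_ARM = "T0"
VEHICLE_ARM = "DMSO"


@dataclass(frozen=True)
class EffectModel:
    """Generative parameters of one simulated screen.

    Parameters
    ----------
    doublings
        Population doublings per grown arm (the baseline arm ``T0`` is
        implicit and not listed).  The study design grows vehicle and drug
        arms for 15-18 doublings; the default config uses 15.
    depth
        Expected total reads per sample; scalar or per-sample mapping.
    dispersion
        Gamma-Poisson dispersion ``theta`` (count variance = mu + mu**2/theta).
    guide_efficiency
        ``(alpha, beta)`` of the Beta law for per-guide effect attenuation.
    baseline_sigma
        Std of the natural-log initial guide abundance (plasmid skew).
    fitness
        gene -> log2 change per doubling in every grown arm (negative =
        dropout; essential controls).
    sensitization
        drug arm -> (gene -> additional log2 change per doubling under that
        drug; negative = sensitizer).
    """

    doublings: Mapping[str, float]
    depth: float | Mapping[str, float]
    dispersion: float = 100.0
    guide_efficiency: tuple[float, float] = (5.0, 1.0)
    baseline_sigma: float = 0.5
    fitness: Mapping[str, float] = field(default_factory=dict)
    sensitization: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doublings:
            raise InvalidParameterError("at least one grown arm is required")
        for arm, d in self.doublings.items():
            if d <= 0:
                raise InvalidParameterError(f"doublings[{arm!r}] must be > 0")
        if self.dispersion <= 0:
            raise InvalidParameterError("dispersion must be > 0")
        a, b = self.guide_efficiency
        if a <= 0 or b <= 0:
            raise InvalidParameterError("guide_efficiency Beta parameters must be > 0")
        if self.baseline_sigma < 0:
            raise InvalidParameterError("baseline_sigma must be >= 0")
        for arm in self.sensitization:
            if arm not in self.doublings:
                raise InvalidParameterError(
                    f"sensitization arm {arm!r} has no doublings entry"
                )

    @property
    def arms(self) -> tuple[str, ...]:
        return (T0_ARM, *self.doublings)

    def depth_for(self, sample: str) -> float:
        if isinstance(self.depth, Mapping):
            if sample not in self.depth:
                raise InvalidParameterError(f"no depth for sample {sample!r}")
            d = float(self.depth[sample])
        else:
            d = float(self.depth)
        if d <= 0:
            raise InvalidParameterError("depth must be > 0")
        return d

    def validate_genes(self, library: LibraryDesign) -> None:
        known = set(g.gene for g in library.guides)
        unknown = sorted(set(self.fitness) - known)
        for arm, per_gene in self.sensitization.items():
            unknown += sorted(set(per_gene) - known)
        if unknown:
            raise ConsistencyError(f"model references unknown genes: {unknown[:5]}")


@dataclass
class SimulatedScreen:
    table: CountTable
    sample_sheet: SampleSheet
    truth: pd.DataFrame
    seed: int
    model: EffectModel


def _effect_arrays(library: LibraryDesign, model: EffectModel, arm: str) -> np.ndarray:
    """Per-guide gene-level effect (before efficiency) for a grown arm."""
    eff = np.zeros(library.n_guides)
    sens = model.sensitization.get(arm, {})
    for i, g in enumerate(library.guides):
        if g.category == "ntc":
            continue
        eff[i] = model.fitness.get(g.gene, 0.0) + sens.get(g.gene, 0.0)
    return eff


def simulate_screen(
    library: LibraryDesign,
    model: EffectModel,
    seed: int,
    cell_line: str = "CELL",
) -> SimulatedScreen:
    """Draw one complete screen (T0 plus every grown arm) with truth labels.

    Same ``(library, model, seed)`` reproduces the count table bit for bit.
    """
    if seed is None:
        raise InvalidParameterError("seed is mandatory (reproducibility)")
    model.validate_genes(library)
    rng = keyed_rng(seed)

    n = library.n_guides
    a, b = model.guide_efficiency
    u = rng.beta(a, b, size=n)
    baseline = rng.lognormal(mean=0.0, sigma=model.baseline_sigma, size=n)
    p0 = baseline / baseline.sum()

    theta = model.dispersion
    columns: dict[str, np.ndarray] = {}
    for arm in model.arms:
        if arm == T0_ARM:
            prop = p0
        else:
            growth = p0 * np.exp2(model.doublings[arm] * u * _effect_arrays(library, model, arm))
            prop = growth / growth.sum()
        mu = model.depth_for(arm) * prop
        lam = rng.gamma(shape=theta, scale=mu / theta)
        columns[arm] = rng.poisson(lam).astype("int64")

    data = library.to_frame()
    for arm in model.arms:
        data[arm] = columns[arm]
    table = CountTable(data)

    entries = []
    for arm in model.arms:
        if arm == T0_ARM:
            entries.append(SampleEntry(arm, "T0", cell_line))
        elif arm == VEHICLE_ARM:
            entries.append(SampleEntry(arm, "vehicle", cell_line))
        else:
            entries.append(SampleEntry(arm, "drug", cell_line, drug_name=arm))
    sheet = SampleSheet(entries=tuple(entries))

    sim = SimulatedScreen(table=table, sample_sheet=sheet, truth=pd.DataFrame(), seed=seed, model=model)
    sim.truth = truth_labels(sim, library)
    return sim


def expected_log2fc(model: EffectModel, gene: str, arm: str, u: float = 1.0) -> float:
    """Pre-renormalisation expected log2 fold change vs T0 for one gene.

    Equals ``D_arm * u * (fitness + sensitization_in_arm)``; NTC placeholder
    labels simply have no model entry and return 0.
    """
    if arm not in model.doublings:
        raise InvalidParameterError(f"unknown arm {arm!r}")
    f = model.fitness.get(gene, 0.0)
    s = model.sensitization.get(arm, {}).get(gene, 0.0)
    return model.doublings[arm] * u * (f + s)


def expected_proportions(
    library: LibraryDesign, model: EffectModel, arm: str, u: float | None = None
) -> pd.Series:
    """Deterministic expected guide proportions for one arm.

    Uses a flat baseline and, unless given, the mean knockout efficiency
    ``alpha / (alpha + beta)``; a plug-in expectation used to reason about
    monotonicity, not the average of the stochastic draw.
    """
    if u is None:
        a, b = model.guide_efficiency
        u = a / (a + b)
    n = library.n_guides
    if arm == T0_ARM:
        w = np.ones(n)
    else:
        if arm not in model.doublings:
            raise InvalidParameterError(f"unknown arm {arm!r}")
        w = np.exp2(model.doublings[arm] * u * _effect_arrays(library, model, arm))
    return pd.Series(w / w.sum(), index=list(library.guide_ids))


def truth_labels(sim: SimulatedScreen, library: LibraryDesign | None = None) -> pd.DataFrame:
    """Per-unit ground truth: class and effect sizes.

    Classes: ``ntc``; else ``sensitizer``/``suppressor`` when any drug-arm
    sensitization is negative/positive (drug interaction takes precedence);
    else ``essential`` when fitness < 0; else ``neutral``.
    """
    model = sim.model
    frame = sim.table.data if library is None else library.to_frame()
    rows = []
    for gene, grp in frame.groupby(GENE_COL, sort=False):
        category = grp[CATEGORY_COL].iloc[0]
        f = model.fitness.get(gene, 0.0)
        sens = {arm: per.get(gene, 0.0) for arm, per in model.sensitization.items()}
        s_min = min(sens.values(), default=0.0)
        s_max = max(sens.values(), default=0.0)
        if category == "ntc":
            cls = "ntc"
        elif s_min < 0:
            cls = "sensitizer"
        elif s_max > 0:
            cls = "suppressor"
        elif f < 0:
            cls = "essential"
        else:
            cls = "neutral"
        row = {"GENE": gene, "CATEGORY": category, "CLASS": cls, "FITNESS": f}
        for arm in model.sensitization:
            row[f"SENSITIZATION_{arm}"] = sens.get(arm, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def build_effect_model(library: LibraryDesign, cfg: Mapping) -> EffectModel:
    """Build an :class:`EffectModel` from a plain config mapping.

    Recognised keys: ``doublings`` (arm -> D), ``depth_per_guide`` or
    ``depth``, ``dispersion``, ``guide_efficiency`` ({alpha, beta}),
    ``baseline_sigma``, ``essential_fitness`` (applied to every essential
    gene), ``fitness`` (explicit per-gene), and ``sensitizers`` (per drug
    arm either ``{n, effect}`` -- the first ``n`` target genes in library
    order -- or an explicit ``{genes: {gene: s}}``).
    """
    allowed = {
        "doublings",
        "depth",
        "depth_per_guide",
        "dispersion",
        "guide_efficiency",
        "baseline_sigma",
        "essential_fitness",
        "fitness",
        "sensitizers",
    }
    unknown = sorted(set(cfg) - allowed)
    if unknown:
        raise InvalidParameterError(f"unknown model config keys: {unknown}")

    doublings = dict(cfg.get("doublings", {VEHICLE_ARM: 15.0}))
    if "depth" in cfg:
        depth = cfg["depth"]
    else:
        depth = float(cfg.get("depth_per_guide", 300.0)) * library.n_guides
    ge = cfg.get("guide_efficiency", {"alpha": 5.0, "beta": 1.0})
    fitness: dict[str, float] = {}
    essential_fitness = float(cfg.get("essential_fitness", -0.5))
    if essential_fitness != 0.0:
        for gene in library.genes("essential"):
            fitness[gene] = essential_fitness
    for gene, f in dict(cfg.get("fitness", {})).items():
        fitness[gene] = float(f)

    sensitization: dict[str, dict[str, float]] = {}
    targets = library.genes("target")
    for arm, spec in dict(cfg.get("sensitizers", {})).items():
        if "genes" in spec:
            sensitization[arm] = {g: float(s) for g, s in spec["genes"].items()}
        else:
            n = int(spec.get("n", 0))
            if n > len(targets):
                raise InvalidParameterError(
                    f"sensitizers[{arm!r}]: n={n} exceeds {len(targets)} target genes"
                )
            effect = float(spec.get("effect", -0.5))
            sensitization[arm] = {g: effect for g in targets[:n]}

    return EffectModel(
        doublings={k: float(v) for k, v in doublings.items()},
        depth=depth,
        dispersion=float(cfg.get("dispersion", 100.0)),
        guide_efficiency=(float(ge["alpha"]), float(ge["beta"])),
        baseline_sigma=float(cfg.get("baseline_sigma", 0.5)),
        fitness=fitness,
        sensitization=sensitization,
    )
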