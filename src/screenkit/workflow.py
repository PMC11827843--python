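"""End-to-end orchestration from a single YAML config and master seed.

A run either simulates a screen per cell line or ingests count tables,
scores every configured contrast through the NTC-resampling pipeline,
nominates hits across cell lines, and writes TSV outputs plus a manifest
(seeds, parameters, SHA-256 digests, warnings).  One master seed drives
everything through the counter-based splitting rule, so a run is fully
reproducible from its config and seed.
"""

from __future__ import annotations

import hashlib
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import matplotlib
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from . import library as lib
from ._random import spawn_seed
from .errors import ConfigError, InvalidParameterError
from .nomination import NominationCriteria, annotate_known, nominate_hits
from .normz import ContrastSpec, EngineParams
from .resampling import AveragedScoreTable, ResamplingParams, resampled_scores
from .simulate import build_effect_model, simulate_screen

__all__ = ["RunConfig", "load_run_config", "run_screen_analysis", "plot_normz_scatter"]

_TOP_KEYS = {
    "seed", "output_dir", "cell_lines", "simulation", "inputs", "contrasts",
    "engine", "resampling", "nomination", "known_genes", "plots",
}


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    cell_lines: list[str]
    simulation: dict | None
    inputs: dict | None
    fitness_contrast: dict
    drug_contrasts: list[dict]
    engine: EngineParams
    resampling: dict
    nomination: NominationCriteria
    known_genes: list[str] = field(default_factory=list)
    plots: bool = True


def _check_keys(section: Mapping, allowed: set[str], where: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigError(f"unknown config key {unknown[0]!r} in {where}")


def _contrast_entry(entry: Mapping, where: str, default_exclude: list[str]) -> dict:
    _check_keys(entry, {"label", "control", "treated", "paired", "exclude"}, where)
    for key in ("label", "control", "treated"):
        if key not in entry:
            raise ConfigError(f"missing config key {key!r} in {where}")
    return {
        "label": entry["label"],
        "control": list(entry["control"]),
        "treated": list(entry["treated"]),
        "paired": bool(entry.get("paired", False)),
        "exclude": list(entry.get("exclude", default_exclude)),
    }


def load_run_config(path_or_dict, output_dir: str | Path | None = None,
                    seed: int | None = None) -> RunConfig:
    """Parse and validate a run config; CLI may override seed/output_dir."""
    if isinstance(path_or_dict, Mapping):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError("run config must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "run config")

    if seed is None:
        if "seed" not in cfg:
            raise ConfigError("missing config key 'seed'")
        seed = int(cfg["seed"])
    out_dir = Path(output_dir if output_dir is not None else cfg.get("output_dir", "screenkit_run"))

    simulation = cfg.get("simulation")
    inputs = cfg.get("inputs")
    if (simulation is None) == (inputs is None):
        raise ConfigError("exactly one of 'simulation' or 'inputs' must be configured")
    if simulation is not None:
        _check_keys(simulation, {"library", "model"}, "simulation")

    contrasts = cfg.get("contrasts")
    if not contrasts:
        raise ConfigError("missing config key 'contrasts'")
    _check_keys(contrasts, {"fitness", "drugs"}, "contrasts")
    if "fitness" not in contrasts:
        raise ConfigError("missing config key 'fitness' in contrasts")
    # fitness keeps essential controls by default (they anchor the scale);
    # drug contrasts exclude them as in the published analysis
    fitness = _contrast_entry(contrasts["fitness"], "contrasts.fitness", default_exclude=[])
    drugs = [
        _contrast_entry(e, f"contrasts.drugs[{i}]", default_exclude=["essential"])
        for i, e in enumerate(contrasts.get("drugs", []))
    ]
    if not drugs:
        raise ConfigError("missing config key 'drugs' in contrasts")

    engine_cfg = dict(cfg.get("engine", {}))
    _check_keys(engine_cfg, {"pseudocount", "scale", "window", "min_std"}, "engine")
    engine = EngineParams(**engine_cfg)

    resampling_cfg = dict(cfg.get("resampling", {}))
    _check_keys(resampling_cfg, {"n_rep", "group_size", "max_cells"}, "resampling")

    nomination_cfg = dict(cfg.get("nomination", {}))
    _check_keys(
        nomination_cfg,
        {"fitness_window", "drug_threshold", "min_cell_lines", "fdr_max", "require_fdr"},
        "nomination",
    )
    if "fitness_window" in nomination_cfg:
        nomination_cfg["fitness_window"] = tuple(nomination_cfg["fitness_window"])
    criteria = NominationCriteria(**nomination_cfg)

    cell_lines = [str(c) for c in cfg.get("cell_lines", ["CELL"])]
    return RunConfig(
        seed=int(seed),
        output_dir=out_dir,
        cell_lines=cell_lines,
        simulation=simulation,
        inputs=inputs,
        fitness_contrast=fitness,
        drug_contrasts=drugs,
        engine=engine,
        resampling=resampling_cfg,
        nomination=criteria,
        known_genes=[str(g) for g in cfg.get("known_genes", [])],
        plots=bool(cfg.get("plots", True)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig, cell_line: str) -> lib.CountTable:
    inputs = config.inputs
    _check_keys(inputs, {"library", "samples", "counts"}, "inputs")
    for key in ("library", "counts"):
        if key not in inputs:
            raise ConfigError(f"missing config key {key!r} in inputs")
    design = lib.read_library(inputs["library"])
    sheet = lib.read_sample_sheet(inputs["samples"]) if "samples" in inputs else None
    counts = inputs["counts"]
    path = counts[cell_line] if isinstance(counts, Mapping) else counts
    return lib.read_count_table(path, design, sheet)


def run_screen_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns artifact paths, tables and manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "cell_lines": config.cell_lines,
        "engine": {
            "pseudocount": config.engine.pseudocount,
            "scale": config.engine.scale,
            "window": config.engine.window,
            "min_std": config.engine.min_std,
        },
        "resampling": dict(config.resampling),
        "stages": [],
        "warnings": [],
        "outputs": {},
    }
    caught: list[str] = []

    scores: dict[tuple[str, str], AveragedScoreTable] = {}
    score_paths: dict[tuple[str, str], Path] = {}
    tables: dict[str, lib.CountTable] = {}
    all_contrasts = [config.fitness_contrast] + config.drug_contrasts

    for i, cell_line in enumerate(config.cell_lines):
        t0 = time.perf_counter()
        cl_dir = out / cell_line
        cl_dir.mkdir(exist_ok=True)
        if config.simulation is not None:
            lib_cfg = dict(config.simulation.get("library", {}))
            design = lib.compose_library(
                n_target_genes=int(lib_cfg.get("n_target_genes", 356)),
                n_essential_genes=int(lib_cfg.get("n_essential_genes", 63)),
                n_ntc_guides=int(lib_cfg.get("n_ntc_guides", 324)),
                guides_per_gene=int(lib_cfg.get("guides_per_gene", 4)),
            )
            model = build_effect_model(design, dict(config.simulation.get("model", {})))
            sim_seed = spawn_seed(config.seed, 0, i)
            sim = simulate_screen(design, model, seed=sim_seed, cell_line=cell_line)
            table = sim.table
            lib.write_count_table(table, cl_dir / "counts.tsv")
            lib.write_library(design, cl_dir / "library.tsv")
            lib.write_sample_sheet(sim.sample_sheet, cl_dir / "samples.tsv")
            sim.truth.to_csv(cl_dir / "truth.tsv", sep="\t", index=False)
            manifest.setdefault("simulation_seeds", {})[cell_line] = sim_seed
        else:
            table = _load_inputs(config, cell_line)
        tables[cell_line] = table
        missing = [c["label"] for c in all_contrasts
                   if any(s not in table.samples for s in c["control"] + c["treated"])]
        if missing:
            raise ConfigError(
                f"cell line {cell_line!r}: contrast samples missing from table for {missing}"
            )

        for j, entry in enumerate(all_contrasts):
            contrast = ContrastSpec(
                label=entry["label"],
                control_samples=tuple(entry["control"]),
                treated_samples=tuple(entry["treated"]),
                paired=entry["paired"],
            )
            params = ResamplingParams(
                seed=spawn_seed(config.seed, 1, i, j),
                group_size=int(config.resampling.get("group_size", 4)),
                n_rep=int(config.resampling.get("n_rep", 100)),
                excluded_categories=frozenset(entry["exclude"]),
                max_cells=int(config.resampling.get("max_cells", 2_000_000_000)),
            )
            with warnings.catch_warnings(record=True) as wrec:
                warnings.simplefilter("always")
                result = resampled_scores(table, contrast, config.engine, params)
            caught += [f"{cell_line}/{contrast.label}: {w.message}" for w in wrec]
            scores[(cell_line, contrast.label)] = result
            path = cl_dir / f"scores_{contrast.label}.tsv"
            result.genes.to_csv(path, sep="\t", index=False, float_format="%.10g")
            result.ntc_diagnostics.to_csv(
                cl_dir / f"ntc_diagnostics_{contrast.label}.tsv",
                sep="\t", index=False, float_format="%.10g",
            )
            score_paths[(cell_line, contrast.label)] = path
        manifest["stages"].append(
            {"stage": f"score[{cell_line}]", "seconds": round(time.perf_counter() - t0, 3)}
        )

    t0 = time.perf_counter()
    hits = nominate_hits(scores, fitness_label=config.fitness_contrast["label"],
                         criteria=config.nomination)
    hits = annotate_known(hits, config.known_genes)
    hits_path = out / "hits.tsv"
    hits.to_csv(hits_path, sep="\t", index=False, float_format="%.10g")
    manifest["stages"].append({"stage": "nominate", "seconds": round(time.perf_counter() - t0, 3)})

    plot_paths: list[Path] = []
    if config.plots:
        fit_label = config.fitness_contrast["label"]
        for cell_line in config.cell_lines:
            for entry in config.drug_contrasts:
                p = out / cell_line / f"scatter_{entry['label']}.png"
                plot_normz_scatter(scores[(cell_line, fit_label)],
                                   scores[(cell_line, entry["label"])], p)
                plot_paths.append(p)

    manifest["warnings"] = sorted(set(caught))
    for path in [*score_paths.values(), hits_path]:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    return {
        "output_dir": out,
        "scores": scores,
        "score_paths": score_paths,
        "hits": hits,
        "hits_path": hits_path,
        "tables": tables,
        "plots": plot_paths,
        "manifest": manifest,
    }


def plot_normz_scatter(fitness, drug, out_path: str | Path):
    """Scatter of drug normZ against fitness normZ with dashed +/-1 guides."""
    fit = fitness.genes if isinstance(fitness, AveragedScoreTable) else fitness
    drg = drug.genes if isinstance(drug, AveragedScoreTable) else drug
    merged = pd.merge(fit[["GENE", "MEAN_NORMZ"]], drg[["GENE", "MEAN_NORMZ"]],
                      on="GENE", suffixes=("_fitness", "_drug"))
    if merged.empty:
        raise InvalidParameterError("fitness and drug tables share no genes")
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(merged["MEAN_NORMZ_fitness"], merged["MEAN_NORMZ_drug"],
               s=12, alpha=0.6, edgecolors="none")
    for v in (-1.0, 1.0):
        ax.axvline(v, linestyle="--", color="grey", linewidth=0.8)
        ax.axhline(v, linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("fitness normZ (vehicle vs T0)")
    ax.set_ylabel("drug normZ (drug vs vehicle)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
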