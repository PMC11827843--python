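import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

import screenkit as sk
from screenkit.cli import main
from screenkit.errors import ConfigError, InvalidParameterError

SMALL_CONFIG = {
    "seed": 7,
    "cell_lines": ["LINE_A"],
    "simulation": {
        "library": {"n_target_genes": 12, "n_essential_genes": 3,
                    "n_ntc_guides": 16, "guides_per_gene": 4},
        "model": {
            "doublings": {"DMSO": 15, "OLA": 15},
            "depth_per_guide": 400,
            "essential_fitness": -0.5,
            "sensitizers": {"OLA": {"n": 3, "effect": -0.5}},
        },
    },
    "contrasts": {
        "fitness": {"label": "DMSO_vs_T0", "control": ["T0"], "treated": ["DMSO"],
                    "exclude": []},
        "drugs": [{"label": "OLA_vs_DMSO", "control": ["DMSO"], "treated": ["OLA"]}],
    },
    "resampling": {"n_rep": 5, "group_size": 4},
    "plots": False,
}


def _run(tmp_path, name, **overrides):
    cfg = {**SMALL_CONFIG, **overrides}
    config = sk.load_run_config(cfg, output_dir=tmp_path / name)
    return sk.run_screen_analysis(config)


def test_run_twice_is_byte_identical(tmp_path):
    a = _run(tmp_path, "a")
    b = _run(tmp_path, "b")
    for key, path_a in a["score_paths"].items():
        assert path_a.read_bytes() == b["score_paths"][key].read_bytes()
    assert a["hits_path"].read_bytes() == b["hits_path"].read_bytes()
    assert a["manifest"]["outputs"] == b["manifest"]["outputs"]


def test_run_outputs_are_consistent(tmp_path):
    result = _run(tmp_path, "run")
    hits = result["hits"].set_index("GENE")
    scores = result["scores"]
    fit = scores[("LINE_A", "DMSO_vs_T0")].genes.set_index("GENE")
    drug = scores[("LINE_A", "OLA_vs_DMSO")].genes.set_index("GENE")
    for gene, row in hits[hits["NOMINATED"]].iterrows():
        assert -1.0 <= fit.loc[gene, "MEAN_NORMZ"] <= 1.0
        assert drug.loc[gene, "MEAN_NORMZ"] < -1.0
    # drug scoring excludes essentials; fitness keeps them
    assert not any(g.startswith("ESS") for g in drug.index)
    assert any(g.startswith("ESS") for g in fit.index)


def test_config_validation_errors(tmp_path):
    with pytest.raises(ConfigError, match="bogus_key"):
        sk.load_run_config({**SMALL_CONFIG, "bogus_key": 1}, output_dir=tmp_path)
    no_fitness = {**SMALL_CONFIG,
                  "contrasts": {"drugs": SMALL_CONFIG["contrasts"]["drugs"]}}
    with pytest.raises(ConfigError, match="fitness"):
        sk.load_run_config(no_fitness, output_dir=tmp_path)
    no_seed = {k: v for k, v in SMALL_CONFIG.items() if k != "seed"}
    with pytest.raises(ConfigError, match="seed"):
        sk.load_run_config(no_seed, output_dir=tmp_path)


def test_plot_normz_scatter(tmp_path):
    genes = [f"G{i}" for i in range(10)]
    rng = np.random.default_rng(0)
    fit = pd.DataFrame({"GENE": genes, "MEAN_NORMZ": rng.normal(size=10)})
    drug = pd.DataFrame({"GENE": genes, "MEAN_NORMZ": rng.normal(size=10)})
    out = sk.plot_normz_scatter(fit, drug, tmp_path / "scatter.png")
    assert out.exists() and out.stat().st_size > 0
    single = sk.plot_normz_scatter(fit.iloc[:1], drug.iloc[:1], tmp_path / "one.png")
    assert single.exists()
    with pytest.raises(InvalidParameterError):
        sk.plot_normz_scatter(fit, drug.assign(GENE=[f"X{i}" for i in range(10)]),
                              tmp_path / "bad.png")


def test_cli_end_to_end(tmp_path):
    runner = CliRunner()
    config_path = tmp_path / "config.yaml"
    config_path.write_text(yaml.safe_dump(SMALL_CONFIG))
    result = runner.invoke(main, ["run", "--config", str(config_path),
                                  "--out", str(tmp_path / "run")])
    assert result.exit_code == 0, result.output
    assert (tmp_path / "run" / "hits.tsv").exists()
    assert (tmp_path / "run" / "manifest.yaml").exists()

    sim_cfg = tmp_path / "sim.yaml"
    sim_cfg.write_text(yaml.safe_dump(SMALL_CONFIG["simulation"]))
    result = runner.invoke(main, ["simulate", "--config", str(sim_cfg), "--seed", "3",
                                  "--out-prefix", str(tmp_path / "sim")])
    assert result.exit_code == 0, result.output
    result = runner.invoke(main, [
        "score", "--counts", str(tmp_path / "sim_counts.tsv"),
        "--library", str(tmp_path / "sim_library.tsv"),
        "--contrast", "OLA_vs_DMSO=DMSO:OLA",
        "--out", str(tmp_path / "scores.tsv")])
    assert result.exit_code == 0, result.output
    scores = pd.read_csv(tmp_path / "scores.tsv", sep="\t")
    assert {"UNIT", "NORMZ", "FDR_LEFT", "RANK"} <= set(scores.columns)


def test_cli_synergy(tmp_path):
    matrix = tmp_path / "m.csv"
    matrix.write_text(",0,10\n0,100,70\n1,60,30\n")
    runner = CliRunner()
    result = runner.invoke(main, ["synergy", "--matrix", str(matrix)])
    assert result.exit_code == 0, result.output
    # I(1,10)=70, singles 40/30 -> excess 30, synergistic
    assert "30.000" in result.output and "synergistic" in result.output
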