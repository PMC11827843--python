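import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import screenkit as sk
from screenkit.errors import InvalidParameterError
from screenkit.normz import bh_adjust

from .oracle import bf_bh, bf_run_contrast


def _table(guides, genes, categories, **columns):
    data = pd.DataFrame({"GUIDE": guides, "GENE": genes, "CATEGORY": categories})
    for name, counts in columns.items():
        data[name] = counts
    return sk.CountTable(data)


@pytest.mark.parametrize(
    "counts, pseudocount, scale, expected",
    [
        ([10, 40], 0.0, 100.0, [20.0, 80.0]),
        ([1, 1], 0.0, 10.0, [5.0, 5.0]),
        ([10, 40], 5.0, 100.0, [25.0, 85.0]),
    ],
)
def test_normalize_counts(counts, pseudocount, scale, expected):
    params = sk.EngineParams(pseudocount=pseudocount, scale=scale)
    assert sk.normalize_counts(counts, params) == pytest.approx(expected)


def test_normalize_rejects_all_zero():
    with pytest.raises(InvalidParameterError):
        sk.normalize_counts([0, 0, 0], sk.EngineParams())


def test_guide_log2fc_values():
    table = _table(["g1", "g2"], ["A", "A"], ["target"] * 2, C=[10, 40], T=[40, 10])
    contrast = sk.ContrastSpec("T_vs_C", ("C",), ("T",))
    params = sk.EngineParams(pseudocount=5.0, scale=100.0)
    stats = sk.guide_log2fc(table, contrast, params).set_index("GUIDE")
    # normalised: control (25, 85), treated (85, 25)
    assert stats.loc["g1", "FC"] == pytest.approx(np.log2(85 / 25), abs=1e-12)
    assert stats.loc["g2", "FC"] == pytest.approx(np.log2(25 / 85), abs=1e-12)
    assert np.log2(85 / 25) == pytest.approx(1.7655, abs=5e-5)


def test_fc_zero_when_treated_equals_control(small_null_sim):
    table = small_null_sim.table
    dup = table.copy()
    dup.data["COPY"] = dup.data["DMSO"]
    contrast = sk.ContrastSpec("self", ("DMSO",), ("COPY",))
    stats = sk.guide_log2fc(sk.CountTable(dup.data), contrast)
    assert np.allclose(stats["FC"], 0.0)


def test_fc_invariant_to_library_scaling(small_null_sim):
    """With pseudocount 0, multiplying one sample's counts by a constant
    leaves fold changes unchanged (proportions renormalise)."""
    table = small_null_sim.table
    params = sk.EngineParams(pseudocount=0.0)
    contrast = sk.ContrastSpec("OLA_vs_DMSO", ("DMSO",), ("OLA",))
    base = sk.guide_log2fc(table, contrast, params)
    scaled = table.copy()
    scaled.data["OLA"] = scaled.data["OLA"] * 3
    after = sk.guide_log2fc(scaled, contrast, params)
    assert np.allclose(base["FC"], after["FC"])


def test_eb_std_floor_and_two_guide_case():
    # all FC equal -> window sd 0 -> floored
    table = _table(["g1", "g2", "g3"], ["A", "A", "B"], ["target"] * 3,
                   C=[100, 200, 300], T=[100, 200, 300])
    params = sk.EngineParams(pseudocount=0.0, window=2, min_std=1e-6)
    stats = sk.eb_std(sk.guide_log2fc(
        table, sk.ContrastSpec("x", ("C",), ("T",)), params), params)
    assert np.allclose(stats["STD"], 1e-6)

    # two guides with fc (-1, +1): sample sd sqrt(2) for both
    table2 = _table(["g1", "g2"], ["A", "B"], ["target"] * 2, C=[40, 20], T=[20, 40])
    params2 = sk.EngineParams(pseudocount=0.0, scale=60.0, window=1)
    stats2 = sk.eb_std(sk.guide_log2fc(
        table2, sk.ContrastSpec("x", ("C",), ("T",)), params2), params2)
    assert np.allclose(stats2["FC"].abs(), 1.0)
    assert np.allclose(stats2["STD"], np.sqrt(2.0))


def test_eb_std_window_clamped_at_boundary():
    """Rank-1 guide with w=3 in a 10-guide table uses ranks 1-4 only."""
    rng = np.random.default_rng(0)
    counts_c = np.arange(1000, 0, -100)  # strictly decreasing -> rank = row order
    counts_t = rng.integers(50, 1500, size=10)
    table = _table([f"g{i:02d}" for i in range(10)], [f"G{i:02d}" for i in range(10)],
                   ["target"] * 10, C=counts_c, T=counts_t)
    params = sk.EngineParams(pseudocount=0.0, window=3)
    stats = sk.eb_std(sk.guide_log2fc(
        table, sk.ContrastSpec("x", ("C",), ("T",)), params), params)
    ranked = stats.sort_values("NORM_CONTROL", ascending=False).reset_index(drop=True)
    expected_first = ranked["FC"].iloc[0:4].std(ddof=1)
    expected_last = ranked["FC"].iloc[6:10].std(ddof=1)
    assert ranked["STD"].iloc[0] == pytest.approx(expected_first, abs=1e-12)
    assert ranked["STD"].iloc[9] == pytest.approx(expected_last, abs=1e-12)


def test_gene_scores_aggregation_and_standardization():
    stats = pd.DataFrame({
        "GUIDE": [f"g{i}" for i in range(8)],
        "GENE": ["A"] * 4 + ["B"] * 4,
        "PAIR": "C|T",
        "NORM_CONTROL": 100.0,
        "FC": 0.0,
        "STD": 1.0,
        "Z": [1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0],
    })
    scores = sk.gene_scores(stats).set_index("UNIT")
    assert scores.loc["A", "SUMZ"] == pytest.approx(4.0)
    assert scores.loc["A", "NUMOBS"] == 4
    # raw score 4/sqrt(4) = 2 before re-standardisation; two symmetric units
    assert scores.loc["A", "NORMZ"] == pytest.approx(1.0)
    assert scores.loc["B", "NORMZ"] == pytest.approx(-1.0)
    assert scores["NORMZ"].mean() == pytest.approx(0.0, abs=1e-9)
    assert scores["NORMZ"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_bh_adjustment_matches_enumeration():
    p = [0.01, 0.02, 0.03, 0.04]
    assert bh_adjust(p) == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert bh_adjust(p) == pytest.approx(bf_bh(p))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-8, 1.0 - 1e-8), min_size=1, max_size=40))
def test_bh_matches_independent_step_up(pvalues):
    assert np.allclose(bh_adjust(pvalues), bf_bh(pvalues), atol=1e-12)
    assert (bh_adjust(pvalues) >= np.asarray(pvalues) - 1e-15).all()


def test_run_contrast_permutation_invariance(small_null_sim):
    table = small_null_sim.table
    contrast = sk.ContrastSpec("OLA_vs_DMSO", ("DMSO",), ("OLA",))
    base = sk.run_contrast(table, contrast)
    rng = np.random.default_rng(3)
    shuffled = sk.CountTable(
        table.data.iloc[rng.permutation(table.n_guides)].reset_index(drop=True)
    )
    after = sk.run_contrast(shuffled, contrast)
    pd.testing.assert_frame_equal(base, after)


def test_run_contrast_degenerate_identity(small_null_sim):
    table = small_null_sim.table.copy()
    table.data["COPY"] = table.data["DMSO"]
    scores = sk.run_contrast(sk.CountTable(table.data),
                             sk.ContrastSpec("self", ("DMSO",), ("COPY",)))
    assert np.allclose(scores["NORMZ"], 0.0)
    assert np.allclose(scores["P_LEFT"], 0.5)
    assert np.allclose(scores["P_RIGHT"], 0.5)


def test_engine_matches_bruteforce_oracle():
    """50-guide/10-gene instance: the vectorised engine agrees with the
    straight-line oracle to 1e-9 in every field."""
    rng = np.random.default_rng(12345)
    guides, genes, cats = [], [], []
    for i in range(10):
        for k in range(4):
            guides.append(f"G{i:02d}_g{k + 1}")
            genes.append(f"G{i:02d}")
            cats.append("target")
    for i in range(10):
        guides.append(f"NTC_{i:02d}")
        genes.append(f"NTC_{i:02d}")
        cats.append("ntc")
    ctrl = rng.integers(50, 2000, size=50)
    trt = rng.integers(50, 2000, size=50)
    table = _table(guides, genes, cats, C=ctrl, T=trt)
    params = sk.EngineParams(pseudocount=5.0, scale=1e7, window=7)

    result = sk.run_contrast(table, sk.ContrastSpec("x", ("C",), ("T",)), params)
    expected = bf_run_contrast(guides, genes, list(ctrl), list(trt),
                               pseudocount=5.0, scale=1e7, window=7, min_std=1e-6)
    assert len(result) == len(expected) == 20
    for row in result.itertuples():
        exp = expected[row.UNIT]
        for field in ("NUMOBS", "SUMZ", "NORMZ", "P_LEFT", "P_RIGHT",
                      "FDR_LEFT", "FDR_RIGHT"):
            assert abs(getattr(row, field) - exp[field]) < 1e-9, (row.UNIT, field)


def test_p_monotone_in_normz_and_fdr_dominates_p(study_null_sim):
    scores = sk.run_contrast(study_null_sim.table,
                             sk.ContrastSpec("OLA_vs_DMSO", ("DMSO",), ("OLA",)))
    ordered = scores.sort_values("NORMZ")
    assert ordered["P_LEFT"].is_monotonic_increasing  # p_left decreasing in -normZ
    assert (scores["FDR_LEFT"] >= scores["P_LEFT"] - 1e-15).all()
    assert (scores["FDR_RIGHT"] >= scores["P_RIGHT"] - 1e-15).all()
    assert np.allclose(scores["P_LEFT"] + scores["P_RIGHT"], 1.0, atol=1e-12)
    assert scores["NORMZ"].mean() == pytest.approx(0.0, abs=1e-9)
    assert scores["NORMZ"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_null_screen_p_value_calibration(study_null_sim):
    """On an all-effects-zero screen the left-tail p-values are uniform
    enough that about 5% of units fall below 0.05."""
    scores = sk.run_contrast(study_null_sim.table,
                             sk.ContrastSpec("OLA_vs_DMSO", ("DMSO",), ("OLA",)))
    frac = (scores["P_LEFT"] < 0.05).mean()
    assert 0.02 <= frac <= 0.08


def test_paired_and_unpaired_pairings():
    c = sk.ContrastSpec("x", ("c1", "c2"), ("t1", "t2"), paired=True)
    assert c.pairs == (("c1", "t1"), ("c2", "t2"))
    u = sk.ContrastSpec("x", ("c1", "c2"), ("t1",))
    assert u.pairs == (("c1", "t1"), ("c2", "t1"))
    with pytest.raises(InvalidParameterError):
        sk.ContrastSpec("x", ("a",), ("a",))
    with pytest.raises(InvalidParameterError):
        sk.ContrastSpec("x", ("c1", "c2"), ("t1",), paired=True)
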