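import pytest

import screenkit as sk

# Study-design constants: 356 target + 63 essential genes at 4 guides/gene,
# 324 NTC guides, 15 population doublings, 300x read depth per guide.
STUDY_LIBRARY = (356, 63, 324, 4)


@pytest.fixture(scope="session")
def small_library():
    return sk.compose_library(10, 2, 12, guides_per_gene=4)


@pytest.fixture(scope="session")
def small_null_sim(small_library):
    model = sk.build_effect_model(
        small_library,
        {"doublings": {"DMSO": 15, "OLA": 15}, "essential_fitness": 0.0,
         "depth_per_guide": 500},
    )
    return sk.simulate_screen(small_library, model, seed=7)


@pytest.fixture(scope="session")
def study_library():
    return sk.compose_library(*STUDY_LIBRARY)


@pytest.fixture(scope="session")
def study_null_sim(study_library):
    """All-effects-zero screen at the study's scale."""
    model = sk.build_effect_model(
        study_library,
        {"doublings": {"DMSO": 15, "OLA": 15}, "essential_fitness": 0.0},
    )
    return sk.simulate_screen(study_library, model, seed=1)


@pytest.fixture(scope="session")
def study_sensitizer_sim(study_library):
    """Study-scale screen: essentials drop out (f=-0.5/doubling), the first
    20 target genes sensitize to both drugs (s=-0.5/doubling)."""
    model = sk.build_effect_model(
        study_library,
        {
            "doublings": {"DMSO": 15, "OLA": 15, "TALA": 15},
            "essential_fitness": -0.5,
            "sensitizers": {
                "OLA": {"n": 20, "effect": -0.5},
                "TALA": {"n": 20, "effect": -0.5},
            },
        },
    )
    return sk.simulate_screen(study_library, model, seed=1)
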