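import numpy as np
import pandas as pd
import pytest

from cargoscreen import (
    CountMatrix,
    GuideLibrary,
    ScreenScenario,
    make_library,
    simulate_screen,
)


@pytest.fixture
def tiny_library() -> GuideLibrary:
    """Three genes, two guides each; GENE3 carries a second guide set."""
    rows = [
        ("A1", "GENE1", "set1", "ACGTACGTACGTACGTACG"),
        ("A2", "GENE1", "set1", "TTTTACGTACGTACGTACG"),
        ("B1", "GENE2", "set1", "GGGGACGTACGTACGTACG"),
        ("B2", "GENE2", "set1", "CCCCACGTACGTACGTACG"),
        ("C1", "GENE3", "set1", "AACCACGTACGTACGTACG"),
        ("C2", "GENE3", "set2", "AAGGACGTACGTACGTACG"),
    ]
    return GuideLibrary(pd.DataFrame(
        rows, columns=["guide_id", "gene_id", "guide_set", "sequence"]))


@pytest.fixture
def tiny_counts(tiny_library) -> CountMatrix:
    counts = pd.DataFrame(
        {
            "low_r1": [10, 20, 30, 40, 50, 60],
            "high_r1": [12, 18, 33, 37, 52, 58],
            "low_r2": [11, 22, 29, 41, 49, 61],
            "high_r2": [13, 19, 30, 39, 50, 59],
        },
        index=pd.Index(tiny_library.table["guide_id"], name="sgRNA"),
    )
    samples = pd.DataFrame({
        "sample": ["low_r1", "high_r1", "low_r2", "high_r2"],
        "condition": ["tau_low", "tau_high", "tau_low", "tau_high"],
        "replicate": [1, 1, 2, 2],
    })
    genes = pd.Series(tiny_library.table["gene_id"].to_numpy(),
                      index=counts.index, name="gene")
    return CountMatrix(counts, genes, samples)


@pytest.fixture(scope="session")
def default_scenario() -> ScreenScenario:
    """Desk-scale default: 1,000 genes, 50 required, 2 replicates."""
    return ScreenScenario(seed=11)


@pytest.fixture(scope="session")
def default_screen(default_scenario):
    library = make_library(default_scenario)
    cm, truth = simulate_screen(library, default_scenario)
    return library, cm, truth


@pytest.fixture(scope="session")
def null_screen():
    """Scenario with a vanishing effect: gate probabilities effectively
    equal for required and neutral genes."""
    sc = ScreenScenario(n_genes=1000, n_required_genes=1,
                        gate_prob_required=0.5 + 1e-9,
                        gate_prob_null=0.5, seed=23)
    library = make_library(sc)
    cm, truth = simulate_screen(library, sc)
    return library, cm, truth
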