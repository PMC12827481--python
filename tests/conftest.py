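import numpy as np
import pandas as pd
import pytest

from aegis import (
    ExpressionMatrix,
    SampleDesign,
    SimulationConfig,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_experiment():
    """Strongly perturbed synthetic experiment, small enough for fast tests."""
    return simulate_experiment(
        SimulationConfig(
            n_genes=400, n_signature=50, n_tf_sets=4, effect_size=2.0, seed=11
        )
    )


@pytest.fixture(scope="session")
def null_experiment():
    """No-effect synthetic experiment (treatment exchangeable with control)."""
    return simulate_experiment(
        SimulationConfig(
            n_genes=400, n_signature=50, n_tf_sets=4, effect_size=0.0, seed=12
        )
    )


@pytest.fixture
def two_group_design():
    """Plain 3-vs-3 treatment/control design."""

    def make(n_treat=3, n_control=3):
        rows = []
        for i in range(n_control):
            rows.append((f"c{i}", "vehicle", 0.0, "control", "donor1"))
        for i in range(n_treat):
            rows.append((f"t{i}", "drug", 10.0, "treatment", "donor1"))
        return SampleDesign(
            pd.DataFrame(rows, columns=["sample_id", "compound", "dose_multiple", "group", "donor"])
        )

    return make


@pytest.fixture
def matrix_from_values():
    def make(values, scale="log", genes=None, samples=None):
        values = np.asarray(values, dtype=float)
        genes = genes or [f"g{i}" for i in range(values.shape[0])]
        samples = samples or [f"s{j}" for j in range(values.shape[1])]
        return ExpressionMatrix(values, genes, samples, scale)

    return make
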