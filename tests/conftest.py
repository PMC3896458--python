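import numpy as np
import pandas as pd
import pytest

from rvmnet import ExpressionMatrix, SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study (seed 1), shared across tests that only read it."""
    return simulate_bundle(SimConfig(seed=1))


@pytest.fixture()
def toy_matrix():
    """4-gene, 2+2-sample matrix with hand-computable geometric means."""
    data = pd.DataFrame(
        {
            "case_1": [2.0, 4.0, 1.0, 8.0],
            "case_2": [8.0, 4.0, 1.0, 2.0],
            "control_1": [1.0, 2.0, 4.0, 4.0],
            "control_2": [1.0, 8.0, 4.0, 4.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    design = pd.Series(
        {"case_1": "case", "case_2": "case", "control_1": "control", "control_2": "control"}
    )
    return ExpressionMatrix(intensities=data, design=design)


def make_matrix(values: np.ndarray, n_case: int, n_control: int, prefix="G") -> ExpressionMatrix:
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_control)]
    design = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return ExpressionMatrix(
        intensities=pd.DataFrame(values, index=genes, columns=samples), design=design
    )
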