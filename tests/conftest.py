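import numpy as np
import pandas as pd
import pytest

from immunosig import ClinicalTable, ExpressionMatrix
from immunosig.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """3 genes x 2 samples, normalized state."""
    values = pd.DataFrame(
        [[2.0, 4.0], [4.0, 6.0], [6.0, 2.0]],
        index=["G1", "G2", "G3"], columns=["A", "B"],
    )
    return ExpressionMatrix(values, state="normalized")


@pytest.fixture
def nanostring_toy() -> ExpressionMatrix:
    """Tiny raw matrix with all four probe classes.

    Sample B's positive probes are exactly double sample A's, giving
    hand-computable positive-control factors (1.5, 0.75).
    """
    values = pd.DataFrame(
        {
            "A": [100.0, 200.0, 16.0, 64.0, 8.0, 10.0, 12.0, 400.0, 400.0],
            "B": [100.0, 200.0, 32.0, 128.0, 8.0, 10.0, 12.0, 400.0, 400.0],
        },
        index=["E1", "E2", "P1", "P2", "N1", "N2", "N3", "H1", "H2"],
    )
    probe_class = pd.Series(
        ["endogenous"] * 2 + ["positive"] * 2 + ["negative"] * 3
        + ["housekeeping"] * 2,
        index=values.index,
    )
    return ExpressionMatrix(values, probe_class, state="raw")


@pytest.fixture
def clinical_toy() -> ClinicalTable:
    table = pd.DataFrame(
        {
            "os_time": [100.0, 400.0, 800.0, 1500.0],
            "os_event": [1, 0, 1, 0],
            "mycn_amplified": [1, 0, np.nan, 0],
            "age_months": [30.0, 10.0, 24.0, 6.0],
            "inrg_stage": ["M", "L1", "L2", np.nan],
            "cd3_density": [5.0, 50.0, 12.0, 80.0],
        },
        index=pd.Index(["A", "B", "C", "D"], name="sample_id"),
    )
    return ClinicalTable(table)


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded synthetic cohort shared across tests (n=200)."""
    cfg = SimulationConfig(
        n_samples=200, n_null_genes=50,
        n_signature_genes={"DC": 10, "NK": 5, "T": 5}, seed=42,
    )
    return cfg, *simulate_cohort(cfg)
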