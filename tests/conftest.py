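import numpy as np
import pandas as pd
import pytest

from coexflow.abundance import ExpressionMatrix
from coexflow.simulate import SampleDesign, SimConfig


@pytest.fixture
def one_tissue_design() -> SampleDesign:
    samples = ["A1_leaf", "A2_leaf", "A3_leaf", "B1_leaf", "B2_leaf", "B3_leaf"]
    return SampleDesign(
        pd.DataFrame(
            {
                "population": ["equatorial"] * 3 + ["subtropical"] * 3,
                "individual": ["A1", "A2", "A3", "B1", "B2", "B3"],
                "tissue": ["leaf"] * 6,
            },
            index=pd.Index(samples, name="sample"),
        )
    )


@pytest.fixture
def toy_matrix(one_tissue_design) -> ExpressionMatrix:
    """Ten transcripts engineered so the three-step classification can be
    derived by hand, plus a stable random background for the EB fits."""
    samples = list(one_tissue_design.table.index)
    rows = {
        "t01": [50, 60, 70, 0, 0, 0],  # UET_A
        "t02": [0, 0, 0, 40, 50, 60],  # UET_B
        "t03": [20, 0, 40, 0, 0, 0],  # absent in one A individual and in B
        "t04": [50, 50, 50, 50, 50, 50],  # EET both, FC = 1
        "t05": [400, 420, 380, 40, 42, 38],  # DET over-expressed in A
        "t06": [30, 33, 27, 300, 330, 270],  # DET over-expressed in B
        "t07": [2000, 20, 2000, 50, 50, 50],  # unstable within A
        "t08": [60, 60, 60, 3000, 30, 3000],  # unstable within B
        "t09": [66, 60, 63, 50, 44, 47],  # EET both but FC < 1.5
        "t10": [0, 0, 0, 0, 0, 0],  # silent
    }
    rng = np.random.default_rng(0)
    for i in range(11, 61):
        rows[f"bg{i:02d}"] = list(rng.poisson(rng.uniform(20, 200), 6))
    vals = pd.DataFrame(rows, index=samples).T.astype(float)
    return ExpressionMatrix(vals, pd.Series(1000, index=vals.index), "count")


@pytest.fixture
def de_benchmark_config() -> SimConfig:
    """One-tissue 3-vs-3 benchmark: 20% DE at fold change 4."""
    return SimConfig(
        n_transcripts=2000,
        tissues=("leaf",),
        frac_uet_A=0.0,
        frac_uet_B=0.0,
        frac_det=0.2,
        det_fold_change=4.0,
        n_modules=0,
        module_size=0,
        seed=11,
    )


@pytest.fixture
def module_chain_config() -> SimConfig:
    """Latent-factor modules for the network-recovery chain."""
    return SimConfig(
        n_transcripts=500,
        frac_uet_A=0.0,
        frac_uet_B=0.0,
        frac_det=0.0,
        n_modules=4,
        module_size=50,
        module_correlation=0.8,
        seed=3,
    )
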