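import numpy as np
import pytest

from paneldx import simulate
from paneldx.io import ExpressionStudy


@pytest.fixture
def tiny_study() -> ExpressionStudy:
    """3 genes x 4 samples, two groups, hand-enterable values."""
    return ExpressionStudy(
        matrix=np.array(
            [[1.0, 2.0, 3.0, 4.0],
             [4.0, 3.0, 2.0, 1.0],
             [5.0, 5.0, 5.0, 5.0]]
        ),
        feature_ids=("gA", "gB", "gC"),
        sample_ids=("s1", "s2", "s3", "s4"),
        groups={"s1": "X", "s2": "X", "s3": "Y", "s4": "Y"},
    )


@pytest.fixture
def planted_sim() -> simulate.SimulatedStudy:
    """Small cohort (5/11) with 5 strong planted DE genes."""
    cfg = simulate.SimConfig(
        n_genes=200,
        group_sizes={"Healthy": 5, "Case": 11},
        n_de_genes=5,
        effect_size_log2=3.0,
        n_modules=0,
        module_size=1,
        noise_sd=0.5,
        seed=11,
    )
    return simulate.simulate_study(cfg)


@pytest.fixture
def module_sim() -> simulate.SimulatedStudy:
    """Two strong planted co-expression modules, many samples."""
    cfg = simulate.SimConfig(
        n_genes=120,
        group_sizes={"A": 30, "B": 30},
        n_de_genes=0,
        effect_size_log2=0.0,
        n_modules=2,
        module_size=20,
        module_loading=0.9,
        noise_sd=0.5,
        seed=7,
    )
    return simulate.simulate_study(cfg)
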