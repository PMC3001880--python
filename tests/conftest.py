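import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from xsilence.io_annotation import ExpressionMatrix
from xsilence.synthetic import PROGRAMS, SyntheticConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_config(**overrides) -> SyntheticConfig:
    """A scaled-down synthetic configuration for fast unit tests."""
    base = dict(
        n_genes_per_chromosome={**{str(i): 12 for i in range(1, 23)}, "X": 60},
        stage_program_sizes={p: 20 for p in PROGRAMS},
        seed=0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture
def small_config() -> SyntheticConfig:
    return make_config()


@pytest.fixture
def toy_annotation() -> pd.DataFrame:
    """Five probes over three genes on two chromosomes plus one unannotated."""
    return pd.DataFrame(
        {
            "gene_symbol": ["ALPHA", "ALPHA", "BETA", "GAMMA", ""],
            "chromosome": ["1", "1", "X", "2", "other"],
        },
        index=pd.Index(["p1", "p2", "p3", "p4", "p5"], name="probe_id"),
    )


@pytest.fixture
def toy_matrix(toy_annotation) -> ExpressionMatrix:
    values = pd.DataFrame(
        {
            "s1": [100.0, 300.0, 50.0, 400.0, 10.0],
            "s2": [110.0, 290.0, 70.0, 380.0, 20.0],
        },
        index=toy_annotation.index,
    )
    return ExpressionMatrix(values=values, species="human", tissue="testis")
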