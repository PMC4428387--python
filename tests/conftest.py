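import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pascore import ArrRole, ExpressionMatrix, Pathway, PathwayDB

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def tiny_db() -> PathwayDB:
    """Two small pathways with mixed activator/repressor roles."""
    return PathwayDB(
        pathways=[
            Pathway(
                id="P1",
                name="Growth",
                members={"EGFR": ArrRole(1.0), "PTEN": ArrRole(-1.0)},
            ),
            Pathway(
                id="P2",
                name="Survival",
                members={"AKT1": ArrRole(0.5), "TP53": ArrRole(-0.5), "MYC": ArrRole(0.0)},
            ),
        ]
    )


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    """5 genes x 4 samples (2 controls), strictly positive values."""
    data = pd.DataFrame(
        {
            "S1": [10.0, 5.0, 8.0, 2.0, 7.0],
            "S2": [12.0, 4.0, 6.0, 3.0, 9.0],
            "C1": [5.0, 5.0, 7.0, 2.5, 8.0],
            "C2": [5.0, 5.0, 9.0, 3.5, 8.0],
        },
        index=["EGFR", "PTEN", "AKT1", "TP53", "MYC"],
    )
    return ExpressionMatrix(data=data, platform_label="array", control_ids=("C1", "C2"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240826)
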