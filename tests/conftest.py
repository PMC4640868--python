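import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from triotarget import ExpressionTable, SimulationConfig, simulate


@pytest.fixture
def toy_table():
    """Five genes spanning kept / filtered / down / up / unchanged paths."""
    frame = pd.DataFrame(
        {
            "knockdown": [2.0, 0.9, 1.0, 5.0, 7.0],
            "control": [2.0, 5.0, 3.0, 0.2, 7.0],
        },
        index=["A", "B", "C", "D", "E"],
    )
    return ExpressionTable(cell_line="toy", data=frame)


SMALL_SIM_KWARGS = dict(
    n_genes=300,
    n_lines=2,
    n_direct_targets=10,
    n_indirect_targets=20,
    n_decoy_peaks=100,
    genes_per_contig=50,
    n_amplified=20,
    n_nonamplified=60,
    n_indeterminate=20,
)


@pytest.fixture
def small_sim_kwargs():
    return dict(SMALL_SIM_KWARGS)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    cfg = SimulationConfig(seed=11, **SMALL_SIM_KWARGS)
    return simulate(cfg, tmp_path_factory.mktemp("bundle"))
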