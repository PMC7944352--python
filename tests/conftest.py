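import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def eca_table():
    """The |P| = 524,288 cropped conditional CTM table (rules 0-127)."""
    from apml.tables import eca_initcond_table
    return eca_initcond_table()


@pytest.fixture(scope="session")
def nk_tables():
    """(rule-list, topology) conditional CTM tables from the full
    331,776-network enumeration."""
    from apml.tables import nk_conditional_tables
    return nk_conditional_tables()


@pytest.fixture(scope="session")
def tm_base():
    """Base CTM table from the 10,000-machine 2-state enumeration."""
    from apml.complexity import build_base_ctm_by_tm_enumeration
    return build_base_ctm_by_tm_enumeration(2, 100)


@pytest.fixture(scope="session")
def initcond_distance(eca_table):
    from apml.classify import DistanceSpec
    from apml.complexity import PairingPlan, PartitionSpec
    return DistanceSpec(
        kind="strong-bdm",
        partition=PartitionSpec((4, 6)),
        centroid_partition=PartitionSpec((6,)),
        cond_table=eca_table,
        plan=PairingPlan(strategy="positional"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
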