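import pytest
from hypothesis import HealthCheck, settings

from granora.model import Pathway, PathwayDatabase
from granora.simulate import SyntheticScenario, coarsen_db, generate_fine_db

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_db() -> PathwayDatabase:
    """Six assigned genes in two pathways; small enough for enumeration."""
    return PathwayDatabase(
        name="tiny",
        pathways=[
            Pathway(id="P1", name="first", genes=frozenset({"g1", "g2", "g3"})),
            Pathway(id="P2", name="second", genes=frozenset({"g3", "g4", "g5", "g6"})),
        ],
    )


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A scaled-down dual-granularity world for fast tests."""
    return SyntheticScenario(
        universe_size=600,
        n_fine_pathways=60,
        fine_size_range=(3, 13),
        grouping_factor=3,
        overlap_noise=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_scenario):
    fine = generate_fine_db(small_scenario)
    coarsened = coarsen_db(fine, small_scenario.grouping_factor, seed=12)
    return fine, coarsened
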