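import numpy as np
import pytest

from fcnet.cohort import CohortSpec, PlantedEffect, generate_cohort, records_to_frame
from fcnet.connectome import compute_fc, stack_fc

PLANTED_EDGES = (
    (0, 1), (0, 5), (0, 9), (0, 13), (0, 17), (0, 21),
    (1, 3), (1, 7), (1, 11), (1, 25), (1, 29),
)  # 11-edge two-hub tree on 12 nodes, spread over a 30-region atlas


def planted_effect(delta: float) -> PlantedEffect:
    return PlantedEffect(edges=PLANTED_EDGES, delta=delta, direction="reduce")


@pytest.fixture(scope="session")
def small_cohort():
    """16+16 subjects, 30 regions, planted 11-edge effect; shared across tests."""
    spec = CohortSpec(
        n_group1=16, n_group2=16, n_regions=30, n_timepoints=150,
        effect=planted_effect(0.4), seed=1234,
    )
    records, series = generate_cohort(spec)
    return spec, records, series


@pytest.fixture(scope="session")
def small_fc(small_cohort):
    spec, records, series = small_cohort
    fcs = [compute_fc(ts) for ts in series]
    stack, eidx = stack_fc(fcs)
    return fcs, stack, eidx


@pytest.fixture(scope="session")
def small_phenotype(small_cohort):
    _, records, _ = small_cohort
    return records_to_frame(records)


def random_connected_adjacency(n: int, rng: np.random.Generator, p: float = 0.5) -> np.ndarray:
    """A random connected simple graph (rejection sampling)."""
    while True:
        a = (rng.random((n, n)) < p).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        if a.sum() == 0:
            continue
        # connectivity via reachability closure
        reach = np.eye(n, dtype=bool) | a.astype(bool)
        for _ in range(n):
            reach = reach | (reach @ a.astype(bool))
        if reach.all():
            return a
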