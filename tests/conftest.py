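import numpy as np
import pytest

import apasig as ap
from apasig.probesets import pairs_to_frame


@pytest.fixture(scope="session")
def small_universe():
    return ap.generate_universe(60, multi_apa_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def small_pairs(small_universe):
    pairs, report = ap.build_all(small_universe.transcripts, small_universe.probes)
    return pairs, report


@pytest.fixture(scope="session")
def synthesis_cohort(small_universe):
    truth = ap.SimulationTruth.synthesis()
    return ap.generate_cohort(small_universe, truth, 40, planted_fraction=0.4, seed=5)


@pytest.fixture(scope="session")
def synthesis_eri(small_universe, small_pairs, synthesis_cohort):
    pairs, _ = small_pairs
    defs = pairs_to_frame(pairs)
    expr = ap.summarize(synthesis_cohort.intensity, defs, method="median_log")
    return expr, ap.compute_eri(expr, pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def planted_groups(cohort):
    """GroupAssignment from the cohort's planted biology labels."""
    return ap.GroupAssignment.from_labels(
        dict(zip(cohort.clinical["sample_id"], cohort.clinical["group"]))
    )
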