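import numpy as np
import pytest

from splitbelt.cohort import PopulationSpec, generate_cohort
from splitbelt.preprocess import filter_trials
from splitbelt.protocol import ProtocolSpec


@pytest.fixture(scope="session")
def cohort39():
    """Full-scale synthetic cohort (39 subjects, 3 blocks) with the
    generating per-subject parameters."""
    table, subjects = generate_cohort(
        PopulationSpec(), ProtocolSpec(), rng=np.random.default_rng(2026)
    )
    return table, subjects


@pytest.fixture(scope="session")
def clean39(cohort39):
    table, subjects = cohort39
    clean, report = filter_trials(table)
    return clean, subjects, report


@pytest.fixture(scope="session")
def small_cohort():
    """Five-subject cohort for cheaper end-to-end checks."""
    pop = PopulationSpec(n_subjects=5)
    return generate_cohort(pop, ProtocolSpec(), rng=np.random.default_rng(7))
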