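import pytest

from lipidfc.synthetic_data import StudyDesign, simulate_study
from lipidfc.pipeline import fixture_design


@pytest.fixture(scope="session")
def default_study():
    """Full default study (3 cell lines, 451 species), seeded."""
    return simulate_study(StudyDesign(seed=1))


@pytest.fixture(scope="session")
def mini_study():
    """The ~50-species, 2-cell-line mini-study."""
    return simulate_study(fixture_design(seed=1))
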