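import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.util imports

from tandemchimera import simulate as sim


@pytest.fixture(scope="session")
def default_study():
    """The full default cohort (462 samples, 240 tandem pairs)."""
    return sim.simulate_study(seed=11)


@pytest.fixture(scope="session")
def default_study_dir(default_study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    return sim.write_study(default_study, d)


@pytest.fixture(scope="session")
def mini_study():
    spec = sim.CohortSpec(
        n_tandem_pairs=40,
        n_testable=3,
        n_subthreshold=5,
        n_repeat_overlap=4,
        n_background_genes=6,
        n_inverted=3,
        n_diff_strand=2,
        n_interchrom=3,
    )
    return sim.simulate_study(spec, seed=5)
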