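import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from decorakin.spr import KineticParams, PhaseSchedule


@pytest.fixture(scope="session")
def study_kinetics() -> KineticParams:
    """The picomolar, transport-limited kinetic regime of the study."""
    from decorakin.synthetic import DEFAULT_KINETICS

    return DEFAULT_KINETICS


@pytest.fixture(scope="session")
def schedule() -> PhaseSchedule:
    return PhaseSchedule(baseline_duration=60.0, association_duration=200.0, dissociation_duration=600.0)
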