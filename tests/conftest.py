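import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blackboxnr import GroundTruth, InconclusivePolicy, StudyPanel

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def make_panel(stats, policy=InconclusivePolicy.AS_CORRECT_OBSERVED,
               stratum=GroundTruth.DIFFERENT_SOURCE):
    """Panel directly from (J, R, E_obs) triples, bypassing record parsing."""
    J, R, E = zip(*stats) if stats else ((), (), ())
    ids = [f"e{i}" for i in range(len(J))]
    return StudyPanel(ids, np.array(J, dtype=np.int64),
                      np.array(R, dtype=np.int64), np.array(E, dtype=np.int64),
                      policy, stratum)


@pytest.fixture
def mkpanel():
    return make_panel
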