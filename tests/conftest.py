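import numpy as np
import pytest

from rpg_regulon import motif


@pytest.fixture(scope="session")
def dyrk1a_pwm():
    return motif.build_pwm(consensus=motif.DYRK1A_CONSENSUS, pseudocount=0.01)


@pytest.fixture(scope="session")
def dyrk1a_table(dyrk1a_pwm):
    return motif.ScorePValueTable(dyrk1a_pwm)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
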