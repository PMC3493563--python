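import numpy as np
import pytest

import clquant as cq


@pytest.fixture(scope="session")
def ctx():
    """Standard imaging conditions: bath chloride 151 mM, RMP -54 mV, 58 mV/decade."""
    return cq.EquilibriumContext(cl_out_mM=151.0, rmp_mV=-54.0)


@pytest.fixture(scope="session")
def wt_cells():
    """Small untreated-population sample with known ground truth."""
    return cq.gen_cell_population(cq.PopulationParams.wild_type(30), seed=11)


@pytest.fixture(scope="session")
def noiseless_kinetics():
    return cq.KineticsParams(noise_sd=0.0)


@pytest.fixture
def flat_trace():
    t = np.arange(0.0, 60.0, 0.5)
    return cq.FluorescenceTrace(t, np.full_like(t, 100.0), cell_id="flat")
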