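import numpy as np
import pytest

from dglat.preprocess import preprocess_session
from dglat.simulate import HemisphereProfile, simulate_session


@pytest.fixture(scope="session")
def rich_session():
    """A session dense in place cells, shared by the spatial/decoding tests."""
    profile = HemisphereProfile(frac_active=0.9, frac_place_of_active=0.7,
                                frac_global_remap=0.5)
    return simulate_session(profile, n_cells=40, seed=11)


@pytest.fixture(scope="session")
def rich_processed(rich_session):
    ext, included, active = preprocess_session(rich_session)
    masked = np.vstack([t.masked_dff for t in ext.traces_])
    tmask = np.vstack([t.transient_mask for t in ext.traces_])
    return ext, included, active, masked, tmask
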