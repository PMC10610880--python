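import dataclasses

import numpy as np
import pytest

from epiopt.phantom import PhantomSpec, make_tissue_phantom
from epiopt.report import _epi_protocol_for_phantom

#: per-slice timing overhead (ms) used for phantom-scale EPI protocols,
#: the value calibrated from the 4 mm reference TR table
OVERHEAD = 18.3125

GM_T1 = 717.2


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom used across the SNR / recovery tests."""
    return PhantomSpec(shape=(32, 32, 8), voxel_size=4.0, seed=77)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_tissue_phantom(small_spec)


@pytest.fixture(scope="session")
def epi_protocol_factory():
    """Phantom-matched EPI protocol at a given TE (Ernst-angle flip)."""
    def make(spec, te):
        return _epi_protocol_for_phantom(spec, te, OVERHEAD, GM_T1)
    return make


def with_lambda(phantom, **lam):
    """Copy of a phantom with physiological amplitudes overridden."""
    return dataclasses.replace(
        phantom, spec=dataclasses.replace(phantom.spec, **lam))
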