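import numpy as np
import pytest

from halodesign import fixtures as fx


@pytest.fixture
def simple_peptide():
    return fx.make_peptide(8)


@pytest.fixture
def bridged_peptide():
    return fx.make_peptide(10, salt_bridges=[(2, 9, 3.5)])


@pytest.fixture
def shell_trajectory():
    """20 ions on an exact 2.7 Å minimum-distance shell around a point protein."""
    return fx.make_ion_trajectory(
        np.zeros((1, 3)), n_ions=20, n_frames=40, shells=[(2.7, 1.0)], seed=11
    )


@pytest.fixture
def uniform_trajectory():
    return fx.make_ion_trajectory(
        np.zeros((1, 3)), n_ions=30, n_frames=60, uniform_weight=1.0, seed=11
    )
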