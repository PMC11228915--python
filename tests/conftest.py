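import numpy as np
import pytest

from crystinv.synthetic import random_periodic_set

MINIMAL_CIF = """\
data_toy
_cell_length_a 2
_cell_length_b 2
_cell_length_c 2
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0 0 0
"""


@pytest.fixture(scope="session")
def random_sets():
    """A reusable batch of small random 3D periodic sets."""
    rng = np.random.default_rng(20260901)
    return [random_periodic_set(3, int(rng.integers(1, 7)), seed=int(rng.integers(2**31)))
            for _ in range(30)]


@pytest.fixture
def minimal_cif():
    return MINIMAL_CIF
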