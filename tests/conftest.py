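"""Shared fixtures: idealized chains, a stub language model, small tasks."""

import numpy as np
import pytest

from geoprot.lm import StubProteinLM
from geoprot.synthetic import ChainSpec, build_chain, make_structure_task


@pytest.fixture(scope="session")
def helix_chain():
    """20-residue ideal alpha-helix."""
    return build_chain(ChainSpec(length=20, phi=-57.0, psi=-47.0, omega=180.0,
                                 seed=1))


@pytest.fixture(scope="session")
def strand_chain():
    """12-residue ideal beta-strand."""
    return build_chain(ChainSpec(length=12, phi=-139.0, psi=135.0, omega=180.0,
                                 seed=2))


@pytest.fixture(scope="session")
def stub_lm():
    return StubProteinLM(seed=0)


@pytest.fixture(scope="session")
def small_task():
    """40 mixed helix/strand/coil chains with binary helix-content labels."""
    return make_structure_task(40, rule="helix_fraction_threshold", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


def rigid_transform_structure(struct, R, t):
    """Apply x -> R x + t to every coordinate array of a BackboneStructure."""
    import copy
    out = copy.deepcopy(struct)
    for name in ("coords_N", "coords_CA", "coords_C", "coords_O", "coords_CB"):
        setattr(out, name, getattr(struct, name) @ R.T + t)
    return out
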