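import numpy as np
import pytest

from fragfit.synthetic_fixtures import (
    FixtureSpec,
    build_mini_db,
    build_toy_protein_set,
    make_experimental_map,
    make_toy_gap,
)


@pytest.fixture(scope="session")
def toy_set():
    return build_toy_protein_set(FixtureSpec(seed=5))


@pytest.fixture(scope="session")
def loop_case(toy_set):
    """A 9-residue loop gap with its mini-DB and 8 Å fixture map."""
    structure, gap = make_toy_gap("loop", 9, seed=3)
    db = build_mini_db(toy_set, gap, include_native=True, n_decoys=20, seed=13)
    exp_map = make_experimental_map(structure, resolution=8.0)
    return structure, gap, db, exp_map


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rigid(rng):
    """A uniformly random proper rotation plus a translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t
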