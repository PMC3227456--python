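import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from surfpatch import FamilySpec, Residue, SurfaceChain

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_chain(coords, types, structure_id="TST", chain_id="A") -> SurfaceChain:
    """Build a SurfaceChain directly from coordinates and one-letter types."""
    residues = [
        Residue(chain_id, i + 1, t, np.asarray(c, dtype=float))
        for i, (c, t) in enumerate(zip(coords, types))
    ]
    return SurfaceChain(structure_id, chain_id, residues)


def random_chain(rng, n=40, radius=14.0, structure_id="RND") -> SurfaceChain:
    """Random shell chain with uniform residue types, for property tests."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    coords = dirs * radius + rng.normal(scale=1.0, size=(n, 3))
    types = rng.choice(list(alphabet), size=n)
    return make_chain(coords, types, structure_id=structure_id)


def random_rigid_transform(rng, reflect=False):
    """A random rotation (optionally improper) plus translation."""
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    if reflect:
        q[:, 0] = -q[:, 0]  # improper: determinant -1
    t = rng.uniform(-50, 50, size=3)
    return q, t


def transform_chain(chain: SurfaceChain, rotation, translation) -> SurfaceChain:
    residues = [
        Residue(r.chain_id, r.residue_seq, r.residue_type,
                rotation @ r.ca_coord + translation)
        for r in chain.residues
    ]
    return SurfaceChain(chain.structure_id, chain.chain_id, residues)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_spec():
    return FamilySpec("uniform", np.full(20, 0.05), size_range=(40, 60))
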