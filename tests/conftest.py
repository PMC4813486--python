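import numpy as np
import pytest

from oligomodel.structures import AtomicStructure


def toy_structure(coords, chain_ids=None, residue_indices=None,
                  names=None, radii=None, resnames=None):
    """Small helper: build a CA-trace structure from bare coordinates."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    chain_ids = chain_ids or ["A"] * n
    residue_indices = residue_indices or list(range(1, n + 1))
    names = names or ["CA"] * n
    resnames = resnames or ["ALA"] * n
    radii = radii if radii is not None else np.full(n, 3.2)
    return AtomicStructure(coords, ["C"] * n, names, residue_indices,
                           resnames, chain_ids, radii=np.asarray(radii, float))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
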