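"""Structure model, PDB round-trips and rigid-body geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from oligomodel.structures import (AtomicStructure, RigidTransform,
                                   assembly_rmsd, ca_coordinates, read_pdb,
                                   superpose_rmsd, write_pdb)
from conftest import toy_structure


# ------------------------------------------------------- independent oracle

def horn_quaternion_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form optimal-superposition RMSD via Horn's quaternion method —
    independent of the Kabsch/SVD route used by the package."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    M = b.T @ a
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(N).max()
    sq = ((a ** 2).sum() + (b ** 2).sum() - 2 * lam) / len(a)
    return math.sqrt(max(sq, 0.0))


MINI_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
END
"""


def test_read_pdb_single_atom(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    s = read_pdb(p)
    assert len(s) == 1
    np.testing.assert_allclose(s.coords[0], [1.0, 2.0, 3.0])
    assert s.elements == ["C"]
    assert s.chain_ids == ["A"]


def test_pdb_round_trip_preserves_structure(tmp_path, rng):
    coords = rng.uniform(-40, 40, size=(100, 3))
    chains = ["A"] * 50 + ["B"] * 50
    resid = list(range(1, 51)) * 2
    s = toy_structure(coords, chain_ids=chains, residue_indices=resid)
    path = tmp_path / "out.pdb"
    write_pdb(s, path)
    back = read_pdb(path)
    assert len(back) == len(s)
    assert back.chain_ids == s.chain_ids
    assert np.abs(back.coords - s.coords).max() <= 5e-4 + 1e-12


def test_write_pdb_fixed_columns(tmp_path):
    s = toy_structure([[1.234, -5.678, 90.123]])
    path = tmp_path / "one.pdb"
    write_pdb(s, path)
    line = path.read_text().splitlines()[0]
    assert line.startswith("ATOM")
    assert float(line[30:38]) == pytest.approx(1.234)
    assert float(line[38:46]) == pytest.approx(-5.678)
    assert float(line[46:54]) == pytest.approx(90.123)


def test_write_pdb_empty_structure_ends_only(tmp_path):
    s = toy_structure(np.zeros((1, 3))).mask(np.array([], dtype=int))
    path = tmp_path / "empty.pdb"
    write_pdb(s, path)
    assert path.read_text().strip() == "END"


def test_multi_model_requires_explicit_index(tmp_path):
    text = "MODEL        1\n" + MINI_PDB.replace("END", "ENDMDL") + \
           "MODEL        2\n" + MINI_PDB.replace("END", "ENDMDL") + "END\n"
    p = tmp_path / "multi.pdb"
    p.write_text(text)
    with pytest.raises(ValueError, match="model"):
        read_pdb(p)
    s = read_pdb(p, model=1)
    assert len(s) == 1


def test_ca_coordinates_order_and_chain_filter():
    coords = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [5, 5, 5]]
    s = toy_structure(coords, chain_ids=["A", "A", "A", "B"],
                      residue_indices=[1, 2, 3, 1])
    ca = ca_coordinates(s)
    assert ca.shape == (4, 3)
    np.testing.assert_allclose(ca[:3, 0], [0, 1, 2])
    cb = ca_coordinates(s, chain="B")
    np.testing.assert_allclose(cb, [[5, 5, 5]])


def test_superpose_identical_is_zero(rng):
    a = rng.normal(size=(10, 3))
    rmsd, t = superpose_rmsd(a, a)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-6)


def test_superpose_rigid_invariance(rng):
    a = rng.normal(size=(12, 3)) * 10
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    b = a @ R.T + np.array([5.0, -3.0, 2.0])
    rmsd, t = superpose_rmsd(a, b)
    assert rmsd == pytest.approx(0.0, abs=1e-6)
    # applying the transform to b reproduces a
    np.testing.assert_allclose(t.apply(b), a, atol=1e-5)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_superpose_matches_quaternion_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(10, 3)) * 8
    b = rng.normal(size=(10, 3)) * 8
    rmsd, t = superpose_rmsd(a, b)
    assert rmsd == pytest.approx(horn_quaternion_rmsd(a, b), abs=1e-6)
    # returned transform reproduces the rmsd by plain distance
    d = a - t.apply(b)
    assert math.sqrt((d * d).sum() / len(a)) == pytest.approx(rmsd, abs=1e-6)


def test_superpose_symmetry(rng):
    a = rng.normal(size=(8, 3))
    b = rng.normal(size=(8, 3))
    assert superpose_rmsd(a, b)[0] == pytest.approx(superpose_rmsd(b, a)[0],
                                                    abs=1e-6)


def test_superpose_errors():
    with pytest.raises(ValueError):
        superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
    with pytest.raises(ValueError):
        superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


def _two_chain_assembly(offset, chain_ids=("A", "B")):
    rng = np.random.default_rng(7)
    chain = rng.normal(size=(6, 3)) * 5
    coords = np.vstack([chain, chain + offset])
    return toy_structure(coords, chain_ids=[chain_ids[0]] * 6 + [chain_ids[1]] * 6,
                         residue_indices=list(range(1, 7)) * 2)


def test_assembly_rmsd_permutation_invariance():
    a = _two_chain_assembly(np.array([20.0, 0, 0]))
    b = _two_chain_assembly(np.array([20.0, 0, 0]))
    # relabel chains: physically identical assembly
    b.chain_ids = ["B"] * 6 + ["A"] * 6
    b.subunit_labels = {"B": "B", "A": "A"}
    assert assembly_rmsd(a, b) == pytest.approx(0.0, abs=1e-6)


def test_assembly_rmsd_translation_invariance():
    a = _two_chain_assembly(np.array([20.0, 0, 0]))
    b = a.transformed(RigidTransform(np.eye(3), np.array([10.0, -4.0, 2.0])))
    assert assembly_rmsd(a, b) == pytest.approx(0.0, abs=1e-6)


def test_assembly_rmsd_equals_explicit_permutation_minimum(rng):
    a = _two_chain_assembly(np.array([20.0, 0, 0]))
    b = _two_chain_assembly(np.array([20.0, 0, 0]))
    b.coords = b.coords + rng.normal(size=b.coords.shape)
    ca = [ca_coordinates(a, c) for c in ("A", "B")]
    cb = [ca_coordinates(b, c) for c in ("A", "B")]
    direct = superpose_rmsd(np.vstack(ca), np.vstack(cb))[0]
    swapped = superpose_rmsd(np.vstack(ca), np.vstack(cb[::-1]))[0]
    assert assembly_rmsd(a, b) == pytest.approx(min(direct, swapped), abs=1e-6)
    # minimum property: never above any single assignment
    assert assembly_rmsd(a, b) <= direct + 1e-9
    assert assembly_rmsd(a, b) <= swapped + 1e-9


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000),
       angle=st.floats(-180, 180, allow_nan=False),
       tx=st.floats(-50, 50, allow_nan=False))
def test_superpose_rigid_invariance_property(seed, angle, tx):
    """RMSD(a, R·a + t) = 0 for any proper rotation R and translation t."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(6, 3)) * 10
    R = Rotation.from_euler("xyz", [angle, angle / 2, -angle / 3],
                            degrees=True).as_matrix()
    b = a @ R.T + np.array([tx, -tx / 2, 1.0])
    rmsd, _ = superpose_rmsd(a, b)
    assert rmsd <= 1e-5


def test_rigid_transform_validation():
    with pytest.raises(ValueError):
        RigidTransform(np.eye(3) * 2, np.zeros(3))
    t = RigidTransform.identity()
    np.testing.assert_allclose(t.apply(np.ones((2, 3))), np.ones((2, 3)))
    inv = t.compose(t.inverse())
    np.testing.assert_allclose(inv.rotation, np.eye(3), atol=1e-12)
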