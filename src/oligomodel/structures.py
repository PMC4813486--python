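"""Atomic structure data model, PDB I/O and rigid-body geometry.

Structures are stored struct-of-arrays (coordinates and collision radii as
numpy arrays, per-atom metadata as lists) because every downstream operation
— collision-cross-section estimation, clash rejection, superposition — is a
whole-array computation.  Chains are grouped into *subunits*: the rigid units
of an assembly (a domain-swapped dimer used as a building block is one
subunit of two chains).  Cross-link restraints are classified intra/inter
with respect to subunits, not chains.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

import gemmi

logger = logging.getLogger(__name__)

#: Hard-sphere collision radii (Å) for collisions with helium buffer gas,
#: MOBCAL-style projection-approximation values.  Configurable per call.
DEFAULT_COLLISION_RADII: dict[str, float] = {
    "H": 2.2,
    "C": 2.7,
    "N": 2.7,
    "O": 2.7,
    "S": 3.5,
    "P": 3.5,
}
FALLBACK_COLLISION_RADIUS = 2.7

#: Approximate atomic masses (Da) used as rasterization amplitudes.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.97, "FE": 55.845, "ZN": 65.38,
}


@dataclass(frozen=True)
class Atom:
    """A single atom with its collision radius (Å, from the element table)."""

    element: str
    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    collision_radius: float

    def __post_init__(self) -> None:
        if not self.collision_radius > 0:
            raise ValueError(f"collision_radius must be > 0, got {self.collision_radius}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation then translation, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = 1)")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


class AtomicStructure:
    """An ordered collection of atoms grouped into chains and subunits.

    Parameters
    ----------
    coords : (N, 3) array of Å positions.
    elements, names, residue_indices, residue_names, chain_ids : per-atom metadata.
    radii : per-atom collision radii (Å); derived from ``DEFAULT_COLLISION_RADII``
        when omitted.
    subunit_labels : mapping chain_id → subunit label; defaults to one subunit
        per chain.
    source_id : free-text provenance (e.g. a PDB ID).
    """

    def __init__(
        self,
        coords: np.ndarray,
        elements: Sequence[str],
        names: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        radii: np.ndarray | None = None,
        subunit_labels: dict[str, str] | None = None,
        source_id: str = "",
    ) -> None:
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        self.elements = [e.upper() for e in elements]
        self.names = list(names)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = list(residue_names)
        self.chain_ids = list(chain_ids)
        if not (len(self.elements) == len(self.names) == len(self.residue_indices)
                == len(self.residue_names) == len(self.chain_ids) == n):
            raise ValueError("per-atom field lengths disagree")
        if radii is None:
            radii = np.array([
                DEFAULT_COLLISION_RADII.get(e, FALLBACK_COLLISION_RADIUS)
                for e in self.elements
            ])
        self.radii = np.asarray(radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("collision radii must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        chains = self.chains()
        if subunit_labels is None:
            subunit_labels = {c: c for c in chains}
        missing = [c for c in chains if c not in subunit_labels]
        if missing:
            raise ValueError(f"subunit_labels missing chains {missing}")
        self.subunit_labels = dict(subunit_labels)
        self.source_id = source_id

    # ------------------------------------------------------------------ basics

    def __len__(self) -> int:
        return len(self.coords)

    def chains(self) -> list[str]:
        """Chain ids in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    def subunits(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chains():
            seen.setdefault(self.subunit_labels[c])
        return list(seen)

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(self.elements[i], self.names[i], int(self.residue_indices[i]),
                 self.residue_names[i], self.chain_ids[i], self.coords[i],
                 float(self.radii[i]))
            for i in range(len(self))
        ]

    def mask(self, keep: np.ndarray) -> "AtomicStructure":
        keep = np.asarray(keep)
        idx = np.nonzero(keep)[0] if keep.dtype == bool else keep
        sub_chains = {self.chain_ids[i] for i in idx}
        return AtomicStructure(
            self.coords[idx],
            [self.elements[i] for i in idx],
            [self.names[i] for i in idx],
            self.residue_indices[idx],
            [self.residue_names[i] for i in idx],
            [self.chain_ids[i] for i in idx],
            radii=self.radii[idx],
            subunit_labels={c: self.subunit_labels[c] for c in sub_chains},
            source_id=self.source_id,
        )

    def select_chain(self, chain_id: str) -> "AtomicStructure":
        m = np.array([c == chain_id for c in self.chain_ids])
        if not m.any():
            raise ValueError(f"no chain {chain_id!r} in structure")
        return self.mask(m)

    def transformed(self, t: RigidTransform) -> "AtomicStructure":
        out = self.copy()
        out.coords = t.apply(self.coords)
        return out

    def copy(self) -> "AtomicStructure":
        return AtomicStructure(
            self.coords.copy(), list(self.elements), list(self.names),
            self.residue_indices.copy(), list(self.residue_names),
            list(self.chain_ids), radii=self.radii.copy(),
            subunit_labels=dict(self.subunit_labels), source_id=self.source_id,
        )

    def ca_lookup(self) -> dict[tuple[str, int], np.ndarray]:
        """(chain_id, residue_index) → Cα position; built once per instance."""
        cache = getattr(self, "_ca_cache", None)
        if cache is None:
            cache = {}
            for i in range(len(self)):
                if self.names[i].strip() == "CA":
                    cache.setdefault(
                        (self.chain_ids[i], int(self.residue_indices[i])),
                        self.coords[i])
            self._ca_cache = cache
        return cache

    def has_hydrogens(self) -> bool:
        return any(e == "H" for e in self.elements)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, 12.011) for e in self.elements])

    def chain_sequence(self, chain_id: str) -> tuple[str, ...]:
        """Residue-name sequence of a chain (one entry per residue)."""
        seq: list[str] = []
        last = None
        for i, c in enumerate(self.chain_ids):
            if c != chain_id:
                continue
            key = int(self.residue_indices[i])
            if key != last:
                seq.append(self.residue_names[i])
                last = key
        return tuple(seq)

    # --------------------------------------------------------------- assembly

    @classmethod
    def concat(cls, parts: Iterable["AtomicStructure"],
               relabel_chains: bool = True,
               subunit_per_part: bool = True) -> "AtomicStructure":
        """Merge structures into one assembly.

        With ``relabel_chains`` the chains are renamed A, B, C, … in order;
        with ``subunit_per_part`` each input part becomes one subunit (the
        rigid-unit bookkeeping used by restraint classification).
        """
        parts = list(parts)
        letters = [chr(ord("A") + i) for i in range(26)]
        coords, elements, names, ridx, rnames, cids = [], [], [], [], [], []
        sublab: dict[str, str] = {}
        radii = []
        next_chain = 0
        for pi, p in enumerate(parts):
            mapping = {}
            for c in p.chains():
                if relabel_chains:
                    mapping[c] = letters[next_chain]
                    next_chain += 1
                else:
                    mapping[c] = c
            for c, new in mapping.items():
                sublab[new] = f"u{pi}" if subunit_per_part else p.subunit_labels[c]
            coords.append(p.coords)
            elements += p.elements
            names += p.names
            ridx.append(p.residue_indices)
            rnames += p.residue_names
            cids += [mapping[c] for c in p.chain_ids]
            radii.append(p.radii)
        return cls(np.vstack(coords), elements, names, np.concatenate(ridx),
                   rnames, cids, radii=np.concatenate(radii),
                   subunit_labels=sublab)


# -------------------------------------------------------------------- PDB I/O

def read_pdb(path: str | Path, model: int | None = None,
             radii_table: dict[str, float] | None = None) -> AtomicStructure:
    """Read ATOM/HETATM records of a PDB file into an :class:`AtomicStructure`.

    Multi-model files (NMR ensembles) require an explicit 1-based ``model``
    index; single-model files need none.  Elements come from columns 77–78
    with an atom-name fallback, collision radii from ``radii_table``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise IOError(f"no models in {path}")
    if len(st) > 1 and model is None:
        raise ValueError(
            f"{path} contains {len(st)} models; pass an explicit 1-based "
            "model index (e.g. model=1)")
    mdl = st[0] if model is None else st[model - 1]
    table = radii_table or DEFAULT_COLLISION_RADII
    coords, elements, names, ridx, rnames, cids = [], [], [], [], [], []
    for chain in mdl:
        for res in chain:
            for atom in res:
                el = atom.element.name.upper()
                if not el or el == "X":
                    el = _element_from_name(atom.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(el)
                names.append(atom.name)
                ridx.append(res.seqid.num)
                rnames.append(res.name)
                cids.append(chain.name)
    if not coords:
        raise IOError(f"no atoms parsed from {path}")
    radii = np.array([table.get(e, FALLBACK_COLLISION_RADIUS) for e in elements])
    return AtomicStructure(np.array(coords), elements, names, ridx, rnames,
                           cids, radii=radii, source_id=path.stem)


def _element_from_name(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def write_pdb(s: AtomicStructure, path: str | Path) -> None:
    """Write fixed-width PDB ATOM records (wwPDB v3.3 layout, 3-decimal Å)."""
    if not np.all(np.isfinite(s.coords)):
        raise ValueError("cannot write non-finite coordinates")
    lines = []
    serial = 0
    prev_chain = None
    for i in range(len(s)):
        chain = s.chain_ids[i]
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        name = s.names[i]
        # atom-name column convention: 1/2-letter elements start at col 14/13
        if len(name) < 4:
            name_field = f" {name:<3s}" if len(s.elements[i]) == 1 else f"{name:<4s}"
        else:
            name_field = name[:4]
        x, y, z = s.coords[i]
        lines.append(
            f"ATOM  {serial % 100000:5d} {name_field} {s.residue_names[i]:<3s} "
            f"{chain[:1]}{int(s.residue_indices[i]) % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{s.elements[i]:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------- geometry

def ca_coordinates(s: AtomicStructure, chain: str | None = None) -> np.ndarray:
    """Cα coordinates, one per residue in residue order.

    Residues lacking a Cα are skipped with a logged warning.
    """
    sel = s if chain is None else s.select_chain(chain)
    out = []
    seen: set[tuple[str, int]] = set()
    is_ca = [n.strip() == "CA" for n in sel.names]
    residues_with_ca = set()
    for i in range(len(sel)):
        key = (sel.chain_ids[i], int(sel.residue_indices[i]))
        if is_ca[i] and key not in seen:
            seen.add(key)
            residues_with_ca.add(key)
            out.append(sel.coords[i])
    all_res = {(sel.chain_ids[i], int(sel.residue_indices[i])) for i in range(len(sel))}
    missing = all_res - residues_with_ca
    if missing:
        logger.warning("%d residue(s) lack a CA atom and were skipped", len(missing))
    if not out:
        raise ValueError("structure contains no CA atoms")
    return np.array(out)


def superpose_rmsd(a: np.ndarray, b: np.ndarray) -> tuple[float, RigidTransform]:
    """Least-squares (Kabsch) superposition of ``b`` onto ``a``.

    Returns the minimal RMSD and the rigid transform T with
    RMSD(a, T(b)) equal to it.
    """
    from scipy.spatial.transform import Rotation

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 points for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(np.vstack([a0, b0])) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    rot, rssd = Rotation.align_vectors(a0, b0)
    rmsd = float(rssd / math.sqrt(len(a)))
    R = rot.as_matrix()
    t = ca - R @ cb
    return rmsd, RigidTransform(R, t)


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a) - np.asarray(b)
    return float(np.sqrt((d * d).sum() / len(d)))


def assembly_rmsd(a: AtomicStructure, b: AtomicStructure) -> float:
    """Minimum Cα RMSD between two assemblies over chain relabelings.

    Chains of identical residue sequence are interchangeable: the RMSD is the
    minimum of the superposed Cα RMSD over all permutations of ``b``'s chains
    within each identical-sequence group (exhaustive — assemblies here have
    ≤ 4–6 chains).
    """
    ca_chains = a.chains()
    cb_chains = b.chains()
    if len(ca_chains) != len(cb_chains):
        raise ValueError("assemblies have different numbers of chains")
    seq_a = {c: a.chain_sequence(c) for c in ca_chains}
    seq_b = {c: b.chain_sequence(c) for c in cb_chains}
    groups_a: dict[tuple, list[str]] = {}
    for c in ca_chains:
        groups_a.setdefault(seq_a[c], []).append(c)
    groups_b: dict[tuple, list[str]] = {}
    for c in cb_chains:
        groups_b.setdefault(seq_b[c], []).append(c)
    if {k: len(v) for k, v in groups_a.items()} != {k: len(v) for k, v in groups_b.items()}:
        raise ValueError("incompatible chain compositions")

    coords_a = np.vstack([ca_coordinates(a, c) for c in ca_chains])
    cb_coords = {c: ca_coordinates(b, c) for c in cb_chains}

    # per-group permutations of b's chains, combined
    group_keys = [seq_a[c] for c in ca_chains]
    best = math.inf
    perms_per_group = {k: list(itertools.permutations(groups_b[k])) for k in groups_a}
    for combo in itertools.product(*[perms_per_group[k] for k in groups_a]):
        assignment: dict[tuple, Iterable[str]] = dict(zip(groups_a.keys(), combo))
        iters = {k: iter(v) for k, v in assignment.items()}
        order = [next(iters[k]) for k in group_keys]
        coords_b = np.vstack([cb_coords[c] for c in order])
        if len(coords_b) != len(coords_a):
            raise ValueError("chain CA counts differ between assemblies")
        rmsd, _ = superpose_rmsd(coords_a, coords_b)
        best = min(best, rmsd)
    return best
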