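"""Chemical cross-linking records, distance mapping and validation arithmetic.

BS3 (bis[sulfosuccinimidyl] suberate) links lysine ε-amines (and protein
N-termini) that sit close in space; a link is compatible with a structure
when the Cα–Cα distance of the two linked residues is within an upper bound
(35 Å by default).  Cross-links identified in an oligomer band are either
*intra* (satisfiable within one rigid reference unit, e.g. a domain-swapped
dimer) or *inter* (must bridge two units); classification is by measuring
distances on the reference structure.

A 1:1 light/heavy (d0/d4) BS3 mixture produces diagnostic isotopic peak
pairs in MS1; :func:`peak_pair_valid` checks a candidate pair against the
expected mass shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .structures import AtomicStructure

PROTON_MASS = 1.007276466  # Da

Band = Literal["monomer", "dimer", "trimer", "tetramer"]


@dataclass
class CrossLink:
    """A residue-pair cross-link restraint with oligomer-band provenance.

    ``ambiguous`` marks loop-link rows where the linked residue could not be
    localized between two candidate positions (e.g. "110/113"); such records
    are kept for bookkeeping but never used as modeling restraints.
    """

    residue_1: int
    residue_2: int
    band: str
    n_spectra: int = 0
    classification: Literal["unknown", "intra", "inter"] = "unknown"
    is_unique_interprotein: bool = False
    ambiguous: bool = False
    peptide_1: str = ""
    peptide_2: str = ""

    def __post_init__(self) -> None:
        if self.residue_1 < 1 or self.residue_2 < 1:
            raise ValueError("residue indices must be >= 1")
        if self.n_spectra < 0:
            raise ValueError("n_spectra must be >= 0")


@dataclass(frozen=True)
class XlChemistry:
    """Cross-linker chemistry: isotopic mass shift and distance bound."""

    name: str = "BS3"
    heavy_light_mass_delta: float = 4.02511  # Da, 4 x (2H - 1H)
    max_ca_distance: float = 35.0  # Å upper bound for a satisfied link

    def __post_init__(self) -> None:
        if self.max_ca_distance <= 0:
            raise ValueError("max_ca_distance must be > 0")
        if self.heavy_light_mass_delta <= 0:
            raise ValueError("heavy_light_mass_delta must be > 0")


def _overlapping(p1: str, p2: str) -> bool:
    if not p1 or not p2:
        return False
    a = p1.replace("H2N-", "")
    b = p2.replace("H2N-", "")
    return a in b or b in a


def parse_crosslink_table(path: str | Path) -> list[CrossLink]:
    """Parse a cross-link table (TSV/CSV with header
    ``band,residue_1,residue_2,n_spectra[,peptide_1,peptide_2]``).

    Loop-link rows whose residue field holds two candidates ("110/113") are
    expanded into a single ambiguous record carrying both positions; they are
    flagged and excluded from restraint use.  Dipeptides with identical or
    overlapping sequences are marked as unambiguously interprotein.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"band", "residue_1", "residue_2", "n_spectra"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out: list[CrossLink] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        band = row.band.strip()
        r1_raw, r2_raw = row.residue_1.strip(), row.residue_2.strip()
        p1 = getattr(row, "peptide_1", "").strip()
        p2 = getattr(row, "peptide_2", "").strip()
        try:
            n_spec = int(row.n_spectra)
            if "/" in r1_raw:
                a, b = (int(x) for x in r1_raw.split("/"))
                xl = CrossLink(a, b, band, n_spec, ambiguous=True,
                               peptide_1=p1, peptide_2=p2)
            else:
                r1 = int(r1_raw)
                r2 = int(r2_raw) if r2_raw else r1
                xl = CrossLink(r1, r2, band, n_spec, peptide_1=p1, peptide_2=p2)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {lineno}: malformed row ({exc})") from exc
        if not xl.ambiguous and band != "monomer" and _overlapping(p1, p2):
            xl.is_unique_interprotein = True
            xl.classification = "inter"
        out.append(xl)
    return out


def packaged_crosslink_table(variant: str = "dn6") -> list[CrossLink]:
    """The identified cross-links shipped with the package.

    ``variant`` selects the truncated ("dn6") or full-length ("b2m")
    β2-microglobulin table.
    """
    fname = {"dn6": "crosslinks_dn6.tsv", "b2m": "crosslinks_b2m.tsv"}[variant]
    with resources.as_file(resources.files("oligomodel.data") / fname) as p:
        return parse_crosslink_table(p)


def peak_pair_valid(mz_light: float, mz_heavy: float, charge: int,
                    chem: XlChemistry, tol_ppm: float = 10.0) -> bool:
    """Whether a light/heavy m/z pair matches the d0/d4 mass shift.

    The measured neutral-mass difference ``(mz_heavy − mz_light)·z`` must
    equal the chemistry's heavy−light delta within ``tol_ppm`` of the light
    species' neutral mass (inclusive bound).
    """
    if mz_light <= 0 or mz_heavy <= 0:
        raise ValueError("m/z values must be positive")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    neutral_mass = (mz_light - PROTON_MASS) * charge
    measured_delta = (mz_heavy - mz_light) * charge
    tol = tol_ppm * 1e-6 * neutral_mass
    # inclusive bound with a float-representation guard
    return abs(measured_delta - chem.heavy_light_mass_delta) <= tol * (1 + 1e-9)


def _ca_position(s: AtomicStructure, res: int, chain: str) -> np.ndarray:
    pos = s.ca_lookup().get((chain, res))
    if pos is None:
        raise ValueError(f"residue {res} of chain {chain} has no CA atom")
    return pos


def ca_distance(s: AtomicStructure, res1: int, chain1: str,
                res2: int, chain2: str) -> float:
    """Euclidean Cα–Cα distance (Å) between two residues."""
    a = _ca_position(s, res1, chain1)
    b = _ca_position(s, res2, chain2)
    return float(np.linalg.norm(a - b))


def min_link_distance(s: AtomicStructure, xl: CrossLink,
                      chain_pairs: list[tuple[str, str]] | None = None) -> float:
    """Minimum Cα–Cα distance of a link over eligible chain assignments.

    A homotypic link (residue i to residue i) is never measured within one
    chain copy — the zero distance of a residue to itself is not a physical
    assignment.
    """
    chains = s.chains()
    if chain_pairs is None:
        chain_pairs = [(c1, c2) for c1 in chains for c2 in chains]
    if xl.residue_1 == xl.residue_2:
        chain_pairs = [(c1, c2) for c1, c2 in chain_pairs if c1 != c2]
    best = math.inf
    err: Exception | None = None
    for c1, c2 in chain_pairs:
        try:
            best = min(best, ca_distance(s, xl.residue_1, c1, xl.residue_2, c2))
        except ValueError as exc:
            err = exc
    if math.isinf(best):
        raise ValueError(
            f"link {xl.residue_1}-{xl.residue_2} unresolvable on structure"
            + (f": {err}" if err else ""))
    return best


def classify_crosslink(ref: AtomicStructure, xl: CrossLink,
                       chem: XlChemistry | None = None) -> str:
    """Classify a link as intra or inter against a rigid reference unit.

    *intra* iff the minimum Cα–Cα distance over chain assignments within the
    reference is ≤ the chemistry's distance bound (inclusive); otherwise the
    link must arise between copies of the reference (*inter*).  Interprotein
    links bridge two protein copies by definition, so on a multi-chain
    reference only distinct-chain assignments are considered (a homotypic
    link such as K110:K110 would otherwise trivially measure 0 Å onto
    itself).
    """
    chem = chem or XlChemistry()
    chains = ref.chains()
    pairs = None
    if len(chains) > 1:
        pairs = [(c1, c2) for c1 in chains for c2 in chains if c1 != c2]
    d = min_link_distance(ref, xl, pairs)
    return "intra" if d <= chem.max_ca_distance else "inter"


def validation_fdr(n_potential: int, n_validated: int) -> float:
    """Percent of potential cross-link hits that failed validation."""
    if n_potential <= 0:
        raise ValueError("n_potential must be > 0")
    if not 0 <= n_validated <= n_potential:
        raise ValueError("need 0 <= n_validated <= n_potential")
    return 100.0 * (n_potential - n_validated) / n_potential
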