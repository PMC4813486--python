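"""Restraint terms and the combined scoring function.

Candidate assemblies are evaluated against three experimental restraints:

* ``S_IM-MS`` — a harmonic penalty on the deviation of the model's scaled PA
  collision cross-section from the ion-mobility target, normalized by the
  method's predictive accuracy (±3% of the target), so a model off by one
  "experimental error" scores 1.
* ``S_CX-MS`` — a flat-bottom upper-bound penalty per cross-link: zero while
  the link's best-assignment Cα–Cα distance is within the linker bound
  (35 Å for BS3), growing quadratically beyond it; averaged over links.
* ``S_EM`` — one minus the cross-correlation between the model's simulated
  density and the experimental map segment.

The total score is the weighted sum S = W·(S_IM-MS, S_CX-MS, S_EM) with
default weights 1:2:2.  Lower is better; the planted/true structure should
score near zero on noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ccs as ccs_mod
from .ccs import CcsParams, CcsValue
from .density import DensityGrid, cross_correlation, rasterize
from .structures import AtomicStructure
from .xlinks import CrossLink, XlChemistry, min_link_distance


@dataclass(frozen=True)
class RestraintWeights:
    """Relative weights of the three restraint classes (default 1:2:2)."""

    w_imms: float = 1.0
    w_cxms: float = 2.0
    w_em: float = 2.0

    def __post_init__(self) -> None:
        if self.w_imms < 0 or self.w_cxms < 0 or self.w_em < 0:
            raise ValueError("restraint weights must be >= 0")


@dataclass(frozen=True)
class ScoreBreakdown:
    s_imms: float
    s_cxms: float
    s_em: float
    total: float


def score_imms(model_ccs: float, target_ccs: float,
               tolerance: float = 0.03) -> float:
    """Harmonic CCS restraint: ((model − target) / (tolerance·target))²."""
    if target_ccs <= 0:
        raise ValueError("target CCS must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    z = (model_ccs - target_ccs) / (tolerance * target_ccs)
    return float(z * z)


def _eligible_chain_pairs(model: AtomicStructure,
                          classification: str) -> list[tuple[str, str]]:
    chains = model.chains()
    sub = model.subunit_labels
    pairs = []
    for c1 in chains:
        for c2 in chains:
            same_unit = sub[c1] == sub[c2]
            if classification == "intra" and not same_unit:
                continue
            if classification == "inter" and same_unit:
                continue
            pairs.append((c1, c2))
    return pairs


def score_cxms(model: AtomicStructure, links: list[CrossLink],
               chem: XlChemistry | None = None) -> float:
    """Flat-bottom cross-link penalty averaged over usable links.

    Each link is measured at its minimum Cα–Cα distance over chain
    assignments eligible for its class ("inter" links over inter-subunit
    pairs, "intra" within subunits, "unknown" over all pairs).  Ambiguous
    loop-links never contribute.
    """
    chem = chem or XlChemistry()
    usable = [xl for xl in links if not xl.ambiguous]
    if not usable:
        return 0.0
    d0 = chem.max_ca_distance
    penalties = []
    for xl in usable:
        pairs = _eligible_chain_pairs(model, xl.classification)
        if not pairs:
            raise ValueError(
                f"link {xl.residue_1}-{xl.residue_2} ({xl.classification}): "
                "no eligible chain pairs on this model")
        d = min_link_distance(model, xl, pairs)
        penalties.append(0.0 if d <= d0 else ((d - d0) / d0) ** 2)
    return float(np.mean(penalties))


def score_em(model, seg: DensityGrid, resolution: float | None = None,
             lowpass: bool = False) -> float:
    """Volume restraint 1 − CCC(rasterized model, map segment) ∈ [0, 2].

    With ``lowpass`` both maps pass a matched Gaussian filter at the nominal
    resolution before correlation (suppresses voxel-scale noise).
    """
    from .density import lowpass_filter

    res = resolution if resolution is not None else seg.resolution
    sim = rasterize(model, seg, res)
    if lowpass:
        sim = lowpass_filter(sim, res)
        seg = lowpass_filter(seg, res)
    return max(1.0 - cross_correlation(sim, seg), 0.0)


def total_score(s_imms: float | None, s_cxms: float | None,
                s_em: float | None,
                w: RestraintWeights | None = None) -> ScoreBreakdown:
    """Weighted sum of restraint terms; absent restraints contribute zero."""
    w = w or RestraintWeights()
    si = 0.0 if s_imms is None else float(s_imms)
    sc = 0.0 if s_cxms is None else float(s_cxms)
    se = 0.0 if s_em is None else float(s_em)
    if min(si, sc, se) < 0:
        raise ValueError("component scores must be >= 0")
    total = w.w_imms * si + w.w_cxms * sc + w.w_em * se
    return ScoreBreakdown(si, sc, se, total)


@dataclass
class ScoringConfig:
    """Everything needed to score a candidate assembly.

    ``em_segment=None`` drops the EM term (the trimer workflow uses IM-MS and
    CX-MS only; the map segment is a tetramer-only restraint).
    """

    ccs_target: float | None = None
    ccs_tolerance: float = 0.03
    links: list[CrossLink] = field(default_factory=list)
    chem: XlChemistry = field(default_factory=XlChemistry)
    em_segment: DensityGrid | None = None
    em_lowpass: bool = False  # optional matched filter; costs effective resolution
    weights: RestraintWeights = field(default_factory=RestraintWeights)
    ccs_params: CcsParams | None = None

    def _filtered_segment(self) -> DensityGrid:
        from .density import lowpass_filter

        cached = getattr(self, "_seg_cache", None)
        if cached is None:
            cached = lowpass_filter(self.em_segment)
            self._seg_cache = cached
        return cached

    def score_structure(self, model: AtomicStructure) -> ScoreBreakdown:
        from .density import lowpass_filter

        si = None
        if self.ccs_target is not None:
            params = self.ccs_params or ccs_mod.atomic_ccs_params()
            val = ccs_mod.pa_ccs(model, params)
            si = score_imms(val.scaled, self.ccs_target, self.ccs_tolerance)
        sc = score_cxms(model, self.links, self.chem) if self.links else None
        se = None
        if self.em_segment is not None:
            if self.em_lowpass:
                seg = self._filtered_segment()
                sim = lowpass_filter(
                    rasterize(model, seg, seg.resolution), seg.resolution)
                se = max(1.0 - cross_correlation(sim, seg), 0.0)
            else:
                se = score_em(model, self.em_segment)
        return total_score(si, sc, se, self.weights)
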