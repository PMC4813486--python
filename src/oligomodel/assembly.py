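"""Candidate-model generation, top-fraction selection and clustering.

Two samplers mirror the two modeling stages:

* a coarse-grained builder that grows an oligomer of identical spheres one
  subunit at a time, choosing at each stage the placement whose sphere-model
  CCS best matches the measured CCS of the (n+1)-mer, followed by a Monte
  Carlo search for the last subunit of the tetramer;
* an atomic rigid-body sampler that places a mobile unit (monomer or dimer)
  at uniformly random orientations against fixed units, rejects clashes, and
  scores every accepted model with the full restraint set.

Sampling is generate-and-score: a fixed number of independent random
placements, each scored, rather than a Metropolis chain — reproducible from
a single seed and embarrassingly parallel.  The lowest-scoring fraction of
the ensemble (1% by default) is clustered by leader clustering at an
assembly-RMSD threshold (5 Å by default); each cluster's representative is
its lowest-scoring member.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .ccs import CcsParams, pa_ccs_spheres, sphere_radius_from_ccs
from .scoring import (RestraintWeights, ScoreBreakdown, ScoringConfig,
                      score_imms, total_score)
from .structures import (AtomicStructure, RigidTransform, assembly_rmsd,
                         superpose_rmsd)

SPHERE_MIN_SEPARATION_FACTOR = 1.2  # centers closer than 1.2 r overlap > 40%


@dataclass
class SphereModel:
    """Coarse-grained assembly: n equal spheres (common radius, Å)."""

    centers: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")

    @property
    def n_subunits(self) -> int:
        return len(self.centers)

    def with_sphere(self, center: np.ndarray) -> "SphereModel":
        return SphereModel(np.vstack([self.centers, center]), self.radius)


@dataclass(frozen=True)
class SamplerConfig:
    """Monte Carlo sampling budget and placement geometry."""

    n_models: int = 10_000
    rng_seed: int = 0
    max_translation: float = 50.0
    clash_min_distance: float = 2.5  # Å, inter-unit heavy-atom minimum
    placement_shell: tuple[float, float] = (3.0, 10.0)  # Å anchor-atom gap

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.clash_min_distance <= 0:
            raise ValueError("clash_min_distance must be > 0")


@dataclass
class ScoredModel:
    """A candidate assembly with its restraint-score breakdown."""

    model: object  # AtomicStructure | SphereModel
    scores: ScoreBreakdown
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClusteringParams:
    top_fraction: float = 0.01
    rmsd_threshold: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be > 0")


@dataclass
class Cluster:
    members: list[ScoredModel]
    representative: ScoredModel
    fraction: float


@dataclass(frozen=True)
class CoarseGrid:
    """Distance × spherical-angle grid for stepwise sphere placement.

    Distances are measured from the centroid of the current model in units
    of the sphere radius; angles step over the full sphere of directions.
    """

    d_min_factor: float = 1.2
    d_max_factor: float = 4.0
    d_step_factor: float = 0.1
    angle_step_deg: float = 15.0

    def directions(self) -> np.ndarray:
        step = math.radians(self.angle_step_deg)
        dirs = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
        n_theta = int(round(math.pi / step))
        for i in range(1, n_theta):
            theta = i * step
            n_phi = max(int(round(2 * math.pi / step)), 1)
            for j in range(n_phi):
                phi = j * step
                dirs.append(np.array([
                    math.sin(theta) * math.cos(phi),
                    math.sin(theta) * math.sin(phi),
                    math.cos(theta)]))
        return np.array(dirs)

    def distances(self, radius: float) -> np.ndarray:
        return np.arange(self.d_min_factor, self.d_max_factor + 1e-9,
                         self.d_step_factor) * radius


def _sphere_clash(centers: np.ndarray, candidate: np.ndarray,
                  radius: float) -> bool:
    d = np.linalg.norm(centers - candidate, axis=1)
    return bool(np.any(d < SPHERE_MIN_SEPARATION_FACTOR * radius))


def _score_sphere_model(m: SphereModel, target_ccs: float, p: CcsParams,
                        weights: RestraintWeights) -> ScoreBreakdown:
    val = pa_ccs_spheres(m, p)
    si = score_imms(val.scaled, target_ccs)
    return total_score(si, None, None, weights)


def build_coarse_stepwise(monomer_ccs: float,
                          oligomer_ccs_targets: dict[int, float],
                          grid: CoarseGrid | None = None,
                          p: CcsParams | None = None,
                          weights: RestraintWeights | None = None,
                          ) -> dict[int, ScoredModel]:
    """Greedy stepwise coarse-grained assembly.

    The monomer is a single sphere whose radius reproduces the measured
    monomer CCS.  For each requested oligomer size n (ascending), every
    placement of one further sphere on a distance × direction grid around
    the current model is scored against the n-mer CCS target and the best
    is kept as the seed for the next stage.  Deterministic given the grid
    and CCS sampling seed (common random numbers across candidates).
    """
    grid = grid or CoarseGrid()
    p = p or CcsParams(target_rel_stderr=None)
    weights = weights or RestraintWeights()
    radius = sphere_radius_from_ccs(monomer_ccs, p.probe_radius)
    model = SphereModel(np.zeros((1, 3)), radius)
    out: dict[int, ScoredModel] = {}
    dirs = grid.directions()
    for n in sorted(oligomer_ccs_targets):
        if n < 2:
            continue
        if model.n_subunits != n - 1:
            raise ValueError(
                f"targets must be contiguous: cannot build {n}-mer from "
                f"{model.n_subunits}-mer")
        target = oligomer_ccs_targets[n]
        centroid = model.centers.mean(axis=0)
        best: tuple[float, SphereModel] | None = None
        for d in grid.distances(radius):
            for u in dirs:
                cand = centroid + d * u
                if _sphere_clash(model.centers, cand, radius):
                    continue
                cand_model = model.with_sphere(cand)
                scores = _score_sphere_model(cand_model, target, p, weights)
                if best is None or scores.total < best[0]:
                    best = (scores.total, cand_model)
        if best is None:
            raise RuntimeError(
                f"no clash-free placement found for the {n}-mer; widen the grid")
        model = best[1]
        out[n] = ScoredModel(model, _score_sphere_model(model, target, p, weights),
                             provenance={"stage": n, "grid": grid})
    return out


def sample_tetramer_coarse(fixed: SphereModel, target_ccs: float,
                           cfg: SamplerConfig, p: CcsParams | None = None,
                           weights: RestraintWeights | None = None,
                           ) -> list[ScoredModel]:
    """Monte Carlo placement of the fourth sphere against a fixed trimer."""
    if fixed.n_subunits != 3:
        raise ValueError("fixed model must have exactly 3 spheres")
    p = p or CcsParams(target_rel_stderr=None)
    weights = weights or RestraintWeights()
    rng = np.random.default_rng(cfg.rng_seed)
    r = fixed.radius
    out: list[ScoredModel] = []
    trials = 0
    max_trials = max(100 * cfg.n_models, 1000)
    while len(out) < cfg.n_models:
        trials += 1
        if trials > max_trials:
            raise RuntimeError(
                f"placement failure rate too high: {len(out)} accepted in "
                f"{trials} trials")
        anchor = fixed.centers[rng.integers(3)]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        gap = rng.uniform(*cfg.placement_shell)
        cand = anchor + u * (2 * r + gap)
        if _sphere_clash(fixed.centers, cand, r):
            continue
        m = fixed.with_sphere(cand)
        out.append(ScoredModel(m, _score_sphere_model(m, target_ccs, p, weights),
                               provenance={"index": len(out), "trial": trials,
                                           "seed": cfg.rng_seed}))
    return out


def sample_rigid_assembly(fixed_units: Sequence[AtomicStructure],
                          mobile_unit: AtomicStructure,
                          restraints: ScoringConfig,
                          cfg: SamplerConfig) -> list[ScoredModel]:
    """Rigid-body Monte Carlo assembly at atomic resolution.

    The mobile unit is rotated uniformly at random about its centroid and
    anchored near a random surface atom of the fixed units (anchor-atom gap
    drawn from ``placement_shell``).  Placements with any inter-unit atom
    pair closer than ``clash_min_distance`` are rejected; accepted models
    are scored with the configured restraints.
    """
    from scipy.spatial.transform import Rotation

    fixed_assembly = AtomicStructure.concat(fixed_units)
    fixed_coords = fixed_assembly.coords
    mob_coords0 = mobile_unit.coords - mobile_unit.coords.mean(axis=0)
    rng = np.random.default_rng(cfg.rng_seed)
    out: list[ScoredModel] = []
    trials = 0
    max_trials = max(100 * cfg.n_models, 1000)
    while len(out) < cfg.n_models:
        trials += 1
        if trials > max_trials:
            raise RuntimeError(
                f"acceptance starvation: {len(out)} models in {trials} trials "
                f"(clash_min_distance={cfg.clash_min_distance}, "
                f"placement_shell={cfg.placement_shell})")
        q = rng.normal(size=4)
        R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
        rotated = mob_coords0 @ R.T
        f_idx = rng.integers(len(fixed_coords))
        m_idx = rng.integers(len(rotated))
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        gap = rng.uniform(*cfg.placement_shell)
        t = fixed_coords[f_idx] + u * gap - rotated[m_idx]
        placed = rotated + t
        dmin = _min_interdistance(fixed_coords, placed)
        if dmin < cfg.clash_min_distance:
            continue
        centroid = mobile_unit.coords.mean(axis=0)
        transform = RigidTransform(R, t - R @ centroid)
        mobile_placed = mobile_unit.copy()
        mobile_placed.coords = placed
        assembly = AtomicStructure.concat(list(fixed_units) + [mobile_placed])
        scores = restraints.score_structure(assembly)
        out.append(ScoredModel(assembly, scores,
                               provenance={"index": len(out), "trial": trials,
                                           "seed": cfg.rng_seed,
                                           "transform": transform}))
    return out


def _min_interdistance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(a)
    d, _ = tree.query(b, k=1)
    return float(d.min())


@dataclass(frozen=True)
class RefinementConfig:
    """Two-phase rigid-pose Monte Carlo refinement of selected models.

    Exploration holds a fixed temperature with large proposals to hop
    between basins; the anneal phase restarts from the best pose found and
    quenches temperature and proposal sizes to zero.  Temperatures are in
    score units.
    """

    n_explore: int = 120
    n_anneal: int = 180
    t_explore: float = 0.25
    t_anneal_start: float = 0.05
    rot_explore_deg: float = 20.0
    trans_explore: float = 4.5
    rot_final_deg: float = 0.5
    trans_final: float = 0.1
    clash_min_distance: float = 2.5
    rng_seed: int = 0


def refine_rigid(model: AtomicStructure, n_fixed_atoms: int,
                 restraints: ScoringConfig, cfg: RefinementConfig,
                 rng: np.random.Generator) -> tuple[AtomicStructure, ScoreBreakdown]:
    """Refine the pose of the mobile unit (atoms beyond ``n_fixed_atoms``)
    by explore-then-quench Monte Carlo; returns the best pose visited."""
    from scipy.spatial import cKDTree
    from scipy.spatial.transform import Rotation

    cur = model.copy()
    cur_s = restraints.score_structure(cur)
    best, best_s = cur, cur_s
    tree = cKDTree(cur.coords[:n_fixed_atoms])
    total = cfg.n_explore + cfg.n_anneal
    for step in range(total):
        if step < cfg.n_explore:
            T = cfg.t_explore
            rot_sd, trans_sd = cfg.rot_explore_deg, cfg.trans_explore
        else:
            frac = (step - cfg.n_explore) / max(cfg.n_anneal, 1)
            T = cfg.t_anneal_start * (1 - frac)
            rot_sd = (cfg.rot_explore_deg * 0.4) * (1 - frac) + cfg.rot_final_deg
            trans_sd = (cfg.trans_explore * 0.55) * (1 - frac) + cfg.trans_final
        cand = cur.copy()
        cand.coords = cur.coords.copy()
        mob = cand.coords[n_fixed_atoms:]
        cen = mob.mean(axis=0)
        ang = math.radians(rng.normal(0.0, rot_sd))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(axis * ang).as_matrix()
        cand.coords[n_fixed_atoms:] = ((mob - cen) @ R.T + cen
                                       + rng.normal(0.0, trans_sd, 3))
        if tree.query(cand.coords[n_fixed_atoms:], k=1)[0].min() \
                < cfg.clash_min_distance:
            continue
        s = restraints.score_structure(cand)
        dS = s.total - cur_s.total
        if dS < 0 or (T > 0 and rng.random() < math.exp(-dS / T)):
            cur, cur_s = cand, s
            if s.total < best_s.total:
                best, best_s = cand, s
        if step == cfg.n_explore - 1:  # quench from the best basin found
            cur, cur_s = best.copy(), best_s
    return best, best_s


def refine_ensemble(models: Sequence[ScoredModel], n_fixed_atoms: int,
                    restraints: ScoringConfig,
                    cfg: RefinementConfig | None = None) -> list[ScoredModel]:
    """Refine each model in turn (one seeded stream, deterministic)."""
    cfg = cfg or RefinementConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    out = []
    for m in models:
        refined, scores = refine_rigid(m.model, n_fixed_atoms, restraints,
                                       cfg, rng)
        prov = dict(m.provenance)
        prov["refined"] = True
        out.append(ScoredModel(refined, scores, prov))
    return out


def select_top_fraction(ensemble: Sequence[ScoredModel],
                        c: ClusteringParams | None = None) -> list[ScoredModel]:
    """The ⌈top_fraction·N⌉ lowest-scoring models, ties broken by order."""
    if not ensemble:
        raise ValueError("ensemble is empty")
    c = c or ClusteringParams()
    k = math.ceil(c.top_fraction * len(ensemble))
    totals = np.array([m.scores.total for m in ensemble])
    order = np.argsort(totals, kind="stable")
    return [ensemble[i] for i in order[:k]]


def sphere_model_rmsd(a: SphereModel, b: SphereModel) -> float:
    """Minimum center RMSD over sphere relabelings after superposition."""
    ca = a.centers
    cb = b.centers
    if len(ca) != len(cb):
        raise ValueError("sphere models differ in size")
    best = math.inf
    for perm in itertools.permutations(range(len(cb))):
        pb = cb[list(perm)]
        if len(ca) >= 3:
            try:
                rmsd, _ = superpose_rmsd(ca, pb)
            except ValueError:  # collinear centers: fall back to distance spectra
                rmsd = _distance_spectrum_rmsd(ca, pb)
        else:
            rmsd = _distance_spectrum_rmsd(ca, pb)
        best = min(best, rmsd)
    return best


def _distance_spectrum_rmsd(ca: np.ndarray, cb: np.ndarray) -> float:
    da = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
    db = np.linalg.norm(cb[:, None] - cb[None, :], axis=-1)
    return float(np.sqrt(((da - db) ** 2).mean()))


def default_model_distance(a: ScoredModel, b: ScoredModel) -> float:
    if isinstance(a.model, AtomicStructure):
        return assembly_rmsd(a.model, b.model)
    return sphere_model_rmsd(a.model, b.model)


def cluster_models(models: Sequence[ScoredModel],
                   c: ClusteringParams | None = None,
                   distance: Callable[[ScoredModel, ScoredModel], float] | None = None,
                   ) -> list[Cluster]:
    """Leader clustering of scored models.

    Models are visited in ascending total-score order; each joins the first
    existing cluster whose leader is within ``rmsd_threshold``, otherwise it
    founds a new cluster.  The representative of a cluster is its
    lowest-scoring member (the leader, by visit order).
    """
    if not models:
        raise ValueError("no models to cluster")
    c = c or ClusteringParams()
    distance = distance or default_model_distance
    totals = np.array([m.scores.total for m in models])
    order = np.argsort(totals, kind="stable")
    clusters: list[list[ScoredModel]] = []
    leaders: list[ScoredModel] = []
    for i in order:
        m = models[i]
        for k, leader in enumerate(leaders):
            if distance(leader, m) <= c.rmsd_threshold:
                clusters[k].append(m)
                break
        else:
            leaders.append(m)
            clusters.append([m])
    n = len(models)
    return [Cluster(members, members[0], len(members) / n)
            for members in clusters]


def largest_cluster(clusters: Sequence[Cluster]) -> Cluster:
    """The biggest cluster; ties go to the better (lower) representative score."""
    return min(clusters,
               key=lambda cl: (-len(cl.members), cl.representative.scores.total))
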