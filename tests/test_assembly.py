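"""Samplers, top-fraction selection and leader clustering."""

import math

import numpy as np
import pytest

from oligomodel.assembly import (ClusteringParams, CoarseGrid, SamplerConfig,
                                 ScoredModel, SphereModel,
                                 build_coarse_stepwise, cluster_models,
                                 largest_cluster, sample_rigid_assembly,
                                 sample_tetramer_coarse, select_top_fraction,
                                 sphere_model_rmsd)
from oligomodel.ccs import CcsParams, pa_ccs_spheres, sphere_radius_from_ccs
from oligomodel.scoring import ScoreBreakdown, ScoringConfig
from oligomodel.synthetic import SyntheticSpec, make_assembly, make_subunit


def _fast_ccs():
    return CcsParams(probe_radius=1.0, n_orientations=48, n_rays=512,
                     rng_seed=0, target_rel_stderr=None)


def _scored(i, total, x=None):
    m = SphereModel(np.array([[float(i if x is None else x), 0.0, 0.0]]), 1.0)
    return ScoredModel(m, ScoreBreakdown(total, 0, 0, total), {"index": i})


# --------------------------------------------------------- coarse builder

def test_coarse_dimer_recovers_tangent_distance():
    # plant the target: CCS of two tangent spheres of the monomer radius
    p = _fast_ccs()
    r = sphere_radius_from_ccs(1200.0, p.probe_radius)
    tangent = SphereModel(np.array([[0, 0, 0], [2 * r, 0, 0]]), r)
    target = pa_ccs_spheres(tangent, p).pa
    out = build_coarse_stepwise(1200.0, {2: target},
                                CoarseGrid(angle_step_deg=30.0), p)
    centers = out[2].model.centers
    d = np.linalg.norm(centers[1] - centers[0])
    assert d == pytest.approx(2 * r, abs=0.1 * r + 1e-9)


def test_coarse_trimer_recovers_equilateral():
    p = _fast_ccs()
    r = sphere_radius_from_ccs(1200.0, p.probe_radius)
    tri = SphereModel(np.array([[0, 0, 0], [2 * r, 0, 0],
                                [r, r * math.sqrt(3), 0]]), r)
    t2 = pa_ccs_spheres(SphereModel(tri.centers[:2], r), p).pa
    t3 = pa_ccs_spheres(tri, p).pa
    out = build_coarse_stepwise(1200.0, {2: t2, 3: t3},
                                CoarseGrid(angle_step_deg=30.0), p)
    built = out[3].model
    assert sphere_model_rmsd(built, tri) <= 0.2 * r


def test_coarse_compact_limit_for_small_target():
    # target equal to the monomer CCS → most compact allowed placement
    p = _fast_ccs()
    r = sphere_radius_from_ccs(1200.0, p.probe_radius)
    out = build_coarse_stepwise(1200.0, {2: 1200.0},
                                CoarseGrid(angle_step_deg=45.0), p)
    d = np.linalg.norm(np.diff(out[2].model.centers, axis=0))
    assert d == pytest.approx(1.2 * r, abs=1e-6)  # clash bound


# --------------------------------------------------------- tetramer coarse MC

def _trimer(r):
    return SphereModel(np.array([[0, 0, 0], [2 * r, 0, 0],
                                 [r, r * math.sqrt(3), 0]]), r)


def test_tetramer_mc_count_and_determinism():
    r = 18.5
    fixed = _trimer(r)
    cfg = SamplerConfig(n_models=10, rng_seed=42, placement_shell=(-10.0, 5.0))
    a = sample_tetramer_coarse(fixed, 2500.0, cfg, _fast_ccs())
    b = sample_tetramer_coarse(fixed, 2500.0, cfg, _fast_ccs())
    assert len(a) == 10
    for ma, mb in zip(a, b):
        np.testing.assert_array_equal(ma.model.centers, mb.model.centers)
        assert ma.scores.total == mb.scores.total


def test_tetramer_mc_recovers_planted_position():
    p = _fast_ccs()
    r = sphere_radius_from_ccs(1200.0, p.probe_radius)
    fixed = _trimer(r)
    planted = np.array([r, r / math.sqrt(3), 2 * r * math.sqrt(2.0 / 3.0)])
    target = pa_ccs_spheres(fixed.with_sphere(planted), p).pa
    hits = 0
    for seed in (1, 2, 3):
        cfg = SamplerConfig(n_models=400, rng_seed=seed,
                            placement_shell=(-12.0, 6.0))
        ens = sample_tetramer_coarse(fixed, target, cfg, p)
        best = min(ens, key=lambda m: m.scores.total)
        # CCS fixes compactness, not the exact site: accept any placement
        # as compact as the planted one (distance from the trimer centroid)
        planted_d = np.linalg.norm(planted - fixed.centers.mean(axis=0))
        best_d = np.linalg.norm(best.model.centers[3] - fixed.centers.mean(axis=0))
        if abs(best_d - planted_d) <= r:
            hits += 1
    assert hits >= 2


# ----------------------------------------------------------- rigid sampler

@pytest.fixture(scope="module")
def small_units():
    spec = SyntheticSpec(n_subunits=2, subunit_size=20, rng_seed=5)
    sub = make_subunit(spec)
    dimer = make_assembly(sub, spec).truth
    return dimer, sub


def test_rigid_sampler_determinism_and_clash(small_units):
    dimer, sub = small_units
    sc = ScoringConfig(ccs_target=900.0,
                       ccs_params=CcsParams(probe_radius=0.0, n_orientations=16,
                                            n_rays=256, target_rel_stderr=None))
    cfg = SamplerConfig(n_models=5, rng_seed=11)
    a = sample_rigid_assembly([dimer], sub, sc, cfg)
    b = sample_rigid_assembly([dimer], sub, sc, cfg)
    assert len(a) == 5
    from scipy.spatial import cKDTree
    nfix = len(dimer)
    for ma, mb in zip(a, b):
        np.testing.assert_array_equal(ma.model.coords, mb.model.coords)
        assert ma.scores.total == mb.scores.total
        d = cKDTree(ma.model.coords[:nfix]).query(
            ma.model.coords[nfix:], k=1)[0].min()
        assert d >= cfg.clash_min_distance


def test_rigid_sampler_truth_injection(small_units):
    # with only a CCS restraint targeted at a planted pose's own CCS, the
    # planted pose scores no worse than any sampled model
    dimer, sub = small_units
    from oligomodel.ccs import pa_ccs
    p = CcsParams(probe_radius=0.0, n_orientations=32, n_rays=512,
                  target_rel_stderr=None)
    spec = SyntheticSpec(n_subunits=3, subunit_size=20, rng_seed=6)
    planted = make_assembly(sub, spec).truth
    target = pa_ccs(planted, p).scaled
    sc = ScoringConfig(ccs_target=target, ccs_params=p)
    ens = sample_rigid_assembly([dimer], sub, sc,
                                SamplerConfig(n_models=30, rng_seed=3))
    truth_score = sc.score_structure(planted).total
    sampled_best = min(m.scores.total for m in ens)
    assert truth_score <= sampled_best + 1e-9


# --------------------------------------------------------------- selection

def test_select_top_fraction_counts():
    ens = [_scored(i, float(i)) for i in range(200)]
    out = select_top_fraction(ens, ClusteringParams(top_fraction=0.01))
    assert len(out) == 2
    assert [m.provenance["index"] for m in out] == [0, 1]
    out10k = select_top_fraction([_scored(i, 0.5) for i in range(10_000)],
                                 ClusteringParams(top_fraction=0.01))
    assert len(out10k) == 100


def test_select_top_fraction_tie_break_stable():
    ens = [_scored(i, 1.0) for i in range(50)]
    out = select_top_fraction(ens, ClusteringParams(top_fraction=0.1))
    assert [m.provenance["index"] for m in out] == list(range(5))


def test_select_output_sorted():
    rng = np.random.default_rng(0)
    ens = [_scored(i, float(t)) for i, t in enumerate(rng.random(100))]
    out = select_top_fraction(ens, ClusteringParams(top_fraction=0.2))
    totals = [m.scores.total for m in out]
    assert totals == sorted(totals)


# -------------------------------------------------------------- clustering

def brute_force_leader(items, threshold, dist):
    """Naive O(N²) reimplementation of ascending-score leader clustering."""
    order = sorted(range(len(items)), key=lambda i: (items[i].scores.total, i))
    leaders, clusters = [], []
    for i in order:
        for k, l in enumerate(leaders):
            if dist(items[l], items[i]) <= threshold:
                clusters[k].append(i)
                break
        else:
            leaders.append(i)
            clusters.append([i])
    return clusters


def _point_distance(a, b):
    return abs(a.model.centers[0, 0] - b.model.centers[0, 0])


def test_cluster_identical_models_single_cluster():
    models = [_scored(i, 1.0, x=0.0) for i in range(6)]
    out = cluster_models(models, ClusteringParams(rmsd_threshold=5.0),
                         distance=_point_distance)
    assert len(out) == 1
    assert out[0].fraction == 1.0


def test_cluster_two_separated_groups():
    models = ([_scored(i, float(i), x=0.0) for i in range(4)]
              + [_scored(10 + i, 5.0 + i, x=20.0) for i in range(3)])
    out = cluster_models(models, ClusteringParams(rmsd_threshold=5.0),
                         distance=_point_distance)
    assert len(out) == 2
    assert {len(c.members) for c in out} == {4, 3}
    big = largest_cluster(out)
    assert big.representative.provenance["index"] == 0


@pytest.mark.parametrize("seed", range(10))
def test_cluster_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 25))
    models = [_scored(i, float(rng.random()), x=float(rng.uniform(0, 30)))
              for i in range(n)]
    thr = float(rng.uniform(1.0, 8.0))
    ours = cluster_models(models, ClusteringParams(rmsd_threshold=thr),
                          distance=_point_distance)
    oracle = brute_force_leader(models, thr, _point_distance)
    ours_sets = [[m.provenance["index"] for m in c.members] for c in ours]
    oracle_sets = [[models[i].provenance["index"] for i in c] for c in oracle]
    assert ours_sets == oracle_sets


def test_cluster_representative_is_lowest_score():
    rng = np.random.default_rng(3)
    models = [_scored(i, float(rng.random()), x=float(rng.uniform(0, 4)))
              for i in range(12)]
    out = cluster_models(models, ClusteringParams(rmsd_threshold=10.0),
                         distance=_point_distance)
    for c in out:
        assert c.representative.scores.total == min(m.scores.total
                                                    for m in c.members)


def test_cluster_fractions_sum_to_one():
    rng = np.random.default_rng(4)
    models = [_scored(i, float(rng.random()), x=float(rng.uniform(0, 50)))
              for i in range(30)]
    out = cluster_models(models, ClusteringParams(rmsd_threshold=3.0),
                         distance=_point_distance)
    assert sum(c.fraction for c in out) == pytest.approx(1.0)
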