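"""Planted-truth generators: determinism and self-consistency."""

import numpy as np
import pytest

from oligomodel.ccs import pa_ccs
from oligomodel.density import cross_correlation, rasterize
from oligomodel.structures import RigidTransform
from oligomodel.synthetic import (SyntheticSpec, default_ccs_params,
                                  make_assembly, make_subunit,
                                  make_tetramer_benchmark, simulate_ccs,
                                  simulate_crosslinks, simulate_map)
from oligomodel.xlinks import min_link_distance


def _rg(coords):
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


# ----------------------------------------------------------------- subunit

def test_subunit_bond_lengths_and_size():
    s = make_subunit(SyntheticSpec(subunit_size=20, rng_seed=1))
    assert len(s) == 20
    d = np.linalg.norm(np.diff(s.coords, axis=0), axis=1)
    np.testing.assert_allclose(d, 3.8, atol=0.01)


def test_subunit_deterministic():
    a = make_subunit(SyntheticSpec(subunit_size=30, rng_seed=7))
    b = make_subunit(SyntheticSpec(subunit_size=30, rng_seed=7))
    np.testing.assert_array_equal(a.coords, b.coords)


def test_compact_more_globular_than_linear():
    compact = make_subunit(SyntheticSpec(subunit_size=40, topology="compact",
                                         rng_seed=2))
    linear = make_subunit(SyntheticSpec(subunit_size=40, topology="linear",
                                        rng_seed=2))
    assert _rg(compact.coords) < _rg(linear.coords)


def test_subunit_has_pseudo_lysines():
    s = make_subunit(SyntheticSpec(subunit_size=30, rng_seed=3))
    lys = [i for i, rn in enumerate(s.residue_names) if rn == "LYS"]
    assert len(lys) >= 3


# ---------------------------------------------------------------- assembly

def test_assembly_contact_and_clash():
    spec = SyntheticSpec(n_subunits=2, subunit_size=30, rng_seed=4)
    sub = make_subunit(spec)
    out = make_assembly(sub, spec, clash_min=4.0)
    a = out.truth.coords[:30]
    b = out.truth.coords[30:]
    d = np.linalg.norm(a[:, None] - b[None, :], axis=-1)
    assert d.min() >= 4.0
    assert d.min() < 6.0  # in contact


def test_linear_assembly_collinear_centers():
    spec = SyntheticSpec(n_subunits=4, subunit_size=25, topology="linear",
                         rng_seed=5)
    sub = make_subunit(spec)
    out = make_assembly(sub, spec)
    centers = np.array([out.truth.coords[25 * i:25 * (i + 1)].mean(axis=0)
                        for i in range(4)])
    centered = centers - centers.mean(axis=0)
    _, sv, _ = np.linalg.svd(centered)
    # perpendicular spread far below the axial spread
    assert sv[1] < sv[0] / 4


def test_recorded_transforms_reproduce_assembly():
    spec = SyntheticSpec(n_subunits=3, subunit_size=20, rng_seed=6)
    sub = make_subunit(spec)
    out = make_assembly(sub, spec)
    for k, t in enumerate(out.transforms):
        rebuilt = t.apply(sub.coords)
        np.testing.assert_allclose(
            rebuilt, out.truth.coords[20 * k:20 * (k + 1)], atol=1e-9)


# -------------------------------------------------------------- observables

def test_simulate_ccs_noise_free_exact():
    spec = SyntheticSpec(n_subunits=2, subunit_size=20, ccs_noise=0.0,
                         rng_seed=8)
    sub = make_subunit(spec)
    truth = make_assembly(sub, spec).truth
    p = default_ccs_params()
    assert simulate_ccs(truth, spec, p) == pytest.approx(
        pa_ccs(truth, p).scaled)


def test_simulate_ccs_noise_statistics():
    spec = SyntheticSpec(n_subunits=2, subunit_size=20, rng_seed=9)
    sub = make_subunit(spec)
    truth = make_assembly(sub, spec).truth
    p = default_ccs_params()
    base = pa_ccs(truth, p).scaled
    draws = np.array([
        simulate_ccs(truth, SyntheticSpec(n_subunits=2, subunit_size=20,
                                          rng_seed=9 + 1000 * k), p)
        for k in range(300)])
    rel = draws / base - 1.0
    assert 0.02 <= rel.std() <= 0.04  # nominal 3%
    assert abs(rel.mean()) < 0.01


def test_crosslinks_true_links_verify_on_truth():
    spec = SyntheticSpec(n_subunits=2, subunit_size=40, xl_decoy_rate=0.0,
                         rng_seed=10)
    sub = make_subunit(spec)
    truth = make_assembly(sub, spec).truth
    links = simulate_crosslinks(truth, spec)
    assert links, "compact dimer should yield inter-unit links"
    for xl in links:
        assert xl.n_spectra == 1
        assert min_link_distance(truth, xl) <= spec.xl_cutoff


def test_crosslink_decoys_beyond_cutoff_and_seeded():
    spec = SyntheticSpec(n_subunits=2, subunit_size=60, xl_decoy_rate=0.3,
                         rng_seed=11)
    sub = make_subunit(spec)
    truth = make_assembly(sub, spec).truth
    links = simulate_crosslinks(truth, spec)
    again = simulate_crosslinks(truth, spec)
    assert [(x.residue_1, x.residue_2, x.n_spectra) for x in links] == \
           [(x.residue_1, x.residue_2, x.n_spectra) for x in again]
    decoys = [xl for xl in links if xl.n_spectra == 0]
    sub_labels = truth.subunit_labels
    inter_pairs = [(c1, c2) for c1 in truth.chains() for c2 in truth.chains()
                   if sub_labels[c1] != sub_labels[c2]]
    for xl in decoys:
        assert min_link_distance(truth, xl, inter_pairs) > spec.xl_cutoff


def test_map_noise_free_perfect_correlation():
    spec = SyntheticSpec(n_subunits=2, subunit_size=20, map_noise_sd=0.0,
                         rng_seed=12)
    sub = make_subunit(spec)
    truth = make_assembly(sub, spec).truth
    g = simulate_map(truth, spec)
    sim = rasterize(truth, g, spec.map_resolution)
    assert cross_correlation(sim, g) == pytest.approx(1.0)


def test_map_ranking_under_noise():
    wins = 0
    for seed in (13, 14, 15):
        spec = SyntheticSpec(n_subunits=2, subunit_size=20, map_noise_sd=0.1,
                             rng_seed=seed)
        sub = make_subunit(spec)
        truth = make_assembly(sub, spec).truth
        g = simulate_map(truth, spec)
        displaced = truth.transformed(
            RigidTransform(np.eye(3), np.array([12.0, 0.0, 0.0])))
        cc_true = cross_correlation(rasterize(truth, g, spec.map_resolution), g)
        cc_disp = cross_correlation(rasterize(displaced, g,
                                              spec.map_resolution), g)
        wins += cc_true > cc_disp
    assert wins == 3


def test_map_resolution_controls_peak_sharpness():
    spec = SyntheticSpec(n_subunits=2, subunit_size=20, map_noise_sd=0.0,
                         map_resolution=12.0, map_voxel=3.0, rng_seed=16)
    sub = make_subunit(spec)
    truth = make_assembly(sub, spec).truth
    sharp = simulate_map(truth, spec)
    from dataclasses import replace
    blurry = simulate_map(truth, replace(spec, map_resolution=24.0))
    assert sharp.values.max() > blurry.values.max()


# ---------------------------------------------------------------- benchmark

def test_tetramer_benchmark_self_consistency():
    bench = make_tetramer_benchmark(SyntheticSpec(rng_seed=17))
    # chains A,B form the fixed unit, C,D the mobile one
    assert bench.truth.subunits() == ["u0", "u1"]
    assert sum(xl.n_spectra == 1 for xl in bench.links) >= 3
    from oligomodel.scoring import ScoringConfig
    from oligomodel.synthetic import default_ccs_params as dcp
    sc = ScoringConfig(ccs_target=bench.ccs_target, links=bench.links,
                       chem=bench.chem, em_segment=bench.em_map,
                       ccs_params=dcp())
    scores = sc.score_structure(bench.truth)
    # truth satisfies every true link; decoys may add a small penalty
    assert scores.s_cxms < 0.2
    # CCS off only by the 3% noise draw (plus estimator error)
    assert scores.s_imms < 9.0
    # EM off only by the voxel-noise floor
    assert scores.s_em < 0.5
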