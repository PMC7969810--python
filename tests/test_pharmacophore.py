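import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import brute_force_fit
from pharmscreen import (PharmacophoreModel, SphereConstraint, fit_value,
                         enumerate_correspondences, score_pose, superpose)
from pharmscreen.features import Feature
from pharmscreen.pharmacophore import best_fit_over_conformers
from pharmscreen.chem_io import MoleculeRecord


def F(kind, xyz):
    return Feature(kind, tuple(xyz), None, (0,))


def feats(*pairs):
    return [Feature(k, tuple(x), None, (i,)) for i, (k, x) in enumerate(pairs)]


# --- superposition ----------------------------------------------------------

def test_superpose_identity_and_translation():
    pts = np.array([[0., 0, 0], [1, 0, 0], [0, 2, 0], [1, 1, 3]])
    tf, rmsd = superpose(pts, pts)
    assert rmsd == pytest.approx(0, abs=1e-12)
    assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
    tf, rmsd = superpose(pts, pts + np.array([1., 2, 3]))
    assert rmsd == pytest.approx(0, abs=1e-9)
    assert np.allclose(tf.translation, [-1, -2, -3], atol=1e-9)


def test_superpose_noisy_rotation_matches_grid_search():
    rng = np.random.default_rng(5)
    pts = rng.uniform(-3, 3, (4, 3))
    th = np.deg2rad(30)
    Rz = np.array([[np.cos(th), -np.sin(th), 0],
                   [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    moved = pts @ Rz.T + rng.normal(0, 0.1, (4, 3))
    _, rmsd = superpose(pts, moved)
    # oracle: dense grid over the generating rotation family + centroid shift
    best = np.inf
    for deg in np.arange(0, 360, 1.0):
        a = np.deg2rad(deg)
        R = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        rot = moved @ R.T
        rot = rot - rot.mean(axis=0) + pts.mean(axis=0)
        best = min(best, np.sqrt(((rot - pts) ** 2).sum(axis=1).mean()))
    assert rmsd <= best + 1e-9
    assert rmsd >= 0.8 * best


def test_superpose_rejects_mismatched_inputs():
    with pytest.raises(ValueError):
        superpose(np.zeros((3, 3)), np.zeros((2, 3)))


# --- correspondence enumeration --------------------------------------------

def test_enumeration_counts_and_kind_compatibility():
    m1 = PharmacophoreModel("m", [SphereConstraint("HBA", (0, 0, 0))])
    fl = feats(("HBA", (0, 0, 0)), ("HBA", (3, 0, 0)))
    assert len(list(enumerate_correspondences(fl, m1))) == 2

    mar = PharmacophoreModel("m", [SphereConstraint("AR", (0, 0, 0))])
    assert list(enumerate_correspondences(feats(("HY", (0, 0, 0))), mar)) == []


def test_enumeration_matches_permutation_count_without_pruning():
    m = PharmacophoreModel("m", [SphereConstraint("HY", (i * 3.0, 0, 0))
                                 for i in range(3)])
    fl = feats(*[("HY", (i * 3.0, 1, 0)) for i in range(4)])
    maps = list(enumerate_correspondences(fl, m, prune=False))
    assert len(maps) == 24  # 4 * 3 * 2 injective assignments
    assert len(set(maps)) == 24


# --- fixed-pose scoring closed forms ----------------------------------------

@pytest.mark.parametrize("displacement,expected", [
    (0.0, 1.0), (1.6, 0.0), (0.8, 0.75)])
def test_quadratic_falloff_closed_form(displacement, expected):
    m = PharmacophoreModel("m", [SphereConstraint("HBA", (0, 0, 0), 1.6, 1.0)])
    res = score_pose(feats(("HBA", (displacement, 0, 0))), m)
    assert res.fit == pytest.approx(expected, abs=1e-12)
    assert res.correspondence == (0,)


def test_out_of_tolerance_pose_does_not_map():
    m = PharmacophoreModel("m", [SphereConstraint("HBA", (0, 0, 0), 1.6, 1.0)])
    res = score_pose(feats(("HBA", (2.0, 0, 0))), m)
    assert res.fit == 0.0 and res.n_mapped == 0


# --- fit_value --------------------------------------------------------------

def _random_instance(seed):
    rng = np.random.default_rng(seed)
    kinds = ["HBA", "HY", "AR", "HBD"]
    nc = int(rng.integers(2, 5))
    while True:
        pts = rng.uniform(-4, 4, (nc, 3))
        if all(np.linalg.norm(pts[i] - pts[j]) > 2.5
               for i, j in itertools.combinations(range(nc), 2)):
            break
    cons = [SphereConstraint(kinds[int(rng.integers(4))], tuple(p), 1.6,
                             float(rng.uniform(0.5, 2.4))) for p in pts]
    model = PharmacophoreModel("m", cons,
                               max_omitted=int(rng.integers(0, 2)) if nc > 1 else 0)
    nf = int(rng.integers(nc, 7))
    R = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    t = rng.uniform(-5, 5, 3)
    fl = []
    for c in cons:
        fl.append(Feature(c.kind, tuple(R @ np.array(c.center) + t
                                        + rng.normal(0, 0.3, 3)), None, (len(fl),)))
    for _ in range(nf - nc):
        fl.append(Feature(kinds[int(rng.integers(4))],
                          tuple(rng.uniform(-8, 8, 3)), None, (len(fl),)))
    return fl, model


@pytest.mark.parametrize("seed", range(6))
def test_fit_equals_brute_force_oracle(seed):
    fl, model = _random_instance(seed)
    impl = fit_value(fl, model).fit
    oracle = brute_force_fit(fl, model)
    assert impl == pytest.approx(oracle, abs=1e-3)
    assert 0 <= impl <= model.total_weight + 1e-9


@pytest.mark.parametrize("seed", range(4))
def test_fit_is_rigid_motion_invariant(seed):
    fl, model = _random_instance(seed)
    base = fit_value(fl, model).fit
    rng = np.random.default_rng(100 + seed)
    R = Rotation.random(random_state=np.random.RandomState(77 + seed)).as_matrix()
    t = rng.uniform(-10, 10, 3)
    moved = [Feature(f.kind, tuple(R @ np.array(f.center) + t), None,
                     f.source_atoms) for f in fl]
    assert fit_value(moved, model).fit == pytest.approx(base, abs=1e-6)


def test_fit_monotone_under_radial_displacement():
    m = PharmacophoreModel("m", [SphereConstraint("HBA", (0, 0, 0)),
                                 SphereConstraint("HY", (5, 0, 0)),
                                 SphereConstraint("AR", (2.5, 4, 0))])
    prev = np.inf
    for d in np.linspace(0, 2.0, 9):
        fl = feats(("HBA", (0, 0, d)), ("HY", (5, 0, 0)), ("AR", (2.5, 4, 0)))
        fit = fit_value(fl, m).fit
        assert fit <= prev + 1e-9
        prev = fit


def test_no_admissible_correspondence_reports_no_map():
    m = PharmacophoreModel("m", [SphereConstraint("HBA", (0, 0, 0)),
                                 SphereConstraint("HBA", (20, 0, 0))])
    fl = feats(("HBA", (0, 0, 0)), ("HBA", (3, 0, 0)))
    res = fit_value(fl, m)
    assert res.fit == 0.0 and res.n_mapped == 0


def test_equal_fit_ties_choose_lowest_lexicographic_mapping():
    m = PharmacophoreModel("m", [SphereConstraint("HBA", (0, 0, 0))])
    fl = feats(("HBA", (1, 0, 0)), ("HBA", (-1, 0, 0)))
    assert fit_value(fl, m).correspondence == (0,)


# --- conformer selection ----------------------------------------------------

def test_best_fit_over_conformers_selects_max_and_breaks_ties_low(mixed_model):
    from pharmscreen.synthetic import molecule_from_features
    good = [(c.kind, c.center) for c in mixed_model.constraints]
    rec = molecule_from_features("m", good, seed=1)
    base = rec.conformers[0]
    rng = np.random.default_rng(2)
    worse = base + rng.normal(0, 0.9, base.shape)   # degraded geometry
    mid = base + rng.normal(0, 0.4, base.shape)
    rec3 = MoleculeRecord(id="m3", mol=rec.mol, conformers=[worse, base, mid])
    per_conf = [fit_value(__import__("pharmscreen").perceive_features(
        MoleculeRecord(id="x", mol=rec.mol, conformers=[c])), mixed_model).fit
        for c in rec3.conformers]
    res = best_fit_over_conformers(rec3, mixed_model)
    assert res.fit == pytest.approx(max(per_conf), abs=1e-9)
    assert res.conformer == int(np.argmax(per_conf))

    twin = MoleculeRecord(id="tw", mol=rec.mol, conformers=[base, base])
    assert best_fit_over_conformers(twin, mixed_model).conformer == 0

    empty = MoleculeRecord(id="e", mol=rec.mol, conformers=[])
    with pytest.raises(ValueError):
        best_fit_over_conformers(empty, mixed_model)
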