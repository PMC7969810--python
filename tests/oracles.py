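"""Independent brute-force oracles used by the test suite.

These re-derive the quantities checked by the tests from first principles
(exhaustive enumeration, dense orientation search, closed-form algebra) and
deliberately avoid the library's own search code paths.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def soft_fit(fxyz, model, mapping, R, t):
    """Spec fit formula for one correspondence under one transform; None if
    any mapped feature lies outside its tolerance sphere."""
    total = 0.0
    for ci, fi in enumerate(mapping):
        if fi is None:
            continue
        con = model.constraints[ci]
        d = np.linalg.norm(R @ fxyz[fi] + t - np.asarray(con.center))
        if d > con.tolerance + 1e-9:
            return None
        total += con.weight * max(0.0, 1.0 - (d / con.tolerance) ** 2)
    return total


def _score_ignore_admissibility(fxyz, model, mapping, R, t):
    total = 0.0
    for ci, fi in enumerate(mapping):
        if fi is None:
            continue
        con = model.constraints[ci]
        d = np.linalg.norm(R @ fxyz[fi] + t - np.asarray(con.center))
        total += con.weight * max(0.0, 1.0 - (d / con.tolerance) ** 2)
    return total


def brute_force_fit(features, model, n_grid=150, seed=1234):
    """Maximum fit over every kind-compatible injective correspondence (with
    allowed omissions), optimizing the rigid transform per correspondence by
    scipy align_vectors, a seeded random-rotation grid, and a Nelder-Mead
    polish of the best pose."""
    fxyz = np.array([f.center for f in features], dtype=float)
    n_c = len(model.constraints)
    rng = np.random.default_rng(seed)
    grid = Rotation.random(n_grid, random_state=np.random.RandomState(seed))

    def correspondences():
        kinds = [c.kind for c in model.constraints]
        fidx = list(range(len(features)))
        for omit in itertools.chain.from_iterable(
                itertools.combinations(range(n_c), k)
                for k in range(model.max_omitted + 1)):
            mapped_c = [c for c in range(n_c) if c not in omit]
            for perm in itertools.permutations(fidx, len(mapped_c)):
                if any(features[fi].kind != kinds[ci]
                       for ci, fi in zip(mapped_c, perm)):
                    continue
                mapping = [None] * n_c
                for ci, fi in zip(mapped_c, perm):
                    mapping[ci] = fi
                yield tuple(mapping)

    best = 0.0
    for mapping in correspondences():
        cidx = [ci for ci, fi in enumerate(mapping) if fi is not None]
        if not cidx:
            continue
        ref = np.array([model.constraints[ci].center for ci in cidx])
        mov = fxyz[[mapping[ci] for ci in cidx]]
        ref_c, mov_c = ref.mean(axis=0), mov.mean(axis=0)
        cands = []
        if len(cidx) >= 2:
            rot, _ = Rotation.align_vectors(ref - ref_c, mov - mov_c)
            cands.append((rot.as_matrix(), ref_c - rot.as_matrix() @ mov_c))
        for rot in grid:
            R = rot.as_matrix()
            cands.append((R, ref_c - R @ mov_c))
        cands.append((np.eye(3), ref_c - mov_c))
        scored = [(_score_ignore_admissibility(fxyz, model, mapping, R, t), R, t)
                  for R, t in cands]
        scored.sort(key=lambda x: -x[0])
        poses = []
        for s0, R0, t0 in scored[:4]:
            def neg(p, R0=R0, t0=t0):
                R = Rotation.from_rotvec(p[:3]).as_matrix() @ R0
                return -_score_ignore_admissibility(fxyz, model, mapping, R,
                                                    t0 + p[3:])
            res = minimize(neg, np.zeros(6), method="Nelder-Mead",
                           options={"maxiter": 600, "xatol": 1e-6, "fatol": 1e-10})
            poses.append((Rotation.from_rotvec(res.x[:3]).as_matrix() @ R0,
                          t0 + res.x[3:]))
            poses.append((R0, t0))
        for RR, tt in poses:
            val = soft_fit(fxyz, model, mapping, RR, tt)
            if val is not None and val > best:
                best = val
    return best


def brute_force_common_subsets(ref_feats, other_feats_list, bin_width):
    """All maximal subsets of reference features realizable (kind-matched,
    pairwise distances within the bin) in every other molecule, by exhaustive
    subset + assignment enumeration."""
    ref_xyz = np.array([f.center for f in ref_feats])

    def realizable(subset, feats):
        xyz = np.array([f.center for f in feats])
        cands = [[j for j, f in enumerate(feats) if f.kind == ref_feats[i].kind]
                 for i in subset]
        for assign in itertools.product(*cands):
            if len(set(assign)) != len(assign):
                continue
            ok = True
            for a, b in itertools.combinations(range(len(subset)), 2):
                dr = np.linalg.norm(ref_xyz[subset[a]] - ref_xyz[subset[b]])
                do = np.linalg.norm(xyz[assign[a]] - xyz[assign[b]])
                if abs(dr - do) > bin_width:
                    ok = False
                    break
            if ok:
                return True
        return False

    n = len(ref_feats)
    common = []
    for k in range(n, 0, -1):
        for subset in itertools.combinations(range(n), k):
            if any(set(subset) <= set(c) for c in common):
                continue
            if all(realizable(subset, feats) for feats in other_feats_list):
                common.append(subset)
    return {frozenset(c) for c in common}


def enumerate_gf_range(max_D=60):
    """GF over every valid (D, A, Ht, Ha) tuple with D <= max_D; returns
    (min, max) for the bound check."""
    lo, hi = np.inf, -np.inf
    for D in range(2, max_D + 1):
        for A in range(1, D):
            for Ht in range(1, D + 1):
                # inactive hits cannot exceed the number of inactives
                for Ha in range(max(0, Ht - (D - A)), min(Ht, A) + 1):
                    gf = (Ha / (4.0 * Ht * A)) * (3 * A + Ht) * (
                        1.0 - (Ht - Ha) / (D - A))
                    lo, hi = min(lo, gf), max(hi, gf)
    return lo, hi
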