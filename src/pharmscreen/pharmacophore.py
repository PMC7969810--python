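"""Pharmacophore model representation and geometric fit scoring.

A model is a set of typed tolerance spheres (kind, center, tolerance radius,
weight). A molecule maps the model when its perceived features can be placed,
by one rigid transform, inside the spheres of a kind-compatible injective
correspondence (with up to ``max_omitted`` constraints left unmatched). The
fit value uses the Catalyst-style quadratic fall-off

    fit = sum_f  w_f * max(0, 1 - (d_f / tol_f)^2)

over mapped constraints f, where d_f is the post-superposition displacement
of the matched feature from the sphere center. The fit is therefore bounded
by the sum of the weights and reaches it only when every sphere is hit dead
center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import KINDS, Feature


@dataclass(frozen=True)
class SphereConstraint:
    kind: str
    center: tuple
    tolerance: float = 1.6
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))

    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class PharmacophoreModel:
    name: str
    constraints: list
    max_omitted: int = 0
    calibration_C: float | None = None  # log10-μM intercept of the fit→IC50 map

    def __post_init__(self):
        if len(self.constraints) < 1:
            raise ValueError("model needs at least one constraint")
        if not 0 <= self.max_omitted < len(self.constraints):
            raise ValueError("max_omitted must be in [0, n_constraints)")

    @property
    def total_weight(self) -> float:
        return float(sum(c.weight for c in self.constraints))

    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.constraints], dtype=float)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "constraints": [
                {"kind": c.kind, "center": list(c.center),
                 "tolerance": c.tolerance, "weight": c.weight}
                for c in self.constraints],
            "max_omitted": self.max_omitted,
            "calibration_C": self.calibration_C,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreModel":
        cons = [SphereConstraint(kind=c["kind"], center=tuple(c["center"]),
                                 tolerance=c["tolerance"], weight=c["weight"])
                for c in d["constraints"]]
        return cls(name=d["name"], constraints=cons,
                   max_omitted=d.get("max_omitted", 0),
                   calibration_C=d.get("calibration_C"))


@dataclass
class RigidTransform:
    """x -> R @ x + t (proper rotation, no scaling, no reflection)."""
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def superpose(reference: np.ndarray, moving: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``reference``
    (Kabsch), optionally weighted. Returns (transform, rmsd) where rmsd is the
    unweighted post-transform RMSD."""
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {ref.shape} vs {mov.shape}")
    n = ref.shape[0]
    if n == 0:
        raise ValueError("need at least one point")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones(n)
    w = w / w.sum()
    ref_c = (w[:, None] * ref).sum(axis=0)
    mov_c = (w[:, None] * mov).sum(axis=0)
    H = (mov - mov_c).T @ (w[:, None] * (ref - ref_c))
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mov_c
    tf = RigidTransform(R, t)
    rmsd = float(np.sqrt(((tf.apply(mov) - ref) ** 2).sum(axis=1).mean()))
    return tf, rmsd


@dataclass
class FitResult:
    fit: float
    correspondence: tuple  # per-constraint feature index, or None if omitted
    displacements: dict  # constraint index -> Å displacement (mapped only)
    transform: RigidTransform
    conformer: int = 0

    @property
    def n_mapped(self) -> int:
        return sum(1 for f in self.correspondence if f is not None)

    @property
    def n_omitted(self) -> int:
        return sum(1 for f in self.correspondence if f is None)

    @property
    def mapped(self) -> bool:
        return self.fit > 0 and self.n_mapped > 0

    @classmethod
    def no_map(cls, n_constraints: int) -> "FitResult":
        return cls(fit=0.0, correspondence=(None,) * n_constraints,
                   displacements={}, transform=RigidTransform.identity())


def enumerate_correspondences(features: list[Feature], model: PharmacophoreModel,
                              prune: bool = True):
    """Yield all injective kind-compatible assignments of model constraints to
    features, with at most ``model.max_omitted`` omissions, in lexicographic
    order (omission sorts after any feature index).

    Each assignment is a tuple of length n_constraints whose i-th entry is a
    feature index or None. With ``prune`` on, partial assignments violating
    pairwise-distance compatibility (|d_feat − d_constr| ≤ tol_i + tol_j) are
    cut early.
    """
    n_c = len(model.constraints)
    fcenters = np.array([f.center for f in features], dtype=float).reshape(len(features), 3)
    ccenters = model.centers()
    tols = [c.tolerance for c in model.constraints]
    candidates = [[fi for fi, f in enumerate(features)
                   if f.kind == model.constraints[ci].kind] for ci in range(n_c)]

    def rec(ci, mapping, used, omitted):
        if ci == n_c:
            yield tuple(mapping)
            return
        for fi in candidates[ci]:
            if fi in used:
                continue
            mapping.append(fi)
            ok = True
            if prune:
                for cj, fj in enumerate(mapping[:-1]):
                    if fj is None:
                        continue
                    df = np.linalg.norm(fcenters[fi] - fcenters[fj])
                    dc = np.linalg.norm(ccenters[ci] - ccenters[cj])
                    if abs(df - dc) > tols[ci] + tols[cj]:
                        ok = False
                        break
            if ok:
                used.add(fi)
                yield from rec(ci + 1, mapping, used, omitted)
                used.discard(fi)
            mapping.pop()
        if omitted < model.max_omitted:
            mapping.append(None)
            yield from rec(ci + 1, mapping, used, omitted + 1)
            mapping.pop()

    yield from rec(0, [], set(), 0)


def _score_mapping(fcenters, model, mapping, transform) -> tuple[float, dict]:
    """Score one correspondence under a given transform; returns (fit, displacements)
    or (-1, {}) if some mapped feature lies outside its tolerance sphere."""
    moved = transform.apply(fcenters)
    fit, disp = 0.0, {}
    for ci, fi in enumerate(mapping):
        if fi is None:
            continue
        con = model.constraints[ci]
        d = float(np.linalg.norm(moved[fi] - con.center_array()))
        if d > con.tolerance + 1e-9:
            return -1.0, {}
        disp[ci] = d
        fit += con.weight * max(0.0, 1.0 - (d / con.tolerance) ** 2)
    return fit, disp


def score_pose(features: list[Feature], model: PharmacophoreModel,
               transform: RigidTransform | None = None) -> FitResult:
    """Fit of a feature set against a model *in its current pose* (no
    transform optimization): the quadratic fall-off evaluated in place,
    maximized over correspondences only. This is the closed-form scoring
    primitive; :func:`fit_value` adds the rigid-alignment search."""
    n_c = len(model.constraints)
    if not features:
        return FitResult.no_map(n_c)
    fcenters = np.array([f.center for f in features], dtype=float)
    tf = transform or RigidTransform.identity()
    best, found = FitResult.no_map(n_c), False
    for mapping in enumerate_correspondences(features, model):
        if all(fi is None for fi in mapping):
            continue
        score, disp = _score_mapping(fcenters, model, mapping, tf)
        if score < 0:
            continue
        if score > best.fit + 1e-12 or not found:
            best = FitResult(fit=score, correspondence=mapping,
                             displacements=disp, transform=tf)
            found = True
    return best


def fit_value(features: list[Feature], model: PharmacophoreModel) -> FitResult:
    """Best fit of a feature set against a model.

    For every admissible correspondence the mapped feature centers are
    superposed onto the constraint centers by least squares (one unweighted
    pass, one pass re-weighted by constraint weight); the correspondence is
    admissible when every mapped feature lands inside its tolerance sphere.
    Returns the maximum-fit result; ties go to the lexicographically lowest
    correspondence. A molecule with no admissible correspondence gets fit 0
    and an empty mapping.
    """
    n_c = len(model.constraints)
    if not features:
        return FitResult.no_map(n_c)
    fcenters = np.array([f.center for f in features], dtype=float)
    best = FitResult.no_map(n_c)
    found = False
    for mapping in enumerate_correspondences(features, model):
        cidx = [ci for ci, fi in enumerate(mapping) if fi is not None]
        if not cidx:
            continue
        fidx = [mapping[ci] for ci in cidx]
        ref = np.array([model.constraints[ci].center for ci in cidx], dtype=float)
        mov = fcenters[fidx]
        tf, _ = superpose(ref, mov)
        score, disp = _score_mapping(fcenters, model, mapping, tf)
        w = np.array([model.constraints[ci].weight for ci in cidx])
        if w.sum() > 0 and len(cidx) > 1:
            tf2, _ = superpose(ref, mov, weights=w)
            score2, disp2 = _score_mapping(fcenters, model, mapping, tf2)
            if score2 > score:
                score, disp, tf = score2, disp2, tf2
        if score < 0:
            continue
        if score > best.fit + 1e-12 or not found:
            best = FitResult(fit=score, correspondence=mapping,
                             displacements=disp, transform=tf)
            found = True
    if not found:
        return FitResult.no_map(n_c)
    return best


def best_fit_over_conformers(record, model: PharmacophoreModel,
                             rules=None) -> FitResult:
    """Maximum fit across a molecule's conformers (ties: lowest conformer
    index). Features are perceived per conformer."""
    from .features import perceive_features
    if not record.has_3d():
        raise ValueError(f"{record.id}: molecule has no conformers")
    best = None
    for k in range(len(record.conformers)):
        feats = perceive_features(record, conformer_idx=k, rules=rules)
        res = fit_value(feats, model)
        res.conformer = k
        if best is None or res.fit > best.fit + 1e-12:
            best = res
    return best
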