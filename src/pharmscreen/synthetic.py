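"""Synthetic data generation: molecules with planted pharmacophore
geometry, activities following a known log-linear fit→IC50 law, and
active/decoy databases with controlled retrieval structure.

Every planted feature is realized as a minimal real chemical fragment whose
perceived feature lands on the planted center:

    HBA  -> dimethyl ether (feature on the O)
    HBD  -> formamide (donor on the amide N; its carbonyl O adds one nearby
            HBA ~2.3 Å away — planted models used for exact-kind recovery
            should avoid HBD, as the screening protocol's quantitative model
            does)
    HY   -> isobutane (feature at the 4-carbon centroid)
    AR   -> benzene (feature at the ring centroid)

Fragments are assembled into one multi-fragment molecule (parsable SDF, so
perception, Lipinski filters and fingerprints all operate on it), each
fragment randomly rotated and translated so its feature-defining point sits
at the planted center plus optional jitter. All randomness is driven by a
single integer seed; the same seed reproduces byte-identical SDF output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import MoleculeRecord
from .pharmacophore import (PharmacophoreModel, SphereConstraint,
                            best_fit_over_conformers)


def _template(smiles: str, coords, anchor_row: int):
    mol = Chem.MolFromSmiles(smiles)
    xyz = np.asarray(coords, dtype=float)
    assert mol.GetNumAtoms() == xyz.shape[0]
    return mol, xyz - xyz[anchor_row]


_T = 109.47 * np.pi / 180  # tetrahedral angle
# heavy-atom fragment templates; anchor point (the perceived feature
# location) is moved to the planted center.
_ETHER = _template("COC", [[1.43, 0.0, 0.0],
                           [0.0, 0.0, 0.0],
                           [1.43 * np.cos(_T), 1.43 * np.sin(_T), 0.0]],
                   anchor_row=1)
_FORMAMIDE = _template("NC=O", [[0.0, 0.0, 0.0],
                                [1.33, 0.0, 0.0],
                                [1.33 + 1.23 * np.cos(2.094), 1.23 * np.sin(2.094), 0.0]],
                       anchor_row=0)
_ISOBUTANE_XYZ = np.array([[0.0, 0.0, 0.0],
                           [1.53, 0.0, 0.0],
                           [1.53 * np.cos(2 * np.pi / 3), 1.53 * np.sin(2 * np.pi / 3), 0.4],
                           [1.53 * np.cos(4 * np.pi / 3), 1.53 * np.sin(4 * np.pi / 3), -0.4]])
_ISOBUTANE = (Chem.MolFromSmiles("CC(C)C"),
              np.array([[1.53, 0.0, 0.0],
                        [0.0, 0.0, 0.0],
                        [1.53 * np.cos(2 * np.pi / 3), 1.53 * np.sin(2 * np.pi / 3), 0.4],
                        [1.53 * np.cos(4 * np.pi / 3), 1.53 * np.sin(4 * np.pi / 3), -0.4]])
              - _ISOBUTANE_XYZ.mean(axis=0))
_R_BENZ = 1.39
_BENZENE = _template("c1ccccc1",
                     [[_R_BENZ * np.cos(k * np.pi / 3),
                       _R_BENZ * np.sin(k * np.pi / 3), 0.0] for k in range(6)],
                     anchor_row=0)
_BENZENE = (_BENZENE[0], _BENZENE[1] + np.array([_R_BENZ, 0.0, 0.0])
            - (_BENZENE[1] + np.array([_R_BENZ, 0.0, 0.0])).mean(axis=0))

FRAGMENTS = {"HBA": _ETHER, "HBD": _FORMAMIDE, "HY": _ISOBUTANE, "AR": _BENZENE}
# fix benzene/isobutane anchors at the heavy-atom centroid (the perceived
# feature location for AR and HY)
FRAGMENTS["AR"] = (_BENZENE[0], _BENZENE[1] - _BENZENE[1].mean(axis=0))


def default_planted_model(name: str = "planted") -> PharmacophoreModel:
    """A quantitative-model-like planted pharmacophore: one HBA plus four
    hydrophobes with learned-scale weights (2.4 each, fit ceiling 12), sphere
    tolerance 1.6 Å, inter-feature distances in the 4–7 Å range."""
    w, t = 2.4, 1.6
    return PharmacophoreModel(name, [
        SphereConstraint("HBA", (0.0, 0.0, 0.0), t, w),
        SphereConstraint("HY", (5.0, 0.0, 0.0), t, w),
        SphereConstraint("HY", (2.5, 4.3, 0.0), t, w),
        SphereConstraint("HY", (2.5, 1.4, 3.5), t, w),
        SphereConstraint("HY", (-1.5, 3.0, -2.0), t, w),
    ])


@dataclass
class SimSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the screening protocol's regimes: a 21-compound
    training set whose activities span roughly four log units (the i-th
    active's features are displaced up to 0.8 of the sphere tolerance, so a
    weight-2.4 five-feature model yields fits between about 7.7 and 12),
    lognormal activity noise of 0.3 log10 units, and a 325-compound decoy
    database (25 actives + 300 decoys).
    """
    model: PharmacophoreModel
    n_actives: int = 21
    n_decoys: int = 300
    true_C: float = 8.33          # log10-μM intercept, as calibrated on the training table
    noise_sigma_log10: float = 0.3
    jitter: float = 0.05          # Å, placement noise on planted feature centers
    max_displacement: float = 0.8  # fraction of tolerance spanned across actives
    decoy_perturb: float = 3.0    # Å, decoy geometry perturbation
    n_extra_features: int = 2     # unshared decoy features per active
    seed: int = 0

    def __post_init__(self):
        if self.n_actives < 0 or self.n_decoys < 0:
            raise ValueError("counts must be >= 0")
        if self.noise_sigma_log10 < 0:
            raise ValueError("noise must be >= 0")
        centers = self.model.centers()
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) < 1.0:
                    raise ValueError(
                        "infeasible planted geometry: feature centers "
                        f"{i} and {j} closer than 1 Å")


def _rotation(rng) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _assemble(placements, rng) -> tuple[Chem.Mol, np.ndarray]:
    """Build one multi-fragment molecule from (kind, target-center) pairs."""
    mol = None
    coords = []
    for kind, target in placements:
        frag, xyz = FRAGMENTS[kind]
        rot = _rotation(rng)
        placed = xyz @ rot.T + np.asarray(target, dtype=float)
        mol = frag if mol is None else Chem.CombineMols(mol, frag)
        coords.append(placed)
    Chem.SanitizeMol(mol)
    return mol, np.vstack(coords)


def _random_point(rng, lo=-8.0, hi=8.0):
    return rng.uniform(lo, hi, size=3)


def molecule_from_features(mol_id: str, placements, seed: int = 0) -> MoleculeRecord:
    """Build one molecule carrying features at given positions.

    ``placements`` is a sequence of (kind, (x, y, z)) pairs; each becomes a
    randomly oriented fragment whose perceived feature sits at the position.
    """
    rng = np.random.default_rng(seed)
    mol, xyz = _assemble(list(placements), rng)
    return MoleculeRecord(id=mol_id, mol=mol, conformers=[xyz])


def generate_feature_molecules(spec: SimSpec) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Generate active and decoy molecules for a planted model.

    Actives carry the planted arrangement; the i-th active's features are
    displaced radially by a fraction ramping from 0 to ``max_displacement``
    of each sphere's tolerance (plus jitter), so fit values — and hence
    activities — span a wide range. Decoys carry the arrangement with every
    center perturbed by a random vector of length ``decoy_perturb`` Å.
    Both get ``n_extra_features`` unshared random features. Deterministic
    per seed.
    """
    rng = np.random.default_rng(spec.seed)
    cons = spec.model.constraints
    actives, decoys = [], []
    for i in range(spec.n_actives):
        q0 = (spec.max_displacement * i / max(spec.n_actives - 1, 1))
        # resample displacement directions until the molecule genuinely maps
        # the planted model (independent displacements can otherwise push a
        # feature out of every rigid alignment); q shrinks 10% per retry.
        for attempt in range(20):
            q = q0 * (0.9 ** attempt)
            placements = []
            for c in cons:
                u = _rotation(rng)[:, 0]  # random unit vector
                center = (np.asarray(c.center) + q * c.tolerance * u
                          + rng.normal(0, spec.jitter, 3))
                placements.append((c.kind, center))
            for _ in range(spec.n_extra_features):
                kind = ("HY", "HBA", "AR")[int(rng.integers(3))]
                placements.append((kind, _random_point(rng, 6.0, 12.0)))
            mol, xyz = _assemble(placements, rng)
            rec = MoleculeRecord(id=f"ACT{i:04d}", mol=mol, conformers=[xyz])
            if best_fit_over_conformers(rec, spec.model).fit > 0:
                break
        actives.append(rec)
    for i in range(spec.n_decoys):
        placements = []
        for c in cons:
            u = _rotation(rng)[:, 0]
            center = np.asarray(c.center) + spec.decoy_perturb * u
            placements.append((c.kind, center))
        for _ in range(spec.n_extra_features):
            kind = ("HY", "HBA", "AR")[int(rng.integers(3))]
            placements.append((kind, _random_point(rng, 6.0, 12.0)))
        mol, xyz = _assemble(placements, rng)
        decoys.append(MoleculeRecord(id=f"DEC{i:04d}", mol=mol, conformers=[xyz]))
    return actives, decoys


def generate_activities(records, model: PharmacophoreModel, true_C: float,
                        noise_sigma_log10: float, seed: int = 0,
                        rules=None) -> pd.DataFrame:
    """Assign IC50s by the planted law IC50 = 10^(C − fit + ε),
    ε ~ N(0, σ²) in log10 units. Sets ``activity_ic50`` on the records and
    returns the activity table."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        fit = best_fit_over_conformers(rec, model, rules=rules).fit
        eps = rng.normal(0.0, noise_sigma_log10) if noise_sigma_log10 > 0 else 0.0
        ic50 = float(10.0 ** (true_C - fit + eps))
        rec.activity_ic50 = ic50
        rows.append({"id": rec.id, "ic50_uM": ic50, "true_fit": fit})
    return pd.DataFrame(rows)


def generate_decoy_database(n_actives: int, n_decoys: int,
                            model: PharmacophoreModel, separation: float = 3.0,
                            seed: int = 0) -> tuple[list[MoleculeRecord], list[str]]:
    """Active/decoy database with known retrieval structure: actives map the
    planted model (small jitter only), decoys are perturbed by ``separation``
    Å. Returns (database, active id list); screening with the planted model
    at a fit threshold yields the (D, A, Ht, Ha) counts for decoy_statistics."""
    spec = SimSpec(model=model, n_actives=n_actives, n_decoys=n_decoys,
                   jitter=0.05, max_displacement=0.5,
                   decoy_perturb=separation, seed=seed)
    actives, decoys = generate_feature_molecules(spec)
    db = actives + decoys
    return db, [r.id for r in actives]
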