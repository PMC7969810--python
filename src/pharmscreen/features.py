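"""Pharmacophore feature perception on 3D conformers.

Four feature kinds are perceived: hydrogen-bond acceptor (HBA), donor (HBD),
hydrophobic (HY) and aromatic ring (AR). HBA/HBD sit on the heavy atom with a
direction along the mean bond axis; AR sits at the ring centroid with the
ring-plane normal; HY collapses each connected component of nonpolar carbons
(size >= 3 by default) to its centroid.

The chemistry lives in an editable SMARTS rule file
(``data/feature_rules.yaml``); the default rules follow published
Catalyst-style conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

import numpy as np
import yaml
from rdkit import Chem

KINDS = ("AR", "HBA", "HBD", "HY")


@dataclass(frozen=True)
class Feature:
    kind: str
    center: tuple  # (x, y, z) in Å
    direction: tuple | None  # unit vector or None
    source_atoms: tuple  # atom indices

    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


class FeatureRuleSet:
    """Compiled substructure patterns per feature kind."""

    def __init__(self, spec: dict):
        self.version = spec.get("version", 1)
        self.hy_min_atoms = int(spec.get("hy_min_atoms", 3))
        self.patterns = {}
        for kind, smarts_list in spec["patterns"].items():
            if kind not in KINDS:
                raise ValueError(f"unknown feature kind {kind!r}")
            compiled = []
            for s in smarts_list:
                q = Chem.MolFromSmarts(s)
                if q is None:
                    raise ValueError(f"SMARTS does not compile: {s!r}")
                compiled.append((s, q))
            self.patterns[kind] = compiled
        for kind in ("HBA", "HBD", "HY"):
            if kind not in self.patterns:
                raise ValueError(f"rule set must cover {kind}")

    @classmethod
    def from_file(cls, path) -> "FeatureRuleSet":
        return cls(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "FeatureRuleSet":
        text = files("pharmscreen.data").joinpath("feature_rules.yaml").read_text()
        return cls(yaml.safe_load(text))

    def match_atoms(self, mol: Chem.Mol, kind: str) -> set:
        hits = set()
        for _, q in self.patterns.get(kind, []):
            for match in mol.GetSubstructMatches(q):
                hits.add(match[0])
        return hits


_DEFAULT_RULES = None


def default_rules() -> FeatureRuleSet:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = FeatureRuleSet.default()
    return _DEFAULT_RULES


def _unit(v: np.ndarray) -> tuple | None:
    n = np.linalg.norm(v)
    if n < 1e-8:
        return None
    return tuple((v / n).tolist())


def _atom_direction(mol, coords, idx) -> tuple | None:
    """Direction away from the mean of the heavy-atom neighbors: the lone-pair
    / H-vector axis for terminal polar atoms."""
    nbrs = [n.GetIdx() for n in mol.GetAtomWithIdx(idx).GetNeighbors()]
    if not nbrs:
        return None
    mean_nbr = coords[nbrs].mean(axis=0)
    return _unit(coords[idx] - mean_nbr)


def _ring_normal(coords: np.ndarray) -> tuple | None:
    centered = coords - coords.mean(axis=0)
    # smallest principal axis of the ring atoms = plane normal
    _, _, vt = np.linalg.svd(centered)
    return _unit(vt[2])


def perceive_features(record, conformer_idx: int = 0,
                      rules: FeatureRuleSet | None = None) -> list[Feature]:
    """Perceive pharmacophore features on one conformer of a molecule.

    Returns a deterministic list sorted by (kind, source atom indices).
    Raises ``ValueError`` if the molecule has no 3D conformer.
    """
    rules = rules or default_rules()
    if not record.has_3d():
        raise ValueError(f"{record.id}: no 3D conformer; geometric stages need one")
    coords = np.asarray(record.conformers[conformer_idx], dtype=float)
    mol = record.mol
    feats: list[Feature] = []

    for kind in ("HBA", "HBD"):
        for idx in sorted(rules.match_atoms(mol, kind)):
            feats.append(Feature(kind=kind,
                                 center=tuple(coords[idx].tolist()),
                                 direction=_atom_direction(mol, coords, idx),
                                 source_atoms=(idx,)))

    # hydrophobic: connected components of nonpolar carbons, collapsed
    hy_atoms = rules.match_atoms(mol, "HY")
    seen = set()
    for start in sorted(hy_atoms):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            a = stack.pop()
            if a in comp:
                continue
            comp.add(a)
            for n in mol.GetAtomWithIdx(a).GetNeighbors():
                if n.GetIdx() in hy_atoms and n.GetIdx() not in comp:
                    stack.append(n.GetIdx())
        seen |= comp
        if len(comp) >= rules.hy_min_atoms:
            idxs = tuple(sorted(comp))
            feats.append(Feature(kind="HY",
                                 center=tuple(coords[list(idxs)].mean(axis=0).tolist()),
                                 direction=None,
                                 source_atoms=idxs))

    # aromatic rings: centroid + plane normal
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring):
            idxs = tuple(sorted(ring))
            ring_coords = coords[list(idxs)]
            feats.append(Feature(kind="AR",
                                 center=tuple(ring_coords.mean(axis=0).tolist()),
                                 direction=_ring_normal(ring_coords),
                                 source_atoms=idxs))

    feats.sort(key=lambda f: (f.kind, f.source_atoms))
    return feats


def features_to_tsv(feats: list[Feature]) -> str:
    lines = ["kind\tx\ty\tz\tatoms"]
    for f in feats:
        x, y, z = f.center
        lines.append(f"{f.kind}\t{x:.4f}\t{y:.4f}\t{z:.4f}\t"
                     + ",".join(map(str, f.source_atoms)))
    return "\n".join(lines) + "\n"
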