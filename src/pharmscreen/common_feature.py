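"""Common-feature (qualitative) pharmacophore generation.

Feature arrangements shared by all active molecules are found by
correspondence-graph clique detection: the most feature-rich active is the
reference; for every other active a product graph is built whose nodes are
kind-matched (reference-feature, other-feature) pairs and whose edges demand
pairwise-distance agreement within a bin; maximal cliques give the
arrangements of reference features present in that molecule, and
intersecting the clique sets across molecules gives the arrangements present
in all of them. Each arrangement is realized as a pharmacophore model with
the reference geometry and ranked by support, then size; a second ranking by
active/inactive fit discrimination selects the final model.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .features import perceive_features
from .pharmacophore import (PharmacophoreModel, SphereConstraint,
                            best_fit_over_conformers)


@dataclass
class CommonFeatureCandidate:
    model: PharmacophoreModel
    ref_indices: tuple       # feature indices on the reference molecule
    support: int             # number of actives mapping the model
    discrimination: float | None = None
    mean_fit_actives: float | None = None
    mean_fit_inactives: float | None = None

    @property
    def size(self) -> int:
        return len(self.model.constraints)


def _clique_ref_sets(ref_feats, other_feats, bin_width: float) -> set[frozenset]:
    """Reference-feature subsets realizable in ``other`` (maximal cliques of
    the correspondence graph)."""
    ref_xyz = np.array([f.center for f in ref_feats])
    oth_xyz = np.array([f.center for f in other_feats])
    nodes = [(i, j) for i, rf in enumerate(ref_feats)
             for j, of in enumerate(other_feats) if rf.kind == of.kind]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a in range(len(nodes)):
        i, j = nodes[a]
        for b in range(a + 1, len(nodes)):
            k, l = nodes[b]
            if i == k or j == l:
                continue
            dr = np.linalg.norm(ref_xyz[i] - ref_xyz[k])
            do = np.linalg.norm(oth_xyz[j] - oth_xyz[l])
            if abs(dr - do) <= bin_width:
                g.add_edge(nodes[a], nodes[b])
    out = set()
    for clique in nx.find_cliques(g):
        out.add(frozenset(i for i, _ in clique))
    return out


def _maximal_only(sets: set[frozenset]) -> set[frozenset]:
    return {s for s in sets
            if not any(s < t for t in sets)}


def build_common_feature_models(actives, min_features: int = 3,
                                max_features: int = 8, bin_width: float = 1.0,
                                tolerance: float = 1.6, weight: float = 1.0,
                                max_omitted: int = 1, rules=None
                                ) -> list[CommonFeatureCandidate]:
    """Arrangements common to all actives, ranked by support then size.

    Requires >= 2 active molecules with conformers and perceivable features.
    ``max_omitted`` is stored on the realized models (qualitative models
    tolerate partial mapping).
    """
    if len(actives) < 2:
        raise ValueError("need at least 2 active molecules")
    feats = {}
    for rec in actives:
        fl = perceive_features(rec, conformer_idx=0, rules=rules)
        if not fl:
            raise ValueError(f"{rec.id}: no perceivable features")
        feats[rec.id] = fl
    order = sorted(actives, key=lambda r: (-len(feats[r.id]), r.id))
    ref, others = order[0], order[1:]
    ref_feats = feats[ref.id]

    common = {frozenset(range(len(ref_feats)))}
    for rec in sorted(others, key=lambda r: r.id):
        cliques = _clique_ref_sets(ref_feats, feats[rec.id], bin_width)
        common = _maximal_only({c & s for c in common for s in cliques})
    common = {s for s in common if len(s) >= max(min_features, 2)}

    candidates = []
    for s in sorted(common, key=lambda s: (-len(s), tuple(sorted(s)))):
        idxs = tuple(sorted(s))[:max_features]
        cons = [SphereConstraint(kind=ref_feats[i].kind,
                                 center=ref_feats[i].center,
                                 tolerance=tolerance, weight=weight)
                for i in idxs]
        try:
            model = PharmacophoreModel(
                name=f"common:{ref.id}:{idxs}", constraints=cons,
                max_omitted=min(max_omitted, len(cons) - 1))
        except ValueError:
            continue
        support = sum(1 for rec in actives
                      if best_fit_over_conformers(rec, model, rules=rules).mapped)
        candidates.append(CommonFeatureCandidate(model=model, ref_indices=idxs,
                                                 support=support))
    candidates.sort(key=lambda c: (-c.support, -c.size, c.ref_indices))
    return candidates


def rank_by_discrimination(candidates, actives, inactives, rules=None
                           ) -> list[CommonFeatureCandidate]:
    """Stable sort of candidates by mean bestfit(actives) − mean
    bestfit(inactives), descending. Both sets must be non-empty."""
    if not actives or not inactives:
        raise ValueError("need non-empty active and inactive sets")
    for cand in candidates:
        fa = [best_fit_over_conformers(r, cand.model, rules=rules).fit
              for r in actives]
        fi = [best_fit_over_conformers(r, cand.model, rules=rules).fit
              for r in inactives]
        cand.mean_fit_actives = float(np.mean(fa))
        cand.mean_fit_inactives = float(np.mean(fi))
        cand.discrimination = cand.mean_fit_actives - cand.mean_fit_inactives
    return sorted(candidates, key=lambda c: -c.discrimination)
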