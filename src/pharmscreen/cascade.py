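"""Screening cascade: drug-likeness and property filters, similarity search,
external docking-score ingestion, and the multi-stage pipeline
(pharmacophore fit → Lipinski → ADMET → docking score → hit-list
intersection) with per-stage accounting.

ADMET levels are produced by surrogate descriptor models (an ESOL-style
log-solubility estimate, a polar-surface-area/logP absorption box, and a
TPSA-binned blood-brain-barrier class), binned to integer levels with the
same level/cutoff semantics as the screening protocol (favorable levels
3, 0 and 3). The bin edges are documented constants, not fitted values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski as RDLipinski, rdMolDescriptors
from rdkit import DataStructs

log = logging.getLogger(__name__)


@dataclass
class FilterThresholds:
    mw_max: float = 500.0
    rotatable_max: int = 10
    hba_max: int = 10
    hbd_max: int = 5
    admet_cutoffs: dict = field(default_factory=lambda: {
        "solubility": 3, "absorption": 0, "bbb": 3})
    similarity_min: float = 0.40
    docking_score_min: float | None = None


def _descriptors(record) -> dict:
    """Compute and cache the topology descriptors used by the filters."""
    if "mw" not in record.properties:
        mol = record.mol
        record.properties.update({
            "mw": Descriptors.MolWt(mol),
            "rotatable": rdMolDescriptors.CalcNumRotatableBonds(
                mol, rdMolDescriptors.NumRotatableBondsOptions.Strict),
            "hba": RDLipinski.NumHAcceptors(mol),
            "hbd": RDLipinski.NumHDonors(mol),
            "logp": Crippen.MolLogP(mol),
            "tpsa": rdMolDescriptors.CalcTPSA(mol),
        })
    return record.properties


def lipinski_filter(record, thresholds: FilterThresholds | None = None
                    ) -> tuple[bool, list[str]]:
    """Strict rule-of-five check (no one-violation allowance): MW ≤ 500 Da,
    rotatable bonds ≤ 10, H-bond acceptors ≤ 10, H-bond donors ≤ 5. All
    bounds inclusive. Rotatable bonds are non-ring single bonds between two
    non-terminal heavy atoms, amide C–N excluded."""
    t = thresholds or FilterThresholds()
    d = _descriptors(record)
    violations = []
    if d["mw"] > t.mw_max:
        violations.append("mw")
    if d["rotatable"] > t.rotatable_max:
        violations.append("rotatable")
    if d["hba"] > t.hba_max:
        violations.append("hba")
    if d["hbd"] > t.hbd_max:
        violations.append("hbd")
    return (not violations), violations


# Surrogate ADMET level bins (documented constants).
# Solubility level from an ESOL-style logS estimate:
#   logS < -8 -> 0, [-8,-6) -> 1, [-6,-4) -> 2, [-4,-2) -> 3 (good),
#   [-2,0) -> 4, >= 0 -> 5.
# Absorption level from a (TPSA, logP) box: 0 (good) inside
#   TPSA <= 131.6 and logP <= 5; 1 inside TPSA <= 148.1 and logP <= 6;
#   2 inside TPSA <= 164.6 and logP <= 7; else 3.
# BBB penetration level from TPSA: < 40 -> 0 (very high), [40,60) -> 1,
#   [60,90) -> 2, >= 90 -> 3 (low).
_SOL_EDGES = (-8.0, -6.0, -4.0, -2.0, 0.0)
_ABS_BOXES = ((131.6, 5.0), (148.1, 6.0), (164.6, 7.0))
_BBB_EDGES = (40.0, 60.0, 90.0)


def esol_logS(record) -> float:
    """ESOL estimate: logS = 0.16 − 0.63·logP − 0.0062·MW + 0.066·RB − 0.74·AP."""
    d = _descriptors(record)
    mol = record.mol
    heavy = mol.GetNumHeavyAtoms()
    arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = arom / heavy if heavy else 0.0
    return 0.16 - 0.63 * d["logp"] - 0.0062 * d["mw"] + 0.066 * d["rotatable"] - 0.74 * ap


def admet_levels(record) -> dict:
    d = _descriptors(record)
    logs = esol_logS(record)
    sol = sum(logs >= e for e in _SOL_EDGES)
    absorption = 3
    for lvl, (tpsa_max, logp_max) in enumerate(_ABS_BOXES):
        if d["tpsa"] <= tpsa_max and d["logp"] <= logp_max:
            absorption = lvl
            break
    bbb = sum(d["tpsa"] >= e for e in _BBB_EDGES)
    return {"solubility": sol, "absorption": absorption, "bbb": bbb}


def admet_filter(record, cutoffs: dict | None = None) -> tuple[bool, dict]:
    """Pass iff every surrogate level equals its favorable cutoff
    (default solubility 3, absorption 0, BBB 3 — equality semantics)."""
    cutoffs = cutoffs or {"solubility": 3, "absorption": 0, "bbb": 3}
    levels = admet_levels(record)
    ok = all(levels[k] == v for k, v in cutoffs.items())
    return ok, levels


# --- similarity search ------------------------------------------------------

def _fingerprint(record):
    if "fp" not in record.properties:
        record.properties["fp"] = Chem.RDKFingerprint(record.mol)
    return record.properties["fp"]


def similarity_search(query, database, min_similarity: float = 0.40,
                      anchor_smarts: str | None = None) -> list[tuple[str, float]]:
    """Tanimoto search on hashed topological fingerprints, optionally
    requiring an anchor substructure. Returns (id, similarity) sorted by
    similarity descending (ties by id)."""
    qfp = _fingerprint(query)
    anchor = Chem.MolFromSmarts(anchor_smarts) if anchor_smarts else None
    if anchor_smarts and anchor is None:
        raise ValueError(f"anchor SMARTS does not compile: {anchor_smarts!r}")
    hits = []
    for rec in database:
        sim = DataStructs.TanimotoSimilarity(qfp, _fingerprint(rec))
        if sim >= min_similarity:
            if anchor is not None and not rec.mol.HasSubstructMatch(anchor):
                continue
            hits.append((rec.id, sim))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


# --- docking-score ingestion ------------------------------------------------

def ingest_docking_scores(path) -> dict[str, float]:
    """Read an externally produced (id, score) TSV; duplicate ids keep the
    last row with a warning."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"malformed docking-score table {path}: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "score" not in cols:
        raise ValueError(f"{path}: need 'id' and 'score' columns, got {list(df.columns)}")
    scores: dict[str, float] = {}
    for _, row in df.iterrows():
        rid = str(row[cols["id"]])
        val = float(row[cols["score"]])
        if rid in scores:
            log.warning("duplicate docking score for %s; keeping last", rid)
        scores[rid] = val
    return scores


def apply_score_filter(hit_ids, scores: dict[str, float],
                       min_score: float) -> list[str]:
    """Keep hits with score >= min_score (inclusive); hits without a score
    are dropped with a warning."""
    kept = []
    for rid in hit_ids:
        if rid not in scores:
            log.warning("no docking score for %s; dropped", rid)
            continue
        if scores[rid] >= min_score:
            kept.append(rid)
    return kept


# --- the cascade ------------------------------------------------------------

@dataclass
class Stage:
    name: str
    n_in: int
    n_out: int
    survivors: list


@dataclass
class ScreenReport:
    stages: list = field(default_factory=list)
    hits: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def add(self, name, ids_in, ids_out):
        self.stages.append(Stage(name=name, n_in=len(ids_in),
                                 n_out=len(ids_out), survivors=list(ids_out)))
        log.info("stage %-28s %6d -> %d", name, len(ids_in), len(ids_out))

    def to_tsv(self) -> str:
        lines = ["stage\tn_in\tn_out"]
        lines += [f"{s.name}\t{s.n_in}\t{s.n_out}" for s in self.stages]
        return "\n".join(lines) + "\n"


def _run_arm(label, database, model, fit_threshold, thresholds,
             docking_scores, report, rules=None):
    from .pharmacophore import best_fit_over_conformers
    by_id = {r.id: r for r in database}
    ids = [r.id for r in database]

    fits = {r.id: best_fit_over_conformers(r, model, rules=rules).fit
            for r in database}
    mapped = [i for i in ids if fits[i] > 0]
    report.add(f"{label}:map", ids, mapped)
    passed_fit = [i for i in mapped if fits[i] > fit_threshold]
    report.add(f"{label}:fit>{fit_threshold:g}", mapped, passed_fit)

    lip = [i for i in passed_fit if lipinski_filter(by_id[i], thresholds)[0]]
    report.add(f"{label}:lipinski", passed_fit, lip)
    adm = [i for i in lip if admet_filter(by_id[i], thresholds.admet_cutoffs)[0]]
    report.add(f"{label}:admet", lip, adm)

    if docking_scores is not None and thresholds.docking_score_min is not None:
        dock = apply_score_filter(adm, docking_scores, thresholds.docking_score_min)
        report.add(f"{label}:dock>={thresholds.docking_score_min:g}", adm, dock)
        return dock
    return adm


def run_cascade(database, models, thresholds: FilterThresholds | None = None,
                docking_scores: dict | None = None, rules=None) -> ScreenReport:
    """Run the full screening cascade.

    ``models`` is a list of one or two ``(PharmacophoreModel, fit_threshold)``
    arms. Each arm runs mapping → fit threshold (strict >) → Lipinski →
    ADMET → optional docking-score filter; with two arms the final hit list
    is the intersection of the survivor sets (order preserved from the first
    arm). Per-stage input/output counts are logged in the report.
    """
    if not database:
        raise ValueError("empty database")
    if not 1 <= len(models) <= 2:
        raise ValueError("need one or two (model, fit_threshold) arms")
    thresholds = thresholds or FilterThresholds()
    report = ScreenReport()
    arm_hits = []
    for k, (model, fit_t) in enumerate(models):
        label = model.name or f"arm{k}"
        arm_hits.append(_run_arm(label, database, model, fit_t, thresholds,
                                 docking_scores, report, rules=rules))
    if len(arm_hits) == 2:
        other = set(arm_hits[1])
        final = [i for i in arm_hits[0] if i in other]
        report.add("intersection", arm_hits[0] + arm_hits[1], final)
    else:
        final = arm_hits[0]
        report.notes.append("single-model run: intersection stage skipped")
    report.hits = final
    return report
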