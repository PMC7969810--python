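import numpy as np
import pytest
from rdkit import Chem

from pharmscreen import (FilterThresholds, MoleculeRecord, PharmacophoreModel,
                         admet_filter, apply_score_filter, admet_levels,
                         ingest_docking_scores, lipinski_filter, run_cascade,
                         similarity_search)
from pharmscreen.cascade import _descriptors
from pharmscreen.synthetic import (SimSpec, default_planted_model,
                                   generate_feature_molecules)

SULFADIAZINE = "Nc1ccc(cc1)S(=O)(=O)Nc1ncccn1"


# --- Lipinski ---------------------------------------------------------------

def test_ethanol_passes_rule_of_five():
    rec = MoleculeRecord.from_smiles("ethanol", "CCO")
    ok, violations = lipinski_filter(rec)
    assert ok and violations == []
    d = rec.properties
    assert d["mw"] == pytest.approx(46.07, abs=0.01)
    assert d["rotatable"] == 0 and d["hba"] == 1 and d["hbd"] == 1


def test_c40_alkane_fails_on_molecular_weight():
    rec = MoleculeRecord.from_smiles("c40", "C" * 40)
    ok, violations = lipinski_filter(rec)
    assert not ok and "mw" in violations
    assert rec.properties["mw"] == pytest.approx(40 * 12.011 + 82 * 1.008, abs=0.05)


def test_mw_bound_is_inclusive():
    rec = MoleculeRecord.from_smiles("x", "CCO")
    mw = _descriptors(rec)["mw"]
    ok, _ = lipinski_filter(rec, FilterThresholds(mw_max=mw))
    assert ok  # sitting exactly at the threshold passes (≤ semantics)


# --- ADMET ------------------------------------------------------------------

def test_favorable_molecule_passes_with_levels_3_0_3():
    rec = MoleculeRecord.from_smiles("sulfadiazine", SULFADIAZINE)
    ok, levels = admet_filter(rec)
    assert ok and levels == {"solubility": 3, "absorption": 0, "bbb": 3}


def test_extreme_logp_fails_absorption_and_cutoffs_are_config():
    rec = MoleculeRecord.from_smiles("c30", "C" * 30)
    ok, levels = admet_filter(rec)
    assert not ok and levels["absorption"] != 0
    ok2, _ = admet_filter(rec, cutoffs=dict(levels))
    assert ok2  # widened (matched) cutoffs pass the same molecule


# --- similarity search ------------------------------------------------------

def test_query_matches_itself_and_not_bitless_molecules():
    q = MoleculeRecord.from_smiles("q", "CCO")
    self_hit = similarity_search(q, [MoleculeRecord.from_smiles("q2", "CCO")])
    assert self_hit == [("q2", 1.0)]
    # single-atom molecule has an empty path fingerprint: similarity 0
    none_hit = similarity_search(q, [MoleculeRecord.from_smiles("m", "C")])
    assert none_hit == []


def test_similarity_matches_explicit_bitset_oracle():
    rng = np.random.default_rng(4)
    smiles = ["CCO", "CCN", "CCCC", "c1ccccc1", "c1ccccc1O", "CC(=O)C",
              "CCOC", "CCCN", "c1ccncc1", "CC(C)C", "CCS", "OCCO",
              "c1ccccc1C", "CC#N", "CCCl", "C1CCCCC1", "CC(C)O", "CCC=O",
              "NCCN", "c1ccccc1N"]
    db = [MoleculeRecord.from_smiles(f"m{i}", s) for i, s in enumerate(smiles)]
    q = MoleculeRecord.from_smiles("q", "CCOCC")
    hits = dict(similarity_search(q, db, min_similarity=0.2))
    qbits = set(Chem.RDKFingerprint(q.mol).GetOnBits())
    expected = {}
    for rec in db:
        bits = set(Chem.RDKFingerprint(rec.mol).GetOnBits())
        inter = len(qbits & bits)
        union = len(qbits | bits)
        tan = inter / union if union else 0.0
        if tan >= 0.2:
            expected[rec.id] = tan
    assert set(hits) == set(expected)
    for k in hits:
        assert hits[k] == pytest.approx(expected[k], abs=1e-12)


def test_anchor_substructure_is_required_when_given():
    q = MoleculeRecord.from_smiles("q", "c1ccccc1CCO")
    db = [MoleculeRecord.from_smiles("arom", "c1ccccc1CCC"),
          MoleculeRecord.from_smiles("aliph", "CCCCCO")]
    hits = similarity_search(q, db, min_similarity=0.1, anchor_smarts="c1ccccc1")
    assert [h[0] for h in hits] == ["arom"]


# --- docking scores ---------------------------------------------------------

def test_score_filter_threshold_and_missing_ids(tmp_path):
    p = tmp_path / "scores.tsv"
    p.write_text("id\tscore\nh1\t62\nh2\t59\nh3\t61\nh4\t60\n")
    scores = ingest_docking_scores(p)
    kept = apply_score_filter(["h1", "h2", "h3", "h4", "h5"], scores, 60)
    assert kept == ["h1", "h3", "h4"]  # >= is inclusive; h5 missing -> dropped
    assert apply_score_filter(["h1"], {}, 60) == []


def test_duplicate_score_rows_keep_last(tmp_path):
    p = tmp_path / "scores.tsv"
    p.write_text("id\tscore\nh1\t10\nh1\t70\n")
    assert ingest_docking_scores(p)["h1"] == 70.0


def test_malformed_score_table_is_fatal(tmp_path):
    p = tmp_path / "scores.tsv"
    p.write_text("id\tscore\nh1\tnot_a_number\n")
    with pytest.raises(ValueError):
        ingest_docking_scores(p)


# --- cascade ----------------------------------------------------------------

def _planted_db(seed=21, n_actives=10, n_decoys=90):
    model = default_planted_model()
    spec = SimSpec(model=model, n_actives=n_actives, n_decoys=n_decoys,
                   max_displacement=0.3, decoy_perturb=3.0,
                   n_extra_features=0, seed=seed)
    actives, decoys = generate_feature_molecules(spec)
    return model, actives, decoys


@pytest.fixture(scope="module")
def planted_cascade():
    model, actives, decoys = _planted_db()
    arm_b = PharmacophoreModel("sub", model.constraints[:4], max_omitted=0)
    # actives share one fragment composition: identical filter descriptors
    cutoffs = admet_levels(actives[0])
    thresholds = FilterThresholds(admet_cutoffs=cutoffs,
                                  docking_score_min=60.0)
    scores = {r.id: 65.0 for r in actives}
    scores.update({r.id: 65.0 for r in decoys[:40]})
    return model, arm_b, actives, decoys, thresholds, scores


def test_planted_survivors_reach_the_final_list(planted_cascade):
    model, arm_b, actives, decoys, thresholds, scores = planted_cascade
    db = actives + decoys
    report = run_cascade(db, [(model, 8.0), (arm_b, 6.0)], thresholds,
                         docking_scores=scores)
    assert set(report.hits) == {r.id for r in actives}
    inter = report.stages[-1]
    assert inter.name == "intersection" and inter.n_out == len(actives)


def test_cascade_attrition_is_monotone(planted_cascade):
    model, arm_b, actives, decoys, thresholds, scores = planted_cascade
    report = run_cascade(actives + decoys, [(model, 8.0), (arm_b, 6.0)],
                         thresholds, docking_scores=scores)
    arm_stages = {}
    for s in report.stages[:-1]:
        arm_stages.setdefault(s.name.split(":")[0], []).append(s)
    for stages in arm_stages.values():
        for prev, nxt in zip(stages, stages[1:]):
            assert nxt.n_in == prev.n_out
            assert nxt.n_out <= nxt.n_in
            assert set(nxt.survivors) <= set(prev.survivors)
    assert set(report.hits) <= set(report.stages[-1].survivors)


def test_intersection_is_symmetric(planted_cascade):
    model, arm_b, actives, decoys, thresholds, scores = planted_cascade
    db = actives + decoys
    ab = run_cascade(db, [(model, 8.0), (arm_b, 6.0)], thresholds,
                     docking_scores=scores)
    ba = run_cascade(db, [(arm_b, 6.0), (model, 8.0)], thresholds,
                     docking_scores=scores)
    assert set(ab.hits) == set(ba.hits)


def test_filter_order_does_not_change_the_final_set(planted_cascade):
    _, _, actives, decoys, thresholds, _ = planted_cascade
    db = actives + decoys
    lip_then_adm = [r.id for r in db
                    if lipinski_filter(r, thresholds)[0]
                    and admet_filter(r, thresholds.admet_cutoffs)[0]]
    adm_then_lip = [r.id for r in db
                    if admet_filter(r, thresholds.admet_cutoffs)[0]
                    and lipinski_filter(r, thresholds)[0]]
    assert lip_then_adm == adm_then_lip


def test_unreachable_fit_threshold_zeroes_the_cascade(planted_cascade):
    model, _, actives, decoys, thresholds, scores = planted_cascade
    report = run_cascade(actives + decoys, [(model, model.total_weight + 1)],
                         thresholds, docking_scores=scores)
    assert report.hits == []
    fit_stage = report.stages[1]
    assert fit_stage.n_out == 0
    for s in report.stages[2:]:
        assert s.n_in == 0 and s.n_out == 0
    assert any("intersection" in n for n in report.notes)


def test_empty_database_rejected(planted_cascade):
    model = planted_cascade[0]
    with pytest.raises(ValueError):
        run_cascade([], [(model, 1.0)])
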