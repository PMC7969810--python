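"""Model validation machinery: decoy-set retrieval statistics, the Fischer
randomization (label-permutation) test, and selectivity indexes.

Decoy-set metrics follow the Güner-Henry conventions. With database size D,
actives A, hits Ht and active hits Ha:

    % yield  = 100 · Ha / Ht
    % ratio  = 100 · Ha / A
    EF       = (Ha · D) / (Ht · A)
    GF       = (Ha / (4·Ht·A)) · (3A + Ht) · (1 − (Ht − Ha)/(D − A))

EF is the fold enrichment of actives in the hit list over random selection
(EF = 1 in expectation under random retrieval); GF lies in [0, 1] with 1 for
perfect retrieval. All fields are kept at full precision; rounding to two
decimals happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DecoyStats:
    D: int
    A: int
    Ht: int
    Ha: int
    yield_pct: float | None
    ratio_pct: float
    EF: float | None
    GF: float
    false_neg: int
    false_pos: int

    def report_rows(self) -> list[tuple[str, object]]:
        r2 = lambda v: None if v is None else round(v, 2)
        return [
            ("Total number of molecules in database (D)", self.D),
            ("Total number of actives in database (A)", self.A),
            ("Total number of hit molecules from the database (Ht)", self.Ht),
            ("Total number of active molecules in hit list (Ha)", self.Ha),
            ("% Yield of actives", r2(self.yield_pct)),
            ("% Ratio of actives", r2(self.ratio_pct)),
            ("Enrichment factor (EF)", r2(self.EF)),
            ("False negatives", self.false_neg),
            ("False positives", self.false_pos),
            ("Goodness of fit score (GF)", round(self.GF, 4)),
        ]


def decoy_statistics(D: int, A: int, Ht: int, Ha: int) -> DecoyStats:
    """Retrieval statistics for a decoy-set screen (see module docstring).

    With an empty hit list (Ht = 0) the yield and EF are undefined and
    reported as None; the remaining fields are still computed.
    """
    if not (0 < A < D):
        raise ValueError("need 0 < A < D")
    if not (0 <= Ht <= D and 0 <= Ha <= min(Ht, A)):
        raise ValueError("need 0 <= Ha <= min(Ht, A) and Ht <= D")
    if Ht - Ha > D - A:
        raise ValueError("inactive hits (Ht - Ha) cannot exceed inactives (D - A)")
    if Ht > 0:
        yield_pct = 100.0 * Ha / Ht
        ef = (Ha * D) / (Ht * A)
        gf = (Ha / (4.0 * Ht * A)) * (3 * A + Ht) * (1.0 - (Ht - Ha) / (D - A))
    else:
        yield_pct, ef, gf = None, None, 0.0
    return DecoyStats(D=D, A=A, Ht=Ht, Ha=Ha, yield_pct=yield_pct,
                      ratio_pct=100.0 * Ha / A, EF=ef, GF=gf,
                      false_neg=A - Ha, false_pos=Ht - Ha)


def screen_counts(database, active_ids, model, fit_threshold: float,
                  rules=None) -> DecoyStats:
    """Screen a database with a model at a fit threshold (strict >) and
    compute decoy statistics against the known active-id list."""
    from .pharmacophore import best_fit_over_conformers
    active_ids = set(active_ids)
    hits = [r.id for r in database
            if best_fit_over_conformers(r, model, rules=rules).fit > fit_threshold]
    ha = sum(1 for h in hits if h in active_ids)
    return decoy_statistics(D=len(database), A=len(active_ids),
                            Ht=len(hits), Ha=ha)


# --- Fischer randomization --------------------------------------------------

def fischer_permutation_count(confidence_pct: float) -> int:
    """Number of label permutations prescribed at a confidence level:
    100/(100 − CL) − 1, e.g. 19 at 95%. Non-integral levels are rejected."""
    if not 0 < confidence_pct < 100:
        raise ValueError("confidence level must be in (0, 100)")
    ratio = 100.0 / (100.0 - confidence_pct)
    n = round(ratio) - 1
    if abs(ratio - round(ratio)) > 1e-9 or n < 1:
        valid = [100 * (1 - 1 / k) for k in (10, 20, 50, 100)]
        raise ValueError(
            f"confidence level {confidence_pct}% does not give an integral "
            f"permutation count; nearest valid levels include {valid}")
    return n


@dataclass
class FischerResult:
    confidence_pct: float
    n_permutations: int
    true_score: float
    permuted_scores: list
    rank: int            # 1 = true score beats every permuted score
    significant: bool    # strict rank 1; ties count against significance


def fischer_randomization(records, model_builder, confidence_pct: float = 95.0,
                          seed: int = 0) -> FischerResult:
    """Label-permutation test of a structure–activity model.

    ``model_builder(records) -> score`` rebuilds the model on the given
    records and returns its training score (here: the fit/activity
    log-correlation). The activities are shuffled ``n_permutations`` times
    (seeded); significance requires the unpermuted score to strictly exceed
    every permuted score (rank 1 of n_permutations + 1).
    """
    n_perm = fischer_permutation_count(confidence_pct)
    rng = np.random.default_rng(seed)
    true_score = float(model_builder(records))
    activities = [r.activity_ic50 for r in records]
    permuted = []
    for _ in range(n_perm):
        shuffled = list(rng.permutation(activities))
        shuffled_records = [_with_activity(r, a) for r, a in zip(records, shuffled)]
        permuted.append(float(model_builder(shuffled_records)))
    rank = 1 + sum(1 for s in permuted if s >= true_score)
    return FischerResult(confidence_pct=confidence_pct, n_permutations=n_perm,
                         true_score=true_score, permuted_scores=permuted,
                         rank=rank, significant=(rank == 1))


def _with_activity(record, activity):
    from .chem_io import MoleculeRecord
    return MoleculeRecord(id=record.id, mol=record.mol,
                          conformers=list(record.conformers),
                          activity_ic50=activity,
                          properties=dict(record.properties))


def selectivity_index(ic50_reference: float, ic50_target: float) -> float:
    """SI = IC50(reference / normal cells) / IC50(target cells); > 1 means the
    compound spares the reference cells. Report to 2 decimals."""
    if not (ic50_reference > 0 and ic50_target > 0):
        raise ValueError("IC50 values must be positive")
    return ic50_reference / ic50_target
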