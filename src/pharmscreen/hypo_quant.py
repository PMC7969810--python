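"""Quantitative pharmacophore layer: fit→IC50 calibration and prediction.

The activity model is log-linear:  log10(IC50_pred) = C − fit,  with a single
calibration constant C (log10-μM units) per model. Higher fit therefore means
lower predicted IC50. The constant is the least-squares intercept

    C = mean_i( fit_i + log10 IC50_i )

over calibration pairs. Predictions are summarized by the signed error factor
(fold over/under-prediction, magnitude always >= 1) and a three-level
activity scale: highly active (+++, IC50 <= 0.1 μM), moderately active (++,
0.1 < IC50 < 3 μM), least active (+, IC50 >= 3 μM).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .features import perceive_features
from .pharmacophore import (PharmacophoreModel, SphereConstraint,
                            best_fit_over_conformers)

log = logging.getLogger(__name__)

SCALE_HIGH = 0.1   # μM; inclusive upper bound of the +++ class
SCALE_LOW = 3.0    # μM; inclusive lower bound of the + class


def calibrate_constant(fits, activities) -> float:
    """Least-squares calibration constant C = mean(fit + log10 IC50)."""
    fits = np.asarray(fits, dtype=float)
    act = np.asarray(act_check(activities), dtype=float)
    if fits.shape != act.shape or fits.size == 0:
        raise ValueError("need equal-length non-empty fit and activity lists")
    return float(np.mean(fits + np.log10(act)))


def act_check(activities):
    act = np.asarray(activities, dtype=float)
    if act.size and not np.all(act > 0):
        raise ValueError("IC50 values must be positive")
    return act


def predict_activity(fit: float, calibration_C: float) -> float:
    """Predicted IC50 in μM: 10^(C − fit)."""
    return float(10.0 ** (calibration_C - fit))


def error_factor(experimental: float, predicted: float) -> float:
    """Signed fold error: +pred/exp when the model over-predicts the IC50
    (pred >= exp), −exp/pred when it under-predicts. |result| >= 1 always."""
    if not (experimental > 0 and predicted > 0):
        raise ValueError("IC50 values must be positive")
    if predicted >= experimental:
        return predicted / experimental
    return -experimental / predicted


def activity_scale(ic50: float) -> str:
    """Three-level activity class of an IC50 in μM."""
    if not ic50 > 0:
        raise ValueError("IC50 must be positive")
    if ic50 <= SCALE_HIGH:
        return "+++"
    if ic50 >= SCALE_LOW:
        return "+"
    return "++"


@dataclass
class Prediction:
    id: str
    fit: float
    predicted_ic50: float
    scale: str
    error_factor: float | None = None


@dataclass
class AssessmentReport:
    """Agreement between experimental and predicted IC50 sets.

    ``pearson_r_log`` is the Pearson correlation of log10 values;
    ``r_squared_log`` its square (the coefficient of determination of the
    log-log regression). Scale agreement counts compounds whose predicted
    activity class matches the experimental one.
    """
    n: int
    pearson_r_log: float
    r_squared_log: float
    scale_agreement: int
    predictions: list = field(default_factory=list)


def assess_predictions(experimental, predicted, ids=None) -> AssessmentReport:
    exp = act_check(experimental)
    pred = act_check(predicted)
    if exp.shape != pred.shape or exp.size < 3:
        raise ValueError("need >= 3 matched (experimental, predicted) pairs")
    r = float(_stats.pearsonr(np.log10(exp), np.log10(pred)).statistic)
    agree = sum(activity_scale(e) == activity_scale(p) for e, p in zip(exp, pred))
    ids = ids if ids is not None else [str(i + 1) for i in range(exp.size)]
    preds = [Prediction(id=str(i), fit=float("nan"), predicted_ic50=float(p),
                        scale=activity_scale(p), error_factor=error_factor(e, p))
             for i, e, p in zip(ids, exp, pred)]
    return AssessmentReport(n=int(exp.size), pearson_r_log=r,
                            r_squared_log=r * r, scale_agreement=int(agree),
                            predictions=preds)


def predict_table(records, model: PharmacophoreModel, rules=None) -> list[Prediction]:
    """Fit every molecule against a calibrated model and predict its IC50."""
    if model.calibration_C is None:
        raise ValueError("model has no calibration constant")
    out = []
    for rec in records:
        res = best_fit_over_conformers(rec, model, rules=rules)
        ic50 = predict_activity(res.fit, model.calibration_C)
        ef = (error_factor(rec.activity_ic50, ic50)
              if rec.activity_ic50 is not None else None)
        out.append(Prediction(id=rec.id, fit=res.fit, predicted_ic50=ic50,
                              scale=activity_scale(ic50), error_factor=ef))
    return out


# --- candidate model construction ------------------------------------------

def training_score(model: PharmacophoreModel, records, rules=None) -> float:
    """Quality of a candidate model: Pearson correlation between fit values
    and −log10(IC50) over the training set. NaN-safe (degenerate fits → −1)."""
    fits = [best_fit_over_conformers(r, model, rules=rules).fit for r in records]
    pic50 = [-np.log10(r.activity_ic50) for r in records]
    if np.std(fits) < 1e-12:
        return -1.0
    return float(np.corrcoef(fits, pic50)[0, 1])


def construct_quantitative_model(records, min_features: int = 4,
                                 max_features: int = 6, tolerance: float = 1.6,
                                 weight: float = 1.0, rules=None,
                                 name: str = "hypo") -> tuple[PharmacophoreModel, list]:
    """Build a quantitative pharmacophore from activity-annotated molecules.

    Candidate constraint sets are taken from the feature arrangements of the
    two most active training compounds (all subsets of ``min_features`` to
    ``max_features`` features, realized as tolerance spheres at the feature
    centers). Each candidate is scored by the correlation of its fit values
    with −log10(IC50) over the whole training set; the best-scoring candidate
    wins and its calibration constant is fitted on the winner's fits.

    Returns ``(model, evaluation_log)`` where the log records every candidate
    and its score. Requires >= 8 compounds spanning >= 1 log unit of
    activity (>= 3 log units is the intended design regime).
    """
    recs = [r for r in records if r.activity_ic50 is not None and r.has_3d()]
    if len(recs) < 8:
        raise ValueError("need at least 8 activity-annotated 3D training compounds")
    span = np.log10(max(r.activity_ic50 for r in recs) /
                    min(r.activity_ic50 for r in recs))
    if span < 1.0:
        raise ValueError(f"activity span {span:.2f} log units < 1; unlearnable")

    seeds = sorted(recs, key=lambda r: (r.activity_ic50, r.id))[:2]
    evaluated, best, best_key = [], None, None
    for seed in seeds:
        feats = perceive_features(seed, conformer_idx=0, rules=rules)
        for k in range(min_features, min(max_features, len(feats)) + 1):
            for combo in itertools.combinations(range(len(feats)), k):
                cons = [SphereConstraint(kind=feats[i].kind,
                                         center=feats[i].center,
                                         tolerance=tolerance, weight=weight)
                        for i in combo]
                cand = PharmacophoreModel(name=f"{name}:{seed.id}:{combo}",
                                          constraints=cons, max_omitted=0)
                score = training_score(cand, recs, rules=rules)
                evaluated.append({"seed": seed.id, "features": combo,
                                  "size": k, "score": score})
                key = (score, k, -len(evaluated))  # ties: larger model, earlier seed
                if best is None or key > best_key:
                    best, best_key = cand, key
    if best is None:
        raise ValueError("no candidate models (too few perceived features)")
    fits = [best_fit_over_conformers(r, best, rules=rules).fit for r in recs]
    best.calibration_C = calibrate_constant(fits, [r.activity_ic50 for r in recs])
    best.name = name
    log.info("selected %s from %d candidates (score %.3f)",
             best.name, len(evaluated), best_key[0])
    return best, evaluated
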