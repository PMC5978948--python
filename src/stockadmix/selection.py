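"""Candidate models and the three-step selection cascade.

Twenty-one beta-regression models of per-lake mean domestic membership are
built from the nine predictors: environment-only models, stocking-only
models, and mixed models (some with interactions between stocking
variables). Selection proceeds in three steps:

1. AICc shortlist — models within 2 Δi of the smallest AICc;
2. predictive screen — leave-one-lake-out jackknife; a model stays only if
   the mean absolute difference between observed and predicted mean
   domestic membership is below 0.05;
3. among the survivors, the model with the highest adjusted pseudo-R² wins.

Akaike weights over the full candidate set and weighted model averaging of
individual coefficients are also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .betareg import BetaRegFit, fit_betareg, predict, standardize
from .datasets import ENVIRONMENT_VARIABLES, STOCKING_VARIABLES

#: Terms of the 21 candidate models, keyed by their published numbering.
CANDIDATE_TERMS: dict[int, list[str]] = {
    1: ["MeanpH", "MeanO2", "MeanTemp", "Depth", "LakeSize"],
    2: ["MeanpH", "MeanO2", "MeanTemp"],
    3: ["Depth", "LakeSize"],
    4: ["MeanTemp", "TotalHa"],
    5: ["TotalHa", "SinceMeanYear", "MeanFishStock", "NbStockEv"],
    6: ["SinceMeanYear", "MeanFishStock", "NbStockEv"],
    7: ["SinceMeanYear", "TotalHa", "MeanFishStock"],
    8: ["TotalHa", "SinceMeanYear"],
    9: ["MeanFishStock", "NbStockEv"],
    10: ["TotalHa", "NbStockEv", "MeanFishStock", "TotalHa:NbStockEv", "SinceMeanYear"],
    11: ["TotalHa:NbStockEv", "TotalHa", "NbStockEv"],
    12: ["TotalHa", "MeanFishStock"],
    13: ["SinceMeanYear", "MeanFishStock"],
    14: ["SinceMeanYear:TotalHa", "SinceMeanYear", "TotalHa", "MeanFishStock"],
    15: ["NbStockEv:TotalHa", "NbStockEv", "TotalHa", "SinceMeanYear"],
    16: ["NbStockEv:TotalHa", "NbStockEv", "TotalHa", "MeanFishStock"],
    17: ["SinceMeanYear"],
    18: ["SinceMeanYear", "MeanFishStock", "MeanTemp"],
    19: ["SinceMeanYear", "MeanFishStock", "NbStockEv", "LakeSize"],
    20: ["TotalHa", "MeanTemp", "MeanO2"],
    21: ["SinceMeanYear", "MeanFishStock", "LakeSize", "MeanTemp"],
}

RESPONSE = "qDomestic"


@dataclass
class ModelSpec:
    model_id: int
    terms: list[str]
    category: str  # environment | stocking | mixed


@dataclass
class JackknifeReport:
    model_id: int
    lake_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    differences: np.ndarray
    mean_abs_difference: float
    failed_lakes: list[str] = field(default_factory=list)


@dataclass
class SelectionResult:
    table: pd.DataFrame  # per-model audit (aicc, delta, weight, flags, ...)
    fits: dict[int, BetaRegFit]
    jackknife: dict[int, JackknifeReport]
    shortlist: list[int]
    survivors: list[int]
    best_model_id: int | None


def _category(terms: list[str]) -> str:
    variables = {v for t in terms for v in t.split(":")}
    has_env = bool(variables & set(ENVIRONMENT_VARIABLES))
    has_stock = bool(variables & set(STOCKING_VARIABLES))
    if has_env and has_stock:
        return "mixed"
    return "environment" if has_env else "stocking"


def build_candidates() -> list[ModelSpec]:
    """The 21 candidate model specifications."""
    return [
        ModelSpec(model_id=mid, terms=list(terms), category=_category(terms))
        for mid, terms in sorted(CANDIDATE_TERMS.items())
    ]


def fit_candidates(data: pd.DataFrame, response: str = RESPONSE) -> dict[int, BetaRegFit]:
    y = data[response].to_numpy(dtype=float)
    fits = {}
    for spec in build_candidates():
        fits[spec.model_id] = fit_betareg(standardize(data, spec.terms), y)
    return fits


def rank_aicc(fits: dict[int, BetaRegFit], delta_max: float = 2.0) -> pd.DataFrame:
    """Δi and Akaike weights; shortlist is Δi <= delta_max.

    Non-converged fits are excluded from ranking with a warning.
    """
    usable = {mid: f for mid, f in fits.items() if f.converged}
    dropped = sorted(set(fits) - set(usable))
    if dropped:
        warnings.warn(f"excluding non-converged fits from ranking: {dropped}")
    if not usable:
        raise ValueError("no converged fits to rank")
    mids = sorted(usable)
    aicc_values = np.array([usable[m].aicc for m in mids])
    delta = aicc_values - aicc_values.min()
    rel = np.exp(-delta / 2.0)
    weights = rel / rel.sum()
    return pd.DataFrame(
        {
            "model_id": mids,
            "aicc": aicc_values,
            "delta_i": delta,
            "weight": weights,
            "shortlisted": delta <= delta_max,
        }
    ).set_index("model_id")


def jackknife_score(
    terms: list[str],
    data: pd.DataFrame,
    response: str = RESPONSE,
    absolute: bool = True,
    model_id: int = 0,
) -> JackknifeReport:
    """Leave-one-lake-out predictive score.

    Each fold refits the model on the remaining lakes — re-standardizing the
    predictors on those lakes only, so no information from the held-out lake
    leaks into the fit — and predicts the held-out lake's mean domestic
    membership. The score is the mean absolute observed-predicted
    difference (signed mean available via ``absolute=False`` for
    sensitivity runs).
    """
    data = data.reset_index(drop=True)
    y = data[response].to_numpy(dtype=float)
    lake_ids = (
        data["lake"].astype(str).tolist() if "lake" in data.columns
        else [str(i) for i in range(len(data))]
    )
    observed, predicted, kept, failed = [], [], [], []
    for i in range(len(data)):
        train = data.drop(index=i)
        try:
            fit = fit_betareg(standardize(train, terms), train[response].to_numpy(dtype=float))
            mu = predict(fit, data.iloc[[i]])[0]
        except Exception as exc:
            warnings.warn(f"jackknife refit failed leaving out {lake_ids[i]}: {exc}")
            failed.append(lake_ids[i])
            continue
        observed.append(y[i])
        predicted.append(float(mu))
        kept.append(lake_ids[i])
    if not observed:
        raise ValueError("all jackknife folds failed")
    observed = np.asarray(observed)
    predicted = np.asarray(predicted)
    diff = observed - predicted
    score = float(np.mean(np.abs(diff))) if absolute else float(np.mean(diff))
    return JackknifeReport(
        model_id=model_id,
        lake_ids=kept,
        observed=observed,
        predicted=predicted,
        differences=diff,
        mean_abs_difference=score,
        failed_lakes=failed,
    )


def select_best(
    data: pd.DataFrame,
    response: str = RESPONSE,
    delta_max: float = 2.0,
    jackknife_threshold: float = 0.05,
) -> SelectionResult:
    """Run the full cascade over the 21 candidates.

    Jackknife scores are computed for the AICc shortlist (the only models
    the predictive screen applies to). The audit table carries one row per
    candidate; the result is invariant to candidate ordering.
    """
    specs = {s.model_id: s for s in build_candidates()}
    fits = fit_candidates(data, response)
    ranking = rank_aicc(fits, delta_max)
    shortlist = sorted(ranking.index[ranking["shortlisted"]])

    jk: dict[int, JackknifeReport] = {}
    for mid in shortlist:
        jk[mid] = jackknife_score(specs[mid].terms, data, response, model_id=mid)
    survivors = [mid for mid in shortlist if jk[mid].mean_abs_difference < jackknife_threshold]

    best: int | None = None
    if survivors:
        best = max(survivors, key=lambda mid: fits[mid].adj_pseudo_r2)

    table = ranking.copy()
    table["terms"] = [" + ".join(specs[m].terms) for m in table.index]
    table["category"] = [specs[m].category for m in table.index]
    table["adj_pseudo_r2"] = [fits[m].adj_pseudo_r2 for m in table.index]
    table["jackknife_score"] = [
        jk[m].mean_abs_difference if m in jk else np.nan for m in table.index
    ]
    table["passed_jackknife"] = [m in survivors for m in table.index]
    table["selected"] = [m == best for m in table.index]
    table = table.sort_values("aicc")
    return SelectionResult(
        table=table,
        fits=fits,
        jackknife=jk,
        shortlist=list(shortlist),
        survivors=survivors,
        best_model_id=best,
    )


def model_average_coef(
    fits: dict[int, BetaRegFit], weights: pd.Series | dict[int, float], term: str
) -> float:
    """Akaike-weighted average of one term's coefficient.

    Weights are renormalized over the models that contain the term.
    """
    if isinstance(weights, pd.Series):
        weights = weights.to_dict()
    values, w = [], []
    for mid, fit in fits.items():
        if term in fit.term_names and mid in weights:
            values.append(fit.coef(term))
            w.append(weights[mid])
    if not values:
        raise ValueError(f"term {term!r} appears in no candidate model")
    w = np.asarray(w, dtype=float)
    return float(np.average(values, weights=w / w.sum()))
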