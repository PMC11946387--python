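"""Subtype-specific logistic models predicting pathologic complete response.

The candidate predictors are the three FTV variables available at the
inter-regimen timepoint: baseline FTV (cc) and the percent changes at T1
and T2.  Model selection considers every non-empty subset of the three,
scores each by mean held-out AUC over stratified k-folds, and refits the
winner on all records.  Ties go to the smaller predictor set (parsimony),
then to lexicographic order.  Predictors enter untransformed — percent
changes in percent units, baseline FTV in cc — so predicted-probability
thresholds stay on the clinical reporting scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .synthetic import PatientRecord

__all__ = [
    "PREDICTOR_NAMES",
    "candidate_predictor_sets",
    "FittedModel",
    "complete_records",
    "fit_logistic",
    "compute_auc",
    "select_model",
    "model_to_json",
    "model_from_json",
]

PREDICTOR_NAMES: tuple[str, ...] = ("dftv_t1", "dftv_t2", "ftv_t0")


def candidate_predictor_sets(
    names: tuple[str, ...] = PREDICTOR_NAMES,
) -> list[tuple[str, ...]]:
    """All non-empty predictor subsets, ordered by size then lexicographically
    (the tie-break order used in model selection)."""
    out: list[tuple[str, ...]] = []
    for k in range(1, len(names) + 1):
        out.extend(combinations(sorted(names), k))
    return out


def complete_records(records: list[PatientRecord]) -> list[PatientRecord]:
    """Drop records with undefined FTV percent change (NaN sentinel)."""
    return [
        r
        for r in records
        if math.isfinite(r.dftv_t1) and math.isfinite(r.dftv_t2)
    ]


def _design(records: list[PatientRecord], predictors: tuple[str, ...]) -> np.ndarray:
    x = np.empty((len(records), len(predictors)))
    for j, name in enumerate(predictors):
        x[:, j] = [getattr(r, name) for r in records]
    return x


@dataclass
class FittedModel:
    """A fitted logistic pCR model for one cohort scope.

    ``scope`` is either "full" or a subtype label; ``cv_auc`` maps each
    candidate predictor set (as a tuple) to its mean held-out AUC, when the
    model came from :func:`select_model`.
    """

    scope: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    cv_auc: dict[tuple[str, ...], float] = field(default_factory=dict)
    k_folds: int | None = None
    seed: int | None = None
    separation_flag: bool = False

    def linear_predictor(self, records: list[PatientRecord]) -> np.ndarray:
        eta = np.full(len(records), self.intercept)
        if self.predictors:
            x = _design(records, self.predictors)
            beta = np.array([self.coefficients[p] for p in self.predictors])
            eta = eta + x @ beta
        return eta

    def predict_proba(self, records: list[PatientRecord]) -> np.ndarray:
        """Predicted probability of pCR per record (inverse-logit)."""
        return expit(self.linear_predictor(records))


def fit_logistic(
    records: list[PatientRecord],
    predictors: tuple[str, ...],
    scope: str = "full",
) -> FittedModel:
    """Maximum-likelihood logistic fit of pCR on the given FTV predictors.

    Complete separation does not abort: the fit is retried with BFGS and
    returned with ``separation_flag`` set, so predicted probabilities remain
    defined (saturated toward 0/1).  An empty predictor tuple fits the
    intercept-only model, whose fitted probability is the pCR prevalence.
    """
    records = complete_records(records)
    y = np.array([r.pcr for r in records], dtype=float)
    if len(records) < 4 or y.sum() < 2 or (len(y) - y.sum()) < 2:
        raise ValueError("need at least 2 records in each outcome class")
    x = sm.add_constant(_design(records, predictors), has_constant="add")

    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, x).fit(disp=0)
            if not res.mle_retvals.get("converged", True):
                raise sm.tools.sm_exceptions.PerfectSeparationWarning("no convergence")
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ):
            flagged = True
            warnings.simplefilter("ignore")
            res = sm.Logit(y, x).fit(method="bfgs", maxiter=500, disp=0)

    params = np.asarray(res.params, dtype=float)
    return FittedModel(
        scope=scope,
        predictors=tuple(predictors),
        intercept=float(params[0]),
        coefficients={p: float(b) for p, b in zip(predictors, params[1:])},
        separation_flag=flagged,
    )


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve as the rank (Mann–Whitney) statistic.

    Equals the probability that a random positive outscores a random
    negative, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _cv_auc(
    records: list[PatientRecord],
    predictors: tuple[str, ...],
    k_folds: int,
    seed: int,
) -> float:
    y = np.array([r.pcr for r in records], dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        model = fit_logistic(train, predictors)
        probs = model.predict_proba(test)
        aucs.append(compute_auc(probs, y[test_idx].astype(bool)))
    return float(np.mean(aucs))


def select_model(
    records: list[PatientRecord],
    candidates: list[tuple[str, ...]] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    scope: str = "full",
    max_retries: int = 3,
    tie_tol: float = 0.01,
    cv: bool = True,
) -> FittedModel:
    """Choose the FTV predictor subset with the highest selection AUC.

    By default every candidate set is scored by mean held-out AUC over
    stratified ``k_folds``; ``cv=False`` scores candidates by in-sample
    AUC instead (optimistic, kept for comparison).  The winner is refit on
    all records.  Candidates within
    ``tie_tol`` of the best mean AUC are treated as tied — a cross-validated
    mean is a noisy estimate, so differences that small do not indicate a
    better model — and ties resolve toward fewer predictors, then
    lexicographic order.  This is what keeps selected models minimal when
    extra FTV variables add no real signal.  If a fold degenerates to a
    single outcome class the folding is retried with a perturbed seed a
    bounded number of times before raising.
    """
    records = complete_records(records)
    if candidates is None:
        candidates = candidate_predictor_sets()
    if not candidates:
        raise ValueError("need at least one candidate predictor set")
    y = np.array([r.pcr for r in records], dtype=int)
    if min(y.sum(), len(y) - y.sum()) < k_folds:
        raise ValueError(
            f"too few records in the minority class for {k_folds}-fold "
            "stratified cross-validation"
        )

    cv_table: dict[tuple[str, ...], float] = {}
    for cand in candidates:
        cand = tuple(cand)
        if not cv:
            model = fit_logistic(records, cand)
            cv_table[cand] = compute_auc(
                model.predict_proba(records), y.astype(bool)
            )
            continue
        last_err: Exception | None = None
        for attempt in range(max_retries + 1):
            try:
                cv_table[cand] = _cv_auc(records, cand, k_folds, seed + attempt)
                break
            except ValueError as err:  # single-class fold
                last_err = err
        else:
            raise ValueError(
                f"cross-validation failed for candidate {cand}: {last_err}"
            )

    # candidates are ordered by (size, lexicographic): the first candidate
    # within tie_tol of the best mean AUC is the parsimonious winner
    best = max(cv_table.values())
    winner = next(
        tuple(c) for c in candidates if cv_table[tuple(c)] >= best - tie_tol
    )

    final = fit_logistic(records, winner, scope=scope)
    final.cv_auc = cv_table
    final.k_folds = k_folds
    final.seed = seed
    return final


def model_to_json(model: FittedModel, path: str | Path | None = None) -> str:
    payload = {
        "scope": model.scope,
        "predictors": list(model.predictors),
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "cv_auc_table": {" ".join(k): v for k, v in model.cv_auc.items()},
        "k_folds": model.k_folds,
        "seed": model.seed,
        "separation_flag": model.separation_flag,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def model_from_json(source: str | Path) -> FittedModel:
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("{")
    ):
        source = Path(source).read_text()
    payload = json.loads(source)
    return FittedModel(
        scope=payload["scope"],
        predictors=tuple(payload["predictors"]),
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        cv_auc={
            tuple(k.split()): float(v)
            for k, v in payload.get("cv_auc_table", {}).items()
        },
        k_folds=payload.get("k_folds"),
        seed=payload.get("seed"),
        separation_flag=bool(payload.get("separation_flag", False)),
    )
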