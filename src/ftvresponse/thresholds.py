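"""PPV-constrained probability-threshold analysis.

A patient is "predicted pCR" when their modelled probability is at or above
a cutoff t.  Sweeping t over the observed probabilities traces the tradeoff
between positive predictive value (the fraction of above-threshold patients
who truly achieve pCR — the quantity that must stay high before advising an
early end to chemotherapy) and sensitivity (the fraction of true pCRs
captured).  Thresholds are then chosen as the smallest cutoff whose PPV
meets a preset minimum level (50, 70 or 90%), which maximizes sensitivity
subject to the PPV constraint; when no cutoff attains the level the
selection is the +Inf sentinel and sensitivity is 0 (nobody is ever
predicted pCR).

PPV is not monotone in t, so "smallest qualifying t" is a genuine search,
not a bisection; at t = 0 everyone is predicted positive, sensitivity is
100% and PPV equals the pCR prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdCurve",
    "ThresholdSelection",
    "Decision",
    "ppv_sensitivity_curve",
    "select_threshold",
    "sensitivity_ci",
    "recommend",
    "threshold_report",
    "implication_report",
]


@dataclass(frozen=True)
class ThresholdCurve:
    """PPV and sensitivity (both in %) over candidate probability cutoffs.

    Candidates are the distinct predicted probabilities plus 0, ascending.
    Confusion-matrix counts are stored per cutoff under the rule
    "predicted pCR iff probability >= t".
    """

    thresholds: np.ndarray
    ppv: np.ndarray  # percent
    sensitivity: np.ndarray  # percent
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n_positive(self) -> int:
        return int(self.tp[0] + self.fn[0])

    @property
    def prevalence_pct(self) -> float:
        total = self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0]
        return float(self.n_positive / total * 100.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "ppv_pct": self.ppv,
                "sensitivity_pct": self.sensitivity,
                "tp": self.tp,
                "fp": self.fp,
                "fn": self.fn,
                "tn": self.tn,
            }
        )


@dataclass(frozen=True)
class ThresholdSelection:
    """Chosen cutoff for one minimum-PPV level.

    ``threshold`` is +inf when the level is unattainable: no patient is then
    ever predicted pCR, so sensitivity is 0 and the achieved PPV undefined
    (NaN).
    """

    ppv_level: float  # percent
    threshold: float  # probability, or math.inf
    ppv: float  # achieved PPV, percent (NaN when +Inf)
    sensitivity: float  # percent
    ci_lo: float  # percent
    ci_hi: float  # percent
    n_pcr: int  # sensitivity denominator

    @property
    def attainable(self) -> bool:
        return math.isfinite(self.threshold)


class Decision(str, Enum):
    """Per-patient recommendation at the inter-regimen timepoint."""

    CONTINUE_NAC = "continue_NAC"
    EARLY_SURGERY_CANDIDATE = "early_surgery_candidate"
    EARLY_SURGERY_RECOMMENDED = "early_surgery_recommended"


def ppv_sensitivity_curve(
    probabilities: np.ndarray, labels: np.ndarray
) -> ThresholdCurve:
    """Trace PPV and sensitivity over every distinct probability plus 0."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be 1-D and aligned")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("probabilities must lie in [0, 1]")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold curve requires both outcome classes")

    thresholds = np.unique(np.concatenate(([0.0], p)))
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    y_sorted = y[order]
    # suffix sums: positives/records with probability >= each sorted position
    pos_suffix = np.concatenate((np.cumsum(y_sorted[::-1])[::-1], [0]))
    # index of first probability >= t
    first = np.searchsorted(p_sorted, thresholds, side="left")
    n_pred = p.size - first
    tp = pos_suffix[first]
    fp = n_pred - tp
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(n_pred > 0, tp / np.maximum(n_pred, 1) * 100.0, np.nan)
    sens = tp / n_pos * 100.0
    return ThresholdCurve(
        thresholds=thresholds,
        ppv=ppv,
        sensitivity=sens,
        tp=tp.astype(int),
        fp=fp.astype(int),
        fn=fn.astype(int),
        tn=tn.astype(int),
    )


def sensitivity_ci(successes: int, n: int) -> tuple[float, float]:
    """95% Wald interval for a sensitivity, in percent, clipped to [0, 100]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    phat = successes / n
    half = 1.96 * math.sqrt(phat * (1 - phat) / n)
    return (
        max(0.0, (phat - half) * 100.0),
        min(100.0, (phat + half) * 100.0),
    )


def select_threshold(curve: ThresholdCurve, ppv_level: float) -> ThresholdSelection:
    """Smallest cutoff whose PPV meets ``ppv_level`` (percent).

    Because sensitivity is non-increasing in the cutoff, the smallest
    qualifying cutoff is also the sensitivity-maximizing one.  Returns the
    +Inf sentinel when no cutoff qualifies.
    """
    if not 0 < ppv_level <= 100:
        raise ValueError("ppv_level must be in (0, 100]")
    qualifies = np.where(np.nan_to_num(curve.ppv, nan=-1.0) >= ppv_level)[0]
    n_pcr = curve.n_positive
    if qualifies.size == 0:
        return ThresholdSelection(
            ppv_level=ppv_level,
            threshold=math.inf,
            ppv=math.nan,
            sensitivity=0.0,
            ci_lo=0.0,
            ci_hi=0.0,
            n_pcr=n_pcr,
        )
    i = int(qualifies[0])
    tp = int(curve.tp[i])
    lo, hi = sensitivity_ci(tp, n_pcr)
    return ThresholdSelection(
        ppv_level=ppv_level,
        threshold=float(curve.thresholds[i]),
        ppv=float(curve.ppv[i]),
        sensitivity=float(curve.sensitivity[i]),
        ci_lo=lo,
        ci_hi=hi,
        n_pcr=n_pcr,
    )


def recommend(
    probability: float,
    selection: ThresholdSelection,
    biopsy_no_invasive: bool | None = None,
) -> Decision:
    """Per-patient decision given the subtype's selected threshold.

    Below the threshold (or against the +Inf sentinel) the patient continues
    chemotherapy as planned.  At or above it they are a candidate for early
    surgery; the recommendation is only firm once a core biopsy confirms no
    residual invasive disease (``biopsy_no_invasive=True``).
    """
    if not 0 <= probability <= 1:
        raise ValueError("probability must be in [0, 1]")
    if not math.isfinite(selection.threshold) or probability < selection.threshold:
        return Decision.CONTINUE_NAC
    if biopsy_no_invasive:
        return Decision.EARLY_SURGERY_RECOMMENDED
    return Decision.EARLY_SURGERY_CANDIDATE


def threshold_report(
    selections: dict[str, list[ThresholdSelection]]
) -> pd.DataFrame:
    """Tabulate selections per cohort scope: one row per (scope, PPV level).

    The +Inf sentinel is serialized as the literal string "+Inf".
    """
    rows = []
    for scope, sels in selections.items():
        for s in sels:
            rows.append(
                {
                    "cohort": scope,
                    "ppv_level": s.ppv_level,
                    "threshold": f"{s.threshold:.6g}" if s.attainable else "+Inf",
                    "sensitivity": round(s.sensitivity, 1),
                    "ci_lo": round(s.ci_lo, 1),
                    "ci_hi": round(s.ci_hi, 1),
                }
            )
    return pd.DataFrame(rows)


def implication_report(
    selections: dict[str, list[ThresholdSelection]], ppv_level: float = 50.0
) -> pd.DataFrame:
    """Clinical-implication summary at one PPV level: per scope, the share of
    true pCR cases proceeding to surgery early (the sensitivity) versus
    continuing chemotherapy (its complement)."""
    rows = []
    for scope, sels in selections.items():
        for s in sels:
            if s.ppv_level == ppv_level:
                rows.append(
                    {
                        "cohort": scope,
                        "ppv_level": ppv_level,
                        "pct_true_pcr_early_surgery": round(s.sensitivity, 1),
                        "pct_true_pcr_continue_nac": round(100.0 - s.sensitivity, 1),
                    }
                )
    return pd.DataFrame(rows)
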