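"""Cohort-comparison statistics: Fisher's exact tests and the Welch t-test.

The two-sided Fisher p-value follows the probability-mass ordering used by
the standard exact-test implementations: under fixed margins, sum the
hypergeometric probabilities of every table no more probable than the
observed one.  For r x c tables an exact enumerator walks all tables with
the observed margins (feasible when the margins are modest — an r x 2 table
whose smaller column total is m has at most ~m^(r-1) tables); larger tables
fall back to Monte-Carlo sampling of the same null via Patefield's
algorithm (``scipy.stats.random_table``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "FisherResult",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "welch_t_from_summary",
]

# relative tolerance for "no more probable than observed", as in the
# conventional exact-test tie rule p <= p_obs * (1 + eps)
_TIE_EPS = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Labelled r x c table of non-negative integer counts."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("table has zero grand total")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContingencyTable":
        df = pd.read_csv(path, index_col=0)
        return cls(
            counts=df.to_numpy(dtype=int),
            row_labels=tuple(map(str, df.index)),
            col_labels=tuple(map(str, df.columns)),
        )

    def to_csv(self, path: str | Path) -> None:
        r, c = self.counts.shape
        df = pd.DataFrame(
            self.counts,
            index=self.row_labels or [f"row{i}" for i in range(r)],
            columns=self.col_labels or [f"col{j}" for j in range(c)],
        )
        df.to_csv(path)


@dataclass(frozen=True)
class FisherResult:
    """Fisher's exact test result; ``se`` is the Monte-Carlo standard error
    (None in exact mode)."""

    p: float
    mode: str  # "exact" | "monte_carlo"
    reps: int | None = None
    seed: int | None = None
    se: float | None = None

    def to_dict(self) -> dict:
        return {
            "test": "fisher_exact",
            "p": self.p,
            "mode": self.mode,
            "reps": self.reps,
            "seed": self.seed,
        }


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    counts = np.asarray(table, dtype=int)
    if counts.ndim != 2:
        raise ValueError("expected a 2-D table")
    return counts


def _check_margins(counts: np.ndarray) -> None:
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("table has an empty margin")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (probability-mass rule)."""
    counts = _as_counts(table)
    if counts.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {counts.shape}")
    _check_margins(counts)
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


def _log_table_prob(counts: np.ndarray, lgfact: np.ndarray) -> float:
    """log multivariate-hypergeometric probability under fixed margins."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    return float(
        lgfact[rows].sum()
        + lgfact[cols].sum()
        - lgfact[n]
        - lgfact[counts].sum()
    )


def _enumerate_exact(
    rows: np.ndarray, cols: np.ndarray, log_obs: float, max_tables: int
) -> float:
    """Sum P(table) over all tables with the given margins and probability
    no greater than the observed one.  Raises when the enumeration exceeds
    ``max_tables`` leaves."""
    n = int(rows.sum())
    lgfact = gammaln(np.arange(n + 2) + 1.0)
    const = lgfact[rows].sum() + lgfact[cols].sum() - lgfact[n]
    r, c = len(rows), len(cols)
    cutoff = log_obs + _TIE_EPS
    visited = 0
    total = 0.0

    def rec(i: int, col_rem: np.ndarray, log_cells: float) -> None:
        nonlocal visited, total
        if i == r - 1:
            # last row forced by remaining column margins
            visited += 1
            if visited > max_tables:
                raise _EnumerationBound()
            logp = const - log_cells - lgfact[col_rem].sum()
            if logp <= cutoff:
                total += np.exp(logp)
            return
        row_rem = int(rows[i])
        # enumerate this row's cells except the last, which is forced
        def rec_cell(j: int, rem: int, crem: np.ndarray, lc: float) -> None:
            if j == c - 1:
                if rem <= crem[j]:
                    crem2 = crem.copy()
                    crem2[j] -= rem
                    rec(i + 1, crem2, lc + lgfact[rem])
                return
            hi = min(rem, int(crem[j]))
            for v in range(hi + 1):
                crem2 = crem.copy()
                crem2[j] -= v
                rec_cell(j + 1, rem - v, crem2, lc + lgfact[v])

        rec_cell(0, row_rem, col_rem, log_cells)

    rec(0, cols.astype(int).copy(), 0.0)
    return total


class _EnumerationBound(Exception):
    pass


def fisher_exact_rxc(
    table,
    mode: str = "exact",
    reps: int = 100_000,
    seed: int = 0,
    max_tables: int = 2_000_000,
) -> FisherResult:
    """Two-sided Fisher's exact test for an r x c table.

    ``mode="exact"`` enumerates every table with the observed margins and
    sums the probabilities of those no more probable than the observed
    table; if the enumeration would exceed ``max_tables`` tables it raises
    and instructs the caller to use Monte Carlo.  ``mode="monte_carlo"``
    samples ``reps`` tables under fixed margins (Patefield's algorithm) and
    estimates the same tail with the add-one-rank estimator, reporting its
    standard error.

    Rows or columns that are entirely zero carry no probability and are
    dropped before testing.
    """
    counts = _as_counts(table)
    _check_margins_soft = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    counts = _check_margins_soft
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("table is degenerate after dropping empty margins")
    # orient so the smaller dimension is the columns (cheaper enumeration)
    if counts.shape[1] > counts.shape[0]:
        counts = counts.T
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = int(counts.sum())
    lgfact = gammaln(np.arange(n + 2) + 1.0)
    log_obs = _log_table_prob(counts, lgfact)

    if mode == "exact":
        try:
            p = _enumerate_exact(rows, cols, log_obs, max_tables)
        except _EnumerationBound:
            raise ValueError(
                f"exact enumeration exceeds {max_tables} tables for these "
                "margins; rerun with mode='monte_carlo'"
            ) from None
        return FisherResult(p=min(p, 1.0), mode="exact")
    if mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        dist = stats.random_table(rows, cols, seed=rng)
        hits = 0
        done = 0
        batch = 20_000
        cutoff = log_obs + _TIE_EPS
        while done < reps:
            k = min(batch, reps - done)
            samples = dist.rvs(k).astype(int)
            logp = -lgfact[samples].sum(axis=(1, 2))  # + const, cancels below
            # observed on the same additive scale
            log_obs_cells = -lgfact[counts].sum()
            hits += int(np.sum(logp <= log_obs_cells + _TIE_EPS))
            done += k
        p = (hits + 1) / (reps + 1)
        se = float(np.sqrt(p * (1 - p) / reps))
        return FisherResult(p=float(p), mode="monte_carlo", reps=reps, seed=seed, se=se)
    raise ValueError(f"unknown mode {mode!r}")


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Two-sided Welch t-test p-value from group summaries
    (Satterthwaite degrees of freedom)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(res.pvalue)
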