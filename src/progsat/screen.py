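"""Per-gene prognostic screening: Kaplan-Meier curves and log-rank tests.

Each gene splits the cohort into mutant and wild-type groups; the two
survival curves are compared with the standard two-group log-rank test
(hypergeometric variance with the (n-d)/(n-1) tie correction at each
distinct event time, statistic referred to chi-square with 1 df).  Genes
mutated in fewer than ``min_mutant`` samples, or in every sample, are
excluded from testing but retained in the output with ``tested=False``.

The screen is vectorised over genes: observed events, expectations and
variances are accumulated for all gene columns at once, which keeps the
cost of screening thousands of genes inside thousands of resampling
replicates negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import CohortData

__all__ = [
    "GeneScreenResult",
    "km_curve",
    "logrank_test",
    "screen_genes",
    "count_significant",
    "results_to_frame",
]


@dataclass(frozen=True)
class GeneScreenResult:
    """Log-rank outcome for one gene (mutant vs. wild-type survival)."""

    gene_id: str
    n_mutant: int
    tested: bool
    chi_square: float | None = None
    p_value: float | None = None
    direction: int = 0  # sign(observed - expected) mutant events

    def __post_init__(self) -> None:
        if self.tested:
            if self.chi_square is None or self.p_value is None:
                raise ValueError("tested results must carry statistic and p-value")
            if self.chi_square < 0 or not (0 <= self.p_value <= 1):
                raise ValueError("invalid statistic or p-value")
        elif self.chi_square is not None or self.p_value is not None:
            raise ValueError("untested results must not carry statistic or p-value")


def km_curve(
    time_months: np.ndarray, status: np.ndarray
) -> list[tuple[float, float]]:
    """Product-limit survival estimate as (event time, survival) pairs.

    Survival starts at 1 and drops only at observed event times; a cohort
    with no events yields an empty list (the constant function 1).
    """
    time_months = np.asarray(time_months, dtype=float)
    status = np.asarray(status)
    if time_months.size == 0:
        raise ValueError("empty survival input")
    if time_months.min() <= 0:
        raise ValueError("all survival times must be strictly positive")
    kmf = KaplanMeierFitter()
    kmf.fit(time_months, event_observed=status)
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = np.unique(time_months[np.asarray(status) == 1])
    return [(float(t), float(sf.loc[t])) for t in event_times]


def _logrank_terms(
    time: np.ndarray, status: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(O1, E1, V) per gene column for the two-group log-rank statistic.

    ``groups`` is an (n_samples, n_genes) 0/1 matrix of group-1 membership.
    Censored samples at an event time remain at risk for that time.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = np.asarray(status)[order].astype(np.int64)
    x = np.asarray(groups)[order].astype(np.float64)
    n = t.size

    # first index of each distinct time, ascending
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    # at-risk counts: everyone with time >= t_k
    n_risk = n - starts
    suffix = np.vstack([np.cumsum(x[::-1], axis=0)[::-1], np.zeros(x.shape[1])])
    n1_risk = suffix[starts]

    d_cum = np.r_[0, np.cumsum(d)]
    ends = np.r_[starts[1:], n]
    d_k = d_cum[ends] - d_cum[starts]
    dx_cum = np.vstack([np.zeros(x.shape[1]), np.cumsum(x * d[:, None], axis=0)])
    d1_k = dx_cum[ends] - dx_cum[starts]

    has_event = d_k > 0
    n_k = n_risk[has_event].astype(float)
    dk = d_k[has_event].astype(float)
    n1 = n1_risk[has_event]
    p1 = n1 / n_k[:, None]

    observed = d1_k[has_event].sum(axis=0)
    expected = (dk[:, None] * p1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tie = np.where(n_k > 1, (n_k - dk) / (n_k - 1), 0.0)
    variance = (dk[:, None] * p1 * (1 - p1) * tie[:, None]).sum(axis=0)
    return observed, expected, variance


def logrank_test(
    time_months: np.ndarray, status: np.ndarray, group: np.ndarray
) -> tuple[float, float, int]:
    """Two-group log-rank test.

    Returns ``(chi_square, p_value, direction)`` where the p-value is the
    upper tail of chi-square(1) and ``direction`` is the sign of observed
    minus expected events in group 1 (+1 adverse, -1 protective).
    """
    time_months = np.asarray(time_months, dtype=float)
    status = np.asarray(status)
    group = np.asarray(group)
    if time_months.size == 0:
        raise ValueError("empty survival input")
    if time_months.min() <= 0:
        raise ValueError("all survival times must be strictly positive")
    n1 = int(np.sum(group == 1))
    if n1 == 0 or n1 == group.size:
        raise ValueError("degenerate grouping: both groups must be nonempty")

    o, e, v = _logrank_terms(
        time_months, status, (group == 1).astype(float)[:, None]
    )
    if v[0] <= 0:
        # no events, or groups indistinguishable at every event time
        return 0.0, 1.0, 0
    chi2 = float((o[0] - e[0]) ** 2 / v[0])
    p = float(stats.chi2.sf(chi2, df=1))
    direction = int(np.sign(o[0] - e[0]))
    return chi2, p, direction


def screen_genes(
    cohort: CohortData, alpha: float = 0.05, min_mutant: int = 5
) -> list[GeneScreenResult]:
    """Log-rank screen of every gene, mutant vs. wild-type.

    Genes with fewer than ``min_mutant`` mutants, mutated in all samples,
    or with a degenerate comparison (e.g. a subcohort without events) are
    returned with ``tested=False``; the output always has one entry per
    gene, in cohort gene order.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if min_mutant < 1:
        raise ValueError("min_mutant must be >= 1")

    m = cohort.mutation_matrix
    n_mutant = m.sum(axis=0).astype(int)
    testable = (n_mutant >= min_mutant) & (n_mutant < cohort.n_samples)

    results: list[GeneScreenResult] = [None] * cohort.n_genes  # type: ignore[list-item]
    if testable.any() and cohort.status.sum() > 0:
        cols = np.flatnonzero(testable)
        o, e, v = _logrank_terms(
            cohort.time_months, cohort.status, m[:, cols].astype(float)
        )
        ok = v > 0
        chi2 = np.zeros_like(v)
        chi2[ok] = (o[ok] - e[ok]) ** 2 / v[ok]
        pvals = stats.chi2.sf(chi2, df=1)
        for k, j in enumerate(cols):
            if not ok[k]:
                results[j] = GeneScreenResult(
                    cohort.gene_ids[j], int(n_mutant[j]), tested=False
                )
            else:
                results[j] = GeneScreenResult(
                    gene_id=cohort.gene_ids[j],
                    n_mutant=int(n_mutant[j]),
                    tested=True,
                    chi_square=float(chi2[k]),
                    p_value=float(pvals[k]),
                    direction=int(np.sign(o[k] - e[k])),
                )
    for j in range(cohort.n_genes):
        if results[j] is None:
            results[j] = GeneScreenResult(
                cohort.gene_ids[j], int(n_mutant[j]), tested=False
            )
    return results


def count_significant(
    results: list[GeneScreenResult], alpha: float = 0.05
) -> int:
    """Number of tested genes with p strictly below alpha (alpha=0 counts none)."""
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1]")
    return sum(1 for r in results if r.tested and r.p_value < alpha)


def results_to_frame(results: list[GeneScreenResult]) -> pd.DataFrame:
    """Per-gene results as a table (gene, n_mutant, chi_square, p_value, direction, tested)."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "n_mutant": [r.n_mutant for r in results],
            "chi_square": [r.chi_square if r.tested else np.nan for r in results],
            "p_value": [r.p_value if r.tested else np.nan for r in results],
            "direction": [r.direction for r in results],
            "tested": [r.tested for r in results],
        }
    )
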