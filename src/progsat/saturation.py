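"""Resampling-based saturation analysis of prognostic-gene discovery.

At each level of a cohort-size grid, random subsamples are drawn without
replacement and screened gene-by-gene; the per-replicate significant-gene
count, together with the subsample's number of outcome events (deaths),
is tabulated.  Per-size summaries report means +/- standard error of the
significant-gene count, the mean events number, and the empirical
probability of obtaining at least one significant gene.

Seed discipline: a master seed spawns one independent child stream per
(size, replicate), so the replicate table is identical whatever order the
replicates are executed in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortData
from .screen import count_significant, screen_genes

__all__ = [
    "ResampleRecord",
    "build_size_grid",
    "subsample",
    "run_saturation",
    "summarize",
    "records_to_frame",
]


@dataclass(frozen=True)
class ResampleRecord:
    """One screened subsample: size level, replicate index, events, hits."""

    size: int
    replicate: int
    n_events: int
    n_significant: int
    rng_stream: str

    def __post_init__(self) -> None:
        if not (0 <= self.n_events <= self.size):
            raise ValueError("n_events must be in [0, size]")
        if self.n_significant < 0:
            raise ValueError("n_significant must be non-negative")


def build_size_grid(
    n_total: int,
    frac_min: float = 0.05,
    frac_max: float = 0.95,
    n_levels: int = 10,
) -> list[int]:
    """Integer subsample sizes at equally spaced fractions of the cohort.

    Sizes are rounded, de-duplicated and floored at 2 (a log-rank test
    needs at least one sample per group); the result is strictly
    increasing.
    """
    if not (0 < frac_min <= frac_max <= 1):
        raise ValueError("need 0 < frac_min <= frac_max <= 1")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    fracs = np.linspace(frac_min, frac_max, n_levels)
    sizes = sorted({int(round(f * n_total)) for f in fracs})
    sizes = [s for s in sizes if 2 <= s <= n_total]
    if not sizes:
        raise ValueError(
            f"size grid is empty for n_total={n_total}, "
            f"fractions {frac_min}-{frac_max}"
        )
    return sizes


def subsample(
    cohort: CohortData, n: int, rng: np.random.Generator
) -> CohortData:
    """Uniform without-replacement draw of ``n`` samples; genes unchanged."""
    if not (2 <= n <= cohort.n_samples):
        raise ValueError(
            f"subsample size {n} out of range [2, {cohort.n_samples}]"
        )
    idx = rng.choice(cohort.n_samples, size=n, replace=False)
    return cohort.take(idx)


def run_saturation(
    cohort: CohortData,
    grid: list[int],
    n_reps: int = 100,
    alpha: float = 0.05,
    min_mutant: int = 5,
    seed: int = 0,
) -> list[ResampleRecord]:
    """Screen ``n_reps`` random subsamples at every grid size.

    Returns exactly ``len(grid) * n_reps`` records.  Each (size,
    replicate) pair gets its own seed-derived stream; subsamples with no
    events are retained with a significant count of 0 (the log-rank test
    is undefined there, so no gene can be significant).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    for n in grid:
        if not (2 <= n <= cohort.n_samples):
            raise ValueError(f"grid size {n} out of range")

    children = np.random.SeedSequence(seed).spawn(len(grid) * n_reps)
    records: list[ResampleRecord] = []
    k = 0
    for size in grid:
        for rep in range(1, n_reps + 1):
            ss = children[k]
            k += 1
            rng = np.random.default_rng(ss)
            sub = subsample(cohort, size, rng)
            n_events = sub.n_events
            if n_events == 0:
                n_sig = 0
            else:
                n_sig = count_significant(
                    screen_genes(sub, alpha=alpha, min_mutant=min_mutant),
                    alpha,
                )
            records.append(
                ResampleRecord(
                    size=size,
                    replicate=rep,
                    n_events=n_events,
                    n_significant=n_sig,
                    rng_stream=f"seed={seed}/size={size}/rep={rep}",
                )
            )
    return records


def records_to_frame(records: list[ResampleRecord]) -> pd.DataFrame:
    """Replicate table (size, replicate, n_events, n_significant)."""
    return pd.DataFrame(
        {
            "size": [r.size for r in records],
            "replicate": [r.replicate for r in records],
            "n_events": [r.n_events for r in records],
            "n_significant": [r.n_significant for r in records],
        }
    )


def summarize(records: list[ResampleRecord]) -> pd.DataFrame:
    """Per-size summary: mean +/- SE of hits, mean events, P(>=1 hit).

    The standard error is the sample standard deviation (ddof=1) over
    replicates divided by the square root of the replicate count; a
    single replicate gives SE 0.
    """
    if not records:
        raise ValueError("no records to summarize")
    df = records_to_frame(records)
    rows = []
    for size, grp in df.groupby("size", sort=True):
        counts = grp["n_significant"].to_numpy(dtype=float)
        n = counts.size
        se = float(counts.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "size": int(size),
                "n_reps": n,
                "mean_significant": float(counts.mean()),
                "se_significant": se,
                "mean_events": float(grp["n_events"].mean()),
                "prob_ge1": float((counts >= 1).mean()),
            }
        )
    return pd.DataFrame(rows)
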