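"""Synthetic survival cohorts with somatic-mutation indicators.

The generator emulates the structure of a single-centre cancer cohort used
for mutation-based prognostic screening: a binary sample x gene mutation
matrix whose per-gene mutation frequencies follow a bounded heavy-tailed
(truncated Pareto) spectrum, overall-survival times from an exponential
baseline with proportional hazards on a configurable set of true prognostic
genes, and administrative censoring from a uniform accrual window plus a
fixed follow-up period.

Cohorts round-trip through standard text formats: a MAF-style tab-delimited
variant table (one row per sample-gene mutation) and a clinical TSV with
per-sample survival time, event status and stage label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "CohortData",
    "sample_mutation_frequencies",
    "truncated_pareto_tail_mass",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

logger = logging.getLogger(__name__)

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode")
CLINICAL_COLUMNS = ("sample", "time_months", "status", "stage")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a stage II-like oesophageal squamous cell carcinoma
    cohort: 222 cases, ~14,000 mutable genes of which ~65 exceed 5%
    mutation frequency, an event fraction near 0.35 and median follow-up
    around 34 months.

    Parameters
    ----------
    n_samples : int
        Number of patients.
    n_genes : int
        Number of mutable genes.
    freq_min, freq_max : float
        Bounds of the per-gene mutation-frequency spectrum, in (0, 1].
    freq_shape : float
        Tail exponent of the truncated-Pareto frequency spectrum; larger
        values concentrate mass on rare genes.
    n_prognostic : int
        Number of genes (the first ``n_prognostic`` columns) carrying a
        true prognostic effect.
    hazard_ratio : float or sequence of float
        Multiplicative hazard per mutated prognostic gene; a scalar is
        shared by all prognostic genes, a sequence gives one per gene.
    prognostic_freq : float, optional
        If given, the mutation frequency assigned to every prognostic
        gene instead of a draw from the spectrum.
    median_survival_months : float
        Baseline (all wild-type) median overall survival.  Note the
        marginal event fraction also depends on the prognostic-gene
        structure: mutated drivers shorten survival, so the cohort-wide
        fraction of deaths exceeds what the baseline alone would give.
    accrual_months : float
        Length of the uniform accrual window; a patient's administrative
        censoring time is ``followup_months`` plus a uniform offset on
        ``[0, accrual_months]``.
    followup_months : float
        Minimum follow-up after the end of accrual.
    round_times_to : float, optional
        If given, observed times are rounded to this resolution (e.g. 0.1
        months) to produce ties; times are continuous otherwise.
    stage_label : str
        Free-text label stored on the cohort.
    seed : int
        RNG seed; the cohort is a pure function of the config.
    """

    n_samples: int = 222
    n_genes: int = 14000
    freq_min: float = 0.005
    freq_max: float = 0.9
    freq_shape: float = 2.33
    n_prognostic: int = 5
    hazard_ratio: float | Sequence[float] = 2.5
    prognostic_freq: float | None = 0.2
    median_survival_months: float = 158.1
    accrual_months: float = 24.0
    followup_months: float = 22.0
    round_times_to: float | None = None
    stage_label: str = "II"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not (0 < self.freq_min <= self.freq_max <= 1):
            raise ValueError("need 0 < freq_min <= freq_max <= 1")
        if self.freq_shape <= 0:
            raise ValueError("freq_shape must be positive")
        if not (0 <= self.n_prognostic <= self.n_genes):
            raise ValueError("n_prognostic must be in [0, n_genes]")
        hr = np.atleast_1d(np.asarray(self.hazard_ratio, dtype=float))
        if np.any(hr <= 0):
            raise ValueError("hazard_ratio must be positive")
        if hr.size not in (1, max(self.n_prognostic, 1)):
            raise ValueError(
                "hazard_ratio must be scalar or length n_prognostic"
            )
        if self.prognostic_freq is not None and not (
            0 < self.prognostic_freq <= 1
        ):
            raise ValueError("prognostic_freq must be in (0, 1]")
        if self.median_survival_months <= 0:
            raise ValueError("median_survival_months must be positive")
        if self.accrual_months < 0 or self.followup_months < 0:
            raise ValueError("censoring durations must be >= 0")
        if self.round_times_to is not None and self.round_times_to <= 0:
            raise ValueError("round_times_to must be positive")

    def hazard_ratios(self) -> np.ndarray:
        """Per-prognostic-gene hazard ratios as an array of length n_prognostic."""
        hr = np.atleast_1d(np.asarray(self.hazard_ratio, dtype=float))
        if self.n_prognostic == 0:
            return np.empty(0)
        if hr.size == 1:
            return np.full(self.n_prognostic, hr[0])
        return hr.copy()

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class CohortData:
    """A survival cohort joined to a binary sample x gene mutation matrix."""

    sample_ids: list[str]
    gene_ids: list[str]
    mutation_matrix: np.ndarray  # shape (n_samples, n_genes), values {0, 1}
    time_months: np.ndarray
    status: np.ndarray
    stage_label: str = ""

    def __post_init__(self) -> None:
        self.mutation_matrix = np.asarray(self.mutation_matrix, dtype=np.int8)
        self.time_months = np.asarray(self.time_months, dtype=float)
        self.status = np.asarray(self.status, dtype=np.int8)
        n, g = len(self.sample_ids), len(self.gene_ids)
        if self.mutation_matrix.shape != (n, g):
            raise ValueError(
                f"mutation_matrix shape {self.mutation_matrix.shape} does not "
                f"match {n} samples x {g} genes"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if self.time_months.shape != (n,) or self.status.shape != (n,):
            raise ValueError("time/status must have one entry per sample")
        if n and self.time_months.min() <= 0:
            raise ValueError("all survival times must be strictly positive")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status values must be 0 or 1")
        if not np.isin(self.mutation_matrix, (0, 1)).all():
            raise ValueError("mutation matrix must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def take(self, indices: np.ndarray) -> "CohortData":
        """Restrict to the given sample indices, genes unchanged."""
        idx = np.asarray(indices)
        return CohortData(
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            mutation_matrix=self.mutation_matrix[idx],
            time_months=self.time_months[idx],
            status=self.status[idx],
            stage_label=self.stage_label,
        )

    def equals(self, other: "CohortData") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.mutation_matrix, other.mutation_matrix)
            and np.allclose(self.time_months, other.time_months)
            and np.array_equal(self.status, other.status)
        )


def truncated_pareto_tail_mass(
    threshold: float, shape: float, lo: float, hi: float
) -> float:
    """P(X > threshold) for a Pareto(shape) truncated to [lo, hi].

    Closed form of the survival function; used both to calibrate the
    frequency spectrum (e.g. the fraction of genes above 5% frequency)
    and as the analytic oracle in tests.
    """
    if not (0 < lo <= hi <= 1):
        raise ValueError("need 0 < lo <= hi <= 1")
    x = min(max(threshold, lo), hi)
    num = x ** (-shape) - hi ** (-shape)
    den = lo ** (-shape) - hi ** (-shape)
    return num / den


def sample_mutation_frequencies(
    n_genes: int,
    freq_shape: float,
    freq_min: float,
    freq_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-gene mutation probabilities from a truncated Pareto.

    Inverse-CDF sampling of a power-law density ~ x**-(shape+1) restricted
    to [freq_min, freq_max]: rare genes dominate, with a thin tail of
    recurrently mutated genes, mirroring observed somatic mutation
    frequency spectra.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if not (0 < freq_min <= freq_max <= 1):
        raise ValueError("need 0 < freq_min <= freq_max <= 1")
    if freq_shape <= 0:
        raise ValueError("freq_shape must be positive")
    if n_genes == 0:
        return np.empty(0)
    u = rng.uniform(size=n_genes)
    a, lo, hi = freq_shape, freq_min, freq_max
    return (lo ** (-a) - u * (lo ** (-a) - hi ** (-a))) ** (-1.0 / a)


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Generate a cohort under the exponential proportional-hazards model.

    Mutation indicators are independent Bernoulli draws per sample-gene at
    the sampled frequencies.  Each sample's death hazard is
    ``ln(2)/median_survival_months`` multiplied by ``hazard_ratio**x_g``
    for every prognostic gene g with indicator ``x_g``; survival times are
    exponential at that rate.  Administrative censoring is
    ``followup_months`` plus a uniform accrual offset, and the observed
    time is the minimum of the two with a matching event status.
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes

    freqs = sample_mutation_frequencies(
        g, config.freq_shape, config.freq_min, config.freq_max, rng
    )
    if config.prognostic_freq is not None and config.n_prognostic:
        freqs[: config.n_prognostic] = config.prognostic_freq

    matrix = (rng.uniform(size=(n, g)) < freqs).astype(np.int8)

    base_rate = np.log(2.0) / config.median_survival_months
    log_hr = np.zeros(n)
    if config.n_prognostic:
        log_hr = matrix[:, : config.n_prognostic] @ np.log(
            config.hazard_ratios()
        )
    rates = base_rate * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rates)
    censor_time = config.followup_months + rng.uniform(
        0.0, config.accrual_months, size=n
    )
    observed = np.minimum(event_time, censor_time)
    status = (event_time <= censor_time).astype(np.int8)
    if config.round_times_to is not None:
        observed = np.round(observed / config.round_times_to) * config.round_times_to
        observed = np.maximum(observed, config.round_times_to)

    width = max(len(str(n)), 3)
    sample_ids = [f"S{i:0{width}d}" for i in range(1, n + 1)]
    gene_ids = [f"G{j:05d}" for j in range(1, g + 1)]
    return CohortData(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        mutation_matrix=matrix,
        time_months=observed,
        status=status,
        stage_label=config.stage_label,
    )


def write_cohort(
    cohort: CohortData, maf_path: str | Path, clinical_path: str | Path
) -> None:
    """Write a cohort as a MAF-style variant table plus a clinical TSV.

    The MAF carries one row per (sample, gene) with indicator 1; samples
    without any mutation still appear in the clinical table.
    """
    rows_s, rows_g = np.nonzero(cohort.mutation_matrix)
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": [cohort.gene_ids[j] for j in rows_g],
            "Tumor_Sample_Barcode": [cohort.sample_ids[i] for i in rows_s],
            "Variant_Classification": "Missense_Mutation",
        }
    )
    maf.to_csv(maf_path, sep="\t", index=False)
    clinical = pd.DataFrame(
        {
            "sample": cohort.sample_ids,
            "time_months": cohort.time_months,
            "status": cohort.status.astype(int),
            "stage": cohort.stage_label or "NA",
        }
    )
    clinical.to_csv(clinical_path, sep="\t", index=False)


def read_cohort(
    maf_path: str | Path, clinical_path: str | Path
) -> CohortData:
    """Load a cohort from a MAF-style table joined to a clinical TSV.

    Multiple variant rows for the same (sample, gene) collapse to a single
    indicator.  Clinical rows with missing time/status are excluded with a
    warning; MAF samples absent from the clinical table are dropped from
    the join.  Raises ``ValueError`` if no usable sample remains or the
    tables are malformed.
    """
    maf = pd.read_csv(maf_path, sep="\t", dtype=str)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in maf.columns]
    if missing:
        raise ValueError(f"MAF is missing required columns: {missing}")

    clinical = pd.read_csv(clinical_path, sep="\t")
    missing = [c for c in ("sample", "time_months", "status") if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table is missing columns: {missing}")
    clinical["sample"] = clinical["sample"].astype(str)
    if clinical["sample"].duplicated().any():
        dupes = clinical.loc[clinical["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate clinical sample ids: {dupes}")

    bad = clinical["time_months"].isna() | clinical["status"].isna()
    if bad.any():
        excluded = clinical.loc[bad, "sample"].tolist()
        logger.warning(
            "excluding %d clinical samples with missing time/status: %s",
            len(excluded), excluded,
        )
        clinical = clinical.loc[~bad]
    if not clinical["status"].isin([0, 1]).all():
        bad_vals = sorted(set(clinical["status"]) - {0, 1})
        raise ValueError(f"status values must be 0/1, found {bad_vals}")
    if (clinical["time_months"] <= 0).any():
        raise ValueError("all survival times must be strictly positive")
    if clinical.empty:
        raise ValueError("no usable samples in the clinical table")

    sample_ids = clinical["sample"].tolist()
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    in_clinical = maf["Tumor_Sample_Barcode"].isin(sample_index)
    dropped = maf.loc[~in_clinical, "Tumor_Sample_Barcode"].nunique()
    if dropped:
        logger.warning(
            "dropping MAF rows for %d samples absent from the clinical table",
            dropped,
        )
    maf = maf.loc[in_clinical]

    gene_ids = sorted(maf["Hugo_Symbol"].unique())
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    matrix = np.zeros((len(sample_ids), len(gene_ids)), dtype=np.int8)
    si = maf["Tumor_Sample_Barcode"].map(sample_index).to_numpy()
    gi = maf["Hugo_Symbol"].map(gene_index).to_numpy()
    matrix[si, gi] = 1  # repeated (sample, gene) rows collapse to one

    stage = ""
    if "stage" in clinical.columns and len(clinical):
        stage = str(clinical["stage"].iloc[0])
    return CohortData(
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        mutation_matrix=matrix,
        time_months=clinical["time_months"].to_numpy(dtype=float),
        status=clinical["status"].to_numpy(dtype=np.int8),
        stage_label=stage,
    )
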