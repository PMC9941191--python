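"""End-to-end orchestration: simulate/load -> screen -> saturate -> fit -> report.

A run is driven by a :class:`RunConfig` (either a simulation config or
paths to MAF + clinical inputs), executes all stages in order, and writes
a report bundle of plain-text tables:

* ``replicates.csv`` — one row per (size, replicate) with events and hits
* ``summary.csv``    — per-size means +/- SE, mean events, P(>=1 hit)
* ``screen_full.tsv``— per-gene log-rank results on the full cohort
* ``fits.json``      — power-law (vs size and vs events) and logistic
  parameters, with minimum sizes/events at the 90% and 100% targets
* ``manifest.json``  — config, seed, grid, version, per-stage row counts

Identical config + master seed reproduce every table byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .cohort import CohortData, SimulationConfig, read_cohort, simulate_cohort
from .fits import (
    LogisticFit,
    PowerLawFit,
    expected_events,
    fit_logistic_cdf,
    fit_power_law,
    size_for_probability,
)
from .saturation import build_size_grid, records_to_frame, run_saturation, summarize
from .screen import results_to_frame, screen_genes

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_fixture", "FIXTURE_PRESETS"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Run-level settings for the full saturation pipeline.

    Exactly one of ``simulation`` (a :class:`SimulationConfig`) or
    ``maf_path`` + ``clinical_path`` must be provided.
    """

    simulation: SimulationConfig | None = None
    maf_path: str | None = None
    clinical_path: str | None = None
    frac_min: float = 0.05
    frac_max: float = 0.95
    n_levels: int = 10
    n_reps: int = 100
    alpha: float = 0.05
    min_mutant: int = 5
    fit_scale: str = "log-log"
    prob_targets: tuple[float, ...] = (0.9, 1.0)
    out_dir: str = "progsat_run"
    seed: int = 0

    def __post_init__(self) -> None:
        have_sim = self.simulation is not None
        have_paths = self.maf_path is not None or self.clinical_path is not None
        if have_sim == have_paths:
            raise ValueError(
                "provide exactly one of a simulation config or MAF+clinical paths"
            )
        if have_paths and (self.maf_path is None or self.clinical_path is None):
            raise ValueError("both maf_path and clinical_path are required")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_mapping(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            if isinstance(sim.get("hazard_ratio"), np.ndarray):
                sim["hazard_ratio"] = sim["hazard_ratio"].tolist()
            d["simulation"] = sim
        d["prob_targets"] = list(self.prob_targets)
        return d


def _power_law_section(fit: PowerLawFit | None, reason: str = "") -> dict[str, Any]:
    if fit is None:
        return {"fitted": False, "reason": reason}
    return {
        "fitted": True,
        "a": fit.a,
        "b": fit.b,
        "r_squared": fit.r_squared,
        "fit_scale": fit.fit_scale,
        "n_points": fit.n_points,
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the cohort, records and summary tables, the fits
    report and the manifest; everything is also written under
    ``config.out_dir``.  Raises :class:`PipelineError` with a stage label
    on failure; partial outputs are written only after their stage
    completes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: cohort -----------------------------------------------------
    try:
        if config.simulation is not None:
            cohort = simulate_cohort(config.simulation)
        else:
            cohort = read_cohort(config.maf_path, config.clinical_path)
    except Exception as exc:  # noqa: BLE001 - re-labelled with the stage
        raise PipelineError("cohort", str(exc)) from exc
    logger.info(
        "cohort: %d samples, %d genes, %d events",
        cohort.n_samples, cohort.n_genes, cohort.n_events,
    )

    # --- stage: screen (full cohort, for the per-gene report) --------------
    try:
        full_screen = screen_genes(
            cohort, alpha=config.alpha, min_mutant=config.min_mutant
        )
        screen_table = results_to_frame(full_screen)
        screen_table.to_csv(out / "screen_full.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("screen", str(exc)) from exc

    # --- stage: saturation --------------------------------------------------
    try:
        grid = build_size_grid(
            cohort.n_samples, config.frac_min, config.frac_max, config.n_levels
        )
        records = run_saturation(
            cohort,
            grid,
            n_reps=config.n_reps,
            alpha=config.alpha,
            min_mutant=config.min_mutant,
            seed=config.seed,
        )
        rep_table = records_to_frame(records)
        summary = summarize(records)
        rep_table.to_csv(out / "replicates.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("saturate", str(exc)) from exc

    # --- stage: fits ---------------------------------------------------------
    try:
        fits_report = build_fits_report(
            summary, records, cohort, config
        )
        with open(out / "fits.json", "w") as fh:
            json.dump(fits_report, fh, indent=2)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", str(exc)) from exc

    manifest = {
        "version": __version__,
        "config": config.to_mapping(),
        "seed": config.seed,
        "grid": grid,
        "n_samples": cohort.n_samples,
        "n_genes": cohort.n_genes,
        "n_events_full": cohort.n_events,
        "rows": {
            "screen_full": int(len(screen_table)),
            "replicates": int(len(rep_table)),
            "summary": int(len(summary)),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "cohort": cohort,
        "screen": screen_table,
        "records": records,
        "replicates": rep_table,
        "summary": summary,
        "fits": fits_report,
        "manifest": manifest,
    }


def build_fits_report(summary, records, cohort, config: RunConfig) -> dict[str, Any]:
    """Fit growth curves to a saturation summary and invert to size targets."""
    sizes = summary["size"].to_numpy(dtype=float)
    means = summary["mean_significant"].to_numpy(dtype=float)
    events = summary["mean_events"].to_numpy(dtype=float)
    probs = summary["prob_ge1"].to_numpy(dtype=float)

    def _try_power(x, y):
        try:
            return _power_law_section(
                fit_power_law(x, y, fit_scale=config.fit_scale)
            )
        except ValueError as exc:
            return _power_law_section(None, str(exc))

    report: dict[str, Any] = {
        "power_law_vs_size": _try_power(sizes, means),
        "power_law_vs_events": _try_power(events[events > 0], means[events > 0]),
    }

    logistic: dict[str, Any]
    try:
        lf = fit_logistic_cdf(sizes, probs)
        logistic = {"fitted": True, "mu": lf.mu, "s": lf.s, "rss": lf.rss}
    except (ValueError, RuntimeError) as exc:
        lf = None
        logistic = {"fitted": False, "reason": str(exc)}
    report["logistic"] = logistic

    targets: dict[str, Any] = {}
    d_total, n_total = cohort.n_events, cohort.n_samples
    for tp in config.prob_targets:
        key = f"p{int(round(tp * 100))}"
        if tp >= 1.0:
            size = size_for_probability(
                lf if lf is not None else LogisticFit(0.0, 1.0, 0.0),
                records,
                1.0,
            )
            note = "empirical: all replicates succeed from this size upward"
        elif lf is None:
            size, note = None, "logistic fit unavailable"
        else:
            size = size_for_probability(lf, records, tp)
            note = "closed-form logistic inverse"
        targets[key] = {
            "target_probability": tp,
            "min_size": size,
            "min_events": (
                expected_events(min(size, n_total), n_total, d_total)
                if size is not None and size <= n_total
                else None
            ),
            "attained": size is not None,
            "note": note,
        }
    report["size_targets"] = targets
    return report


FIXTURE_PRESETS = {
    # hazard_ratio=1 everywhere: survival independent of every gene
    "null-cohort": SimulationConfig(
        n_samples=100,
        n_genes=200,
        freq_min=0.05,
        freq_max=0.5,
        freq_shape=1.0,
        n_prognostic=0,
        hazard_ratio=1.0,
        prognostic_freq=None,
        median_survival_months=30.0,
        accrual_months=24.0,
        followup_months=18.0,
        stage_label="null",
    ),
    # one common strong driver in a small panel
    "one-strong-gene": SimulationConfig(
        n_samples=200,
        n_genes=50,
        freq_min=0.05,
        freq_max=0.3,
        freq_shape=1.5,
        n_prognostic=1,
        hazard_ratio=3.0,
        prognostic_freq=0.25,
        median_survival_months=30.0,
        accrual_months=24.0,
        followup_months=18.0,
        stage_label="planted",
    ),
    # stage II-like: event fraction ~0.35, median follow-up ~34 months
    "stageII-like": SimulationConfig(
        n_samples=200,
        n_genes=500,
        n_prognostic=5,
        hazard_ratio=2.5,
        prognostic_freq=0.2,
        median_survival_months=158.1,
        accrual_months=24.0,
        followup_months=22.0,
        stage_label="II",
    ),
    # stage III-like: event fraction ~0.60, median follow-up ~27 months
    "stageIII-like": SimulationConfig(
        n_samples=165,
        n_genes=500,
        n_prognostic=5,
        hazard_ratio=2.5,
        prognostic_freq=0.2,
        median_survival_months=47.25,
        accrual_months=24.0,
        followup_months=15.0,
        stage_label="III",
    ),
}


def make_fixture(preset: str, seed: int = 0) -> tuple[CohortData, dict[str, Any]]:
    """Deterministic miniature cohorts for tests and documentation.

    Returns the cohort plus a small expected-summary dict (sample/gene
    counts, event count and fraction, the preset's config).
    """
    if preset not in FIXTURE_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(FIXTURE_PRESETS)}"
        )
    cfg = FIXTURE_PRESETS[preset].with_seed(seed)
    cohort = simulate_cohort(cfg)
    expected = {
        "preset": preset,
        "config": dataclasses.asdict(cfg),
        "n_samples": cohort.n_samples,
        "n_genes": cohort.n_genes,
        "n_events": cohort.n_events,
        "event_fraction": cohort.n_events / cohort.n_samples,
    }
    return cohort, expected
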