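"""Synthetic cohort generator: spectrum calibration, survival model, I/O."""

import numpy as np
import pytest
from scipy import stats

from progsat import (
    SimulationConfig,
    read_cohort,
    sample_mutation_frequencies,
    simulate_cohort,
    truncated_pareto_tail_mass,
    write_cohort,
)
from progsat.screen import logrank_test


class TestMutationFrequencies:
    def test_empty(self):
        rng = np.random.default_rng(0)
        assert sample_mutation_frequencies(0, 2.0, 0.01, 0.9, rng).size == 0

    def test_bounds_enforced(self):
        rng = np.random.default_rng(1)
        f = sample_mutation_frequencies(10000, 2.33, 0.005, 0.9, rng)
        assert f.size == 10000
        assert f.min() >= 0.005 and f.max() <= 0.9

    def test_invalid_bounds_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_mutation_frequencies(10, 2.0, 0.5, 0.1, rng)
        with pytest.raises(ValueError):
            sample_mutation_frequencies(10, 2.0, 0.0, 0.9, rng)

    def test_tail_mass_matches_analytic_pareto(self):
        """Count of genes above 5% frequency agrees with the closed-form
        truncated-Pareto survival function within +/-20%."""
        rng = np.random.default_rng(7)
        n = 14000
        f = sample_mutation_frequencies(n, 2.33, 0.005, 0.9, rng)
        expected = n * truncated_pareto_tail_mass(0.05, 2.33, 0.005, 0.9)
        observed = int((f > 0.05).sum())
        assert abs(observed - expected) <= 0.2 * expected

    def test_default_spectrum_reproduces_65_of_14000_over_5pct(self):
        """The default spectrum is calibrated so roughly 65 of 14,000
        genes exceed 5% mutation frequency."""
        expected = 14000 * truncated_pareto_tail_mass(0.05, 2.33, 0.005, 0.9)
        assert 52 <= expected <= 78


class TestSimulateCohort:
    def test_deterministic_given_config(self):
        cfg = SimulationConfig(n_samples=50, n_genes=30, seed=11)
        assert simulate_cohort(cfg).equals(simulate_cohort(cfg))

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(n_samples=50, n_genes=30, seed=1))
        b = simulate_cohort(SimulationConfig(n_samples=50, n_genes=30, seed=2))
        assert not a.equals(b)

    def test_marginal_mutation_frequencies_binomial(self):
        """Under the null each gene's mutant count is Binomial(n, freq);
        observed counts stay inside the 99% binomial envelope."""
        cfg = SimulationConfig(
            n_samples=300,
            n_genes=60,
            freq_min=0.05,
            freq_max=0.6,
            freq_shape=1.0,
            n_prognostic=0,
            hazard_ratio=1.0,
            prognostic_freq=None,
            seed=5,
        )
        rng = np.random.default_rng(cfg.seed)
        freqs = sample_mutation_frequencies(
            cfg.n_genes, cfg.freq_shape, cfg.freq_min, cfg.freq_max, rng
        )
        cohort = simulate_cohort(cfg)
        counts = cohort.mutation_matrix.sum(axis=0)
        # per-gene 99.9% envelope -> family-wise miss rate ~6% over 60 genes
        lo, hi = stats.binom.interval(0.999, cfg.n_samples, freqs)
        inside = (counts >= lo) & (counts <= hi)
        assert inside.mean() >= 0.95

    def test_planted_gene_detectable(self):
        """One prognostic gene (freq 0.2, HR 3) in a 200-sample cohort is
        rejected by the log-rank test in well over half of cohorts."""
        hits = 0
        n_cohorts = 100
        for seed in range(n_cohorts):
            cfg = SimulationConfig(
                n_samples=200,
                n_genes=1,
                n_prognostic=1,
                hazard_ratio=3.0,
                prognostic_freq=0.2,
                median_survival_months=30.0,
                accrual_months=24.0,
                followup_months=18.0,
                seed=seed,
            )
            c = simulate_cohort(cfg)
            g = c.mutation_matrix[:, 0]
            if g.sum() in (0, c.n_samples):
                continue
            _, p, _ = logrank_test(c.time_months, c.status, g)
            hits += p < 0.05
        assert hits / n_cohorts > 0.5

    def test_event_fraction_matches_model_and_decreases_with_followup(self):
        """Without prognostic effects the event fraction matches the
        closed-form exponential/uniform-censoring probability within 3
        binomial SEs, and truncating follow-up lowers it."""
        def analytic_p_event(median, followup, accrual):
            lam = np.log(2) / median
            return 1 - np.exp(-lam * followup) * (
                (1 - np.exp(-lam * accrual)) / (lam * accrual)
            )

        base = dict(
            n_samples=400,
            n_genes=5,
            n_prognostic=0,
            hazard_ratio=1.0,
            prognostic_freq=None,
            median_survival_months=30.0,
            accrual_months=24.0,
            seed=9,
        )
        fractions = []
        for fu in (30.0, 10.0):
            cfg = SimulationConfig(followup_months=fu, **base)
            c = simulate_cohort(cfg)
            p = analytic_p_event(30.0, fu, 24.0)
            se = np.sqrt(p * (1 - p) / cfg.n_samples)
            frac = c.n_events / cfg.n_samples
            assert abs(frac - p) <= 3 * se
            fractions.append(frac)
        assert fractions[1] < fractions[0]

    def test_time_rounding_produces_ties(self):
        cfg = SimulationConfig(
            n_samples=100, n_genes=5, round_times_to=1.0, seed=3
        )
        c = simulate_cohort(cfg)
        assert np.allclose(c.time_months, np.round(c.time_months))
        assert c.time_months.min() > 0
        assert np.unique(c.time_months).size < c.n_samples

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_samples": 0},
            {"freq_min": 0.0},
            {"freq_min": 0.5, "freq_max": 0.1},
            {"hazard_ratio": -1.0},
            {"n_prognostic": 100, "n_genes": 10},
            {"median_survival_months": 0.0},
            {"accrual_months": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        kwargs = dict(n_samples=10, n_genes=10)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_per_gene_hazard_ratio_vector(self):
        cfg = SimulationConfig(
            n_samples=20, n_genes=10, n_prognostic=3, hazard_ratio=[2.0, 1.0, 3.0]
        )
        assert np.allclose(cfg.hazard_ratios(), [2.0, 1.0, 3.0])
        with pytest.raises(ValueError):
            SimulationConfig(
                n_samples=20, n_genes=10, n_prognostic=3, hazard_ratio=[2.0, 1.0]
            )


class TestCohortIO:
    def test_round_trip(self, tmp_path, small_cohort):
        maf, clin = tmp_path / "m.maf", tmp_path / "c.tsv"
        write_cohort(small_cohort, maf, clin)
        back = read_cohort(maf, clin)
        assert back.sample_ids == small_cohort.sample_ids
        assert np.allclose(back.time_months, small_cohort.time_months)
        assert np.array_equal(back.status, small_cohort.status)
        # gene order may differ (lexicographic on read); compare by id
        col = {g: j for j, g in enumerate(back.gene_ids)}
        for j, g in enumerate(small_cohort.gene_ids):
            if g in col:
                assert np.array_equal(
                    back.mutation_matrix[:, col[g]],
                    small_cohort.mutation_matrix[:, j],
                )
            else:  # gene absent from MAF => no mutations
                assert small_cohort.mutation_matrix[:, j].sum() == 0

    def test_multiple_variant_rows_collapse_to_one_indicator(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text(
            "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"
            "TP53\tS1\tMissense_Mutation\n"
            "TP53\tS1\tNonsense_Mutation\n"
            "TP53\tS1\tSplice_Site\n"
        )
        clin = tmp_path / "c.tsv"
        clin.write_text(
            "sample\ttime_months\tstatus\tstage\nS1\t10\t1\tII\nS2\t20\t0\tII\n"
        )
        c = read_cohort(maf, clin)
        assert c.mutation_matrix.sum() == 1
        assert c.mutation_matrix[0, 0] == 1

    def test_invalid_status_rejected(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text(
            "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"
            "TP53\tS1\tMissense_Mutation\n"
        )
        clin = tmp_path / "c.tsv"
        clin.write_text("sample\ttime_months\tstatus\tstage\nS1\t10\t2\tII\n")
        with pytest.raises(ValueError, match="status"):
            read_cohort(maf, clin)

    def test_missing_time_excluded_with_warning(self, tmp_path, caplog):
        maf = tmp_path / "m.maf"
        maf.write_text(
            "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"
            "TP53\tS1\tMissense_Mutation\n"
        )
        clin = tmp_path / "c.tsv"
        clin.write_text(
            "sample\ttime_months\tstatus\tstage\nS1\t10\t1\tII\nS2\t\t0\tII\n"
        )
        with caplog.at_level("WARNING"):
            c = read_cohort(maf, clin)
        assert c.n_samples == 1
        assert any("excluding" in r.message for r in caplog.records)

    def test_no_usable_samples_is_an_error(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text("Hugo_Symbol\tTumor_Sample_Barcode\n")
        clin = tmp_path / "c.tsv"
        clin.write_text("sample\ttime_months\tstatus\nS1\t\t\n")
        with pytest.raises(ValueError, match="no usable samples"):
            read_cohort(maf, clin)

    def test_missing_maf_columns_rejected(self, tmp_path):
        maf = tmp_path / "m.maf"
        maf.write_text("Gene\tSample\nTP53\tS1\n")
        clin = tmp_path / "c.tsv"
        clin.write_text("sample\ttime_months\tstatus\nS1\t10\t1\n")
        with pytest.raises(ValueError, match="Hugo_Symbol"):
            read_cohort(maf, clin)
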