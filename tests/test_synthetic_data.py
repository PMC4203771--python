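import numpy as np
import pytest

from cfnipt import (
    SimulationConfig,
    expected_chrom_proportions,
    make_layout,
    simulate_bin_counts,
    simulate_reads,
)
from cfnipt.synthetic_data import QualityDecay

TWO_CHROM = make_layout([("chrA", 1_000_000), ("chrB", 1_000_000)], bin_size=250_000)


class TestExpectedChromProportions:
    def test_zero_fetal_fraction_equals_baseline(self):
        base = expected_chrom_proportions(TWO_CHROM, "euploid", 0.0)
        tri = expected_chrom_proportions(TWO_CHROM, "T21", 0.0, trisomy_map={"T21": "chrB"})
        assert tri == pytest.approx(base)
        assert base["chrA"] == pytest.approx(0.5)

    def test_trisomy_dosage_closed_form(self):
        # equal-length chromosomes, f = 0.10: (1 + f/2)·0.5 / (1 + 0.5·f/2)
        props = expected_chrom_proportions(TWO_CHROM, "T21", 0.10, trisomy_map={"T21": "chrB"})
        assert props["chrB"] == pytest.approx(0.525 / 1.025)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_euploid_proportions_independent_of_f(self):
        a = expected_chrom_proportions(TWO_CHROM, "euploid", 0.0)
        b = expected_chrom_proportions(TWO_CHROM, "euploid", 0.3)
        assert a == pytest.approx(b)

    def test_unknown_karyotype_rejected(self):
        with pytest.raises(ValueError, match="karyotype"):
            expected_chrom_proportions(TWO_CHROM, "T13", 0.1)


class TestSimulateBinCounts:
    def test_same_seed_is_bit_identical_different_seed_differs(self, toy_layout):
        config = SimulationConfig(n_euploid=5, n_t18=1, n_t21=1, reads_per_sample=10_000, seed=3)
        a, la = simulate_bin_counts(config, toy_layout)
        b, lb = simulate_bin_counts(config, toy_layout)
        for x, y in zip(a, b):
            for chrom in toy_layout.names:
                assert np.array_equal(x.counts[chrom], y.counts[chrom])
        assert la == lb
        c, _ = simulate_bin_counts(
            SimulationConfig(n_euploid=5, n_t18=1, n_t21=1, reads_per_sample=10_000, seed=4),
            toy_layout,
        )
        assert any(
            not np.array_equal(x.counts[ch], y.counts[ch])
            for x, y in zip(a, c)
            for ch in toy_layout.names
        )

    def test_counts_sum_to_retained_total(self, toy_cohort):
        config, counts, _ = toy_cohort
        retained = round(config.reads_per_sample * config.unique_map_rate)
        for sample in counts:
            assert sample.total_retained == retained

    def test_euploid_chromosome_fraction_matches_multinomial_mean(self):
        # oracle: multinomial mean n·p and SE sqrt(p(1-p)/n) per sample
        config = SimulationConfig(
            n_euploid=200, n_t18=0, n_t21=0, reads_per_sample=100_000,
            unique_map_rate=1.0, seed=5,
        )
        counts, _ = simulate_bin_counts(config, TWO_CHROM)
        p_b = 0.5
        fractions = np.array([s.chrom_total("chrB") / s.total_retained for s in counts])
        se = np.sqrt(p_b * (1 - p_b) / 100_000) / np.sqrt(len(fractions))
        assert abs(fractions.mean() - p_b) < 3 * se

    def test_trisomic_mean_exceeds_euploid_by_dosage_factor(self):
        common = dict(reads_per_sample=200_000, unique_map_rate=1.0,
                      fetal_fraction_mean=0.10, fetal_fraction_sd=0.0,
                      trisomy_map={"T21": "chrB"})
        eu, _ = simulate_bin_counts(
            SimulationConfig(n_euploid=150, n_t18=0, n_t21=0, seed=6, **common), TWO_CHROM
        )
        tri, _ = simulate_bin_counts(
            SimulationConfig(n_euploid=0, n_t18=0, n_t21=150, seed=7, **common), TWO_CHROM
        )
        mean_eu = np.mean([s.chrom_total("chrB") for s in eu])
        mean_tri = np.mean([s.chrom_total("chrB") for s in tri])
        expected_ratio = (0.525 / 1.025) / 0.5  # expected_chrom_proportions oracle
        assert mean_tri / mean_eu == pytest.approx(expected_ratio, rel=2e-3)

    def test_zero_reads_yields_empty_counts_with_warning(self, toy_layout, caplog):
        config = SimulationConfig(n_euploid=2, n_t18=0, n_t21=0, reads_per_sample=0, seed=0)
        with caplog.at_level("WARNING"):
            counts, labels = simulate_bin_counts(config, toy_layout)
        assert all(s.total_retained == 0 for s in counts)
        assert any("reads_per_sample" in r.message for r in caplog.records)

    def test_fetal_fraction_draws_respect_truncation(self, toy_layout):
        config = SimulationConfig(
            n_euploid=50, n_t18=0, n_t21=0, reads_per_sample=100,
            fetal_fraction_mean=0.10, fetal_fraction_sd=0.05,
            fetal_fraction_min=0.08, fetal_fraction_max=0.12, seed=9,
        )
        _, labels = simulate_bin_counts(config, toy_layout)
        assert all(0.08 <= l.fetal_fraction <= 0.12 for l in labels)


class TestSimulateReads:
    def test_deterministic_and_truth_schema(self, toy_layout):
        config = SimulationConfig(n_euploid=2, n_t18=1, n_t21=0, reads_per_sample=50, seed=2)
        reads_a, truth_a = simulate_reads(config, toy_layout)
        reads_b, truth_b = simulate_reads(config, toy_layout)
        assert reads_a == reads_b
        assert truth_a.equals(truth_b)
        assert list(truth_a.columns) == ["sample", "read_id", "chrom", "start0", "strand", "unique"]
        assert len(truth_a) == 3 * 50

    def test_duplicate_rate_creates_exact_positional_copies(self, toy_layout):
        config = SimulationConfig(
            n_euploid=1, n_t18=0, n_t21=0, reads_per_sample=10_000,
            duplicate_rate=0.2, seed=8,
        )
        _, truth = simulate_reads(config, toy_layout)
        distinct = truth[["chrom", "start0", "strand"]].drop_duplicates()
        # at most 8000 distinct sites (2000 reads are copies of earlier ones)
        assert len(distinct) <= 8_000
        assert len(truth) == 10_000

    def test_quality_profile_plateau_and_ramp(self):
        decay = QualityDecay(start=36, end=8, tail=12)
        q = decay.qualities(100)
        assert (q[:88] == 36).all()
        assert q[-1] == 8
        assert (np.diff(q[88:]) <= 0).all()

    def test_non_unique_share_close_to_configured_rate(self, toy_layout):
        config = SimulationConfig(
            n_euploid=1, n_t18=0, n_t21=0, reads_per_sample=5_000,
            unique_map_rate=0.59, duplicate_rate=0.0, seed=4,
        )
        _, truth = simulate_reads(config, toy_layout)
        rate = truth["unique"].mean()
        assert rate == pytest.approx(0.59, abs=3 * np.sqrt(0.59 * 0.41 / 5_000))


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_euploid=-1)
    with pytest.raises(ValueError):
        SimulationConfig(unique_map_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(fetal_fraction_min=0.0)
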