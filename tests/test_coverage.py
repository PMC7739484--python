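import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichepart import (
    ThresholdConfig,
    call_presence,
    classify_specificity,
    compute_detection,
    non_outlier_mean,
    normalization_factors,
    normalized_coverage,
    prevalence,
    relative_abundance,
    site_association_test,
)


class TestDetection:
    @pytest.mark.parametrize(
        "vector,expected",
        [([0, 0, 3, 5], 0.5), ([0, 0, 0], 0.0), ([1, 1, 1, 1], 1.0)],
    )
    def test_breadth_of_coverage(self, vector, expected):
        assert compute_detection(np.array(vector)) == pytest.approx(expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            compute_detection(np.array([]))

    @settings(max_examples=50, deadline=None)
    @given(
        vector=st.lists(st.integers(0, 50), min_size=1, max_size=200),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariant_and_monotone(self, vector, seed):
        v = np.array(vector)
        d = compute_detection(v)
        shuffled = np.random.default_rng(seed).permutation(v)
        assert compute_detection(shuffled) == d
        assert compute_detection(v + 1) >= d


class TestPresence:
    def test_above_threshold_is_present(self, cfg):
        assert call_presence(0.51, cfg)

    def test_boundary_depends_on_comparator(self):
        strict = ThresholdConfig(presence_comparator="strict_greater")
        at_least = ThresholdConfig(presence_comparator="at_least")
        assert not call_presence(0.50, strict)
        assert call_presence(0.50, at_least)

    def test_mcg_alpha_mode_uses_point_six(self):
        cfg = ThresholdConfig()
        mcg = ThresholdConfig(detection_presence_threshold=cfg.mcg_presence_threshold)
        assert not call_presence(0.55, mcg)
        assert call_presence(0.55, cfg)


class TestNonOutlierMean:
    def test_constant_vector(self, cfg):
        assert non_outlier_mean(np.full(10, 10.0), cfg) == 10.0

    def test_zeros_are_outliers(self, cfg):
        assert non_outlier_mean(np.array([0, 0, 10, 10]), cfg) == 10.0

    def test_mad_zero_keeps_median_positions_only(self, cfg):
        v = np.array([10.0] * 99 + [1000.0])
        assert non_outlier_mean(v, cfg) == 10.0

    def test_all_zero_vector_gives_zero(self, cfg):
        assert non_outlier_mean(np.zeros(5), cfg) == 0.0

    def test_keeping_zeros_changes_the_estimate(self):
        keep = ThresholdConfig(zeros_are_outliers=False)
        v = np.array([0.0] * 10 + [10.0] * 2)
        # median 0, MAD 0 -> only zero positions qualify
        assert non_outlier_mean(v, keep) == 0.0


class TestNormalization:
    def test_factors_from_read_counts(self):
        samples = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "subject_id": ["a", "a"],
                "site": ["tongue", "tongue"],
                "total_reads": [200, 100],
                "nonhuman_reads": [150, 90],
            }
        )
        factors = normalization_factors(samples)
        assert factors["s1"] == 1.0 and factors["s2"] == 0.5

    def test_equal_reads_give_unit_factors(self, samples_two_sites):
        equal = samples_two_sites.assign(total_reads=5_000_000)
        assert (normalization_factors(equal) == 1.0).all()

    def test_normalized_coverage_divides_by_factor(self):
        assert normalized_coverage(7.0, 0.5) == 14.0
        assert normalized_coverage(3.0, 1.0) == 3.0
        assert normalized_coverage(0.0, 0.2) == 0.0
        with pytest.raises(ValueError):
            normalized_coverage(1.0, 0.0)

    def test_downsampling_leaves_normalized_coverage_invariant(self, cfg, rng):
        """Halving a sample's reads halves depth and the factor alike."""
        L, depth = 50_000, 40.0
        full = rng.poisson(depth, L)
        keep = rng.binomial(full, 0.5)  # uniform random half of the reads
        samples = pd.DataFrame(
            {
                "sample_id": ["full", "half"],
                "subject_id": ["x", "x"],
                "site": ["tongue", "tongue"],
                "total_reads": [1_000_000, 500_000],
                "nonhuman_reads": [900_000, 450_000],
            }
        )
        factors = normalization_factors(samples)
        a = normalized_coverage(non_outlier_mean(full, cfg), factors["full"])
        b = normalized_coverage(non_outlier_mean(keep, cfg), factors["half"])
        assert abs(a - b) / a < 0.05


class TestRelativeAbundance:
    def _samples(self, nonhuman):
        return pd.DataFrame(
            {
                "sample_id": ["s1"],
                "subject_id": ["a"],
                "site": ["tongue"],
                "total_reads": [nonhuman * 2],
                "nonhuman_reads": [nonhuman],
            }
        )

    def test_equal_lengths_reduce_to_read_fractions(self, cfg):
        mapped = pd.DataFrame({"s1": [600, 200]}, index=["g1", "g2"])
        lengths = pd.Series([2_000_000, 2_000_000], index=["g1", "g2"])
        ab = relative_abundance(mapped, self._samples(1000), lengths, cfg)
        assert ab.loc["g1", "s1"] == pytest.approx(0.6)
        assert ab.loc["UNKNOWN", "s1"] == pytest.approx(0.2)

    def test_length_correction_weights_short_genomes_up(self, cfg):
        # 100 reads to a 1 Mbp genome vs 900 unknown at 2 Mbp surrogate
        mapped = pd.DataFrame({"s1": [100]}, index=["g"])
        lengths = pd.Series([1_000_000], index=["g"])
        ab = relative_abundance(mapped, self._samples(1000), lengths, cfg)
        assert ab.loc["g", "s1"] == pytest.approx(100 / 1 / (100 / 1 + 900 / 2))
        assert ab.loc["UNKNOWN", "s1"] == pytest.approx(0.8181818, rel=1e-6)

    def test_single_genome_recruiting_everything(self, cfg):
        mapped = pd.DataFrame({"s1": [1000]}, index=["g"])
        lengths = pd.Series([3_000_000], index=["g"])
        ab = relative_abundance(mapped, self._samples(1000), lengths, cfg)
        assert ab.loc["g", "s1"] == pytest.approx(1.0)

    def test_columns_sum_to_one(self, cfg, samples_two_sites, rng):
        genomes = [f"g{i}" for i in range(8)]
        mapped = pd.DataFrame(
            rng.integers(0, 10_000, (8, len(samples_two_sites))),
            index=genomes,
            columns=samples_two_sites["sample_id"],
        )
        lengths = pd.Series(rng.integers(500_000, 3_000_000, 8), index=genomes)
        ab = relative_abundance(mapped, samples_two_sites, lengths, cfg)
        np.testing.assert_allclose(ab.sum(axis=0), 1.0, atol=1e-9)

    def test_mapped_exceeding_nonhuman_rejected(self, cfg):
        mapped = pd.DataFrame({"s1": [2000]}, index=["g"])
        lengths = pd.Series([1_000_000], index=["g"])
        with pytest.raises(ValueError, match="exceed"):
            relative_abundance(mapped, self._samples(1000), lengths, cfg)


def _presence(samples, positives):
    m = pd.DataFrame(
        False, index=["g"], columns=samples["sample_id"], dtype=bool
    )
    m.loc["g", positives] = True
    return m


class TestPrevalenceAndSpecificity:
    def test_sample_level_prevalence(self, samples_two_sites):
        tongue = samples_two_sites.query("site == 'tongue'")["sample_id"]
        m = _presence(samples_two_sites, tongue.iloc[:3])
        prev = prevalence(m, samples_two_sites, level="sample")
        assert prev.loc["g", "tongue"] == pytest.approx(0.5)
        assert prev.loc["g", "plaque"] == 0.0

    def test_subject_level_counts_any_positive_sample(self, samples_two_sites):
        # one subject positive in 1 of its 2 tongue samples -> 1/3 subjects
        m = _presence(samples_two_sites, ["s1_tongue_d1"])
        prev = prevalence(m, samples_two_sites, level="subject")
        assert prev.loc["g", "tongue"] == pytest.approx(1 / 3)

    def test_absent_everywhere_is_zero_at_both_levels(self, samples_two_sites):
        m = _presence(samples_two_sites, [])
        for level in ("sample", "subject"):
            assert (prevalence(m, samples_two_sites, level=level).loc["g"] == 0).all()

    def test_unknown_sample_ids_rejected(self, samples_two_sites):
        m = _presence(samples_two_sites, [])
        m["mystery_sample"] = True
        with pytest.raises(ValueError, match="unknown sample ids"):
            prevalence(m, samples_two_sites, level="sample")

    def test_chi2_for_perfect_site_split(self):
        samples = pd.DataFrame(
            {
                "sample_id": [f"p{i}" for i in range(10)] + [f"t{i}" for i in range(10)],
                "subject_id": ["x"] * 20,
                "site": ["plaque"] * 10 + ["tongue"] * 10,
                "total_reads": [100] * 20,
                "nonhuman_reads": [90] * 20,
            }
        )
        row = pd.Series(
            [True] * 10 + [False] * 10, index=samples["sample_id"]
        )
        chi2, df, p = site_association_test(row, samples, "plaque", "tongue")
        assert chi2 == pytest.approx(20.0)
        assert df == 1
        assert p == pytest.approx(7.7e-6, rel=0.01)

    def test_chi2_degenerate_margins(self, samples_two_sites):
        all_detected = pd.Series(True, index=samples_two_sites["sample_id"])
        chi2, _, p = site_association_test(
            all_detected, samples_two_sites, "tongue", "plaque"
        )
        assert chi2 == 0.0 and p == 1.0
        equal_rates = pd.Series(
            samples_two_sites["sample_id"].str.endswith("d1").to_numpy(),
            index=samples_two_sites["sample_id"],
        )
        chi2, _, p = site_association_test(
            equal_rates, samples_two_sites, "tongue", "plaque"
        )
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_specialist_cosmopolitan_and_not_detected(self, samples_two_sites):
        ids = samples_two_sites["sample_id"]
        plaque = ids[ids.str.contains("plaque")]
        m = pd.DataFrame(False, index=["gp", "gc", "gn"], columns=ids, dtype=bool)
        m.loc["gp", plaque.iloc[:2]] = True
        m.loc["gc", [plaque.iloc[0], ids[ids.str.contains("tongue")].iloc[0]]] = True
        calls = classify_specificity(m, samples_two_sites).set_index("genome_id")
        assert calls.loc["gp", "class"] == "site_specific:plaque"
        assert calls.loc["gc", "class"] == "cosmopolitan"
        assert calls.loc["gn", "class"] == "not_detected"
        assert calls.loc["gp", "n_detected_plaque"] == 2
        assert "chi2_p" in calls.columns
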