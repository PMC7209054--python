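import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paleodiv.richness import (
    GCRConfig,
    chao2,
    coverage_stats,
    face_value,
    frequency_vector,
    gcr_sqs,
    interpolated_coverage,
    interpolated_richness,
    reference_coverage,
    sqs_richness,
    squares,
)
from oracles import mc_subsample_expectations

counts_strategy = st.lists(st.integers(1, 12), min_size=2, max_size=25)


class TestCoverageStats:
    def test_worked_example(self):
        cs = coverage_stats([4, 3, 2, 1])
        assert cs.goods_u == pytest.approx(0.9, abs=1e-9)
        assert cs.multiton_ratio == pytest.approx(0.75, abs=1e-9)
        assert cs.chao_jost_coverage == pytest.approx(1 - 0.1 * 9 / 11, abs=1e-9)

    def test_all_singletons_boundary(self):
        cs = coverage_stats([1, 1, 1])
        assert cs.goods_u == 0.0
        assert cs.multiton_ratio == 0.0

    def test_no_singletons_gives_full_coverage(self):
        cs = coverage_stats([5, 5])
        assert cs.chao_jost_coverage == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            coverage_stats([])

    @settings(max_examples=100, deadline=None)
    @given(counts=counts_strategy)
    def test_all_measures_bounded(self, counts):
        cs = coverage_stats(counts)
        for v in (cs.goods_u, cs.multiton_ratio, cs.chao_jost_coverage):
            assert 0.0 <= v <= 1.0


class TestSqs:
    def test_single_species_is_one(self):
        assert sqs_richness([7], 0.6).value == 1.0
        assert sqs_richness([1], 0.6).value == 1.0

    def test_quorum_at_reference_coverage_returns_observed(self):
        counts = [4, 3, 2, 1]
        q = reference_coverage(counts)
        assert sqs_richness(counts, q).value == pytest.approx(4.0, abs=1e-9)

    def test_interpolation_matches_resampling_oracle(self, rng):
        counts = np.array([4, 3, 2, 1])
        n = counts.sum()
        m = 5
        s_mc, s_se, d_mc, d_se = mc_subsample_expectations(counts, m, 20000, rng)
        assert interpolated_richness(counts, m) == pytest.approx(s_mc, abs=3 * s_se + 1e-9)
        cov_mc = 1.0 - n / (n - m) * d_mc
        cov_se = n / (n - m) * d_se
        assert interpolated_coverage(counts, m) == pytest.approx(cov_mc, abs=3 * cov_se + 1e-9)

    def test_below_reference_quorum_not_above_observed(self):
        counts = [4, 3, 2, 1]
        est = sqs_richness(counts, 0.5)
        assert est.value <= 4.0

    def test_all_singletons_undefined(self):
        est = sqs_richness([1, 1, 1, 1], 0.6)
        assert est.is_missing
        assert "undefined_fallback" in est.flags

    def test_deep_extrapolation_flagged(self):
        counts = [3, 2, 2, 1, 1, 1]
        est = sqs_richness(counts, 0.999)
        assert "extrapolated_beyond_2n" in est.flags
        assert est.value >= 6.0

    def test_invalid_quorum_rejected(self):
        with pytest.raises(ValueError):
            sqs_richness([2, 1], 0.0)
        with pytest.raises(ValueError):
            sqs_richness([2, 1], 1.0)

    @settings(max_examples=60, deadline=None)
    @given(counts=counts_strategy, qs=st.tuples(st.floats(0.05, 0.95), st.floats(0.05, 0.95)))
    def test_monotone_in_quorum(self, counts, qs):
        q1, q2 = sorted(qs)
        e1, e2 = sqs_richness(counts, q1), sqs_richness(counts, q2)
        if not (e1.is_missing or e2.is_missing):
            assert e1.value <= e2.value + 1e-9

    @settings(max_examples=60, deadline=None)
    @given(counts=counts_strategy, q=st.floats(0.05, 0.95))
    def test_extrapolators_not_below_observed(self, counts, q):
        s_obs = len(counts)
        for est in (chao2(np.minimum(counts, 5), max(counts)), squares(counts)):
            if not est.is_missing:
                assert est.value >= s_obs - 1e-9


class TestChao2:
    def test_classical_worked_example(self):
        # S=5, m=4 units, q1=2, q2=1 -> 5 + (3/4)*4/2 = 6.5
        est = chao2([3, 3, 2, 1, 1], 4)
        assert est.value == pytest.approx(6.5, abs=1e-9)

    def test_no_singletons_returns_observed(self):
        assert chao2([3, 2, 2], 4).value == 3.0

    def test_single_unit_returns_observed(self):
        assert chao2([1, 1, 1], 1).value == 3.0

    def test_bias_corrected_when_no_doubletons(self):
        est = chao2([3, 1, 1], 4)
        assert est.value == pytest.approx(3 + (3 / 4) * 2 * 1 / 2, abs=1e-9)
        assert "bias_corrected" in est.flags


class TestSquares:
    def test_worked_example(self):
        est = squares([3, 2, 1])
        assert est.value == pytest.approx(3 + 1 * 14 / (36 - 3), abs=1e-9)

    def test_no_singletons_returns_observed(self):
        assert squares([3, 2, 2]).value == 3.0

    def test_all_singletons_missing_with_flag(self):
        est = squares([1, 1, 1])
        assert est.is_missing
        assert "undefined_fallback" in est.flags


class TestFaceValue:
    def test_counts_species(self):
        assert face_value([4, 1, 1]).value == 3.0

    def test_frequency_vector_from_taxa(self):
        counts = frequency_vector(["a", "b", "a", "c", "a"])
        assert sorted(counts.tolist()) == [1, 1, 3]


class TestGcrSqs:
    def test_quota_arithmetic_and_insufficient_cells(self):
        cfg = GCRConfig(quota_per_1000km=3, trials=5, rng_seed=1)
        # MST 2000 km -> quota 6 cells; only 3 occupied cells -> missing
        cells = ["c1"] * 4 + ["c2"] * 4 + ["c3"] * 4
        taxa = ["a", "b", "a", "c"] * 3
        est = gcr_sqs(cells, taxa, 2000.0, cfg, 0.6)
        assert est.params["quota"] == 6
        assert est.is_missing
        assert "insufficient_cells" in est.flags

    def test_identical_cells_make_trials_irrelevant(self):
        taxa_one = ["a", "a", "b", "b", "c"]
        cells = [f"c{i}" for i in range(4) for _ in taxa_one]
        taxa = taxa_one * 4
        one = gcr_sqs(cells, taxa, 1000.0, GCRConfig(3, 200, 1, 0), 0.6)
        many = gcr_sqs(cells, taxa, 1000.0, GCRConfig(3, 200, 50, 0), 0.6)
        assert one.value == pytest.approx(many.value, abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        cells = rng.integers(0, 8, 200).astype(str)
        taxa = rng.integers(0, 30, 200).astype(str)
        a = gcr_sqs(cells, taxa, 1500.0, GCRConfig(3, 200, 10, 42), 0.6)
        b = gcr_sqs(cells, taxa, 1500.0, GCRConfig(3, 200, 10, 42), 0.6)
        assert a.value == b.value

    def test_mean_stabilizes_with_trials(self, rng):
        cells = rng.integers(0, 12, 600).astype(str)
        taxa = rng.integers(0, 40, 600).astype(str)
        a = gcr_sqs(cells, taxa, 1800.0, GCRConfig(3, 200, 50, 7), 0.6)
        b = gcr_sqs(cells, taxa, 1800.0, GCRConfig(3, 200, 100, 8), 0.6)
        assert abs(a.value - b.value) / b.value < 0.02


class TestInterpolationProperties:
    @settings(max_examples=30, deadline=None)
    @given(counts=st.lists(st.integers(1, 8), min_size=3, max_size=15))
    def test_interpolated_richness_monotone_in_m(self, counts):
        n = sum(counts)
        values = [interpolated_richness(counts, m) for m in range(n + 1)]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(len(counts))

    @settings(max_examples=30, deadline=None)
    @given(counts=st.lists(st.integers(1, 8), min_size=3, max_size=15))
    def test_interpolated_coverage_monotone_and_below_reference(self, counts):
        n = sum(counts)
        cov = [interpolated_coverage(counts, m) for m in range(n)]
        assert all(b >= a - 1e-9 for a, b in zip(cov, cov[1:]))
        assert cov[-1] <= reference_coverage(counts) + 1e-9
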