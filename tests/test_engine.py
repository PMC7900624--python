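"""AFC/AAFC scores, resampled nulls, empirical p, Fisher's method."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxsets import (
    CombinatorialLimitError,
    DegenerateNullError,
    DomainError,
    GeneSet,
    NullConfig,
    NullDistribution,
    aafc_score,
    afc_score,
    empirical_p,
    exhaustive_null,
    fisher_combined,
    sample_null,
    score_collection,
    score_gene_set,
    z_score,
)

from conftest import make_table

finite_floats = st.floats(min_value=-100, max_value=100, allow_nan=False)


class TestScores:
    @pytest.mark.parametrize(
        "values,expected",
        [([1.0, -0.5, 0.5], 1.0), ([0, 0, 0], 0.0), ([-1.2, -0.8], -2.0)],
    )
    def test_afc_is_sum(self, values, expected):
        assert afc_score(values) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "values,expected", [([1.0, -0.5, 0.5], 2.0), ([0, 0], 0.0)]
    )
    def test_aafc_is_sum_of_abs(self, values, expected):
        assert aafc_score(values) == pytest.approx(expected)

    @pytest.mark.parametrize("fn", [afc_score, aafc_score])
    def test_empty_rejected(self, fn):
        with pytest.raises(DomainError):
            fn([])

    @given(st.lists(finite_floats, min_size=1, max_size=30))
    def test_triangle_inequality(self, values):
        assert aafc_score(values) >= abs(afc_score(values)) - 1e-9


class TestSampleNull:
    def test_constant_background_gives_zero_sd(self):
        null = sample_null([2.0] * 10, 3, "afc", NullConfig(n_draws=500, seed=0))
        assert np.all(null.draws == 6.0)
        assert null.sd == 0.0
        assert null.degenerate

    def test_null_mean_matches_closed_form(self):
        # mean of 2-subset sums of [1..5] is 2 * mean(background) = 6
        null = sample_null(
            [1, 2, 3, 4, 5], 2, "afc", NullConfig(n_draws=40_000, seed=2)
        )
        exact = exhaustive_null([1, 2, 3, 4, 5], 2, "afc")
        se = exact.std() / math.sqrt(null.n_draws)
        assert null.mean == pytest.approx(6.0, abs=4 * se)

    def test_seeded_runs_identical(self):
        cfg = NullConfig(n_draws=1000, seed=42)
        a = sample_null([1, 2, 3, 4, 5, 6], 2, "afc", cfg)
        b = sample_null([1, 2, 3, 4, 5, 6], 2, "afc", cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_draws_are_without_replacement(self):
        # size-2 draws from {0, 10}: only subset sum is 10, never 0 or 20
        null = sample_null([0.0, 10.0, 5.0], 2, "afc", NullConfig(n_draws=2000, seed=1))
        assert set(np.unique(null.draws)) <= {10.0, 5.0, 15.0}

    def test_large_sample_size_uses_exact_subsets(self):
        # k(k-1) > N exercises the top-k sampling path; every draw must
        # still be a valid subset sum of the background
        bg = np.arange(8, dtype=float)
        null = sample_null(bg, 6, "afc", NullConfig(n_draws=3000, seed=3))
        exact = set(np.round(exhaustive_null(bg, 6, "afc"), 9))
        assert set(np.round(null.draws, 9)) <= exact

    def test_moments_recomputable_from_draws(self):
        null = sample_null([1, 2, 3, 4, 5], 2, "aafc", NullConfig(1000, 7))
        assert null.mean == pytest.approx(null.draws.mean(), abs=1e-9)
        assert null.sd == pytest.approx(null.draws.std(ddof=0), abs=1e-9)

    @pytest.mark.parametrize("size", [5, 6])
    def test_degenerate_sample_size_rejected(self, size):
        with pytest.raises(DegenerateNullError):
            sample_null([1, 2, 3, 4, 5], size, "afc", NullConfig(10, 0))

    def test_sample_size_below_one_rejected(self):
        with pytest.raises(DomainError):
            sample_null([1, 2, 3], 0, "afc", NullConfig(10, 0))


class TestZAndP:
    def _null(self, draws):
        draws = np.asarray(draws, dtype=float)
        return NullDistribution(
            "afc", 2, draws, float(draws.mean()), float(draws.std(ddof=0))
        )

    def test_z_at_mean_is_zero(self):
        null = self._null([1, 2, 3])
        assert z_score(null.mean, null) == 0.0

    def test_z_two_sd_above(self):
        null = self._null([1, 2, 3])
        assert z_score(null.mean + 2 * null.sd, null) == pytest.approx(2.0)

    def test_degenerate_sd_yields_zero(self):
        null = self._null([5, 5, 5])
        assert z_score(7.0, null) == 0.0

    def test_p_actual_below_all_draws(self):
        null = self._null(range(1, 10))
        assert empirical_p(-100, null, "upper") == 1.0

    def test_p_actual_above_all_draws(self):
        null = self._null(range(1, 10))
        assert empirical_p(100, null, "upper") == pytest.approx(0.1)

    def test_lower_tail_symmetry(self):
        null = self._null(range(1, 10))
        assert empirical_p(-100, null, "lower") == pytest.approx(0.1)
        assert empirical_p(100, null, "lower") == 1.0


class TestExhaustiveNull:
    def test_all_pairs_of_three(self):
        scores = exhaustive_null([1, 2, 3], 2, "afc")
        assert sorted(scores) == [3, 4, 5]

    def test_mean_of_pairs_of_five(self):
        scores = exhaustive_null([1, 2, 3, 4, 5], 2, "afc")
        assert len(scores) == 10
        assert scores.mean() == pytest.approx(6.0)

    def test_aafc_single_draw(self):
        scores = exhaustive_null([-1, 1], 1, "aafc")
        assert list(scores) == [1, 1]
        assert np.mean(scores >= 1) == 1.0

    def test_combinatorial_bound_enforced(self):
        with pytest.raises(CombinatorialLimitError):
            exhaustive_null(list(range(60)), 30, "afc")


class TestOracleAgreement:
    """Resampled null vs exact enumeration on small instances."""

    @pytest.mark.parametrize("method", ["afc", "aafc"])
    @pytest.mark.parametrize("case_seed", range(8))
    def test_p_and_moments_within_3se(self, method, case_seed):
        rng = np.random.default_rng(1000 + case_seed)
        n = int(rng.integers(6, 13))
        k = int(rng.integers(1, 5))
        bg = rng.normal(0, 1, size=n)
        exact = exhaustive_null(bg, k, method)
        cfg = NullConfig(n_draws=10_000, seed=case_seed)
        null = sample_null(bg, k, method, cfg)

        mu, sd = exact.mean(), exact.std(ddof=0)
        assert null.mean == pytest.approx(mu, abs=3 * sd / math.sqrt(cfg.n_draws) + 1e-12)
        kurt = np.mean((exact - mu) ** 4) / sd**4 if sd > 0 else 3.0
        sd_se = sd * math.sqrt(max(kurt - 1, 0) / (4 * cfg.n_draws))
        assert null.sd == pytest.approx(sd, abs=3 * sd_se + 1e-12)

        actual = mu + float(rng.uniform(-2, 2)) * sd  # generic, untied point
        p_exact = np.mean(exact >= actual)
        se = math.sqrt(p_exact * (1 - p_exact) / cfg.n_draws)
        assert empirical_p(actual, null, "upper") == pytest.approx(
            p_exact, abs=3 * se + 2 / cfg.n_draws
        )


class TestFisherCombined:
    @pytest.mark.parametrize("p", [1e-6, 1e-3, 0.05, 0.3, 0.9999, 1.0])
    def test_k1_identity(self, p):
        combined, k = fisher_combined([p])
        assert k == 1
        assert combined == pytest.approx(p, rel=1e-9)

    def test_two_p05_closed_form(self):
        # even-df chi-square survival: exp(-X/2) * (1 + X/2) at X = -4 ln 0.05
        x = -4 * math.log(0.05)
        expected = math.exp(-x / 2) * (1 + x / 2)
        combined, k = fisher_combined([0.05, 0.05])
        assert k == 2
        assert combined == pytest.approx(expected, abs=1e-12)

    def test_all_ones(self):
        combined, _ = fisher_combined([1.0, 1.0, 1.0])
        assert combined == pytest.approx(1.0)

    def test_absent_values_dropped(self):
        combined, k = fisher_combined([None, 0.3, None])
        assert (combined, k) == (pytest.approx(0.3), 1)

    def test_no_p_values_returns_absent(self):
        assert fisher_combined([None, None]) == (None, 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            fisher_combined([0.5, 1.5])

    def test_tiny_p_floored_not_crashed(self):
        combined, _ = fisher_combined([1e-320, 1e-320])
        assert 0 < combined <= 1


class TestScoreGeneSet:
    def test_absent_set_is_unscored(self, tiny_table):
        gs = GeneSet("NONE", "d", ("x1", "x2", "x3"))
        r = score_gene_set(tiny_table, gs, NullConfig(100, 0))
        assert r.n_matched == 0 and r.unscored
        assert r.afc_score is None

    def test_below_min_matched_is_unscored(self, tiny_table):
        gs = GeneSet("TWO", "d", ("g1", "g2"))
        r = score_gene_set(tiny_table, gs, NullConfig(100, 0), min_matched=3)
        assert r.unscored and r.n_matched == 2

    def test_scores_on_matched_values(self, tiny_table):
        gs = GeneSet("S", "d", ("g1", "g2", "g5", "nope"))
        r = score_gene_set(tiny_table, gs, NullConfig(500, 0))
        assert r.n_set == 4 and r.n_matched == 3
        assert r.afc_score == pytest.approx(1.0 - 0.5 - 1.0)
        assert r.aafc_score == pytest.approx(2.5)
        assert r.direction == "down"

    def test_whole_table_set_degenerate(self, tiny_table):
        gs = GeneSet("ALL", "d", tuple(tiny_table.records))
        r = score_gene_set(tiny_table, gs, NullConfig(100, 0))
        assert r.degenerate
        assert r.afc_z == 0.0 and r.afc_p == 1.0
        assert r.aafc_significant is False

    def test_spike_in_detected(self, spiked):
        table, planted = spiked
        r = score_gene_set(table, planted["SPIKE25"], NullConfig(10_000, 11))
        assert r.direction == "up"
        assert r.afc_z > 5 and r.aafc_z > 5
        assert r.aafc_significant
        assert r.fisher_p < 1e-6

    def test_negative_effect_flips_afc_only(self, spiked, spike_design):
        from dataclasses import replace

        from toxsets import generate_background, plant_signal

        design = replace(
            spike_design,
            planted_sets=(type(spike_design.planted_sets[0])(
                "SPIKE25", 25, -1.0, "shift"
            ),),
        )
        table, planted = plant_signal(generate_background(design), design)
        r = score_gene_set(table, planted["SPIKE25"], NullConfig(10_000, 11))
        assert r.direction == "down"
        assert r.afc_z < -5
        assert r.aafc_z > 0


class TestEngineSymmetries:
    def _spiked_result(self, table, members, seed):
        gs = GeneSet("S", "d", tuple(members))
        return score_gene_set(table, gs, NullConfig(4000, seed))

    def test_afc_antisymmetry_aafc_invariance(self):
        rng = np.random.default_rng(5)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 50))}
        neg = {g: -v for g, v in values.items()}
        members = [f"g{i}" for i in range(0, 10)]
        a = self._spiked_result(make_table(values), members, seed=9)
        b = self._spiked_result(make_table(neg), members, seed=9)
        assert b.afc_score == pytest.approx(-a.afc_score)
        assert b.afc_z == pytest.approx(-a.afc_z, abs=1e-9)
        assert b.aafc_score == pytest.approx(a.aafc_score)
        assert b.aafc_z == pytest.approx(a.aafc_z, abs=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 50))}
        scaled = {g: 3.5 * v for g, v in values.items()}
        members = [f"g{i}" for i in range(5, 17)]
        a = self._spiked_result(make_table(values), members, seed=4)
        b = self._spiked_result(make_table(scaled), members, seed=4)
        assert b.afc_score == pytest.approx(3.5 * a.afc_score)
        assert b.aafc_score == pytest.approx(3.5 * a.aafc_score)
        assert b.afc_z == pytest.approx(a.afc_z, abs=1e-9)
        assert b.aafc_z == pytest.approx(a.aafc_z, abs=1e-9)


class TestScoreCollection:
    def test_results_independent_of_gmt_order(self, tiny_table, tiny_collection):
        from toxsets import GeneSetCollection

        reversed_coll = GeneSetCollection(
            tuple(reversed(tiny_collection.sets)), "fixture"
        )
        cfg = NullConfig(n_draws=500, seed=13)
        a = score_collection(tiny_table, tiny_collection, cfg, min_matched=2)
        b = score_collection(tiny_table, reversed_coll, cfg, min_matched=2)
        assert [(r.set_name, r.afc_z, r.aafc_p) for r in a] == [
            (r.set_name, r.afc_z, r.aafc_p) for r in b
        ]

    def test_unmatched_sets_do_not_raise(self, tiny_table, tiny_collection):
        results = score_collection(
            tiny_table, tiny_collection, NullConfig(200, 3), min_matched=2
        )
        by_name = {r.set_name: r for r in results}
        assert by_name["ABSENT"].unscored
        assert not by_name["MIXED"].unscored
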