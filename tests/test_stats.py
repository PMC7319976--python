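"""Replicate aggregation, two-tailed t-tests, percent change and power."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lungmorph.stats import (
    StatsError,
    aggregate_mouse,
    compare_groups,
    percent_change,
    round_percent,
    simulate_power,
    two_tailed_t,
    two_tailed_t_from_stats,
)
from lungmorph.synth import CohortSpec, MetricGroupSpec, generate_cohort


class TestAggregateMouse:
    def test_mean_of_replicates(self):
        out = aggregate_mouse([("m1", 10.0), ("m1", 20.0), ("m1", 30.0)])
        assert len(out) == 1 and out[0].value == 20.0

    def test_single_value(self):
        assert aggregate_mouse([("m1", 7.5)])[0].value == 7.5

    def test_matches_brute_force_sum_over_count(self, rng):
        vals = [(f"m{i % 5}", float(v)) for i, v in enumerate(rng.normal(0, 1, 60))]
        out = {s.mouse_id: s.value for s in aggregate_mouse(vals)}
        for mouse in {m for m, _ in vals}:
            vs = [v for m, v in vals if m == mouse]
            assert out[mouse] == pytest.approx(sum(vs) / len(vs))

    def test_empty_input_rejected(self):
        with pytest.raises(StatsError):
            aggregate_mouse([])


class TestTwoTailedT:
    def test_identical_groups(self):
        c = two_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.t_stat == pytest.approx(0.0)
        assert c.p_two_tailed == pytest.approx(1.0)

    def test_printed_type_one_density_stats_round_to_p_003(self):
        """Type I density summary (n = 4/4) reproduces the published p."""
        c = two_tailed_t_from_stats(9453, 1863, 4, 6279, 1173, 4, variant="pooled")
        assert round(c.p_two_tailed, 2) == 0.03
        assert c.df == 6

    def test_matches_permutation_oracle(self, rng):
        young = list(rng.normal(10, 2, 4))
        old = list(rng.normal(8, 2, 4))
        p_t = two_tailed_t(young, old).p_two_tailed
        pooled = np.array(young + old)
        obs = abs(np.mean(young) - np.mean(old))
        hits = 0
        n_perm = 10000
        prng = np.random.default_rng(1)
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            hits += abs(perm[:4].mean() - perm[4:].mean()) >= obs - 1e-12
        assert abs(p_t - hits / n_perm) <= 0.03

    def test_pooled_close_to_welch_under_equal_variance(self, rng):
        young = list(rng.normal(5, 1, 12))
        old = list(rng.normal(5, 1, 12))
        p1 = two_tailed_t(young, old, "pooled").p_two_tailed
        p2 = two_tailed_t(young, old, "welch").p_two_tailed
        assert abs(p1 - p2) <= 0.005

    def test_zero_variance_equal_means(self):
        c = two_tailed_t([5.0, 5.0], [5.0, 5.0])
        assert c.p_two_tailed == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            two_tailed_t([1.0], [1.0, 2.0])


class TestPercentChange:
    @pytest.mark.parametrize(
        "young,old,reported",
        [
            (33096, 25308, 24),  # bronchiole cross-sectional area
            (9453, 6279, 34),  # Type I density
            (243, 217, 11),  # bronchiole diameter
            (17.7, 10.7, 40),  # club-cell EdU fraction
            (13.5, 8.6, 36),  # ciliated-cell EdU fraction
            (20207, 15587, 23),  # lumen area
        ],
    )
    def test_published_group_means_reproduce_prose_percents(self, young, old, reported):
        assert round_percent(percent_change(young, old)) == reported

    def test_no_change(self):
        assert percent_change(4.2, 4.2) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(StatsError):
            percent_change(0.0, 1.0)

    @given(st.floats(1, 1e4), st.floats(0.01, 1e4))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_swap_identity(self, young, old):
        """reduction(young→old) and increase(old→young) are consistent."""
        r = percent_change(young, old) / 100.0
        inc = -percent_change(old, young) / 100.0
        assert inc == pytest.approx(r / (1 - r), rel=1e-9, abs=1e-9)


class TestSimulatePower:
    def test_null_rejection_near_alpha(self):
        rate = simulate_power((10, 2, 1), (10, 2, 1), n_mice=4, reps=1000, seed=11)
        assert 0.03 <= rate <= 0.07

    def test_noiseless_effect_has_full_power(self):
        rate = simulate_power((10, 0, 0), (8, 0, 0), n_mice=4, reps=100, seed=1)
        assert rate == 1.0

    def test_seed_stable(self):
        a = simulate_power((9453, 1863, 900), (6279, 1173, 900), reps=200, seed=5)
        b = simulate_power((9453, 1863, 900), (6279, 1173, 900), reps=200, seed=5)
        assert 0.0 < a < 1.0 and a == b

    def test_too_few_reps_rejected(self):
        with pytest.raises(StatsError):
            simulate_power((1, 1, 1), (1, 1, 1), reps=10, seed=0)


class TestCohortPipeline:
    def test_fig3_parameterisation_recovers_reduction(self):
        """Type I density cohort: the expected reduction rounds to 34 %."""
        pcs = []
        for seed in range(40):
            spec = CohortSpec(
                metrics={"typeI": MetricGroupSpec(9453, 1863, 6279, 1173, 900)},
                n_mice=4, fields_per_mouse=3, seed=seed,
            )
            res = compare_groups(generate_cohort(spec).values)
            pcs.append(res.percent_change.iloc[0])
        assert round_percent(float(np.mean(pcs))) in (33, 34, 35)

    def test_fields_collapse_to_mouse_value_when_noiseless(self):
        spec = CohortSpec(
            metrics={"m": MetricGroupSpec(10, 1, 9, 1, 0.0)},
            n_mice=3, fields_per_mouse=1, seed=2,
        )
        ds = generate_cohort(spec)
        merged = ds.values.merge(ds.mouse_truth, on=["group", "mouse_id", "metric"])
        assert np.allclose(merged.value_x, merged.value_y)

    def test_adding_mice_does_not_perturb_earlier_mice(self):
        m = {"m": MetricGroupSpec(10, 1, 9, 1, 0.5)}
        small = generate_cohort(CohortSpec(metrics=m, n_mice=3, seed=7)).values
        big = generate_cohort(CohortSpec(metrics=m, n_mice=5, seed=7)).values
        common = small.mouse_id.unique()
        a = small[small.mouse_id.isin(common)].reset_index(drop=True)
        b = big[big.mouse_id.isin(common)].reset_index(drop=True)
        assert np.allclose(
            a.sort_values(["mouse_id", "field_id"]).value.to_numpy(),
            b.sort_values(["mouse_id", "field_id"]).value.to_numpy(),
        )
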