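import numpy as np
import pandas as pd
import pytest

from refugia.abc import (
    ReferenceTable,
    build_reference_table,
    estimate_error_rates,
    estimate_parameters,
    model_posterior,
    pca_model_check,
    reject,
    relative_median_absolute_error,
    run_tournament,
)
from refugia.coalescent import (
    Prior,
    default_priors,
    sample_prior,
    scenario,
    simulate_dataset,
)
from refugia.errors import ConfigError, DataError
from refugia.popgen import SummaryStatisticVector, summary_vector
from refugia.synthetic import default_truth_draw, separated_priors


@pytest.fixture(scope="module")
def small_table(request):
    from refugia.coalescent import LocusConfig

    loci = (
        LocusConfig("mtDNA", 300, "mitochondrial_haploid", "mu_mt"),
        LocusConfig("nDNA", 150, "nuclear_diploid", "mu_nuc"),
    )
    sizes = {"Southern": 4, "Northern": 4, "Central": 6}
    specs = [scenario(s) for s in ("R1", "DS1", "V")]
    table = build_reference_table(
        specs, separated_priors(), loci, sizes, 60, seed=11
    )
    return table, loci, sizes


def synthetic_gaussian_table(seed=0, n=400, separation=6.0):
    """A hand-built table with two cleanly separated scenario clouds."""
    rng = np.random.default_rng(seed)
    stats_a = rng.normal(0.0, 1.0, size=(n, 4))
    stats_b = rng.normal(separation, 1.0, size=(n, 4))
    stats = np.empty((2 * n, 4))
    stats[0::2] = stats_a
    stats[1::2] = stats_b
    sids = np.empty(2 * n, dtype=object)
    sids[0::2] = "A"
    sids[1::2] = "B"
    params = pd.DataFrame({"theta": rng.uniform(1, 2, size=2 * n)})
    return ReferenceTable(
        sids.astype(str), params, stats, np.ones_like(stats, dtype=bool),
        ("s1", "s2", "s3", "s4"),
    )


def obs_vector(values):
    values = np.asarray(values, dtype=float)
    return SummaryStatisticVector(values, np.ones(len(values), dtype=bool),
                                  tuple(f"s{i+1}" for i in range(len(values))))


class TestReferenceTable:
    def test_row_count_and_interleaving(self, small_table):
        table, _, _ = small_table
        assert table.n_rows == 3 * 60
        assert list(table.scenario_ids[:3]) == ["R1", "DS1", "V"]

    def test_deterministic_given_seed(self, small_table):
        table, loci, sizes = small_table
        again = build_reference_table(
            [scenario(s) for s in ("R1", "DS1", "V")],
            separated_priors(), loci, sizes, 60, seed=11,
        )
        assert np.array_equal(table.stats, again.stats)
        assert table.params.equals(again.params)

    def test_standardization_centers_on_median(self, small_table):
        table, _, _ = small_table
        z = table.standardized(table.stats)
        med = np.median(z, axis=0)
        assert np.allclose(med, 0.0, atol=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            ReferenceTable(
                np.array([]), pd.DataFrame(), np.zeros((0, 3)),
                np.zeros((0, 3), dtype=bool), ("a", "b", "c"),
            )


class TestReject:
    def test_count_contract(self):
        table = synthetic_gaussian_table()
        acc = reject(obs_vector([0, 0, 0, 0]), table, tolerance=0.01)
        assert len(acc) == int(np.ceil(0.01 * table.n_rows))

    def test_zero_distance_row_ranked_first(self):
        table = synthetic_gaussian_table()
        acc = reject(obs_vector(table.stats[37]), table, tolerance=0.01)
        assert acc[0] == 37

    def test_rescaling_a_statistic_leaves_accepted_set_unchanged(self):
        table1 = synthetic_gaussian_table(seed=3)
        stats2 = table1.stats.copy()
        stats2[:, 2] *= 1000.0
        table2 = ReferenceTable(
            table1.scenario_ids, table1.params, stats2,
            np.ones_like(stats2, dtype=bool), table1.stat_names,
        )
        obs1 = obs_vector([1.0, -0.5, 0.7, 0.1])
        obs2 = obs_vector([1.0, -0.5, 700.0, 0.1])
        a1 = reject(obs1, table1, 0.02)
        a2 = reject(obs2, table2, 0.02)
        assert np.array_equal(a1, a2)

    def test_bad_tolerance_rejected(self):
        table = synthetic_gaussian_table()
        with pytest.raises(ConfigError):
            reject(obs_vector([0, 0, 0, 0]), table, tolerance=0.0)


class TestModelPosterior:
    def test_probabilities_sum_to_one(self, small_table):
        table, loci, sizes = small_table
        rng = np.random.default_rng(1)
        draw = sample_prior(separated_priors(), scenario("DS1"), rng)
        data, pa = simulate_dataset(scenario("DS1"), draw, loci, sizes, rng)
        vec = summary_vector(data, pa)
        for method in ("rejection", "logistic"):
            res = model_posterior(vec, table, 0.1, method=method)
            assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert ((res.ci >= 0) & (res.ci <= 1)).all()

    def test_degenerate_single_scenario_acceptance(self):
        table = synthetic_gaussian_table()
        res = model_posterior(obs_vector([0, 0, 0, 0]), table, 0.01)
        assert res.best == "A"
        assert res.probabilities[list(res.scenario_ids).index("A")] > 0.99

    def test_logistic_and_rejection_agree_when_separated(self):
        table = synthetic_gaussian_table(separation=8.0)
        obs = obs_vector([1.0, 1.0, 1.0, 1.0])
        rej = model_posterior(obs, table, 0.2, method="rejection")
        log = model_posterior(obs, table, 0.2, method="logistic")
        pa_r = rej.probabilities[list(rej.scenario_ids).index("A")]
        pa_l = log.probabilities[list(log.scenario_ids).index("A")]
        assert abs(pa_r - pa_l) < 0.1
        assert rej.best == log.best == "A"


class TestTournament:
    def test_structure_and_determinism(self, small_table):
        _, loci, sizes = small_table
        rng = np.random.default_rng(5)
        draw = sample_prior(separated_priors(), scenario("DS1"), rng)
        data, pa = simulate_dataset(scenario("DS1"), draw, loci, sizes, rng)
        vec = summary_vector(data, pa)
        groups = [
            [scenario(s) for s in ("R1", "R3")],
            [scenario(s) for s in ("DS1", "DS3")],
        ]
        res1 = run_tournament(
            groups, [scenario("V")], vec, separated_priors(), loci, sizes,
            n_sims_per_scenario=40, tolerance=0.1, seed=9, method="rejection",
        )
        assert len(res1.tier2.scenario_ids) == 3
        assert res1.best_scenario in {"R1", "R3", "DS1", "DS3", "V"}
        res2 = run_tournament(
            groups, [scenario("V")], vec, separated_priors(), loci, sizes,
            n_sims_per_scenario=40, tolerance=0.1, seed=9, method="rejection",
        )
        assert res1.best_scenario == res2.best_scenario
        assert res1.audit == res2.audit

    def test_single_group_plus_extra(self, small_table):
        _, loci, sizes = small_table
        rng = np.random.default_rng(6)
        draw = sample_prior(separated_priors(), scenario("V"), rng)
        data, pa = simulate_dataset(scenario("V"), draw, loci, sizes, rng)
        vec = summary_vector(data, pa)
        res = run_tournament(
            [[scenario("R1"), scenario("DS1")]], [scenario("V")], vec,
            separated_priors(), loci, sizes, 30, 0.2, seed=1, method="rejection",
        )
        assert len(res.tier2.scenario_ids) == 2

    def test_group_of_one_rejected(self, small_table):
        _, loci, sizes = small_table
        with pytest.raises(ConfigError):
            run_tournament(
                [[scenario("R1")]], [], obs_vector([0.0]), separated_priors(),
                loci, sizes, 10,
            )


class TestErrorRates:
    def test_rates_bounded_and_confusion_normalized(self, small_table):
        table, loci, sizes = small_table
        err = estimate_error_rates(
            scenario("DS1"), [scenario("R1"), scenario("V")], table,
            separated_priors(), loci, sizes, n_pseudo_observed=15,
            tolerance=0.1, seed=2, method="rejection",
        )
        assert 0 <= err.type_I <= 1
        assert 0 <= err.type_II <= 1
        assert np.allclose(err.confusion.sum(axis=1), 1.0)

    def test_indistinguishable_scenarios_near_chance(self, small_table):
        # two scenario specs with identical events are the same model in
        # different clothes: classification cannot beat chance
        _, loci, sizes = small_table
        from refugia.coalescent import ScenarioSpec

        ds1 = scenario("DS1")
        clone = ScenarioSpec("DS1b", ds1.events)
        table = build_reference_table(
            [ds1, clone], separated_priors(), loci, sizes, 50, seed=3
        )
        err = estimate_error_rates(
            ds1, [clone], table, separated_priors(), loci, sizes,
            n_pseudo_observed=20, tolerance=0.2, seed=4, method="rejection",
        )
        assert 0.2 <= err.type_I <= 0.8
        assert 0.2 <= err.type_II <= 0.8


class TestParameterEstimation:
    def test_point_mass_prior_gives_point_posterior(self, small_table):
        _, loci, sizes = small_table
        ds1 = scenario("DS1")
        truth = default_truth_draw("DS1")
        point = separated_priors().replace(
            **{name: Prior("point", value)
               for name, value in truth.values.items()
               if not name.startswith("T_") or name in ("T_old", "T_recent")}
        )
        table = build_reference_table([ds1], point, loci, sizes, 80, seed=5)
        rng = np.random.default_rng(6)
        data, pa = simulate_dataset(ds1, truth, loci, sizes, rng)
        vec = summary_vector(data, pa)
        post = estimate_parameters(vec, "DS1", table, tolerance=0.2)
        assert float(post.median["T_old"]) == pytest.approx(64_800.0)
        assert float(post.ci_high["T_old"] - post.ci_low["T_old"]) == pytest.approx(0.0)

    def test_rmedae_zero_for_point_mass_model(self, small_table):
        _, loci, sizes = small_table
        ds1 = scenario("DS1")
        truth = default_truth_draw("DS1")
        point = separated_priors().replace(
            **{name: Prior("point", value)
               for name, value in truth.values.items()
               if not name.startswith("T_") or name in ("T_old", "T_recent")}
        )
        table = build_reference_table([ds1], point, loci, sizes, 40, seed=7)
        rmedae = relative_median_absolute_error(
            ds1, table, point, loci, sizes, n_datasets=5, tolerance=0.2, seed=8
        )
        assert float(rmedae["T_old"]) == pytest.approx(0.0, abs=1e-12)

    def test_times_reported_in_generations_convertible_to_kya(self, small_table):
        table, _, _ = small_table
        rows = table.params["T_old"].dropna()
        assert ((rows > 1_000) & (rows < 1e6)).all()


class TestPcaCheck:
    def test_simulated_row_inside_cloud(self, small_table):
        table, _, _ = small_table
        obs = SummaryStatisticVector(
            table.stats[10].copy(), table.defined[10].copy(), table.stat_names
        )
        check = pca_model_check(table, obs)
        assert check.within_cloud
        assert np.allclose(check.simulated_coords.mean(axis=0), 0.0, atol=1e-9)

    def test_outlier_outside_cloud(self, small_table):
        table, _, _ = small_table
        values = table.stats[0] + 100.0 * table.stats.std(axis=0) + 100.0
        obs = SummaryStatisticVector(
            values, np.ones_like(values, dtype=bool), table.stat_names
        )
        assert not pca_model_check(table, obs).within_cloud
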