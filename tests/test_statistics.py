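import numpy as np
import pandas as pd
import pytest

import cdshape as cs
from cdshape.constants import KB_KCAL_MOL_K


class TestPooledPairSamples:
    @pytest.mark.parametrize("n_frames", [1, 10])
    def test_sample_count_is_frames_times_units(self, regular_cd, n_frames):
        conf, topo = regular_cd
        table = cs.metrics_table([conf] * n_frames, topo)
        assert cs.pooled_pair_samples(table).shape == (n_frames * 7, 2)

    def test_single_frame_preserves_per_unit_order(self, regular_cd):
        conf, topo = regular_cd
        table = cs.metrics_table([conf], topo)
        samples = cs.pooled_pair_samples(table)
        expected = np.column_stack(
            [cs.d1_distances(conf, topo), cs.d2_distances(conf, topo)]
        )
        assert np.allclose(samples, expected)


class TestFreeEnergySurface:
    def test_equal_occupancy_gives_zero_free_energy_difference(self):
        samples = np.array([[2.05, 2.05], [2.05, 2.05], [3.05, 3.05], [3.05, 3.05]])
        grid = cs.free_energy_surface(samples, 300.0, bin_width=0.1)
        occupied = grid.free_energy[grid.probability > 0]
        assert occupied.size == 2
        assert abs(occupied[0] - occupied[1]) < 1e-12

    def test_probability_ratio_e_gives_kbt(self):
        # bins occupied in ratio e : 1 (within float rounding of counts)
        samples = [[2.05, 2.05]] * 2718 + [[3.05, 3.05]] * 1000
        grid = cs.free_energy_surface(np.array(samples), 300.0, bin_width=0.1)
        occ = np.sort(grid.free_energy[grid.probability > 0])
        expected = KB_KCAL_MOL_K * 300.0 * np.log(2.718)
        assert occ[1] - occ[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.59616, abs=2e-4)

    def test_single_occupied_bin(self):
        grid = cs.free_energy_surface(np.array([[4.0, 4.0]] * 5), 300.0)
        assert grid.probability.max() == 1.0
        occupied = grid.free_energy[grid.probability > 0]
        assert occupied == pytest.approx([0.0])
        assert np.isnan(grid.free_energy[grid.probability == 0]).all()

    def test_normalization_and_minimum_alignment(self, rng):
        samples = rng.uniform(2.5, 6.5, size=(5000, 2))
        grid = cs.free_energy_surface(samples, 300.0)
        assert grid.probability.sum() == pytest.approx(1.0, abs=1e-9)
        masked = np.where(np.isnan(grid.free_energy), np.inf, grid.free_energy)
        assert np.argmin(masked) == np.argmax(grid.probability)

    def test_invariant_under_sample_duplication(self, rng):
        samples = rng.uniform(2.5, 6.5, size=(500, 2))
        g1 = cs.free_energy_surface(samples, 300.0)
        g2 = cs.free_energy_surface(np.vstack([samples, samples]), 300.0)
        assert np.allclose(g1.probability, g2.probability)

    def test_pairwise_differences_match_log_probability_ratios(self, rng):
        samples = rng.uniform(2.5, 6.5, size=(2000, 2))
        grid = cs.free_energy_surface(samples, 320.0)
        p = grid.probability[grid.probability > 0]
        f = grid.free_energy[grid.probability > 0]
        ratio = -KB_KCAL_MOL_K * 320.0 * np.log(p[1:] / p[0])
        assert np.allclose(f[1:] - f[0], ratio, rtol=1e-9, atol=1e-12)

    def test_empty_samples_error(self):
        with pytest.raises(cs.StatisticsError):
            cs.free_energy_surface(np.empty((0, 2)), 300.0)


class TestClassifyFlips:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            ((80, 85, 70, 60, 75, 88, 89), 0),
            ((95, 85, 70, 60, 75, 88, 89), 1),
            ((90, 90, 90, 90, 90, 90, 90), 0),  # threshold is strict
            ((91, 92, 180, 0, 45, 90.0001, 89.9999), 4),
        ],
    )
    def test_counts_angles_strictly_above_threshold(self, theta, expected):
        assert cs.classify_flips(np.array(theta, dtype=float)) == expected


class TestFlipPopulation:
    def test_exact_percentages_from_built_states(self):
        specs = {k: spec for (spec, _), k in zip(cs.flip_mixture(), range(3))}
        frames = []
        topo = None
        for k, count in [(0, 58), (1, 35), (2, 7)]:
            conf, topo = cs.build_conformation(specs[k])
            frames += [conf] * count
        table = cs.metrics_table(frames, topo)
        pop = cs.flip_population(table)
        # one flipped unit shows as 2 counted angles; two isolated units as 4
        assert pop.percentage(0) == pytest.approx(58.0)
        assert pop.percentage(2) == pytest.approx(35.0)
        assert pop.percentage(4) == pytest.approx(7.0)
        assert pop.percentage(6) == 0.0

    def test_all_no_flip(self, regular_cd):
        conf, topo = regular_cd
        pop = cs.flip_population(cs.metrics_table([conf] * 5, topo))
        assert pop.percentage(0) == 100.0 and pop.percentage(1) == 0.0

    def test_percentages_sum_to_100(self):
        ensemble, topo, _ = cs.generate_ensemble(cs.flip_mixture(), 300, 0.05, seed=11)
        pop = cs.flip_population(cs.metrics_table(ensemble, topo))
        assert sum(pop.percentages.values()) == pytest.approx(100.0)

    def test_binomial_recovery_of_mixing_fraction(self):
        p, n = 0.25, 2000
        mixture = [
            (cs.BuilderSpec(), 1 - p),
            (cs.BuilderSpec(flip_units=frozenset({2})), p),
        ]
        ensemble, topo, _ = cs.generate_ensemble(mixture, n, 0.05, seed=21)
        pop = cs.flip_population(cs.metrics_table(ensemble, topo))
        bound = 3 * np.sqrt(p * (1 - p) / n) * 100
        assert abs(pop.percentage(2) - 25.0) <= bound


class TestInsertion:
    @pytest.mark.parametrize(
        "d4, expected",
        [((2.5, 7.8, 9.1), 1), ((7, 8, 9, 10), 0), ((1.0, 2.9), 2), ((3.0,), 0)],
    )
    def test_counts_strictly_below_cutoff(self, d4, expected):
        assert cs.n_hp_inserted(np.array(d4, dtype=float)) == expected

    def test_seeded_closure_fraction_recovery(self):
        ensemble, topo, truth = cs.generate_ensemble(cs.closure_mixture(0.4), 2000, 0.05, seed=33)
        summary = cs.self_closure_summary(cs.metrics_table(ensemble, topo))
        bound = 3 * np.sqrt(0.4 * 0.6 / 2000) * 100
        assert abs(summary.closure_percentage - 40.0) <= bound
        truth_pct = truth.table["n_inserted"].gt(0).mean() * 100
        assert summary.closure_percentage == pytest.approx(truth_pct)

    def test_all_exterior_is_zero_closure(self):
        ensemble, topo, _ = cs.generate_ensemble(cs.closure_mixture(0.0), 50, 0.05, seed=2)
        summary = cs.self_closure_summary(cs.metrics_table(ensemble, topo))
        assert summary.closure_percentage == 0.0

    def test_two_inserted_hp_everywhere(self, regular_cd):
        conf, topo = regular_cd
        conf, topo = cs.place_hp(conf, topo, 1, "O6", "inserted", 1.5)
        conf, topo = cs.place_hp(conf, topo, 4, "O6", "inserted", 2.0)
        summary = cs.self_closure_summary(cs.metrics_table([conf] * 10, topo))
        assert summary.closure_percentage == 100.0
        assert summary.probability_by_n_inserted == {2: 100.0}

    def test_closure_plus_open_percentage_is_100(self):
        ensemble, topo, _ = cs.generate_ensemble(cs.closure_mixture(0.3), 400, 0.05, seed=5)
        summary = cs.self_closure_summary(cs.metrics_table(ensemble, topo))
        assert summary.closure_percentage + summary.probability_by_n_inserted.get(0, 0.0) == (
            pytest.approx(100.0)
        )

    def test_unsubstituted_cd_is_error(self, regular_cd):
        conf, topo = regular_cd
        with pytest.raises(cs.StatisticsError, match="self-closure undefined"):
            cs.self_closure_summary(cs.metrics_table([conf], topo))


class TestScalarStats:
    def test_identical_frames_have_zero_sd(self, regular_cd):
        conf, topo = regular_cd
        mean, sd = cs.circularity_stats(cs.metrics_table([conf] * 4, topo))
        assert sd == 0.0 and mean == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_two_values(self):
        table = pd.DataFrame({"circularity": [0.6, 0.8]})
        mean, sd = cs.circularity_stats(table)
        assert (mean, sd) == (pytest.approx(0.7), pytest.approx(0.1))

    def test_matches_two_pass_oracle(self, rng):
        c = rng.uniform(0.5, 1.0, 500)
        table = pd.DataFrame({"circularity": c})
        mean, sd = cs.circularity_stats(table)
        mu = sum(c) / len(c)
        var = sum((x - mu) ** 2 for x in c) / len(c)
        assert mean == pytest.approx(mu, rel=1e-12)
        assert sd == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_rg_distribution_constant_ensemble(self, regular_cd):
        conf, topo = regular_cd
        edges, prob, mean = cs.rg_distribution(cs.metrics_table([conf] * 6, topo))
        assert np.count_nonzero(prob) == 1
        assert mean == pytest.approx(cs.radius_of_gyration(conf, topo))

    def test_rg_mean_recovers_gaussian_center(self, rng):
        n, mu, sigma = 5000, 6.2, 0.1
        table = pd.DataFrame({"rg": rng.normal(mu, sigma, n)})
        _, prob, mean = cs.rg_distribution(table)
        assert prob.sum() == pytest.approx(1.0, abs=1e-12)
        assert abs(mean - mu) <= 3 * sigma / np.sqrt(n)


class TestTemperatureSweep:
    def _metrics(self, closure_fraction, seed):
        ensemble, topo, _ = cs.generate_ensemble(
            cs.closure_mixture(closure_fraction), 200, 0.05, seed=seed
        )
        return cs.metrics_table(ensemble, topo)

    def test_rows_sorted_by_temperature(self):
        sweep = cs.temperature_sweep(
            {400.0: self._metrics(0.2, 1), 300.0: self._metrics(0.5, 2)}
        )
        assert list(sweep["temperature_K"]) == [300.0, 400.0]

    def test_closure_column_tracks_built_fractions(self):
        metrics = {
            300.0: self._metrics(0.6, 3),
            400.0: self._metrics(0.4, 4),
            500.0: self._metrics(0.2, 5),
        }
        sweep = cs.temperature_sweep(metrics)
        closure = sweep["closure_pct"].to_numpy()
        assert np.all(np.diff(closure) < 0)

    def test_single_temperature_is_error(self):
        with pytest.raises(cs.StatisticsError):
            cs.temperature_sweep({300.0: self._metrics(0.2, 6)})


class TestSummarize:
    def test_summary_fields_and_consistency(self):
        ensemble, topo, _ = cs.generate_ensemble(cs.closure_mixture(0.3), 200, 0.05, seed=8)
        summary = cs.summarize(cs.metrics_table(ensemble, topo), temperature=300.0)
        assert summary["n_frames"] == 200
        assert sum(summary["flip_population_pct"].values()) == pytest.approx(100.0)
        closure = summary["self_closure"]
        assert sum(closure["probability_by_n_inserted_pct"].values()) == pytest.approx(100.0)

    def test_summary_without_hp_marks_closure_not_applicable(self, regular_cd):
        conf, topo = regular_cd
        summary = cs.summarize(cs.metrics_table([conf], topo))
        assert summary["self_closure"] is None
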