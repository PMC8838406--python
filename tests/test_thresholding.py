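import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    brute_force_otsu_single,
    direct_between_class_variance,
    random_histogram,
)
from vesselseg.errors import DegenerateHistogramError, ParameterError
from vesselseg.thresholding import (
    GrayHistogram,
    PSOConfig,
    apply_thresholds,
    between_class_variance,
    class_moments,
    histogram256,
    init_swarm,
    otsu_pso,
    otsu_single,
    pso_step,
    render_labels,
    repair_position,
)


def point_mass_histogram(levels_masses: dict[int, float]) -> GrayHistogram:
    p = np.zeros(256)
    for level, mass in levels_masses.items():
        p[level] = mass
    return GrayHistogram(probabilities=p / p.sum())


class TestHistogram256:
    def test_all_zeros_image_is_point_mass_at_zero(self):
        hist = histogram256(np.zeros((8, 8)))
        assert hist.probabilities[0] == 1.0
        assert hist.probabilities[1:].sum() == 0.0

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        hist = histogram256(rng.random((17, 23)))
        assert abs(hist.probabilities.sum() - 1.0) < 1e-12

    def test_hand_counted_four_pixel_image(self):
        image = np.array([[0.0, 0.0], [128 / 255, 1.0]])
        hist = histogram256(image)
        assert hist.probabilities[0] == 0.5
        assert hist.probabilities[128] == 0.25
        assert hist.probabilities[255] == 0.25

    def test_mask_restricts_counting(self):
        image = np.array([[0.0, 1.0], [1.0, 1.0]])
        mask = np.array([[True, False], [False, False]])
        hist = histogram256(image, mask)
        assert hist.probabilities[0] == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            histogram256(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))


class TestBetweenClassVariance:
    def test_two_point_masses_hand_computed(self):
        """w0=0.4 at 50, w1=0.6 at 200, t=100: u_T=140, sigma_B^2=5400."""
        hist = point_mass_histogram({50: 0.4, 200: 0.6})
        assert between_class_variance(hist, (100,)) == pytest.approx(5400.0)

    def test_single_bin_histogram_gives_zero_everywhere(self):
        hist = point_mass_histogram({77: 1.0})
        for t in ((10,), (76,), (77,), (10, 100, 200)):
            assert between_class_variance(hist, t) == 0.0

    def test_matches_direct_loop_oracle(self):
        rng = np.random.default_rng(1)
        p = random_histogram(rng)
        hist = GrayHistogram(probabilities=p)
        for thresholds in ((30,), (10, 128), (63, 127, 191)):
            assert between_class_variance(hist, thresholds) == pytest.approx(
                direct_between_class_variance(p, thresholds), rel=1e-12
            )

    def test_unordered_thresholds_rejected(self):
        hist = point_mass_histogram({50: 0.5, 200: 0.5})
        with pytest.raises(ParameterError):
            between_class_variance(hist, (100, 100, 150))
        with pytest.raises(ParameterError):
            between_class_variance(hist, (150, 100))

    def test_two_class_identities_for_all_thresholds(self):
        """w0+w1 = 1 and w0 u0 + w1 u1 = u_T for every t."""
        rng = np.random.default_rng(2)
        p = random_histogram(rng)
        hist = GrayHistogram(probabilities=p)
        u_t = float(np.arange(256) @ p)
        for t in range(255):
            w, u = class_moments(hist, (t,))
            assert abs(w.sum() - 1.0) < 1e-12
            assert abs(w @ u - u_t) < 1e-12

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_multiclass_identities_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        p = random_histogram(rng, sparse=bool(seed % 2))
        hist = GrayHistogram(probabilities=p)
        t = tuple(sorted(rng.choice(255, size=3, replace=False)))
        w, u = class_moments(hist, t)
        u_t = float(np.arange(256) @ p)
        assert abs(w.sum() - 1.0) < 1e-12
        assert abs(w @ u - u_t) < 1e-12


class TestOtsuSingle:
    def test_two_separated_point_masses_plateau_tie_rule(self):
        hist = point_mass_histogram({50: 0.5, 200: 0.5})
        # every t in [50, 199] is optimal; smallest wins
        assert otsu_single(hist) == 50

    def test_extreme_bins_tie_at_zero(self):
        hist = point_mass_histogram({0: 0.5, 255: 0.5})
        assert otsu_single(hist) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = random_histogram(rng, sparse=bool(seed % 2))
        hist = GrayHistogram(probabilities=p)
        t = otsu_single(hist)
        t_oracle, v_oracle = brute_force_otsu_single(p)
        assert t == t_oracle
        assert between_class_variance(hist, (t,)) == pytest.approx(
            v_oracle, rel=1e-12
        )

    def test_single_bin_histogram_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_single(point_mass_histogram({128: 1.0}))


class TestRepair:
    @given(st.lists(st.floats(-50.0, 320.0), min_size=1, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_repaired_positions_strictly_ordered_in_range(self, values):
        t = repair_position(np.array(values))
        assert all(0 <= v <= 254 for v in t)
        assert all(b > a for a, b in zip(t, t[1:]))

    def test_duplicates_bumped_upward(self):
        assert repair_position(np.array([100.2, 99.8, 100.1])) == (100, 101, 102)

    def test_top_overflow_pushed_down(self):
        assert repair_position(np.array([254.4, 254.2, 253.9])) == (252, 253, 254)


class TestPsoStep:
    @staticmethod
    def _fitness(hist):
        return lambda t: between_class_variance(hist, t)

    def test_null_dynamics_freezes_positions(self):
        hist = point_mass_histogram({50: 0.5, 200: 0.5})
        config = PSOConfig(
            population_size=5, inertia=0.0, accel=(0.0, 0.0), rng_seed=0,
            dimension=2,
        )
        state = init_swarm(config, self._fitness(hist))
        state.velocities[:] = 0.0
        stepped = pso_step(state, config, self._fitness(hist))
        assert np.array_equal(stepped.positions, state.positions)
        assert np.all(stepped.velocities == 0.0)

    def test_particle_at_gbest_with_zero_velocity_stays_put(self):
        hist = point_mass_histogram({50: 0.5, 200: 0.5})
        config = PSOConfig(population_size=3, rng_seed=1, dimension=2)
        state = init_swarm(config, self._fitness(hist))
        best = np.argmax(state.pbest_fitness)
        state.positions[best] = state.pbest_positions[best] = state.gbest_position
        state.velocities[best] = 0.0
        stepped = pso_step(state, config, self._fitness(hist))
        assert np.array_equal(stepped.positions[best], state.gbest_position)

    def test_pbest_and_gbest_monotone_over_iterations(self):
        rng = np.random.default_rng(3)
        hist = GrayHistogram(probabilities=random_histogram(rng))
        config = PSOConfig(population_size=10, rng_seed=3, dimension=3)
        fitness = self._fitness(hist)
        state = init_swarm(config, fitness)
        for _ in range(10):
            prev_pbest = state.pbest_fitness.copy()
            prev_gbest = state.gbest_fitness
            state = pso_step(state, config, fitness)
            assert (state.pbest_fitness >= prev_pbest).all()
            assert state.gbest_fitness >= prev_gbest
            assert state.gbest_fitness == state.pbest_fitness.max()


class TestOtsuPso:
    def test_m1_matches_single_threshold_optimum(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            hist = GrayHistogram(probabilities=random_histogram(rng))
            t = otsu_pso(hist, m=1, config=PSOConfig(rng_seed=seed))
            best = between_class_variance(hist, (otsu_single(hist),))
            attained = between_class_variance(hist, t)
            assert attained >= best * (1 - 1e-9)

    def test_deterministic_for_fixed_seed(self):
        from vesselseg.phantom import generate_histogram_fixture

        hist = generate_histogram_fixture(4, 8)
        config = PSOConfig(rng_seed=42)
        assert otsu_pso(hist, 3, config) == otsu_pso(hist, 3, config)

    def test_table_defaults(self):
        config = PSOConfig()
        assert (config.population_size, config.inertia) == (40, 0.5)
        assert config.accel == (2.0, 2.0)
        assert config.max_iterations == 20

    def test_infeasible_when_more_thresholds_than_bins(self):
        hist = point_mass_histogram({10: 0.5, 20: 0.5})
        with pytest.raises(DegenerateHistogramError):
            otsu_pso(hist, m=3)


class TestApplyThresholds:
    def test_single_threshold_splits_ramp(self):
        ramp = np.linspace(0.0, 1.0, 256).reshape(16, 16)
        labels = apply_thresholds(ramp, (127,))
        levels = np.floor(ramp * 255 + 1e-6)
        assert np.array_equal(labels == 1, levels > 127)

    def test_interval_membership(self):
        image = np.array([0.0, 100 / 255, 150 / 255, 1.0])
        assert apply_thresholds(image, (63, 127, 191)).tolist() == [0, 1, 2, 3]

    def test_rebinarizing_two_class_labeling_reproduces_split(self):
        rng = np.random.default_rng(4)
        image = rng.random((20, 20))
        labels = apply_thresholds(image, (127,))
        rendered = render_labels(labels, 1)
        t = otsu_single(histogram256(rendered))
        labels2 = apply_thresholds(rendered, (t,))
        assert np.array_equal(labels, labels2)

    def test_render_levels_equally_spaced(self):
        rendered = render_labels(np.array([0, 1, 2, 3]), 3)
        assert np.allclose(rendered * 255, [0, 85, 170, 255])
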