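import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopipe import cboa


class TestFragrance:
    def test_zero_exponent_gives_c(self):
        assert cboa.fragrance(7.3, 0.01, 0.0) == pytest.approx(0.01)

    def test_linear_case(self):
        assert cboa.fragrance(5.0, 0.01, 1.0) == pytest.approx(0.05)

    def test_square_root_absorption(self):
        assert cboa.fragrance(4.0, 0.01, 0.5) == pytest.approx(0.02)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            cboa.fragrance(-1.0, 0.01, 0.5)

    @given(st.floats(0.0, 100.0), st.floats(0.001, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_always_nonnegative(self, intensity, c, a):
        assert cboa.fragrance(intensity, c, a) >= 0.0


class TestSchedules:
    def test_a_endpoints(self):
        cfg = cboa.CBOAConfig(t_max=100, a_start=0.1, a_final=0.3, mu=1.0)
        assert cboa.update_a(0, cfg) == pytest.approx(0.1)
        assert cboa.update_a(100, cfg) == pytest.approx(0.3)

    def test_a_midpoint(self):
        cfg = cboa.CBOAConfig(t_max=100, a_start=0.1, a_final=0.3, mu=1.0)
        expected = 0.1 + 0.2 * np.sin(np.pi / 4)
        assert cboa.update_a(50, cfg) == pytest.approx(expected)
        assert cboa.update_a(50, cfg) == pytest.approx(0.2414, abs=1e-4)

    def test_a_out_of_range_rejected(self):
        cfg = cboa.CBOAConfig(t_max=10)
        with pytest.raises(ValueError):
            cboa.update_a(11, cfg)

    def test_sin2_schedule_keeps_endpoints(self):
        cfg = cboa.CBOAConfig(t_max=10, a_schedule="sin2")
        assert cboa.update_a(0, cfg) == pytest.approx(cfg.a_start)
        assert cboa.update_a(10, cfg) == pytest.approx(cfg.a_final)

    def test_c_update_value(self):
        assert cboa.update_c(0.01, 100) == pytest.approx(0.035)

    @given(st.floats(1e-4, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_c_strictly_increasing(self, c):
        assert cboa.update_c(c, 50) > c

    def test_c_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cboa.update_c(0.0, 10)


class TestMoves:
    bounds = ((-10.0, 10.0), (-10.0, 10.0))

    def test_at_gbest_no_move(self):
        b = cboa.Butterfly(x=np.array([1.0, 2.0]), fragrance=0.7)
        assert np.array_equal(
            cboa.global_move(b, np.array([1.0, 2.0]), 0.9, self.bounds), b.x)

    def test_zero_scalar_no_move(self):
        b = cboa.Butterfly(x=np.array([1.0, 2.0]), fragrance=0.7)
        assert np.array_equal(
            cboa.global_move(b, np.array([5.0, 5.0]), 0.0, self.bounds), b.x)

    def test_global_move_arithmetic(self):
        b = cboa.Butterfly(x=np.zeros(2), fragrance=1.0)
        got = cboa.global_move(b, np.ones(2), 0.5, self.bounds)
        assert np.allclose(got, [0.25, 0.25])

    def test_local_move_arithmetic(self):
        b = cboa.Butterfly(x=np.zeros(1), fragrance=1.0)
        got = cboa.local_move(b, np.array([2.0]), np.array([1.0]), 1.0,
                              ((-10.0, 10.0),))
        assert np.allclose(got, [1.0])

    def test_equal_peers_no_move(self):
        b = cboa.Butterfly(x=np.array([3.0]), fragrance=0.5)
        got = cboa.local_move(b, np.array([2.0]), np.array([2.0]), 0.8,
                              ((-10.0, 10.0),))
        assert np.array_equal(got, b.x)

    def test_moves_are_clipped(self):
        b = cboa.Butterfly(x=np.array([0.9]), fragrance=100.0)
        got = cboa.global_move(b, np.array([1.0]), 1.0, ((0.0, 1.0),))
        assert got[0] == 1.0


class TestLogisticMap:
    def test_fixed_points(self):
        assert cboa.logistic_map_next(0.0) == 0.0
        assert cboa.logistic_map_next(0.75) == pytest.approx(0.75)

    def test_direct_value(self):
        assert cboa.logistic_map_next(0.2) == pytest.approx(0.64)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cboa.logistic_map_next(1.2)

    def test_trajectory_is_non_degenerate(self):
        x = 0.7
        xs = np.empty(100_000)
        for i in range(xs.size):
            x = cboa.logistic_map_next(x)
            xs[i] = x
        hist, _ = np.histogram(xs, bins=20, range=(0, 1))
        assert (hist > 0).all()            # visits every bin
        assert hist.max() < 0.5 * xs.size  # no collapse to a point

    def test_fixed_point_seed_rejected_in_config(self):
        with pytest.raises(ValueError):
            cboa.CBOAConfig(chaos_x0=0.75)


class TestOptimize:
    @staticmethod
    def _bowl(target):
        return lambda x: float(((x - target) ** 2).sum())

    def test_converges_on_convex_bowl(self):
        target = np.array([0.3, -0.2])
        cfg = cboa.CBOAConfig(pop_size=20, t_max=50,
                              bounds=((-1.0, 1.0), (-1.0, 1.0)), rng_seed=0)
        result = cboa.optimize(self._bowl(target), cfg)
        assert result.best_fitness < 1e-2

    def test_best_so_far_trace_is_monotone(self):
        cfg = cboa.CBOAConfig(pop_size=8, t_max=30,
                              bounds=((-1.0, 1.0), (-1.0, 1.0)), rng_seed=1)
        result = cboa.optimize(self._bowl(np.zeros(2)), cfg)
        best = result.trace["best_fitness"].to_numpy()
        assert (np.diff(best) <= 0).all()

    def test_positions_respect_bounds(self):
        seen = []

        def objective(x):
            seen.append(x.copy())
            return float((x ** 2).sum())

        cfg = cboa.CBOAConfig(pop_size=5, t_max=10,
                              bounds=((-0.5, 0.5), (0.0, 2.0)), rng_seed=3)
        cboa.optimize(objective, cfg)
        arr = np.stack(seen)
        assert arr[:, 0].min() >= -0.5 and arr[:, 0].max() <= 0.5
        assert arr[:, 1].min() >= 0.0 and arr[:, 1].max() <= 2.0

    def test_random_and_chaotic_variants_differ(self):
        cfg = dict(pop_size=6, t_max=15, bounds=((-1.0, 1.0), (-1.0, 1.0)),
                   rng_seed=5)
        r1 = cboa.optimize(self._bowl(np.zeros(2)),
                           cboa.CBOAConfig(chaotic_map="none", **cfg))
        r2 = cboa.optimize(self._bowl(np.zeros(2)),
                           cboa.CBOAConfig(chaotic_map="logistic", **cfg))
        assert not np.array_equal(r1.best_x, r2.best_x)

    def test_constant_zero_map_freezes_population(self):
        cfg = cboa.CBOAConfig(pop_size=4, t_max=5, chaotic_map=lambda x: 0.0,
                              bounds=((-1.0, 1.0),), rng_seed=9)
        # replicate the seeded initial population
        gen = np.random.default_rng(9)
        init = [gen.uniform(-1.0, 1.0, size=1) for _ in range(4)]
        result = cboa.optimize(lambda x: float((x ** 2).sum()), cfg)
        finals = sorted(float(b.x[0]) for b in result.population)
        assert finals == sorted(float(x[0]) for x in init)

    def test_nonfinite_objective_is_reported(self):
        cfg = cboa.CBOAConfig(pop_size=3, t_max=5, bounds=((0.0, 1.0),),
                              rng_seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            cboa.optimize(lambda x: float("nan"), cfg)


class TestFitness:
    @staticmethod
    def _position():
        return np.array([-2.0, 64.0, 32.0, 10.0, -2.0])

    @staticmethod
    def _label_features(n):
        """Feature 0 encodes the label; feature 1 is the sample index."""
        gen = np.random.default_rng(0)
        y = np.arange(n) % 2
        x = np.column_stack([y.astype(float), np.arange(n, dtype=float),
                             gen.random(n)])
        return x, y

    def test_perfect_stub_gives_zero(self):
        x, y = self._label_features(30)
        res = cboa.fitness_error_rate(
            self._position(), x, y, k_folds=3,
            train_predict=lambda xtr, ytr, xte, cfg: xte[:, 0].astype(int))
        assert res.error_rate_percent == 0.0
        assert res.n_total == 30

    def test_four_of_ninety_misclassified(self):
        x, y = self._label_features(90)

        def stub(xtr, ytr, xte, cfg):
            pred = xte[:, 0].astype(int)
            flip = xte[:, 1] < 4          # exactly samples 0..3 overall
            return np.where(flip, 1 - pred, pred)

        res = cboa.fitness_error_rate(self._position(), x, y, k_folds=3,
                                      train_predict=stub)
        assert res.n_misclassified == 4
        assert res.error_rate_percent == pytest.approx(100 * 4 / 90)

    def test_all_wrong_stub_gives_hundred(self):
        x, y = self._label_features(30)
        res = cboa.fitness_error_rate(
            self._position(), x, y, k_folds=3,
            train_predict=lambda xtr, ytr, xte, cfg: 1 - xte[:, 0].astype(int))
        assert res.error_rate_percent == 100.0

    def test_out_of_bounds_position_rejected(self):
        x, y = self._label_features(20)
        with pytest.raises(ValueError):
            cboa.fitness_error_rate(np.array([0.0, 64.0, 32.0, 10.0, -2.0]),
                                    x, y, k_folds=2)

    def test_decode_round_trip(self):
        cfg = cboa.decode_position(self._position())
        assert cfg.layer_sizes == (64, 32)
        assert cfg.rbm_train.epsilon == pytest.approx(0.01)
        assert cfg.rbm_train.epochs == 10
        assert cfg.finetune_lr == pytest.approx(0.01)


class TestTuneDBN:
    @staticmethod
    def _nearest_centroid(xtr, ytr, xte, cfg):
        c0 = xtr[ytr == 0].mean(axis=0)
        c1 = xtr[ytr == 1].mean(axis=0)
        d0 = ((xte - c0) ** 2).sum(axis=1)
        d1 = ((xte - c1) ** 2).sum(axis=1)
        return (d1 < d0).astype(int)

    def test_returned_error_not_worse_than_initial_best(self,
                                                        separable_features):
        x, y = separable_features
        cfg = cboa.CBOAConfig(pop_size=6, t_max=5,
                              bounds=cboa.DEFAULT_HYPERPARAM_BOUNDS,
                              rng_seed=2)
        best_cfg, best_fit, trace = cboa.tune_dbn(
            x, y, config=cfg, k_folds=3, train_predict=self._nearest_centroid)
        assert best_fit.error_rate_percent <= trace["best_fitness"].iloc[0]
        for w, (lo, hi) in zip(best_cfg.layer_sizes,
                               cboa.DEFAULT_HYPERPARAM_BOUNDS[1:3]):
            assert lo - 0.5 <= w <= hi + 0.5

    def test_tuned_error_low_on_separable_features(self, separable_features):
        x, y = separable_features
        cfg = cboa.CBOAConfig(pop_size=6, t_max=5,
                              bounds=cboa.DEFAULT_HYPERPARAM_BOUNDS,
                              rng_seed=0)
        _, best_fit, _ = cboa.tune_dbn(x, y, config=cfg, k_folds=3)
        assert best_fit.error_rate_percent <= 10.0

    def test_single_class_rejected(self, separable_features):
        x, _ = separable_features
        with pytest.raises(ValueError):
            cboa.tune_dbn(x, np.zeros(len(x), dtype=int))


def test_config_yaml_round_trip(tmp_path):
    cfg = cboa.CBOAConfig(pop_size=7, t_max=9, bounds=((0.0, 2.0), (1.0, 3.0)))
    path = str(tmp_path / "cboa.yaml")
    cboa.config_to_yaml(cfg, path)
    assert cboa.config_from_yaml(path) == cfg
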