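"""Unit and property tests for the lattice bioturbation engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioturb import (
    ConfigurationError,
    ConsistencyError,
    DisplacementLedger,
    LatticeState,
    ModelParams,
    SimConfig,
    apply_ledger,
    draw_active_displacements,
    init_lattice,
    magnitude_second_moment,
    passive_rebalance,
    simulate,
    step,
)
from conftest import make_state, point_release_state, random_balanced_state


class TestInitLattice:
    @pytest.mark.parametrize(
        "d,w,d_lum,total_tracer",
        [
            (149, 2980, 20, 59_600),  # full experimental grid
            (5, 10, 0, 0),            # no tracer anywhere
            (3, 4, 3, 12),            # fully marked column
        ],
    )
    def test_initial_inventories(self, d, w, d_lum, total_tracer):
        state = init_lattice(SimConfig(d=d, w=w, d_lum=d_lum))
        assert state.total_tracer == total_tracer
        assert (state.totals == w).all()
        assert (state.tracer[:d_lum] == w).all()
        assert (state.nonmarked[d_lum:] == w).all()

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(d=0, w=5, d_lum=0), "d"),
            (dict(d=5, w=0, d_lum=0), "w"),
            (dict(d=5, w=5, d_lum=6), "d_lum"),
            (dict(d=5, w=5, d_lum=0, n_steps=-1), "n_steps"),
            (dict(d=5, w=5, d_lum=0, layer_height_mm=0.0), "layer_height"),
            (dict(d=5, w=5, d_lum=0, magnitude_dist="cauchy"), "magnitude_dist"),
        ],
    )
    def test_invalid_config_names_offending_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            SimConfig(**kwargs)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(activity=1.2, distance=1.0), "activity"),
            (dict(activity=0.5, distance=0.0), "distance"),
            (dict(activity=0.5, distance=1.0, downwards=-0.1), "downwards"),
            (dict(activity=0.5, distance=1.0, range_frac=0.0), "range_frac"),
            (dict(activity=0.5, distance=1.0, tracerdif=1.5), "tracerdif"),
        ],
    )
    def test_invalid_params_rejected(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            ModelParams(**kwargs)


class TestActiveDisplacement:
    def test_zero_activity_gives_empty_ledger(self, rng):
        state = make_state([5, 5, 5, 5], 10)
        params = ModelParams(activity=0.0, distance=2.0)
        ledger = draw_active_displacements(
            state, params, SimConfig(d=4, w=10, d_lum=1), rng
        )
        assert ledger.n_moved == 0
        assert (ledger.additions == 0).all()

    def test_deterministic_corner_moves_two_layers_down(self, rng):
        # one tracer in layer 1, certain displacement, fixed magnitude 2, down
        state = make_state([0, 1, 0, 0, 0], 8)
        params = ModelParams(activity=1.0, distance=2.0, downwards=1.0)
        config = SimConfig(d=5, w=8, d_lum=1, magnitude_dist="fixed")
        ledger = draw_active_displacements(state, params, config, rng)
        assert ledger.removals.tolist() == [0, 1, 0, 0, 0]
        assert ledger.additions.tolist() == [0, 0, 0, 1, 0]

    def test_displaced_count_matches_binomial_moments(self):
        # 20 tracers in one layer, activity 0.5 -> Binomial(20, 0.5)
        rng = np.random.default_rng(99)
        state = make_state([20, 0, 0, 0, 0], 20)
        params = ModelParams(activity=0.5, distance=1.0)
        config = SimConfig(d=5, w=20, d_lum=1)
        n, p, reps = 20, 0.5, 10_000
        draws = np.array([
            draw_active_displacements(state, params, config, rng).n_moved
            for _ in range(reps)
        ])
        se_mean = np.sqrt(n * p * (1 - p) / reps)
        assert abs(draws.mean() - n * p) < 3 * se_mean
        # variance of a binomial sample variance: compare loosely (10%)
        assert abs(draws.var() - n * p * (1 - p)) < 0.1 * n * p * (1 - p)

    def test_range_limits_origin_layers(self, rng):
        d, w = 10, 30
        state = make_state([15] * d, w)
        params = ModelParams(activity=1.0, distance=2.0, range_frac=0.5)
        config = SimConfig(d=d, w=w, d_lum=d)
        cutoff = round(0.5 * d)
        for _ in range(50):
            ledger = draw_active_displacements(state, params, config, rng)
            assert (ledger.removals[cutoff:] == 0).all()
            assert ledger.removals.sum() == ledger.additions.sum()

    def test_wall_boundary_keeps_targets_on_grid(self, rng):
        # huge mean displacement: everything clamps to the two walls
        state = make_state([10, 0, 0, 10], 10)
        params = ModelParams(activity=1.0, distance=50.0, downwards=0.5)
        config = SimConfig(d=4, w=10, d_lum=1)
        ledger = draw_active_displacements(state, params, config, rng)
        assert ledger.additions.sum() == ledger.removals.sum() == 20
        # nothing lost off-grid; everything still within layers [0, 3]
        assert (ledger.additions >= 0).all()


class TestApplyLedger:
    def test_empty_ledger_is_identity(self):
        state = make_state([3, 1, 4], 6)
        ledger = DisplacementLedger(np.zeros(3, np.int64), np.zeros(3, np.int64))
        out = apply_ledger(state, ledger)
        assert (out.tracer == state.tracer).all()
        assert (out.nonmarked == state.nonmarked).all()

    def test_conservation_arithmetic(self):
        state = make_state([5, 2, 0, 1, 0], 5)
        removals = np.array([3, 0, 0, 0, 0], np.int64)
        additions = np.array([0, 0, 0, 0, 3], np.int64)
        out = apply_ledger(state, DisplacementLedger(removals, additions))
        assert out.total_tracer == state.total_tracer
        assert out.totals[0] == 5 - 3
        assert out.totals[4] == 5 + 3

    def test_overdraw_raises_consistency_error(self):
        state = make_state([1, 0], 4)
        removals = np.array([2, 0], np.int64)
        additions = np.array([0, 2], np.int64)
        with pytest.raises(ConsistencyError):
            apply_ledger(state, DisplacementLedger(removals, additions))

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_ledgers_conserve_tracer(self, seed):
        rng = np.random.default_rng(seed)
        d, w = 6, 9
        state = random_balanced_state(rng, d, w)
        removals = rng.integers(0, state.tracer + 1)
        targets = rng.integers(0, d, size=int(removals.sum()))
        additions = np.bincount(targets, minlength=d).astype(np.int64)
        out = apply_ledger(state, DisplacementLedger(removals, additions))
        assert out.tracer.sum() == state.tracer.sum()
        assert (out.tracer >= 0).all()


class TestPassiveRebalance:
    def test_balanced_state_is_fixed_point(self, rng):
        state = make_state([4, 2, 7], 8)
        out = passive_rebalance(state, 0.9, rng)
        assert (out.tracer == state.tracer).all()
        assert (out.nonmarked == state.nonmarked).all()

    def test_bottom_surplus_restores_capacity(self, rng):
        # surplus of 3 at the bottom layer, deficits of 1 in each layer above
        tracer = np.array([0, 0, 0, 5], np.int64)
        nonmarked = np.array([5, 5, 5, 4], np.int64)  # totals 5,5,5,9; w = 6
        state = LatticeState(tracer, nonmarked, 6)
        out = passive_rebalance(state, 1.0, rng)
        assert (out.totals == 6).all()
        assert out.tracer.sum() == 5
        assert out.nonmarked.sum() == 4 * 6 - 5

    def test_surface_surplus_triggers_downward_pass(self, rng):
        tracer = np.array([9, 0, 0], np.int64)
        nonmarked = np.array([0, 3, 6], np.int64)  # totals 9, 3, 6; w = 6
        state = LatticeState(tracer, nonmarked, 6)
        out = passive_rebalance(state, 1.0, rng)
        assert (out.totals == 6).all()
        assert out.tracer.sum() == 9

    def test_global_mass_mismatch_raises(self, rng):
        state = LatticeState(np.array([5, 0], np.int64),
                             np.array([0, 0], np.int64), 4)
        with pytest.raises(ConsistencyError):
            passive_rebalance(state, 1.0, rng)

    @settings(max_examples=150, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_imbalances_restore_capacity_and_conserve(self, seed):
        rng = np.random.default_rng(seed)
        d, w = 7, 11
        # random composition with correct global mass but scrambled layer totals
        total = d * w
        tracer_total = int(rng.integers(0, total + 1))
        slots = np.zeros(total, np.int64)
        slots[:tracer_total] = 1
        rng.shuffle(slots)
        # random layer totals summing to d*w
        cuts = np.sort(rng.integers(0, total + 1, size=d - 1))
        sizes = np.diff(np.concatenate([[0], cuts, [total]]))
        tracer = np.array([slots[a:b].sum() for a, b in
                           zip(np.cumsum(np.concatenate([[0], sizes[:-1]])),
                               np.cumsum(sizes))], np.int64)
        nonmarked = sizes - tracer
        state = LatticeState(tracer, nonmarked.astype(np.int64), w)
        weight = float(rng.uniform(0.1, 1.0))
        out = passive_rebalance(state, weight, rng)
        assert (out.totals == w).all()
        assert out.tracer.sum() == tracer.sum()
        assert out.nonmarked.sum() == nonmarked.sum()
        assert (out.tracer >= 0).all() and (out.nonmarked >= 0).all()


class TestStepAndSimulate:
    def test_null_activity_is_fixed_point(self, rng, small_config):
        params = ModelParams(activity=0.0, distance=2.0)
        state = init_lattice(small_config)
        out = state
        for _ in range(5):
            out = step(out, params, small_config, rng)
        assert (out.tracer == state.tracer).all()

    @pytest.mark.parametrize("tracerdif", [1.0, 0.7])
    def test_step_conserves_and_restores_capacity(self, rng, tracerdif):
        config = SimConfig(d=9, w=15, d_lum=3)
        params = ModelParams(activity=0.8, distance=2.5, downwards=0.3,
                             range_frac=0.8, tracerdif=tracerdif)
        state = init_lattice(config)
        for _ in range(10):
            state = step(state, params, config, rng)
            assert (state.totals == config.w).all()
            assert state.total_tracer == 3 * 15

    def test_all_downward_accumulates_at_bottom_wall(self, rng):
        config = SimConfig(d=6, w=10, d_lum=2)
        params = ModelParams(activity=1.0, distance=3.0, downwards=1.0)
        state = init_lattice(config)
        for _ in range(60):
            state = step(state, params, config, rng)
        assert state.total_tracer == 20
        assert state.tracer[-1] > 0  # tracer reached, and stays on, the bottom

    def test_simulate_zero_steps_returns_initial_column(self, small_params):
        config = SimConfig(d=6, w=4, d_lum=2, n_steps=0)
        series = simulate(small_params, config)
        assert series.counts.shape == (6, 1)
        assert series.counts[:, 0].tolist() == [4, 4, 0, 0, 0, 0]

    def test_simulate_experiment_scale_shape_and_conservation(self):
        params = ModelParams(activity=0.674, distance=4.3, tracerdif=0.929)
        config = SimConfig(d=149, w=298, d_lum=20, n_steps=24, seed=5)
        series = simulate(params, config)
        assert series.counts.shape == (149, 25)
        assert (series.total_per_time() == 5_960).all()

    def test_simulate_seed_determinism(self, small_params):
        config = SimConfig(d=12, w=20, d_lum=3, n_steps=8, seed=42)
        a = simulate(small_params, config)
        b = simulate(small_params, config)
        assert (a.counts == b.counts).all()
        from dataclasses import replace
        c = simulate(small_params, replace(config, seed=43))
        assert (a.counts != c.counts).any()

    def test_custom_initial_state_shape_checked(self, small_params):
        config = SimConfig(d=12, w=20, d_lum=3, n_steps=2)
        with pytest.raises(ConfigurationError):
            simulate(small_params, config, initial=make_state([1, 2], 20))

    def test_depth_variance_grows_at_random_walk_rate(self):
        # dilute mid-column release, symmetric direction, neutral weighting:
        # variance growth per step = activity * E[m^2] before boundary contact
        d, w, n_tr, steps = 81, 300, 30, 6
        params = ModelParams(activity=0.4, distance=1.2, downwards=0.5,
                             range_frac=1.0, tracerdif=1.0)
        expected = params.activity * magnitude_second_moment("poisson", 1.2)
        init = point_release_state(d, w, 40, n_tr)
        growth = []
        for seed in range(200):
            cfg = SimConfig(d=d, w=w, d_lum=0, n_steps=steps, seed=seed)
            ser = simulate(params, cfg, initial=init)
            growth.append(
                (ser.depth_variance_layers(-1) - ser.depth_variance_layers(0)) / steps
            )
        assert np.mean(growth) == pytest.approx(expected, rel=0.10)


class TestMagnitudeDistributions:
    @pytest.mark.parametrize("name,mean", [
        ("poisson", 2.3), ("fixed", 2.3), ("geometric", 2.3),
    ])
    def test_sample_mean_and_second_moment(self, name, mean, rng):
        from bioturb import MAGNITUDE_DISTRIBUTIONS
        draws = MAGNITUDE_DISTRIBUTIONS[name](rng, mean, 200_000)
        assert (draws >= 0).all()
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert np.mean(draws.astype(float) ** 2) == pytest.approx(
            magnitude_second_moment(name, mean), rel=0.03
        )
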