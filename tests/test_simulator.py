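"""Step-wise attrition simulation and the random-segmentation null model."""

import numpy as np
import pytest

from fibresim import (
    SimConfig,
    WeakeningSchedule,
    attrition_step,
    load_config,
    mu_over_p_at_step,
    random_segmentation_step,
    run_attrition,
    run_random_segmentation,
)


class TestWeakeningSchedule:
    @pytest.mark.parametrize(
        "step, expected",
        [
            (1, 400.0),            # initial strength
            (2, 300.0),            # one 25% decay
            (9, 400.0 * 0.75**8),  # ~40.05, still above the floor
            (10, 40.0),            # geometric value ~30.0, clamped
            (50, 40.0),            # floor is held
        ],
    )
    def test_decay_with_floor(self, step, expected):
        assert mu_over_p_at_step(WeakeningSchedule(), step) == pytest.approx(expected)

    def test_non_increasing(self):
        sched = WeakeningSchedule(500.0, 0.9, 20.0)
        values = [mu_over_p_at_step(sched, k) for k in range(1, 40)]
        assert all(b <= a for a, b in zip(values[:-1], values[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mu_over_p_at_step(WeakeningSchedule(), 0)
        with pytest.raises(ValueError):
            WeakeningSchedule(decay_factor=1.0)
        with pytest.raises(ValueError):
            WeakeningSchedule(floor_mu_over_p=500.0, initial_mu_over_p=400.0)


class TestAttritionStep:
    def test_empty_population(self, rng):
        fwd, ret, counts = attrition_step([], 400.0, rng)
        assert fwd.size == 0 and ret.size == 0
        assert counts.broken == counts.passed == counts.retired == 0

    def test_all_short_fibres_retired(self, rng):
        lengths = [100.0, 500.0, 1599.0]  # all below 4 * 400
        fwd, ret, counts = attrition_step(lengths, 400.0, rng)
        assert fwd.size == 0
        assert sorted(ret) == sorted(lengths)
        assert counts.broken == 0 and counts.retired == 3

    def test_event_counts_partition_entering_fibres(self, rng):
        lengths = np.random.default_rng(0).uniform(100.0, 7000.0, 5000)
        fwd, ret, counts = attrition_step(lengths, 400.0, rng)
        assert counts.entering == lengths.size
        assert fwd.size == counts.passed + 2 * counts.broken
        assert ret.size == counts.retired

    def test_total_length_conserved(self, rng):
        lengths = np.random.default_rng(1).uniform(100.0, 7000.0, 5000)
        fwd, ret, _ = attrition_step(lengths, 400.0, rng)
        assert fwd.sum() + ret.sum() == pytest.approx(lengths.sum(), rel=1e-12)

    def test_fragments_at_least_mu_over_p(self, rng):
        mu = 300.0
        lengths = np.random.default_rng(2).uniform(4 * mu, 8000.0, 5000)
        fwd, _, counts = attrition_step(lengths, mu, rng)
        assert counts.broken > 0
        assert fwd.min() >= mu - 1e-9

    def test_break_frequency_matches_pfr_extent(self):
        # a fibre of length 8*(M_u/P) breaks with probability sqrt(1/2);
        # one vectorised step over 10^5 identical fibres = 10^5 trials
        mu = 400.0
        n = 100_000
        rng = np.random.default_rng(99)
        _, _, counts = attrition_step(np.full(n, 8 * mu), mu, rng)
        p = np.sqrt(0.5)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts.broken / n - p) < 3 * se

    def test_deterministic_given_rng_state(self):
        lengths = np.random.default_rng(3).uniform(100.0, 7000.0, 1000)
        a = attrition_step(lengths, 250.0, np.random.default_rng(42))
        b = attrition_step(lengths, 250.0, np.random.default_rng(42))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rejects_non_positive_lengths(self, rng):
        with pytest.raises(ValueError):
            attrition_step([100.0, -5.0], 400.0, rng)


class TestRunAttrition:
    def test_population_too_short_to_break_retires_in_one_step(self):
        lengths = np.full(200, 1000.0)  # all below 4*400 µm
        traj = run_attrition(lengths, config=SimConfig(min_active_to_continue=1, seed=0))
        assert traj.n_steps == 1
        assert traj.steps[0].counts.retired == 200
        assert traj.final_active_lengths.size == 0
        assert traj.stop_reason == "stop_rule"

    def test_stop_rule_before_first_step(self):
        traj = run_attrition([5000.0], config=SimConfig(min_active_to_continue=100))
        assert traj.n_steps == 0
        assert traj.stop_reason == "stop_rule"
        assert np.array_equal(traj.final_active_lengths, [5000.0])

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            run_attrition([])

    def test_full_run_postconditions(self, default_trajectory, default_population):
        traj = default_trajectory
        assert traj.stop_reason == "stop_rule"
        assert traj.n_steps < 500
        assert traj.final_active_lengths.size < 100
        total0 = default_population.total_length
        prev_retired = 0
        for rec in traj.steps:
            # conservation at every step
            total = rec.active_lengths.sum() + traj.retired_lengths_after(rec.step_index).sum()
            assert abs(total - total0) / total0 <= 1e-9
            # every forwarded fibre (fragment or passed) is >= current strength
            assert rec.active_lengths.min() >= rec.mu_over_p - 1e-9
            # retired pool only grows, event counts partition entrants
            assert rec.total_retired >= prev_retired
            assert rec.counts.entering == (
                traj.steps[rec.step_index - 2].active_lengths.size
                if rec.step_index > 1
                else traj.initial_lengths.size
            )
            prev_retired = rec.total_retired

    def test_bit_identical_trajectory_for_same_seed(self):
        lengths = np.random.default_rng(8).uniform(500.0, 7000.0, 2000)
        cfg = SimConfig(seed=77)
        a = run_attrition(lengths, config=cfg).to_json()
        b = run_attrition(lengths, config=cfg).to_json()
        assert a == b
        c = run_attrition(lengths, config=SimConfig(seed=78)).to_json()
        assert a != c


class TestRandomSegmentation:
    def test_single_split_conserves_length(self, rng):
        out = random_segmentation_step([5000.0], rng)
        assert out.size == 2
        assert out.sum() == pytest.approx(5000.0)
        assert np.all(out > 0)

    def test_empty_input(self, rng):
        assert random_segmentation_step([], rng).size == 0

    def test_count_doubles_and_mean_halves(self):
        lengths = np.random.default_rng(4).uniform(3000.0, 7000.0, 250)
        traj = run_random_segmentation(lengths, n_steps=8, seed=5)
        mean0 = lengths.mean()
        for k, rec in enumerate(traj.steps, start=1):
            assert rec.active_lengths.size == 250 * 2**k
            assert rec.active_lengths.mean() == pytest.approx(mean0 / 2**k, rel=1e-9)

    def test_zero_steps_is_snapshot_only(self):
        traj = run_random_segmentation([1000.0, 2000.0], n_steps=0, seed=0)
        assert traj.n_steps == 0
        assert np.array_equal(traj.final_active_lengths, [1000.0, 2000.0])

    def test_refuses_unrepresentable_runs(self):
        with pytest.raises(ValueError, match="reduce n_steps"):
            run_random_segmentation(np.full(10_000, 5000.0), n_steps=67)


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(
            "initial_mu_over_p: 350\ndecay_factor: 0.8\nfloor_mu_over_p: 35\n"
            "min_active_to_continue: 50\nmax_steps: 200\nseed: 9\n"
        )
        schedule, config = load_config(path)
        assert schedule == WeakeningSchedule(350, 0.8, 35)
        assert config == SimConfig(50, 200, 9)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("initial_mu_over_p: 350\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            load_config(path)
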