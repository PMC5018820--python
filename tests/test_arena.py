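import math

import numpy as np
import pytest

from reciprobots.arena import (
    ArenaConfig,
    ConfigurationError,
    WorldState,
    run_evaluation,
    sense_camera,
    sense_proximity,
    simulate_stuck_episodes,
    step,
)

DIAM = 0.07


def make_world(config=None, pos=((0.2, 0.5), (0.8, 0.5)), heading=(0.0, 0.0),
               food=((0.5, 0.9), (0.5, 0.1)), stuck=(False, False), seed=0):
    return WorldState.create(
        config or ArenaConfig(), seed, pos=np.array(pos, float),
        heading=np.array(heading, float), food=np.array(food, float), stuck=stuck,
    )


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            ArenaConfig(p_stuck=1.5)
        with pytest.raises(ConfigurationError):
            ArenaConfig(robot_diameter=-1)
        with pytest.raises(ConfigurationError):
            ArenaConfig(p_self_release=0.5, help_multiplier=5)  # helped prob > 1


class TestStep:
    def test_food_count_conserved_and_motionless_robots_never_eat(self):
        w = make_world()
        for _ in range(200):
            w, _ = step(w, np.zeros((2, 2)), p_stuck=(0, 0))
            assert w.food.shape == (2, 2)
        assert tuple(w.food_counts) == (0, 0)

    def test_straight_drive_and_torus_wrap(self):
        cfg = ArenaConfig(p_stuck=0.0)
        w = make_world(cfg, pos=((0.99, 0.5), (0.5, 0.9)), food=((0.1, 0.1), (0.2, 0.1)))
        v = np.array([[8.2, 8.2], [0.0, 0.0]])
        w, _ = step(w, v)
        # 8.2 cm/s * 0.1 s = 0.0082 m forward, wrapped around the torus edge
        assert w.pos[0, 0] == pytest.approx((0.99 + 0.0082) % 1.0, abs=1e-12)
        assert w.pos[0, 1] == pytest.approx(0.5)
        assert w.heading[0] == pytest.approx(0.0)

    def test_differential_drive_turns(self):
        cfg = ArenaConfig(p_stuck=0.0)
        w = make_world(cfg)
        w, _ = step(w, np.array([[-8.2, 8.2], [0.0, 0.0]]))
        # pure rotation: omega = (vr - vl)/axle = 16.4 cm/s / 7 cm
        assert w.pos[0] == pytest.approx([0.2, 0.5], abs=1e-12)
        assert w.heading[0] == pytest.approx(0.164 / 0.07 * 0.1)

    def test_stuck_robots_do_not_move(self):
        w = make_world(stuck=(True, False))
        p0 = w.pos[0].copy()
        for _ in range(50):
            w, _ = step(w, np.full((2, 2), 8.2), p_stuck=(0, 0))
        assert np.array_equal(w.pos[0], p0)

    def test_collision_resolution_never_overlaps(self):
        cfg = ArenaConfig(p_stuck=0.0)
        w = make_world(cfg, pos=((0.5, 0.5), (0.5 + DIAM + 0.002, 0.5)),
                       heading=(0.0, math.pi))
        for _ in range(100):
            w, _ = step(w, np.full((2, 2), 8.2))  # drive into each other
            dx = w.pos[1] - w.pos[0]
            dx -= np.round(dx)
            assert np.hypot(*dx) >= DIAM - 1e-9

    def test_eating_increments_and_respawns(self):
        cfg = ArenaConfig(p_stuck=0.0)
        w = make_world(cfg, pos=((0.5, 0.5), (0.9, 0.9)),
                       food=((0.56, 0.5), (0.1, 0.1)))
        w, _ = step(w, np.array([[8.2, 8.2], [0.0, 0.0]]))
        assert w.food_counts[0] == 1
        assert not np.array_equal(w.food[0], [0.56, 0.5])  # respawned elsewhere

    def test_release_hazard_ratio_is_help_multiplier(self):
        cfg = ArenaConfig()
        far = simulate_stuck_episodes(4000, cfg, 11, partner_adjacent=False)
        near = simulate_stuck_episodes(4000, cfg, 12, partner_adjacent=True)
        ratio = far.mean() / near.mean()
        # geometric means 2000 and 400; 3 SE on the ratio ~ 0.34 at n=4000
        se = 5.0 * math.sqrt(2.0 / 4000)
        assert abs(ratio - cfg.help_multiplier) < 3 * se

    def test_helped_release_attributed_to_partner(self):
        cfg = ArenaConfig(p_self_release=0.2, help_multiplier=5.0)
        w = make_world(cfg, pos=((0.5, 0.5), (0.5 + DIAM + 0.005, 0.5)),
                       stuck=(True, False))
        released = False
        for _ in range(500):
            w, ev = step(w, np.zeros((2, 2)), p_stuck=(0, 0))
            if ev.released[0]:
                released = True
                assert ev.helped[0]
                break
        assert released
        assert w.helping_given[1] == 1
        assert w.memory_state(0).helps == 1
        assert w.memory_state(0).opportunities == 1


class TestProximity:
    def test_partner_out_of_range_all_zero(self):
        w = make_world(pos=((0.2, 0.5), (0.8, 0.5)))
        assert sense_proximity(w, 0) == pytest.approx(np.zeros(8))

    def test_contact_ahead_saturates_front_sensor(self):
        w = make_world(pos=((0.5, 0.5), (0.5 + DIAM, 0.5)))
        act = sense_proximity(w, 0)
        assert act[0] == pytest.approx(1.0)
        assert act[1:] == pytest.approx(np.zeros(7))

    def test_rear_sensor_faces_backwards(self):
        w = make_world(pos=((0.5, 0.5), (0.5 - DIAM - 0.01, 0.5)))
        act = sense_proximity(w, 0)
        assert act[4] > 0  # sensor 4 faces heading + 180 degrees
        assert act[[0, 1, 2, 3, 5, 6, 7]] == pytest.approx(np.zeros(7))

    def test_activation_non_increasing_with_gap(self):
        acts = []
        for gap in np.linspace(0.0, 0.06, 25):
            w = make_world(pos=((0.5, 0.5), (0.5 + DIAM + gap, 0.5)))
            acts.append(sense_proximity(w, 0)[0])
        assert all(b <= a + 1e-12 for a, b in zip(acts, acts[1:]))
        assert acts[0] == pytest.approx(1.0) and acts[-1] == 0.0

    def test_invisible_partner_gives_empty_world_reading(self):
        w = make_world(pos=((0.5, 0.5), (0.5 + DIAM, 0.5)))
        assert sense_proximity(w, 0, include_partner=False) == pytest.approx(np.zeros(8))


class TestCamera:
    far_food = ((0.5, 0.05), (0.4, 0.05))  # behind the focal robot at (.5,.5)->+x

    def test_empty_cone_all_zero(self):
        w = make_world(pos=((0.5, 0.5), (0.3, 0.5)), food=self.far_food)
        act = sense_camera(w, 0, include_partner=False)
        assert act == pytest.approx(np.zeros(9))

    def test_mobile_partner_fills_central_green(self):
        w = make_world(pos=((0.5, 0.5), (0.65, 0.5)), food=self.far_food)
        act = sense_camera(w, 0)
        # half-width asin(0.035/0.15) ~ 13.5 deg covers the central 20 deg sector
        assert act[1 * 3 + 1] == pytest.approx(1.0)  # central green
        assert act[2 * 3 + 1] == 0.0  # central blue

    def test_stuck_partner_renders_blue(self):
        w = make_world(pos=((0.5, 0.5), (0.65, 0.5)), food=self.far_food,
                       stuck=(False, True))
        act = sense_camera(w, 0)
        assert act[2 * 3 + 1] == pytest.approx(1.0)
        assert act[1 * 3 + 1] == 0.0

    def test_food_renders_red_proportionally(self):
        w = make_world(pos=((0.5, 0.5), (0.5, 0.95)), food=((0.7, 0.5), (0.1, 0.9)))
        act = sense_camera(w, 0, include_partner=False)
        half = math.degrees(math.asin(0.027 / 0.2))  # ~7.76 deg of the 20 deg sector
        assert act[0 * 3 + 1] == pytest.approx(2 * half / 20.0, rel=1e-6)
        assert act[[3, 4, 5, 6, 7, 8]] == pytest.approx(np.zeros(6))

    def test_nearer_object_occludes(self):
        # food directly behind the partner: the partner hides it entirely
        w = make_world(pos=((0.5, 0.5), (0.62, 0.5)), food=((0.75, 0.5), (0.1, 0.9)))
        act = sense_camera(w, 0)
        assert act[0 * 3 + 1] == 0.0  # central red fully occluded
        assert act[1 * 3 + 1] == pytest.approx(1.0)

    def test_coverage_never_exceeds_sector(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            w = make_world(pos=rng.random((2, 2)), heading=rng.random(2) * 6.28,
                           food=rng.random((2, 2)))
            act = sense_camera(w, 0)
            assert (act >= 0).all() and (act <= 1 + 1e-12).all()


class TestRunEvaluation:
    def test_motionless_pair_scores_nothing(self, motionless_genome, topology):
        cfg = ArenaConfig(p_stuck=0.0, eval_steps=1000)
        res = run_evaluation((motionless_genome, motionless_genome), topology, cfg, seed=2)
        # food may only be eaten by moving over it; a motionless pair can
        # score only if food spawns beneath a robot, excluded by this seed
        assert res.food_counts == (0, 0)
        assert res.helping_given == (0, 0)

    def test_fixed_seed_bit_identical(self, random_genome_182, topology, short_arena):
        a = run_evaluation((random_genome_182, random_genome_182), topology,
                           short_arena, seed=99, record_trajectory=True)
        b = run_evaluation((random_genome_182, random_genome_182), topology,
                           short_arena, seed=99, record_trajectory=True)
        assert a.food_counts == b.food_counts
        assert a.stuck_episodes == b.stuck_episodes
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_stuck_onset_rate_matches_binomial(self, motionless_genome, topology):
        # instant release (p_rel = 1) keeps robots mobile: onsets ~ Bin(T, p)
        cfg = ArenaConfig(p_stuck=5e-3, p_self_release=0.2, help_multiplier=1.0,
                          eval_steps=2000)
        onsets = []
        for s in range(100):
            res = run_evaluation((motionless_genome, motionless_genome), topology,
                                 cfg, seed=s)
            for r in range(2):
                n = len(res.stuck_episodes[r]) + (res.censored[r] is not None)
                onsets.append(n)
        # renewal argument: onset every 1/p mobile steps + 1/p_rel stuck steps
        expected = cfg.eval_steps / (1 / cfg.p_stuck + 1 / cfg.p_self_release)
        se = math.sqrt(expected / len(onsets))
        assert abs(np.mean(onsets) - expected) < 3 * se + 1.0

    def test_memory_counters_match_episode_log(self, random_genome_182, topology,
                                               short_arena):
        res = run_evaluation((random_genome_182, random_genome_182), topology,
                             short_arena, seed=5)
        for r in range(2):
            helped = sum(1 for *_ , h in res.stuck_episodes[r] if h)
            assert res.memory[r].opportunities == len(res.stuck_episodes[r])
            assert res.memory[r].helps == helped
            assert res.helping_given[1 - r] == helped
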