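"""Generator contracts: walk statistics, killing kinetics, rendering, seeding."""

import numpy as np
import pytest

from nk3d.errors import InvalidConfigError
from nk3d.killing import CUBIC_100UM_VOLUME_UM3
from nk3d.synthetic_data import (SceneConfig, render_stack, simulate_killing,
                                 simulate_trajectories)

BIG_BOX = dict(volume=1.0e11, depth=1000.0)  # 10 x 10 mm: walls out of reach


def test_ballistic_limit_straight_lines():
    cfg = SceneConfig(n_nk=20, motile_fraction=1.0, persistence_true=1.0,
                      jitter_sigma=0.0, seed=3, **BIG_BOX)
    truth = simulate_trajectories(cfg)
    steps = np.diff(truth.positions[:, :, :2], axis=1)
    # every motile trajectory is a straight line: all steps of a cell equal
    assert np.allclose(steps, steps[:, :1, :])
    headings = np.arctan2(steps[..., 1], steps[..., 0])
    assert np.cos(np.diff(headings, axis=1)).mean() == 1.0


def test_stationary_population_never_displaces():
    cfg = SceneConfig(n_nk=50, motile_fraction=0.0, jitter_sigma=0.3, seed=4,
                      **BIG_BOX)
    truth = simulate_trajectories(cfg)
    assert truth.config.n_frames == 11
    disp = np.linalg.norm(
        truth.positions - truth.positions[:, :1, :], axis=2)
    assert disp.max() < 13.0


def test_turning_angle_cosine_matches_persistence():
    """Monte-Carlo oracle: mean cosine over all steps ~ persistence_true."""
    p = 0.7
    cfg = SceneConfig(n_nk=1000, motile_fraction=1.0, persistence_true=p,
                      jitter_sigma=0.0, duration=100 * 30.0 / 3600.0,
                      seed=5, **BIG_BOX)
    truth = simulate_trajectories(cfg)
    steps = np.diff(truth.positions[:, :, :2], axis=1)
    headings = np.arctan2(steps[..., 1], steps[..., 0])
    mean_cos = float(np.cos(np.diff(headings, axis=1)).mean())
    assert abs(mean_cos - p) < 0.02


def test_motile_flags_binomial(seeded=11):
    cfg = SceneConfig(n_nk=10_000, motile_fraction=0.292, seed=seeded, **BIG_BOX)
    truth = simulate_trajectories(cfg)
    frac = truth.motile.mean()
    half = 1.96 * np.sqrt(0.292 * 0.708 / 10_000)
    assert abs(frac - 0.292) < half * 1.5  # binomial 95% CI with slack


def test_positions_stay_in_volume():
    cfg = SceneConfig(n_nk=100, motile_fraction=1.0, speed_mean=20.0,
                      persistence_true=0.2, seed=6,
                      volume=50.0 ** 2 * 50.0, depth=50.0)
    truth = simulate_trajectories(cfg)
    Lx, Ly, Lz = cfg.box
    assert truth.positions[:, :, 0].min() >= 0 and truth.positions[:, :, 0].max() <= Lx
    assert truth.positions[:, :, 1].min() >= 0 and truth.positions[:, :, 1].max() <= Ly
    assert truth.positions[:, :, 2].min() >= 0 and truth.positions[:, :, 2].max() <= Lz


def test_reproducibility_bit_exact():
    cfg = SceneConfig(n_nk=10, n_k562=3, seed=42, volume=200.0 ** 2 * 60, depth=60.0)
    t1 = simulate_trajectories(cfg)
    t2 = simulate_trajectories(cfg)
    assert np.array_equal(t1.positions, t2.positions)
    assert np.array_equal(t1.motile, t2.motile)
    s1 = render_stack(t1, noise_sigma=5.0)
    s2 = render_stack(t2, noise_sigma=5.0)
    assert np.array_equal(s1.data, s2.data)


def test_invalid_config_rejected():
    with pytest.raises(InvalidConfigError):
        SceneConfig(frame_interval=0.0)
    with pytest.raises(InvalidConfigError):
        SceneConfig(duration=-1.0)
    with pytest.raises(InvalidConfigError):
        SceneConfig(motile_fraction=1.5)


class TestKillingSimulation:
    def test_no_reaction_when_k_zero(self):
        cfg = SceneConfig.cytotoxicity_assay(k_true=0.0, seed=1,
                                             frame_interval=60.0)
        exp = simulate_killing(cfg, mode="stochastic")
        assert np.all(exp.live_targets == cfg.n_k562)
        assert exp.kill_event_times_h.size == 0

    def test_deterministic_half_life(self):
        """k * [NK_motile] * T = ln 2 leaves exactly half the targets."""
        cfg = SceneConfig(n_nk=1000, n_k562=64, motile_fraction=0.5,
                          volume=1.0e9, duration=10.0, frame_interval=3600.0,
                          k_true=float(np.log(2)) / (500 / 1000.0 * 10.0),
                          seed=0)
        exp = simulate_killing(cfg, mode="deterministic")
        assert exp.live_targets[-1] == pytest.approx(32.0, rel=1e-12)

    def test_stochastic_mean_matches_deterministic(self):
        """Monte-Carlo vs closed form: 100 seeds, 3 standard errors."""
        base = dict(n_nk=2000, n_k562=500, motile_fraction=0.3, volume=5.0e9,
                    duration=15.0, frame_interval=1800.0, k_true=0.5)
        det = simulate_killing(SceneConfig(seed=0, **base), "deterministic")
        finals = np.array([
            simulate_killing(SceneConfig(seed=s, **base), "stochastic")
            .live_targets[-1]
            for s in range(100)
        ])
        se = finals.std(ddof=1) / 10.0
        assert abs(finals.mean() - det.live_targets[-1]) < 3 * se

    def test_conservation_and_monotonicity(self):
        cfg = SceneConfig.cytotoxicity_assay(seed=9, frame_interval=600.0,
                                             n_nk=300, n_k562=60)
        exp = simulate_killing(cfg, mode="stochastic")
        assert np.all(exp.live_targets + exp.dead_targets == cfg.n_k562)
        assert np.all(np.diff(exp.live_targets) <= 0)

    def test_dt_exceeding_duration_rejected(self):
        cfg = SceneConfig.cytotoxicity_assay(duration=0.1, frame_interval=3600.0)
        with pytest.raises(InvalidConfigError):
            simulate_killing(cfg, mode="stochastic")

    def test_death_times_only_on_k562(self):
        cfg = SceneConfig(n_nk=50, n_k562=20, motile_fraction=0.5, k_true=50.0,
                          volume=1.0e8, duration=15.0, frame_interval=1800.0,
                          seed=2, depth=100.0)
        truth = simulate_trajectories(cfg)
        has_death = np.isfinite(truth.death_time_h)
        assert not np.any(has_death & (truth.cell_class == "NK"))
        assert np.any(has_death[truth.cell_class == "K562"])


class TestRendering:
    def test_empty_scene_is_background(self):
        cfg = SceneConfig(n_nk=0, seed=0, volume=100.0 ** 2 * 40, depth=40.0)
        truth = simulate_trajectories(cfg)
        stack = render_stack(truth, background=500.0, noise_sigma=0.0)
        assert np.all(stack.data == 500.0)

    def test_single_cell_darkest_at_position(self):
        cfg = SceneConfig(n_nk=1, motile_fraction=0.0, jitter_sigma=0.0,
                          seed=13, volume=150.0 ** 2 * 60, depth=60.0)
        truth = simulate_trajectories(cfg)
        stack = render_stack(truth, noise_sigma=0.0)
        x, y, z = truth.positions[0, 0]
        zi, yi, xi = np.unravel_index(np.argmin(stack.data[0]),
                                      stack.data[0].shape)
        assert abs(xi * stack.pixel_size - x) <= 1.0
        assert abs(yi * stack.pixel_size - y) <= 1.0
        assert abs(zi * stack.z_step - z) <= stack.z_step

    def test_pixel_size_too_coarse_rejected(self):
        cfg = SceneConfig(n_nk=1, seed=0, volume=100.0 ** 2 * 40, depth=40.0)
        truth = simulate_trajectories(cfg)
        with pytest.raises(InvalidConfigError):
            render_stack(truth, pixel_size=5.0)


def test_cytotoxicity_preset_matches_reported_concentrations():
    """600k NK + 120k targets in 2.5 ml: 0.24 and 0.048 cells per 10^6 µm^3."""
    cfg = SceneConfig.cytotoxicity_assay()
    vol_units = cfg.volume / CUBIC_100UM_VOLUME_UM3
    assert cfg.n_nk / vol_units == pytest.approx(0.24, rel=0.01)
    assert cfg.n_k562 / vol_units == pytest.approx(0.048, rel=0.01)
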