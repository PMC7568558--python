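"""Ground-truthed synthetic scenes for the 3-D migration/cytotoxicity assays.

The generator emulates the two imaging assays the pipeline analyses:

* **Motility assay** — NK cells suspended in a ~1 mm deep collagen gel and
  z-scanned every 30 s for 5 min.  A binomially sampled motile
  subpopulation performs a persistent random walk in the imaging plane
  (fixed-length steps, wrapped-normal turning angles); the rest only
  jitters around an anchor point.

* **Cytotoxicity assay** — NK cells mixed with K562 target cells and imaged
  at two frames per minute for 15 h.  Live targets wiggle with a 1–2 µm
  amplitude and die at a first-order rate proportional to the motile-NK
  concentration; dead targets stop wiggling, lose bright-field contrast and
  become elongated.

Scenes can be rendered into bright-field-like z-stacks (dark Gaussian
blobs on a bright noisy background) so the whole detection → tracking →
metrics chain can be exercised against known ground truth.

All randomness derives from a single root seed through spawned NumPy
``SeedSequence`` streams, so identical configurations produce bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .killing import CUBIC_100UM_VOLUME_UM3, KillingExperiment
from .projection import ImageStack

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "simulate_trajectories",
    "simulate_killing",
    "render_stack",
]

# Rendered cell appearance.  NK cells sit comfortably inside the 4–14 µm
# detection class; K562 targets are rendered at 18 µm so they stay above the
# 14 µm class boundary even after the dead-cell contrast loss shrinks their
# thresholded footprint.
NK_DIAMETER_UM = 9.0
K562_DIAMETER_UM = 18.0
DIP_FRACTION = 0.6          # blob depth as a fraction of background
DEAD_CONTRAST_LOSS = 0.3    # dead K562 lose 30% of their dip amplitude
DEAD_AXIS_RATIO = 1.5       # dead K562 elongation (major/minor sigma)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one simulated field of view.

    Units: speeds in µm/min, lengths in µm, ``volume`` in µm^3, ``duration``
    in hours, ``frame_interval`` in seconds, ``k_true`` in
    (10^6 µm^3/cell)/h.  ``wiggle_amplitude`` is the RMS frame-to-frame
    planar displacement of a live K562 cell.
    """

    n_nk: int = 80
    n_k562: int = 0
    motile_fraction: float = 0.292
    speed_mean: float = 6.0
    persistence_true: float = 0.85
    jitter_sigma: float = 0.3
    wiggle_amplitude: float = 1.5
    k_true: float = 0.5
    volume: float = 1.3225e9          # 1.15 x 1.15 mm FOV x 1 mm depth
    depth: float = 1000.0             # gel depth in µm; lateral box from volume
    duration: float = 5.0 / 60.0
    frame_interval: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nk < 0 or self.n_k562 < 0:
            raise InvalidConfigError("cell counts must be >= 0")
        if not 0.0 <= self.motile_fraction <= 1.0:
            raise InvalidConfigError("motile_fraction must be in [0, 1]")
        if self.volume <= 0 or self.depth <= 0:
            raise InvalidConfigError("volume and depth must be > 0")
        if self.duration <= 0:
            raise InvalidConfigError("duration must be > 0")
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be > 0")
        if self.k_true < 0:
            raise InvalidConfigError("k_true must be >= 0")
        if not 0.0 <= self.persistence_true <= 1.0:
            raise InvalidConfigError("persistence_true must be in [0, 1]")

    @property
    def box(self) -> tuple[float, float, float]:
        """(Lx, Ly, Lz) of the simulated volume in µm."""
        side = math.sqrt(self.volume / self.depth)
        return (side, side, self.depth)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * 3600.0 / self.frame_interval)) + 1

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of the root seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))

    @classmethod
    def motility_assay(cls, **overrides) -> "SceneConfig":
        """Defaults emulating the migration assay: ~80 NK cells per FOV,
        30 s z-scans for 5 min."""
        return cls(**overrides)

    @classmethod
    def cytotoxicity_assay(cls, **overrides) -> "SceneConfig":
        """Defaults emulating the killing assay: NK and K562 at 5:1 in the
        same FOV volume, two frames per minute for 15 h.

        Counts correspond to 600,000 NK + 120,000 K562 cells in 2.5 ml,
        i.e. 0.24 NK and 0.048 K562 per 10^6 µm^3.
        """
        base = dict(
            n_nk=317, n_k562=63, duration=15.0, frame_interval=30.0,
            k_true=0.5,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Known per-cell state of a simulated scene.

    ``positions`` has shape (n_cells, n_frames, 3) in µm; ``death_time_h``
    is NaN for cells that never die (always for NK cells).
    """

    config: SceneConfig
    cell_class: np.ndarray       # '<U4': 'NK' or 'K562'
    motile: np.ndarray           # bool, False for K562
    positions: np.ndarray
    death_time_h: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.config.times_s

    def alive_at(self, frame: int) -> np.ndarray:
        """Boolean mask of cells alive at a frame (NK cells are always alive)."""
        t_h = self.times_s[frame] / 3600.0
        return ~(self.death_time_h <= t_h)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per cell per frame."""
        n, T = self.positions.shape[:2]
        t_s = np.tile(self.times_s, n)
        frames = np.tile(np.arange(T), n)
        ids = np.repeat(np.arange(n), T)
        alive = ~(np.repeat(self.death_time_h, T) <= t_s / 3600.0)
        return pd.DataFrame({
            "cell_id": ids,
            "class": np.repeat(self.cell_class, T),
            "frame": frames,
            "t_s": t_s,
            "x_um": self.positions[:, :, 0].ravel(),
            "y_um": self.positions[:, :, 1].ravel(),
            "z_um": self.positions[:, :, 2].ravel(),
            "motile": np.repeat(self.motile, T),
            "alive": alive,
        })


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by mirror reflection at the faces."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


def _persistent_walk(rng: np.random.Generator, n: int, n_steps: int,
                     step_len: float, persistence: float) -> np.ndarray:
    """Planar correlated random walk displacements, shape (n, n_steps, 2).

    Fixed step length; turning angles are wrapped-normal with mean cosine
    equal to ``persistence`` (sigma = sqrt(-2 ln p), exact for the wrapped
    normal).  persistence 0 means uniformly random headings, 1 is ballistic.
    """
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=(n, 1))
    if persistence >= 1.0:
        turns = np.zeros((n, max(n_steps - 1, 0)))
    elif persistence <= 0.0:
        turns = rng.uniform(-np.pi, np.pi, size=(n, max(n_steps - 1, 0)))
    else:
        sigma = math.sqrt(-2.0 * math.log(persistence))
        turns = rng.normal(0.0, sigma, size=(n, max(n_steps - 1, 0)))
    headings = theta0 + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(turns, axis=1)], axis=1
    )
    return step_len * np.stack([np.cos(headings), np.sin(headings)], axis=-1)


def simulate_trajectories(config: SceneConfig) -> GroundTruth:
    """Simulate per-frame positions, motility flags and K562 death times.

    Motile NK cells perform a fixed-speed persistent random walk in the
    x–y plane at constant z; nonmotile NK cells and live K562 targets
    jitter isotropically around fixed anchors.  Dead K562 cells freeze at
    their death position.  All positions are folded back into the volume by
    reflection at the faces.
    """
    cfg = config
    n_frames = cfg.n_frames
    Lx, Ly, Lz = cfg.box
    n_total = cfg.n_nk + cfg.n_k562
    cell_class = np.array(["NK"] * cfg.n_nk + ["K562"] * cfg.n_k562, dtype="<U4")

    rng_flags = cfg.rng(0)
    rng_init = cfg.rng(1)
    rng_walk = cfg.rng(2)
    rng_jit = cfg.rng(3)
    rng_death = cfg.rng(4)

    motile = np.zeros(n_total, dtype=bool)
    motile[: cfg.n_nk] = rng_flags.random(cfg.n_nk) < cfg.motile_fraction

    start = np.column_stack([
        rng_init.uniform(0, Lx, n_total),
        rng_init.uniform(0, Ly, n_total),
        rng_init.uniform(0, Lz, n_total),
    ])
    positions = np.repeat(start[:, None, :], n_frames, axis=1)

    # Motile NK: correlated walk in the plane, constant z.
    idx_mot = np.flatnonzero(motile)
    if idx_mot.size:
        step_len = cfg.speed_mean * cfg.frame_interval / 60.0
        steps = _persistent_walk(rng_walk, idx_mot.size, n_frames - 1,
                                 step_len, cfg.persistence_true)
        positions[idx_mot, 1:, :2] = (
            start[idx_mot, None, :2] + np.cumsum(steps, axis=1)
        )

    # Nonmotile NK: anchored isotropic jitter.
    idx_non = np.flatnonzero((cell_class == "NK") & ~motile)
    if idx_non.size and cfg.jitter_sigma > 0:
        positions[idx_non] = start[idx_non, None, :] + rng_jit.normal(
            0.0, cfg.jitter_sigma, size=(idx_non.size, n_frames, 3)
        )

    # K562 death times: first-order rate set by the motile-NK concentration.
    death_time_h = np.full(n_total, np.nan)
    idx_k562 = np.flatnonzero(cell_class == "K562")
    motile_conc = motile.sum() / (cfg.volume / CUBIC_100UM_VOLUME_UM3)
    rate = cfg.k_true * motile_conc  # per hour per live target
    if idx_k562.size and rate > 0:
        draws = rng_death.exponential(1.0 / rate, size=idx_k562.size)
        died = draws <= cfg.duration
        death_time_h[idx_k562[died]] = draws[died]

    # K562 wiggle: anchored jitter with per-axis sd w/2 so the RMS planar
    # frame-to-frame displacement equals wiggle_amplitude; frozen after death.
    if idx_k562.size and cfg.wiggle_amplitude > 0:
        sd = cfg.wiggle_amplitude / 2.0
        wig = rng_jit.normal(0.0, sd, size=(idx_k562.size, n_frames, 3))
        t_h = cfg.times_s / 3600.0
        for row, ci in enumerate(idx_k562):
            dt = death_time_h[ci]
            alive_mask = ~(t_h >= dt) if np.isfinite(dt) else np.ones(n_frames, bool)
            pos = start[ci, None, :] + wig[row]
            if alive_mask.all():
                positions[ci] = pos
            else:
                f_death = int(np.argmax(~alive_mask))
                positions[ci, :f_death] = pos[:f_death]
                freeze = pos[f_death - 1] if f_death > 0 else start[ci]
                positions[ci, f_death:] = freeze

    positions[:, :, 0] = _reflect(positions[:, :, 0], 0.0, Lx)
    positions[:, :, 1] = _reflect(positions[:, :, 1], 0.0, Ly)
    positions[:, :, 2] = _reflect(positions[:, :, 2], 0.0, Lz)

    return GroundTruth(
        config=cfg,
        cell_class=cell_class,
        motile=motile,
        positions=positions,
        death_time_h=death_time_h,
    )


def simulate_killing(
    config: SceneConfig,
    mode: Literal["deterministic", "stochastic"] = "stochastic",
    experiment_id: str = "sim",
) -> KillingExperiment:
    """Simulate the live/dead target time series of one killing experiment.

    ``deterministic`` evaluates the exponential solution of the first-order
    rate equation exactly (live counts are real-valued); ``stochastic``
    draws an independent exponential death time per target.  The motile NK
    concentration is held constant, matching the model's assumption.
    """
    cfg = config
    if cfg.frame_interval > cfg.duration * 3600.0:
        raise InvalidConfigError("frame_interval exceeds total duration")
    if cfg.n_k562 <= 0:
        raise InvalidConfigError("killing simulation needs n_k562 > 0")

    vol_units = cfg.volume / CUBIC_100UM_VOLUME_UM3
    times_h = cfg.times_s / 3600.0
    n0 = float(cfg.n_k562)

    if mode == "deterministic":
        n_motile = cfg.n_nk * cfg.motile_fraction
        motile_conc = n_motile / vol_units
        rate = cfg.k_true * motile_conc
        live = n0 * np.exp(-rate * times_h)
        # Event times where the continuous solution crosses integer counts.
        n_events = int(np.floor(n0 - live[-1]))
        if rate > 0 and n_events > 0:
            levels = n0 - np.arange(1, n_events + 1)
            events = np.log(n0 / levels) / rate
        else:
            events = np.array([])
    elif mode == "stochastic":
        rng = cfg.rng(10)
        n_motile = rng.binomial(cfg.n_nk, cfg.motile_fraction)
        motile_conc = n_motile / vol_units
        rate = cfg.k_true * motile_conc
        if rate > 0:
            draws = rng.exponential(1.0 / rate, size=cfg.n_k562)
            events = np.sort(draws[draws <= cfg.duration])
        else:
            events = np.array([])
        live = n0 - np.searchsorted(events, times_h, side="right")
    else:
        raise InvalidConfigError(f"unknown mode {mode!r}")

    nonmotile_conc = (cfg.n_nk - n_motile) / vol_units
    return KillingExperiment(
        experiment_id=experiment_id,
        times_h=times_h,
        live_targets=live,
        dead_targets=n0 - live,
        nk_motile_conc=motile_conc,
        nk_nonmotile_conc=nonmotile_conc,
        observation_volume_um3=cfg.volume,
        duration_h=cfg.duration,
        kill_event_times_h=events,
    )


def _render_blob(img: np.ndarray, cx: float, cy: float, sx: float, sy: float,
                 z_weights: np.ndarray, amplitude: float) -> None:
    """Subtract a separable Gaussian dip at (cx, cy) px from every z-plane."""
    nz, ny, nx = img.shape
    half = int(math.ceil(4.0 * max(sx, sy)))
    x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, nx)
    y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, ny)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - cx
    ys = np.arange(y0, y1) - cy
    g = np.exp(-0.5 * (ys[:, None] / sy) ** 2) * np.exp(-0.5 * (xs[None, :] / sx) ** 2)
    img[:, y0:y1, x0:x1] -= amplitude * z_weights[:, None, None] * g[None]


def render_stack(
    truth: GroundTruth,
    pixel_size: float = 0.65,
    z_step: float = 10.0,
    background: float = 1000.0,
    noise_sigma: float = 20.0,
) -> ImageStack:
    """Render a ground-truth scene as a bright-field-like (t, z, y, x) stack.

    Cells become dark Gaussian blobs on a bright background with additive
    Gaussian noise; each cell produces a local intensity minimum at its
    position.  Dead K562 cells are rendered with a 30% weaker dip and a
    1.5:1 axis ratio (blebby, low-contrast appearance); their wiggle is
    already zero in the ground truth.
    """
    cfg = truth.config
    if min(NK_DIAMETER_UM, K562_DIAMETER_UM) / pixel_size < 2.0:
        raise InvalidConfigError("pixel_size too coarse: cells smaller than 2 px")
    Lx, Ly, Lz = cfg.box
    nx = int(math.ceil(Lx / pixel_size))
    ny = int(math.ceil(Ly / pixel_size))
    nz = max(int(math.ceil(Lz / z_step)), 1)
    n_frames = cfg.n_frames
    rng = cfg.rng(20)

    z_planes = np.arange(nz) * z_step  # plane i images depth i*z_step
    data = np.empty((n_frames, nz, ny, nx), dtype=np.float32)
    t_h = cfg.times_s / 3600.0

    for t in range(n_frames):
        frame = background + rng.normal(0.0, noise_sigma, size=(nz, ny, nx))
        for i in range(truth.n_cells):
            x, y, z = truth.positions[i, t]
            cls = truth.cell_class[i]
            dead = np.isfinite(truth.death_time_h[i]) and t_h[t] >= truth.death_time_h[i]
            diam = NK_DIAMETER_UM if cls == "NK" else K562_DIAMETER_UM
            sigma_um = diam / 4.0
            amp = DIP_FRACTION * background
            sx = sy = sigma_um / pixel_size
            if dead:
                amp *= 1.0 - DEAD_CONTRAST_LOSS
                sx *= math.sqrt(DEAD_AXIS_RATIO)
                sy /= math.sqrt(DEAD_AXIS_RATIO)
            # Bright-field cells stay dark over a wide defocus range, so the
            # axial footprint must span the z sampling, not the cell size.
            sigma_z = max(sigma_um, 0.6 * z_step)
            zw = np.exp(-0.5 * ((z_planes - z) / sigma_z) ** 2)
            _render_blob(frame, x / pixel_size, y / pixel_size, sx, sy, zw, amp)
        data[t] = np.maximum(frame, 0.0)

    return ImageStack(
        data=data,
        pixel_size=pixel_size,
        z_step=z_step,
        frame_interval=cfg.frame_interval,
    )
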