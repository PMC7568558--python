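"""First-order killing-efficiency estimation.

NK-mediated target-cell death over a long observation window is modelled as
a first-order reaction

    NK + K562_live  --k-->  NK + K562_dead

in which the NK cells act as a catalyst: the concentration of motile NK
cells is treated as constant, dead targets never revert, and the live
target concentration decays exponentially.  Solving the rate equation gives
the killing efficiency

    k = (ln [K562_live, t=0] - ln [K562_live, t=T]) / ([NK_motile] * T)

normalised to 1 h and to one motile NK cell and one live target per
10^6 µm^3 of gel (a 100 µm cube).  A *composite* efficiency divides the
same log-decay by the total (motile + nonmotile) NK concentration, coupling
cytotoxicity and motility into a single number.  Experiments with different
cell concentrations are combined by a weighted mean with weights
[K562_live, t=0] * [NK_motile]; group differences are assessed by a
bootstrap over experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import InvalidConfigError, UndefinedStatisticError

__all__ = [
    "CUBIC_100UM_VOLUME_UM3",
    "KillingExperiment",
    "KillingEfficiency",
    "killing_efficiency",
    "composite_k",
    "weighted_mean_k",
    "fit_exponential",
    "bootstrap_compare",
    "efficiency_from_experiment",
]

#: Normalisation volume for all concentrations: a cube of 100 µm edge.
CUBIC_100UM_VOLUME_UM3 = 100.0 ** 3


@dataclass
class KillingExperiment:
    """Live/dead target time series in a known observation volume.

    Concentrations are in cells per 10^6 µm^3; ``duration_h`` is the total
    observation time T in hours.  ``kill_event_times_h`` holds the times of
    individual confirmed killing events.
    """

    experiment_id: str
    times_h: np.ndarray
    live_targets: np.ndarray
    dead_targets: np.ndarray
    nk_motile_conc: float
    nk_nonmotile_conc: float
    observation_volume_um3: float
    duration_h: float
    kill_event_times_h: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.live_targets = np.asarray(self.live_targets, dtype=float)
        self.dead_targets = np.asarray(self.dead_targets, dtype=float)
        self.kill_event_times_h = np.asarray(self.kill_event_times_h, dtype=float)
        if self.duration_h <= 0:
            raise InvalidConfigError("duration_h must be > 0")
        if self.observation_volume_um3 <= 0:
            raise InvalidConfigError("observation_volume_um3 must be > 0")
        if self.live_targets.size and self.live_targets[0] <= 0:
            raise InvalidConfigError("initial live target count must be > 0")
        if self.nk_motile_conc < 0 or self.nk_nonmotile_conc < 0:
            raise InvalidConfigError("concentrations must be >= 0")

    def conc(self, count: float) -> float:
        """Convert a cell count in this volume to cells per 10^6 µm^3."""
        return count / (self.observation_volume_um3 / CUBIC_100UM_VOLUME_UM3)

    @property
    def live0_conc(self) -> float:
        return self.conc(self.live_targets[0])

    @property
    def liveT_conc(self) -> float:
        return self.conc(self.live_targets[-1])


@dataclass
class KillingEfficiency:
    """Per-experiment efficiency estimates in (10^6 µm^3/cell)/h."""

    k: float
    k_composite: float
    nk_motile_conc: float
    nk_nonmotile_conc: float
    live0_conc: float


def killing_efficiency(live0: float, liveT: float, nk_motile: float, T: float) -> float:
    """Killing efficiency of motile NK cells from endpoint live-target concentrations.

    Parameters are concentrations in cells per 10^6 µm^3 (``live0``,
    ``liveT``, ``nk_motile``) and the observation time ``T`` in hours.
    Returns k in (10^6 µm^3/cell)/h.
    """
    if live0 <= 0:
        raise InvalidConfigError("live0 must be > 0")
    if T <= 0:
        raise InvalidConfigError("T must be > 0")
    if nk_motile <= 0:
        raise UndefinedStatisticError(
            "killing efficiency undefined without motile NK cells"
        )
    if liveT <= 0:
        raise UndefinedStatisticError(
            "liveT = 0: rate unbounded; apply a half-count correction on counts"
        )
    return (math.log(live0) - math.log(liveT)) / (nk_motile * T)


def composite_k(live0: float, liveT: float, nk_motile: float,
                nk_nonmotile: float, T: float) -> float:
    """Composite killing efficiency attributing the decay to all NK cells.

    Satisfies the identity
    ``composite_k = killing_efficiency * nk_motile / (nk_motile + nk_nonmotile)``.
    """
    if nk_nonmotile < 0:
        raise InvalidConfigError("nk_nonmotile must be >= 0")
    k = killing_efficiency(live0, liveT, nk_motile, T)
    return k * nk_motile / (nk_motile + nk_nonmotile)


def killing_efficiency_from_counts(
    live0_count: float, liveT_count: float, nk_motile_count: float,
    volume_um3: float, T: float,
) -> tuple[float, bool]:
    """Efficiency from raw counts in a known volume.

    A final count of zero makes the rate unbounded; in that case the
    estimate is a lower bound computed with a half-count (0.5 cells)
    correction and the returned flag is True.
    """
    scale = volume_um3 / CUBIC_100UM_VOLUME_UM3
    corrected = liveT_count <= 0
    if corrected:
        warnings.warn(
            "final live count is 0; reporting a lower bound using 0.5 cells",
            stacklevel=2,
        )
        liveT_count = 0.5
    k = killing_efficiency(live0_count / scale, liveT_count / scale,
                           nk_motile_count / scale, T)
    return k, corrected


def efficiency_from_experiment(exp: KillingExperiment) -> KillingEfficiency:
    """Endpoint k and composite k for one experiment."""
    k = killing_efficiency(exp.live0_conc, exp.liveT_conc,
                           exp.nk_motile_conc, exp.duration_h)
    kc = composite_k(exp.live0_conc, exp.liveT_conc, exp.nk_motile_conc,
                     exp.nk_nonmotile_conc, exp.duration_h)
    return KillingEfficiency(
        k=k, k_composite=kc,
        nk_motile_conc=exp.nk_motile_conc,
        nk_nonmotile_conc=exp.nk_nonmotile_conc,
        live0_conc=exp.live0_conc,
    )


def _weights(experiments: Sequence[KillingExperiment]) -> np.ndarray:
    return np.array([e.live0_conc * e.nk_motile_conc for e in experiments])


def weighted_mean_k(
    experiments: Sequence[KillingExperiment],
    kind: Literal["motile", "composite"] = "motile",
) -> float:
    """Concentration-weighted mean efficiency over experiments.

    Weights are ``[K562_live, t=0]_i * [NK_motile]_i`` so that experiments
    with more cells (hence better-determined rates) count more.
    """
    if len(experiments) == 0:
        raise InvalidConfigError("need at least one experiment")
    w = _weights(experiments)
    if np.all(w == 0):
        raise UndefinedStatisticError("all weights are zero")
    effs = [efficiency_from_experiment(e) for e in experiments]
    k = np.array([eff.k if kind == "motile" else eff.k_composite for eff in effs])
    return float(np.sum(k * w) / np.sum(w))


def fit_exponential(kill_event_times: Sequence[float], live0: float,
                    T: float) -> tuple[float, float]:
    """Decay rate (/h) from individual killing events, plus the endpoint rate.

    Builds the event-resolved step series of live counts — live0 at t = 0,
    dropping by one at each event time — and fits ln(count) against time by
    ordinary least squares.  Also returns the endpoint-only approximation
    ``(ln live0 - ln liveT) / T``.  Returns ``(fitted_rate, endpoint_rate)``;
    with no events both are 0.
    """
    if live0 <= 0:
        raise InvalidConfigError("live0 must be > 0")
    if T <= 0:
        raise InvalidConfigError("T must be > 0")
    times = np.sort(np.asarray(kill_event_times, dtype=float))
    if times.size == 0:
        return 0.0, 0.0
    if times.size >= live0:
        raise InvalidConfigError("more killing events than initial live targets")
    counts = live0 - np.arange(1, times.size + 1)
    t_pts = np.concatenate([[0.0], times])
    y = np.log(np.concatenate([[live0], counts]))
    liveT = live0 - times.size
    endpoint_rate = (math.log(live0) - math.log(liveT)) / T
    slope = np.polyfit(t_pts, y, 1)[0]
    return float(-slope), endpoint_rate


def bootstrap_compare(
    group_a: Sequence[KillingExperiment],
    group_b: Sequence[KillingExperiment],
    B: int = 10_000,
    seed: int | None = None,
    kind: Literal["motile", "composite"] = "motile",
) -> dict:
    """Two-sided bootstrap test for a difference in weighted mean efficiency.

    Experiments are resampled with replacement within each group; the
    weighted mean is recomputed on every resample.  The two-sided p-value is
    twice the smaller tail probability of the bootstrap difference
    distribution around zero, floored at 2/B.  Also reports each group's
    bootstrap standard error.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InvalidConfigError("need >= 2 experiments per group")
    if B < 1000:
        raise InvalidConfigError("B must be >= 1000")
    rng = np.random.default_rng(seed)

    def resampled_means(group: Sequence[KillingExperiment]) -> np.ndarray:
        n = len(group)
        idx = rng.integers(0, n, size=(B, n))
        ks = np.array([
            efficiency_from_experiment(e).k if kind == "motile"
            else efficiency_from_experiment(e).k_composite
            for e in group
        ])
        w = _weights(group)
        return (ks[idx] * w[idx]).sum(axis=1) / w[idx].sum(axis=1)

    means_a = resampled_means(group_a)
    means_b = resampled_means(group_b)
    diff = means_a - means_b
    k_a = weighted_mean_k(group_a, kind)
    k_b = weighted_mean_k(group_b, kind)
    if np.all(diff == diff[0]):
        warnings.warn("degenerate bootstrap distribution; p = 1", stacklevel=2)
        p = 1.0
    else:
        lo = float(np.mean(diff <= 0))
        hi = float(np.mean(diff >= 0))
        p = min(1.0, max(2 * min(lo, hi), 2.0 / B))
    return {
        "k_avg_a": k_a,
        "k_avg_b": k_b,
        "se_a": float(np.std(means_a, ddof=1)),
        "se_b": float(np.std(means_b, ddof=1)),
        "p": p,
        "B": B,
    }
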