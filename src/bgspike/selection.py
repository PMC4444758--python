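"""Race-model readout of GPi activity into a selected action.

The GPi lattice is partitioned into one pool per competing stimulus
(halves for two stimuli, quadrants for four). Each pool's smoothed mean
spike rate f' is normalized and *reversed*,

    f_k = (f_max - f'_k) / f_max,

so that a disinhibited (quiet) GPi pool provides high drive. Leaky
integrators race on these drives,

    dz_k/dt = (-z_k + f_k) / tau,

and the first to cross the threshold (0.15) selects its action; no
crossing by trial end is a No-Go.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import SpikeRaster

RACE_THRESHOLD = 0.15

GO = "Go"
EXPLORE = "Explore"
NO_GO = "NoGo"


@dataclass
class PoolRateSeries:
    """Sliding-window pool rates and their normalized reversed drives."""

    times: np.ndarray  # bin centers, ms
    raw: np.ndarray  # (n_pools, n_bins) spikes/neuron/ms
    drive: np.ndarray  # (n_pools, n_bins) normalized reversed rates


def gpi_pool_rates(
    raster: SpikeRaster,
    pool_labels: np.ndarray,
    smoothing_window: float = 10.0,
    bin_ms: float = 1.0,
) -> PoolRateSeries:
    """Per-pool smoothed mean rates and race drives from a GPi raster.

    ``pool_labels`` assigns each flat GPi index to a pool (0..k-1) and
    must cover every neuron. The drive is computed per time bin with
    f_max the largest pool rate across pools at that bin (zero drive
    everywhere when all pools are silent).
    """
    labels = np.asarray(pool_labels)
    if labels.size != raster.n_neurons:
        raise ValueError("pool labels must cover the whole lattice")
    n_pools = int(labels.max()) + 1
    pool_sizes = np.bincount(labels, minlength=n_pools)
    if (pool_sizes == 0).any():
        raise ValueError("empty GPi pool")
    n_bins = max(int(np.ceil(raster.duration / bin_ms)), 1)
    counts = np.zeros((n_pools, n_bins))
    bin_idx = np.minimum(
        (raster.times / bin_ms).astype(np.int64), n_bins - 1
    )
    pool_of_event = labels[raster.neuron_ids]
    np.add.at(counts, (pool_of_event, bin_idx), 1.0)
    # sliding mean over the smoothing window
    w = max(int(round(smoothing_window / bin_ms)), 1)
    kernel = np.ones(w) / w
    smoothed = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), 1, counts
    )
    raw = smoothed / (pool_sizes[:, None] * bin_ms)
    f_max = raw.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        drive = np.where(f_max > 0, (f_max - raw) / f_max, 0.0)
    times = (np.arange(n_bins) + 0.5) * bin_ms
    return PoolRateSeries(times, raw, drive)


@dataclass
class RaceOutcome:
    winner: int | None  # pool index, or None for no crossing
    crossing_time: float | None  # ms, on the rate-series time axis
    z_final: np.ndarray


def race_integrate(
    drive: np.ndarray,
    dt: float,
    tau: float = 1.0,
    threshold: float = RACE_THRESHOLD,
    start_time: float = 0.0,
    times: np.ndarray | None = None,
) -> RaceOutcome:
    """Race ``k`` leaky integrators on the drive series.

    ``drive`` is (n_pools, n_t) sampled every ``dt`` ms; integration
    starts at ``start_time`` (integrators are held at zero before it,
    e.g. until stimulus onset). Returns the first pool to cross
    ``threshold`` and the crossing time, or a No-Go outcome.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n_pools, n_t = drive.shape
    if times is None:
        times = np.arange(n_t) * dt
    z = np.zeros(n_pools)
    for i in range(n_t):
        if times[i] < start_time:
            continue
        z = z + dt * (drive[:, i] - z) / tau
        if (z >= threshold).any():
            winner = int(np.argmax(z))
            return RaceOutcome(winner, float(times[i]), z)
    return RaceOutcome(None, None, z)


def classify_outcome(
    winner: int | None, saliences
) -> str:
    """Label a race result Go / Explore / No-Go.

    Go if the most salient stimulus won, Explore if a less salient one
    did, No-Go if nothing crossed. Ties in salience are a configuration
    error (the labels would be meaningless).
    """
    saliences = np.asarray(saliences, dtype=np.float64)
    best = np.flatnonzero(saliences == saliences.max())
    if best.size > 1:
        raise ValueError("tied saliences: Go/Explore labels undefined")
    if winner is None:
        return NO_GO
    return GO if winner == int(best[0]) else EXPLORE
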