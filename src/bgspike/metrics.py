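"""Raster analysis: spike-phase synchrony, rates, spectra, group tests.

The synchrony measure is a Kuramoto-type order parameter on linearly
interpolated spike phases. A neuron's phase at time t between its k-th
and (k+1)-th spikes is

    phi_j(t) = 2*pi * (t - t_{j,k}) / (t_{j,k+1} - t_{j,k}),

and the population order parameter is R(t) e^{i theta} =
(1/N) sum_j e^{i phi_j(t)} over neurons with a bracketing spike pair.
R = 1 means perfect phase locking; independent phases give R ~ 1/sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .raster import SpikeRaster


@dataclass
class PhaseField:
    """Per-neuron phases (radians in [0, 2*pi)) at query times.

    ``valid[j, q]`` is False where neuron j has no bracketing spike
    pair at query time q (fewer than two spikes, or t outside its
    spiking span); such entries carry phase 0 but must be ignored.
    """

    query_times: np.ndarray
    phases: np.ndarray  # (n_neurons, n_queries)
    valid: np.ndarray  # bool, same shape


@dataclass
class SyncSeries:
    """Kuramoto order parameter over time for one population."""

    times: np.ndarray
    R: np.ndarray  # NaN where no neuron had a valid phase
    theta: np.ndarray
    n_valid: np.ndarray
    label: str = ""

    def mean(self) -> float:
        """Time-averaged R over defined query times."""
        if not np.any(self.n_valid > 0):
            return float("nan")
        return float(np.nanmean(self.R))


def spike_phases(raster: SpikeRaster, query_times) -> PhaseField:
    """Interpolated spike phase of every neuron at the query times."""
    q = np.asarray(query_times, dtype=np.float64)
    if q.size and (q.min() < 0 or q.max() > raster.duration):
        raise ValueError("query times outside the raster duration")
    n = raster.n_neurons
    phases = np.zeros((n, q.size))
    valid = np.zeros((n, q.size), dtype=bool)
    for j, train in enumerate(raster.spike_trains()):
        if train.size < 2:
            continue
        idx = np.searchsorted(train, q, side="right") - 1
        ok = (idx >= 0) & (idx < train.size - 1)
        i = idx[ok]
        t0 = train[i]
        t1 = train[i + 1]
        phases[j, ok] = 2.0 * np.pi * (q[ok] - t0) / (t1 - t0)
        valid[j, ok] = True
    return PhaseField(q, phases, valid)


def sync_order_parameter(
    field: PhaseField, label: str = ""
) -> SyncSeries:
    """Order parameter R(t), mean phase theta(t) over valid neurons."""
    z = np.where(field.valid, np.exp(1j * field.phases), 0.0)
    n_valid = field.valid.sum(axis=0)
    mean_z = np.full(field.query_times.shape, np.nan + 0j)
    nonzero = n_valid > 0
    mean_z[nonzero] = z[:, nonzero].sum(axis=0) / n_valid[nonzero]
    R = np.abs(mean_z)
    theta = np.angle(mean_z)
    return SyncSeries(field.query_times, R, theta, n_valid, label)


def sync_series(
    raster: SpikeRaster,
    t0: float | None = None,
    t1: float | None = None,
    step: float = 1.0,
    label: str = "",
) -> SyncSeries:
    """R(t) on a regular query grid (default every 1 ms)."""
    t0 = 0.0 if t0 is None else t0
    t1 = raster.duration if t1 is None else t1
    q = np.arange(t0, t1, step)
    return sync_order_parameter(spike_phases(raster, q), label)


def mean_sync(
    raster: SpikeRaster,
    burn_in: float = 100.0,
    t1: float | None = None,
    step: float = 1.0,
) -> float:
    """Time-averaged R after the burn-in window."""
    return sync_series(raster, t0=burn_in, t1=t1, step=step).mean()


def joint_sync_series(
    a: SpikeRaster, b: SpikeRaster, t0: float = 0.0,
    t1: float | None = None, step: float = 1.0,
) -> SyncSeries:
    """Order parameter over the pooled union of two populations."""
    if a.duration != b.duration:
        raise ValueError("rasters must share a duration")
    merged = SpikeRaster(
        np.concatenate([a.neuron_ids, b.neuron_ids + a.n_neurons]),
        np.concatenate([a.times, b.times]),
        a.n_neurons + b.n_neurons,
        a.duration,
    )
    return sync_series(merged, t0=t0, t1=t1, step=step, label="joint")


def mean_firing_rate(
    raster: SpikeRaster,
    window: tuple[float, float] | None = None,
    n_alive: int | None = None,
) -> float:
    """Population mean firing rate in Hz over ``window``.

    Total spike count divided by (number of live neurons x window
    length); ``n_alive`` defaults to the full population size.
    """
    t0, t1 = (0.0, raster.duration) if window is None else window
    if t1 <= t0:
        raise ValueError("zero-length or negative rate window")
    if t1 > raster.duration or t0 < 0:
        raise ValueError("rate window outside the raster duration")
    n = raster.n_neurons if n_alive is None else n_alive
    count = np.count_nonzero((raster.times >= t0) & (raster.times < t1))
    return count / (n * (t1 - t0) / 1000.0)


def population_oscillation_frequency(
    raster: SpikeRaster,
    band: tuple[float, float] = (2.0, 30.0),
    bin_ms: float = 1.0,
    peak_factor: float = 3.0,
) -> float | None:
    """Dominant oscillation frequency of the population spike count.

    Bins all spikes (1 ms default), mean-subtracts, and estimates the
    spectrum by Welch averaging (the raw periodogram of a flat Poisson
    spectrum is exponentially distributed, so its in-band maximum
    always towers over the median and every raster would "oscillate");
    returns the peak frequency within ``band`` if its averaged power
    exceeds ``peak_factor`` times the median spectral power, else None
    (no significant rhythm).
    """
    if raster.duration < 1000.0:
        raise ValueError("need >= 1 s of data for spectral analysis")
    counts = raster.binned_counts(bin_ms)
    counts = counts - counts.mean()
    fs = 1000.0 / bin_ms
    nperseg = min(1000, counts.size)
    freqs, power = signal.welch(counts, fs=fs, nperseg=nperseg)
    keep = freqs > 0
    freqs, power = freqs[keep], power[keep]
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any() or power[in_band].max() <= 0:
        return None
    ref = np.median(power)
    peak_idx = np.argmax(power[in_band])
    if power[in_band][peak_idx] < peak_factor * ref:
        return None
    return float(freqs[in_band][peak_idx])


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_stat: float
    p_value: float
    degenerate: bool  # both groups had (near-)zero variance


def compare_sync_groups(values_a, values_b) -> GroupComparison:
    """Pooled two-sample t-test between per-trial synchrony values."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    degenerate = a.std() == 0 and b.std() == 0
    if degenerate and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        float(a.mean()), float(b.mean()),
        float(a.std(ddof=1)), float(b.std(ddof=1)),
        float(t_stat), float(p), bool(degenerate),
    )
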