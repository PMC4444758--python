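"""Poisson striatal spike pools and stimulus-to-lattice layouts.

The striatum is not modeled at the membrane level: D1- and D2-expressing
medium spiny neuron populations are emitted as Poisson spike trains
whose rates encode stimulus saliency. A pool's rate profile is piecewise
constant in time, and neurons are partitioned into *correlation groups*:
all members of a group share one spike train (drawn once per step),
which is how "fully correlated" stimulus packets are produced. Singleton
groups give independent (uncorrelated) trains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import SpikeRaster

BACKGROUND_RATE_HZ = 1.0  # spontaneous striatal output rate


def lattice_halves(shape: tuple[int, int]) -> np.ndarray:
    """Flat labels splitting the lattice into upper (0) / lower (1) halves."""
    n = shape[0] * shape[1]
    labels = np.zeros(n, dtype=np.int64)
    labels[n // 2:] = 1
    return labels


def lattice_quadrants(shape: tuple[int, int]) -> np.ndarray:
    """Flat labels for the four equal quadrants of the lattice (0..3)."""
    rows, cols = shape
    i, j = np.divmod(np.arange(rows * cols), cols)
    return (2 * (i >= rows // 2) + (j >= cols // 2)).astype(np.int64)


@dataclass
class RateSegment:
    """One piecewise-constant interval ``[t0, t1)`` of a pool's drive.

    ``group_of`` maps each flat neuron index to its correlation group;
    ``group_rates`` gives the Poisson rate (Hz) of each group.
    """

    t0: float
    t1: float
    group_of: np.ndarray
    group_rates: np.ndarray

    @property
    def n_groups(self) -> int:
        return int(self.group_rates.size)


@dataclass
class StriatalPool:
    """One striatal output pool (D1 or D2 branch)."""

    branch: str
    shape: tuple[int, int]
    segments: list[RateSegment]

    @property
    def n_neurons(self) -> int:
        return self.shape[0] * self.shape[1]

    def segment_at(self, t: float) -> RateSegment | None:
        for seg in self.segments:
            if seg.t0 <= t < seg.t1:
                return seg
        return None

    def rate_map(self, t: float) -> np.ndarray:
        """Per-neuron rate (Hz) at time ``t`` ms."""
        seg = self.segment_at(t)
        if seg is None:
            return np.zeros(self.n_neurons)
        return seg.group_rates[seg.group_of]

    def sample_step(
        self, t: float, dt: float, rng: np.random.Generator
    ) -> np.ndarray:
        """Bernoulli-thinned Poisson spikes for one step (flat bool array).

        One draw per correlation group, copied to all its members.
        """
        seg = self.segment_at(t)
        if seg is None:
            return np.zeros(self.n_neurons, dtype=bool)
        p = seg.group_rates * (dt / 1000.0)
        if np.any(p >= 1.0):
            raise ValueError(
                "rate*dt >= 1: Bernoulli thinning invalid; reduce dt"
            )
        group_spikes = rng.random(seg.n_groups) < p
        return group_spikes[seg.group_of]


def generate_poisson(
    pool: StriatalPool,
    duration: float,
    dt: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> SpikeRaster:
    """Realize a pool as a :class:`SpikeRaster` over ``[0, duration]`` ms."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_steps = int(round(duration / dt))
    step_idx, neuron_idx = [], []
    for step in range(n_steps):
        spikes = pool.sample_step(step * dt, dt, rng)
        if spikes.any():
            flat = np.flatnonzero(spikes)
            neuron_idx.append(flat)
            step_idx.append(np.full(flat.size, step, dtype=np.int64))
    if step_idx:
        steps = np.concatenate(step_idx)
        neurons = np.concatenate(neuron_idx)
    else:
        steps = neurons = np.empty(0, dtype=np.int64)
    return SpikeRaster.from_step_events(
        steps, neurons, dt, pool.n_neurons, duration
    )


def _background_segment(
    t0: float, t1: float, n: int, rate: float
) -> RateSegment:
    # uncorrelated background: every neuron its own group
    return RateSegment(
        t0, t1, np.arange(n), np.full(n, rate, dtype=np.float64)
    )


def _constant_pool(
    branch: str,
    shape: tuple[int, int],
    stim_segment: RateSegment,
    duration: float,
    window: tuple[float, float],
    background: float,
) -> StriatalPool:
    n = shape[0] * shape[1]
    t0, t1 = window
    segments = []
    if t0 > 0:
        segments.append(_background_segment(0.0, t0, n, background))
    segments.append(stim_segment)
    if t1 < duration:
        segments.append(_background_segment(t1, duration, n, background))
    return StriatalPool(branch, shape, segments)


def binary_stimulus_layout(
    f1: float = 4.0,
    f2: float = 8.0,
    window: tuple[float, float] = (100.0, 200.0),
    background: float = BACKGROUND_RATE_HZ,
    shape: tuple[int, int] = (50, 50),
    duration: float = 250.0,
) -> tuple[StriatalPool, StriatalPool]:
    """Two-stimulus saliency layout for the binary selection task.

    Inside the stimulus window the upper half of each pool carries
    stimulus #1 at ``f1`` Hz and the lower half stimulus #2 at ``f2``
    Hz, each half fully correlated within itself; outside the window all
    neurons fire independently at the background rate. D1 and D2 pools
    share the layout but are independent Poisson realizations.
    """
    if not (0.0 <= window[0] < window[1] <= duration):
        raise ValueError("stimulus window must lie within the trial")
    n = shape[0] * shape[1]
    halves = lattice_halves(shape)
    stim = RateSegment(
        window[0], window[1], halves,
        np.array([f1, f2], dtype=np.float64),
    )
    make = lambda branch: _constant_pool(
        branch, shape, stim, duration, window, background
    )
    return make("D1"), make("D2")


def default_saliency_rate(weight: np.ndarray | float) -> np.ndarray:
    """Map a cortico-striatal weight in [0, 100] to a firing rate (Hz).

    rate = w / 10, keeping rates in the physiological few-tens-of-Hz
    band for striatal output (weights start at 50 -> 5 Hz).
    """
    return np.asarray(weight, dtype=np.float64) / 10.0


def bandit_stimulus_layout(
    weights_d1: np.ndarray,
    weights_d2: np.ndarray,
    rate_map_fn=default_saliency_rate,
    window: tuple[float, float] = (100.0, 200.0),
    background: float = BACKGROUND_RATE_HZ,
    shape: tuple[int, int] = (50, 50),
    duration: float = 250.0,
) -> tuple[StriatalPool, StriatalPool]:
    """Four-quadrant saliency layout for the bandit task.

    Quadrant ``q`` of the D1 (D2) pool fires at
    ``rate_map_fn(weights_d1[q])`` (resp. D2) inside the stimulus
    window, fully correlated within the quadrant; background activity
    is uncorrelated at 1 Hz. Weights outside [0, 100] are clipped.
    """
    weights_d1 = np.clip(np.asarray(weights_d1, dtype=np.float64), 0, 100)
    weights_d2 = np.clip(np.asarray(weights_d2, dtype=np.float64), 0, 100)
    if weights_d1.shape != (4,) or weights_d2.shape != (4,):
        raise ValueError("expected 4 weights per striatal branch")
    quads = lattice_quadrants(shape)
    pools = []
    for branch, w in (("D1", weights_d1), ("D2", weights_d2)):
        stim = RateSegment(
            window[0], window[1], quads, rate_map_fn(w)
        )
        pools.append(
            _constant_pool(branch, shape, stim, duration, window, background)
        )
    return pools[0], pools[1]
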