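"""Spike rasters: time-stamped spike events for a population.

A :class:`SpikeRaster` is the common substrate for every analysis in the
package (phase synchrony, firing rates, population spectra, pool rates).
Events are stored as parallel arrays of flat neuron indices and spike
times in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SpikeRaster:
    """Spike events of one population.

    Parameters
    ----------
    neuron_ids : array of int
        Flat neuron index per event.
    times : array of float
        Spike time per event, in ms; within ``[0, duration]``.
    n_neurons : int
        Population size (fixed, independent of which neurons fired).
    duration : float
        Recording length in ms.
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float

    def __post_init__(self) -> None:
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.neuron_ids.shape != self.times.shape:
            raise ValueError("neuron_ids and times must have equal length")
        if self.times.size and (
            self.times.min() < 0 or self.times.max() > self.duration
        ):
            raise ValueError("spike times outside [0, duration]")

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_step_events(
        cls,
        step_indices: np.ndarray,
        neuron_indices: np.ndarray,
        dt: float,
        n_neurons: int,
        duration: float,
    ) -> "SpikeRaster":
        """Build from (step, neuron) event pairs of a dt-stepped simulation."""
        times = (np.asarray(step_indices, dtype=np.float64) + 1.0) * dt
        # last step may land exactly on `duration`; keep it inside
        np.clip(times, 0.0, duration, out=times)
        return cls(np.asarray(neuron_indices), times, n_neurons, duration)

    def spike_trains(self) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays (length ``n_neurons``)."""
        order = np.lexsort((self.times, self.neuron_ids))
        ids = self.neuron_ids[order]
        ts = self.times[order]
        bounds = np.searchsorted(ids, np.arange(self.n_neurons + 1))
        return [ts[bounds[i]:bounds[i + 1]] for i in range(self.n_neurons)]

    def counts(self) -> np.ndarray:
        """Spike count per neuron."""
        return np.bincount(self.neuron_ids, minlength=self.n_neurons)

    def window(self, t0: float, t1: float) -> "SpikeRaster":
        """Events with ``t0 <= t < t1`` (times kept on the original axis)."""
        if t1 <= t0:
            raise ValueError("empty or negative window")
        keep = (self.times >= t0) & (self.times < t1)
        return SpikeRaster(
            self.neuron_ids[keep], self.times[keep], self.n_neurons,
            self.duration,
        )

    def binned_counts(self, bin_ms: float = 1.0) -> np.ndarray:
        """Population spike count per time bin over ``[0, duration]``."""
        n_bins = max(int(np.ceil(self.duration / bin_ms)), 1)
        idx = np.minimum((self.times / bin_ms).astype(np.int64), n_bins - 1)
        return np.bincount(idx, minlength=n_bins).astype(np.float64)

    # -- text serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"neuron_id": self.neuron_ids, "time_ms": self.times}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, n_neurons: int, duration: float) -> "SpikeRaster":
        df = pd.read_csv(path)
        return cls(
            df["neuron_id"].to_numpy(), df["time_ms"].to_numpy(),
            n_neurons, duration,
        )
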