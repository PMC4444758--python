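"""2D lattices of Izhikevich neurons with spike detection and reset.

The membrane model is the two-variable quadratic integrate model

    dv/dt = 0.04 v^2 + 5 v - u + 140 + I_ext + I_syn
    du/dt = a (b v - u)
    if v >= v_peak:  v <- c,  u <- u + d

stepped on a ms-scale grid (canonical two-half-step scheme or plain
forward Euler). The lattice is a plain (N, M) array of
independent neurons; coupling between neurons enters only through the
per-neuron synaptic current field ``I_syn`` supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import IzhikevichParams, nucleus_params
from .raster import SpikeRaster


class NumericalBlowupError(RuntimeError):
    """Raised when the Euler update produces non-finite state."""

    def __init__(self, dt: float, step: int | None = None):
        msg = f"non-finite membrane state after Euler step with dt={dt}"
        if step is not None:
            msg += f" at step {step}"
        super().__init__(msg)
        self.dt = dt
        self.step = step


@dataclass
class NeuronLattice:
    """State (v, u) of one N x M Izhikevich population.

    ``alive_mask`` marks lesioned neurons False: they are held at the
    reset potential, never spike, and (by construction of the synaptic
    wiring) never contribute to any postsynaptic current.
    """

    params: IzhikevichParams
    v: np.ndarray
    u: np.ndarray
    alive_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.v.shape

    @property
    def n_neurons(self) -> int:
        return self.v.size

    def copy(self) -> "NeuronLattice":
        return NeuronLattice(
            self.params, self.v.copy(), self.u.copy(), self.alive_mask.copy()
        )


def init_lattice(
    preset: str | IzhikevichParams,
    shape: tuple[int, int] = (50, 50),
    seed: int | np.random.Generator | None = 0,
    jitter: float = 1.0,
) -> NeuronLattice:
    """Create a lattice resting at the reset potential with seeded jitter.

    ``v`` starts at ``c + U(0, jitter)`` mV (jitter breaks the perfect
    lattice symmetry that would otherwise lock identical neurons
    together forever) and ``u = b * v``. Deterministic for a fixed seed.
    """
    params = nucleus_params(preset) if isinstance(preset, str) else preset
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    v = np.full(shape, params.c, dtype=np.float64)
    if jitter > 0:
        v += rng.uniform(0.0, jitter, size=shape)
    u = params.b * v
    return NeuronLattice(params, v, u, np.ones(shape, dtype=bool))


def step_lattice(
    lattice: NeuronLattice,
    I_syn: np.ndarray | float,
    dt: float,
    scheme: str = "izhikevich",
    v_floor: float = -300.0,
) -> np.ndarray:
    """Advance the lattice by one step of length ``dt`` ms, in place.

    ``I_syn`` is the explicit per-neuron synaptic current field
    (broadcastable to the lattice shape). After the update the membrane
    is clamped from below at ``v_floor`` (mV), a deep guard that leaves
    the physiological voltage range untouched but stops the runaway
    u-v spiral that strong GABA pulses can otherwise seed on the
    model's coarse ms grid (v overshooting far below the GABA reversal
    acquires an unbounded depolarizing driving force).

    Returns the boolean spike mask for this step; spiking neurons have
    already been reset. Lesioned neurons are held at reset and never
    appear in the mask.

    Two stepping schemes are available:

    - ``"izhikevich"`` (default): the canonical reference loop for this
      neuron model - two half-steps for v, one full step for u, then
      the reset check. The model's published firing rates are defined
      on this scheme at its native dt = 1 ms grid (e.g. the GPe preset
      at I = 10 fires ~64 Hz here but ~131 Hz in the continuum limit).
    - ``"euler"``: plain simultaneous forward Euler for v and u.

    Raises :class:`NumericalBlowupError` if the update produces NaN/Inf.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = lattice.params
    v, u = lattice.v, lattice.u
    if scheme == "izhikevich":
        drive = -u + 140.0 + p.I_ext + I_syn
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + drive)
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + drive)
        np.maximum(v, v_floor, out=v)
        u += dt * p.a * (p.b * v - u)
    elif scheme == "euler":
        dv = 0.04 * v * v + 5.0 * v - u + 140.0 + p.I_ext + I_syn
        du = p.a * (p.b * v - u)
        v += dt * dv
        np.maximum(v, v_floor, out=v)
        u += dt * du
    else:
        raise ValueError(f"unknown integration scheme {scheme!r}")
    if not (np.isfinite(v).all() and np.isfinite(u).all()):
        raise NumericalBlowupError(dt)
    spikes = v >= p.v_peak
    alive = lattice.alive_mask
    spikes &= alive
    v[spikes] = p.c
    u[spikes] += p.d
    if not alive.all():
        dead = ~alive
        v[dead] = p.c
        u[dead] = p.b * p.c
    return spikes


def run_lattice(
    lattice: NeuronLattice,
    duration: float,
    dt: float = 1.0,
    I_syn=None,
    scheme: str = "izhikevich",
) -> SpikeRaster:
    """Free-run a lattice for ``duration`` ms and collect its raster.

    ``I_syn`` may be None (isolated neurons), a constant array/scalar,
    or a callable ``I_syn(step, t) -> field`` for time-varying drive.
    """
    n_steps = int(round(duration / dt))
    step_idx: list[np.ndarray] = []
    neuron_idx: list[np.ndarray] = []
    for step in range(n_steps):
        if I_syn is None:
            drive = 0.0
        elif callable(I_syn):
            drive = I_syn(step, step * dt)
        else:
            drive = I_syn
        spikes = step_lattice(lattice, drive, dt, scheme=scheme)
        if spikes.any():
            flat = np.flatnonzero(spikes.ravel())
            neuron_idx.append(flat)
            step_idx.append(np.full(flat.size, step, dtype=np.int64))
    if step_idx:
        steps = np.concatenate(step_idx)
        neurons = np.concatenate(neuron_idx)
    else:
        steps = np.empty(0, dtype=np.int64)
        neurons = np.empty(0, dtype=np.int64)
    return SpikeRaster.from_step_events(
        steps, neurons, dt, lattice.n_neurons, duration
    )


def characterize_fi(
    preset: str | IzhikevichParams,
    I_values,
    duration: float = 1000.0,
    dt: float = 1.0,
    scheme: str = "izhikevich",
) -> np.ndarray:
    """Mean firing rate (Hz) of a single neuron per constant current.

    Runs one isolated neuron (no jitter) for ``duration`` ms at each
    external current in ``I_values`` and returns spikes / duration.
    """
    if duration < 500.0:
        raise ValueError("duration must be >= 500 ms for a stable rate")
    base = nucleus_params(preset) if isinstance(preset, str) else preset
    rates = []
    for I in I_values:
        p = IzhikevichParams(
            a=base.a, b=base.b, c=base.c, d=base.d,
            v_peak=base.v_peak, I_ext=float(I),
        )
        lat = init_lattice(p, shape=(1, 1), jitter=0.0)
        raster = run_lattice(lat, duration, dt=dt, scheme=scheme)
        rates.append(len(raster) / (duration / 1000.0))
    return np.asarray(rates)
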