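"""Full-circuit assembly and the time-stepped simulation loop.

Wiring (all inter-nucleus projections one-to-one by lattice index):

    StrD2 --GABA--> GPe      STN --AMPA+NMDA--> GPe (w_sg, DA-scaled)
    GPe  --GABA--> STN       STN collaterals --AMPA+NMDA--> STN
    GPe collaterals --GABA--> GPe
    StrD1 --GABA--> GPi      STN --AMPA+NMDA--> GPi (w_STN->GPi)

Dopamine enters through (i) the striatal gains cD1/cD2, (ii) linear
attenuation of the STN<->GPe weights, and (iii) the radius of the
collateral Gaussian kernels. Update order per step: striatal spikes are
sampled, gating variables are driven by the previous step's spikes,
currents are assembled, lattices take one Euler step, and spikes are
detected and reset - a uniform one-step causal delay on every pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

from . import params as P
from .izhikevich import (
    NeuronLattice, NumericalBlowupError, init_lattice, step_lattice,
)
from .raster import SpikeRaster
from .striatum import StriatalPool
from .synapses import (
    AMPA, GABA, NMDA, NMDA_GPI, DEFAULT_RADIUS_MAPPING, SynapseState,
    build_lateral_kernel, da_scaled_weight, lateral_current, mg_block,
    receptor_current, striatal_gain, update_gating,
)


@dataclass
class CircuitConfig:
    """Everything needed to reproduce one circuit simulation."""

    shape: tuple[int, int] = (50, 50)
    dt: float = 1.0  # ms
    scheme: str = "izhikevich"  # membrane stepping scheme
    duration: float = 1000.0  # ms
    da: float = 0.5
    seed: int = 0
    jitter: float = 1.0  # mV of initial-condition jitter
    burn_in: float = 100.0  # ms excluded from summary metrics
    ramp_ms: float = 0.0  # optional soft-start ramp on synaptic currents

    # synaptic weights (published defaults)
    w_strd1_gpi: float = P.W_STRD1_GPI
    w_strd2_gpe: float = P.W_STRD2_GPE
    w_sg: float = P.W_SG
    w_gs: float = P.W_GS
    w_stn_gpi: float = P.W_STN_GPI
    a_stn: float = P.A_STN
    a_gpe: float = P.A_GPE

    # dopamine -> lateral-radius mapping
    radius_mapping: str = DEFAULT_RADIUS_MAPPING
    radius_floor: float = 0.05

    # ablations
    ip_removed: bool = False
    stn_lesion: tuple[int, int, int, int] | None = None  # (i0, i1, j0, j1)

    # GABA currents clipped to be non-depolarizing (see methods note)
    gaba_rectified: bool = True

    # skip integrating GPi when only STN-GPe dynamics are of interest
    simulate_gpi: bool = True

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if not (P.DA_MIN <= self.da <= P.DA_MAX):
            raise ValueError("DA outside the working range [0.1, 0.9]")
        if self.stn_lesion is not None:
            i0, i1, j0, j1 = self.stn_lesion
            if not (0 <= i0 <= i1 <= self.shape[0]
                    and 0 <= j0 <= j1 <= self.shape[1]):
                raise ValueError("lesion patch exceeds lattice bounds")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        if self.stn_lesion is not None:
            d["stn_lesion"] = list(self.stn_lesion)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitConfig":
        d = dict(d)
        d["shape"] = tuple(d["shape"])
        if d.get("stn_lesion") is not None:
            d["stn_lesion"] = tuple(d["stn_lesion"])
        return cls(**d)


def apply_stn_lesion(
    config: CircuitConfig, patch_size: tuple[int, int]
) -> CircuitConfig:
    """Return a config with a centered rectangular STN lesion.

    Lesioned neurons are silenced: they are held at the reset potential
    and contribute no spikes to any postsynaptic target.
    """
    pi, pj = patch_size
    if pi > config.shape[0] or pj > config.shape[1]:
        raise ValueError("lesion patch exceeds lattice bounds")
    i0 = (config.shape[0] - pi) // 2
    j0 = (config.shape[1] - pj) // 2
    cfg = replace(config, stn_lesion=(i0, i0 + pi, j0, j0 + pj))
    cfg.validate()
    return cfg


def remove_indirect_pathway(config: CircuitConfig) -> CircuitConfig:
    """Return a config with the STN->GPi projection removed.

    The GPi then receives only the D1-striatal GABA current; STN-GPe
    dynamics themselves are untouched.
    """
    return replace(config, ip_removed=True)


@dataclass
class SimulationResult:
    """Rasters and provenance of one circuit run."""

    stn: SpikeRaster
    gpe: SpikeRaster
    gpi: SpikeRaster | None
    striatum_d1: SpikeRaster | None
    striatum_d2: SpikeRaster | None
    config: CircuitConfig

    @property
    def duration(self) -> float:
        return self.config.duration


class _EventBuffer:
    """Accumulates (step, neuron) spike events cheaply during the loop."""

    def __init__(self) -> None:
        self.steps: list[np.ndarray] = []
        self.neurons: list[np.ndarray] = []

    def add(self, step: int, spike_mask: np.ndarray) -> None:
        flat = np.flatnonzero(spike_mask.ravel())
        if flat.size:
            self.neurons.append(flat)
            self.steps.append(np.full(flat.size, step, dtype=np.int64))

    def raster(self, dt: float, n_neurons: int, duration: float) -> SpikeRaster:
        if self.steps:
            steps = np.concatenate(self.steps)
            neurons = np.concatenate(self.neurons)
        else:
            steps = neurons = np.empty(0, dtype=np.int64)
        return SpikeRaster.from_step_events(
            steps, neurons, dt, n_neurons, duration
        )


def run_circuit(
    config: CircuitConfig,
    d1_pool: StriatalPool | None = None,
    d2_pool: StriatalPool | None = None,
) -> SimulationResult:
    """Co-simulate the STN-GPe-GPi circuit with optional striatal drive.

    With both pools None the STN-GPe loop free-runs on its tonic
    currents (the synchrony-characterization protocol). Deterministic
    for a fixed config seed.
    """
    config.validate()
    shape = config.shape
    n = shape[0] * shape[1]
    dt = config.dt
    da = config.da
    n_steps = int(round(config.duration / dt))

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(5)
    rng_init = np.random.default_rng(seeds[0])
    rng_d1 = np.random.default_rng(seeds[1])
    rng_d2 = np.random.default_rng(seeds[2])

    stn = init_lattice("STN", shape, seed=rng_init, jitter=config.jitter)
    gpe = init_lattice("GPe", shape, seed=rng_init, jitter=config.jitter)
    gpi = (
        init_lattice("GPi", shape, seed=rng_init, jitter=config.jitter)
        if config.simulate_gpi else None
    )
    if config.stn_lesion is not None:
        i0, i1, j0, j1 = config.stn_lesion
        stn.alive_mask[i0:i1, j0:j1] = False
        dead = ~stn.alive_mask
        stn.v[dead] = stn.params.c
        stn.u[dead] = stn.params.b * stn.params.c

    # dopamine-dependent scalars and kernels (fixed within a run)
    cd1 = striatal_gain(da, "D1")
    cd2 = striatal_gain(da, "D2")
    w_sg = da_scaled_weight(config.w_sg, da)
    w_gs = da_scaled_weight(config.w_gs, da)
    k_stn = build_lateral_kernel(
        "STN", da, mapping=config.radius_mapping,
        floor=config.radius_floor, amplitude=config.a_stn,
    )
    k_gpe = build_lateral_kernel(
        "GPe", da, mapping=config.radius_mapping,
        floor=config.radius_floor, amplitude=config.a_gpe,
    )

    # gating variables, one per (presynaptic population, receptor) pair
    h_stn_ampa = SynapseState.zeros(shape, AMPA)
    h_stn_nmda = SynapseState.zeros(shape, NMDA)
    h_stn_nmda_gpi = SynapseState.zeros(shape, NMDA_GPI)
    h_gpe_gaba = SynapseState.zeros(shape, GABA)
    h_d1 = SynapseState.zeros(shape, GABA, W=config.w_strd1_gpi,
                              impulse="saturating")
    h_d2 = SynapseState.zeros(shape, GABA, W=config.w_strd2_gpe,
                              impulse="saturating")

    prev_stn = np.zeros(shape)
    prev_gpe = np.zeros(shape)
    prev_d1 = np.zeros(shape)
    prev_d2 = np.zeros(shape)

    ev_stn, ev_gpe, ev_gpi = _EventBuffer(), _EventBuffer(), _EventBuffer()
    ev_d1, ev_d2 = _EventBuffer(), _EventBuffer()

    zero = np.zeros(shape)
    for step in range(n_steps):
        t = step * dt
        # (1) striatal spikes for this step (applied next step)
        if d1_pool is not None:
            s_d1 = d1_pool.sample_step(t, dt, rng_d1).reshape(shape)
            ev_d1.add(step, s_d1)
        else:
            s_d1 = zero
        if d2_pool is not None:
            s_d2 = d2_pool.sample_step(t, dt, rng_d2).reshape(shape)
            ev_d2.add(step, s_d2)
        else:
            s_d2 = zero

        # (2) gating from the previous step's spikes
        update_gating(h_stn_ampa, prev_stn, dt)
        update_gating(h_stn_nmda, prev_stn, dt)
        update_gating(h_gpe_gaba, prev_gpe, dt)
        if gpi is not None:
            update_gating(h_stn_nmda_gpi, prev_stn, dt)
            update_gating(h_d1, prev_d1, dt)
        update_gating(h_d2, prev_d2, dt)

        # (3) per-nucleus current assembly; a soft-start ramp scales all
        # synaptic currents up over the first `ramp_ms` so the common
        # initial transient cannot lock the loop into a runaway state
        ramp = min(1.0, (t + dt) / config.ramp_ms) if config.ramp_ms else 1.0
        rect = (
            (lambda I: np.minimum(I, 0.0)) if config.gaba_rectified
            else (lambda I: I)
        )
        b_gpe = mg_block(gpe.v)
        I_gpe = ramp * (
            rect(lateral_current(k_gpe, h_gpe_gaba.h, gpe.v, GABA))
            + w_sg * h_stn_ampa.h * (AMPA.E_rev - gpe.v)
            + w_sg * h_stn_nmda.h * (NMDA.E_rev - gpe.v) * b_gpe
            + cd2 * rect(receptor_current(h_d2, gpe.v))
        )
        I_stn = ramp * (
            rect(w_gs * h_gpe_gaba.h * (GABA.E_rev - stn.v))
            + lateral_current(k_stn, h_stn_ampa.h, stn.v, AMPA)
            + lateral_current(k_stn, h_stn_nmda.h, stn.v, NMDA)
        )

        # (4)-(5) integrate and detect
        try:
            sp_stn = step_lattice(stn, I_stn, dt, scheme=config.scheme)
            sp_gpe = step_lattice(gpe, I_gpe, dt, scheme=config.scheme)
            if gpi is not None:
                I_gpi = cd1 * rect(receptor_current(h_d1, gpi.v))
                if not config.ip_removed:
                    I_gpi = I_gpi + (
                        config.w_stn_gpi * h_stn_ampa.h
                        * (AMPA.E_rev - gpi.v)
                        + config.w_stn_gpi * h_stn_nmda_gpi.h
                        * (NMDA.E_rev - gpi.v) * mg_block(gpi.v)
                    )
                sp_gpi = step_lattice(gpi, ramp * I_gpi, dt,
                                      scheme=config.scheme)
                ev_gpi.add(step, sp_gpi)
        except NumericalBlowupError as err:
            raise NumericalBlowupError(dt, step) from err

        ev_stn.add(step, sp_stn)
        ev_gpe.add(step, sp_gpe)
        prev_stn, prev_gpe = sp_stn, sp_gpe
        prev_d1, prev_d2 = s_d1, s_d2

    dur = config.duration
    return SimulationResult(
        stn=ev_stn.raster(dt, n, dur),
        gpe=ev_gpe.raster(dt, n, dur),
        gpi=ev_gpi.raster(dt, n, dur) if gpi is not None else None,
        striatum_d1=ev_d1.raster(dt, n, dur) if d1_pool is not None else None,
        striatum_d2=ev_d2.raster(dt, n, dur) if d2_pool is not None else None,
        config=config,
    )


def connectivity_table(config: CircuitConfig) -> "pd.DataFrame":
    """Effective connectivity dump for audit, as a flat table.

    One row per synapse: one-to-one inter-nucleus projections plus the
    within-nucleus collateral stencils at the config's dopamine level,
    with columns (source_nucleus, i, j, target_nucleus, p, q, receptor,
    weight). Lesioned STN sources are omitted.
    """
    import pandas as pd

    config.validate()
    rows_i, rows_j = np.indices(config.shape)
    flat_i, flat_j = rows_i.ravel(), rows_j.ravel()
    da = config.da
    alive = np.ones(config.shape, dtype=bool)
    if config.stn_lesion is not None:
        i0, i1, j0, j1 = config.stn_lesion
        alive[i0:i1, j0:j1] = False
    frames = []

    def one_to_one(src, dst, receptor, weight, src_alive=None):
        keep = np.ones(flat_i.size, bool) if src_alive is None \
            else src_alive.ravel()
        frames.append(pd.DataFrame({
            "source_nucleus": src, "i": flat_i[keep], "j": flat_j[keep],
            "target_nucleus": dst, "p": flat_i[keep], "q": flat_j[keep],
            "receptor": receptor, "weight": weight,
        }))

    w_sg = da_scaled_weight(config.w_sg, da)
    w_gs = da_scaled_weight(config.w_gs, da)
    one_to_one("STN", "GPe", "AMPA", w_sg, alive)
    one_to_one("STN", "GPe", "NMDA", w_sg, alive)
    one_to_one("GPe", "STN", "GABA", w_gs)
    if not config.ip_removed:
        one_to_one("STN", "GPi", "AMPA", config.w_stn_gpi, alive)
        one_to_one("STN", "GPi", "NMDA", config.w_stn_gpi, alive)
    one_to_one("StrD1", "GPi", "GABA",
               config.w_strd1_gpi * striatal_gain(da, "D1"))
    one_to_one("StrD2", "GPe", "GABA",
               config.w_strd2_gpe * striatal_gain(da, "D2"))

    for nucleus, receptors, amp, src_alive in (
        ("STN", ("AMPA", "NMDA"), config.a_stn, alive),
        ("GPe", ("GABA",), config.a_gpe, None),
    ):
        kern = build_lateral_kernel(
            nucleus, da, mapping=config.radius_mapping,
            floor=config.radius_floor, amplitude=amp,
        )
        half = kern.weights.shape[0] // 2
        offs = [(di, dj) for di in range(-half, half + 1)
                for dj in range(-half, half + 1)
                if kern.weights[half + di, half + dj] > 0]
        for di, dj in offs:
            p, q = flat_i + di, flat_j + dj
            keep = (p >= 0) & (p < config.shape[0]) \
                & (q >= 0) & (q < config.shape[1])
            if src_alive is not None:
                keep &= src_alive.ravel()
            frames.append(pd.DataFrame({
                "source_nucleus": nucleus,
                "i": flat_i[keep], "j": flat_j[keep],
                "target_nucleus": nucleus, "p": p[keep], "q": q[keep],
                "receptor": "/".join(receptors),
                "weight": kern.weights[half + di, half + dj],
            }))
    return pd.concat(frames, ignore_index=True)
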