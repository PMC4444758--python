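"""Synaptic machinery: receptor gating, currents, Mg block, lateral kernels.

Every projection in the circuit is a first-order gated synapse,

    tau dh/dt = -h + S(t),          (gating; S = presynaptic spikes)
    I = W * h * (E_rev - V_post),   (receptor current)

with NMDA currents additionally multiplied by the Jahr-Stevens
voltage-dependent magnesium block B(V). Collaterals within STN and GPe
use a Gaussian distance kernel whose radius is modulated by dopamine,
and the STN<->GPe projection weights are linearly attenuated by
dopamine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import params as P


@dataclass(frozen=True)
class ReceptorParams:
    """Kinetics of one receptor channel: decay tau (ms), reversal (mV)."""

    kind: str  # "AMPA" | "NMDA" | "GABA"
    tau: float
    E_rev: float


AMPA = ReceptorParams("AMPA", P.TAU_AMPA, P.E_AMPA)
NMDA = ReceptorParams("NMDA", P.TAU_NMDA, P.E_NMDA)
GABA = ReceptorParams("GABA", P.TAU_GABA, P.E_GABA)
NMDA_GPI = ReceptorParams("NMDA", P.TAU_NMDA_GPI, P.E_NMDA)


@dataclass
class SynapseState:
    """Per-neuron gating of one projection plus its base weight.

    ``impulse`` selects how a presynaptic spike enters the gating ODE:

    - ``"euler"`` (default): S = 1 on the spike step, h += dt*(S-h)/tau.
      On the native 1 ms grid each spike deposits ~1/tau of gate. Used
      for spikes of individual model neurons (all intra-pallidal and
      subthalamic projections).
    - ``"saturating"``: a spike drives the gate to 1, after which it
      decays with tau. Used for the striatal projections, where each
      spike train stands for a correlated assembly of medium spiny
      neurons converging on its target, so a volley transiently
      saturates the postsynaptic GABA conductance.
    """

    receptor: ReceptorParams
    h: np.ndarray
    W: float = 1.0
    impulse: str = "euler"

    @classmethod
    def zeros(
        cls, shape, receptor: ReceptorParams, W: float = 1.0,
        impulse: str = "euler",
    ) -> "SynapseState":
        return cls(receptor, np.zeros(shape, dtype=np.float64), W, impulse)


def update_gating(
    state: SynapseState, presyn_spikes: np.ndarray, dt: float
) -> SynapseState:
    """Advance the gating variable one step in place; returns the state.

    See :class:`SynapseState` for the two spike-impulse conventions.
    h stays within [0, 1] under both.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    h = state.h
    if state.impulse == "euler":
        h += dt * (presyn_spikes - h) / state.receptor.tau
    elif state.impulse == "saturating":
        h *= 1.0 - dt / state.receptor.tau
        np.maximum(h, presyn_spikes, out=h)
    else:
        raise ValueError(f"unknown impulse convention {state.impulse!r}")
    return state


def mg_block(V: np.ndarray | float, mg: float = P.MG_CONCENTRATION):
    """Jahr-Stevens magnesium block of the NMDA channel.

    B(V) = 1 / (1 + (Mg / 3.57) * exp(-0.062 V)); strictly increasing
    in V with range (0, 1).
    """
    if mg <= 0:
        raise ValueError("Mg concentration must be positive")
    return 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * np.asarray(V, float)))


def receptor_current(
    state: SynapseState,
    V_post: np.ndarray,
    gain: float = 1.0,
) -> np.ndarray:
    """Current ``gain * W * h * (E_rev - V)``, Mg-blocked for NMDA."""
    I = gain * state.W * state.h * (state.receptor.E_rev - V_post)
    if state.receptor.kind == "NMDA":
        I = I * mg_block(V_post)
    return I


# ---------------------------------------------------------------------------
# Dopamine-modulated scalar gains
# ---------------------------------------------------------------------------

def da_scaled_weight(base_w: float, da: float, cd2: float = P.CD2_WEIGHT):
    """Dopamine attenuation of STN<->GPe weights: W = (1 - cd2*DA) * w."""
    return (1.0 - cd2 * da) * base_w


def striatal_gain(da: float, branch: str) -> float:
    """Dopaminergic gain on striatal GABA currents.

    D1 (direct pathway, onto GPi) increases with dopamine,
    cD1 = A_D1 / (1 + exp(-lambda*(DA-1))); D2 (indirect pathway, onto
    GPe) decreases, cD2 = A_D2 / (1 + exp(lambda*DA)).
    """
    if branch == "D1":
        return P.A_D1 / (1.0 + np.exp(-P.LAMBDA_STR * (da - 1.0)))
    if branch == "D2":
        return P.A_D2 / (1.0 + np.exp(P.LAMBDA_STR * da))
    raise ValueError(f"unknown striatal branch {branch!r}")


# ---------------------------------------------------------------------------
# Dopamine-dependent Gaussian lateral kernels
# ---------------------------------------------------------------------------

def _radius_as_printed(nucleus: str, da: float, floor: float) -> float:
    if nucleus == "STN":
        return P.R_S * (P.CD21 * da)
    return P.R_G * (1.0 - P.CD21 * da)


def _radius_swapped(nucleus: str, da: float, floor: float) -> float:
    # Direction-corrected mapping: STN collateral spread shrinks with
    # dopamine (synchrony at low DA), GPe spread grows with dopamine
    # (lateral decorrelation at high DA).
    if nucleus == "STN":
        return P.R_S * (1.0 - P.CD21 * da)
    return P.R_G * (P.CD21 * da + floor)


def _radius_full_range(nucleus: str, da: float, floor: float) -> float:
    # Same directions as "swapped" but letting DA span the whole unit
    # coefficient, so the kernels change substantially over the working
    # dopamine range instead of by a few percent.
    if nucleus == "STN":
        return P.R_S * (1.0 - da + floor)
    return P.R_G * (da + floor)


def _radius_da_linear(nucleus: str, da: float, floor: float) -> float:
    # Calibrated default: interpolate the STN radius from 5*r_s at the
    # bottom of the dopamine range down to 0.5*r_s at the top (wide
    # collateral spread -> partial synchrony at low DA), and the GPe
    # radius from 0.2*r_g up to 2*r_g (lateral decorrelation grows with
    # DA). The span covers the whole lateral stencil at low DA.
    x = (da - 0.1) / 0.8  # 0 at DA=0.1, 1 at DA=0.9
    if nucleus == "STN":
        return P.R_S * (5.0 * (1.0 - x) + 0.5 * x)
    return P.R_G * (0.2 * (1.0 - x) + 2.0 * x)


RADIUS_MAPPINGS = {
    "as_printed": _radius_as_printed,
    "swapped": _radius_swapped,
    "full_range": _radius_full_range,
    "da_linear": _radius_da_linear,
}

DEFAULT_RADIUS_MAPPING = "da_linear"


def lateral_radius(
    nucleus: str,
    da: float,
    mapping: str = DEFAULT_RADIUS_MAPPING,
    floor: float = 0.05,
) -> float:
    """Effective Gaussian radius R_m of a nucleus' collaterals at ``da``."""
    try:
        fn = RADIUS_MAPPINGS[mapping]
    except KeyError:
        raise ValueError(
            f"unknown radius mapping {mapping!r}; "
            f"expected one of {sorted(RADIUS_MAPPINGS)}"
        ) from None
    R = fn(nucleus, da, floor)
    if R <= 0:
        raise ValueError(
            f"radius mapping {mapping!r} produced non-positive R={R} "
            f"for {nucleus} at DA={da}"
        )
    return R


@dataclass
class LateralKernel:
    """Gaussian collateral stencil of one nucleus at one dopamine level.

    ``weights`` is the (nlat, nlat) stencil w = A * exp(-d^2 / R^2) with
    the self-term (d = 0) excluded; d^2 is the squared lattice distance
    from the stencil center.
    """

    nucleus: str
    amplitude: float
    effective_radius: float
    weights: np.ndarray

    def total_weight(self) -> float:
        return float(self.weights.sum())


def build_lateral_kernel(
    nucleus: str,
    da: float,
    mapping: str = DEFAULT_RADIUS_MAPPING,
    floor: float = 0.05,
    amplitude: float | None = None,
    nlat: int | None = None,
) -> LateralKernel:
    """Build the dopamine-modulated collateral stencil for STN or GPe."""
    if nucleus == "STN":
        A = P.A_STN if amplitude is None else amplitude
        n = P.NLAT_STN if nlat is None else nlat
    elif nucleus == "GPe":
        A = P.A_GPE if amplitude is None else amplitude
        n = P.NLAT_GPE if nlat is None else nlat
    else:
        raise ValueError(f"no lateral kernel for nucleus {nucleus!r}")
    R = lateral_radius(nucleus, da, mapping=mapping, floor=floor)
    half = n // 2
    off = np.arange(-half, half + 1)
    d2 = off[:, None] ** 2 + off[None, :] ** 2
    w = A * np.exp(-d2 / R**2)
    w[half, half] = 0.0  # no self-synapse
    return LateralKernel(nucleus, A, R, w)


def lateral_current(
    kernel: LateralKernel,
    h_field: np.ndarray,
    V_field: np.ndarray,
    receptor: ReceptorParams,
    gain: float = 1.0,
) -> np.ndarray:
    """Collateral current field: (kernel * h) x driving force.

    For each neuron, presynaptic gating from its stencil neighborhood is
    weighted and summed (lattice edges clip the stencil; the lattice is
    not toroidal), then multiplied by the postsynaptic driving force
    (E - V). The Mg block applies only when the receptor is NMDA.
    """
    if h_field.shape != V_field.shape:
        raise ValueError("h and V fields must share the lattice shape")
    summed = ndimage.convolve(h_field, kernel.weights, mode="constant", cval=0.0)
    I = gain * summed * (receptor.E_rev - V_field)
    if receptor.kind == "NMDA":
        I = I * mg_block(V_field)
    return I
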