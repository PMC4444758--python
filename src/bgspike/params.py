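"""Model constants and parameter containers.

All numerical defaults are the published parameter set of the spiking
basal-ganglia model this package implements: Izhikevich (a, b, c, d)
triples and tonic drive currents for STN/GPe/GPi, receptor kinetics,
inter-nucleus synaptic weights, and the dopamine-dependent gain and
lateral-kernel constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

V_PEAK = 30.0  # spike cutoff, mV

# Dopamine operating range of the model (dimensionless).
DA_MIN = 0.1
DA_MAX = 0.9


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of one Izhikevich neuron population.

    ``a`` is the recovery rate (1/ms scale), ``b`` the voltage-recovery
    coupling, ``c`` the post-spike reset potential (mV), ``d`` the
    post-spike recovery increment, ``v_peak`` the spike cutoff (mV) and
    ``I_ext`` the constant external drive (dimensionless Izhikevich
    current convention).
    """

    a: float
    b: float
    c: float
    d: float
    v_peak: float = V_PEAK
    I_ext: float = 0.0


#: Published parameter triples per nucleus.
NUCLEUS_PRESETS: dict[str, IzhikevichParams] = {
    "STN": IzhikevichParams(a=0.005, b=0.265, c=-65.0, d=1.5, I_ext=30.0),
    "GPe": IzhikevichParams(a=0.1, b=0.2, c=-65.0, d=2.0, I_ext=10.0),
    "GPi": IzhikevichParams(a=0.1, b=0.2, c=-65.0, d=2.0, I_ext=10.0),
}


def nucleus_params(name: str) -> IzhikevichParams:
    """Return the preset for ``name`` in {'STN', 'GPe', 'GPi'}."""
    try:
        return NUCLEUS_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown nucleus preset {name!r}; expected one of "
            f"{sorted(NUCLEUS_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Receptor kinetics (ms, mV)
# ---------------------------------------------------------------------------

TAU_AMPA = 6.0
TAU_NMDA = 160.0
TAU_GABA = 4.0
TAU_NMDA_GPI = 67.0  # NMDA decay onto GPi neurons

E_AMPA = 0.0
E_NMDA = 0.0
E_GABA = -60.0

MG_CONCENTRATION = 1.0  # Mg2+ concentration entering the NMDA block


# ---------------------------------------------------------------------------
# Synaptic weights and dopamine-modulation constants
# ---------------------------------------------------------------------------

W_STRD1_GPI = 0.8  # D1 striatum -> GPi GABA weight
W_STRD2_GPE = 1.0  # D2 striatum -> GPe GABA weight
W_SG = 1.0  # STN -> GPe weight
W_GS = 20.0  # GPe -> STN weight
W_STN_GPI = 1.15  # STN -> GPi weight (AMPA and NMDA alike)
CD2_WEIGHT = 0.1  # DA attenuation constant on STN<->GPe weights

A_D1 = 10.0  # amplitude of the D1-striatal gain sigmoid
A_D2 = 7.5  # amplitude of the D2-striatal gain sigmoid
LAMBDA_STR = 7.5  # slope of both striatal gain sigmoids

R_S = 1.0  # base radius of the STN lateral Gaussian
R_G = 0.5  # base radius of the GPe lateral Gaussian
CD21 = 0.1  # DA coefficient inside the lateral-radius mappings
A_STN = 0.2  # STN collateral strength
A_GPE = 1.0  # GPe collateral strength
NLAT_STN = 5  # STN lateral stencil edge (5x5 neighborhood)
NLAT_GPE = 11  # GPe lateral stencil edge (11x11 neighborhood)


@dataclass
class DopamineState:
    """Scalar dopamine level, clipped to the model's working range."""

    level: float = 0.5

    def __post_init__(self) -> None:
        if not (DA_MIN <= self.level <= DA_MAX):
            raise ValueError(
                f"DA level {self.level} outside working range "
                f"[{DA_MIN}, {DA_MAX}]"
            )


def clip_da(level: float) -> float:
    """Clip a raw dopamine value into the model's working range."""
    return min(max(level, DA_MIN), DA_MAX)


def params_dict() -> dict:
    """All model constants as one flat mapping (for config snapshots)."""
    out = {
        "v_peak": V_PEAK,
        "tau_ampa": TAU_AMPA,
        "tau_nmda": TAU_NMDA,
        "tau_gaba": TAU_GABA,
        "tau_nmda_gpi": TAU_NMDA_GPI,
        "e_ampa": E_AMPA,
        "e_nmda": E_NMDA,
        "e_gaba": E_GABA,
        "mg": MG_CONCENTRATION,
        "w_strd1_gpi": W_STRD1_GPI,
        "w_strd2_gpe": W_STRD2_GPE,
        "w_sg": W_SG,
        "w_gs": W_GS,
        "w_stn_gpi": W_STN_GPI,
        "cd2": CD2_WEIGHT,
        "a_d1": A_D1,
        "a_d2": A_D2,
        "lambda_str": LAMBDA_STR,
        "r_s": R_S,
        "r_g": R_G,
        "cd21": CD21,
        "a_stn": A_STN,
        "a_gpe": A_GPE,
        "nlat_stn": NLAT_STN,
        "nlat_gpe": NLAT_GPE,
    }
    for name, p in NUCLEUS_PRESETS.items():
        out[f"izh_{name.lower()}"] = asdict(p)
    return out
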