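# Methods and numerical conventions

This note records the model as implemented, the places where the
published description left the numerics open, what this package chose
and why, and the known gaps between this reconstruction and the
originally reported values. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Membrane model and integration

STN, GPe and GPi are lattices of two-variable quadratic
integrate-and-fire (Izhikevich) neurons with the published parameter
triples (STN: a=0.005, b=0.265, c=−65, d=1.5, I=30; GPe/GPi: a=0.1,
b=0.2, c=−65, d=2, I=10) and a +30 mV spike cutoff. The default
integrator is the canonical reference loop for this neuron model — two
half-steps for v, one full step for u, then the reset check — on its
native dt = 1 ms grid. This choice is load-bearing: the published
firing rates are properties of that scheme at that step, not of the
continuum limit. The GPe preset at I = 10 fires ≈ 64 Hz under the
canonical ms-grid loop (inside the reported 60–70 Hz range) but
≈ 131 Hz under accurate integration; no continuum-limit integrator can
reproduce the reported rate set. Plain forward Euler is available via
`scheme="euler"`; dt is configurable, but the defaults define the
model.

Two numerical guards apply. (1) The membrane is clamped at
v ≥ −300 mV: a deep floor that never touches the physiological range
but stops a runaway u–v spiral that strong GABA pulses can otherwise
seed on the coarse grid. (2) GABA currents are clipped to be
non-depolarizing (`gaba_rectified=True`): with E_GABA = −60 mV and the
GPe→STN weight of 20, explicit ms-grid integration is stiff
(conductance × dt > 1), so a strong inhibitory pulse overshoots the
reversal within one step and the spurious depolarizing driving force
on the next step fires the cell. Rectification removes the artifact at
the cost of making GABA purely shunting below −60 mV; the tradeoffs
are discussed under "Known gaps".

Initial conditions: v = c + U(0, jitter) with jitter = 1 mV by default
(configurable); u = b·v. Jitter breaks the perfect lattice symmetry
under which identical neurons would stay locked forever. Free-running
summary metrics exclude a 100 ms burn-in.

## Synapses

Every projection is a first-order gated synapse, τ dh/dt = −h + S(t),
with receptor current I = W·h·(E − V) and the Jahr–Stevens Mg²⁺ block
on NMDA currents (the printed form of the block equation is ambiguous;
the standard Jahr–Stevens reading is used). Receptor constants follow
the published table (τ_AMPA = 6, τ_NMDA = 160, τ_GABA = 4 ms, NMDA
onto GPi τ = 67 ms; E_AMPA = E_NMDA = 0, E_GABA = −60 mV), as do all
weights (w_sg = 1, w_gs = 20, w_STN→GPi = 1.15, W_StrD1→GPi = 0.8,
W_StrD2→GPe = 1). Wiring is one-to-one by lattice index for all
inter-nucleus projections; lattice edges clip the collateral stencils
(no wraparound).

Spikes enter the gating ODE in two conventions. Intra-BG projections
use a unit impulse on the spike step (h += dt·(S − h)/τ), which on the
native grid deposits ≈ 1/τ of gate per spike. The striatal projections
use a saturating convention — a spike drives h to 1, then it decays —
because each striatal train stands for a correlated assembly of medium
spiny neurons converging on one target; under the unit-impulse
convention the mean striatal gate would be ~0.03 and striatal input
would be a ~1 % perturbation of its targets, which contradicts the
task behavior the model is meant to produce.

Dopamine enters through (i) cD1 = A_D1/(1+e^(−λ(DA−1))) and
cD2 = A_D2/(1+e^(λ·DA)) on the striatal GABA currents (A_D1 = 10,
A_D2 = 7.5, λ = 7.5), (ii) W = (1 − 0.1·DA)·w on both STN↔GPe
projections, and (iii) the collateral kernel radii.

### The dopamine → kernel-radius mapping

The published radius formulas (R_s = r_s·(cD21·DA),
R_g = r_g·(1 − cD21·DA) with r_s = 1, r_g = 0.5, cD21 = 0.1) move the
radii by only a few percent across the whole dopamine range and point
the STN modulation in the direction opposite to the mechanism the
results describe. The mapping is therefore a named, configurable
strategy. Four are provided: `as_printed`, `swapped` (the same forms
with the directions exchanged), `full_range` (unit coefficient on DA),
and the calibrated default `da_linear`, which interpolates the STN
radius from 5·r_s down to 0.5·r_s and the GPe radius from 0.2·r_g up
to 2.0·r_g linearly across DA ∈ [0.1, 0.9]. The wide STN span is the
only setting found under the stabilized integration in which the
collaterals are strong enough at low dopamine to partially
phase-order the lattice, giving the reported monotone decrease of the
synchrony order parameter with dopamine together with an STN firing
rate that falls as dopamine rises; the constants were fixed once from
that qualitative requirement.

## Analysis

Spike phase is linear interpolation between bracketing spikes,
φ_j(t) = 2π(t − t_{j,k})/(t_{j,k+1} − t_{j,k}); neurons without a
bracketing pair at a query time are excluded (validity mask) rather
than assigned phase zero — silent neurons must not fake synchrony.
Phases are queried every 1 ms; reported R values are tail averages
after the burn-in. The joint STN∪GPe measure pools both populations
into one order parameter.

Population rhythms: the 1 ms binned, mean-subtracted population count
is analyzed with Welch averaging (1000-sample segments). A raw
periodogram is unusable here — its bins are exponentially distributed,
so the in-band maximum of a *flat* Poisson spectrum always towers over
the median and every raster would "oscillate". A peak is significant
when it exceeds 3× the median Welch power; the band is 2–30 Hz.

Explore/exploit synchrony contrasts use a pooled two-sample t-test on
per-trial mean R values, matching the independent-samples test of the
original analysis.

## Action selection

GPi pools (halves for two stimuli, quadrants for four) are read out as
sliding-window rates (10 ms default), normalized and reversed per time
bin: f_k = (f_max − f′_k)/f_max with f_max the largest pool rate in
that bin, and zero drive when all pools are silent. The race
integrators use the leak written in the model (no separate time
constant is published); τ defaults to 1 ms on the simulation grid and
is configurable. Integration starts at stimulus onset — the
pre-stimulus background carries no decision-relevant signal — and the
threshold is 0.15. A whole-trial variant of the pool rate (the
equation as printed averages over the full trial) is available through
the rate series, but the windowed form is the default since the
trial-resolved variability it admits is the model's exploration
mechanism.

Trials are 250 ms with the stimulus in 100–200 ms; each trial
re-initializes the network with an independent child seed, so trials
are independent replicates (only the integrators and gating would
carry over otherwise; the published protocol resets "all variables"
after each selection).

## Bandit

Arm means follow the decaying Gaussian random walk
μ_{k+1} = λμ_k + (1−λ)θ + e with payoffs ~N(μ, σ₀²) rounded and
clipped to [0, 100], μ₀ = 50. The walk constants are not printed in
the source description; the defaults (λ = 0.9836, θ = 50, σ_d = 2.8,
σ₀ = 4) follow the standard restless-bandit convention of the human
studies this task derives from and are external defaults, clearly
marked. Cortico-striatal weights start at 50/50 per arm and update
Δw^D1 = ηδ, Δw^D2 = −ηδ (η = 0.3) for the chosen arm only, so
w^D1 + w^D2 = 100 is invariant. The saliency → rate map is
rate = w/10 Hz (not published; keeps rates in the physiological
few-tens-of-Hz band). DA for trial k+1 is sig(0.2·δ_k) clipped into
[0.1, 0.9]; `clamp_delta=-20` pins the input of that map (learning
still uses the true δ), which floors DA at 0.1. No-Go trials earn no
reward and trigger no update. A trial is labeled *exploit* when the
selected arm has the highest current true mean payoff. Per-trial STN
synchrony is measured over the stimulus window. The behavioral
reference agent is a soft-max over delta-rule values
(P_i ∝ e^{βV_i}, default β = 0.1 on the payoff scale, learning rate
shared with η); its exploitation rate rises with β through the useful
range and falls again at extreme greed, as expected in a restless
environment.

## What the synthetic inputs do and do not emulate

All inputs are generated: Poisson striatal trains with exact
correlation-group structure (fully correlated saliency packets,
independent background), and the payoff walk above. Real striatal
output is neither Poisson at a fixed rate nor perfectly correlated
within a stimulus; real payoff schedules are not stationary AR(1)
walks. Passing tests therefore certify the circuit's behavior under
the idealized drive the model defines, not under biological input
statistics.

## Known gaps against the originally reported values

These are computed by `tests/test_acceptance.py` and
`scripts/acceptance.py`; the failing checks are left failing rather
than tuned away.

- **Global synchrony magnitude.** At DA = 0.1 the reconstruction
  reaches R ≈ 0.4–0.6 within STN (waves and domains under the local
  5×5 coupling) and R ≈ 0.06 within GPe, against reported values near
  1 for both. A globally phase-locked state does exist on the ms grid
  — but only as a stiff artifact regime of the unguarded explicit
  GABA coupling, with 250 Hz locked firing; with the stiffness
  removed, no parameterization of the published couplings was found
  that globally orders either lattice. The monotone *decrease* of R
  with dopamine, and the disappearance of the low-DA slow rhythm at
  high DA, are reproduced.
- **STN rate at high dopamine.** The reconstruction gives ≈ 61 Hz
  against a reported 35–40 Hz. With E_GABA = −60 mV sitting at the
  subthreshold bottleneck of the Izhikevich trajectory (the parabola
  minimum is near −62.5 mV), pallidal GABA has little leverage on STN
  under any non-artifactual integration, capping how far inhibition
  can slow it.
- **Low-DA rhythm frequency.** The significant population rhythm at
  low dopamine sits at 2–8 Hz rather than ≈ 10 Hz.
- **Task saliency coupling.** The same GABA-leverage cap limits how
  strongly striatal volleys gate GPi pools, so selection retains a
  large network-fluctuation component: the Go fraction rises and the
  No-Go fraction falls with dopamine, but indirect-pathway removal
  reduces rather than abolishes exploration, and bandit learning
  stays weak (exploitation near chance), which also keeps the
  clamped-δ "parkinsonian" exploitation below the reported 44 %.
  Exploratory trials do show higher STN synchrony than exploitative
  ones, in the reported direction.

## Problem sizes

Default study scales: 50×50 lattices for free-running
characterization (1 s, 2 s for spectra; five seeds per condition) and
a reduced 20×20 lattice for the 250 ms task trials and 300-trial
bandit sessions (three sessions per condition in the acceptance
script). The test suite runs the same protocols with fewer seeds,
trials and dopamine levels; all scales are configuration fields.
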