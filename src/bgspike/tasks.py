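"""The binary Go / Explore / No-Go action-selection task.

Protocol: a 250 ms trial in which two competing stimuli (Poisson
saliency packets at ~4 Hz and ~8 Hz) drive the upper and lower halves
of the striatal pools during a 100-200 ms window, with 1 Hz
uncorrelated background elsewhere. The GPi lattice splits into the two
corresponding pools; the race model selects the action. Selecting the
more salient stimulus is a Go, the less salient one an Explore, no
threshold crossing a No-Go. The dopamine level is swept as a parameter
to map the three behavioral regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import CircuitConfig, run_circuit
from .selection import (
    EXPLORE, GO, NO_GO, classify_outcome, gpi_pool_rates, race_integrate,
)
from .striatum import binary_stimulus_layout, lattice_halves

TRIAL_MS = 250.0
STIM_WINDOW = (100.0, 200.0)


@dataclass
class BinaryTrialResult:
    label: str  # Go | Explore | NoGo
    winner: int | None
    crossing_time: float | None
    da: float
    seed: int


def run_binary_trial(
    config: CircuitConfig,
    f1: float = 4.0,
    f2: float = 8.0,
    smoothing_window: float = 10.0,
    race_start: float | None = None,
) -> BinaryTrialResult:
    """One trial of the binary selection task at ``config.da``.

    The race integrators start accumulating at stimulus onset (the
    pre-stimulus background carries no decision-relevant signal).
    """
    cfg = replace(config, duration=TRIAL_MS, burn_in=0.0)
    d1, d2 = binary_stimulus_layout(
        f1=f1, f2=f2, window=STIM_WINDOW, shape=cfg.shape,
        duration=TRIAL_MS,
    )
    res = run_circuit(cfg, d1_pool=d1, d2_pool=d2)
    pools = lattice_halves(cfg.shape)
    rates = gpi_pool_rates(res.gpi, pools, smoothing_window=smoothing_window)
    start = STIM_WINDOW[0] if race_start is None else race_start
    race = race_integrate(
        rates.drive, dt=1.0, start_time=start, times=rates.times
    )
    label = classify_outcome(race.winner, [f1, f2])
    return BinaryTrialResult(
        label, race.winner, race.crossing_time, cfg.da, cfg.seed
    )


def binary_task_fractions(
    config: CircuitConfig,
    da_values,
    n_trials: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Go/Explore/No-Go fractions per dopamine level.

    Each trial re-initializes the network with an independent child
    seed, so trials are statistically independent replicates.
    """
    master = np.random.SeedSequence(seed)
    rows = []
    for da in da_values:
        counts = {GO: 0, EXPLORE: 0, NO_GO: 0}
        for child in master.spawn(n_trials):
            trial_seed = int(child.generate_state(1)[0] % (2**31))
            cfg = replace(config, da=float(da), seed=trial_seed)
            counts[run_binary_trial(cfg).label] += 1
        rows.append(
            {
                "da": float(da),
                "go": counts[GO] / n_trials,
                "explore": counts[EXPLORE] / n_trials,
                "nogo": counts[NO_GO] / n_trials,
                "n_trials": n_trials,
            }
        )
    return pd.DataFrame(rows)


def explore_fraction(
    config: CircuitConfig,
    da_values=(0.4, 0.5, 0.6),
    n_trials: int = 50,
    seed: int = 0,
) -> float:
    """Mean Explore fraction over intermediate dopamine levels."""
    table = binary_task_fractions(config, da_values, n_trials, seed)
    return float(table["explore"].mean())


def sweep_stn_lateral_strength(
    config: CircuitConfig,
    a_stn_values=(0.05, 0.10, 0.15, 0.20, 0.25),
    da_values=(0.4, 0.5, 0.6),
    n_trials: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Explore percentage at intermediate DA as the STN collateral
    strength is varied (the lesioned-exploration analysis)."""
    rows = []
    for a in a_stn_values:
        frac = explore_fraction(
            replace(config, a_stn=float(a)), da_values, n_trials, seed
        )
        rows.append({"a_stn": float(a), "explore": frac})
    return pd.DataFrame(rows)
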