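"""Seeded scenario generation and the dopamine-sweep experiment.

Fixtures are reduced-scale, fully seeded scenarios used by the test
suite and the demo CLI; each writes its outputs as delimited text plus
a manifest with content digests, so a re-run with the same name and
seed must reproduce the digests bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .metrics import (
    joint_sync_series, mean_firing_rate, mean_sync,
    population_oscillation_frequency, sync_series,
)
from .network import CircuitConfig, run_circuit
from .tasks import binary_task_fractions, run_binary_trial
from .bandit import records_frame, run_bandit_session

FIXTURE_NAMES = ("tiny_lattice", "binary_trial", "bandit_short", "sync_sweep")


def sweep_da(
    config: CircuitConfig,
    da_values=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    duration: float | None = None,
) -> pd.DataFrame:
    """Free-running STN-GPe characterization across dopamine levels.

    Returns one row per DA level with the time-averaged synchrony of
    STN, GPe and the pooled STN+GPe populations, the mean firing
    rates, and the dominant population-oscillation frequency of STN
    (NaN when no significant spectral peak exists).
    """
    rows = []
    for da in da_values:
        cfg = replace(config, da=float(da), simulate_gpi=False)
        if duration is not None:
            cfg = replace(cfg, duration=duration)
        res = run_circuit(cfg)
        burn = cfg.burn_in
        osc = (
            population_oscillation_frequency(res.stn)
            if cfg.duration >= 1000.0 else None
        )
        rows.append({
            "da": float(da),
            "r_stn": mean_sync(res.stn, burn_in=burn),
            "r_gpe": mean_sync(res.gpe, burn_in=burn),
            "r_joint": joint_sync_series(
                res.stn, res.gpe, t0=burn
            ).mean(),
            "rate_stn": mean_firing_rate(res.stn, (burn, cfg.duration)),
            "rate_gpe": mean_firing_rate(res.gpe, (burn, cfg.duration)),
            "osc_stn": osc if osc is not None else float("nan"),
        })
    return pd.DataFrame(rows)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture(name: str, seed: int, out_dir) -> dict:
    """Write one named reduced-scale scenario; returns its manifest.

    Known names: ``tiny_lattice`` (10x10 free run, 500 ms),
    ``binary_trial`` (one 250 ms selection trial), ``bandit_short``
    (25-trial bandit session), ``sync_sweep`` (coarse DA sweep).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    if name == "tiny_lattice":
        cfg = CircuitConfig(
            shape=(10, 10), duration=500.0, da=0.5, seed=seed,
            simulate_gpi=False,
        )
        res = run_circuit(cfg)
        for nucleus in ("stn", "gpe"):
            p = out / f"{nucleus}_raster.csv"
            getattr(res, nucleus).to_csv(p)
            files.append(p)
    elif name == "binary_trial":
        cfg = CircuitConfig(shape=(10, 10), da=0.5, seed=seed)
        trial = run_binary_trial(cfg)
        p = out / "trial.json"
        p.write_text(json.dumps({
            "label": trial.label,
            "winner": trial.winner,
            "crossing_time_ms": trial.crossing_time,
            "da": trial.da,
        }, indent=2))
        files.append(p)
    elif name == "bandit_short":
        cfg = CircuitConfig(shape=(10, 10))
        rec = run_bandit_session(cfg, n_trials=25, seed=seed)
        p = out / "session.csv"
        records_frame(rec).to_csv(p, index=False)
        files.append(p)
    elif name == "sync_sweep":
        cfg = CircuitConfig(
            shape=(10, 10), duration=500.0, seed=seed,
        )
        table = sweep_da(cfg, da_values=np.arange(0.1, 0.95, 0.1))
        p = out / "sweep.csv"
        table.to_csv(p, index=False)
        files.append(p)
    else:
        raise ValueError(
            f"unknown fixture {name!r}; known: {FIXTURE_NAMES}"
        )
    manifest = {
        "fixture": name,
        "seed": seed,
        "version": __version__,
        "files": {p.name: _digest(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
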