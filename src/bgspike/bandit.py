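"""Restless 4-armed bandit: environment, plasticity, and sessions.

The environment is a restless bandit: each arm's mean payoff follows a
decaying Gaussian random walk,

    mu_{i,k+1} = lam * mu_{i,k} + (1 - lam) * theta + e,   e ~ N(0, sd_d^2)

and the observed payoff is r ~ N(mu, sd_0^2), rounded and clipped to
[0, 100]. The agent is the spiking circuit: cortico-striatal weights
(one D1 and one D2 weight per arm, initialized at 50) set the striatal
quadrant saliencies, the race model selects an arm, and the
reward-prediction error delta = received - expected drives a Hebbian
update (D1 up, D2 down, learning rate eta) and is mapped through a
sigmoid to the dopamine level used on the next trial. A matched
soft-max agent on the same payoff walk serves as the behavioral
reference model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import compare_sync_groups, mean_sync, sync_series
from .network import CircuitConfig, run_circuit
from .params import clip_da
from .selection import classify_outcome, gpi_pool_rates, race_integrate
from .striatum import bandit_stimulus_layout, lattice_quadrants
from .tasks import STIM_WINDOW, TRIAL_MS

ETA = 0.3  # cortico-striatal learning rate
DELTA_SIGMOID_SLOPE = 0.2  # slope of the delta -> dopamine sigmoid


# ---------------------------------------------------------------------------
# Payoff walk
# ---------------------------------------------------------------------------

@dataclass
class PayoffWalk:
    """Decaying Gaussian random walk over arm mean payoffs.

    Default walk constants follow the restless-bandit convention of the
    human studies this task family derives from (decay 0.9836 toward a
    center of 50, diffusion SD 2.8, payoff noise SD 4); they are
    external defaults, not values fixed by this model.
    """

    n_arms: int = 4
    lam: float = 0.9836
    theta: float = 50.0
    sigma_d: float = 2.8
    sigma_0: float = 4.0
    mu: np.ndarray = field(default_factory=lambda: np.full(4, 50.0))

    def step(self, rng: np.random.Generator) -> None:
        """Diffuse all arm means by one trial."""
        e = rng.normal(0.0, self.sigma_d, size=self.n_arms)
        self.mu = self.lam * self.mu + (1.0 - self.lam) * self.theta + e

    def payoff(self, arm: int, rng: np.random.Generator) -> int:
        """Sample the (rounded, clipped) payoff of ``arm``."""
        r = rng.normal(self.mu[arm], self.sigma_0)
        return int(np.clip(np.round(r), 0, 100))

    def best_arm(self) -> int:
        return int(np.argmax(self.mu))


# ---------------------------------------------------------------------------
# Cortico-striatal plasticity and the delta -> dopamine map
# ---------------------------------------------------------------------------

@dataclass
class CorticostriatalWeights:
    """Per-arm D1/D2 saliency weights with opponent Hebbian updates."""

    w_d1: np.ndarray = field(default_factory=lambda: np.full(4, 50.0))
    w_d2: np.ndarray = field(default_factory=lambda: np.full(4, 50.0))
    eta: float = ETA

    def expected_value(self, arm: int) -> float:
        return float(self.w_d1[arm])

    def update(self, arm: int, delta: float) -> None:
        self.w_d1[arm] += self.eta * delta
        self.w_d2[arm] -= self.eta * delta


def delta_to_dopamine(delta: float, slope: float = DELTA_SIGMOID_SLOPE):
    """Map a reward-prediction error onto the dopamine working range.

    DA = 1 / (1 + exp(-slope * delta)), clipped into [0.1, 0.9].
    """
    return clip_da(1.0 / (1.0 + np.exp(-slope * delta)))


def rl_update(
    weights: CorticostriatalWeights, arm: int, reward: float
) -> tuple[float, float]:
    """Apply one reward outcome; returns (delta, next dopamine level)."""
    v = weights.expected_value(arm)
    delta = reward - v
    weights.update(arm, delta)
    return delta, delta_to_dopamine(delta)


# ---------------------------------------------------------------------------
# Network bandit session
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    trial: int
    arm: int | None  # None for a No-Go trial
    reward: float | None
    expected: float | None
    delta: float | None
    da: float
    label: str  # "exploit" | "explore" | "nogo"
    r_sync_stn: float
    best_arm: int


def run_bandit_session(
    config: CircuitConfig,
    n_trials: int = 300,
    seed: int = 0,
    walk: PayoffWalk | None = None,
    clamp_delta: float | None = None,
    rate_divisor: float = 10.0,
) -> list[TrialRecord]:
    """One session of the 4-armed bandit driven by the spiking circuit.

    Per trial: quadrant saliencies are built from the cortico-striatal
    weights (rate = w / ``rate_divisor`` Hz), the circuit runs a 250 ms
    trial at the current dopamine level, the race selects an arm, the
    payoff walk pays out, and the opponent weight update plus the
    delta->DA map set the next trial's dopamine. A No-Go trial earns no
    reward and triggers no update. ``clamp_delta`` pins the
    reward-prediction error fed to the DA map (e.g. -20 to emulate the
    dopamine-depleted condition); learning itself still uses the true
    delta. A trial is labeled "exploit" when the selected arm has the
    highest current true mean payoff.
    """
    master = np.random.SeedSequence(seed)
    walk_rng, payoff_rng, trial_ss = (
        np.random.default_rng(master.spawn(1)[0]),
        np.random.default_rng(master.spawn(1)[0]),
        master.spawn(n_trials),
    )
    if walk is None:
        walk = PayoffWalk()
    weights = CorticostriatalWeights(
        w_d1=np.full(walk.n_arms, 50.0), w_d2=np.full(walk.n_arms, 50.0)
    )
    da = (
        delta_to_dopamine(clamp_delta) if clamp_delta is not None else 0.5
    )
    pools = lattice_quadrants(config.shape)
    records: list[TrialRecord] = []
    for k in range(n_trials):
        trial_seed = int(trial_ss[k].generate_state(1)[0] % (2**31))
        cfg = replace(
            config, da=da, seed=trial_seed,
            duration=TRIAL_MS, burn_in=0.0,
        )
        d1, d2 = bandit_stimulus_layout(
            weights.w_d1, weights.w_d2,
            rate_map_fn=lambda w: np.asarray(w, float) / rate_divisor,
            window=STIM_WINDOW, shape=cfg.shape, duration=TRIAL_MS,
        )
        res = run_circuit(cfg, d1_pool=d1, d2_pool=d2)
        rates = gpi_pool_rates(res.gpi, pools, smoothing_window=10.0)
        race = race_integrate(
            rates.drive, dt=1.0, start_time=STIM_WINDOW[0],
            times=rates.times,
        )
        r_sync = mean_sync(
            res.stn, burn_in=STIM_WINDOW[0], t1=STIM_WINDOW[1]
        )
        best = walk.best_arm()
        if race.winner is None:
            records.append(TrialRecord(
                k, None, None, None, None, da, "nogo", r_sync, best
            ))
        else:
            arm = int(race.winner)
            reward = walk.payoff(arm, payoff_rng)
            expected = weights.expected_value(arm)
            delta, da_next = rl_update(weights, arm, reward)
            if clamp_delta is not None:
                da_next = delta_to_dopamine(clamp_delta)
            da = da_next
            label = "exploit" if arm == best else "explore"
            records.append(TrialRecord(
                k, arm, float(reward), expected, delta, cfg.da, label,
                r_sync, best,
            ))
        walk.step(walk_rng)
    return records


# ---------------------------------------------------------------------------
# Behavioral (soft-max) reference agent
# ---------------------------------------------------------------------------

@dataclass
class BehavioralAgent:
    """Soft-max agent over delta-rule value estimates."""

    beta: float = 0.1  # inverse temperature on the payoff scale
    learning_rate: float = ETA
    values: np.ndarray = field(default_factory=lambda: np.full(4, 50.0))

    def choice_probabilities(self) -> np.ndarray:
        z = self.beta * self.values
        z = z - z.max()
        p = np.exp(z)
        return p / p.sum()

    def choose(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.values.size, p=self.choice_probabilities()))

    def update(self, arm: int, reward: float) -> float:
        delta = reward - self.values[arm]
        self.values[arm] += self.learning_rate * delta
        return float(delta)


def behavioral_session(
    agent: BehavioralAgent,
    n_trials: int = 300,
    seed: int = 0,
    walk: PayoffWalk | None = None,
) -> list[TrialRecord]:
    """Soft-max reference run with the same labeling as the network."""
    if agent.beta <= 0:
        raise ValueError("beta must be positive")
    master = np.random.SeedSequence(seed)
    walk_rng = np.random.default_rng(master.spawn(1)[0])
    payoff_rng = np.random.default_rng(master.spawn(1)[0])
    choice_rng = np.random.default_rng(master.spawn(1)[0])
    if walk is None:
        walk = PayoffWalk()
    records = []
    for k in range(n_trials):
        arm = agent.choose(choice_rng)
        best = walk.best_arm()
        reward = walk.payoff(arm, payoff_rng)
        expected = float(agent.values[arm])
        delta = agent.update(arm, reward)
        records.append(TrialRecord(
            k, arm, float(reward), expected, delta,
            delta_to_dopamine(delta), "exploit" if arm == best else "explore",
            float("nan"), best,
        ))
        walk.step(walk_rng)
    return records


# ---------------------------------------------------------------------------
# Session metrics
# ---------------------------------------------------------------------------

def records_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def percent_exploitation(records: list[TrialRecord]) -> float:
    """Share of trials (in %) selecting the truly best arm."""
    if not records:
        raise ValueError("empty session")
    n_exploit = sum(r.label == "exploit" for r in records)
    return 100.0 * n_exploit / len(records)


def session_metrics(
    records: list[TrialRecord],
    behavioral: list[TrialRecord] | None = None,
) -> dict:
    """Summary statistics of one or more concatenated sessions.

    Returns percent exploitation, mean |delta| over rewarded trials,
    mean per-trial STN synchrony split by explore/exploit label, and,
    when a matched behavioral run on the same walk is supplied, the
    per-trial expected-value discrepancy e = V_net - V_behavioral.
    """
    if not records:
        raise ValueError("empty session")
    df = records_frame(records)
    out = {
        "percent_exploitation": percent_exploitation(records),
        "mean_abs_delta": float(df["delta"].abs().mean()),
        "n_nogo": int((df["label"] == "nogo").sum()),
    }
    for label in ("exploit", "explore"):
        vals = df.loc[df["label"] == label, "r_sync_stn"]
        out[f"mean_r_sync_{label}"] = (
            float(vals.mean()) if len(vals) else float("nan")
        )
    if behavioral is not None:
        db = records_frame(behavioral)
        n = min(len(df), len(db))
        e = (
            df["expected"].to_numpy()[:n] - db["expected"].to_numpy()[:n]
        )
        e = e[~np.isnan(e.astype(float))]
        out["mean_abs_e_bebg"] = float(np.abs(e).mean())
    return out


def sync_label_comparison(records: list[TrialRecord]):
    """Two-sample t-test of STN synchrony: explore vs exploit trials."""
    df = records_frame(records)
    a = df.loc[df["label"] == "explore", "r_sync_stn"].dropna()
    b = df.loc[df["label"] == "exploit", "r_sync_stn"].dropna()
    return compare_sync_groups(a, b)


def sweep_pathway_weights(
    config: CircuitConfig,
    axis: str,
    values,
    n_trials: int = 300,
    n_sessions: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent exploitation as one pathway weight is varied.

    ``axis`` is ``"w_strd1_gpi"`` (direct pathway, exploitation rises
    with it) or ``"w_stn_gpi"`` (indirect pathway, exploitation falls).
    """
    if axis not in ("w_strd1_gpi", "w_stn_gpi"):
        raise ValueError("axis must be 'w_strd1_gpi' or 'w_stn_gpi'")
    rows = []
    for value in values:
        cfg = replace(config, **{axis: float(value)})
        pct = []
        for s in range(n_sessions):
            rec = run_bandit_session(
                cfg, n_trials=n_trials, seed=seed + 1000 * s
            )
            pct.append(percent_exploitation(rec))
        rows.append({
            axis: float(value),
            "percent_exploitation": float(np.mean(pct)),
            "sd": float(np.std(pct)),
        })
    return pd.DataFrame(rows)
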