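"""Generative simulation of cued-recall saccade datasets.

Trials are simulated at the event level from the same mechanisms the
likelihood tabulates analytically: Poisson spiking at the (delay-adjusted)
effective gain is integrated to the spike threshold, giving the Erlang
latency component; each accumulated spike survives decay with probability
set by its age; the surviving spikes are decoded by vector summation, with
spike directions drawn from the von Mises tuning profile (the dense-tiling
limit of the neuron population, which is what the analytic error density
describes); drift adds a von Mises increment; the observable latency adds
the shifted-exponential residual.

Datasets follow the experimental design: set sizes {1, 2, 4} crossed with
delays {0.5, 1, 2, 4} s, item locations on a circle with >= 30 deg
separation, a small fraction of swap and uniform lapses, and a configurable
fraction of trials violating each saccade-quality filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .population import InvalidParameterError, wrap_angle
from .latency import spike_survival_prob
from .mechanisms import drift_concentration, effective_gain
from .likelihood import ParameterSet
from .classification import TRIAL_COLUMNS, write_trials_csv

__all__ = [
    "GeneratorConfig",
    "default_truth_params",
    "sample_array",
    "simulate_responses",
    "simulate_trial",
    "generate_dataset",
    "save_dataset",
]

MIN_SEPARATION_DEG = 30.0


_TRUTH_BY_VARIANT = {
    # gamma, m, kappa, tau, nu, o, mechanism parameter
    "linear_decay": (95.2, 7, 22.0, 0.18, 9.2, 0.21, 0.16),
    "exp_decay": (98.7, 7, 22.2, 0.18, 9.3, 0.21, 0.017),
    "const_drift": (99.5, 7, 26.0, 0.14, 9.2, 0.21, 3415.0),
    "setsize_drift": (94.2, 7, 31.9, 0.44, 9.3, 0.21, 4637.0),
}


def default_truth_params(variant: str = "setsize_drift") -> ParameterSet:
    """Generating parameters at the group-level estimates for each variant.

    Each variant uses its own fitted column (gain ~ 95-100 spikes/s, m = 7
    spikes, kappa ~ 22-32, tau ~ 0.14-0.44 s, nu ~ 9.2/s, o = 0.21 s, and
    the mechanism parameter at its group mean), so simulated data sit in
    the regime the task produces under that mechanism.
    """
    gamma, m, kappa, tau, nu, o, mech_param = _TRUTH_BY_VARIANT[variant]
    return ParameterSet.from_values(gamma=gamma, m=m, kappa=kappa, tau=tau,
                                    nu=nu, o=o, variant=variant,
                                    mech_param=mech_param)


@dataclass
class GeneratorConfig:
    """Design and ground truth of a synthetic experiment.

    Defaults mirror the study design: a 3 x 4 factorial of set size and
    delay with ~24 trials per cell per participant, lapse rates of 2.2%
    (swaps) and 0.4% (uniform guesses), and a total ~20% of trials
    violating the saccade-quality filters (split evenly across the five
    filter types).
    """

    participants: int = 10
    trials_per_cell: int = 24
    set_sizes: tuple = (1, 2, 4)
    delays: tuple = (0.5, 1.0, 2.0, 4.0)
    params: ParameterSet = field(default_factory=default_truth_params)
    p_swap: float = 0.022
    p_uniform: float = 0.004
    exclusion_rates: dict = field(default_factory=lambda: {
        "latency-too-early": 0.04, "latency-too-late": 0.04,
        "amplitude": 0.04, "deflection": 0.04, "blink": 0.04})
    seed: int = 0

    def __post_init__(self):
        rates = [self.p_swap, self.p_uniform, *self.exclusion_rates.values()]
        if any(r < 0 or r > 1 for r in rates) or sum(rates) >= 1:
            raise InvalidParameterError(
                "lapse and exclusion rates must lie in [0, 1] and sum to < 1"
            )
        if self.trials_per_cell < 1:
            raise InvalidParameterError("trials_per_cell must be >= 1")


def sample_array(set_size: int, seed) -> np.ndarray:
    """Item angles in degrees, uniform with pairwise separation >= 30 deg."""
    if set_size < 1:
        raise InvalidParameterError(f"set_size must be >= 1, got {set_size}")
    rng = np.random.default_rng(seed)
    while True:
        angles = rng.uniform(0.0, 360.0, size=set_size)
        if set_size == 1:
            return angles
        diffs = np.abs(angles[:, None] - angles[None, :])
        diffs = np.minimum(diffs, 360.0 - diffs)
        np.fill_diagonal(diffs, np.inf)
        if diffs.min() >= MIN_SEPARATION_DEG:
            return angles


def simulate_responses(params: ParameterSet, set_size: int, t_d: float,
                       n: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-level simulation of ``n`` target responses in one condition.

    Returns ``(error_rad, latency_s, k)``: the angular response error
    relative to the encoded value, the response latency, and the number of
    surviving spikes decoded on each trial.
    """
    rng = np.random.default_rng(rng)
    gamma_eff = effective_gain(params.pop.gain, params.mech, t_d)
    if gamma_eff <= 0:
        raise InvalidParameterError("effective gain is 0; no spikes to integrate")
    rho = gamma_eff / set_size
    m = params.lat.threshold
    t_m = rng.gamma(shape=m, scale=1.0 / rho, size=n)
    if m > 1:
        ps = spike_survival_prob(t_m, params.lat.survival_tau)
        k = 1 + rng.binomial(m - 1, ps)
    else:
        k = np.ones(n, dtype=int)
    # decode: resultant direction of k von Mises spike directions per trial
    total = int(k.sum())
    angles = rng.vonmises(0.0, params.pop.kappa, size=total)
    starts = np.concatenate(([0], np.cumsum(k)[:-1]))
    zc = np.add.reduceat(np.cos(angles), starts)
    zs = np.add.reduceat(np.sin(angles), starts)
    err = np.arctan2(zs, zc)
    chi = drift_concentration(params.mech, t_d, set_size)
    if np.isfinite(chi):
        err = wrap_angle(err + rng.vonmises(0.0, chi, size=n))
    latency = t_m + params.lat.offset + rng.exponential(
        1.0 / params.lat.residual_rate, size=n)
    return err, latency, k


def _clean_saccade_fields(rng, n):
    return {
        "saccade_amplitude_fraction": rng.uniform(0.85, 1.15, size=n),
        "correction_deflection": rng.uniform(0.0, 10.0, size=n),
        "blink": np.zeros(n, dtype=bool),
    }


_CLASSES = ("target", "nontarget", "uniform")


def _simulate_cell(config: GeneratorConfig, participant: str, set_size: int,
                   t_d: float, n: int, rng) -> tuple[pd.DataFrame, dict]:
    """Simulate one participant's trials in one condition cell."""
    err, lat, _ = simulate_responses(config.params, set_size, t_d, n, rng)
    arrays = [sample_array(set_size, rng) for _ in range(n)]
    # lapse classes; swaps require a nontarget, so at N = 1 swap mass
    # is folded back into target responses
    p_swap = config.p_swap if set_size > 1 else 0.0
    probs = [1.0 - p_swap - config.p_uniform, p_swap, config.p_uniform]
    cls = rng.choice(3, size=n, p=probs)
    resp = np.empty(n)
    for i in range(n):
        target = arrays[i][0]
        if cls[i] == 0:
            resp[i] = (target + np.rad2deg(err[i])) % 360.0
        elif cls[i] == 1:
            nt = arrays[i][1 + rng.integers(set_size - 1)]
            # lapse responses reuse the same error machinery about the swapped item
            resp[i] = (nt + np.rad2deg(err[i])) % 360.0
        else:
            resp[i] = rng.uniform(0.0, 360.0)
    fields = _clean_saccade_fields(rng, n)
    # inject exclusion violations (first matching rule wins downstream)
    types = list(config.exclusion_rates)
    p_types = np.array([config.exclusion_rates[t] for t in types])
    draw = rng.choice(len(types) + 1, size=n,
                      p=np.concatenate(([1 - p_types.sum()], p_types)))
    valid = draw == 0
    for i in np.nonzero(~valid)[0]:
        t = types[draw[i] - 1]
        if t == "latency-too-early":
            lat[i] = rng.uniform(0.03, 0.149)
        elif t == "latency-too-late":
            lat[i] = rng.uniform(2.01, 2.6)
        elif t == "amplitude":
            fields["saccade_amplitude_fraction"][i] = (
                rng.uniform(1.51, 1.9) if rng.random() < 0.5
                else rng.uniform(0.15, 0.49))
        elif t == "deflection":
            fields["correction_deflection"][i] = rng.uniform(15.1, 45.0)
        elif t == "blink":
            fields["blink"][i] = True
    df = pd.DataFrame({
        "participant": participant,
        "experiment": "1",
        "set_size": set_size,
        "delay": t_d,
        "target_angle": [a[0] for a in arrays],
        "nontarget_angles": [list(a[1:]) for a in arrays],
        "response_angle": resp,
        "latency": lat,
        "saccade_amplitude_fraction": fields["saccade_amplitude_fraction"],
        "correction_deflection": fields["correction_deflection"],
        "blink": fields["blink"],
    })
    truth = {
        "true_class": [_CLASSES[c] for c in cls],
        "true_valid": valid.tolist(),
    }
    return df, truth


def simulate_trial(config: GeneratorConfig, set_size: int, t_d: float, seed):
    """Simulate a single trial; returns a :class:`TrialRecord`-style Series."""
    rng = np.random.default_rng(seed)
    df, truth = _simulate_cell(config, "p00", set_size, t_d, 1, rng)
    row = df.iloc[0].copy()
    row["true_class"] = truth["true_class"][0]
    row["true_valid"] = truth["true_valid"][0]
    return row


def generate_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Full factorial synthetic dataset plus ground-truth sidecar.

    Every participant contributes ``trials_per_cell`` trials to each
    (set size, delay) cell.  The sidecar holds the generating parameters
    and per-trial class and validity labels (aligned with the row order of
    the trial table); lapse-trial latencies are drawn from the same latency
    model as target trials, which the sidecar flags as a modeling
    simplification.
    """
    frames, classes, valids = [], [], []
    seeds = np.random.SeedSequence(config.seed).spawn(config.participants)
    for p in range(config.participants):
        rng = np.random.default_rng(seeds[p])
        name = f"p{p + 1:02d}"
        for n_items in config.set_sizes:
            for t_d in config.delays:
                df, truth = _simulate_cell(config, name, int(n_items),
                                           float(t_d), config.trials_per_cell,
                                           rng)
                frames.append(df)
                classes.extend(truth["true_class"])
                valids.extend(truth["true_valid"])
    trials = pd.concat(frames, ignore_index=True)
    truth = {
        "params": config.params.to_dict(),
        "design": {
            "participants": config.participants,
            "trials_per_cell": config.trials_per_cell,
            "set_sizes": list(config.set_sizes),
            "delays": list(config.delays),
        },
        "lapse_rates": {"swap": config.p_swap, "uniform": config.p_uniform},
        "exclusion_rates": dict(config.exclusion_rates),
        "seed": config.seed,
        "true_class": classes,
        "true_valid": valids,
        "notes": "lapse latencies are drawn from the target latency model",
    }
    return trials, truth


def save_dataset(trials: pd.DataFrame, truth: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trials_csv(trials[TRIAL_COLUMNS], outdir / "trials.csv")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
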