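"""Per-trial and per-dataset log-likelihood under any delay-mechanism variant.

The joint likelihood of a trial's (response error, latency) pair is the
product of the marginal error density and the marginal latency density for
its (set size, delay) condition.  Errors and latencies share the gain and
threshold parameters but are otherwise driven by disjoint parameter subsets
(kappa, tau and the drift parameter shape only the error factor; nu and o
only the latency factor), which the grid search exploits.

Densities are tabulated once per condition cell and evaluated at trial
observations by linear interpolation on the density scale, floored at 1e-12
before taking logs so that quadrature zeros do not produce spurious -inf.
A latency below the offset o is genuinely outside the model support and
does return -inf (flagged per trial in the detailed output).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .population import (
    DENSITY_FLOOR,
    ErrorDistribution,
    InvalidParameterError,
    PopulationParams,
    default_error_grid,
    error_dist_marginal,
    wrap_angle,
)
from .latency import (
    LatencyDistribution,
    LatencyParams,
    default_time_grid,
    latency_pdf,
    surviving_spike_dist,
)
from .mechanisms import DelayMechanism, apply_drift, drift_concentration, effective_gain
from .classification import wrap_deg

__all__ = [
    "ParameterSet",
    "DegenerateGainError",
    "condition_densities",
    "trial_loglik",
    "dataset_loglik",
    "DatasetEvaluator",
    "error_loglik_terms",
    "latency_loglik_terms",
]

FREE_PARAM_NAMES = ("gamma", "m", "kappa", "tau", "nu", "o", "mech_param")


class DegenerateGainError(InvalidParameterError):
    """Effective gain reached zero; the model cannot emit a response."""


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter vector: population + latency + delay mechanism.

    Seven free parameters: the six of the basic model (gamma, m, kappa,
    tau, nu, o) plus the one mechanism parameter.
    """

    pop: PopulationParams
    lat: LatencyParams
    mech: DelayMechanism

    @classmethod
    def from_values(cls, gamma, m, kappa, tau, nu, o, variant, mech_param,
                    n_neurons: int = 64, relative_slope: bool = False):
        return cls(
            pop=PopulationParams(gain=float(gamma), kappa=float(kappa),
                                 n_neurons=n_neurons),
            lat=LatencyParams(threshold=int(round(m)), residual_rate=float(nu),
                              offset=float(o), survival_tau=float(tau)),
            mech=DelayMechanism(variant=variant, param=float(mech_param),
                                relative_slope=relative_slope),
        )

    def to_dict(self) -> dict:
        return {
            "gamma": self.pop.gain, "m": self.lat.threshold,
            "kappa": self.pop.kappa, "tau": self.lat.survival_tau,
            "nu": self.lat.residual_rate, "o": self.lat.offset,
            "variant": self.mech.variant, "mech_param": self.mech.param,
        }

    def signature(self) -> tuple:
        d = self.to_dict()
        return tuple(d[k] for k in ("gamma", "m", "kappa", "tau", "nu", "o",
                                    "variant", "mech_param"))


def condition_densities(
    params: ParameterSet,
    set_size: int,
    t_d: float,
    *,
    error_grid: np.ndarray | None = None,
    time_grid: np.ndarray | None = None,
    psi_grid: int | None = None,
    n_quad: int = 2000,
) -> tuple[ErrorDistribution, LatencyDistribution]:
    """Error and latency densities for one (set size, delay) condition.

    Pipeline: effective gain under the delay mechanism, surviving-spike
    distribution, error mixture over k, drift convolution; and in parallel
    the latency convolution at the effective gain.
    """
    ev = DatasetEvaluator(params, error_grid=error_grid, time_grid=time_grid,
                          psi_grid=psi_grid, n_quad=n_quad)
    return ev.densities(set_size, t_d)


class DatasetEvaluator:
    """Caches condition densities and intermediate steps for one ParameterSet.

    Intermediate results that are shared across delays at a fixed set size
    under drift variants (the spike-count distribution and the pre-drift
    error density depend only on the effective gain) are memoized so a
    drift-variant likelihood over 12 cells costs only 3 base densities.
    """

    def __init__(self, params: ParameterSet, *, error_grid=None, time_grid=None,
                 psi_grid=None, n_quad: int = 2000):
        self.params = params
        self.error_grid = default_error_grid() if error_grid is None else error_grid
        self.time_grid = default_time_grid() if time_grid is None else time_grid
        self.psi_kwargs = {} if psi_grid is None else {"psi_grid": int(psi_grid)}
        self.n_quad = int(n_quad)
        self._base_error: dict = {}
        self._latency: dict = {}
        self._cells: dict = {}

    def _gamma_eff(self, t_d: float) -> float:
        g = effective_gain(self.params.pop.gain, self.params.mech, t_d)
        if g <= 0:
            raise DegenerateGainError(
                f"effective gain is 0 at t_d={t_d}; no responses can be generated"
            )
        return g

    def _base_error_dist(self, gamma_eff: float, set_size: int) -> ErrorDistribution:
        key = (gamma_eff, set_size)
        if key not in self._base_error:
            pop_eff = replace(self.params.pop, gain=gamma_eff)
            kdist = surviving_spike_dist(pop_eff, self.params.lat, set_size,
                                         n_quad=self.n_quad)
            self._base_error[key] = error_dist_marginal(
                kdist, self.params.pop.kappa, self.error_grid, **self.psi_kwargs)
        return self._base_error[key]

    def _latency_dist(self, gamma_eff: float, set_size: int) -> LatencyDistribution:
        key = (gamma_eff, set_size)
        if key not in self._latency:
            pop_eff = replace(self.params.pop, gain=gamma_eff)
            self._latency[key] = latency_pdf(pop_eff, self.params.lat, set_size,
                                             self.time_grid)
        return self._latency[key]

    def densities(self, set_size: int, t_d: float):
        key = (set_size, t_d)
        if key not in self._cells:
            g = self._gamma_eff(t_d)
            err = self._base_error_dist(g, set_size)
            chi = drift_concentration(self.params.mech, t_d, set_size)
            err = apply_drift(err, chi)
            lat = self._latency_dist(g, set_size)
            self._cells[key] = (err, lat)
        return self._cells[key]

    def cell_loglik(self, set_size, t_d, error_rad, latency):
        """Summed log-likelihood of arrays of (error, latency) observations."""
        err, lat = self.densities(set_size, t_d)
        return (error_loglik_terms(err, error_rad)
                + latency_loglik_terms(lat, latency, self.params.lat.offset))


def error_loglik_terms(err_dist: ErrorDistribution, error_rad) -> np.ndarray:
    """Per-trial log error densities (floored before the log)."""
    return np.log(np.maximum(err_dist.interp(error_rad), DENSITY_FLOOR))


def latency_loglik_terms(lat_dist: LatencyDistribution, latency, offset) -> np.ndarray:
    """Per-trial log latency densities; -inf below the offset support."""
    ll = np.log(np.maximum(lat_dist.interp(latency), DENSITY_FLOOR))
    return np.where(np.asarray(latency) < offset, -np.inf, ll)


def _trial_arrays(trials: pd.DataFrame):
    err = np.deg2rad(wrap_deg(trials["response_angle"].to_numpy(float)
                              - trials["target_angle"].to_numpy(float)))
    lat = trials["latency"].to_numpy(float)
    return err, lat


def trial_loglik(params: ParameterSet, trial, evaluator: DatasetEvaluator | None = None,
                 **kwargs) -> float:
    """Log-density of a single trial's (error, latency) pair.

    ``trial`` is a mapping/Series/record with set_size, delay, target_angle,
    response_angle (degrees) and latency (seconds).  Returns -inf when the
    latency lies below the offset o (outside the model support).
    """
    get = (trial.get if isinstance(trial, (dict, pd.Series))
           else lambda k: getattr(trial, k))
    ev = evaluator or DatasetEvaluator(params, **kwargs)
    err = np.deg2rad(wrap_deg(float(get("response_angle")) - float(get("target_angle"))))
    ll = ev.cell_loglik(int(get("set_size")), float(get("delay")),
                        np.array([err]), np.array([float(get("latency"))]))
    return float(ll[0])


def dataset_loglik(params: ParameterSet, trials: pd.DataFrame,
                   evaluator: DatasetEvaluator | None = None,
                   return_trials: bool = False, **kwargs):
    """Summed log-likelihood over a trial table (densities built per cell).

    With ``return_trials=True`` also returns a DataFrame with per-trial
    log-likelihoods and a ``below_offset`` diagnostic flag (latencies below
    the offset o are a candidate for reducing o during fitting).
    """
    if len(trials) == 0:
        raise InvalidParameterError("trial table is empty")
    ev = evaluator or DatasetEvaluator(params, **kwargs)
    ll_all = np.empty(len(trials))
    for (n, td), idx in trials.groupby(["set_size", "delay"]).indices.items():
        cell = trials.iloc[idx]
        err, lat = _trial_arrays(cell)
        ll_all[idx] = ev.cell_loglik(int(n), float(td), err, lat)
    total = float(np.sum(ll_all))
    if return_trials:
        detail = pd.DataFrame({
            "loglik": ll_all,
            "below_offset": trials["latency"].to_numpy(float) < params.lat.offset,
        }, index=trials.index)
        return total, detail
    return total
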