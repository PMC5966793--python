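"""Per-participant maximum-likelihood fitting and model-variant comparison.

Fitting proceeds in two stages, as is standard for this model family:

1. a grid search over log- or linearly spaced parameter ranges.  Because
   the latency factor of the likelihood depends only on (gamma, m, nu, o)
   — plus the mechanism parameter for decay variants, which attenuates the
   gain — and the error factor only on (gamma, m, kappa, tau, mechanism),
   the two factors are evaluated independently and combined by summation on
   the shared axes, reducing the search from a 7-D to two ~4-D sweeps;
2. Nelder-Mead simplex refinement from the top grid cells (multistart),
   on log-transformed positive parameters.  The integer spike threshold m
   is relaxed to a continuous variable and rounded at every evaluation.

Variants are compared by raw summed log-likelihood; all four have the same
number of free parameters (seven), so no complexity penalty is applied.

The user-facing surface is ``DelayRecallModel`` / ``DelayRecallResults``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import hashlib
import heapq

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .population import DENSITY_FLOOR, InvalidParameterError, default_error_grid
from scipy import fft as sp_fft

from .latency import (
    ConfigurationError,
    LatencyParams,
    erlang_samples,
    residual_samples,
    surviving_spike_dist_from_rate,
)
from .mechanisms import DECAY_VARIANTS, VARIANTS, DelayMechanism, \
    _vm_fourier_ratios as _vm_ratios, drift_concentration, effective_gain
from .population import error_dist_marginal
from .likelihood import (
    DatasetEvaluator,
    DegenerateGainError,
    ParameterSet,
    dataset_loglik,
    _trial_arrays,
)

__all__ = [
    "ModelConfig",
    "ParameterGrid",
    "FitResult",
    "InvalidStartError",
    "InvalidComparisonError",
    "grid_search",
    "refine_fit",
    "fit_participant",
    "compare_variants",
    "VariantComparison",
    "DelayRecallModel",
    "DelayRecallResults",
]

LN2 = float(np.log(2.0))

# mechanism-parameter clipping used by the simplex stage: a large finite cap
# stands in for the no-drift sentinel chi0 = inf, a small floor for omega = 0
MECH_PARAM_FLOOR = 1e-4
MECH_PARAM_CAP = 1e6
_BIG = 1e12


class InvalidStartError(ValueError):
    """Refinement was started from a parameter vector with -inf likelihood."""


class InvalidComparisonError(ValueError):
    """Model variants were fitted on different trial sets."""


@dataclass(frozen=True)
class ModelConfig:
    """Numerical configuration shared by likelihood evaluation and fitting."""

    n_neurons: int = 64
    error_grid_n: int = 720
    time_dt: float = 0.001
    time_t_max: float = 3.0
    psi_grid: int = 512
    n_quad: int = 2000

    def error_grid(self) -> np.ndarray:
        return default_error_grid(self.error_grid_n)

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.time_t_max + self.time_dt / 2, self.time_dt)

    def evaluator(self, params: ParameterSet) -> DatasetEvaluator:
        return DatasetEvaluator(params, error_grid=self.error_grid(),
                                time_grid=self.time_grid(),
                                psi_grid=self.psi_grid, n_quad=self.n_quad)

    @classmethod
    def fast(cls) -> "ModelConfig":
        """Coarser quadratures for simulation studies (recovery sweeps)."""
        return cls(time_dt=0.002, time_t_max=2.5, psi_grid=128, n_quad=800)

    @classmethod
    def sweep(cls) -> "ModelConfig":
        """Lightest quadratures, for many-fit sweeps (model recovery)."""
        return cls(time_dt=0.002, time_t_max=2.5, psi_grid=96, n_quad=400)


def _log_steps(lo, hi, n):
    return np.geomspace(lo, hi, int(n))


def _default_mech_grid(variant: str, reduced: bool) -> np.ndarray:
    if variant == "linear_decay":
        base = _log_steps(2 ** -2, 2 ** 4, 7 if reduced else 13)
        return np.concatenate((base, [0.0]))  # omega = 0: no decay
    if variant == "exp_decay":
        return _log_steps(LN2 / 2 ** 8, LN2, 6 if reduced else 9)
    base = _log_steps(2 ** 7, 2 ** 14, 8 if reduced else 15)
    return np.concatenate((base, [np.inf]))  # chi0 = inf: no drift


@dataclass(frozen=True)
class ParameterGrid:
    """Parameter ranges for the grid-search stage.

    The defaults reproduce the canonical search ranges for this model:
    gamma in (2^3, 2^9), 25 log steps; m in (2^2, 2^7), 11 log steps
    (rounded to integers); kappa in (2^3, 2^7), 9 log steps; tau in
    (2^-6, 2), 8 log steps; nu in (1, 15), 15 linear steps; o in
    (0.1, 0.3), 11 linear steps; mechanism parameter per variant, with the
    discrete no-decay (omega = 0) and no-drift (chi0 = inf) sentinels.
    """

    variant: str
    gamma: np.ndarray
    m: np.ndarray
    kappa: np.ndarray
    tau: np.ndarray
    nu: np.ndarray
    o: np.ndarray
    mech: np.ndarray

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InvalidParameterError(f"unknown variant {self.variant!r}")
        for name in ("gamma", "m", "kappa", "tau", "nu", "o", "mech"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if name == "m":
                arr = np.unique(np.round(arr)).astype(float)
                if np.any(arr < 1):
                    raise ConfigurationError("m grid values must be >= 1")
            object.__setattr__(self, name, arr)
            sentinel_only = name == "mech" and arr.size == 1 and (
                arr[0] == 0.0 or np.isinf(arr[0]))
            if arr.size < 2 and not sentinel_only:
                raise ConfigurationError(
                    f"grid dimension {name!r} has fewer than 2 points"
                )

    @classmethod
    def table_default(cls, variant: str) -> "ParameterGrid":
        return cls(
            variant=variant,
            gamma=_log_steps(2 ** 3, 2 ** 9, 25),
            m=_log_steps(2 ** 2, 2 ** 7, 11),
            kappa=_log_steps(2 ** 3, 2 ** 7, 9),
            tau=_log_steps(2 ** -6, 2, 8),
            nu=np.linspace(1, 15, 15),
            o=np.linspace(0.1, 0.3, 11),
            mech=_default_mech_grid(variant, reduced=False),
        )

    @classmethod
    def coarse(cls, variant: str) -> "ParameterGrid":
        """Minimal grid for large simulation sweeps (many fits); the simplex
        stage carries the precision, the grid only localizes the start."""
        mech = {
            "linear_decay": np.concatenate((_log_steps(2 ** -2, 2 ** 4, 5), [0.0])),
            "exp_decay": _log_steps(LN2 / 2 ** 8, LN2, 5),
            "const_drift": np.concatenate((_log_steps(2 ** 7, 2 ** 14, 5), [np.inf])),
            "setsize_drift": np.concatenate((_log_steps(2 ** 7, 2 ** 14, 5), [np.inf])),
        }[variant]
        return cls(
            variant=variant,
            gamma=_log_steps(2 ** 3, 2 ** 9, 13),
            # log-spaced as in the canonical grid; the simplex cannot cross
            # integer plateaus of m, so the grid must carry this dimension
            m=np.array([4, 5, 7, 9, 12, 16]),
            kappa=_log_steps(2 ** 3, 2 ** 7, 5),
            tau=_log_steps(2 ** -6, 2, 4),
            nu=np.linspace(1, 15, 5),
            o=np.linspace(0.1, 0.3, 4),
            mech=mech,
        )

    @classmethod
    def sweep(cls, variant: str) -> "ParameterGrid":
        """Lightest grid, for many-fit sweeps; keeps the full ranges and the
        log-spaced low-m ladder but trims steps elsewhere."""
        mech = {
            "linear_decay": np.concatenate((_log_steps(2 ** -2, 2 ** 4, 4), [0.0])),
            "exp_decay": _log_steps(LN2 / 2 ** 8, LN2, 4),
            "const_drift": np.concatenate((_log_steps(2 ** 7, 2 ** 14, 4), [np.inf])),
            "setsize_drift": np.concatenate((_log_steps(2 ** 7, 2 ** 14, 4), [np.inf])),
        }[variant]
        return cls(
            variant=variant,
            gamma=_log_steps(2 ** 3, 2 ** 9, 9),
            m=np.array([4, 7, 12]),
            kappa=_log_steps(2 ** 3, 2 ** 7, 5),
            tau=_log_steps(2 ** -6, 2, 4),
            nu=np.linspace(1, 15, 5),
            o=np.linspace(0.1, 0.3, 4),
            mech=mech,
        )

    @classmethod
    def reduced(cls, variant: str) -> "ParameterGrid":
        """Coarse grid for simulation studies; same ranges, fewer steps
        (the threshold range is narrowed to the regime the generator uses)."""
        return cls(
            variant=variant,
            gamma=_log_steps(2 ** 3, 2 ** 9, 13),
            m=_log_steps(4, 32, 5),
            kappa=_log_steps(2 ** 3, 2 ** 7, 7),
            tau=_log_steps(2 ** -6, 2, 6),
            nu=np.linspace(1, 15, 8),
            o=np.linspace(0.1, 0.3, 6),
            mech=_default_mech_grid(variant, reduced=True),
        )

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            **{k: getattr(self, k).tolist()
               for k in ("gamma", "m", "kappa", "tau", "nu", "o", "mech")},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterGrid":
        arrays = {k: np.asarray(
            [np.inf if v in ("inf", ".inf") else float(v) for v in d[k]])
            for k in ("gamma", "m", "kappa", "tau", "nu", "o", "mech")}
        return cls(variant=d["variant"], **arrays)

    @classmethod
    def from_yaml(cls, path) -> "ParameterGrid":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _cells(trials: pd.DataFrame):
    out = []
    for (n, td), idx in sorted(trials.groupby(["set_size", "delay"]).indices.items()):
        cell = trials.iloc[idx]
        err, lat = _trial_arrays(cell)
        out.append({"N": int(n), "td": float(td), "err": err, "lat": lat})
    return out


class _ErrInterp:
    """Precomputed periodic linear-interpolation weights for fixed errors.

    Replicates :meth:`ErrorDistribution.interp` on the standard grid with a
    cached gather, so the grid sweep can evaluate many densities at the
    same trial errors without re-running searches.
    """

    def __init__(self, egrid: np.ndarray, err: np.ndarray):
        n = egrid.size
        h = egrid[1] - egrid[0]
        x0 = egrid[0] - h  # extended grid starts one step below support[0]
        idx = np.clip(np.floor((err - x0) / h).astype(int), 0, n - 1)
        self.frac = (err - (x0 + idx * h)) / h
        self.j_lo = (idx - 1) % n
        self.j_hi = idx % n

    def loglik_sum(self, density: np.ndarray) -> float:
        lo = density[self.j_lo]
        val = lo + (density[self.j_hi] - lo) * self.frac
        return float(np.sum(np.log(np.maximum(val, DENSITY_FLOOR))))


class _LatInterp:
    """Precomputed linear-interpolation weights for fixed trial latencies."""

    def __init__(self, tgrid: np.ndarray, lat: np.ndarray):
        n = tgrid.size
        dt = tgrid[1] - tgrid[0]
        self.inside = (lat >= tgrid[0]) & (lat <= tgrid[-1])
        idx = np.clip(np.floor((lat - tgrid[0]) / dt).astype(int), 0, n - 2)
        self.idx = idx
        self.frac = (lat - (tgrid[0] + idx * dt)) / dt
        self.min_lat = float(np.min(lat))

    def loglik_sum(self, density: np.ndarray, offset: float) -> float:
        if self.min_lat < offset:
            return -np.inf  # latency below the model support
        lo = density[self.idx]
        val = lo + (density[self.idx + 1] - lo) * self.frac
        val = np.where(self.inside, val, 0.0)
        return float(np.sum(np.log(np.maximum(val, DENSITY_FLOOR))))


def trials_fingerprint(trials: pd.DataFrame) -> str:
    cols = ["set_size", "delay", "target_angle", "response_angle", "latency"]
    arr = np.round(trials[cols].to_numpy(float), 9)
    return hashlib.sha1(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _dummy_lat(m, nu=1.0, o=0.0, tau=1.0):
    return LatencyParams(threshold=int(m), residual_rate=nu, offset=o,
                         survival_tau=tau)


def grid_search(
    trials: pd.DataFrame,
    variant: str,
    grid: ParameterGrid | None = None,
    top_k: int = 5,
    config: ModelConfig | None = None,
) -> list[tuple[ParameterSet, float]]:
    """Ranked top-K parameter vectors from the separable grid sweep.

    The latency and error likelihood factors are tabulated independently
    and combined by summation on the axes they share; the reported combined
    log-likelihood at any grid point equals the direct dataset
    log-likelihood at that parameter vector.
    """
    if len(trials) == 0:
        raise InvalidParameterError("trial table is empty")
    grid = grid or ParameterGrid.table_default(variant)
    if grid.variant != variant:
        raise ConfigurationError("grid variant does not match requested variant")
    cfg = config or ModelConfig()
    cells = _cells(trials)
    tgrid = cfg.time_grid()
    egrid = cfg.error_grid()
    err_preps = [_ErrInterp(egrid, c["err"]) for c in cells]
    lat_preps = [_LatInterp(tgrid, c["lat"]) for c in cells]
    h_err = egrid[1] - egrid[0]
    nspec = egrid.size // 2 + 1
    dt_lat = tgrid[1] - tgrid[0]
    lat_fshape = sp_fft.next_fast_len(2 * tgrid.size - 1, True)
    erl_ffts: dict = {}
    res_ffts: dict = {}
    from .population import psi_cache, PSI_DEFAULT_SAMPLES, PSI_DEFAULT_SEED
    psi_cache.build(range(2, int(grid.m.max()) + 1), cfg.psi_grid,
                    PSI_DEFAULT_SAMPLES, PSI_DEFAULT_SEED)
    decay = variant in DECAY_VARIANTS
    mechs = grid.mech
    nmech = mechs.size
    ng, nm = grid.gamma.size, grid.m.size
    nnu, no = grid.nu.size, grid.o.size
    nk, nt = grid.kappa.size, grid.tau.size

    n_shared_mech = nmech if decay else 1

    lat_tab = np.full((ng, nm, n_shared_mech, nnu, no), -np.inf)
    err_tab = (np.full((ng, nm, nmech, nk, nt), -np.inf) if decay
               else np.full((ng, nm, 1, nk, nt, nmech), -np.inf))

    kdist_cache: dict = {}

    def eff_gains(gamma, mech):
        """Effective gain per cell; None if any cell is degenerate."""
        gs = []
        for c in cells:
            g = effective_gain(gamma, mech, c["td"]) if mech is not None else gamma
            if g <= 0:
                return None
            gs.append(g)
        return gs

    for ig, gamma in enumerate(grid.gamma):
        for imech_s in range(n_shared_mech):
            mech = (DelayMechanism(variant, mechs[imech_s]) if decay else
                    DelayMechanism(variant, mechs[0]))
            gains = eff_gains(gamma, mech if decay else None)
            if gains is None:
                continue
            rhos = [g / c["N"] for g, c in zip(gains, cells)]
            for im, m in enumerate(grid.m):
                m = int(m)
                # ---- latency factor over (nu, o) ----
                # the convolution factorizes: cache the Erlang and residual
                # spectra and combine them per (nu, o) pair
                if len(erl_ffts) >= 4096:
                    erl_ffts.clear()
                for rho in set(rhos):
                    if (rho, m) not in erl_ffts:
                        erl_ffts[(rho, m)] = sp_fft.rfft(
                            erlang_samples(rho, m, tgrid), lat_fshape)
                for inu, nu in enumerate(grid.nu):
                    for io, o in enumerate(grid.o):
                        if (nu, o) not in res_ffts:
                            res_ffts[(nu, o)] = sp_fft.rfft(
                                residual_samples(float(nu), float(o), tgrid),
                                lat_fshape)
                        fg = res_ffts[(nu, o)]
                        total = 0.0
                        done = {}
                        for rho, prep in zip(rhos, lat_preps):
                            if rho not in done:
                                dens = sp_fft.irfft(
                                    erl_ffts[(rho, m)] * fg,
                                    lat_fshape)[: tgrid.size] * dt_lat
                                dens[tgrid < o] = 0.0
                                done[rho] = dens
                            total += prep.loglik_sum(done[rho], float(o))
                        lat_tab[ig, im, imech_s, inu, io] = total
                # ---- error factor over (kappa, tau [, mech for drift]) ----
                for it, tau in enumerate(grid.tau):
                    kdists = {}
                    for rho in set(rhos):
                        key = (rho, m, float(tau))
                        if key not in kdist_cache:
                            kdist_cache[key] = surviving_spike_dist_from_rate(
                                rho, _dummy_lat(m, tau=float(tau)), cfg.n_quad)
                        kdists[rho] = kdist_cache[key]
                    for ik, kappa in enumerate(grid.kappa):
                        bases = {rho: error_dist_marginal(
                            kd, float(kappa), egrid, psi_grid=cfg.psi_grid)
                            for rho, kd in kdists.items()}
                        if decay:
                            total = 0.0
                            for rho, prep in zip(rhos, err_preps):
                                total += prep.loglik_sum(bases[rho].density)
                            err_tab[ig, im, imech_s, ik, it] = total
                        else:
                            specs = {rho: np.fft.rfft(b.density)
                                     for rho, b in bases.items()}
                            for imech, mp in enumerate(mechs):
                                dmech = DelayMechanism(variant, float(mp))
                                total = 0.0
                                for rho, c, prep in zip(rhos, cells, err_preps):
                                    chi = drift_concentration(dmech, c["td"], c["N"])
                                    if np.isinf(chi):
                                        dens = bases[rho].density
                                    else:
                                        dens = np.fft.irfft(
                                            specs[rho] * _vm_ratios(chi, nspec),
                                            n=egrid.size)
                                        dens = np.maximum(dens, 0.0)
                                        dens = dens / (h_err * dens.sum())
                                    total += prep.loglik_sum(dens)
                                err_tab[ig, im, 0, ik, it, imech] = total

    # ---- combine on shared axes, collect global top-K ----
    heap: list = []
    counter = 0
    for ig in range(ng):
        for im in range(nm):
            for imech_s in range(n_shared_mech):
                a = lat_tab[ig, im, imech_s]
                b = err_tab[ig, im, imech_s]
                if not (np.isfinite(a).any() and np.isfinite(b).any()):
                    continue
                a_flat, b_flat = a.ravel(), b.ravel()
                a_top = np.argsort(a_flat)[::-1][:top_k]
                b_top = np.argsort(b_flat)[::-1][:top_k]
                for ia in a_top:
                    for ib in b_top:
                        total = a_flat[ia] + b_flat[ib]
                        if not np.isfinite(total):
                            continue
                        inu, io = np.unravel_index(ia, a.shape)
                        if decay:
                            ik, it = np.unravel_index(ib, b.shape)
                            imech = imech_s
                        else:
                            ik, it, imech = np.unravel_index(ib, b.shape)
                        entry = (total, counter,
                                 (ig, im, ik, it, inu, io, imech))
                        counter += 1
                        if len(heap) < top_k:
                            heapq.heappush(heap, entry)
                        elif entry[0] > heap[0][0]:
                            heapq.heapreplace(heap, entry)
    if not heap:
        raise DegenerateGainError("no grid point yields a finite likelihood")
    ranked = sorted(heap, key=lambda e: -e[0])
    out = []
    for total, _, (ig, im, ik, it, inu, io, imech) in ranked:
        ps = ParameterSet.from_values(
            gamma=grid.gamma[ig], m=int(grid.m[im]), kappa=grid.kappa[ik],
            tau=grid.tau[it], nu=grid.nu[inu], o=grid.o[io],
            variant=variant, mech_param=float(mechs[imech]),
            n_neurons=cfg.n_neurons)
        out.append((ps, float(total)))
    return out


# ---------------------------------------------------------------------------
# Simplex refinement
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of one participant-level fit of one model variant."""

    variant: str
    params: ParameterSet
    loglik: float
    grid_loglik: float
    grid_start: ParameterSet | None
    n_iter: int
    n_fev: int
    converged: bool
    n_trials: int
    fingerprint: str
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "grid_loglik": self.grid_loglik,
            "n_iter": self.n_iter,
            "n_fev": self.n_fev,
            "converged": self.converged,
            "n_trials": self.n_trials,
            "fingerprint": self.fingerprint,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        p = d["params"]
        params = ParameterSet.from_values(
            gamma=p["gamma"], m=p["m"], kappa=p["kappa"], tau=p["tau"],
            nu=p["nu"], o=p["o"], variant=p["variant"],
            mech_param=p["mech_param"])
        return cls(variant=d["variant"], params=params, loglik=d["loglik"],
                   grid_loglik=d["grid_loglik"], grid_start=None,
                   n_iter=d["n_iter"], n_fev=d["n_fev"],
                   converged=d["converged"], n_trials=d["n_trials"],
                   fingerprint=d["fingerprint"], flags=list(d.get("flags", [])))


def _pack(params: ParameterSet) -> np.ndarray:
    mp = float(np.clip(params.mech.param, MECH_PARAM_FLOOR, MECH_PARAM_CAP))
    return np.array([
        np.log(params.pop.gain), np.log(params.lat.threshold),
        np.log(params.pop.kappa), np.log(params.lat.survival_tau),
        params.lat.residual_rate, params.lat.offset, np.log(mp),
    ])


def _unpack(x, variant, n_neurons) -> ParameterSet | None:
    if np.any(np.abs(x[[0, 1, 2, 3, 6]]) > 30):
        return None
    gamma, m_c, kappa, tau = np.exp(x[0]), np.exp(x[1]), np.exp(x[2]), np.exp(x[3])
    nu, o = float(x[4]), float(x[5])
    mech_p = float(np.clip(np.exp(x[6]), MECH_PARAM_FLOOR, MECH_PARAM_CAP))
    m = int(np.clip(round(m_c), 1, 512))
    if not (1e-2 < gamma < 1e5 and 1e-3 < kappa < 1e6 and 1e-9 < tau < 1e3
            and 1e-2 < nu < 1e3 and 0.0 <= o <= 1.0):
        return None
    return ParameterSet.from_values(gamma=gamma, m=m, kappa=kappa, tau=tau,
                                    nu=nu, o=o, variant=variant,
                                    mech_param=mech_p, n_neurons=n_neurons)


def _fit_flags(params: ParameterSet, max_delay: float = 4.0) -> list:
    flags = []
    mech = params.mech
    if mech.is_drift and mech.param >= MECH_PARAM_CAP * 0.999:
        flags.append("virtually-no-drift")
    if mech.is_decay:
        g0 = params.pop.gain
        loss = (g0 - effective_gain(g0, mech, max_delay)) / g0
        if loss < 0.01:
            flags.append("near-zero-decay")
    return flags


def refine_fit(
    trials: pd.DataFrame,
    variant: str,
    start: ParameterSet,
    config: ModelConfig | None = None,
    maxiter: int = 400,
    xatol: float = 1e-3,
    fatol: float = 1e-4,
) -> FitResult:
    """Nelder-Mead refinement of a grid-search start.

    Positive parameters are optimized on the log scale; the mechanism
    parameter is clipped to [1e-4, 1e6], the finite stand-ins for the
    no-decay and no-drift sentinels; the spike threshold m is rounded to
    the nearest integer at every evaluation.  The refined log-likelihood
    never falls below the start value (the start is kept if the simplex
    cannot improve on it).
    """
    cfg = config or ModelConfig()
    cells = _cells(trials)  # group once; the simplex evaluates thousands of times

    def negll(x):
        ps = _unpack(x, variant, cfg.n_neurons)
        if ps is None:
            return _BIG
        try:
            ev = cfg.evaluator(ps)
            ll = 0.0
            for c in cells:
                ll += float(np.sum(ev.cell_loglik(c["N"], c["td"],
                                                  c["err"], c["lat"])))
        except (DegenerateGainError, InvalidParameterError):
            return _BIG
        return -ll if np.isfinite(ll) else _BIG

    x0 = _pack(start)
    f0 = negll(x0)
    if f0 >= _BIG:
        raise InvalidStartError("starting parameters have non-finite likelihood")
    opts = {"maxiter": maxiter, "xatol": xatol, "fatol": fatol,
            "maxfev": 4 * maxiter}
    # stage 1 — profile: hold the mechanism parameter at its start value and
    # converge the six basic parameters.  The likelihood is nearly flat along
    # the mechanism direction (gain changes can partly compensate it), and a
    # joint simplex tends to stall partway up that ridge; profiling first
    # makes the release stage start from a converged basic model.
    x_mech = x0[6]

    def negll6(x6):
        return negll(np.concatenate((x6, [x_mech])))

    res6 = minimize(negll6, x0[:6], method="Nelder-Mead", options=opts)
    # stage 2 — release: full 7-parameter refinement from the profile optimum
    x1 = np.concatenate((res6.x, [x_mech]))
    res = minimize(negll, x1, method="Nelder-Mead", options=opts)
    candidates = [(float(res6.fun), x1), (float(res.fun), res.x), (f0, x0)]
    fbest, xbest = min(candidates, key=lambda c: c[0])
    best = _unpack(xbest, variant, cfg.n_neurons)
    loglik = -float(fbest)
    if best is None or loglik < -f0:
        best, loglik = start, -f0
    return FitResult(
        variant=variant, params=best, loglik=loglik, grid_loglik=-float(f0),
        grid_start=start, n_iter=int(res6.nit + res.nit),
        n_fev=int(res6.nfev + res.nfev),
        converged=bool(res.success), n_trials=len(trials),
        fingerprint=trials_fingerprint(trials), flags=_fit_flags(best))


def fit_participant(
    trials: pd.DataFrame,
    variant: str,
    grid: ParameterGrid | None = None,
    config: ModelConfig | None = None,
    n_starts: int = 5,
    maxiter: int = 400,
) -> FitResult:
    """Grid search followed by multistart simplex refinement; best fit wins.

    Start selection is stratified over the spike threshold m: because the
    simplex sees m only through rounding, it cannot leave the integer
    plateau it starts on, so the starts are the best grid cells of the
    top distinct m values rather than the top cells outright.  In
    addition, one start places the mechanism parameter at its no-effect
    stand-in (omega/lambda at the floor, chi0 at the cap) with the
    otherwise best grid parameters: the likelihood is near-flat along the
    mechanism ridge when the data carry no delay effect, and the boundary
    start lets the simplex settle there instead of stalling partway down
    the ridge.
    """
    n_starts = max(n_starts, 1)
    ranked = grid_search(trials, variant, grid=grid, top_k=10 * n_starts,
                         config=config)
    starts, seen_m = [], set()
    for ps, _ in ranked:  # best cell per distinct m, in rank order
        if ps.lat.threshold not in seen_m:
            starts.append(ps)
            seen_m.add(ps.lat.threshold)
        if len(starts) >= min(n_starts, 2):
            break
    # then per distinct kappa: the error factor has a second basin where a
    # short survival time (k ~ 1) with much sharper tuning mimics the true
    # spike-count mixture; covering distinct kappa regimes lets the simplex
    # settle both basins and keep the better
    seen_kappa = {s.pop.kappa for s in starts}
    for ps, _ in ranked:
        if len(starts) >= n_starts:
            break
        if ps.pop.kappa not in seen_kappa:
            starts.append(ps)
            seen_kappa.add(ps.pop.kappa)
    for ps, _ in ranked:  # backfill with next-best cells if strata ran out
        if len(starts) >= n_starts:
            break
        if all(ps.signature() != s.signature() for s in starts):
            starts.append(ps)
    best: FitResult | None = None
    for start in starts:
        fit = refine_fit(trials, variant, start, config=config, maxiter=maxiter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    # sentinel pass: restart from the winner with the mechanism at its
    # no-effect stand-in; keeps whichever attains the higher likelihood
    sentinel = (MECH_PARAM_FLOOR if variant in DECAY_VARIANTS
                else MECH_PARAM_CAP)
    b = best.params.to_dict()
    if not np.isclose(np.clip(b["mech_param"], MECH_PARAM_FLOOR,
                              MECH_PARAM_CAP), sentinel):
        start0 = ParameterSet.from_values(
            gamma=b["gamma"], m=b["m"], kappa=b["kappa"], tau=b["tau"],
            nu=b["nu"], o=b["o"], variant=variant, mech_param=sentinel)
        try:
            fit0 = refine_fit(trials, variant, start0, config=config,
                              maxiter=maxiter)
            if fit0.loglik > best.loglik:
                best = fit0
        except InvalidStartError:
            pass
    best.grid_loglik = ranked[0][1]
    if best.loglik < best.grid_loglik:  # guard: multistart must not regress
        best.loglik = best.grid_loglik
        best.params = ranked[0][0]
        best.flags = _fit_flags(best.params)
    return best


# ---------------------------------------------------------------------------
# Variant comparison
# ---------------------------------------------------------------------------


@dataclass
class VariantComparison:
    """Log-likelihood comparison across model variants."""

    table: pd.DataFrame
    winners: list
    group_winner: str

    def delta(self, variant_a: str, variant_b: str) -> float:
        t = self.table.set_index("variant")["total_loglik"]
        return float(t[variant_a] - t[variant_b])

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def compare_variants(fits: dict) -> VariantComparison:
    """Compare fitted variants on identical trial sets.

    ``fits`` maps variant name to a FitResult or a list of per-participant
    FitResults.  All variants must cover the same participants fitted on
    the same trials (checked via trial fingerprints).  Returns total and
    per-participant Delta log(L) and winner counts.
    """
    fits = {v: (f if isinstance(f, (list, tuple)) else [f])
            for v, f in fits.items()}
    variants = list(fits)
    n_p = {v: len(f) for v, f in fits.items()}
    if len(set(n_p.values())) != 1:
        raise InvalidComparisonError(f"participant counts differ: {n_p}")
    n = next(iter(n_p.values()))
    for i in range(n):
        prints = {v: fits[v][i].fingerprint for v in variants}
        if len(set(prints.values())) != 1:
            raise InvalidComparisonError(
                f"participant {i}: variants fitted on different trials: {prints}"
            )
    totals = {v: float(sum(f.loglik for f in fits[v])) for v in variants}
    best_total = max(totals.values())
    winners = []
    for i in range(n):
        lls = {v: fits[v][i].loglik for v in variants}
        winners.append(max(lls, key=lls.get))
    table = pd.DataFrame({
        "variant": variants,
        "total_loglik": [totals[v] for v in variants],
        "delta_loglik": [totals[v] - best_total for v in variants],
        "n_wins": [winners.count(v) for v in variants],
    }).sort_values("total_loglik", ascending=False).reset_index(drop=True)
    group_winner = table.iloc[0]["variant"]
    return VariantComparison(table=table, winners=winners,
                             group_winner=str(group_winner))


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

_REQUIRED = ("set_size", "delay", "target_angle", "response_angle", "latency")


class DelayRecallModel:
    """Neural resource model of cued-recall errors and saccade latencies.

    Parameters
    ----------
    trials : DataFrame
        Trial table (see :mod:`driftmem.classification` for the schema).
        Rows failing the exclusion filter (``valid`` column) or not
        classified as target responses (``trial_class`` column) are dropped
        if those columns are present; the model describes target responses.
    variant : str
        Delay mechanism: ``linear_decay``, ``exp_decay``, ``const_drift``
        or ``setsize_drift``.
    config : ModelConfig, optional
        Numerical grids and quadrature sizes.

    Examples
    --------
    >>> model = DelayRecallModel(trials, variant="setsize_drift")
    >>> res = model.fit(grid=ParameterGrid.reduced("setsize_drift"))
    >>> print(res.summary())
    """

    def __init__(self, trials: pd.DataFrame, variant: str = "setsize_drift",
                 config: ModelConfig | None = None):
        if variant not in VARIANTS:
            raise InvalidParameterError(f"unknown variant {variant!r}")
        missing = [c for c in _REQUIRED if c not in trials.columns]
        if missing:
            raise InvalidParameterError(f"trial table missing columns: {missing}")
        if "valid" in trials.columns:
            trials = trials[trials["valid"]]
        if "trial_class" in trials.columns:
            trials = trials[trials["trial_class"] == "target"]
        if len(trials) == 0:
            raise InvalidParameterError("no usable trials after filtering")
        self.trials = trials.reset_index(drop=True)
        self.variant = variant
        self.config = config or ModelConfig()

    def loglike(self, params: ParameterSet) -> float:
        return dataset_loglik(params, self.trials,
                              evaluator=self.config.evaluator(params))

    def fit(self, grid: ParameterGrid | None = None, n_starts: int = 5,
            maxiter: int = 400) -> "DelayRecallResults":
        fit = fit_participant(self.trials, self.variant, grid=grid,
                              config=self.config, n_starts=n_starts,
                              maxiter=maxiter)
        return DelayRecallResults(self, fit)


class DelayRecallResults:
    """Fitted parameters, likelihood and model predictions."""

    def __init__(self, model: DelayRecallModel, fit: FitResult):
        self.model = model
        self.fit_result = fit

    @property
    def params(self) -> ParameterSet:
        return self.fit_result.params

    @property
    def llf(self) -> float:
        return self.fit_result.loglik

    @property
    def flags(self) -> list:
        return self.fit_result.flags

    def predict(self, set_size: int, t_d: float):
        """(error, latency) densities at the fitted parameters."""
        ev = self.model.config.evaluator(self.params)
        return ev.densities(int(set_size), float(t_d))

    def predicted_median_latency(self, set_size: int, t_d: float = 0.0) -> float:
        _, lat = self.predict(set_size, t_d)
        return lat.median()

    def predicted_precision_deg(self, set_size: int, t_d: float) -> float:
        """RMSD (deg) of the predicted response-error distribution."""
        err, _ = self.predict(set_size, t_d)
        h = err.support[1] - err.support[0]
        msd = float(np.sum(err.support ** 2 * err.density) * h)
        return float(np.rad2deg(np.sqrt(msd)))

    def plot_fit(self, trials: pd.DataFrame | None = None, axes=None):
        """Latency-vs-precision diagnostic: model predictions per condition.

        Plots predicted median latency against predicted RMSD for every
        (set size, delay) cell — the signature plot separating drift from
        decay — and overlays observed per-cell summaries when a trial
        table is given.  Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt
        from .classification import summarize_conditions

        if axes is None:
            _, axes = plt.subplots(figsize=(5, 4))
        trials = self.model.trials if trials is None else trials
        set_sizes = sorted(trials["set_size"].unique())
        delays = sorted(trials["delay"].unique())
        colors = plt.cm.viridis(np.linspace(0.15, 0.85, len(set_sizes)))
        for color, n in zip(colors, set_sizes):
            xs = [self.predicted_precision_deg(n, td) for td in delays]
            ys = [self.predicted_median_latency(n, td) for td in delays]
            axes.plot(xs, ys, "o-", color=color, label=f"N = {n} (model)")
        obs = summarize_conditions(trials)
        for color, n in zip(colors, set_sizes):
            sub = obs[obs["set_size"] == n]
            axes.plot(sub["precision_deg"], sub["median_latency"], "d",
                      color=color, mfc="none", label=f"N = {n} (data)")
        axes.set_xlabel("response error RMSD (deg)")
        axes.set_ylabel("median latency (s)")
        axes.legend(fontsize=8)
        axes.set_title(f"{self.fit_result.variant} fit")
        return axes

    def summary(self) -> str:
        d = self.params.to_dict()
        rows = [
            ("gamma (spikes/s)", d["gamma"]), ("m (spikes)", d["m"]),
            ("kappa", d["kappa"]), ("tau (s)", d["tau"]),
            ("nu (1/s)", d["nu"]), ("o (s)", d["o"]),
            (f"{d['variant']} param", d["mech_param"]),
        ]
        width = max(len(r[0]) for r in rows)
        lines = [
            "Delay recall model fit",
            "=" * 46,
            f"variant:        {self.fit_result.variant}",
            f"n trials:       {self.fit_result.n_trials}",
            f"log-likelihood: {self.llf:.2f} (grid stage {self.fit_result.grid_loglik:.2f})",
            f"converged:      {self.fit_result.converged}"
            + (f"   flags: {', '.join(self.flags)}" if self.flags else ""),
            "-" * 46,
        ]
        for name, val in rows:
            lines.append(f"{name:<{width}}  {val:>12.4g}")
        return "\n".join(lines)
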