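"""Integration-to-threshold saccade latencies and surviving-spike counts.

Response generation integrates population spikes to a fixed threshold of
``m`` spikes.  With a per-item population rate rho = gain / N the
integration time is Erlang(m, rho); the observable latency adds an
exponential residual (rate nu) with a constant offset o, reflecting
cue processing and motor execution.

Spikes emitted early in the accumulation window decay with time constant
tau, so only k <= m spikes survive to inform the decoded direction; the
final spike, arriving at the end of the window, always survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .population import InvalidParameterError, PopulationParams

__all__ = [
    "LatencyParams",
    "LatencyDistribution",
    "SpikeCountDistribution",
    "ConfigurationError",
    "default_time_grid",
    "integration_time_pdf",
    "residual_pdf",
    "latency_pdf",
    "latency_pdf_from_rate",
    "spike_survival_prob",
    "surviving_spike_dist",
    "surviving_spike_dist_from_rate",
]


class ConfigurationError(ValueError):
    """A numerical-configuration constraint (e.g. grid resolution) is violated."""


@dataclass(frozen=True)
class LatencyParams:
    """Latency-mechanism parameters.

    threshold : int
        Spike threshold m (>= 1).
    residual_rate : float
        Rate nu (1/s) of the exponential residual component.
    offset : float
        Constant offset o (s) of the residual; latency support starts at o.
    survival_tau : float
        Time constant tau (s) of spike decay during accumulation.
    """

    threshold: int
    residual_rate: float
    offset: float
    survival_tau: float

    def __post_init__(self):
        if int(self.threshold) != self.threshold or self.threshold < 1:
            raise InvalidParameterError(
                f"threshold must be an integer >= 1, got {self.threshold}"
            )
        object.__setattr__(self, "threshold", int(self.threshold))
        if not (self.residual_rate > 0):
            raise InvalidParameterError("residual_rate must be > 0")
        if self.offset < 0:
            raise InvalidParameterError("offset must be >= 0")
        if not (self.survival_tau > 0):
            raise InvalidParameterError("survival_tau must be > 0")


@dataclass(frozen=True)
class LatencyDistribution:
    """Tabulated latency density on a uniform time grid."""

    support: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "support", np.asarray(self.support, dtype=float))
        object.__setattr__(self, "density",
                           np.maximum(np.asarray(self.density, dtype=float), 0.0))

    @property
    def dt(self) -> float:
        return float(self.support[1] - self.support[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.support))

    def mean(self) -> float:
        return float(np.trapezoid(self.support * self.density, self.support))

    def variance(self) -> float:
        mu = self.mean()
        return float(np.trapezoid((self.support - mu) ** 2 * self.density,
                                  self.support))

    def cdf(self) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(
            0.5 * (self.density[1:] + self.density[:-1]) * np.diff(self.support))))
        return c

    def median(self) -> float:
        c = self.cdf()
        total = c[-1]
        return float(np.interp(0.5 * total, c, self.support))

    def interp(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.support, self.density,
                         left=0.0, right=0.0)


@dataclass(frozen=True)
class SpikeCountDistribution:
    """Distribution of the number of surviving spikes, support {1..m}."""

    k: np.ndarray
    pmf: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "k", np.asarray(self.k, dtype=int))
        object.__setattr__(self, "pmf", np.asarray(self.pmf, dtype=float))

    def mean(self) -> float:
        return float(np.sum(self.k * self.pmf))


def default_time_grid(t_max: float = 3.0, dt: float = 0.001) -> np.ndarray:
    return np.arange(0.0, t_max + dt / 2, dt)


def integration_time_pdf(rate: float, threshold: int, t) -> np.ndarray:
    """Erlang density of the time to accumulate ``threshold`` spikes.

    m - 1 Poisson events in [0, t) at rate rho, times the constant hazard
    of the final spike at t, gives rho^m t^(m-1) exp(-rho t) / (m-1)!.
    """
    if not (rate > 0):
        raise InvalidParameterError(f"rate must be > 0, got {rate}")
    if int(threshold) != threshold or threshold < 1:
        raise InvalidParameterError(f"threshold must be an integer >= 1, got {threshold}")
    t = np.asarray(t, dtype=float)
    m = int(threshold)
    with np.errstate(divide="ignore", invalid="ignore"):
        logpdf = m * np.log(rate) + special.xlogy(m - 1.0, t) - rate * t \
            - special.gammaln(m)
    out = np.where(t >= 0, np.exp(logpdf), 0.0)
    return out if out.ndim else float(out)


def residual_pdf(params: LatencyParams, t) -> np.ndarray:
    """Shifted-exponential density nu * exp(-nu (t - o)) for t >= o, else 0."""
    t = np.asarray(t, dtype=float)
    nu, o = params.residual_rate, params.offset
    out = np.where(t >= o, nu * np.exp(-nu * np.clip(t - o, 0.0, None)), 0.0)
    return out if out.ndim else float(out)


def erlang_samples(rho: float, threshold: int, grid: np.ndarray) -> np.ndarray:
    """Erlang density sampled on the grid, rescaled to its exact in-window mass."""
    f = integration_time_pdf(rho, threshold, grid)
    dt = grid[1] - grid[0]
    mass = stats.gamma.cdf(grid[-1], a=int(threshold), scale=1.0 / rho)
    s = f.sum() * dt
    return f * (mass / s) if s > 0 else f


def residual_samples(nu: float, o: float, grid: np.ndarray) -> np.ndarray:
    """Shifted-exponential density sampled on the grid, rescaled so that the
    jump at the offset does not inflate the rectangle-rule mass by nu*dt/2."""
    t = grid
    g = np.where(t >= o, nu * np.exp(-nu * np.clip(t - o, 0.0, None)), 0.0)
    dt = grid[1] - grid[0]
    mass = -np.expm1(-nu * (grid[-1] - o)) if grid[-1] > o else 0.0
    s = g.sum() * dt
    return g * (mass / s) if s > 0 else g


def latency_pdf_from_rate(
    rho: float,
    lat: LatencyParams,
    grid: np.ndarray | None = None,
) -> LatencyDistribution:
    """Latency density at a given per-item population rate rho = gain / N."""
    if grid is None:
        grid = default_time_grid()
    dt = grid[1] - grid[0]
    if dt > 0.002 + 1e-12:
        raise ConfigurationError(
            f"time grid spacing {dt:.4f} s is too coarse (max 0.002 s)"
        )
    from scipy import fft as sp_fft
    f = erlang_samples(rho, lat.threshold, grid)
    g = residual_samples(lat.residual_rate, lat.offset, grid)
    fshape = sp_fft.next_fast_len(2 * grid.size - 1, True)
    conv = sp_fft.irfft(sp_fft.rfft(f, fshape) * sp_fft.rfft(g, fshape),
                        fshape)[: grid.size] * dt
    conv[grid < lat.offset] = 0.0  # exact support; clears FFT roundoff
    return LatencyDistribution(support=grid, density=conv)


def latency_pdf(
    pop: PopulationParams,
    lat: LatencyParams,
    set_size: int,
    grid: np.ndarray | None = None,
) -> LatencyDistribution:
    """Response-latency density: Erlang(m, gain/N) convolved with the residual.

    The convolution runs on the supplied uniform grid (default [0, 3] s at
    1 ms); spacing above 2 ms is rejected as too coarse for the saccade
    latency scales modeled here.  Mean is m N / gain + o + 1 / nu up to
    quadrature error.
    """
    if set_size < 1:
        raise InvalidParameterError(f"set_size must be >= 1, got {set_size}")
    return latency_pdf_from_rate(pop.gain / set_size, lat, grid)


def spike_survival_prob(t_m, tau: float):
    """Probability that a spike emitted uniformly in [0, t_m) survives decay.

    Averaging exp(-(t_m - t)/tau) over t ~ Uniform[0, t_m) gives
    (tau / t_m) (1 - exp(-t_m / tau)), with continuous limit 1 at t_m = 0.
    """
    if not (tau > 0):
        raise InvalidParameterError(f"tau must be > 0, got {tau}")
    t_m = np.asarray(t_m, dtype=float)
    if np.any(t_m < 0):
        raise InvalidParameterError("t_m must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(t_m > 0, -(tau / np.where(t_m > 0, t_m, 1.0))
                      * np.expm1(-t_m / tau), 1.0)
    return ps if ps.ndim else float(ps)


def _integration_quad_grid(rho: float, m: int, n_points: int = 2000) -> np.ndarray:
    """Quadrature nodes for the Erlang integration time: [0, 20 m / rho],
    quadratically clustered near 0 to control the short-time region."""
    u = np.linspace(0.0, 1.0, n_points)
    return (20.0 * m / rho) * u ** 2


def surviving_spike_dist(
    pop: PopulationParams,
    lat: LatencyParams,
    set_size: int,
    n_quad: int = 2000,
) -> SpikeCountDistribution:
    """Distribution over the number k of spikes informing the saccade.

    Conditioned on integration time t_m, k - 1 ~ Binomial(m - 1, p_s(t_m));
    the final spike always survives, so support is {1..m}.  The Erlang
    distribution of t_m is marginalized by trapezoid quadrature.
    """
    return surviving_spike_dist_from_rate(pop.gain / set_size, lat, n_quad)


def surviving_spike_dist_from_rate(
    rho: float,
    lat: LatencyParams,
    n_quad: int = 2000,
) -> SpikeCountDistribution:
    """Surviving-spike distribution at per-item population rate rho."""
    m = lat.threshold
    ks = np.arange(1, m + 1)
    if m == 1:
        return SpikeCountDistribution(k=ks, pmf=np.array([1.0]))
    t = _integration_quad_grid(rho, m, n_quad)
    weights = integration_time_pdf(rho, m, t)
    ps = spike_survival_prob(t, lat.survival_tau)
    # binomial pmf matrix (rows: quadrature nodes, cols: k in {1..m}),
    # in log space via xlogy so ps = 1 (t -> 0) stays exact
    j = ks[None, :] - 1.0
    logc = (special.gammaln(m) - special.gammaln(ks)
            - special.gammaln(m - ks + 1.0))[None, :]
    logpmf = logc + special.xlogy(j, ps[:, None]) \
        + special.xlogy(m - 1.0 - j, 1.0 - ps[:, None])
    pmf_t = np.exp(logpmf)
    num = np.trapezoid(weights[:, None] * pmf_t, t, axis=0)
    denom = np.trapezoid(weights, t)
    pmf = num / denom
    pmf = pmf / pmf.sum()
    return SpikeCountDistribution(k=ks, pmf=pmf)
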