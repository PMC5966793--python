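"""Normalized von Mises / Poisson population code and maximum-likelihood decoding.

A set of ``M`` neurons with von Mises tuning curves encodes an angular
location.  Total population activity is normalized: when ``N`` items are held
in memory, the population representing each item fires at a combined rate of
``gain / N`` spikes per second, independent of the encoded value.  Spike
counts are Poisson.  The encoded angle is recovered from a spike pattern by
maximum-likelihood estimation, which for von Mises tuning reduces to the
direction of the vector sum of the preferred values of the spiking neurons.

The analytic distribution of the decoding error given ``k`` spikes is a
mixture, over the resultant length ``r`` of a uniform random walk of ``k``
steps, of von-Mises-like kernels ``exp(kappa * r * cos(err))``.  The
resultant-length density is estimated once per ``k`` by Monte Carlo and
cached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from scipy import special

__all__ = [
    "PopulationParams",
    "SpikePattern",
    "ErrorDistribution",
    "InvalidParameterError",
    "NoSpikeError",
    "default_error_grid",
    "circ_integral",
    "wrap_angle",
    "tuning_rates",
    "sample_spikes",
    "ml_decode",
    "decode_loglik",
    "resultant_length_density",
    "error_dist_given_k",
    "error_dist_marginal",
    "psi_cache",
]

_TWO_PI = 2.0 * np.pi

DENSITY_FLOOR = 1e-12


class InvalidParameterError(ValueError):
    """A model parameter violates its domain constraints."""


class NoSpikeError(RuntimeError):
    """A spike pattern with zero total spikes cannot be decoded."""


def wrap_angle(theta):
    """Wrap angles (radians) to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.mod(-theta + np.pi, _TWO_PI)
    out = -(wrapped - np.pi)
    return out if out.ndim else float(out)


def default_error_grid(n: int = 720) -> np.ndarray:
    """Uniform angular grid on (-pi, pi] with ``n`` points (includes 0 and pi)."""
    h = _TWO_PI / n
    return -np.pi + h * np.arange(1, n + 1)


def circ_integral(density: np.ndarray, grid: np.ndarray) -> float:
    """Integral of a tabulated density over the full circle.

    On a uniform periodic grid the trapezoid rule coincides with the
    rectangle rule, so this is spacing * sum.
    """
    h = grid[1] - grid[0]
    return float(h * np.sum(density))


@dataclass(frozen=True)
class PopulationParams:
    """Encoding substrate: gain budget, neuron count, tuning width.

    Parameters
    ----------
    gain : float
        Total population rate budget gamma in spikes/s, shared across items.
    n_neurons : int
        Number of neurons M tiling the circle (>= 8).
    kappa : float
        von Mises concentration of the tuning curves (dimensionless).
    preferred_values : ndarray, optional
        Preferred angles phi_i in radians; defaults to M evenly spaced
        angles on [0, 2 pi).
    """

    gain: float
    kappa: float
    n_neurons: int = 64
    preferred_values: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if not (self.gain > 0):
            raise InvalidParameterError(f"gain must be > 0, got {self.gain}")
        if not (self.kappa > 0):
            raise InvalidParameterError(f"kappa must be > 0, got {self.kappa}")
        if self.n_neurons < 8:
            raise InvalidParameterError(
                f"n_neurons must be >= 8, got {self.n_neurons}"
            )
        if self.preferred_values is None:
            phi = _TWO_PI * np.arange(self.n_neurons) / self.n_neurons
            object.__setattr__(self, "preferred_values", phi)
        else:
            phi = np.asarray(self.preferred_values, dtype=float)
            if phi.shape != (self.n_neurons,):
                raise InvalidParameterError(
                    "preferred_values must have length n_neurons"
                )
            if np.any(np.diff(phi) <= 0):
                raise InvalidParameterError(
                    "preferred_values must be strictly increasing"
                )
            object.__setattr__(self, "preferred_values", phi)


@dataclass(frozen=True)
class SpikePattern:
    """Spike counts per neuron over one decoding interval."""

    counts: np.ndarray
    window: float

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise InvalidParameterError("spike counts must be non-negative")
        if not (self.window > 0):
            raise InvalidParameterError("window must be > 0")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ErrorDistribution:
    """Tabulated density of the angular response error on (-pi, pi]."""

    support: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        support = np.asarray(self.support, dtype=float)
        density = np.asarray(self.density, dtype=float)
        if support.shape != density.shape:
            raise InvalidParameterError("support and density shapes differ")
        if np.any(density < -1e-12):
            raise InvalidParameterError("density must be non-negative")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "density", np.maximum(density, 0.0))

    def integral(self) -> float:
        return circ_integral(self.density, self.support)

    def resultant_length(self) -> float:
        h = self.support[1] - self.support[0]
        z = np.sum(self.density * np.exp(1j * self.support)) * h
        return float(np.abs(z))

    def circular_sd(self) -> float:
        """Circular standard deviation sqrt(-2 ln R) in radians."""
        r = self.resultant_length()
        r = min(max(r, 1e-300), 1.0)
        return float(np.sqrt(-2.0 * np.log(r)))

    def interp(self, theta) -> np.ndarray:
        """Periodic linear interpolation of the density at wrapped angles."""
        theta = wrap_angle(theta)
        x = np.concatenate(([self.support[0] - (self.support[1] - self.support[0])],
                            self.support))
        y = np.concatenate(([self.density[-1]], self.density))
        return np.interp(theta, x, y)


def tuning_rates(params: PopulationParams, theta: float, set_size: int) -> np.ndarray:
    """Firing rates r_i of every neuron encoding angle ``theta``.

    Rates follow the von Mises tuning profile and are normalized so that the
    population rate for one of ``set_size`` items sums exactly to
    ``gain / set_size``.
    """
    if int(set_size) != set_size or set_size < 1:
        raise InvalidParameterError(f"set_size must be a positive integer, got {set_size}")
    w = np.exp(params.kappa * (np.cos(theta - params.preferred_values) - 1.0))
    return (params.gain / set_size) * w / w.sum()


def sample_spikes(
    params: PopulationParams,
    theta: float,
    set_size: int,
    window: float,
    seed: int | np.random.Generator,
) -> SpikePattern:
    """Draw independent Poisson spike counts over a fixed decoding window."""
    if not (window > 0):
        raise InvalidParameterError(f"window must be > 0, got {window}")
    rng = np.random.default_rng(seed)
    rates = tuning_rates(params, theta, set_size)
    counts = rng.poisson(rates * window)
    return SpikePattern(counts=counts, window=window)


def decode_loglik(pattern: SpikePattern, params: PopulationParams, theta) -> np.ndarray:
    """Poisson log-likelihood of the pattern as a function of candidate angle.

    The rate-sum term is constant in theta because of the exact
    normalization, so it is dropped; this is the quantity ``ml_decode``
    maximizes and serves as the brute-force decoding oracle.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    ll = np.empty(theta.shape)
    for i, th in enumerate(theta):
        rates = tuning_rates(params, th, 1)
        ll[i] = np.sum(pattern.counts * np.log(rates))
    return ll


def ml_decode(pattern: SpikePattern, params: PopulationParams) -> float:
    """Maximum-likelihood decoded angle from a spike pattern.

    For von Mises tuning with normalized rates the ML estimate is the
    direction of the resultant vector sum(n_i * exp(1j * phi_i)).  Antipodal
    patterns with zero resultant leave the likelihood flat; the tie is broken
    deterministically by returning the smallest wrapped preferred value among
    spiking neurons.
    """
    if pattern.total < 1:
        raise NoSpikeError("cannot decode a pattern with zero spikes")
    z = np.sum(pattern.counts * np.exp(1j * params.preferred_values))
    if np.abs(z) < 1e-12:
        active = wrap_angle(params.preferred_values[pattern.counts > 0])
        return float(np.min(active))
    return float(np.angle(z))


# ---------------------------------------------------------------------------
# Resultant-length density psi_k of a uniform random walk (Monte Carlo, cached)
# ---------------------------------------------------------------------------


class PsiCache:
    """In-process cache of Monte Carlo resultant-length densities.

    Tables may be persisted with :meth:`save` / :meth:`load` (JSON with
    metadata ``k``, ``n_grid``, ``n_samples``, ``seed``).
    """

    def __init__(self):
        self._tables: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

    def key(self, k, n_grid, n_samples, seed):
        return (int(k), int(n_grid), int(n_samples), int(seed))

    def get(self, k, n_grid, n_samples, seed):
        key = self.key(k, n_grid, n_samples, seed)
        if key not in self._tables:
            # a miss for k usually precedes misses for smaller k (mixtures
            # over spike counts); one cumulative walk fills them all
            self.build(range(1, k + 1), n_grid, n_samples, seed)
        return self._tables[key]

    def build(self, k_values, n_grid, n_samples, seed):
        """Build tables for all ``k_values`` in one cumulative random walk.

        The resultant after k steps is obtained by adding one unit step to
        the resultant after k - 1 steps, so a single pass over the largest k
        yields every intermediate table at no extra sampling cost.
        """
        k_values = sorted(int(k) for k in k_values)
        missing = [k for k in k_values
                   if self.key(k, n_grid, n_samples, seed) not in self._tables]
        if not missing:
            return
        rng = np.random.default_rng(seed)
        k_max = max(missing)
        want = set(missing)
        z = np.zeros(int(n_samples), dtype=np.complex128)
        for k in range(1, k_max + 1):
            z += np.exp(1j * rng.uniform(0.0, _TWO_PI, size=int(n_samples)))
            if k in want:
                self._tables[self.key(k, n_grid, n_samples, seed)] = \
                    self._histogram(np.abs(z), k, n_grid)

    @staticmethod
    def _histogram(r, k, n_grid):
        """Bin the resultant lengths, keeping per-bin moments.

        Besides the mass, each bin stores the mean and variance of r within
        it, so that downstream exponential integrals ∫ psi(r) e^{c r} dr can
        be corrected for within-bin variation (the kernel varies by a factor
        e^{c h} across one bin, which biases a plain midpoint rule when
        c = kappa cos(dtheta) is large).
        """
        edges = np.linspace(0.0, k, int(n_grid) + 1)
        mass, _ = np.histogram(r, bins=edges)
        sum_r, _ = np.histogram(r, bins=edges, weights=r)
        sum_r2, _ = np.histogram(r, bins=edges, weights=r * r)
        centers = 0.5 * (edges[:-1] + edges[1:])
        n = np.maximum(mass, 1)
        rmean = np.where(mass > 0, sum_r / n, centers)
        rvar = np.maximum(np.where(mass > 0, sum_r2 / n - rmean ** 2, 0.0), 0.0)
        return centers, mass / mass.sum(), rmean, rvar

    def save(self, path):
        payload = []
        for (k, n_grid, n_samples, seed), (centers, mass, rmean, rvar) \
                in self._tables.items():
            payload.append({
                "k": k, "n_grid": n_grid, "n_samples": n_samples, "seed": seed,
                "centers": centers.tolist(), "mass": mass.tolist(),
                "rmean": rmean.tolist(), "rvar": rvar.tolist(),
            })
        Path(path).write_text(json.dumps({"version": 2, "tables": payload}))

    def load(self, path):
        data = json.loads(Path(path).read_text())
        for tab in data["tables"]:
            key = self.key(tab["k"], tab["n_grid"], tab["n_samples"], tab["seed"])
            self._tables[key] = (np.asarray(tab["centers"]),
                                 np.asarray(tab["mass"]),
                                 np.asarray(tab["rmean"]),
                                 np.asarray(tab["rvar"]))


psi_cache = PsiCache()

PSI_DEFAULT_GRID = 512
PSI_DEFAULT_SAMPLES = 1_000_000
PSI_DEFAULT_SEED = 20180523


def resultant_length_density(
    k: int,
    n_grid: int = PSI_DEFAULT_GRID,
    n_samples: int = PSI_DEFAULT_SAMPLES,
    seed: int = PSI_DEFAULT_SEED,
) -> tuple[np.ndarray, np.ndarray]:
    """Density of the resultant length of a uniform random walk of ``k`` steps.

    Returns ``(grid, density)`` where ``grid`` holds bin centers on [0, k]
    and ``density`` integrates to 1 (it is the pdf of the scalar resultant,
    the quantity written ``r psi_k(r)`` in the 2-D random-walk literature).
    For ``k = 1`` the resultant is exactly 1 and all mass falls in the bin
    containing r = 1.
    """
    if int(k) != k or k < 1:
        raise InvalidParameterError(f"k must be a positive integer, got {k}")
    if k == 1:
        edges = np.linspace(0.0, 1.0, int(n_grid) + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mass = np.zeros(int(n_grid))
        mass[-1] = 1.0  # the single unit step: resultant exactly 1
        width = edges[1] - edges[0]
        return centers, mass / width
    centers, mass, _, _ = psi_cache.get(k, n_grid, n_samples, seed)
    width = centers[1] - centers[0]
    return centers, mass / width


def _psi_nodes(k, n_grid, n_samples, seed):
    """Per-bin (mean r, mass, within-bin variance) of psi_k, nonzero bins only."""
    if k == 1:
        return np.array([1.0]), np.array([1.0]), np.array([0.0])
    _, mass, rmean, rvar = psi_cache.get(k, n_grid, n_samples, seed)
    keep = mass > 0
    return rmean[keep], mass[keep], rvar[keep]


# ---------------------------------------------------------------------------
# Analytic decoding-error distributions
# ---------------------------------------------------------------------------


def error_dist_given_k(
    k: int,
    kappa: float,
    grid: np.ndarray | None = None,
    *,
    psi_grid: int = PSI_DEFAULT_GRID,
    psi_samples: int = PSI_DEFAULT_SAMPLES,
    psi_seed: int = PSI_DEFAULT_SEED,
) -> ErrorDistribution:
    """Analytic distribution of the ML decoding error from ``k`` spikes.

    The joint density of the spike-vector resultant (length r, direction
    dtheta) factorizes as psi_k(r) * exp(kappa r cos(dtheta)) / (2 pi
    I_0(kappa)^k); marginalizing r over its Monte Carlo density gives the
    error distribution.  For k = 1 this is exactly von Mises(0, kappa).
    Computed in log space and normalized on the grid.
    """
    if int(k) != k or k < 1:
        raise InvalidParameterError(f"k must be a positive integer, got {k}")
    if not (kappa > 0):
        raise InvalidParameterError(f"kappa must be > 0, got {kappa}")
    if grid is None:
        grid = default_error_grid()
    if k == 1:
        dens = np.exp(kappa * (np.cos(grid) - 1.0)) / (_TWO_PI * special.i0e(kappa))
    else:
        r, w, v = _psi_nodes(k, psi_grid, psi_samples, psi_seed)
        # E[e^{c r}] per bin to second order in the within-bin spread:
        # e^{c rbar + c^2 var/2}; the correction matters once
        # kappa * binwidth is of order 1
        c = kappa * np.cos(grid)
        logmat = np.outer(c, r) + np.outer(c * c, v) / 2.0 + np.log(w)[None, :]
        peak = logmat.max()
        dens = np.exp(logmat - peak).sum(axis=1)
    dens = dens / circ_integral(dens, grid)
    return ErrorDistribution(support=grid, density=dens)


_default_grids: dict[int, np.ndarray] = {}
_density_memo: dict[tuple, np.ndarray] = {}
_DENSITY_MEMO_MAX = 8192


def _cached_density_given_k(k, kappa, n, psi_grid, psi_samples, psi_seed):
    """Memoized error density for (k, kappa) on the standard n-point grid.

    The grid search and simplex refinement evaluate many (gamma, m, tau)
    combinations at the same kappa; caching per (k, kappa) makes the
    spike-count mixture a cheap weighted sum.
    """
    key = (int(k), float(kappa), int(n), psi_grid, psi_samples, psi_seed)
    if key not in _density_memo:
        if len(_density_memo) >= _DENSITY_MEMO_MAX:
            _density_memo.clear()
        grid = _default_grids.setdefault(n, default_error_grid(n))
        _density_memo[key] = error_dist_given_k(
            int(k), kappa, grid, psi_grid=psi_grid, psi_samples=psi_samples,
            psi_seed=psi_seed).density
    return _density_memo[key]


def error_dist_marginal(
    spike_count_dist,
    kappa: float,
    grid: np.ndarray | None = None,
    *,
    psi_grid: int = PSI_DEFAULT_GRID,
    psi_samples: int = PSI_DEFAULT_SAMPLES,
    psi_seed: int = PSI_DEFAULT_SEED,
) -> ErrorDistribution:
    """Error distribution marginalized over the spike-count distribution.

    ``spike_count_dist`` is a mapping k -> probability, or an object with
    ``k`` and ``pmf`` attributes.  Mass on k = 0 is invalid: the threshold
    mechanism guarantees at least the final spike survives.
    """
    if hasattr(spike_count_dist, "k") and hasattr(spike_count_dist, "pmf"):
        ks = np.asarray(spike_count_dist.k, dtype=int)
        ps = np.asarray(spike_count_dist.pmf, dtype=float)
    else:
        items = sorted(spike_count_dist.items())
        ks = np.array([k for k, _ in items], dtype=int)
        ps = np.array([p for _, p in items], dtype=float)
    if np.any(ks < 1):
        raise InvalidParameterError("spike-count distribution has mass on k = 0")
    if abs(ps.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(
            f"spike-count probabilities sum to {ps.sum()}, expected 1"
        )
    n = default_error_grid().size if grid is None else int(np.size(grid))
    std_grid = _default_grids.setdefault(n, default_error_grid(n))
    standard = grid is None or np.array_equal(grid, std_grid)
    out_grid = std_grid if standard else grid
    need = [int(k) for k, p in zip(ks, ps) if p > 0 and k >= 2]
    if need:  # one cumulative walk fills every missing table
        psi_cache.build(need, psi_grid, psi_samples, psi_seed)
    dens = np.zeros(n)
    for k, p in zip(ks, ps):
        if p <= 0:
            continue
        if standard:
            comp = _cached_density_given_k(int(k), kappa, n, psi_grid,
                                           psi_samples, psi_seed)
        else:
            comp = error_dist_given_k(int(k), kappa, out_grid,
                                      psi_grid=psi_grid,
                                      psi_samples=psi_samples,
                                      psi_seed=psi_seed).density
        dens = dens + p * comp
    dens = dens / circ_integral(dens, out_grid)
    return ErrorDistribution(support=out_grid, density=dens)
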