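"""Helpers for comparing tabulated model densities with simulated samples.

Used by the test suite and by the reproduction script to measure
total-variation (TV) distances between analytic densities and event-level
simulation histograms.  Bin probabilities are computed by trapezoid
integration of the tabulated density so that the comparison error is
dominated by Monte Carlo noise, not by quadrature.
"""

from __future__ import annotations

import numpy as np

from .population import ErrorDistribution
from .latency import LatencyDistribution

__all__ = ["error_bin_probs", "latency_bin_probs", "total_variation",
           "tv_error_vs_samples", "tv_latency_vs_samples"]


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return float(0.5 * np.abs(np.asarray(p) - np.asarray(q)).sum())


def error_bin_probs(err: ErrorDistribution, edges: np.ndarray) -> np.ndarray:
    """Probability mass of an error density in angular bins (radians)."""
    h = err.support[1] - err.support[0]
    x = np.concatenate(([err.support[0] - h], err.support))
    y = np.concatenate(([err.density[-1]], err.density))  # periodic closure
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * h)))
    c = np.interp(edges, x, cdf)
    p = np.diff(c)
    return p / p.sum()


def latency_bin_probs(lat: LatencyDistribution, edges: np.ndarray) -> np.ndarray:
    """Probability mass of a latency density in time bins (seconds)."""
    cdf_vals = lat.cdf()
    c = np.interp(edges, lat.support, cdf_vals, left=0.0, right=cdf_vals[-1])
    p = np.diff(c)
    return p / p.sum()


def tv_error_vs_samples(err: ErrorDistribution, samples: np.ndarray,
                        n_bins: int = 60) -> float:
    """TV distance between an error density and sampled errors (radians)."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hist, _ = np.histogram(samples, bins=edges)
    return total_variation(hist / samples.size, error_bin_probs(err, edges))


def tv_latency_vs_samples(lat: LatencyDistribution, samples: np.ndarray,
                          n_bins: int = 60) -> float:
    """TV distance between a latency density and sampled latencies (s).

    Bins cover the sampled range; samples beyond the tabulated support
    contribute to the distance (the model assigns them no mass).
    """
    lo = min(float(np.min(samples)), float(lat.support[0]))
    hi = float(np.max(samples))
    edges = np.linspace(lo, hi, n_bins + 1)
    hist, _ = np.histogram(samples, bins=edges)
    return total_variation(hist / samples.size, latency_bin_probs(lat, edges))
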