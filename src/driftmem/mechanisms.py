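"""Delay-effect mechanisms: gain decay versus representational drift.

Two families of hypotheses for why recall degrades with retention interval:

* decay — the gain of the population attenuates with delay t_d, either
  linearly (slope omega, floored at zero) or exponentially (rate lambda).
  Because the latency mechanism integrates the same spikes, decay predicts
  slower responses at longer delays.
* drift — the encoded value performs a Brownian random walk during the
  delay while total activity is unchanged.  The accumulated drift is a von
  Mises increment with concentration chi = chi0 / t_d (constant drift rate)
  or chi0 / (N t_d) (drift rate scaling with set size).  Latencies are
  untouched by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .population import ErrorDistribution, InvalidParameterError, circ_integral

__all__ = [
    "VARIANTS",
    "DECAY_VARIANTS",
    "DRIFT_VARIANTS",
    "DelayMechanism",
    "effective_gain",
    "drift_concentration",
    "apply_drift",
]

DECAY_VARIANTS = ("linear_decay", "exp_decay")
DRIFT_VARIANTS = ("const_drift", "setsize_drift")
VARIANTS = DECAY_VARIANTS + DRIFT_VARIANTS

#: parameter symbol and unit per variant
MECH_PARAM_INFO = {
    "linear_decay": ("omega", "s^-2"),
    "exp_decay": ("lambda", "s^-1"),
    "const_drift": ("chi0", "s^-1"),
    "setsize_drift": ("chi0", "s^-1"),
}


@dataclass(frozen=True)
class DelayMechanism:
    """One delay-effect variant and its single parameter.

    ``param`` is omega (linear_decay), lambda (exp_decay) or chi0 (drift
    variants).  ``param = 0`` means no decay; ``param = inf`` for a drift
    variant means no drift.  ``relative_slope`` switches the linear decay to
    the gain-normalized form gamma * max(1 - omega t_d, 0).
    """

    variant: str
    param: float
    relative_slope: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InvalidParameterError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if not (self.param >= 0):
            raise InvalidParameterError("mechanism parameter must be >= 0")

    @property
    def is_decay(self) -> bool:
        return self.variant in DECAY_VARIANTS

    @property
    def is_drift(self) -> bool:
        return self.variant in DRIFT_VARIANTS


def effective_gain(gamma: float, mech: DelayMechanism, t_d: float) -> float:
    """Population gain after a delay of ``t_d`` seconds.

    Decay variants attenuate gamma (linear decay is floored at zero); drift
    variants leave it unchanged — the defining property that makes latency
    independent of delay under drift.
    """
    if t_d < 0:
        raise InvalidParameterError(f"t_d must be >= 0, got {t_d}")
    if mech.variant == "linear_decay":
        if mech.relative_slope:
            return gamma * max(1.0 - mech.param * t_d, 0.0)
        return max(gamma - mech.param * t_d, 0.0)
    if mech.variant == "exp_decay":
        return gamma * float(np.exp(-mech.param * t_d))
    return gamma


def drift_concentration(mech: DelayMechanism, t_d: float, set_size: int) -> float:
    """von Mises concentration chi of the accumulated drift after ``t_d``.

    Brownian motion accumulates variance linearly in time, so the
    concentration scales as chi0 / t_d; the set-size-dependent variant
    divides further by N.  Decay variants (and t_d = 0) return +inf,
    the identity (no-drift) kernel.
    """
    if set_size < 1:
        raise InvalidParameterError(f"set_size must be >= 1, got {set_size}")
    if mech.is_decay:
        return np.inf
    if t_d == 0:
        return np.inf  # degenerate: no time for drift to accumulate
    if not (t_d > 0):
        raise InvalidParameterError(f"t_d must be >= 0, got {t_d}")
    chi = mech.param / t_d
    if mech.variant == "setsize_drift":
        chi = chi / set_size
    return float(chi)


_ratio_cache: dict[tuple, np.ndarray] = {}
_RATIO_CACHE_MAX = 8192


def _vm_fourier_ratios(chi: float, n: int) -> np.ndarray:
    """Fourier coefficients I_n(chi)/I_0(chi) of the von Mises kernel."""
    key = (float(chi), int(n))
    if key not in _ratio_cache:
        if len(_ratio_cache) >= _RATIO_CACHE_MAX:
            _ratio_cache.clear()
        _ratio_cache[key] = special.ive(np.arange(n), chi) / special.ive(0, chi)
    return _ratio_cache[key]


def drift_from_spectrum(spec: np.ndarray, chi: float, support: np.ndarray,
                        size: int) -> ErrorDistribution:
    """Drift convolution given the precomputed rFFT of the base density."""
    ratios = _vm_fourier_ratios(chi, spec.size)
    dens = np.fft.irfft(spec * ratios, n=size)
    dens = np.maximum(dens, 0.0)
    dens = dens / circ_integral(dens, support)
    return ErrorDistribution(support=support, density=dens)


def apply_drift(err: ErrorDistribution, chi: float) -> ErrorDistribution:
    """Circular convolution of an error distribution with von Mises(0, chi).

    Implemented spectrally: the Fourier coefficients of the von Mises kernel
    are the Bessel ratios I_n(chi) / I_0(chi), so the convolution multiplies
    the density's DFT by those ratios.  This is exact for grid-bandlimited
    densities and remains well behaved when chi is large enough that a
    tabulated kernel would be narrower than the grid spacing.  chi = inf is
    the identity.
    """
    if not (chi > 0):
        raise InvalidParameterError(f"chi must be > 0 (or inf), got {chi}")
    if np.isinf(chi):
        return ErrorDistribution(support=err.support, density=err.density.copy())
    spec = np.fft.rfft(err.density)
    return drift_from_spectrum(spec, chi, err.support, err.density.size)
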