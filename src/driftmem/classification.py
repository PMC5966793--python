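"""Trial records, exclusion filters, mixture classification, behavioral summaries.

A trial table holds one cued-recall saccade trial per row.  Angles are in
degrees at this boundary (radians are used internally by the model code),
latencies in seconds.  Columns:

====================  =====================================================
participant           participant identifier
experiment            experiment tag (pooling across experiments is allowed)
set_size              number of items N in the sample array
delay                 retention interval t_d in seconds
target_angle          angular location of the cued item (deg, [0, 360))
nontarget_angles      other item locations, ';'-joined degrees ('' if N = 1)
response_angle        angular location of the response fixation (deg)
latency               saccade onset latency (s)
saccade_amplitude_fraction  response amplitude / array eccentricity
correction_deflection direction change by correction saccades (deg)
blink                 blink before stable fixation (bool)
====================  =====================================================

Response errors are classified with a three-component mixture: a von Mises
component centered on the target, von Mises components on each nontarget
(shared concentration, capturing swap errors), and a uniform guessing
component.  Trials whose posterior probability of arising from the target
component exceeds 75% are retained as target responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .population import InvalidParameterError

__all__ = [
    "TrialRecord",
    "MixtureFit",
    "TRIAL_COLUMNS",
    "read_trials_csv",
    "write_trials_csv",
    "wrap_deg",
    "apply_exclusions",
    "filter_trials",
    "exclusion_rate",
    "exclusion_report",
    "fit_mixture",
    "classify_trials",
    "summarize_conditions",
    "condition_difference",
]

TRIAL_COLUMNS = [
    "participant", "experiment", "set_size", "delay", "target_angle",
    "nontarget_angles", "response_angle", "latency",
    "saccade_amplitude_fraction", "correction_deflection", "blink",
]

# exclusion thresholds, applied in order; reason names the first violation
LATENCY_MIN = 0.15   # s after cue onset
LATENCY_MAX = 2.0    # s
AMPLITUDE_MIN = 0.5  # fraction of array eccentricity
AMPLITUDE_MAX = 1.5
DEFLECTION_MAX = 15.0  # deg


@dataclass
class TrialRecord:
    """One cued-recall trial; angles in degrees, latency in seconds."""

    participant: str
    set_size: int
    delay: float
    target_angle: float
    nontarget_angles: list = field(default_factory=list)
    response_angle: float = np.nan
    latency: float = np.nan
    saccade_amplitude_fraction: float = 1.0
    correction_deflection: float = 0.0
    blink: bool = False
    experiment: str = "1"
    valid: bool = True
    trial_class: str = "unclassified"
    target_posterior: float = np.nan


def wrap_deg(x):
    """Wrap angular differences in degrees to (-180, 180]."""
    x = np.asarray(x, dtype=float)
    out = -(np.mod(-x + 180.0, 360.0) - 180.0)
    return out if out.ndim else float(out)


def _parse_nontargets(value) -> np.ndarray:
    if isinstance(value, (list, tuple, np.ndarray)):
        return np.asarray(value, dtype=float)
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return np.array([], dtype=float)
    return np.array([float(v) for v in str(value).split(";")])


def _format_nontargets(value) -> str:
    arr = _parse_nontargets(value)
    return ";".join(f"{v:.6g}" for v in arr)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=["NA", "nan", "NaN"],
                     dtype={"nontarget_angles": str, "participant": str,
                            "experiment": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"trial table missing columns: {missing}")
    df["blink"] = df["blink"].astype(str).str.lower().isin(["true", "1"])
    for col in ("set_size",):
        df[col] = df[col].astype(int)
    for col in ("delay", "target_angle", "response_angle", "latency",
                "saccade_amplitude_fraction", "correction_deflection"):
        df[col] = df[col].astype(float)
    return df


def write_trials_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["nontarget_angles"] = out["nontarget_angles"].map(_format_nontargets)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Exclusion filters
# ---------------------------------------------------------------------------


def apply_exclusions(trial) -> tuple[bool, str | None]:
    """Check one trial against the saccade-quality filters.

    Returns ``(excluded, reason)`` with ``reason`` naming the first violated
    rule: the response saccade must start between 0.15 and 2 s after the
    cue, land between 50% and 150% of the array eccentricity, correction
    saccades may not deflect the response by more than 15 deg, and no blink
    may occur before fixation is re-established.
    """
    required = ("latency", "saccade_amplitude_fraction",
                "correction_deflection", "blink")
    get = (trial.get if isinstance(trial, (dict, pd.Series))
           else lambda k: getattr(trial, k, None))
    vals = {k: get(k) for k in required}
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals.values()):
        raise InvalidParameterError(f"trial record missing fields: {vals}")
    if vals["latency"] < LATENCY_MIN:
        return True, "latency-too-early"
    if vals["latency"] > LATENCY_MAX:
        return True, "latency-too-late"
    frac = vals["saccade_amplitude_fraction"]
    if frac < AMPLITUDE_MIN or frac > AMPLITUDE_MAX:
        return True, "amplitude"
    if vals["correction_deflection"] > DEFLECTION_MAX:
        return True, "deflection"
    if bool(vals["blink"]):
        return True, "blink"
    return False, None


def filter_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized exclusion filter; adds ``valid`` and ``exclusion_reason``."""
    out = df.copy()
    lat = out["latency"].to_numpy(float)
    frac = out["saccade_amplitude_fraction"].to_numpy(float)
    defl = out["correction_deflection"].to_numpy(float)
    blink = out["blink"].to_numpy(bool)
    reason = np.full(len(out), "", dtype=object)
    checks = [
        (lat < LATENCY_MIN, "latency-too-early"),
        (lat > LATENCY_MAX, "latency-too-late"),
        ((frac < AMPLITUDE_MIN) | (frac > AMPLITUDE_MAX), "amplitude"),
        (defl > DEFLECTION_MAX, "deflection"),
        (blink, "blink"),
    ]
    for mask, name in checks:
        hit = mask & (reason == "")
        reason[hit] = name
    out["valid"] = reason == ""
    out["exclusion_reason"] = reason
    return out


def exclusion_rate(n_excluded: int, n_total: int) -> float:
    """Exclusion percentage as conventionally reported (one decimal place)."""
    if n_total <= 0:
        raise InvalidParameterError("n_total must be positive")
    return round(100.0 * n_excluded / n_total, 1)


def exclusion_report(df: pd.DataFrame) -> dict:
    """Summary of the exclusion filter over a trial table."""
    if "valid" not in df.columns:
        df = filter_trials(df)
    n_total = len(df)
    n_excluded = int((~df["valid"]).sum())
    by_reason = (df.loc[~df["valid"], "exclusion_reason"]
                 .value_counts().to_dict())
    return {
        "n_total": n_total,
        "n_excluded": n_excluded,
        "percent_excluded": exclusion_rate(n_excluded, n_total),
        "by_reason": by_reason,
    }


# ---------------------------------------------------------------------------
# Three-component mixture model (target / nontarget / uniform)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureFit:
    """Fitted weights and concentration of the response mixture."""

    p_target: float
    p_nontarget: float
    p_uniform: float
    kappa: float
    loglik: float
    n_iter: int
    converged: bool
    kappa_identifiable: bool = True

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.p_target, self.p_nontarget, self.p_uniform)


_KAPPA_MAX = 1e7


def _vm_logpdf(dev_rad, kappa):
    return kappa * (np.cos(dev_rad) - 1.0) - np.log(2 * np.pi * special.i0e(kappa))


def _a1inv(r):
    """Inverse of A1(kappa) = I1/I0 (Best & Fisher approximation)."""
    r = min(max(r, 0.0), 1.0 - 1e-12)
    if r < 0.53:
        k = 2 * r + r ** 3 + 5 * r ** 5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)
    return float(min(max(k, 1e-6), _KAPPA_MAX))


def fit_mixture(df: pd.DataFrame, max_iter: int = 500, tol: float = 1e-8) -> MixtureFit:
    """EM fit of the target / nontarget / uniform response mixture.

    The target component is von Mises about the cued location; the swap
    component places von Mises components (shared concentration, equal
    sub-weights) on every nontarget location; guesses are uniform.  With
    only set-size-1 trials the nontarget weight is fixed at zero.  The EM
    log-likelihood is non-decreasing across iterations.
    """
    if len(df) < 30:
        raise InvalidParameterError(
            f"need at least 30 trials for a mixture fit, got {len(df)}"
        )
    dev_t = np.deg2rad(wrap_deg(df["response_angle"].to_numpy(float)
                                - df["target_angle"].to_numpy(float)))
    nts = [_parse_nontargets(v) for v in df["nontarget_angles"]]
    resp = df["response_angle"].to_numpy(float)
    dev_nt = [np.deg2rad(wrap_deg(resp[i] - nts[i])) if nts[i].size else
              np.array([]) for i in range(len(df))]
    n = len(dev_t)
    any_nt = any(d.size for d in dev_nt)

    # moment-based initialization from target deviations
    r0 = float(np.abs(np.mean(np.exp(1j * dev_t))))
    kappa = max(_a1inv(r0), 0.5)
    p_t, p_n, p_u = (0.9, 0.05, 0.05) if any_nt else (0.95, 0.0, 0.05)

    log_u = -np.log(2 * np.pi)
    prev_ll = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E-step: per-trial component densities
        f_t = np.exp(_vm_logpdf(dev_t, kappa))
        f_n = np.zeros(n)
        for i, d in enumerate(dev_nt):
            if d.size:
                f_n[i] = np.mean(np.exp(_vm_logpdf(d, kappa)))
        mix = p_t * f_t + p_n * f_n + p_u * np.exp(log_u)
        mix = np.maximum(mix, 1e-300)
        ll = float(np.sum(np.log(mix)))
        w_t = p_t * f_t / mix
        w_n = p_n * f_n / mix
        w_u = 1.0 - w_t - w_n
        # M-step
        p_t = float(np.mean(w_t))
        p_n = float(np.mean(w_n)) if any_nt else 0.0
        p_u = max(1.0 - p_t - p_n, 0.0)
        # concentration from responsibility-weighted resultant of deviations
        zc = np.sum(w_t * np.cos(dev_t))
        zs = np.sum(w_t * np.sin(dev_t))
        wsum = np.sum(w_t)
        for i, d in enumerate(dev_nt):
            if d.size and w_n[i] > 0:
                f_each = np.exp(_vm_logpdf(d, kappa))
                sub = f_each / max(f_each.sum(), 1e-300)
                zc += w_n[i] * np.sum(sub * np.cos(d))
                zs += w_n[i] * np.sum(sub * np.sin(d))
                wsum += w_n[i]
        if wsum > 1e-6:
            kappa = _a1inv(np.hypot(zc, zs) / wsum)
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    kappa_ok = wsum > max(1e-3 * n, 1.0)
    if kappa < 0.5:
        # a near-flat von Mises is indistinguishable from the uniform
        # component; resolve the label degeneracy in favor of 'uniform'
        # and flag the concentration as unidentifiable
        p_u = min(1.0, p_u + p_t + p_n)
        p_t, p_n = 0.0, 0.0
        kappa_ok = False
    return MixtureFit(p_target=p_t, p_nontarget=p_n, p_uniform=p_u,
                      kappa=kappa, loglik=prev_ll, n_iter=n_iter,
                      converged=converged, kappa_identifiable=bool(kappa_ok))


def _posteriors(df: pd.DataFrame, fit: MixtureFit) -> np.ndarray:
    dev_t = np.deg2rad(wrap_deg(df["response_angle"].to_numpy(float)
                                - df["target_angle"].to_numpy(float)))
    resp = df["response_angle"].to_numpy(float)
    nts = [_parse_nontargets(v) for v in df["nontarget_angles"]]
    f_t = np.exp(_vm_logpdf(dev_t, fit.kappa))
    f_n = np.zeros(len(df))
    for i, ang in enumerate(nts):
        if ang.size:
            d = np.deg2rad(wrap_deg(resp[i] - ang))
            f_n[i] = np.mean(np.exp(_vm_logpdf(d, fit.kappa)))
    f_u = np.full(len(df), 1.0 / (2 * np.pi))
    num_t = fit.p_target * f_t
    num_n = fit.p_nontarget * f_n
    num_u = fit.p_uniform * f_u
    total = np.maximum(num_t + num_n + num_u, 1e-300)
    return np.column_stack([num_t, num_n, num_u]) / total[:, None]


def classify_trials(df: pd.DataFrame, fit: MixtureFit,
                    threshold: float = 0.75) -> pd.DataFrame:
    """Label each trial target / nontarget / uniform from mixture posteriors.

    A trial is a target response iff its posterior probability of arising
    from the target component strictly exceeds ``threshold`` (a posterior
    exactly at the threshold is not a target).  Remaining trials take the
    larger of the nontarget and uniform posteriors.
    """
    post = _posteriors(df, fit)
    out = df.copy()
    out["target_posterior"] = post[:, 0]
    labels = np.where(post[:, 0] > threshold, "target",
                      np.where(post[:, 1] >= post[:, 2], "nontarget", "uniform"))
    out["trial_class"] = labels
    return out


# ---------------------------------------------------------------------------
# Behavioral summaries
# ---------------------------------------------------------------------------


def _precision(dev_deg: np.ndarray, measure: str) -> float:
    if measure == "rmsd":
        return float(np.sqrt(np.mean(dev_deg ** 2)))
    if measure == "csd":
        r = float(np.abs(np.mean(np.exp(1j * np.deg2rad(dev_deg)))))
        r = min(max(r, 1e-300), 1.0)
        return float(np.rad2deg(np.sqrt(-2 * np.log(r))))
    if measure == "mae":
        return float(np.mean(np.abs(dev_deg)))
    raise InvalidParameterError(f"unknown precision measure {measure!r}")


def condition_difference(memory: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Plain per-cell subtraction of control summaries from memory summaries.

    Both inputs are outputs of :func:`summarize_conditions`; the result
    holds precision and median-latency differences per (set size, delay)
    cell, used to remove non-memory effects (e.g. preparedness) that are
    common to both task conditions.
    """
    keys = ["set_size", "delay"]
    merged = memory.merge(control, on=keys, suffixes=("_mem", "_ctl"))
    out = merged[keys].copy()
    for col in ("precision_deg", "median_latency"):
        out[col + "_diff"] = merged[col + "_mem"] - merged[col + "_ctl"]
    out["flagged"] = merged["flagged_mem"] | merged["flagged_ctl"]
    return out


def summarize_conditions(df: pd.DataFrame, measure: str = "rmsd",
                         min_trials: int = 5) -> pd.DataFrame:
    """Per-(set size, delay) precision and median latency of target trials.

    Precision defaults to the RMSD of wrapped signed deviations in degrees
    (circular SD and mean absolute error are available via ``measure``).
    Cells with fewer than ``min_trials`` target trials are flagged, not
    dropped.
    """
    if "trial_class" in df.columns:
        df = df[df["trial_class"] == "target"]
    rows = []
    for (n, td), cell in df.groupby(["set_size", "delay"]):
        dev = wrap_deg(cell["response_angle"].to_numpy(float)
                       - cell["target_angle"].to_numpy(float))
        rows.append({
            "set_size": int(n),
            "delay": float(td),
            "n_trials": len(cell),
            "precision_deg": _precision(dev, measure) if len(cell) else np.nan,
            "median_latency": float(np.median(cell["latency"])) if len(cell)
            else np.nan,
            "flagged": len(cell) < min_trials,
        })
    return pd.DataFrame(rows).sort_values(["set_size", "delay"]).reset_index(drop=True)
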