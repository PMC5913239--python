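"""Concentration-response fitting and scalar response indices.

Covers four-parameter logistic (4PL) fits of agonist dose-response data,
normalization of responses to the assay maximum defined by a reference
agonist's fitted top, the insulin stimulation index (fold increase over the
glucose-only control), percent release (secreted over total synthesized
pool), baseline normalization of time-series traces (F/F_baseline), and
baseline-referenced trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ConcentrationResponseSet",
    "FourPLFit",
    "SecretionSample",
    "ResponseTrace",
    "fit_4pl",
    "normalize_to_assay_max",
    "insulin_stimulation_index",
    "percent_release",
    "baseline_normalize",
    "trace_auc",
]

HILL_BOUNDS = (0.2, 5.0)


@dataclass
class ConcentrationResponseSet:
    """Replicate-structured responses for one agonist on one pathway.

    ``responses`` has shape (n_replicates, n_concentrations); missing
    replicate readings are NaN.
    """

    agonist: str
    pathway: str
    concentrations: np.ndarray  # molar
    responses: np.ndarray
    is_reference: bool = False
    experiment: int = 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive (molar)")
        if np.unique(self.concentrations).size < 4:
            raise ValueError("need >= 4 distinct concentrations")
        if self.responses.shape[1] != self.concentrations.size:
            raise ValueError("responses must have one column per concentration")

    def mean_responses(self) -> np.ndarray:
        return np.nanmean(self.responses, axis=0)


@dataclass
class FourPLFit:
    bottom: float
    top: float
    log10_ec50: float
    hill: float
    se: dict[str, float]
    converged: bool
    no_response: bool = False

    @property
    def ec50(self) -> float:
        return 10.0**self.log10_ec50


@dataclass
class SecretionSample:
    condition: str
    secreted: float
    residual_content: float | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.secreted < 0 or (self.residual_content is not None and self.residual_content < 0):
            raise ValueError("secretion quantities must be non-negative")


@dataclass
class ResponseTrace:
    time_min: np.ndarray
    signal: np.ndarray
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")
        a, b = self.baseline_window
        if a < self.time_min[0] or b > self.time_min[-1] or a >= b:
            raise ValueError("baseline window must lie within the trace")


def _4pl(logx: np.ndarray, bottom: float, top: float, log10_ec50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_ec50 - logx) * hill))


def fit_4pl(crs: ConcentrationResponseSet, flat_tol: float | None = None) -> FourPLFit:
    """Least-squares 4PL fit on the log10-concentration scale.

    Flat data (response span below ``flat_tol``, default 2% of the absolute
    signal level) are flagged ``no_response`` with undefined parameters
    rather than producing an arbitrary curve.  Hill slope is bounded to
    [0.2, 5] for stability on sparse grids.
    """
    logx = np.log10(crs.concentrations)
    # replicate-average per concentration; intra-experiment replicates count once
    y = crs.mean_responses()
    span = float(np.nanmax(y) - np.nanmin(y))
    if flat_tol is None:
        flat_tol = 0.02 * max(float(np.nanmax(np.abs(y))), 1e-12)
    if span <= flat_tol:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, {}, converged=False, no_response=True)

    p0 = [float(np.nanmin(y)), float(np.nanmax(y)), float(logx[np.nanargmin(np.abs(y - np.nanmean(y)))]), 1.0]
    lo = [-np.inf, -np.inf, logx.min() - 6, HILL_BOUNDS[0]]
    hi = [np.inf, np.inf, logx.max() + 6, HILL_BOUNDS[1]]
    try:
        popt, pcov = curve_fit(_4pl, logx, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        converged = np.all(np.isfinite(popt))
    except RuntimeError:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, {}, converged=False)
    se = dict(zip(("bottom", "top", "log10_ec50", "hill"), perr))
    bottom, top, log_ec50, hill = popt
    if top < bottom:  # reflect to the standard orientation
        bottom, top, hill = top, bottom, -hill
    return FourPLFit(float(bottom), float(top), float(log_ec50), float(hill), se, bool(converged))


def normalize_to_assay_max(
    sets: Sequence[ConcentrationResponseSet], reference_fit: FourPLFit
) -> list[ConcentrationResponseSet]:
    """Express responses as % of the reference agonist's fitted top.

    The assay maximum is the fitted ``top`` of the full reference-agonist
    curve run on the same plate, so the reference's own top maps to 100%.
    """
    if reference_fit.no_response or not reference_fit.converged:
        raise ValueError("cannot normalize: reference fit is flat or did not converge")
    scale = 100.0 / reference_fit.top
    return [replace(s, responses=s.responses * scale) for s in sets]


def insulin_stimulation_index(samples: Sequence[SecretionSample]) -> pd.Series:
    """Fold secretion increase of each condition over the glucose-only control.

    Samples carrying a residual-content measurement are first converted to
    percent release so conditions with different cell numbers compare fairly;
    otherwise raw secreted amounts are used.
    """
    controls = [s for s in samples if s.is_control]
    if not controls:
        raise ValueError("at least one control (glucose-only) sample required")

    def value(s: SecretionSample) -> float:
        if s.residual_content is not None:
            return percent_release(s.secreted, s.residual_content)
        return s.secreted

    control_mean = float(np.mean([value(s) for s in controls]))
    if control_mean == 0:
        raise ZeroDivisionError("control mean secretion is zero; ISI undefined")
    by_cond: dict[str, list[float]] = {}
    for s in samples:
        by_cond.setdefault(s.condition, []).append(value(s))
    return pd.Series(
        {cond: float(np.mean(v)) / control_mean for cond, v in by_cond.items()}, name="isi"
    )


def percent_release(secreted: float, residual_content: float) -> float:
    """Secreted insulin as % of the total pool (secreted + residual content)."""
    if secreted < 0 or residual_content < 0:
        raise ValueError("quantities must be non-negative")
    total = secreted + residual_content
    if total == 0:
        raise ZeroDivisionError("secreted and residual content both zero")
    return 100.0 * secreted / total


def baseline_normalize(trace: ResponseTrace) -> ResponseTrace:
    """Divide a trace by its mean over the baseline window (F/F_baseline)."""
    a, b = trace.baseline_window
    mask = (trace.time_min >= a) & (trace.time_min <= b)
    if mask.sum() < 2:
        raise ValueError("baseline window must contain >= 2 samples")
    baseline = float(np.mean(trace.signal[mask]))
    if baseline == 0:
        raise ZeroDivisionError("baseline mean is zero")
    return ResponseTrace(trace.time_min, trace.signal / baseline, trace.baseline_window)


def trace_auc(
    trace: ResponseTrace, t_start: float, t_end: float, baseline_value: float
) -> float:
    """Trapezoidal area of (signal - baseline) over [t_start, t_end]; may be negative."""
    if t_start >= t_end:
        raise ValueError("t_start must precede t_end")
    if t_start < trace.time_min[0] or t_end > trace.time_min[-1]:
        raise ValueError("integration window must lie within the trace")
    grid = np.unique(np.concatenate([[t_start, t_end], trace.time_min[
        (trace.time_min > t_start) & (trace.time_min < t_end)
    ]]))
    y = np.interp(grid, trace.time_min, trace.signal) - baseline_value
    return float(np.trapezoid(y, grid))
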