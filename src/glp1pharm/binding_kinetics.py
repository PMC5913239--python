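"""Receptor-ligand binding kinetics from time-resolved FRET traces.

Implements specific-binding computation (total minus nonspecific), one-phase
dissociation fitting, the closed-form competitive-association model for a
labeled tracer binding in the presence of an unlabeled competitor
(Motulsky & Mahan), a global fit of that model across competitor
concentrations, and the derived constants residence time = 1/k_off and
K_d = k_off/k_on.

Units are minutes for time and molar for concentrations throughout, so
association rates are 1/(M*min), dissociation rates 1/min and residence
times minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingTrace",
    "TracerParams",
    "KineticParams",
    "MmIntermediates",
    "specific_binding",
    "fit_dissociation",
    "DissociationFit",
    "mm_intermediates",
    "mm_predict",
    "fit_competitive",
    "derive_constants",
]

# Relative eigenvalue gap below which the repeated-root limit of the
# competitive-binding solution is used instead of the direct formula.
DEGENERATE_ROOT_RTOL = 1e-9


@dataclass
class BindingTrace:
    """A single time-resolved specific-binding (or raw ratio) trace.

    ``signal`` is the TR-FRET acceptor/donor ratio (520 nm over 620 nm for
    surface binding) or, after processing, specific binding in the same
    arbitrary units.
    """

    time_min: np.ndarray
    signal: np.ndarray
    tracer_conc: float = 0.0
    competitor: str | None = None
    competitor_conc: float = 0.0
    condition: str = "total"  # "total" | "nonspecific"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_min.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.tracer_conc < 0 or self.competitor_conc < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass
class TracerParams:
    """Kinetic parameters of the labeled tracer (k1, k2) and plate Bmax."""

    k1: float  # association, 1/(M*min)
    k2: float  # dissociation, 1/min
    bmax: float  # signal units

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("tracer rate constants must be positive")


@dataclass
class KineticParams:
    """Competitor rate constants and the derived residence time and K_d."""

    k_on: float  # 1/(M*min)
    k_off: float  # 1/min
    residence_time: float  # min
    k_d: float  # M
    se_k_on: float = np.nan
    se_k_off: float = np.nan
    converged: bool = True
    bmax: float = np.nan


@dataclass
class MmIntermediates:
    """Internal rate aggregates of the competitive-binding solution (1/min)."""

    k_a: float
    k_b: float
    s: float
    k_f: float
    k_s: float


@dataclass
class DissociationFit:
    k_off: float
    b0: float
    se_k_off: float
    se_b0: float
    half_life: float
    no_dissociation: bool = False


def specific_binding(
    total: BindingTrace, nonspecific: BindingTrace, clip_negative: bool = False
) -> BindingTrace:
    """Subtract nonspecific binding (excess unlabeled agonist) pointwise.

    Nonspecific traces sampled on a different grid are linearly interpolated
    onto the total trace's grid; disjoint time ranges are an error.
    """
    t = total.time_min
    if nonspecific.time_min[0] > t[-1] or nonspecific.time_min[-1] < t[0]:
        raise ValueError("total and nonspecific traces cover disjoint time ranges")
    if np.array_equal(nonspecific.time_min, t):
        ns = nonspecific.signal
    else:
        ns = np.interp(t, nonspecific.time_min, nonspecific.signal)
    sig = total.signal - ns
    if clip_negative:
        sig = np.clip(sig, 0.0, None)
    return BindingTrace(
        time_min=t,
        signal=sig,
        tracer_conc=total.tracer_conc,
        competitor=total.competitor,
        competitor_conc=total.competitor_conc,
        condition="total",
    )


def fit_dissociation(trace: BindingTrace) -> DissociationFit:
    """Fit a one-phase exponential decay B(t) = B0*exp(-k_off*t).

    The plateau is fixed at zero: after nonspecific subtraction, specific
    binding under complete blockade must decay to nothing.  A trace that does
    not decrease overall is flagged ``no_dissociation`` rather than fitted.
    """
    t = trace.time_min - trace.time_min[0]
    y = trace.signal
    if y[-1] >= y[0] or np.all(np.diff(y) >= 0):
        return DissociationFit(np.nan, np.nan, np.nan, np.nan, np.nan, no_dissociation=True)

    b0_init = max(y[0], 1e-12)
    # crude rate guess from the time to drop to half the initial signal
    below = np.nonzero(y <= b0_init / 2)[0]
    k_init = np.log(2.0) / t[below[0]] if below.size and t[below[0]] > 0 else 1.0 / t[-1]

    def resid(p: np.ndarray) -> np.ndarray:
        b0, log_k = p
        return b0 * np.exp(-np.exp(log_k) * t) - y

    sol = least_squares(resid, x0=[b0_init, np.log(k_init)], method="lm")
    b0, log_k = sol.x
    k_off = float(np.exp(log_k))
    se_b0, se_logk = _covariance_se(sol)
    return DissociationFit(
        k_off=k_off,
        b0=float(b0),
        se_k_off=k_off * se_logk,  # delta method on log scale
        se_b0=se_b0,
        half_life=np.log(2.0) / k_off,
    )


def mm_intermediates(
    k1: float, k2: float, k3: float, k4: float, tracer_conc: float, competitor_conc: float
) -> MmIntermediates:
    """Rate aggregates K_A, K_B, S and the fast/slow eigenrates K_F, K_S."""
    k_a = k1 * tracer_conc + k2
    k_b = k3 * competitor_conc + k4
    s = np.sqrt((k_a - k_b) ** 2 + 4.0 * k1 * k3 * tracer_conc * competitor_conc)
    k_f = 0.5 * (k_a + k_b + s)
    k_s = 0.5 * (k_a + k_b - s)
    return MmIntermediates(k_a=k_a, k_b=k_b, s=s, k_f=k_f, k_s=k_s)


def mm_predict(
    tracer: TracerParams,
    k3: float,
    k4: float,
    tracer_conc: float,
    competitor_conc: float,
    times: np.ndarray,
) -> np.ndarray:
    """Closed-form tracer-receptor occupancy under competitive association.

    Tracer (rates k1, k2 at concentration [L]) and unlabeled competitor
    (rates k3, k4 at [I]) are added simultaneously to free receptor, and the
    tracer-bound signal is

        RL(t) = Q * [ k4*(K_F - K_S)/(K_F*K_S)
                      + (k4 - K_F)/K_F * exp(-K_F t)
                      - (k4 - K_S)/K_S * exp(-K_S t) ],
        Q = Bmax*k1*[L] / (K_F - K_S),

    with the analytic repeated-root limit substituted when K_F ≈ K_S.
    """
    if k3 < 0 or k4 < 0 or tracer_conc < 0 or competitor_conc < 0:
        raise ValueError("rates and concentrations must be non-negative")
    t = np.asarray(times, dtype=float)
    mm = mm_intermediates(tracer.k1, tracer.k2, k3, k4, tracer_conc, competitor_conc)
    k_f, k_s = mm.k_f, mm.k_s
    c = tracer.bmax * tracer.k1 * tracer_conc
    d = k_f - k_s
    if d <= DEGENERATE_ROOT_RTOL * k_f:
        # repeated root K = K_F = K_S: terms 2-3 collapse to the derivative
        # of f(K) = (k4 - K)/K * exp(-K t) at the common root.
        k = 0.5 * (k_f + k_s)
        fprime = (-k4 / k**2) * np.exp(-k * t) + ((k4 - k) / k) * (-t) * np.exp(-k * t)
        return c * (k4 / (k_f * k_s) + fprime)
    q = c / d
    return q * (
        k4 * d / (k_f * k_s)
        + ((k4 - k_f) / k_f) * np.exp(-k_f * t)
        - ((k4 - k_s) / k_s) * np.exp(-k_s * t)
    )


def fit_competitive(
    traces: Sequence[BindingTrace],
    tracer: TracerParams,
    co_fit_bmax: bool = False,
    x0: tuple[float, float] | None = None,
) -> KineticParams:
    """Global fit of the competitive-association model across traces.

    All traces must share the tracer concentration; at least four distinct
    competitor concentrations spanning >= 10-fold are required, matching the
    design of the assay.  Tracer k1/k2 are taken as known (estimated from
    competitor-free traces upstream); Bmax may optionally be co-fit, shared
    across all traces on the plate.
    """
    if len({round(tr.competitor_conc, 15) for tr in traces}) < 4:
        raise ValueError("need >= 4 distinct competitor concentrations")
    tracer_concs = {tr.tracer_conc for tr in traces}
    if len(tracer_concs) != 1:
        raise ValueError("all traces must share the tracer concentration")
    tracer_conc = tracer_concs.pop()
    concs = np.array(sorted(tr.competitor_conc for tr in traces))
    positive = concs[concs > 0]
    if positive.size and positive.max() / positive.min() < 10.0:
        raise ValueError("competitor concentrations must span >= 10-fold")

    if x0 is None:
        x0 = (1e7, 0.1)
    log_x0 = [np.log(x0[0]), np.log(x0[1])]
    if co_fit_bmax:
        log_x0.append(np.log(tracer.bmax))

    def resid(p: np.ndarray) -> np.ndarray:
        k3, k4 = np.exp(p[0]), np.exp(p[1])
        trc = tracer if not co_fit_bmax else TracerParams(tracer.k1, tracer.k2, np.exp(p[2]))
        out = [
            mm_predict(trc, k3, k4, tracer_conc, tr.competitor_conc, tr.time_min) - tr.signal
            for tr in traces
        ]
        return np.concatenate(out)

    sol = least_squares(resid, x0=log_x0, method="lm", xtol=1e-12, ftol=1e-12)
    k_on, k_off = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
    ses = _covariance_se(sol)
    residence, k_d = derive_constants(k_on, k_off)
    return KineticParams(
        k_on=k_on,
        k_off=k_off,
        residence_time=residence,
        k_d=k_d,
        se_k_on=k_on * ses[0],
        se_k_off=k_off * ses[1],
        converged=sol.success,
        bmax=float(np.exp(sol.x[2])) if co_fit_bmax else tracer.bmax,
    )


def derive_constants(k_on: float, k_off: float) -> tuple[float, float]:
    """Residence time = 1/k_off (min) and K_d = k_off/k_on (M)."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rate constants must be positive")
    return 1.0 / k_off, k_off / k_on


def _covariance_se(sol) -> np.ndarray:
    """Parameter standard errors from a least_squares solution's Jacobian."""
    dof = max(sol.fun.size - sol.x.size, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(sol.x.size, np.nan)
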