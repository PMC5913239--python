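"""Signal-bias quantification via the operational model of agonism.

Concentration-response panels (all agonists on one pathway, one experiment)
are fitted globally with the transduction-coefficient parameterization of
the operational model,

    E([A]) = basal + (E_m - basal) / (1 + ((1 + [A]/K_A) / (R*[A]))^n),
    R = 10^log10(tau/K_A),

with E_m, basal and the transducer slope n shared across agonists within a
pathway and log10(tau/K_A), log10(K_A) free per agonist.  Parameterizing the
fit directly in log(tau/K_A) makes the transduction coefficient a fitted
quantity rather than a ratio of two weakly identified parameters.

Bias is then the usual double-difference: per experiment, log(tau/K_A) is
normalized to the reference agonist (Delta), Deltas are averaged across
experiments with SEM, and the between-pathway contrast DeltaDelta carries a
propagated standard error sqrt(SEM_A^2 + SEM_B^2) and a 95% CI; an agonist
is called biased when that CI excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .response_quant import ConcentrationResponseSet

__all__ = [
    "OperationalFit",
    "BiasTable",
    "BiasContrast",
    "fit_operational_model",
    "delta_log_tka",
    "ddelta_log_tka",
    "web_of_bias",
    "operational_response",
]

HILL_BOUNDS = (0.2, 5.0)


def operational_response(
    conc: np.ndarray,
    basal: float,
    e_max: float,
    hill: float,
    log10_ka: float,
    log10_tau_over_ka: float,
) -> np.ndarray:
    """Operational-model mean response at agonist concentrations ``conc`` (M)."""
    conc = np.asarray(conc, dtype=float)
    ka = 10.0**log10_ka
    r = 10.0**log10_tau_over_ka
    ratio = (1.0 + conc / ka) / (r * conc)
    return basal + (e_max - basal) / (1.0 + ratio**hill)


@dataclass
class OperationalFit:
    """Global operational-model fit for one pathway in one experiment."""

    pathway: str
    experiment: int
    e_max: float
    basal: float
    hill: float
    # per-agonist tables indexed by agonist id
    log10_ka: pd.Series
    log10_tau_over_ka: pd.Series
    se_log10_tau_over_ka: pd.Series
    quantifiable: pd.Series
    converged: bool = True
    reference: str | None = None

    def params_for(self, agonist: str) -> tuple[float, float]:
        return float(self.log10_ka[agonist]), float(self.log10_tau_over_ka[agonist])


@dataclass
class BiasTable:
    """Per-experiment Delta log(tau/K_A) values and their cross-experiment summary."""

    per_experiment: pd.DataFrame  # columns: agonist, pathway, experiment, delta
    summary: pd.DataFrame  # columns: agonist, pathway, mean, sem, n
    reference: str


@dataclass
class BiasContrast:
    agonist: str
    pathway_a: str
    pathway_b: str
    ddelta: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool
    bias_factor: float


def _initial_log_r(crs: ConcentrationResponseSet, basal: float, e_max: float) -> float:
    """Half-max crossing concentration as a cheap pEC50-like init for log(tau/K_A)."""
    y = crs.mean_responses()
    half = basal + 0.5 * (np.nanmax(y) - basal)
    above = np.nonzero(y >= half)[0]
    idx = above[0] if above.size else y.size // 2
    return -float(np.log10(crs.concentrations[idx]))


def fit_operational_model(
    panel: Sequence[ConcentrationResponseSet],
    reference: str | None = None,
    noise_floor: float | None = None,
) -> OperationalFit:
    """Globally fit one pathway's agonist panel with shared E_m, basal, n.

    Agonists whose response span never rises above ``noise_floor`` (default
    5% of the panel-wide span) are flagged unquantifiable and excluded from
    the fit; their parameters are NaN, never imputed.
    """
    if not panel:
        raise ValueError("empty panel")
    pathways = {c.pathway for c in panel}
    if len(pathways) != 1:
        raise ValueError("panel must contain a single pathway")
    pathway = pathways.pop()
    experiments = {c.experiment for c in panel}
    experiment = experiments.pop() if len(experiments) == 1 else -1

    if reference is None:
        refs = [c.agonist for c in panel if c.is_reference]
        reference = refs[0] if refs else None
    if reference is not None and reference not in {c.agonist for c in panel}:
        raise ValueError(f"reference agonist {reference!r} absent from panel")

    spans = {c.agonist: float(np.ptp(c.mean_responses())) for c in panel}
    if noise_floor is None:
        noise_floor = 0.05 * max(spans.values())
    quantifiable = {a: s > noise_floor for a, s in spans.items()}
    if reference is not None and not quantifiable[reference]:
        raise ValueError("reference agonist is unquantifiable in this panel")

    fit_sets = [c for c in panel if quantifiable[c.agonist]]
    agonists = [c.agonist for c in fit_sets]

    all_y = np.concatenate([c.mean_responses() for c in fit_sets])
    basal0 = float(np.min(all_y))
    ymax = float(np.max(all_y))
    emax0 = ymax * 1.05
    # constrain the system maximum near the observed maximal response: with a
    # transducer slope near 1 the model is flat along an E_m/K_A/(tau/K_A)
    # trade-off, and an unbounded E_m wanders off along it
    p0 = [basal0, emax0, 1.0]
    lo = [-np.inf, 0.5 * ymax, HILL_BOUNDS[0]]
    hi = [np.inf, 3.0 * ymax, HILL_BOUNDS[1]]
    for c in fit_sets:
        log_r0 = _initial_log_r(c, basal0, emax0)  # ~ pEC50
        p0 += [-log_r0 + 1.0, log_r0]  # K_A initialized one decade above EC50
        lo += [-15.0, -5.0]
        hi += [0.0, 20.0]

    def unpack(p: np.ndarray):
        basal, e_max, hill = p[0], p[1], p[2]
        per = {a: (p[3 + 2 * i], p[4 + 2 * i]) for i, a in enumerate(agonists)}
        return basal, e_max, hill, per

    def resid(p: np.ndarray) -> np.ndarray:
        basal, e_max, hill, per = unpack(p)
        out = []
        for c in fit_sets:
            lka, lr = per[c.agonist]
            pred = operational_response(c.concentrations, basal, e_max, hill, lka, lr)
            obs = c.responses
            out.append((pred[None, :] - obs)[~np.isnan(obs)])
        return np.concatenate(out)

    sol = least_squares(
        resid, x0=p0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10, gtol=1e-10,
        x_scale="jac", max_nfev=2000,
    )
    basal, e_max, hill, per = unpack(sol.x)

    # SEs from the Jacobian; log(tau/K_A) entries sit at 4 + 2i
    dof = max(sol.fun.size - sol.x.size, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * s2
        se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(sol.x.size, np.nan)

    idx = sorted({c.agonist for c in panel})
    log_ka = pd.Series(np.nan, index=idx, dtype=float)
    log_r = pd.Series(np.nan, index=idx, dtype=float)
    se_r = pd.Series(np.nan, index=idx, dtype=float)
    for i, a in enumerate(agonists):
        log_ka[a], log_r[a] = per[a]
        se_r[a] = se_all[4 + 2 * i]
    return OperationalFit(
        pathway=pathway,
        experiment=experiment,
        e_max=float(e_max),
        basal=float(basal),
        hill=float(hill),
        log10_ka=log_ka,
        log10_tau_over_ka=log_r,
        se_log10_tau_over_ka=se_r,
        quantifiable=pd.Series(quantifiable).reindex(idx).astype(bool),
        converged=bool(sol.success),
        reference=reference,
    )


def delta_log_tka(fits: Sequence[OperationalFit], reference: str) -> BiasTable:
    """Normalize log(tau/K_A) to the reference agonist within each experiment.

    Experiments in which the reference is unquantifiable are excluded with a
    warning; the cross-experiment mean, SEM and n are reported per agonist
    and pathway.
    """
    rows = []
    for fit in fits:
        if reference not in fit.quantifiable.index or not fit.quantifiable[reference]:
            warnings.warn(
                f"reference {reference!r} unquantifiable in pathway {fit.pathway} "
                f"experiment {fit.experiment}; experiment excluded",
                stacklevel=2,
            )
            continue
        ref_val = fit.log10_tau_over_ka[reference]
        for agonist in fit.log10_tau_over_ka.index:
            if not fit.quantifiable[agonist]:
                continue
            rows.append(
                {
                    "agonist": agonist,
                    "pathway": fit.pathway,
                    "experiment": fit.experiment,
                    "delta": float(fit.log10_tau_over_ka[agonist] - ref_val),
                }
            )
    per_exp = pd.DataFrame(rows, columns=["agonist", "pathway", "experiment", "delta"])
    grp = per_exp.groupby(["agonist", "pathway"])["delta"]
    summary = grp.agg(mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else 0.0, n="count")
    summary = summary.reset_index()
    return BiasTable(per_experiment=per_exp, summary=summary, reference=reference)


def ddelta_log_tka(
    table: BiasTable,
    pathway_a: str,
    pathway_b: str,
    ci_method: str = "z",
) -> pd.DataFrame:
    """Between-pathway bias contrast DeltaDelta log(tau/K_A) per agonist.

    SE is propagated from the two cross-experiment SEMs; the 95% CI uses
    z = 1.96 by default or a Student-t multiplier with Welch-Satterthwaite
    degrees of freedom (``ci_method='t'``).  ``significant`` records whether
    the CI excludes zero.
    """
    s = table.summary.set_index(["agonist", "pathway"])
    agonists = sorted({a for a, _ in s.index})
    rows = []
    for agonist in agonists:
        if (agonist, pathway_a) not in s.index or (agonist, pathway_b) not in s.index:
            continue
        a, b = s.loc[(agonist, pathway_a)], s.loc[(agonist, pathway_b)]
        dd = float(a["mean"] - b["mean"])
        se = float(np.hypot(a["sem"], b["sem"]))
        if ci_method == "t":
            va, vb = a["sem"] ** 2, b["sem"] ** 2
            if va + vb > 0 and a["n"] > 1 and b["n"] > 1:
                df = (va + vb) ** 2 / (va**2 / (a["n"] - 1) + vb**2 / (b["n"] - 1))
            else:
                df = max(a["n"] + b["n"] - 2, 1)
            mult = float(stats.t.ppf(0.975, df))
        elif ci_method == "z":
            mult = 1.959963984540054
        else:
            raise ValueError("ci_method must be 'z' or 't'")
        lo, hi = dd - mult * se, dd + mult * se
        significant = bool(se > 0 and (lo > 0 or hi < 0))
        rows.append(
            BiasContrast(
                agonist=agonist,
                pathway_a=pathway_a,
                pathway_b=pathway_b,
                ddelta=dd,
                se=se,
                ci_low=lo,
                ci_high=hi,
                significant=significant,
                bias_factor=float(10.0**dd),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def web_of_bias(table: BiasTable, reference_pathway: str) -> pd.DataFrame:
    """Radar-plot coordinates: 10^(Delta additionally normalized to a pathway).

    Each agonist's mean Delta log(tau/K_A) is re-centered on its own value in
    the reference pathway before taking the inverse logarithm, so the
    reference agonist maps to 1 everywhere and any agonist maps to 1 on the
    reference pathway.  Unquantifiable cells stay absent (NaN).
    """
    piv = table.summary.pivot(index="agonist", columns="pathway", values="mean")
    if reference_pathway not in piv.columns:
        raise ValueError(f"reference pathway {reference_pathway!r} absent")
    normed = piv.sub(piv[reference_pathway], axis=0)
    coords = 10.0**normed
    coords.columns.name = "pathway"
    return coords
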