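"""Multi-readout agonist profiles: feature assembly, PCA, and regressions.

Each agonist's pharmacological fingerprint is a row of: dissociation rate
k_off normalized to the reference agonist within the binding assay, bias
coefficients Delta log(tau/K_A) for cAMP and beta-arrestin-2, and the fixed
time-point internalization and recycling percentages.  The matrix feeds a
standardized PCA and ordinary least-squares relationships such as maximal
internalization vs. prolonged insulin stimulation index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "AgonistFeatureMatrix",
    "PcaResult",
    "RegressionResult",
    "assemble_features",
    "pca_profile",
    "regress_relationship",
]

logger = logging.getLogger("glp1pharm")

DEFAULT_FEATURES = (
    "k_off_norm",
    "dlog_tka_cAMP",
    "dlog_tka_barr2",
    "internalization_pct",
    "recycling_pct",
)


@dataclass
class AgonistFeatureMatrix:
    """Agonist-by-feature table; missing cells are NaN and masked, never imputed."""

    values: pd.DataFrame  # index = agonist, columns = features
    units: dict[str, str]
    reference: str

    @property
    def mask(self) -> pd.DataFrame:
        """True where a feature is missing."""
        return self.values.isna()

    def complete_rows(self) -> pd.DataFrame:
        return self.values.dropna(axis=0, how="any")


@dataclass
class PcaResult:
    scores: pd.DataFrame  # agonists x components
    loadings: pd.DataFrame  # features x components
    variance_explained: np.ndarray  # percent per component, sums to 100


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    x_label: str = "x"
    y_label: str = "y"


def assemble_features(
    bias_summary: pd.DataFrame,
    kinetics: pd.DataFrame,
    trafficking: pd.DataFrame,
    reference: str,
    features: tuple[str, ...] = DEFAULT_FEATURES,
) -> AgonistFeatureMatrix:
    """Join per-assay tables into one agonist-by-feature matrix.

    ``bias_summary`` carries columns (agonist, pathway, mean) of
    Delta log(tau/K_A); ``kinetics`` carries (agonist, k_off); ``trafficking``
    carries (agonist, internalization_pct, recycling_pct).  The kinetic
    feature is normalized to the reference agonist within the assay before
    pooling, so the reference row's value is 1 by construction.  Agonists
    absent from a table get a masked (NaN) cell and a logged warning.
    """
    agonists = sorted(
        set(bias_summary["agonist"])
        | set(kinetics["agonist"])
        | set(trafficking["agonist"])
    )
    mat = pd.DataFrame(np.nan, index=pd.Index(agonists, name="agonist"), columns=list(features))

    kin_cols = {"k_off_norm": "k_off", "residence_time_norm": "residence_time_min"}
    for feat, col in kin_cols.items():
        if feat not in mat.columns or col not in kinetics.columns:
            continue
        kin = kinetics.set_index("agonist")[col]
        if reference in kin.index and kin[reference] > 0:
            mat[feat] = (kin / kin[reference]).reindex(agonists)
        else:
            logger.warning(
                "reference %r missing from kinetics table; %s left unnormalized", reference, col
            )
            mat[feat] = kin.reindex(agonists)

    piv = bias_summary.pivot(index="agonist", columns="pathway", values="mean")
    for pathway in ("cAMP", "barr2"):
        col = f"dlog_tka_{pathway}"
        if col in mat.columns and pathway in piv.columns:
            mat[col] = piv[pathway].reindex(agonists)

    tr = trafficking.set_index("agonist")
    for col in ("internalization_pct", "recycling_pct"):
        if col in mat.columns and col in tr.columns:
            mat[col] = tr[col].reindex(agonists)

    for agonist in agonists:
        missing = mat.columns[mat.loc[agonist].isna()].tolist()
        if missing:
            logger.warning("agonist %r missing features %s; cells masked", agonist, missing)

    units = {
        "k_off_norm": "fold of reference",
        "residence_time_norm": "fold of reference (note: varies inversely with k_off)",
        "dlog_tka_cAMP": "log10",
        "dlog_tka_barr2": "log10",
        "internalization_pct": "%",
        "recycling_pct": "%",
    }
    return AgonistFeatureMatrix(values=mat, units={k: units.get(k, "") for k in features}, reference=reference)


def pca_profile(matrix: AgonistFeatureMatrix, drop_incomplete: bool = False) -> PcaResult:
    """PCA of the z-scored feature matrix.

    Columns are standardized to mean 0 / SD 1 before decomposition, so
    scores are invariant to affine rescaling of any input feature.  Masked
    cells are an error unless ``drop_incomplete`` removes those rows; no
    imputation is ever performed.
    """
    vals = matrix.values
    if vals.isna().any().any():
        if not drop_incomplete:
            raise ValueError(
                "feature matrix contains masked cells; drop or complete those rows "
                "(drop_incomplete=True) - imputation is not supported"
            )
        dropped = vals.index[vals.isna().any(axis=1)].tolist()
        logger.warning("dropping incomplete rows for PCA: %s", dropped)
        vals = vals.dropna(axis=0, how="any")
    if len(vals) < 3:
        raise ValueError("PCA requires >= 3 complete agonist rows")
    x = vals.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z)
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    var_pct = 100.0 * pca.explained_variance_ratio_
    return PcaResult(
        scores=pd.DataFrame(scores, index=vals.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_.T, index=vals.columns, columns=comp_names),
        variance_explained=var_pct,
    )


def regress_relationship(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    x_label: str = "x",
    y_label: str = "y",
) -> RegressionResult:
    """Ordinary least-squares line through per-agonist (x, y) pairs.

    The slope sign is the headline output for relationships such as
    internalization vs. prolonged secretion.  Pairs with a missing member
    are dropped; fewer than 3 remaining pairs or zero variance in x is an
    error.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
        xv, yv = joined["x"].to_numpy(float), joined["y"].to_numpy(float)
    else:
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
        keep = ~(np.isnan(xv) | np.isnan(yv))
        xv, yv = xv[keep], yv[keep]
    if xv.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(xv) == 0:
        raise ValueError("zero variance in x; slope undefined")
    if np.ptp(yv) == 0:
        return RegressionResult(0.0, float(yv[0]), 0.0, 1.0, int(xv.size), x_label, y_label)
    res = stats.linregress(xv, yv)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(xv.size),
        x_label=x_label,
        y_label=y_label,
    )
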