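"""Receptor internalization, recycling, downregulation, and endosomal pH.

Flow-cytometry internalization uses the stripping-corrected ratio formula:
with F+Me / F-Me the median fluorescences with / without surface-label
stripping (MesNa), percent internalized at time t_x is

    100 * [ r(t_x) - r(t_0) ] / [ 1 - r(t_0) ],   r(t) = F+Me(t) / F-Me(t),

which corrects for imperfect stripping via the t_0 ratio.  Plate-reader
surface-labeling metrics, DERET (diffusion-enhanced RET) surface-loss
processing, and FITC-agonist endosomal-pH estimation against a per-ligand
linear fluorescence-pH calibration (with the bafilomycin condition anchored
at pH 7.4) complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FacsMeasurement",
    "RecyclingMeasurement",
    "DeretSeries",
    "PhCalibration",
    "PhEstimate",
    "facs_internalized_percent",
    "facs_recycled_percent",
    "plate_internalization_percent",
    "plate_recycling_percent",
    "deret_surface_loss",
    "surface_downregulation_percent",
    "fit_ph_calibration",
    "estimate_endosomal_ph",
]

BAFILOMYCIN_PH = 7.4
# negative percentages within this tolerance are reported with a flag, not clipped
PERCENT_TOLERANCE = 2.0


@dataclass
class FacsMeasurement:
    """Paired stripped/unstripped median fluorescences at t0 and a later time."""

    condition: str
    time_min: float
    f_plus_me: float  # with stripping
    f_minus_me: float  # without stripping
    f_plus_me_t0: float
    f_minus_me_t0: float

    def __post_init__(self) -> None:
        for v in (self.f_plus_me, self.f_minus_me, self.f_plus_me_t0, self.f_minus_me_t0):
            if v <= 0:
                raise ValueError("fluorescences must be positive")


@dataclass
class RecyclingMeasurement:
    condition: str
    f_int15: float  # internalized label after 15 min pulse + strip
    f_rec: float  # residual internalized label after recycling period + second strip
    internalized_percent_15: float


@dataclass
class DeretSeries:
    time_min: np.ndarray
    a620: np.ndarray  # terbium donor channel
    a520: np.ndarray  # fluorescein acceptor channel
    condition: str = "agonist"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.a620 = np.asarray(self.a620, dtype=float)
        self.a520 = np.asarray(self.a520, dtype=float)
        if np.any(self.a520 == 0):
            raise ZeroDivisionError("zero 520 nm signal in DERET series")
        if np.any(self.a620 <= 0) or np.any(self.a520 < 0):
            raise ValueError("DERET signals must be positive")

    def ratio(self) -> np.ndarray:
        return self.a620 / self.a520


@dataclass
class PhCalibration:
    ligand: str
    slope: float  # AU per pH unit
    intercept: float  # AU
    ph_range: tuple[float, float]
    r_squared: float
    usable: bool = True

    def intensity_at(self, ph: float) -> float:
        return self.intercept + self.slope * ph


@dataclass
class PhEstimate:
    ligand: str
    ph: float
    extrapolated: bool


def facs_internalized_percent(m: FacsMeasurement) -> float:
    """Stripping-corrected percent internalized receptor at ``m.time_min``."""
    r0 = m.f_plus_me_t0 / m.f_minus_me_t0
    if r0 >= 1:
        raise ValueError("t0 stripped/unstripped ratio >= 1: surface stripping failed")
    rx = m.f_plus_me / m.f_minus_me
    pct = 100.0 * (rx - r0) / (1.0 - r0)
    if not -PERCENT_TOLERANCE <= pct <= 100.0 + PERCENT_TOLERANCE:
        import warnings

        warnings.warn(
            f"internalized percent {pct:.1f} outside [0, 100] beyond tolerance "
            f"for condition {m.condition!r}",
            stacklevel=2,
        )
    return float(pct)


def facs_recycled_percent(m: RecyclingMeasurement, absolute: bool = False) -> float:
    """Percent of the 15-min internalized pool that returned to the surface.

    The loss of internal label between the first and second strip,
    100*(F_int15 - F_rec)/F_int15, is the fraction of the internalized pool
    recycled (and re-stripped).  With ``absolute=True`` the result is instead
    expressed in percentage points of total receptor, i.e. scaled by the
    15-min internalized percentage.
    """
    if m.f_int15 <= 0:
        raise ValueError("F_int15 must be positive")
    if m.f_rec > m.f_int15 * (1 + PERCENT_TOLERANCE / 100.0):
        import warnings

        warnings.warn(
            f"residual internal label exceeds the 15-min pool for {m.condition!r}",
            stacklevel=2,
        )
    frac = 100.0 * (m.f_int15 - m.f_rec) / m.f_int15
    if absolute:
        return float(frac * m.internalized_percent_15 / 100.0)
    return float(frac)


def plate_internalization_percent(surface_agonist: float, surface_vehicle: float) -> float:
    """Percent surface-receptor loss from agonist- vs. vehicle-treated wells."""
    if surface_vehicle <= 0:
        raise ValueError("vehicle surface signal must be positive")
    return 100.0 * (1.0 - surface_agonist / surface_vehicle)


def plate_recycling_percent(
    s_vehicle: float, s_after_internalization: float, s_after_recycling: float
) -> float:
    """Percent recovery of surface receptor relative to the internalized deficit."""
    deficit = s_vehicle - s_after_internalization
    if deficit <= 0:
        raise ValueError("no internalization deficit to recover from")
    return 100.0 * (s_after_recycling - s_after_internalization) / deficit


def deret_surface_loss(series: DeretSeries, vehicle: DeretSeries) -> np.ndarray:
    """Vehicle-referenced, baseline-anchored surface-loss time course.

    The per-well donor/acceptor ratio R(t) = A620/A520 rises as surface
    receptors escape fluorescein quenching on internalization.  Each well is
    anchored to its own t0 ratio (removing labeling variation) and the
    agonist course is expressed relative to the vehicle course:

        loss(t) = R_ag(t)/R_ag(0) - R_veh(t)/R_veh(0)

    so a vehicle well against itself is identically zero.
    """
    if not np.array_equal(series.time_min, vehicle.time_min):
        raise ValueError("agonist and vehicle series must share the time grid")
    r_a = series.ratio()
    r_v = vehicle.ratio()
    return r_a / r_a[0] - r_v / r_v[0]


def surface_downregulation_percent(fluor_agonist: float, fluor_vehicle: float) -> float:
    """Residual surface receptor after prolonged treatment, % of vehicle."""
    if fluor_vehicle <= 0:
        raise ValueError("vehicle fluorescence must be positive")
    return 100.0 * fluor_agonist / fluor_vehicle


def fit_ph_calibration(points: pd.DataFrame, ligand: str | None = None) -> PhCalibration:
    """Ordinary least-squares line intensity = a + b*pH for one FITC-ligand.

    ``points`` needs columns ``ph`` and ``intensity`` (and ``ligand`` when a
    ligand id is not given).  Fluorescein-type probes brighten with pH, but
    only a non-zero slope is required; an all-equal intensity set is flagged
    unusable.
    """
    if ligand is not None and "ligand" in points.columns:
        points = points[points["ligand"] == ligand]
    elif ligand is None:
        ligand = str(points["ligand"].iloc[0]) if "ligand" in points.columns else "unknown"
    ph = points["ph"].to_numpy(dtype=float)
    inten = points["intensity"].to_numpy(dtype=float)
    if np.unique(ph).size < 3:
        raise ValueError("need >= 3 distinct pH values for calibration")
    res = stats.linregress(ph, inten)
    usable = bool(res.slope != 0 and np.ptp(inten) > 0)
    return PhCalibration(
        ligand=ligand,
        slope=float(res.slope),
        intercept=float(res.intercept),
        ph_range=(float(ph.min()), float(ph.max())),
        r_squared=float(res.rvalue**2),
        usable=usable,
    )


def estimate_endosomal_ph(
    f_control: float, f_bafilomycin: float, calib: PhCalibration
) -> PhEstimate:
    """Invert the calibration line using the signal ratio to bafilomycin.

    Bafilomycin collapses the endosomal proton gradient, so its condition is
    anchored at pH 7.4; the control/bafilomycin intensity ratio then rescales
    the calibrated intensity at 7.4 to the intensity the probe would show at
    the unknown endosomal pH, cancelling loading differences between wells.
    """
    if not calib.usable or calib.slope == 0:
        raise ValueError("calibration unusable (zero slope)")
    if f_bafilomycin <= 0:
        raise ValueError("bafilomycin fluorescence must be positive")
    target = (f_control / f_bafilomycin) * calib.intensity_at(BAFILOMYCIN_PH)
    ph = (target - calib.intercept) / calib.slope
    lo, hi = calib.ph_range
    return PhEstimate(ligand=calib.ligand, ph=float(ph), extrapolated=not lo <= ph <= hi)
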