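"""Synthetic ground-truth generators for every pipeline input.

The package analyses plate-reader and flow-cytometry style measurements; no
public dataset accompanies the study design it implements, so this module
fabricates all of them from a known ground truth: per-agonist operational
model parameters for each signaling pathway, binding rate constants for the
competitive-association assay, and a three-state linear trafficking model

    dS/dt = -k_e*S + k_r*I          (surface receptor)
    dI/dt =  k_e*S - (k_r + k_d)*I  (internalized receptor)
    dD/dt =  k_d*I                  (degraded receptor)

solved by matrix exponential so S + I + D is conserved to machine precision
and round-trip tests carry no integrator tolerance.  Measurement noise is
Gaussian (CV- or SD-parameterized), truncated at zero for physically
non-negative readouts.  A single integer seed fans out to independent
per-generator streams, so an entire pipeline run is reproducible.

The bundled :func:`default_panel` plants the study conditions the rest of
the package is exercised against: six agonists whose trafficking profiles
produce a negative relationship between internalization efficacy and the
prolonged insulin stimulation index, with one slow-internalizing /
fast-recycling compound standing apart from the rest.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .binding_kinetics import BindingTrace, TracerParams, mm_predict
from .response_quant import ConcentrationResponseSet, SecretionSample
from .bias_quant import operational_response
from .trafficking_quant import DeretSeries, FacsMeasurement, RecyclingMeasurement

__all__ = [
    "OperationalParams",
    "AgonistTruth",
    "GroundTruthPanel",
    "NoiseModel",
    "AssayDesign",
    "default_panel",
    "default_design",
    "compartment_trajectories",
    "generate_dose_response_panel",
    "generate_kinetic_traces",
    "generate_dissociation_trace",
    "generate_trafficking_measurements",
    "generate_ph_dataset",
    "generate_secretion_timecourse",
    "child_rng",
]

PATHWAYS = ("cAMP", "barr1", "barr2")


@dataclass
class OperationalParams:
    """Operational-model truth for one agonist on one pathway."""

    e_max: float = 100.0  # system maximal response, response units
    basal: float = 2.0
    hill: float = 1.0  # transducer slope n
    log10_ka: float = -7.0  # functional affinity, log10 M
    log10_tau_over_ka: float = 8.5  # log transduction coefficient, log10 1/M

    def __post_init__(self) -> None:
        if self.e_max <= self.basal:
            raise ValueError("E_max must exceed basal")
        if self.hill <= 0:
            raise ValueError("transducer slope must be positive")


@dataclass
class AgonistTruth:
    name: str
    pathways: dict[str, OperationalParams]
    k_on: float  # 1/(M*min)
    k_off: float  # 1/min
    k_e: float  # endocytosis, 1/min
    k_r: float  # recycling, 1/min
    k_d: float  # degradation, 1/min
    secretion_coupling: float = 5.0  # unitless
    endosomal_ph: float = 6.0
    ph_slope: float = 100.0  # calibration AU per pH unit
    ph_intercept: float = 260.0  # calibration AU

    def __post_init__(self) -> None:
        for rate in (self.k_on, self.k_off, self.k_e, self.k_r, self.k_d):
            if rate < 0:
                raise ValueError("rate constants must be non-negative")

    @property
    def k_diss(self) -> float:
        """Equilibrium dissociation constant k_off/k_on (M)."""
        return self.k_off / self.k_on


@dataclass
class GroundTruthPanel:
    agonists: list[AgonistTruth]
    reference: str
    tracer: TracerParams = field(default_factory=lambda: TracerParams(k1=2e8, k2=0.08, bmax=1.0))

    def __post_init__(self) -> None:
        if not self.agonists:
            raise ValueError("agonist list must be non-empty")
        if self.reference not in {a.name for a in self.agonists}:
            raise ValueError(f"reference {self.reference!r} not in panel")

    def agonist(self, name: str) -> AgonistTruth:
        for a in self.agonists:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass
class NoiseModel:
    """Gaussian measurement noise, multiplicative (cv) or additive (sd)."""

    cv: float = 0.0  # fractional, applied as sd = cv*|mean|
    sd: float = 0.0  # absolute, in readout units
    seed: int = 0
    truncate_at_zero: bool = True

    def __post_init__(self) -> None:
        if self.cv < 0 or self.sd < 0:
            raise ValueError("noise magnitudes must be non-negative")

    def apply(self, mean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        sigma = self.cv * np.abs(mean) + self.sd
        out = mean + rng.normal(0.0, 1.0, size=mean.shape) * sigma
        if self.truncate_at_zero:
            out = np.clip(out, 0.0, None)
        return out


@dataclass
class AssayDesign:
    concentrations: np.ndarray = field(
        default_factory=lambda: np.logspace(-11, -6, 8)
    )  # molar, log-spaced
    time_points: np.ndarray = field(default_factory=lambda: np.array([0.0, 15.0, 30.0, 60.0]))
    n_replicates: int = 2
    n_experiments: int = 5
    tracer_conc: float = 1e-8  # 10 nM labeled reference agonist
    competitor_concs: tuple[float, ...] = (3e-9, 1e-8, 3e-8, 1e-7)
    kinetic_times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 30.5, 0.5))
    recycling_period_min: float = 30.0
    secretion_duration_min: float = 960.0  # 16 h prolonged incubation
    agonist_conc: float = 1e-7  # 100 nM stimulations

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.size < 4:
            raise ValueError("dose-response design needs >= 4 concentrations")
        if len(self.competitor_concs) < 4:
            raise ValueError("competitive kinetics needs >= 4 competitor concentrations")


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-generator stream derived from one global seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def default_panel() -> GroundTruthPanel:
    """Six-agonist ground truth emulating a biased-agonist exendin-4 series.

    The reference compound internalizes briskly with modest recycling; one
    analog ("exendin-phe1-like") couples weak beta-arrestin recruitment with
    slow endocytosis, fast recycling, fast dissociation and the least acidic
    endosomes, while another ("exendin-asp3-like") has the opposite profile.
    Its beta-arrestin-1 transduction is set low enough that the readout
    never rises above noise, exercising the unquantifiable path.
    """

    def op(l_r: float, ka: float = -7.0, basal: float = 2.0) -> OperationalParams:
        return OperationalParams(e_max=100.0, basal=basal, hill=1.0, log10_ka=ka, log10_tau_over_ka=l_r)

    agonists = [
        AgonistTruth(
            name="exendin-4",
            pathways={"cAMP": op(9.0), "barr1": op(8.0), "barr2": op(8.3)},
            k_on=1.0e8, k_off=0.05, k_e=0.05, k_r=0.010, k_d=0.0012,
            endosomal_ph=6.1, ph_slope=100.0, ph_intercept=260.0,
        ),
        AgonistTruth(
            name="exendin-phe1",
            pathways={"cAMP": op(8.6), "barr1": op(3.0), "barr2": op(6.9)},
            k_on=1.1e8, k_off=0.20, k_e=0.012, k_r=0.040, k_d=0.0002,
            endosomal_ph=6.9, ph_slope=110.0, ph_intercept=200.0,
        ),
        AgonistTruth(
            name="exendin-asp3",
            pathways={"cAMP": op(8.8), "barr1": op(8.3), "barr2": op(8.9)},
            k_on=0.9e8, k_off=0.02, k_e=0.060, k_r=0.004, k_d=0.0020,
            endosomal_ph=5.7, ph_slope=95.0, ph_intercept=280.0,
        ),
        AgonistTruth(
            name="glp-1",
            pathways={"cAMP": op(9.2), "barr1": op(8.2), "barr2": op(8.5)},
            k_on=1.5e8, k_off=0.15, k_e=0.050, k_r=0.020, k_d=0.0010,
            endosomal_ph=6.2, ph_slope=105.0, ph_intercept=250.0,
        ),
        AgonistTruth(
            name="liraglutide",
            pathways={"cAMP": op(9.1), "barr1": op(7.9), "barr2": op(8.2)},
            k_on=1.2e8, k_off=0.04, k_e=0.040, k_r=0.015, k_d=0.0010,
            endosomal_ph=6.0, ph_slope=100.0, ph_intercept=255.0,
        ),
        AgonistTruth(
            name="lixisenatide",
            pathways={"cAMP": op(8.9), "barr1": op(8.1), "barr2": op(8.6)},
            k_on=1.0e8, k_off=0.03, k_e=0.055, k_r=0.008, k_d=0.0015,
            endosomal_ph=5.9, ph_slope=98.0, ph_intercept=265.0,
        ),
    ]
    return GroundTruthPanel(agonists=agonists, reference="exendin-4")


def default_design() -> AssayDesign:
    return AssayDesign()


# ---------------------------------------------------------------------------
# compartment model
# ---------------------------------------------------------------------------

def compartment_trajectories(
    k_e: float, k_r: float, k_d: float, times: np.ndarray, s0: float = 1.0
) -> pd.DataFrame:
    """Analytic S/I/D trajectories of the three-state trafficking model.

    Solved with the matrix exponential of the full 3x3 generator, so the
    conservation law S + I + D = S(0) holds to round-off at every time.
    """
    if min(k_e, k_r, k_d) < 0:
        raise ValueError("rate constants must be non-negative")
    times = np.asarray(times, dtype=float)
    m = np.array(
        [
            [-k_e, k_r, 0.0],
            [k_e, -(k_r + k_d), 0.0],
            [0.0, k_d, 0.0],
        ]
    )
    x0 = np.array([s0, 0.0, 0.0])
    lam, vec = np.linalg.eig(m)
    try:
        cond = np.linalg.cond(vec)
    except np.linalg.LinAlgError:
        cond = np.inf
    if cond < 1e8:  # diagonalizable: one decomposition covers all times
        coef = np.linalg.solve(vec, x0)
        out = np.real(np.exp(np.outer(times, lam)) * coef @ vec.T)
    else:  # (near-)defective generator, e.g. repeated eigenvalues
        out = np.empty((times.size, 3))
        for i, t in enumerate(times):
            out[i] = expm(m * t) @ x0
    return pd.DataFrame(out, columns=["S", "I", "D"]).assign(time_min=times)


def _surface_integral(truth: AgonistTruth, duration: float, dt: float = 1.0) -> float:
    """Time integral of the surface fraction S(t)/S(0) over [0, duration] (min)."""
    grid = np.arange(0.0, duration + dt / 2, dt)
    traj = compartment_trajectories(truth.k_e, truth.k_r, truth.k_d, grid)
    return float(np.trapezoid(traj["S"].to_numpy(), grid))


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

def generate_dose_response_panel(
    truth: GroundTruthPanel,
    design: AssayDesign,
    noise: NoiseModel,
    seed: int | None = None,
    experiment_shift_sd: float = 0.1,
) -> list[ConcentrationResponseSet]:
    """Draw replicate responses around the operational-model mean.

    Each pathway x experiment receives a common random shift of
    log10(tau/K_A) (SD ``experiment_shift_sd``) emulating day-to-day assay
    sensitivity drift; the shift is shared by all agonists so within-
    experiment normalization removes it, as in the real design.
    """
    rng = child_rng(seed if seed is not None else noise.seed, "dose_response")
    out: list[ConcentrationResponseSet] = []
    for exp in range(design.n_experiments):
        for pathway in PATHWAYS:
            shift = rng.normal(0.0, experiment_shift_sd) if experiment_shift_sd > 0 else 0.0
            for agonist in truth.agonists:
                if pathway not in agonist.pathways:
                    continue
                p = agonist.pathways[pathway]
                mean = operational_response(
                    design.concentrations,
                    p.basal,
                    p.e_max,
                    p.hill,
                    p.log10_ka,
                    p.log10_tau_over_ka + shift,
                )
                responses = np.vstack(
                    [noise.apply(mean, rng) for _ in range(design.n_replicates)]
                )
                out.append(
                    ConcentrationResponseSet(
                        agonist=agonist.name,
                        pathway=pathway,
                        concentrations=design.concentrations.copy(),
                        responses=responses,
                        is_reference=agonist.name == truth.reference,
                        experiment=exp,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# binding kinetics
# ---------------------------------------------------------------------------

NONSPECIFIC_COMPETITOR_CONC = 1e-5  # "excess" unlabeled agonist, M
NONSPECIFIC_LEVEL = 0.05  # background binding, fraction of Bmax


def generate_kinetic_traces(
    truth: GroundTruthPanel,
    agonist: str,
    design: AssayDesign,
    noise: NoiseModel,
    seed: int | None = None,
) -> list[BindingTrace]:
    """Competitive-association traces for one unlabeled agonist.

    Emits one total-binding trace per competitor concentration (including a
    competitor-free trace and an excess-competitor trace at 10 uM) plus a
    matching nonspecific trace, all following the competitive-binding mean
    with Gaussian noise.
    """
    a = truth.agonist(agonist)
    rng = child_rng(seed if seed is not None else noise.seed, f"kinetics:{agonist}")
    ns = NONSPECIFIC_LEVEL * truth.tracer.bmax
    times = design.kinetic_times
    concs = [0.0, *design.competitor_concs, NONSPECIFIC_COMPETITOR_CONC]
    traces = []
    for conc in concs:
        if conc < 0:
            raise ValueError("competitor concentration must be non-negative")
        mean = mm_predict(truth.tracer, a.k_on, a.k_off, design.tracer_conc, conc, times) + ns
        traces.append(
            BindingTrace(
                time_min=times.copy(),
                signal=noise.apply(mean, rng),
                tracer_conc=design.tracer_conc,
                competitor=agonist,
                competitor_conc=conc,
                condition="total",
            )
        )
    traces.append(
        BindingTrace(
            time_min=times.copy(),
            signal=noise.apply(np.full_like(times, ns), rng),
            tracer_conc=design.tracer_conc,
            competitor=agonist,
            competitor_conc=NONSPECIFIC_COMPETITOR_CONC,
            condition="nonspecific",
        )
    )
    return traces


def generate_dissociation_trace(
    truth: GroundTruthPanel,
    agonist: str,
    noise: NoiseModel,
    seed: int | None = None,
    b0: float = 1.0,
    times: np.ndarray | None = None,
) -> BindingTrace:
    """Specific-binding decay after washout into excess antagonist."""
    a = truth.agonist(agonist)
    if times is None:
        times = np.arange(0.0, 60.5, 1.0)
    rng = child_rng(seed if seed is not None else noise.seed, f"dissociation:{agonist}")
    mean = b0 * np.exp(-a.k_off * np.asarray(times, dtype=float))
    return BindingTrace(
        time_min=np.asarray(times, dtype=float),
        signal=noise.apply(mean, rng),
        competitor=agonist,
        condition="total",
    )


# ---------------------------------------------------------------------------
# trafficking
# ---------------------------------------------------------------------------

STRIP_EFFICIENCY = 0.90  # fraction of surface label removed by MesNa
FACS_SCALE = 1000.0  # arbitrary median-fluorescence scale
DERET_BASE_620 = 5000.0
DERET_BASE_520 = 20000.0
DERET_GAIN = 2.0


def generate_trafficking_measurements(
    truth: GroundTruthPanel,
    design: AssayDesign,
    noise: NoiseModel,
    seed: int | None = None,
    strip_efficiency: float = STRIP_EFFICIENCY,
) -> dict:
    """FACS, DERET, and plate-reader surface signals from the compartment model.

    Degradation destroys the label, so the unstripped FACS signal tracks
    S + I while the stripped signal tracks I plus the unstripped surface
    residue (1 - strip_efficiency)*S; the t0 stripped/unstripped ratio then
    equals the residue fraction, which the downstream formula corrects for.
    Returns a dict with keys ``facs``, ``recycling``, ``deret``, ``plate``
    and a ``truth_trajectories`` table for round-trip testing.
    """
    if strip_efficiency <= 0 or strip_efficiency > 1:
        raise ValueError("strip efficiency must be in (0, 1]")
    eps = 1.0 - strip_efficiency
    rng = child_rng(seed if seed is not None else noise.seed, "trafficking")
    times = np.asarray(design.time_points, dtype=float)

    facs: list[FacsMeasurement] = []
    recycling: list[RecyclingMeasurement] = []
    deret: dict[str, DeretSeries] = {}
    plate_rows = []
    truth_rows = []

    deret_times = np.arange(0.0, 30.5, 1.0)
    for a in truth.agonists:
        traj = compartment_trajectories(a.k_e, a.k_r, a.k_d, times)
        for _, row in traj.iterrows():
            truth_rows.append(
                {"agonist": a.name, "time_min": row["time_min"], "S": row["S"], "I": row["I"], "D": row["D"]}
            )
        s0 = traj["S"].iloc[0]
        f_minus_t0 = float(noise.apply(FACS_SCALE, rng))
        f_plus_t0 = float(noise.apply(FACS_SCALE * eps, rng))
        for _, row in traj.iloc[1:].iterrows():
            s, i = row["S"], row["I"]
            f_minus = FACS_SCALE * (s + i) / s0
            f_plus = FACS_SCALE * (i + eps * s) / s0
            facs.append(
                FacsMeasurement(
                    condition=a.name,
                    time_min=float(row["time_min"]),
                    f_plus_me=float(noise.apply(f_plus, rng)),
                    f_minus_me=float(noise.apply(f_minus, rng)),
                    f_plus_me_t0=f_plus_t0,
                    f_minus_me_t0=f_minus_t0,
                )
            )

        # recycling: 15 min pulse, strip, recycling period with endocytosis blocked
        pulse = compartment_trajectories(a.k_e, a.k_r, a.k_d, np.array([0.0, 15.0]))
        s1, i1 = pulse["S"].iloc[-1], pulse["I"].iloc[-1]
        lam = a.k_r + a.k_d
        dt_rec = design.recycling_period_min
        decay = np.exp(-lam * dt_rec)
        recycled = i1 * (a.k_r / lam) * (1.0 - decay) if lam > 0 else 0.0
        f_int15 = FACS_SCALE * (i1 + eps * s1) / s0
        # residual internal label + epsilon of the re-stripped surface label
        f_rec = FACS_SCALE * (i1 * decay + eps * (eps * s1 + recycled)) / s0
        r0 = eps
        int15_pct = 100.0 * ((i1 + eps * s1) / (s1 + i1) - r0) / (1.0 - r0)
        recycling.append(
            RecyclingMeasurement(
                condition=a.name,
                f_int15=float(noise.apply(f_int15, rng)),
                f_rec=float(noise.apply(f_rec, rng)),
                internalized_percent_15=float(int15_pct),
            )
        )

        # DERET: donor de-quenches as receptor leaves the fluorescein bath
        dtraj = compartment_trajectories(a.k_e, a.k_r, a.k_d, deret_times)
        loss = 1.0 - dtraj["S"].to_numpy() / s0
        a620 = noise.apply(DERET_BASE_620 * (1.0 + DERET_GAIN * loss), rng)
        a520 = noise.apply(np.full_like(deret_times, DERET_BASE_520), rng)
        deret[a.name] = DeretSeries(deret_times.copy(), a620, a520, condition="agonist")

        # plate-reader surface labeling, internalization + recycling stages
        t_int = float(times[-1])
        ptraj = compartment_trajectories(a.k_e, a.k_r, a.k_d, np.array([0.0, t_int]))
        s_int, i_int = ptraj["S"].iloc[-1], ptraj["I"].iloc[-1]
        rec2 = i_int * (a.k_r / lam) * (1.0 - np.exp(-lam * dt_rec)) if lam > 0 else 0.0
        plate_rows += [
            {"condition": a.name, "stage": "vehicle", "signal": float(noise.apply(1.0, rng))},
            {"condition": a.name, "stage": "internalized", "signal": float(noise.apply(s_int / s0, rng))},
            {"condition": a.name, "stage": "recycled", "signal": float(noise.apply((s_int + rec2) / s0, rng))},
        ]

    vehicle_620 = noise.apply(np.full_like(deret_times, DERET_BASE_620), rng)
    vehicle_520 = noise.apply(np.full_like(deret_times, DERET_BASE_520), rng)
    deret["vehicle"] = DeretSeries(deret_times.copy(), vehicle_620, vehicle_520, condition="vehicle")

    return {
        "facs": facs,
        "recycling": recycling,
        "deret": deret,
        "plate": pd.DataFrame(plate_rows),
        "truth_trajectories": pd.DataFrame(truth_rows),
        "strip_efficiency": strip_efficiency,
    }


# ---------------------------------------------------------------------------
# endosomal pH
# ---------------------------------------------------------------------------

PH_CALIBRATION_GRID = np.arange(4.5, 8.1, 0.5)


def generate_ph_dataset(
    truth: GroundTruthPanel,
    noise: NoiseModel,
    seed: int | None = None,
    n_readings: int = 12,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ligand fluorescence-pH calibration points and paired well intensities.

    Calibration points lie on each ligand's planted line plus noise; the
    bafilomycin wells are generated at pH 7.4 and control wells at the
    planted endosomal pH, both scaled by a common random loading factor that
    the ratio-based estimator must cancel.  ``n_readings`` serial fluorescence
    readings per well emulate the repeated measurements taken over the
    post-internalization hour; estimators average them.
    """
    rng = child_rng(seed if seed is not None else noise.seed, "ph")
    lo, hi = float(PH_CALIBRATION_GRID.min()), float(PH_CALIBRATION_GRID.max())
    cal_rows, well_rows = [], []
    for a in truth.agonists:
        if not lo <= a.endosomal_ph <= hi:
            raise ValueError(f"planted pH for {a.name} outside calibration range")
        if a.ph_slope == 0:
            raise ValueError("calibration line must have non-zero slope")
        for ph in PH_CALIBRATION_GRID:
            mean = a.ph_intercept + a.ph_slope * ph
            cal_rows.append(
                {"ligand": a.name, "ph": float(ph), "intensity": float(noise.apply(mean, rng))}
            )
        loading = rng.uniform(0.5, 2.0)
        f_control = loading * (a.ph_intercept + a.ph_slope * a.endosomal_ph)
        f_baf = loading * (a.ph_intercept + a.ph_slope * 7.4)
        for reading in range(n_readings):
            well_rows.append(
                {
                    "ligand": a.name,
                    "reading": reading,
                    "control": float(noise.apply(f_control, rng)),
                    "bafilomycin": float(noise.apply(f_baf, rng)),
                }
            )
    return pd.DataFrame(cal_rows), pd.DataFrame(well_rows)


# ---------------------------------------------------------------------------
# secretion
# ---------------------------------------------------------------------------

BASAL_SECRETION_RATE = 20.0 / 960.0  # units/min: control releases ~2% of pool over 16 h
TOTAL_INSULIN_POOL = 1000.0


def generate_secretion_timecourse(
    truth: GroundTruthPanel,
    design: AssayDesign,
    noise: NoiseModel,
    seed: int | None = None,
    n_replicates: int = 6,
) -> list[SecretionSample]:
    """Cumulative insulin secretion samples with glucose-only controls.

    Secretion is modeled as a basal glucose-driven rate plus an agonist term
    proportional to receptor occupancy times the time-averaged surface
    availability,

        secreted = r0*T + kappa * rho * integral_0^T S(t)/S(0) dt,

    so fast-internalizing, slow-recycling agonists (small surface integral)
    produce lower prolonged secretion.  This coupling law is an explicit
    stand-in for an unknown mechanism, chosen only to plant a monotone
    negative internalization-secretion relationship.
    """
    rng = child_rng(seed if seed is not None else noise.seed, "secretion")
    duration = design.secretion_duration_min
    samples: list[SecretionSample] = []
    base = BASAL_SECRETION_RATE * duration
    for _ in range(n_replicates):
        sec = float(noise.apply(base, rng))
        samples.append(
            SecretionSample(
                condition="control",
                secreted=sec,
                residual_content=max(TOTAL_INSULIN_POOL - sec, 0.0),
                is_control=True,
            )
        )
    for a in truth.agonists:
        occupancy = design.agonist_conc / (design.agonist_conc + a.k_diss)
        surf_int = _surface_integral(a, duration)
        mean = base + a.secretion_coupling * occupancy * surf_int * BASAL_SECRETION_RATE
        for _ in range(n_replicates):
            sec = float(noise.apply(mean, rng))
            samples.append(
                SecretionSample(
                    condition=a.name,
                    secreted=sec,
                    residual_content=max(TOTAL_INSULIN_POOL - sec, 0.0),
                    is_control=False,
                )
            )
    return samples
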