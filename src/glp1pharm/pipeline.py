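"""End-to-end pipeline: simulate, fit, and profile a GLP-1R agonist panel.

A :class:`RunConfig` (YAML-serializable) drives the stages in method order:
synthetic-data generation (optional), dose-response fitting and assay-max
normalization, operational-model bias quantification, binding-kinetics
fitting, trafficking and endosomal-pH metrics, secretion indices, and the
multi-readout profile (feature matrix, PCA, regressions).  All stage inputs
and outputs are tidy CSV; a JSON manifest records seeds and stage status so
a run is reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias_quant, binding_kinetics, profiling, response_quant, synthetic_data, trafficking_quant
from .binding_kinetics import BindingTrace, TracerParams
from .response_quant import ConcentrationResponseSet, SecretionSample
from .trafficking_quant import DeretSeries, FacsMeasurement, RecyclingMeasurement

__all__ = ["RunConfig", "run_pipeline", "demo_config", "PipelineError"]

logger = logging.getLogger("glp1pharm")

CSV_FLOAT_FORMAT = "%.10g"
DONOR_SCALE = 1e4  # arbitrary 620 nm donor counts used when writing raw channels


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    outdir: str = "glp1pharm_run"
    seed: int = 0
    simulate: bool = True
    reference_agonist: str = "exendin-4"
    reference_pathway: str = "cAMP"
    trafficking_time_min: float = 60.0
    ci_method: str = "z"
    n_experiments: int = 5
    dose_response_cv: float = 0.10
    kinetics_cv: float = 0.01
    trafficking_cv: float = 0.03
    ph_cv: float = 0.01
    secretion_cv: float = 0.08
    # tracer kinetics are treated as known plate constants; Bmax is
    # re-estimated from the competitor-free trace of each assay
    tracer_k1: float = 2e8
    tracer_k2: float = 0.08

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def validate(self, panel: synthetic_data.GroundTruthPanel | None = None) -> None:
        if self.ci_method not in ("z", "t"):
            raise PipelineError("config", "ci_method must be 'z' or 't'")
        if panel is not None and self.reference_agonist not in {a.name for a in panel.agonists}:
            raise PipelineError(
                "config", f"reference agonist {self.reference_agonist!r} not present in panel"
            )


def demo_config(outdir: str | Path = "glp1pharm_demo", seed: int = 0) -> RunConfig:
    """The bundled demonstration configuration (see data/demo_config.yaml)."""
    cfg = RunConfig.from_yaml(Path(__file__).parent / "data" / "demo_config.yaml")
    cfg.outdir = str(outdir)
    cfg.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# CSV writers / readers (tidy dialects shared by simulate and fit stages)
# ---------------------------------------------------------------------------

def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def dose_response_to_csv(sets: list[ConcentrationResponseSet], path: Path) -> None:
    rows = []
    for s in sets:
        for rep in range(s.responses.shape[0]):
            for j, conc in enumerate(s.concentrations):
                rows.append(
                    {
                        "agonist": s.agonist,
                        "pathway": s.pathway,
                        "experiment": s.experiment,
                        "concentration_M": conc,
                        "replicate": rep,
                        "response": s.responses[rep, j],
                        "is_reference": int(s.is_reference),
                    }
                )
    _write(pd.DataFrame(rows), path)


def dose_response_from_csv(path: Path) -> list[ConcentrationResponseSet]:
    df = pd.read_csv(path)
    out = []
    for (agonist, pathway, experiment), grp in df.groupby(
        ["agonist", "pathway", "experiment"], sort=True
    ):
        piv = grp.pivot_table(
            index="replicate", columns="concentration_M", values="response", aggfunc="mean"
        ).sort_index(axis=1)
        out.append(
            ConcentrationResponseSet(
                agonist=str(agonist),
                pathway=str(pathway),
                concentrations=piv.columns.to_numpy(dtype=float),
                responses=piv.to_numpy(dtype=float),
                is_reference=bool(grp["is_reference"].iloc[0]),
                experiment=int(experiment),
            )
        )
    return out


def binding_traces_to_csv(traces: list[BindingTrace], path: Path, assay: str) -> None:
    rows = []
    for i, tr in enumerate(traces):
        for t, sig in zip(tr.time_min, tr.signal):
            rows.append(
                {
                    "trace_id": f"{tr.competitor}:{assay}:{i}",
                    "assay": assay,
                    "time_min": t,
                    "signal_520": sig * DONOR_SCALE,
                    "signal_620": DONOR_SCALE,
                    "tracer_M": tr.tracer_conc,
                    "competitor": tr.competitor,
                    "competitor_M": tr.competitor_conc,
                    "condition": tr.condition,
                }
            )
    _write(pd.DataFrame(rows), path)


def binding_traces_from_csv(path: Path) -> list[BindingTrace]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            BindingTrace(
                time_min=grp["time_min"].to_numpy(float),
                signal=(grp["signal_520"] / grp["signal_620"]).to_numpy(float),
                tracer_conc=float(grp["tracer_M"].iloc[0]),
                competitor=str(grp["competitor"].iloc[0]),
                competitor_conc=float(grp["competitor_M"].iloc[0]),
                condition=str(grp["condition"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, datadir: Path) -> synthetic_data.GroundTruthPanel:
    panel = synthetic_data.default_panel()
    design = synthetic_data.default_design()
    design.n_experiments = cfg.n_experiments
    seed = cfg.seed

    dr = synthetic_data.generate_dose_response_panel(
        panel, design, synthetic_data.NoiseModel(cv=cfg.dose_response_cv), seed=seed
    )
    dose_response_to_csv(dr, datadir / "dose_response.csv")

    assoc, diss = [], []
    for a in panel.agonists:
        assoc += synthetic_data.generate_kinetic_traces(
            panel, a.name, design, synthetic_data.NoiseModel(cv=cfg.kinetics_cv), seed=seed
        )
        diss.append(
            synthetic_data.generate_dissociation_trace(
                panel, a.name, synthetic_data.NoiseModel(cv=cfg.kinetics_cv), seed=seed
            )
        )
    binding_traces_to_csv(assoc, datadir / "kinetics_association.csv", assay="association")
    binding_traces_to_csv(diss, datadir / "kinetics_dissociation.csv", assay="dissociation")

    tr = synthetic_data.generate_trafficking_measurements(
        panel, design, synthetic_data.NoiseModel(cv=cfg.trafficking_cv), seed=seed
    )
    facs_rows = [
        {
            "condition": m.condition,
            "time_min": m.time_min,
            "f_plus_me": m.f_plus_me,
            "f_minus_me": m.f_minus_me,
            "f_plus_me_t0": m.f_plus_me_t0,
            "f_minus_me_t0": m.f_minus_me_t0,
        }
        for m in tr["facs"]
    ]
    _write(pd.DataFrame(facs_rows), datadir / "facs.csv")
    rec_rows = [
        {
            "condition": m.condition,
            "f_int15": m.f_int15,
            "f_rec": m.f_rec,
            "internalized_percent_15": m.internalized_percent_15,
        }
        for m in tr["recycling"]
    ]
    _write(pd.DataFrame(rec_rows), datadir / "facs_recycling.csv")
    deret_rows = []
    for name, series in tr["deret"].items():
        for t, a620, a520 in zip(series.time_min, series.a620, series.a520):
            deret_rows.append(
                {"condition": name, "time_min": t, "a620": a620, "a520": a520}
            )
    _write(pd.DataFrame(deret_rows), datadir / "deret.csv")
    _write(tr["plate"], datadir / "plate_surface.csv")
    _write(tr["truth_trajectories"], datadir / "truth_trajectories.csv")

    cal, wells = synthetic_data.generate_ph_dataset(
        panel, synthetic_data.NoiseModel(cv=cfg.ph_cv), seed=seed
    )
    _write(cal, datadir / "ph_calibration.csv")
    _write(wells, datadir / "ph_wells.csv")

    sec = synthetic_data.generate_secretion_timecourse(
        panel, design, synthetic_data.NoiseModel(cv=cfg.secretion_cv), seed=seed
    )
    sec_rows = [
        {
            "condition": s.condition,
            "secreted": s.secreted,
            "content": s.residual_content,
            "is_control": int(s.is_control),
        }
        for s in sec
    ]
    _write(pd.DataFrame(sec_rows), datadir / "secretion.csv")

    truth_rows = []
    for a in panel.agonists:
        rec = {
            "name": a.name,
            "k_on": a.k_on,
            "k_off": a.k_off,
            "k_e": a.k_e,
            "k_r": a.k_r,
            "k_d": a.k_d,
            "secretion_coupling": a.secretion_coupling,
            "endosomal_ph": a.endosomal_ph,
            "pathways": {
                pw: asdict(p) for pw, p in a.pathways.items()
            },
        }
        truth_rows.append(rec)
    with open(datadir / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump({"reference": panel.reference, "agonists": truth_rows}, fh, sort_keys=True)
    return panel


def _stage_bias(cfg: RunConfig, datadir: Path, resdir: Path) -> pd.DataFrame:
    sets = dose_response_from_csv(datadir / "dose_response.csv")
    by_pe: dict[tuple[str, int], list[ConcentrationResponseSet]] = {}
    for s in sets:
        by_pe.setdefault((s.pathway, s.experiment), []).append(s)

    fits, fit_records = [], []
    for (pathway, experiment), panel_sets in sorted(by_pe.items()):
        # normalize to the reference agonist's fitted 4PL top (assay E_max)
        ref_sets = [s for s in panel_sets if s.is_reference]
        if not ref_sets:
            raise PipelineError("bias", f"no reference agonist in {pathway} exp {experiment}")
        ref_fit = response_quant.fit_4pl(ref_sets[0])
        if ref_fit.no_response or not ref_fit.converged:
            raise PipelineError("bias", f"reference 4PL flat in {pathway} exp {experiment}")
        normalized = response_quant.normalize_to_assay_max(panel_sets, ref_fit)
        fit = bias_quant.fit_operational_model(normalized, reference=cfg.reference_agonist)
        fits.append(fit)
        for agonist in fit.log10_tau_over_ka.index:
            fit_records.append(
                {
                    "pathway": pathway,
                    "experiment": experiment,
                    "agonist": agonist,
                    "log10_tau_over_ka": fit.log10_tau_over_ka[agonist],
                    "log10_ka": fit.log10_ka[agonist],
                    "quantifiable": bool(fit.quantifiable[agonist]),
                    "e_max": fit.e_max,
                    "basal": fit.basal,
                    "hill": fit.hill,
                }
            )
    _write(pd.DataFrame(fit_records), resdir / "operational_fits.csv")

    table = bias_quant.delta_log_tka(fits, reference=cfg.reference_agonist)
    _write(table.summary, resdir / "bias_delta.csv")
    pathways = sorted(table.summary["pathway"].unique())
    contrasts = []
    for pw in pathways:
        if pw == cfg.reference_pathway:
            continue
        contrasts.append(
            bias_quant.ddelta_log_tka(table, cfg.reference_pathway, pw, ci_method=cfg.ci_method)
        )
    contrast_df = pd.concat(contrasts, ignore_index=True) if contrasts else pd.DataFrame()
    _write(contrast_df, resdir / "bias_contrasts.csv")
    web = bias_quant.web_of_bias(table, cfg.reference_pathway)
    web.reset_index().to_csv(resdir / "web_of_bias.csv", index=False, float_format=CSV_FLOAT_FORMAT)
    return table.summary


def _stage_kinetics(cfg: RunConfig, datadir: Path, resdir: Path) -> pd.DataFrame:
    assoc = binding_traces_from_csv(datadir / "kinetics_association.csv")
    diss = binding_traces_from_csv(datadir / "kinetics_dissociation.csv")
    by_agonist: dict[str, list[BindingTrace]] = {}
    for tr in assoc:
        by_agonist.setdefault(tr.competitor, []).append(tr)

    rows = []
    for agonist, traces in sorted(by_agonist.items()):
        nonspec = [t for t in traces if t.condition == "nonspecific"]
        totals = [t for t in traces if t.condition == "total"]
        if not nonspec:
            raise PipelineError("kinetics", f"no nonspecific trace for {agonist}")
        specific = [binding_kinetics.specific_binding(t, nonspec[0]) for t in totals]
        # excess-competitor total traces duplicate the nonspecific level; drop them
        fit_traces = [
            t
            for t in specific
            if t.competitor_conc < synthetic_data.NONSPECIFIC_COMPETITOR_CONC
        ]
        free = [t for t in fit_traces if t.competitor_conc == 0]
        if not free:
            raise PipelineError("kinetics", f"no competitor-free trace for {agonist}")
        tracer = _estimate_tracer(free[0], cfg.tracer_k1, cfg.tracer_k2)
        params = binding_kinetics.fit_competitive(
            [t for t in fit_traces if t.competitor_conc > 0], tracer
        )
        row = {
            "agonist": agonist,
            "k_on": params.k_on,
            "k_off": params.k_off,
            "se_k_on": params.se_k_on,
            "se_k_off": params.se_k_off,
            "residence_time_min": params.residence_time,
            "k_d_M": params.k_d,
            "bmax": params.bmax,
            "converged": params.converged,
        }
        washout = [t for t in diss if t.competitor == agonist]
        if washout:
            dfit = binding_kinetics.fit_dissociation(washout[0])
            row["k_off_washout"] = dfit.k_off
            row["k_off_washout_se"] = dfit.se_k_off
        rows.append(row)
    table = pd.DataFrame(rows)
    _write(table, resdir / "kinetic_constants.csv")
    return table


def _estimate_tracer(free_trace: BindingTrace, k1: float, k2: float) -> TracerParams:
    """Bmax from the competitor-free association trace given known tracer rates."""
    unit = binding_kinetics.mm_predict(
        TracerParams(k1, k2, 1.0), 0.0, 1e-12, free_trace.tracer_conc, 0.0, free_trace.time_min
    )
    denom = float(unit @ unit)
    if denom == 0:
        raise PipelineError("kinetics", "degenerate competitor-free trace")
    bmax = float(unit @ free_trace.signal) / denom
    return TracerParams(k1, k2, bmax)


def _stage_trafficking(cfg: RunConfig, datadir: Path, resdir: Path) -> pd.DataFrame:
    facs = pd.read_csv(datadir / "facs.csv")
    rec = pd.read_csv(datadir / "facs_recycling.csv")
    deret = pd.read_csv(datadir / "deret.csv")
    plate = pd.read_csv(datadir / "plate_surface.csv")
    cal = pd.read_csv(datadir / "ph_calibration.csv")
    wells = pd.read_csv(datadir / "ph_wells.csv")

    rows = []
    vehicle_rows = deret[deret["condition"] == "vehicle"].sort_values("time_min")
    vehicle_series = DeretSeries(
        vehicle_rows["time_min"].to_numpy(float),
        vehicle_rows["a620"].to_numpy(float),
        vehicle_rows["a520"].to_numpy(float),
        condition="vehicle",
    )
    for agonist, grp in facs.groupby("condition", sort=True):
        sub = grp[grp["time_min"] == cfg.trafficking_time_min]
        if sub.empty:
            raise PipelineError("trafficking", f"no FACS point at t={cfg.trafficking_time_min}")
        m = sub.iloc[0]
        internal = trafficking_quant.facs_internalized_percent(
            FacsMeasurement(
                condition=str(agonist),
                time_min=float(m["time_min"]),
                f_plus_me=float(m["f_plus_me"]),
                f_minus_me=float(m["f_minus_me"]),
                f_plus_me_t0=float(m["f_plus_me_t0"]),
                f_minus_me_t0=float(m["f_minus_me_t0"]),
            )
        )
        r = rec[rec["condition"] == agonist].iloc[0]
        recycled = trafficking_quant.facs_recycled_percent(
            RecyclingMeasurement(
                condition=str(agonist),
                f_int15=float(r["f_int15"]),
                f_rec=float(r["f_rec"]),
                internalized_percent_15=float(r["internalized_percent_15"]),
            )
        )
        drows = deret[deret["condition"] == agonist].sort_values("time_min")
        series = DeretSeries(
            drows["time_min"].to_numpy(float),
            drows["a620"].to_numpy(float),
            drows["a520"].to_numpy(float),
        )
        loss = trafficking_quant.deret_surface_loss(series, vehicle_series)
        p = plate[plate["condition"] == agonist].set_index("stage")["signal"]
        plate_int = trafficking_quant.plate_internalization_percent(
            p["internalized"], p["vehicle"]
        )
        plate_rec = trafficking_quant.plate_recycling_percent(
            p["vehicle"], p["internalized"], p["recycled"]
        )
        calibration = trafficking_quant.fit_ph_calibration(cal, ligand=str(agonist))
        w = wells[wells["ligand"] == agonist]
        ph = trafficking_quant.estimate_endosomal_ph(
            float(w["control"].mean()), float(w["bafilomycin"].mean()), calibration
        )
        rows.append(
            {
                "agonist": agonist,
                "internalization_pct": internal,
                "recycling_pct": recycled,
                "deret_final_loss": float(loss[-1]),
                "plate_internalization_pct": plate_int,
                "plate_recycling_pct": plate_rec,
                "endosomal_ph": ph.ph,
                "ph_extrapolated": ph.extrapolated,
                "ph_calibration_r2": calibration.r_squared,
            }
        )
    table = pd.DataFrame(rows)
    _write(table, resdir / "trafficking_metrics.csv")
    return table


def _stage_secretion(cfg: RunConfig, datadir: Path, resdir: Path) -> pd.Series:
    df = pd.read_csv(datadir / "secretion.csv")
    samples = [
        SecretionSample(
            condition=str(r["condition"]),
            secreted=float(r["secreted"]),
            residual_content=float(r["content"]),
            is_control=bool(r["is_control"]),
        )
        for _, r in df.iterrows()
    ]
    isi = response_quant.insulin_stimulation_index(samples)
    isi.sort_index().rename_axis("condition").reset_index().to_csv(
        resdir / "secretion_isi.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    return isi


def _stage_profile(
    cfg: RunConfig,
    resdir: Path,
    bias_summary: pd.DataFrame,
    kinetics: pd.DataFrame,
    trafficking: pd.DataFrame,
    isi: pd.Series,
) -> dict:
    matrix = profiling.assemble_features(
        bias_summary, kinetics, trafficking, reference=cfg.reference_agonist
    )
    matrix.values.reset_index().to_csv(
        resdir / "feature_matrix.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    pca = profiling.pca_profile(matrix, drop_incomplete=True)
    pca.scores.reset_index().to_csv(
        resdir / "pca_scores.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    pca.loadings.reset_index(names="feature").to_csv(
        resdir / "pca_loadings.csv", index=False, float_format=CSV_FLOAT_FORMAT
    )
    internal = trafficking.set_index("agonist")["internalization_pct"]
    reg = profiling.regress_relationship(
        internal,
        isi.drop(labels=["control"], errors="ignore"),
        x_label="internalization_pct",
        y_label="isi",
    )
    out = {
        "regression_internalization_vs_isi": reg.__dict__,
        "pca_variance_explained_pct": pca.variance_explained.tolist(),
        "pca_metadata": {"scaling": "z-score", "rows": pca.scores.index.tolist()},
    }
    with open(resdir / "profile_summary.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order; raises :class:`PipelineError` on failure.

    Returns a result bundle with the key tables and the manifest dict.
    Partial outputs are retained on failure for inspection.
    """
    cfg.validate(synthetic_data.default_panel() if cfg.simulate else None)
    outdir = Path(cfg.outdir)
    datadir = outdir / "data"
    resdir = outdir / "results"
    datadir.mkdir(parents=True, exist_ok=True)
    resdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {"seed": cfg.seed, "config": asdict(cfg), "stages": {}}
    bundle: dict = {"manifest": manifest}
    try:
        stages = []
        if cfg.simulate:
            stages.append(("simulate", lambda: _stage_simulate(cfg, datadir)))
        stages += [
            ("bias", lambda: _stage_bias(cfg, datadir, resdir)),
            ("kinetics", lambda: _stage_kinetics(cfg, datadir, resdir)),
            ("trafficking", lambda: _stage_trafficking(cfg, datadir, resdir)),
            ("secretion", lambda: _stage_secretion(cfg, datadir, resdir)),
        ]
        for name, fn in stages:
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                bundle[name] = fn()
            except PipelineError:
                raise
            except Exception as exc:  # tag unexpected failures with the stage
                raise PipelineError(name, str(exc)) from exc
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s: done in %.2fs", name, manifest["stages"][name]["seconds"])

        t0 = time.perf_counter()
        bundle["profile"] = _stage_profile(
            cfg, resdir, bundle["bias"], bundle["kinetics"], bundle["trafficking"], bundle["secretion"]
        )
        manifest["stages"]["profile"] = {"seconds": round(time.perf_counter() - t0, 3)}

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        cfg.to_yaml(outdir / "config_used.yaml")
        return bundle
    finally:
        logger.removeHandler(handler)
        handler.close()
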