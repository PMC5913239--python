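"""Generator correctness: closed forms, conservation, determinism, round trips."""

import numpy as np
import pandas as pd
import pytest

from glp1pharm import synthetic_data as sd
from glp1pharm.bias_quant import operational_response
from glp1pharm.binding_kinetics import fit_competitive, specific_binding
from glp1pharm.trafficking_quant import (
    estimate_endosomal_ph,
    facs_internalized_percent,
    fit_ph_calibration,
)


class TestDoseResponseGenerator:
    def test_zero_noise_equals_operational_mean(self, panel, design, no_noise):
        sets = sd.generate_dose_response_panel(
            panel, design, no_noise, seed=0, experiment_shift_sd=0.0
        )
        for s in sets:
            truth = panel.agonist(s.agonist).pathways[s.pathway]
            mean = operational_response(
                s.concentrations, truth.basal, truth.e_max, truth.hill,
                truth.log10_ka, truth.log10_tau_over_ka,
            )
            np.testing.assert_allclose(s.responses, np.tile(mean, (design.n_replicates, 1)))

    def test_seed_determinism(self, panel, design):
        noise = sd.NoiseModel(cv=0.1)
        a = sd.generate_dose_response_panel(panel, design, noise, seed=42)
        b = sd.generate_dose_response_panel(panel, design, noise, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.responses, y.responses)

    def test_mid_curve_cv_near_planted_level(self, panel):
        # pooled across replicates and experiments, the per-concentration
        # sample CV should sit near the planted 10%
        design = sd.AssayDesign(n_replicates=5, n_experiments=10)
        sets = sd.generate_dose_response_panel(
            panel, design, sd.NoiseModel(cv=0.1), seed=0, experiment_shift_sd=0.0
        )
        ref = [s for s in sets if s.agonist == "exendin-4" and s.pathway == "cAMP"]
        stacked = np.vstack([s.responses for s in ref])  # 50 draws per conc
        mean, std = stacked.mean(axis=0), stacked.std(axis=0, ddof=1)
        mid = mean > 0.3 * mean.max()
        cv = std[mid] / mean[mid]
        assert np.all((cv > 0.05) & (cv < 0.2))

    def test_empty_agonist_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sd.GroundTruthPanel(agonists=[], reference="x")


class TestKineticTraceGenerator:
    def test_zero_noise_competitor_free_is_one_phase(self, panel, design, no_noise):
        traces = sd.generate_kinetic_traces(panel, "exendin-4", design, no_noise, seed=0)
        free = next(t for t in traces if t.condition == "total" and t.competitor_conc == 0)
        ns = next(t for t in traces if t.condition == "nonspecific")
        sb = specific_binding(free, ns)
        tr = panel.tracer
        kobs = tr.k1 * design.tracer_conc + tr.k2
        expected = tr.bmax * tr.k1 * design.tracer_conc / kobs * (1 - np.exp(-kobs * free.time_min))
        np.testing.assert_allclose(sb.signal, expected, atol=1e-12)

    def test_excess_competitor_abolishes_specific_binding(self, panel, design, no_noise):
        traces = sd.generate_kinetic_traces(panel, "exendin-4", design, no_noise, seed=0)
        excess = next(
            t for t in traces
            if t.condition == "total" and t.competitor_conc == sd.NONSPECIFIC_COMPETITOR_CONC
        )
        ns = next(t for t in traces if t.condition == "nonspecific")
        sb = specific_binding(excess, ns)
        assert np.max(np.abs(sb.signal)) < 0.02 * panel.tracer.bmax

    def test_noiseless_round_trip_recovers_rates(self, panel, design, no_noise):
        truth = panel.agonist("exendin-4")
        traces = sd.generate_kinetic_traces(panel, "exendin-4", design, no_noise, seed=0)
        ns = next(t for t in traces if t.condition == "nonspecific")
        fit_traces = [
            specific_binding(t, ns)
            for t in traces
            if t.condition == "total" and 0 < t.competitor_conc < sd.NONSPECIFIC_COMPETITOR_CONC
        ]
        params = fit_competitive(fit_traces, panel.tracer)
        assert abs(params.k_on - truth.k_on) / truth.k_on < 1e-3
        assert abs(params.k_off - truth.k_off) / truth.k_off < 1e-3

    def test_negative_concentration_rejected(self, panel, design, no_noise):
        design.competitor_concs = (-1e-9, 1e-8, 3e-8, 1e-7)
        with pytest.raises(ValueError, match="non-negative"):
            sd.generate_kinetic_traces(panel, "exendin-4", design, no_noise, seed=0)


class TestCompartmentModel:
    def test_one_way_decay_closed_form(self):
        t = np.linspace(0, 60, 25)
        traj = sd.compartment_trajectories(0.05, 0.0, 0.0, t)
        np.testing.assert_allclose(traj["I"], 1 - np.exp(-0.05 * t), rtol=1e-10, atol=1e-14)

    def test_no_endocytosis_no_internalization(self):
        t = np.linspace(0, 60, 25)
        traj = sd.compartment_trajectories(0.0, 0.02, 0.01, t)
        np.testing.assert_allclose(traj["I"], 0.0, atol=1e-15)
        np.testing.assert_allclose(traj["S"], 1.0, rtol=1e-12)

    def test_conservation(self):
        t = np.linspace(0, 120, 49)
        traj = sd.compartment_trajectories(0.05, 0.01, 0.008, t)
        total = traj[["S", "I", "D"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0, rtol=1e-9)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sd.compartment_trajectories(-0.1, 0.0, 0.0, np.array([0.0, 1.0]))


class TestTraffickingGenerator:
    def test_noiseless_facs_matches_internal_fraction(self, panel, design, no_noise):
        out = sd.generate_trafficking_measurements(panel, design, no_noise, seed=0)
        truth = out["truth_trajectories"].set_index(["agonist", "time_min"])
        for m in out["facs"]:
            s, i = truth.loc[(m.condition, m.time_min)][["S", "I"]]
            # label is destroyed on degradation, so the readout reports I/(S+I)
            expected = 100.0 * i / (s + i)
            assert facs_internalized_percent(m) == pytest.approx(expected, abs=1e-9)

    def test_seed_determinism(self, panel, design):
        noise = sd.NoiseModel(cv=0.03)
        a = sd.generate_trafficking_measurements(panel, design, noise, seed=9)
        b = sd.generate_trafficking_measurements(panel, design, noise, seed=9)
        pd.testing.assert_frame_equal(a["plate"], b["plate"])
        assert [m.f_plus_me for m in a["facs"]] == [m.f_plus_me for m in b["facs"]]

    def test_invalid_strip_efficiency_rejected(self, panel, design, no_noise):
        with pytest.raises(ValueError, match="strip"):
            sd.generate_trafficking_measurements(panel, design, no_noise, seed=0, strip_efficiency=1.5)


class TestPhGenerator:
    def test_neutral_planting_equalizes_conditions(self, design, no_noise):
        a = sd.default_panel().agonists[0]
        a.endosomal_ph = 7.4
        panel = sd.GroundTruthPanel(agonists=[a], reference=a.name)
        _, wells = sd.generate_ph_dataset(panel, no_noise, seed=0)
        np.testing.assert_allclose(wells["control"], wells["bafilomycin"], rtol=1e-12)

    def test_noiseless_round_trip_exact(self, panel, no_noise):
        cal, wells = sd.generate_ph_dataset(panel, no_noise, seed=0)
        for a in panel.agonists:
            c = fit_ph_calibration(cal, ligand=a.name)
            w = wells[wells["ligand"] == a.name]
            est = estimate_endosomal_ph(w["control"].mean(), w["bafilomycin"].mean(), c)
            assert est.ph == pytest.approx(a.endosomal_ph, abs=1e-9)

    def test_one_percent_noise_recovery(self, panel):
        cal, wells = sd.generate_ph_dataset(panel, sd.NoiseModel(cv=0.01), seed=0)
        a = panel.agonists[0]
        c = fit_ph_calibration(cal, ligand=a.name)
        w = wells[wells["ligand"] == a.name]
        est = estimate_endosomal_ph(w["control"].mean(), w["bafilomycin"].mean(), c)
        assert abs(est.ph - a.endosomal_ph) < 0.05


class TestSecretionGenerator:
    def test_zero_coupling_gives_unit_isi(self, design, no_noise):
        from glp1pharm.response_quant import insulin_stimulation_index

        panel = sd.default_panel()
        for a in panel.agonists:
            a.secretion_coupling = 0.0
        samples = sd.generate_secretion_timecourse(panel, design, no_noise, seed=0)
        isi = insulin_stimulation_index(samples)
        np.testing.assert_allclose(isi.to_numpy(), 1.0, rtol=1e-9)

    def test_faster_internalizer_secretes_less(self, design, no_noise):
        base = sd.default_panel().agonists[0]
        slow = sd.AgonistTruth(
            name="slow", pathways=base.pathways, k_on=base.k_on, k_off=base.k_off,
            k_e=0.02, k_r=base.k_r, k_d=base.k_d,
        )
        fast = sd.AgonistTruth(
            name="fast", pathways=base.pathways, k_on=base.k_on, k_off=base.k_off,
            k_e=0.04, k_r=base.k_r, k_d=base.k_d,
        )
        panel = sd.GroundTruthPanel(agonists=[slow, fast], reference="slow")
        samples = sd.generate_secretion_timecourse(panel, design, no_noise, seed=0)
        by = {s.condition: s.secreted for s in samples}
        assert by["fast"] < by["slow"]

    def test_seed_determinism(self, panel, design):
        noise = sd.NoiseModel(cv=0.08)
        a = sd.generate_secretion_timecourse(panel, design, noise, seed=5)
        b = sd.generate_secretion_timecourse(panel, design, noise, seed=5)
        assert [s.secreted for s in a] == [s.secreted for s in b]
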