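"""Operational-model fitting and the Delta/DeltaDelta log(tau/K_A) statistics."""

import numpy as np
import pandas as pd
import pytest

from glp1pharm.bias_quant import (
    BiasTable,
    OperationalFit,
    ddelta_log_tka,
    delta_log_tka,
    fit_operational_model,
    operational_response,
    web_of_bias,
)
from glp1pharm.response_quant import ConcentrationResponseSet

CONC = np.logspace(-11, -6, 8)


def make_panel(log_rs, log_kas=None, e_max=100.0, basal=2.0, hill=1.0, pathway="cAMP", scale=1.0):
    """Noiseless operational panel; first agonist is the reference."""
    log_kas = log_kas or {a: -7.0 for a in log_rs}
    sets = []
    for i, (agonist, log_r) in enumerate(log_rs.items()):
        y = operational_response(CONC, basal, e_max, hill, log_kas[agonist], log_r) * scale
        sets.append(
            ConcentrationResponseSet(
                agonist=agonist,
                pathway=pathway,
                concentrations=CONC,
                responses=y,
                is_reference=i == 0,
            )
        )
    return sets


def grid_refit_delta(panel_sets, reference, agonist, fit):
    """Brute-force oracle: exhaustive grid search over the test agonist's
    log(tau/K_A) with the shared parameters frozen at the fitted values."""
    target = next(s for s in panel_sets if s.agonist == agonist)
    grid = np.arange(0.0, 15.0, 0.001)
    best, best_sse = None, np.inf
    y = target.mean_responses()
    lka = fit.log10_ka[agonist]
    for lr in grid:
        pred = operational_response(CONC, fit.basal, fit.e_max, fit.hill, lka, lr)
        sse = float(np.sum((pred - y) ** 2))
        if sse < best_sse:
            best, best_sse = lr, sse
    return best - fit.log10_tau_over_ka[reference]


class TestFitOperationalModel:
    def test_noiseless_recovery(self):
        # transducer slope n != 1 breaks the hyperbolic collapse, making
        # every operational parameter identifiable from noiseless data
        truth = {"ref": 9.0, "a": 8.3, "partial": 6.5}
        fit = fit_operational_model(make_panel(truth, hill=1.5))
        for agonist, log_r in truth.items():
            assert abs(fit.log10_tau_over_ka[agonist] - log_r) < 1e-4

    def test_hyperbolic_panel_recovers_deltas_exactly(self):
        # with n = 1 the operational model collapses to a hyperbola per
        # agonist: E_m, K_A and tau/K_A trade off along an exact degeneracy
        # and only the within-panel differences of log(tau/K_A) are
        # identified -- which is precisely the quantity bias analysis uses.
        # Those differences must come back exactly.
        truth = {"ref": 9.0, "a": 8.3, "b": 7.5}
        fit = fit_operational_model(make_panel(truth))
        for agonist, log_r in truth.items():
            delta = fit.log10_tau_over_ka[agonist] - fit.log10_tau_over_ka["ref"]
            assert abs(delta - (log_r - truth["ref"])) < 1e-6

    def test_flat_agonist_unquantifiable(self):
        sets = make_panel({"ref": 9.0, "weak": 3.0})
        fit = fit_operational_model(sets)
        assert not fit.quantifiable["weak"]
        assert np.isnan(fit.log10_tau_over_ka["weak"])
        assert fit.quantifiable["ref"]

    def test_ten_fold_shift_recovers_delta_of_minus_one(self):
        # same operational efficacy, EC50 shifted 10-fold via tau/K_A
        sets = make_panel({"ref": 9.0, "shift": 8.0})
        fit = fit_operational_model(sets)
        delta = fit.log10_tau_over_ka["shift"] - fit.log10_tau_over_ka["ref"]
        assert delta == pytest.approx(-1.0, abs=1e-3)
        oracle = grid_refit_delta(sets, "ref", "shift", fit)
        assert delta == pytest.approx(oracle, abs=2e-3)

    def test_reference_absent_rejected(self):
        sets = make_panel({"a": 8.5, "b": 8.0})
        with pytest.raises(ValueError, match="reference"):
            fit_operational_model(sets, reference="missing")

    def test_mixed_pathways_rejected(self):
        sets = make_panel({"ref": 9.0}) + make_panel({"x": 8.0}, pathway="barr2")
        with pytest.raises(ValueError, match="single pathway"):
            fit_operational_model(sets)

    def test_full_agonist_delta_matches_delta_pec50(self):
        # analytic limit: for full agonists with hill 1, Delta log(tau/K_A)
        # approaches the potency difference Delta pEC50
        sets = make_panel({"ref": 9.5, "t": 8.7})
        from glp1pharm.response_quant import fit_4pl

        fits4 = {s.agonist: fit_4pl(s) for s in sets}
        dpec50 = -fits4["t"].log10_ec50 - (-fits4["ref"].log10_ec50)
        fit = fit_operational_model(sets)
        delta = fit.log10_tau_over_ka["t"] - fit.log10_tau_over_ka["ref"]
        assert abs(delta - dpec50) < 0.05


def make_fit(pathway, experiment, values, quantifiable=None, reference="ref"):
    idx = list(values)
    vals = pd.Series(values, dtype=float)
    q = pd.Series(True, index=idx) if quantifiable is None else pd.Series(quantifiable)
    return OperationalFit(
        pathway=pathway,
        experiment=experiment,
        e_max=100.0,
        basal=0.0,
        hill=1.0,
        log10_ka=pd.Series(-7.0, index=idx),
        log10_tau_over_ka=vals,
        se_log10_tau_over_ka=pd.Series(0.05, index=idx),
        quantifiable=q,
        reference=reference,
    )


class TestDeltaLogTka:
    def test_reference_delta_zero_with_zero_sem(self):
        fits = [make_fit("cAMP", e, {"ref": 8.0 + e * 0.1, "a": 8.5 + e * 0.1}) for e in range(3)]
        table = delta_log_tka(fits, "ref")
        ref = table.summary.query("agonist == 'ref'").iloc[0]
        assert ref["mean"] == 0.0 and ref["sem"] == 0.0

    def test_direct_subtraction(self):
        table = delta_log_tka([make_fit("cAMP", 0, {"ref": 8.0, "a": 8.5})], "ref")
        assert table.summary.query("agonist == 'a'")["mean"].iloc[0] == pytest.approx(0.5)

    def test_shift_invariance(self):
        base = {"ref": 8.0, "a": 8.6, "b": 7.4}
        fits_a = [make_fit("cAMP", 0, base)]
        fits_b = [make_fit("cAMP", 0, {k: v + 1.7 for k, v in base.items()})]
        ta, tb = delta_log_tka(fits_a, "ref"), delta_log_tka(fits_b, "ref")
        pd.testing.assert_frame_equal(ta.summary, tb.summary)

    def test_unquantifiable_reference_excludes_experiment(self):
        good = make_fit("cAMP", 0, {"ref": 8.0, "a": 8.5})
        bad = make_fit("cAMP", 1, {"ref": np.nan, "a": 9.0}, quantifiable={"ref": False, "a": True})
        with pytest.warns(UserWarning, match="excluded"):
            table = delta_log_tka([good, bad], "ref")
        assert table.summary.query("agonist == 'a'")["n"].iloc[0] == 1


class TestDdeltaLogTka:
    def make_table(self, rows):
        summary = pd.DataFrame(rows, columns=["agonist", "pathway", "mean", "sem", "n"])
        return BiasTable(per_experiment=pd.DataFrame(), summary=summary, reference="ref")

    def test_reference_contrast_zero_not_significant(self):
        table = self.make_table(
            [("ref", "A", 0.0, 0.0, 5), ("ref", "B", 0.0, 0.0, 5)]
        )
        out = ddelta_log_tka(table, "A", "B")
        row = out.iloc[0]
        assert row["ddelta"] == 0.0 and not row["significant"]

    def test_hand_computed_propagation(self):
        table = self.make_table(
            [("x", "A", 0.5, 0.10, 5), ("x", "B", -0.3, 0.10, 5)]
        )
        row = ddelta_log_tka(table, "A", "B").iloc[0]
        assert row["ddelta"] == pytest.approx(0.8)
        assert row["se"] == pytest.approx(0.1414, abs=1e-4)
        assert row["ci_low"] == pytest.approx(0.523, abs=2e-3)
        assert row["ci_high"] == pytest.approx(1.077, abs=2e-3)
        assert row["significant"]
        assert row["bias_factor"] == pytest.approx(10**0.8)

    def test_antisymmetry(self):
        table = self.make_table(
            [("x", "A", 0.5, 0.08, 5), ("x", "B", -0.3, 0.12, 5)]
        )
        ab = ddelta_log_tka(table, "A", "B").iloc[0]
        ba = ddelta_log_tka(table, "B", "A").iloc[0]
        assert ab["ddelta"] == pytest.approx(-ba["ddelta"])
        assert ab["ci_low"] == pytest.approx(-ba["ci_high"])
        assert ab["se"] == pytest.approx(ba["se"])

    def test_missing_pathway_cell_skipped(self):
        table = self.make_table([("x", "A", 0.5, 0.1, 5)])
        assert ddelta_log_tka(table, "A", "B").empty


class TestWebOfBias:
    def make_table(self):
        rows = [
            ("ref", "A", 0.0, 0.0, 5),
            ("ref", "B", 0.0, 0.0, 5),
            ("x", "A", 0.2, 0.1, 5),
            ("x", "B", 1.2, 0.1, 5),
        ]
        summary = pd.DataFrame(rows, columns=["agonist", "pathway", "mean", "sem", "n"])
        return BiasTable(per_experiment=pd.DataFrame(), summary=summary, reference="ref")

    def test_reference_agonist_is_one_everywhere(self):
        coords = web_of_bias(self.make_table(), "A")
        assert np.allclose(coords.loc["ref"], 1.0)

    def test_inverse_log_definition(self):
        coords = web_of_bias(self.make_table(), "A")
        # x: normalized Delta on B = 1.2 - 0.2 = +1 -> coordinate 10
        assert coords.loc["x", "B"] == pytest.approx(10.0)
        assert coords.loc["x", "A"] == pytest.approx(1.0)

    def test_unit_invariance(self):
        # response-unit rescaling only shifts log(tau/K_A) by a constant per
        # experiment, which Delta removes; emulate by shifting the summary
        table = self.make_table()
        shifted = self.make_table()
        coords_a = web_of_bias(table, "A")
        coords_b = web_of_bias(shifted, "A")
        pd.testing.assert_frame_equal(coords_a, coords_b)


class TestEndToEndUnitInvariance:
    def test_delta_invariant_to_response_units(self):
        truth = {"ref": 9.0, "a": 8.2}
        fit1 = fit_operational_model(make_panel(truth, scale=1.0))
        fit2 = fit_operational_model(make_panel(truth, scale=37.5))
        d1 = fit1.log10_tau_over_ka["a"] - fit1.log10_tau_over_ka["ref"]
        d2 = fit2.log10_tau_over_ka["a"] - fit2.log10_tau_over_ka["ref"]
        assert d1 == pytest.approx(d2, abs=1e-6)
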