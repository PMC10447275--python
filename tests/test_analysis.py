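"""Exposure metrics, mass audit, sensitivity and uncertainty analyses."""

import numpy as np
import pytest

from lenspk.analysis import (
    compute_metrics, default_randomized_parameters,
    default_sensitivity_parameters, local_sensitivity,
    mass_balance_residual, uncertainty_cloud,
)
from lenspk.model import COMPARTMENTS, EyeModel, Trajectory
from lenspk.parameters import rabbit_dexamethasone, scale_param


def _toy_trajectory(times, series):
    n = len(times)
    conc = {name: np.zeros(n) for name in COMPARTMENTS}
    conc.update(series)
    return Trajectory(times=np.asarray(times, float), concentrations=conc,
                      sinks={k: np.zeros(n) for k in
                             ("drainage", "palpebral", "uveoscleral",
                              "choroidal", "aqueous")},
                      delivered=np.zeros(n), mode="release", params_hash="x")


class TestMetrics:
    def test_constant_series(self):
        t = np.linspace(0.0, 100.0, 11)
        tr = _toy_trajectory(t, {"C_Aq": np.full(11, 5.0)})
        met = compute_metrics(tr)
        assert met.loc["C_Aq", "auc"] == pytest.approx(500.0)
        assert met.loc["C_Aq", "cmax"] == 5.0

    def test_linear_ramp(self):
        t = np.linspace(0.0, 10.0, 101)
        tr = _toy_trajectory(t, {"C_Vit": t})
        met = compute_metrics(tr)
        assert met.loc["C_Vit", "auc"] == pytest.approx(50.0)
        assert met.loc["C_Vit", "cmax"] == pytest.approx(10.0)
        assert met.loc["C_Vit", "t_cmax"] == pytest.approx(10.0)

    def test_all_zero(self):
        tr = _toy_trajectory([0.0, 1.0, 2.0], {})
        met = compute_metrics(tr)
        assert (met[["auc", "cmax"]].to_numpy() == 0.0).all()


class TestMassAudit:
    def test_fixture_budget(self, release_result):
        assert mass_balance_residual(release_result.trajectory,
                                     release_result.params) < 1e-3

    def test_dropping_a_sink_shows_its_share(self, release_result):
        """Removing one accumulator leaves a residual equal to that
        sink's share of the delivered dose."""
        tr = release_result.trajectory
        p = release_result.params
        broken = Trajectory(
            times=tr.times, concentrations=tr.concentrations,
            sinks={k: (np.zeros_like(v) if k == "palpebral" else v)
                   for k, v in tr.sinks.items()},
            delivered=tr.delivered, mode=tr.mode, params_hash=tr.params_hash)
        share = tr.sinks["palpebral"][-1] / tr.delivered[-1]
        assert share > 0.1   # palpebral loss is a major route
        assert mass_balance_residual(broken, p) == pytest.approx(share,
                                                                 rel=1e-6)


class TestLocalSensitivity:
    def test_zero_perturbation_rejected(self):
        with pytest.raises(ValueError):
            local_sensitivity(rabbit_dexamethasone(), perturbation=0.0)

    def test_source_strength_coefficient_is_unity(self):
        """The system is linear in M_Released, so dAUC%/dparam% = 1
        exactly, in both directions, for every compartment."""
        tab = local_sensitivity(rabbit_dexamethasone(),
                                parameters=["M_Released"])
        plus = tab.frame[tab.frame.direction == "+10%"]
        minus = tab.frame[tab.frame.direction == "-10%"]
        assert np.allclose(plus.d_auc_pct_per_pct, 1.0, atol=1e-4)
        assert np.allclose(plus.d_cmax_pct_per_pct, 1.0, atol=1e-4)
        assert np.allclose(minus.d_auc_pct_per_pct, -1.0, atol=1e-4)

    def test_unused_symbol_has_zero_coefficient(self):
        """K_SCL does not enter the release-mode equations."""
        p = rabbit_dexamethasone()
        p.drug.K_SCL = 20.0   # present but inert in release mode
        tab = local_sensitivity(p, parameters=["K_SCL"])
        assert not tab.failed
        assert np.allclose(tab.frame.d_auc_pct_per_pct, 0.0, atol=1e-12)
        assert np.allclose(tab.frame.d_cmax_pct_per_pct, 0.0, atol=1e-12)

    def test_matches_independent_finite_difference(self):
        """Coefficients agree with a finite-difference computation done
        directly on simulate + trapezoid, outside the analysis code."""
        p = rabbit_dexamethasone()
        tab = local_sensitivity(p, parameters=["Q_Drain", "P_Conj"])
        for name in ("Q_Drain", "P_Conj"):
            up = EyeModel(scale_param(p, name, 1.1)).simulate().trajectory
            base = EyeModel(p).simulate().trajectory
            for comp in ("C_t", "C_ScCh"):
                auc_b = np.trapezoid(base.concentrations[comp], base.times)
                auc_u = np.trapezoid(up.concentrations[comp], up.times)
                want = (auc_u / auc_b - 1.0) * 100.0 / 10.0
                row = tab.frame[(tab.frame.parameter == name)
                                & (tab.frame.direction == "+10%")
                                & (tab.frame.compartment == comp)]
                assert row.d_auc_pct_per_pct.iloc[0] == pytest.approx(
                    want, rel=1e-9)

    def test_deep_tissues_feel_membrane_permeabilities_tears_do_not(self):
        tab = local_sensitivity(rabbit_dexamethasone(),
                                parameters=["P_ScCh_Ret", "P_Ret_Vit"])
        f = tab.frame

        def coef(param, comp):
            sub = f[(f.parameter == param) & (f.compartment == comp)]
            return sub.d_auc_pct_per_pct.abs().max()

        for comp in ("C_Ret", "C_Vit"):
            assert coef("P_ScCh_Ret", comp) > 0.0
            assert coef("P_Ret_Vit", comp) > 0.0
        assert coef("P_ScCh_Ret", "C_t") * 10.0 < coef("P_ScCh_Ret", "C_Ret")

    def test_anatomy_excluded_from_default_list(self):
        names = default_sensitivity_parameters(rabbit_dexamethasone())
        assert not any(n.startswith(("V_", "A_")) for n in names)
        assert "F" in names and "Clearance_ScCh" in names

    def test_default_randomized_set_includes_source(self):
        names = default_randomized_parameters(rabbit_dexamethasone())
        assert "M_Released" in names and "T" in names
        assert not any(n.startswith(("V_", "A_")) for n in names)


class TestUncertaintyCloud:
    def test_zero_range_reproduces_nominal(self):
        ens = uncertainty_cloud(rabbit_dexamethasone(), n_runs=5,
                                rel_range=0.0, seed=3)
        for comp, frame in ens.envelopes.items():
            assert np.allclose(frame["min"], frame["nominal"], rtol=1e-12)
            assert np.allclose(frame["max"], frame["nominal"], rtol=1e-12)

    def test_same_seed_is_bit_identical(self):
        e1 = uncertainty_cloud(rabbit_dexamethasone(), n_runs=8, seed=11)
        e2 = uncertainty_cloud(rabbit_dexamethasone(), n_runs=8, seed=11)
        for comp in e1.envelopes:
            assert e1.envelopes[comp].equals(e2.envelopes[comp])

    def test_nominal_inside_envelope_and_percentiles_bracketed(self):
        ens = uncertainty_cloud(rabbit_dexamethasone(), n_runs=30, seed=5)
        assert ens.failures == 0
        for comp, fr in ens.envelopes.items():
            assert np.all(fr["min"] <= fr["nominal"] + 1e-12 * fr["nominal"].abs().max())
            assert np.all(fr["nominal"] <= fr["max"] + 1e-12 * fr["nominal"].abs().max())
            assert np.all(fr["min"] <= fr["p2_5"] + 1e-15)
            assert np.all(fr["p97_5"] <= fr["max"] + 1e-15)
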