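"""Compartmental balances, integration, conservation and linearity."""

import numpy as np
import pytest

from lenspk.analysis import mass_balance_residual
from lenspk.model import (
    COMPARTMENTS, EyeModel, EyeState, epithelium_concentration,
    rhs_diffusion_mode, rhs_release_mode, simulate,
)
from lenspk.parameters import (
    rabbit_dexamethasone, rabbit_diffusion_demo, set_param,
)


class TestRightHandSides:
    def test_zero_state_zero_source_gives_zero_derivative(self):
        p = rabbit_dexamethasone()
        p.release.M_Released = 1e-300   # vanishing source
        d = rhs_release_mode(EyeState(), 1e9, p)   # R ~ 0 at huge t anyway
        for name in COMPARTMENTS:
            assert getattr(d, name) == pytest.approx(0.0, abs=1e-290)

    def test_bulbar_exchange_vanishes_at_equilibrium(self):
        """C_t/K_t = C_ScCh/K_ScCh kills the conjunctival driving force:
        tears then lose only drainage + palpebral terms."""
        p = rabbit_dexamethasone()
        p.release.M_Released = 1e-300
        a, ph, dg = p.anatomy, p.physiology, p.drug
        C_t = 6.0
        st = EyeState(C_t=C_t, C_ScCh=C_t / dg.K_t * dg.K_ScCh)
        d = rhs_release_mode(st, 1e9, p)
        expected = -(ph.Q_Drain + dg.P_Conj * a.A_Palp) * C_t / a.V_t
        assert d.C_t == pytest.approx(expected, rel=1e-9)

    def test_vitreous_to_aqueous_coupling_term(self):
        """With only C_Vit populated, dC_Aq/dt = Q_Vit_Aq*C_Vit/V_Aq."""
        p = rabbit_dexamethasone()
        p.release.M_Released = 1e-300
        p.physiology.Q_Vit_Aq = 1.9e-3
        p.anatomy.V_Aq = 0.325
        d = rhs_release_mode(EyeState(C_Vit=10.0), 1e9, p)
        assert d.C_Aq == pytest.approx(10.0 * 1.9e-3 / 0.325, rel=1e-9)

    @pytest.mark.parametrize("F,check", [
        (1.0, "tears"),   # all release goes transcorneal: tears get nothing
        (0.0, "aqueous"),  # aqueous receives only the vitreous inflow
    ])
    def test_release_split_extremes(self, F, check):
        p = rabbit_dexamethasone()
        p.drug.F = F
        d = rhs_release_mode(EyeState(), 0.0, p)
        if check == "tears":
            assert d.C_t == 0.0
            assert d.C_Aq > 0.0
        else:
            assert d.C_Aq == 0.0
            assert d.C_t > 0.0

    def test_release_source_decays_to_zero(self):
        p = rabbit_dexamethasone()
        d = rhs_release_mode(EyeState(), 100.0 * p.release.T, p)
        assert d.C_t == pytest.approx(0.0, abs=1e-30)
        assert d.C_Aq == pytest.approx(0.0, abs=1e-30)

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rhs_release_mode(EyeState(), 0.0, rabbit_diffusion_demo())
        with pytest.raises(ValueError):
            rhs_diffusion_mode(EyeState(), rabbit_dexamethasone())


class TestEpithelium:
    def test_weighted_mean(self):
        p = rabbit_dexamethasone()
        p.drug.K_Ep_Aq, p.drug.K_Ep_t = 2.0, 3.0
        assert epithelium_concentration(10.0, 4.0, p) == pytest.approx(16.0)

    def test_unit_partition_gives_arithmetic_mean(self):
        p = rabbit_dexamethasone()
        p.drug.K_Ep_Aq = p.drug.K_Ep_t = 1.0
        assert epithelium_concentration(10.0, 4.0, p) == pytest.approx(7.0)
        assert epithelium_concentration(0.0, 0.0, p) == 0.0

    def test_missing_partition_coefficients_rejected(self):
        with pytest.raises(ValueError):
            epithelium_concentration(1.0, 1.0, rabbit_dexamethasone())

    def test_series_emitted_only_when_computable(self):
        p = rabbit_dexamethasone()
        tr = EyeModel(p).simulate(t_end=3600, output_step=600).trajectory
        assert "C_Ep" not in tr.concentrations
        p.drug.K_Ep_Aq, p.drug.K_Ep_t = 4.0, 2.0
        tr = EyeModel(p).simulate(t_end=3600, output_step=600).trajectory
        assert np.allclose(
            tr.concentrations["C_Ep"],
            (4.0 * tr.concentrations["C_Aq"] + 2.0 * tr.concentrations["C_t"]) / 2.0)


class TestSimulate:
    def test_zero_source_stays_identically_zero(self):
        p = rabbit_diffusion_demo()
        p.lens.C0_SCL = 0.0
        tr = EyeModel(p).simulate(t_end=7200, output_step=600).trajectory
        for name in COMPARTMENTS:
            assert np.all(tr.concentrations[name] == 0.0)

    def test_mass_budget_closes_release_mode(self, release_result):
        tr = release_result.trajectory
        p = release_result.params
        resid = [mass_balance_residual(tr, p, i) for i in range(tr.times.size)]
        assert max(resid) < 1e-3

    def test_mass_budget_closes_diffusion_mode(self, diffusion_result):
        tr = diffusion_result.trajectory
        p = diffusion_result.params
        resid = [mass_balance_residual(tr, p, i) for i in range(tr.times.size)]
        assert max(resid) < 1e-3

    def test_linearity_in_source_strength(self, release_result):
        base = release_result.trajectory
        p2 = rabbit_dexamethasone()
        p2.release.M_Released *= 3.0
        tr2 = EyeModel(p2).simulate().trajectory
        for name in COMPARTMENTS:
            a, b = base.concentrations[name], tr2.concentrations[name]
            mask = a > a.max() * 1e-9
            assert np.max(np.abs(b[mask] / a[mask] - 3.0)) / 3.0 < 1e-6

    def test_non_negativity(self, release_result, diffusion_result):
        for res in (release_result, diffusion_result):
            scale = max(s.max() for s in res.trajectory.concentrations.values())
            floor = -10.0 * res.params.solver.abs_tol * max(1.0, scale)
            for name, series in res.trajectory.concentrations.items():
                assert series.min() >= floor, name

    def test_sink_accumulators_non_decreasing(self, release_result):
        for name, series in release_result.trajectory.sinks.items():
            assert np.all(np.diff(series) >= -1e-9 * max(series.max(), 1.0)), name

    def test_stronger_choroidal_clearance_lowers_posterior_exposure(self):
        aucs = {}
        for factor in (0.5, 1.5):
            p = set_param(rabbit_dexamethasone(), "Clearance_ScCh",
                          rabbit_dexamethasone().physiology.Clearance_ScCh * factor)
            met = EyeModel(p).simulate().metrics()
            aucs[factor] = met
        for comp in ("C_ScCh", "C_Ret", "C_Vit"):
            assert aucs[1.5].loc[comp, "auc"] < aucs[0.5].loc[comp, "auc"]

    def test_release_mode_ignores_lens_symbols(self):
        """D_SCL and K_SCL do not appear in the release-mode equations."""
        from lenspk.parameters import LensParams
        base = EyeModel(rabbit_dexamethasone()).simulate().trajectory
        p = rabbit_dexamethasone()
        p.drug.K_SCL = 123.0
        p.lens = LensParams(H=0.02, D_SCL=5e-9, C0_SCL=1e6)
        tr = EyeModel(p).simulate().trajectory
        for name in COMPARTMENTS:
            assert np.array_equal(base.concentrations[name],
                                  tr.concentrations[name])

    def test_deterministic_repeat(self, release_result):
        tr2 = simulate(rabbit_dexamethasone())
        for name in COMPARTMENTS:
            assert np.array_equal(release_result.trajectory.concentrations[name],
                                  tr2.concentrations[name])

    def test_summary_mentions_mode_and_metrics(self, release_result):
        text = release_result.summary()
        assert "release" in text and "AUC" in text and "C_Aq" in text


class TestClosedSystem:
    def test_conservative_system_equilibrates_uniformly(self):
        """With flows and clearances off, unit partition everywhere and
        the source split matching the volume fraction, every compartment
        relaxes to M_Released / (total volume)."""
        p = rabbit_dexamethasone()
        a = p.anatomy
        sumV = a.V_t + a.V_ScCh + a.V_Ret + a.V_Vit + a.V_Aq
        for name in ("Q_UvSc", "Q_Vit_Aq", "Q_Aq", "Q_Drain", "Clearance_ScCh"):
            p = set_param(p, name, 0.0)
        for name in ("K_t", "K_ScCh", "K_Ret", "K_Vit", "K_Aq"):
            p = set_param(p, name, 1.0)
        p.anatomy.A_Palp = 1e-30      # palpebral loss is a one-way sink
        p.drug.F = a.V_Aq / sumV      # split consistent with uniformity
        model = EyeModel(p)
        A, _ = model.system_matrix()
        lam = np.abs(np.linalg.eigvals(A[:5, :5]).real)
        slowest = 1.0 / np.min(lam[lam > 1e-15])
        t_end = 100.0 * max(slowest, p.release.T)
        tr = model.simulate(t_end=t_end, output_step=t_end / 100).trajectory
        target = p.release.M_Released / sumV
        for name in COMPARTMENTS:
            assert tr.concentrations[name][-1] == pytest.approx(
                target, rel=5e-3), name

    def test_tears_component_equilibrates_at_printed_split(self):
        """At the literature F the aqueous chamber is decoupled (flows
        off), and the tears-connected tissues share (1-F) M uniformly."""
        p = rabbit_dexamethasone()
        a = p.anatomy
        for name in ("Q_UvSc", "Q_Vit_Aq", "Q_Aq", "Q_Drain", "Clearance_ScCh"):
            p = set_param(p, name, 0.0)
        for name in ("K_t", "K_ScCh", "K_Ret", "K_Vit", "K_Aq"):
            p = set_param(p, name, 1.0)
        p.anatomy.A_Palp = 1e-30
        t_end = 100.0 * 0.361 / (p.drug.P_Conj * a.A_Bulb)
        tr = EyeModel(p).simulate(t_end=t_end, output_step=t_end / 100).trajectory
        comp_V = a.V_t + a.V_ScCh + a.V_Ret + a.V_Vit
        target = (1.0 - p.drug.F) * p.release.M_Released / comp_V
        for name in ("C_t", "C_ScCh", "C_Ret", "C_Vit"):
            assert tr.concentrations[name][-1] == pytest.approx(
                target, rel=5e-3), name
        assert tr.concentrations["C_Aq"][-1] == pytest.approx(
            p.drug.F * p.release.M_Released / a.V_Aq, rel=5e-3)
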