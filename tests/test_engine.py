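import math

import numpy as np
import pytest

from pbpkddi.compound import Compound
from pbpkddi.engine import (
    DoseEvent,
    EngineError,
    SolverOptions,
    build_model,
    metabolism_flux,
    simulate,
)
from pbpkddi.physiology import GISpec, OrganSpec, PhysiologyModel


def neutral_compound(**kw):
    base = dict(
        name="tracer",
        molecular_weight_g_mol=300.0,
        lipophilicity_logd74=0.0,
        pka=7.0,
        pka_type="neutral",
        solubility_mg_ml=10.0,
        solubility_ref_ph=7.0,
        fraction_unbound={"rat": 1.0, "human": 1.0},
        specific_intestinal_permeability_cm_s=1e-6,
        cellular_permeability=0.01,
        cellular_permeability_unit="cm/s",
    )
    base.update(kw)
    return Compound(**base)


def lung_liver_physiology(flow_ml_min=2000.0):
    """Minimal circulation (lung in series, one systemic organ) with water-only
    tissues and fast exchange, for analytic-limit tests."""
    def organ(name, vol, drains):
        return OrganSpec(
            name=name, total_volume_ml=vol, blood_flow_ml_min=flow_ml_min,
            f_vascular=0.1, f_interstitial=0.3, f_intracellular=0.6,
            f_water=1.0, f_lipid=0.0, f_protein=0.0,
            sa_endothelial_cm2_per_ml=1e5, sa_cell_cm2_per_ml=1e5,
            drains_to=drains, enzyme_relative_expression={},
        )

    return PhysiologyModel(
        species="rat", body_weight_kg=0.25,
        organs=[organ("lung", 5.0, "arterial"), organ("liver", 50.0, "venous")],
        hematocrit=0.45, mppgl_mg_per_g=44.8,
        enzyme_reference_concentration_pmol_per_mg={"CYP3A2": 101.0},
        gfr_ml_min_kg=5.2, cardiac_output_ml_min=flow_ml_min,
        arterial_volume_ml=6.8, venous_volume_ml=11.7,
        gi=GISpec(3.4, 10.0, [1.7, 1.7, 1.7], [20.0] * 3, [800.0, 480.0, 320.0]),
    )


class TestStructure:
    def test_state_count_matches_documentation(self, saxagliptin, rat_phys):
        m = build_model(saxagliptin, rat_phys)
        doc = m.describe()
        assert doc["n_states"] == 4 * doc["n_organs"] + 4 + doc["n_lumen_states"] + 4
        assert doc["n_states"] == len(doc["state_names"]) == m.n_states
        assert doc["n_organs"] == 13

    def test_liver_outflow_carries_portal_inflow(self, saxagliptin, rat_phys):
        m = build_model(saxagliptin, rat_phys)
        q = {o.name: o.blood_flow_ml_min for o in rat_phys.organs}
        expected = (q["liver"] + q["gut_wall"] + q["spleen"]) * (1 - rat_phys.hematocrit)
        assert m.Q_out_pl[m.i_liver] == pytest.approx(expected, rel=1e-12)


class TestMetabolismFlux:
    def test_unit_reconciliation_of_printed_constants(self):
        # 45,248 pmol x 1.99 uL/min/pmol x 1 uM -> 90.04 nmol/min
        assert metabolism_flux(45248.0, 1.99, 1.0) == pytest.approx(90.04, abs=0.005)

    def test_zero_concentration_gives_zero_flux(self):
        assert metabolism_flux(45248.0, 1.99, 0.0) == 0.0

    def test_first_order_in_concentration(self):
        assert metabolism_flux(1000.0, 2.0, 3.0) == pytest.approx(
            2 * metabolism_flux(1000.0, 2.0, 1.5), rel=1e-12
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(EngineError):
            metabolism_flux(-1.0, 1.0, 1.0)


class TestSimulation:
    def test_zero_dose_gives_identically_zero_trajectory(self, saxagliptin, rat_phys):
        m = build_model(saxagliptin, rat_phys)
        res = simulate(m, [DoseEvent("oral", 0.0)], 2.0, SolverOptions(output_dt_h=0.1))
        assert np.all(res.compounds["saxagliptin"].states_nmol == 0.0)

    def test_iv_bolus_equilibrates_to_uniform_unbound_concentration(self):
        """No elimination + fast exchange: every sub-compartment reaches the same
        unbound concentration."""
        phys = lung_liver_physiology()
        m = build_model(neutral_compound(), phys)
        res = simulate(m, [DoseEvent("iv_bolus", 1.0)], 4.0, SolverOptions(output_dt_h=0.5))
        y = res.compounds["tracer"].states_nmol[-1]
        u = []
        for i in range(m.n_organs):
            a = y[4 * i : 4 * i + 4]
            u += [
                a[0] / (m.V_pl[i] / m.fu),
                a[1] / (m.V_bc[i] * m.k_bc),
                a[2] / (m.V_int[i] / m.fu),
                a[3] / (m.V_cell[i] * m.k_cell[i]),
            ]
        u.append(y[m.off_pools + 2] / (m.V_ven_pl / m.fu))
        u.append(y[m.off_pools + 0] / (m.V_art_pl / m.fu))
        assert np.ptp(u) / np.mean(u) < 1e-6

    def test_one_compartment_reduction_matches_closed_form(self):
        """Well-mixed limit with a single first-order hepatic clearance: venous plasma
        follows C0*exp(-k t) within 0.1% pointwise."""
        phys = lung_liver_physiology()
        t_half = 30.0  # min, plasma-referenced
        cmp = neutral_compound()
        d = cmp.to_dict()
        d["clearance"] = [
            {"kind": "total_hepatic_halflife", "species": "rat", "hepatic_t_half_min": t_half}
        ]
        cmp = Compound.from_dict(d)
        m = build_model(cmp, phys)
        res = simulate(m, [DoseEvent("iv_bolus", 1.0)], 12.0, SolverOptions(output_dt_h=0.05))
        t, c = res.profile()

        v_eff = float(
            np.sum(m.V_pl + m.V_bc * m.k_bc + m.V_int + m.V_cell * m.k_cell)
            + m.V_art_pl + m.V_ven_pl + (m.V_art_bc + m.V_ven_bc) * m.k_bc
        )
        dose_nmol = 1e6 / 300.0
        k_per_h = math.log(2.0) / t_half * phys.plasma_volume_ml / v_eff * 60.0
        mask = t >= 0.5  # past the brief mixing transient
        expected = dose_nmol / v_eff * np.exp(-k_per_h * t[mask]) * 300.0
        assert np.max(np.abs(c[mask] - expected) / expected) < 1e-3

    def test_mass_balance_at_every_output_time(self, rat_sxg_result):
        traj = rat_sxg_result.compounds["saxagliptin"]
        assert traj.mass_balance_rel_err.max() < 1e-6

    def test_auc_is_dose_proportional_under_linear_clearance(self, saxagliptin, rat_phys):
        m = build_model(saxagliptin, rat_phys)
        opts = SolverOptions(output_dt_h=0.05)
        auc = []
        for dose in (5.0, 10.0):
            res = simulate(m, [DoseEvent("oral", dose, per_kg=True)], 24.0, opts)
            t, c = res.profile()
            auc.append(np.trapezoid(c, t))
        assert abs(auc[1] / auc[0] - 2.0) < 1e-6

    def test_tightening_solver_tolerances_leaves_metrics_unchanged(self, saxagliptin, rat_phys):
        m = build_model(saxagliptin, rat_phys)
        doses = [DoseEvent("oral", 5.0, per_kg=True)]
        base = simulate(m, doses, 24.0, SolverOptions(output_dt_h=0.05))
        tight = simulate(
            m, doses, 24.0, SolverOptions(rtol=1e-9, atol=1e-11, output_dt_h=0.05)
        )
        t, c1 = base.profile()
        _, c2 = tight.profile()
        assert abs(c1.max() - c2.max()) / c2.max() < 1e-3
        assert abs(np.trapezoid(c1, t) - np.trapezoid(c2, t)) / np.trapezoid(c2, t) < 1e-3

    def test_repeated_dosing_reaches_periodic_steady_state(self, saxagliptin, rat_phys):
        m = build_model(saxagliptin, rat_phys)
        tau = 12.0
        doses = [DoseEvent("oral", 5.0, per_kg=True, time_h=i * tau) for i in range(6)]
        res = simulate(m, doses, 6 * tau, SolverOptions(output_dt_h=0.05))
        t, c = res.profile()

        def interval_auc(i):
            mask = (t >= i * tau) & (t <= (i + 1) * tau)
            return np.trapezoid(c[mask], t[mask])

        assert abs(interval_auc(5) / interval_auc(4) - 1.0) < 1e-3

    def test_rat_victim_cmax_within_twofold_of_reported_prediction(self, rat_sxg_result):
        _, c = rat_sxg_result.profile("saxagliptin")
        assert 144.0 / 2 <= c.max() <= 144.0 * 2

    def test_duration_must_cover_dose_times(self, saxagliptin, rat_phys):
        m = build_model(saxagliptin, rat_phys)
        with pytest.raises(EngineError, match="duration"):
            simulate(m, [DoseEvent("oral", 5.0, time_h=30.0)], 24.0)

    def test_dose_event_validation(self):
        with pytest.raises(EngineError):
            DoseEvent("intramuscular", 5.0)
        with pytest.raises(EngineError):
            DoseEvent("oral", -1.0)
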