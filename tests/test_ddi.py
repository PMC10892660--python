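import dataclasses

import numpy as np
import pytest

from pbpkddi.ddi import (
    DDIError,
    apparent_clint,
    get_param,
    set_param,
    simulate_ddi,
    static_index,
)
from pbpkddi.engine import DoseEvent, SolverOptions
from pbpkddi.nca import ConcProfile, nca_single


def coarse(scenario, **changes):
    sc = dataclasses.replace(scenario, solver=SolverOptions(output_dt_h=0.05), **changes)
    return sc


class TestApparentClint:
    def test_no_inhibitor_leaves_clint_unchanged(self):
        assert apparent_clint(1.99, 0.0, 0.39) == 1.99

    def test_half_inhibition_at_ki(self):
        assert apparent_clint(2.0, 0.39, 0.39) == pytest.approx(1.0, rel=1e-12)

    def test_hand_evaluation_at_static_rat_exposure(self):
        assert apparent_clint(1.99, 0.0121, 0.39) == pytest.approx(1.930, abs=5e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DDIError):
            apparent_clint(-1.0, 0.0, 0.39)
        with pytest.raises(DDIError):
            apparent_clint(1.0, 0.1, 0.0)


class TestStaticIndex:
    def test_rat_screen_from_predicted_perpetrator_exposure(self):
        assert round(static_index(69.3, 0.084, 479.59, 0.39), 2) == 1.03

    def test_human_screen_from_predicted_perpetrator_exposure(self):
        assert round(static_index(36.4, 0.01, 479.59, 0.06), 2) == 1.01

    def test_no_free_inhibitor_limit(self):
        assert static_index(69.3, 1e-9, 479.59, 0.39) == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DDIError):
            static_index(0.0, 0.1, 479.59, 0.39)


@pytest.fixture(scope="module")
def alone_auc(rat_scenario):
    sc = coarse(rat_scenario)
    res = sc.simulate_victim_alone()
    return nca_single(sc.victim_profile(res)).auc_inf_ng_h_ml


class TestDynamicCoupling:
    def test_zero_perpetrator_dose_gives_unit_ratios(self, rat_scenario):
        sc = coarse(
            rat_scenario,
            perpetrator_doses=[DoseEvent("oral", 0.0, per_kg=True)],
        )
        r = simulate_ddi(sc)
        assert r.auc_ratio == pytest.approx(1.0, abs=1e-6)
        assert r.cmax_ratio == pytest.approx(1.0, abs=1e-6)

    def test_infinite_ki_decouples_the_models(self, rat_scenario):
        sc = set_param(coarse(rat_scenario), "perpetrator.inhibition.CYP3A2.ki_um", 1e12)
        r = simulate_ddi(sc, keep_results=True)
        assert r.auc_ratio == pytest.approx(1.0, abs=1e-6)
        # victim mass balance is untouched by the coupling
        traj = r.combo_result.compounds["saxagliptin"]
        assert traj.mass_balance_rel_err.max() < 1e-6

    def test_auc_ratio_monotone_in_perpetrator_dose(self, rat_scenario, alone_auc):
        aucs = []
        for dose in (5.0, 15.0, 45.0):
            sc = coarse(rat_scenario, perpetrator_doses=[DoseEvent("oral", dose, per_kg=True)])
            combo = nca_single(sc.victim_profile(sc.simulate_co())).auc_inf_ng_h_ml
            aucs.append(combo / alone_auc)
        assert aucs[0] < aucs[1] < aucs[2]
        assert all(a > 1.0 for a in aucs)

    def test_auc_ratio_monotone_in_ki(self, rat_scenario, alone_auc):
        ratios = []
        for ki in (0.1, 0.39, 1.56):
            sc = set_param(coarse(rat_scenario), "perpetrator.inhibition.CYP3A2.ki_um", ki)
            combo = nca_single(sc.victim_profile(sc.simulate_co())).auc_inf_ng_h_ml
            ratios.append(combo / alone_auc)
        assert ratios[0] > ratios[1] > ratios[2]

    def test_weak_static_inhibition_implies_weak_dynamic_interaction(self, rat_scenario):
        """A perpetrator exposure whose static screen stays below 1.05 must not produce
        more than a 1.25-fold dynamic AUC shift."""
        sc = coarse(rat_scenario, perpetrator_doses=[DoseEvent("oral", 0.2, per_kg=True)])
        r = simulate_ddi(sc, keep_results=True)
        t, c = r.combo_result.profile("nicardipine")
        idx = static_index(float(c.max()), 0.084, 479.59, 0.39)
        assert idx < 1.05
        assert r.auc_ratio < 1.25

    def test_mismatched_enzymes_are_rejected(self, rat_scenario, nicardipine):
        d = nicardipine.to_dict()
        d["inhibition"] = [
            {"enzyme": "CYP2D6", "species": "rat", "ki_um": 0.5, "mechanism": "competitive"}
        ]
        from pbpkddi.compound import Compound

        sc = coarse(rat_scenario, perpetrator=Compound.from_dict(d))
        with pytest.raises(DDIError, match="no perpetrator inhibition"):
            simulate_ddi(sc)


class TestParameterPaths:
    def test_round_trip_get_set(self, rat_scenario):
        assert get_param(rat_scenario, "victim.fraction_unbound") == 0.82
        assert get_param(rat_scenario, "victim.clearance.CYP3A2.clint_ul_min_pmol") == 1.99
        assert get_param(rat_scenario, "perpetrator.clearance.hepatic.hepatic_t_half_min") == 0.62
        sc = set_param(rat_scenario, "victim.fraction_unbound", 0.5)
        assert get_param(sc, "victim.fraction_unbound") == 0.5
        assert get_param(rat_scenario, "victim.fraction_unbound") == 0.82  # original intact

    def test_unknown_path_raises(self, rat_scenario):
        with pytest.raises(DDIError):
            get_param(rat_scenario, "victim.clearance.CYP2C9.clint_ul_min_pmol")
        with pytest.raises(DDIError):
            set_param(rat_scenario, "nonsense.path", 1.0)
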