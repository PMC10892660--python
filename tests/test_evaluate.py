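import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pbpkddi.evaluate import (
    EvaluationError,
    PopulationSpec,
    ddi_ratios,
    fold_classification,
    gmfe,
    mrd,
    prediction_interval,
)
from pbpkddi.engine import SolverOptions
from pbpkddi.nca import ConcProfile, PKParameters


def profile(conc, t=None, subject="s"):
    conc = np.asarray(conc, dtype=float)
    t = np.arange(1.0, len(conc) + 1) if t is None else np.asarray(t)
    return ConcProfile(subject, t, conc, 1.0)


def pk(cmax, auc):
    return PKParameters(
        cmax_ng_ml=cmax, tmax_h=0.5, auc_last_ng_h_ml=auc, auc_inf_ng_h_ml=auc,
        t_half_h=1.0, cl_f=1.0, lambda_z_per_h=0.7, n_lambda_points=3,
        extrapolated_fraction=0.05,
    )


class TestMRD:
    def test_identical_profiles_give_one(self):
        p = profile([10.0, 5.0, 2.0])
        assert mrd(p, p) == pytest.approx(1.0, rel=1e-12)

    def test_single_point_tenfold_off(self):
        assert mrd(profile([10.0]), profile([100.0])) == pytest.approx(10.0, rel=1e-9)

    def test_two_points_twofold_and_exact(self):
        # 10^sqrt((log10(2)^2 + 0)/2) = 1.632
        assert mrd(profile([2.0, 5.0]), profile([1.0, 5.0])) == pytest.approx(1.632, abs=1e-3)

    def test_invariant_to_joint_unit_rescaling(self):
        obs, pred = profile([12.0, 6.0, 2.5]), profile([10.0, 5.0, 2.0])
        scaled = mrd(profile(obs.conc_ng_ml * 1000), profile(pred.conc_ng_ml * 1000))
        assert scaled == pytest.approx(mrd(obs, pred), rel=1e-12)

    def test_disjoint_timepoints_rejected(self):
        with pytest.raises(EvaluationError):
            mrd(profile([1.0, 2.0], t=[1.0, 2.0]), profile([1.0, 2.0], t=[40.0, 50.0]))

    def test_nonpositive_concentrations_rejected(self):
        with pytest.raises(EvaluationError):
            mrd(profile([0.0, 1.0]), profile([1.0, 1.0]))


class TestGMFE:
    def test_reported_ratio_pair_reproduces_reported_value(self):
        assert round(gmfe([2.05, 1.46]), 2) == 1.73

    def test_perfect_predictions_give_one(self):
        assert gmfe([1.0, 1.0]) == 1.0

    def test_symmetric_fold_errors(self):
        assert gmfe([2.0, 0.5]) == pytest.approx(2.0, rel=1e-12)

    @given(st.lists(st.floats(0.05, 20.0), min_size=1, max_size=8))
    def test_invariant_under_elementwise_inversion(self, ratios):
        assert gmfe(ratios) == pytest.approx(gmfe([1.0 / r for r in ratios]), rel=1e-9)

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(EvaluationError):
            gmfe([])
        with pytest.raises(EvaluationError):
            gmfe([1.0, -2.0])


class TestDDIRatios:
    def test_observed_rat_means(self):
        auc_r, cmax_r = ddi_ratios(pk(98.5, 157.0), pk(281.0, 408.0))
        assert round(auc_r, 2) == 2.60
        assert round(cmax_r, 2) == 2.85

    def test_predicted_human_means(self):
        auc_r, cmax_r = ddi_ratios(pk(9.81, 50.5), pk(10.8, 52.9))
        assert round(auc_r, 2) == 1.05
        assert round(cmax_r, 2) == 1.10

    def test_identical_parameters_give_unit_ratios(self):
        assert ddi_ratios(pk(10.0, 100.0), pk(10.0, 100.0)) == (1.0, 1.0)

    def test_incomplete_parameters_rejected(self):
        bad = dataclasses.replace(pk(1.0, 1.0), computable=False)
        with pytest.raises(EvaluationError):
            ddi_ratios(bad, pk(1.0, 1.0))


class TestFoldClassification:
    def test_bands(self):
        fc = fold_classification([(144.0, 98.5), (100.0, 100.0), (205.0, 100.0)])
        assert (fc.within_1_25, fc.within_2, fc.outside_2) == (1, 1, 1)
        assert fc.n == 3 and not fc.all_within_2

    def test_symmetric_in_log_space(self):
        fc = fold_classification([(1.0, 1.9), (1.9, 1.0)])
        assert fc.within_2 == 2

    def test_nonpositive_rejected(self):
        with pytest.raises(EvaluationError):
            fold_classification([(0.0, 1.0)])


@pytest.fixture(scope="module")
def small_scenario(rat_scenario):
    return dataclasses.replace(
        rat_scenario, duration_h=6.0, solver=SolverOptions(output_dt_h=0.1)
    )


class TestPredictionInterval:
    def test_zero_cv_collapses_to_the_point_prediction(self, small_scenario):
        pop = PopulationSpec(3, {"victim.fraction_unbound": 0.0}, seed=1)
        pi = prediction_interval(small_scenario, pop)
        assert np.allclose(pi.lower, pi.point, rtol=1e-9)
        assert np.allclose(pi.upper, pi.point, rtol=1e-9)

    def test_interval_width_grows_with_cv(self, small_scenario):
        widths = []
        for cv in (0.1, 0.4):
            pop = PopulationSpec(6, {"victim.clearance.CYP3A2.clint_ul_min_pmol": cv}, seed=3)
            pi = prediction_interval(small_scenario, pop)
            widths.append(np.trapezoid(pi.upper - pi.lower, pi.time_h))
        assert widths[1] > widths[0]

    def test_interval_contains_the_point_trajectory(self, small_scenario):
        pop = PopulationSpec(8, {"victim.clearance.CYP3A2.clint_ul_min_pmol": 0.3}, seed=5)
        pi = prediction_interval(small_scenario, pop)
        inside = (pi.point >= pi.lower - 1e-9) & (pi.point <= pi.upper + 1e-9)
        assert inside[pi.time_h > 0.2].mean() > 0.95

    def test_deterministic_given_seed(self, small_scenario):
        pop = PopulationSpec(3, {"victim.fraction_unbound": 0.2}, seed=9)
        a = prediction_interval(small_scenario, pop)
        b = prediction_interval(small_scenario, pop)
        assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)

    def test_invalid_population_rejected(self):
        with pytest.raises(EvaluationError):
            PopulationSpec(1, {}, seed=0)
        with pytest.raises(EvaluationError):
            PopulationSpec(5, {"x": -0.1}, seed=0)
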