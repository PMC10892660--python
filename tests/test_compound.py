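import math

import pytest
from hypothesis import given, strategies as st

from pbpkddi.compound import (
    Compound,
    CompoundError,
    FormulationSpec,
    dissolved_fraction,
    load_compound,
    partition_coefficients,
)
from pbpkddi.physiology import load_physiology


def make_compound(**kw):
    base = dict(
        name="probe",
        molecular_weight_g_mol=300.0,
        lipophilicity_logd74=0.0,
        pka=7.0,
        pka_type="neutral",
        solubility_mg_ml=10.0,
        solubility_ref_ph=7.0,
        fraction_unbound={"rat": 1.0, "human": 1.0},
        specific_intestinal_permeability_cm_s=1e-6,
        cellular_permeability=10.0,
        cellular_permeability_unit="1e-6 cm/s",
    )
    base.update(kw)
    return Compound(**base)


class TestPartitioning:
    def test_water_only_tissue_with_no_binding_gives_unit_kp(self):
        phys = load_physiology(
            "rat",
            0.25,
            {
                "organs.muscle.f_water": 1.0,
                "organs.muscle.f_lipid": 0.0,
                "organs.muscle.f_protein": 0.0,
            },
        )
        kps = partition_coefficients(make_compound(), phys)
        assert kps.kp["muscle"] == pytest.approx(1.0, abs=1e-6)

    def test_adipose_kp_increases_with_lipophilicity(self, rat_phys):
        kp_ad = [
            partition_coefficients(make_compound(lipophilicity_logd74=ld), rat_phys).kp["adipose"]
            for ld in (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
        ]
        assert all(b > a for a, b in zip(kp_ad, kp_ad[1:]))

    def test_hydrophilic_victim_partitions_less_into_fat_than_muscle(
        self, saxagliptin, rat_phys
    ):
        kps = partition_coefficients(saxagliptin, rat_phys)
        assert kps.kp["adipose"] < kps.kp["muscle"]

    def test_kp_is_scale_free_in_organ_volumes(self, saxagliptin):
        small = load_physiology("rat", 0.2)
        large = load_physiology("rat", 0.4)
        kp_s = partition_coefficients(saxagliptin, small).kp
        kp_l = partition_coefficients(saxagliptin, large).kp
        for organ in kp_s:
            assert kp_s[organ] == pytest.approx(kp_l[organ], rel=1e-12)

    def test_method_is_recorded_and_overrides_are_honored(self, saxagliptin, rat_phys):
        kps = partition_coefficients(saxagliptin, rat_phys, overrides={"liver": 3.21})
        assert kps.method == "composition-v1"
        assert kps.kp["liver"] == 3.21


class TestDissolution:
    def test_half_dissolved_at_the_anchor_time(self):
        for shape, t50 in [(0.68, 120.5), (1.18, 5.59), (0.8, 71.0)]:
            form = FormulationSpec("t", "tablet", shape, t50)
            assert dissolved_fraction(form, t50) == pytest.approx(0.5, rel=1e-12)

    def test_nothing_dissolved_at_time_zero(self):
        form = FormulationSpec("t", "tablet", 1.18, 5.59)
        assert dissolved_fraction(form, 0.0) == 0.0

    def test_weibull_cdf_matches_direct_evaluation(self):
        form = FormulationSpec("t", "tablet", 0.68, 120.5)
        expected = 1.0 - math.exp(-math.log(2.0) * (241.0 / 120.5) ** 0.68)
        assert dissolved_fraction(form, 241.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.6706, abs=2e-4)

    def test_solution_dissolves_instantly(self):
        assert dissolved_fraction(FormulationSpec("s", "solution"), 0.5) == 1.0

    @given(
        shape=st.floats(0.2, 5.0),
        t50=st.floats(1.0, 500.0),
        t=st.floats(0.0, 2000.0),
        dt=st.floats(0.0, 2000.0),
    )
    def test_dissolved_fraction_is_monotone_nondecreasing(self, shape, t50, t, dt):
        form = FormulationSpec("t", "tablet", shape, t50)
        assert dissolved_fraction(form, t + dt) >= dissolved_fraction(form, t) - 1e-12

    def test_negative_time_rejected(self):
        with pytest.raises(CompoundError):
            dissolved_fraction(FormulationSpec("t", "tablet", 1.0, 10.0), -1.0)


class TestCompoundIO:
    def test_bundled_definitions_match_the_parameter_tables(self, saxagliptin, nicardipine):
        assert saxagliptin.molecular_weight_g_mol == 315.41
        assert saxagliptin.fu("rat") == 0.82 and saxagliptin.fu("human") == 1.0
        rat_cl = {c.kind for c in saxagliptin.clearances("rat")}
        assert rat_cl == {"enzyme_mediated", "renal"}
        assert nicardipine.inhibitions("rat")[0].ki_um == 0.39
        assert nicardipine.inhibitions("human")[0].ki_um == 0.06

    def test_yaml_round_trip(self, nicardipine):
        clone = Compound.from_yaml(nicardipine.to_yaml())
        assert clone.to_dict() == nicardipine.to_dict()

    def test_cellular_permeability_unit_is_selectable(self, nicardipine):
        assert nicardipine.cellular_permeability_cm_s == pytest.approx(0.09)
        d = nicardipine.to_dict()
        d["cellular_permeability_unit"] = "1e-6 cm/s"
        assert Compound.from_dict(d).cellular_permeability_cm_s == pytest.approx(0.09e-6)

    @pytest.mark.parametrize(
        "field, value",
        [
            ("molecular_weight_g_mol", -1.0),
            ("fraction_unbound", {"rat": 1.3}),
            ("solubility_mg_ml", 0.0),
            ("pka_type", "zwitterion"),
        ],
    )
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(CompoundError):
            make_compound(**{field: value})

    def test_unknown_bundled_compound_raises(self):
        with pytest.raises(FileNotFoundError):
            load_compound("no_such_drug")
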