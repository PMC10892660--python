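"""Synthetic study generation with known ground truth.

Emulates the data this pipeline consumes without any external inputs: virtual PK
studies (parallel-group oral dosing in rats, dense or sparse sampling, lognormal
inter-individual variability, proportional + additive residual error), and in vitro
assay readouts (substrate-depletion time courses, IC50 inhibition curves). Every
generator takes an explicit seed and emits a ground-truth log sufficient to re-derive
the data.

Defaults mirror the emulated study conditions: a three-group rat design (perpetrator
15 mg/kg n=7, victim 5 mg/kg n=6, co-administration n=7) sampled at 0.25, 0.5, 1, 2,
3, 4, 6, 8, 12 and 24 h; depletion sampling at 0/5/10/20/30 min in triplicate;
inhibition at nine concentrations spanning 0-100 uM. Residual error defaults to 10%
proportional + 1 ng/mL additive; inter-individual CVs default to 30%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ddi import Scenario, get_param, set_param
from .invitro import DepletionAssay, InhibitionAssay
from .nca import ConcProfile

__all__ = [
    "GroupSpec",
    "StudyDesign",
    "generate_pk_study",
    "generate_invitro",
    "default_rat_design",
    "SyntheticError",
]

RAT_SAMPLING_H = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
DEPLETION_TIMES_MIN = (0.0, 5.0, 10.0, 20.0, 30.0)
INHIBITION_CONCS_UM = (0.0, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)


class SyntheticError(ValueError):
    """Invalid study design or generator parameters."""


@dataclass
class GroupSpec:
    name: str
    n: int
    give_victim: bool
    give_perpetrator: bool
    measured: str = "victim"  # which compound's plasma profile is sampled

    def __post_init__(self):
        if self.n < 1:
            raise SyntheticError("group size must be >= 1")
        if not (self.give_victim or self.give_perpetrator):
            raise SyntheticError("group must receive at least one drug")


@dataclass
class StudyDesign:
    groups: list[GroupSpec]
    sampling_times_h: tuple = RAT_SAMPLING_H
    proportional_cv: float = 0.10
    additive_sd_ng_ml: float = 1.0
    iiv_cv: dict[str, float] = field(default_factory=dict)  # parameter path -> CV
    seed: int = 0
    lloq_ng_ml: float | None = None

    def __post_init__(self):
        if self.proportional_cv < 0 or self.additive_sd_ng_ml < 0:
            raise SyntheticError("residual error terms must be >= 0")
        if any(cv < 0 for cv in self.iiv_cv.values()):
            raise SyntheticError("inter-individual CVs must be >= 0")


def default_rat_design(seed: int, iiv_cv: float = 0.30) -> StudyDesign:
    """The emulated three-group rat DDI study with default variability on the
    parameters that dominate exposure."""
    return StudyDesign(
        groups=[
            GroupSpec("perpetrator_alone", 7, False, True, measured="perpetrator"),
            GroupSpec("victim_alone", 6, True, False),
            GroupSpec("co_administration", 7, True, True),
        ],
        iiv_cv={
            "victim.clearance.CYP3A2.clint_ul_min_pmol": iiv_cv,
            "victim.clearance.renal.clearance_ml_min_kg": iiv_cv,
            "victim.fraction_unbound": iiv_cv / 2,
        },
        seed=seed,
    )


def _subject_scenario(scenario: Scenario, mult: dict[str, float]) -> Scenario:
    sc = scenario
    for path, m in mult.items():
        if m != 1.0:
            val = get_param(sc, path) * m
            # fraction unbound is bounded above by 1
            if path.endswith("fraction_unbound"):
                val = min(val, 1.0)
            sc = set_param(sc, path, val)
    return sc


def generate_pk_study(
    design: StudyDesign, scenario: Scenario
) -> tuple[list[ConcProfile], dict]:
    """Simulate a parallel-group study; returns per-subject noisy profiles and a
    ground-truth log (seed, per-subject multipliers, noise-free concentrations)."""
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.sampling_times_h, dtype=float)
    profiles: list[ConcProfile] = []
    truth: dict = {"seed": design.seed, "subjects": {}, "sampling_times_h": times.tolist()}

    for group in design.groups:
        for j in range(group.n):
            subject = f"{group.name}-{j + 1}"
            mult = {}
            for path, cv in design.iiv_cv.items():
                if cv == 0:
                    mult[path] = 1.0
                else:
                    sigma = math.sqrt(math.log(1.0 + cv * cv))
                    mult[path] = float(rng.lognormal(0.0, sigma))
            sc = _subject_scenario(scenario, mult)
            if group.give_victim and group.give_perpetrator:
                res = sc.simulate_co()
            elif group.give_victim:
                res = sc.simulate_victim_alone()
            else:
                from .engine import simulate

                res = simulate(
                    sc.build_perpetrator(), sc.perpetrator_doses, sc.duration_h, sc.solver
                )
            compound = sc.victim.name if group.measured == "victim" else sc.perpetrator.name
            t_grid, c_grid = res.profile(compound)
            clean = np.interp(times, t_grid, c_grid)
            eps = rng.standard_normal(len(times))
            eta = rng.standard_normal(len(times))
            noisy = clean * (1.0 + design.proportional_cv * eps) + design.additive_sd_ng_ml * eta
            noisy = np.clip(noisy, 0.0, None)
            below = None
            if design.lloq_ng_ml is not None:
                below = noisy < design.lloq_ng_ml
                noisy = np.where(below, 0.0, noisy)
            dose = (
                sc.victim_doses[0] if group.measured == "victim" else sc.perpetrator_doses[0]
            )
            profiles.append(
                ConcProfile(
                    subject=subject,
                    time_h=times,
                    conc_ng_ml=noisy,
                    dose=dose.amount,
                    dose_per_kg=dose.per_kg,
                    role="observed",
                    group=group.name,
                    lloq_ng_ml=design.lloq_ng_ml,
                )
            )
            truth["subjects"][subject] = {
                "group": group.name,
                "multipliers": mult,
                "clean_conc_ng_ml": clean.tolist(),
                "n_below_lloq": int(below.sum()) if below is not None else 0,
            }
    return profiles, truth


def generate_invitro(
    kind: str,
    truth: dict,
    noise_cv: float = 0.0,
    seed: int = 0,
):
    """Synthetic in vitro assay with known truth.

    kind='depletion': truth needs t_half_min (and optionally enzyme_conc_pmol_ml,
    default 10); triplicate 0/5/10/20/30 min design. kind='inhibition': truth needs
    ic50_um (and optionally hill, default 1.0); nine concentrations 0-100 uM, control
    fixed at 100% by construction. Noise is proportional with the given CV.
    """
    if noise_cv < 0:
        raise SyntheticError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    if kind == "depletion":
        t_half = truth["t_half_min"]
        if t_half <= 0:
            raise SyntheticError("t_half_min must be > 0")
        k = math.log(2.0) / t_half
        times = np.tile(DEPLETION_TIMES_MIN, 3)
        clean = np.exp(-k * times)
        noisy = clean * (1.0 + noise_cv * rng.standard_normal(len(times)))
        noisy = np.clip(noisy, 1e-6, 1.2)
        order = np.argsort(times, kind="stable")
        return DepletionAssay(
            time_min=times[order],
            fraction_remaining=noisy[order],
            enzyme_conc_pmol_ml=truth.get("enzyme_conc_pmol_ml", 10.0),
        )
    if kind == "inhibition":
        ic50 = truth["ic50_um"]
        if ic50 <= 0:
            raise SyntheticError("ic50_um must be > 0")
        h = truth.get("hill", 1.0)
        conc = np.asarray(INHIBITION_CONCS_UM)
        clean = 100.0 / (1.0 + (conc / ic50) ** h)
        clean[conc == 0] = 100.0
        noisy = clean * (1.0 + noise_cv * rng.standard_normal(len(conc)))
        noisy[conc == 0] = 100.0  # control defines 100% by construction
        return InhibitionAssay(inhibitor_um=conc, pct_control=np.clip(noisy, 0.0, None))
    raise SyntheticError(f"unknown assay kind {kind!r}")
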