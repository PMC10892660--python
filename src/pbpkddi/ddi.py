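"""Victim-perpetrator coupling: dynamic competitive inhibition and the static screen.

The dynamic model co-simulates both whole-body models and, at every solver step,
replaces the victim's enzyme-mediated intrinsic clearance with the apparent value
CL_int/(1 + [I]/Ki), where [I] is the perpetrator's current free concentration at the
configured site (liver intracellular unbound by default, i.e. the site of metabolism;
venous plasma unbound selectable). The static screen computes 1 + [I]/Ki from the
perpetrator's unbound plasma Cmax converted to molarity.

A :class:`Scenario` bundles everything needed to simulate (compounds, species, doses,
duration) and supports dotted-path parameter access, which the sensitivity scan and the
Monte-Carlo population machinery build on.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import yaml

from .compound import Compound, load_compound
from .engine import (
    DoseEvent,
    PBPKModel,
    SimulationResult,
    SolverOptions,
    build_model,
    simulate,
    simulate_coupled,
)
from .nca import ConcProfile, PKParameters, nca_single
from .physiology import PhysiologyModel, load_physiology

__all__ = [
    "Scenario",
    "DDIResult",
    "apparent_clint",
    "static_index",
    "simulate_ddi",
    "get_param",
    "set_param",
    "DDIError",
]


class DDIError(ValueError):
    """Invalid interaction configuration."""


def apparent_clint(clint: float, inhibitor_um: float, ki_um: float) -> float:
    """Competitive-inhibition apparent intrinsic clearance CL_int / (1 + [I]/Ki)."""
    if clint < 0 or inhibitor_um < 0:
        raise DDIError("CL_int and inhibitor concentration must be >= 0")
    if ki_um <= 0:
        raise DDIError("Ki must be > 0")
    return clint / (1.0 + inhibitor_um / ki_um)


def static_index(cmax_ng_ml: float, fu: float, mw_g_mol: float, ki_um: float) -> float:
    """Static DDI screen 1 + [I]/Ki with [I] = unbound plasma Cmax in uM
    (ng/mL x fu / MW)."""
    if min(cmax_ng_ml, fu, mw_g_mol, ki_um) <= 0:
        raise DDIError("all static-index inputs must be > 0")
    i_um = cmax_ng_ml * fu / mw_g_mol
    return 1.0 + i_um / ki_um


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class Scenario:
    """A single-drug or two-drug simulation setting.

    For single-drug use leave ``perpetrator`` as None. Doses default to the study
    design (victim oral at t=0).
    """

    victim: Compound
    victim_doses: list[DoseEvent]
    species: str
    body_weight_kg: float
    duration_h: float
    perpetrator: Compound | None = None
    perpetrator_doses: list[DoseEvent] = field(default_factory=list)
    inhibitor_source: str = "liver_intracellular_unbound"
    physiology_overrides: dict = field(default_factory=dict)
    kp_overrides_victim: dict[str, float] = field(default_factory=dict)
    kp_overrides_perpetrator: dict[str, float] = field(default_factory=dict)
    solver: SolverOptions = field(default_factory=SolverOptions)

    def physiology(self) -> PhysiologyModel:
        return load_physiology(self.species, self.body_weight_kg, self.physiology_overrides)

    def build_victim(self, phys: PhysiologyModel | None = None) -> PBPKModel:
        from .compound import partition_coefficients

        phys = phys or self.physiology()
        kps = partition_coefficients(self.victim, phys, self.kp_overrides_victim or None)
        return build_model(self.victim, phys, kps)

    def build_perpetrator(self, phys: PhysiologyModel | None = None) -> PBPKModel:
        from .compound import partition_coefficients

        if self.perpetrator is None:
            raise DDIError("scenario has no perpetrator")
        phys = phys or self.physiology()
        kps = partition_coefficients(self.perpetrator, phys, self.kp_overrides_perpetrator or None)
        return build_model(self.perpetrator, phys, kps)

    def inhibited_pairs(self) -> list[tuple[str, float]]:
        """(enzyme, Ki) pairs: perpetrator inhibitions matching a victim
        enzyme-mediated clearance in this species."""
        if self.perpetrator is None:
            return []
        victim_enzymes = {
            c.enzyme for c in self.victim.clearances(self.species) if c.kind == "enzyme_mediated"
        }
        pairs = []
        for spec in self.perpetrator.inhibitions(self.species):
            if spec.enzyme in victim_enzymes:
                pairs.append((spec.enzyme, spec.ki_um))
        return pairs

    def simulate_victim_alone(self) -> SimulationResult:
        phys = self.physiology()
        return simulate(self.build_victim(phys), self.victim_doses, self.duration_h, self.solver)

    def simulate_co(self) -> SimulationResult:
        if self.perpetrator is None:
            raise DDIError("scenario has no perpetrator")
        pairs = self.inhibited_pairs()
        phys = self.physiology()
        return simulate_coupled(
            self.build_victim(phys),
            self.victim_doses,
            self.build_perpetrator(phys),
            self.perpetrator_doses,
            self.duration_h,
            pairs,
            source=self.inhibitor_source,
            options=self.solver,
        )

    def victim_profile(self, result: SimulationResult, role: str = "predicted") -> ConcProfile:
        t, c = result.profile(self.victim.name)
        dose = self.victim_doses[0]
        return ConcProfile(
            subject=f"{self.victim.name}-{self.species}",
            time_h=t[t > 0],
            conc_ng_ml=c[t > 0],
            dose=dose.amount,
            dose_per_kg=dose.per_kg,
            role=role,
        )


@dataclass
class DDIResult:
    alone: PKParameters
    combo: PKParameters
    auc_ratio: float
    cmax_ratio: float
    alone_result: SimulationResult | None = None
    combo_result: SimulationResult | None = None

    def as_dict(self) -> dict:
        return {
            "victim_alone": self.alone.as_dict(),
            "victim_coadministered": self.combo.as_dict(),
            "ddi_auc_ratio": self.auc_ratio,
            "ddi_cmax_ratio": self.cmax_ratio,
        }


def simulate_ddi(scenario: Scenario, keep_results: bool = False) -> DDIResult:
    """Victim exposure with and without the perpetrator, and the exposure ratios
    (co-administered / alone) for AUC_inf and Cmax."""
    if scenario.perpetrator is not None and not scenario.inhibited_pairs():
        raise DDIError(
            "no perpetrator inhibition matches a victim enzyme-mediated clearance "
            f"in species {scenario.species!r}"
        )
    res_alone = scenario.simulate_victim_alone()
    res_combo = scenario.simulate_co()
    pk_alone = nca_single(scenario.victim_profile(res_alone))
    pk_combo = nca_single(scenario.victim_profile(res_combo))
    return DDIResult(
        alone=pk_alone,
        combo=pk_combo,
        auc_ratio=pk_combo.auc_inf_ng_h_ml / pk_alone.auc_inf_ng_h_ml,
        cmax_ratio=pk_combo.cmax_ng_ml / pk_alone.cmax_ng_ml,
        alone_result=res_alone if keep_results else None,
        combo_result=res_combo if keep_results else None,
    )


# ---------------------------------------------------------------------------
# dotted-path parameter access (used by sensitivity and Monte-Carlo population draws)
#
# Grammar:
#   victim.<field> | perpetrator.<field>     compound scalar fields, plus:
#       fraction_unbound                     (resolved for the scenario's species)
#       clearance.<enzyme>.clint_ul_min_pmol
#       clearance.renal.clearance_ml_min_kg
#       clearance.hepatic.hepatic_t_half_min
#       inhibition.<enzyme>.ki_um
#       formulations.<name>.<field>
#   victim_dose.amount | perpetrator_dose.amount
#   physiology.<dotted-key>                  forwarded to load_physiology overrides


def _compound_node(cmp_dict: dict, parts: list[str], species: str):
    if parts[0] == "fraction_unbound" and len(parts) == 1:
        return cmp_dict["fraction_unbound"], species
    # list-valued heads: <head>.<name>.<field>; the name may itself contain dots
    # (e.g. formulations.tablet_2.5mg.dissolution_time_min)
    if parts[0] in ("clearance", "inhibition", "formulations") and len(parts) >= 3:
        name, fld = ".".join(parts[1:-1]), parts[-1]
        if parts[0] == "clearance":
            kind_map = {"renal": "renal", "hepatic": "total_hepatic_halflife"}
            for proc in cmp_dict["clearance"]:
                if proc["species"] != species:
                    continue
                if proc["kind"] == "enzyme_mediated" and proc.get("enzyme") == name:
                    return proc, fld
                if proc["kind"] == kind_map.get(name):
                    return proc, fld
            raise DDIError(f"no clearance process matching {'.'.join(parts)!r} for {species}")
        if parts[0] == "inhibition":
            for spec in cmp_dict["inhibition"]:
                if spec["species"] == species and spec["enzyme"] == name:
                    return spec, fld
            raise DDIError(f"no inhibition spec matching {'.'.join(parts)!r} for {species}")
        for form in cmp_dict["formulations"]:
            if form["name"] == name:
                return form, fld
        raise DDIError(f"no formulation named {name!r}")
    if len(parts) == 1 and parts[0] in cmp_dict:
        return cmp_dict, parts[0]
    raise DDIError(f"cannot resolve compound parameter path {'.'.join(parts)!r}")


def get_param(scenario: Scenario, path: str) -> float:
    """Read a scalar model parameter by dotted path."""
    head, _, rest = path.partition(".")
    if head in ("victim", "perpetrator"):
        cmp = getattr(scenario, head)
        if cmp is None:
            raise DDIError(f"scenario has no {head}")
        node, key = _compound_node(cmp.to_dict(), rest.split("."), scenario.species)
        return float(node[key])
    if head in ("victim_dose", "perpetrator_dose"):
        doses = scenario.victim_doses if head == "victim_dose" else scenario.perpetrator_doses
        if not doses:
            raise DDIError(f"scenario has no {head}")
        return float(getattr(doses[0], rest))
    if head == "physiology":
        raise DDIError(
            "physiology paths are write-only overrides; read them from load_physiology()"
        )
    raise DDIError(f"cannot resolve parameter path {path!r}")


def set_param(scenario: Scenario, path: str, value: float) -> Scenario:
    """Return a deep-copied scenario with one scalar parameter replaced."""
    sc = copy.deepcopy(scenario)
    head, _, rest = path.partition(".")
    if head in ("victim", "perpetrator"):
        cmp = getattr(sc, head)
        if cmp is None:
            raise DDIError(f"scenario has no {head}")
        d = cmp.to_dict()
        node, key = _compound_node(d, rest.split("."), sc.species)
        node[key] = value
        setattr(sc, head, Compound.from_dict(d))
        return sc
    if head in ("victim_dose", "perpetrator_dose"):
        attr = "victim_doses" if head == "victim_dose" else "perpetrator_doses"
        doses = getattr(sc, attr)
        if not doses:
            raise DDIError(f"scenario has no {head}")
        setattr(sc, attr, [replace(doses[0], **{rest: value})] + doses[1:])
        return sc
    if head == "physiology":
        sc.physiology_overrides = dict(sc.physiology_overrides)
        sc.physiology_overrides[rest] = value
        return sc
    raise DDIError(f"cannot resolve parameter path {path!r}")


# ---------------------------------------------------------------------------
# scenario YAML


def scenario_from_yaml(text: str) -> Scenario:
    """Build a scenario from YAML (see the bundled examples in the documentation)."""
    cfg = yaml.safe_load(text)

    def _doses(items):
        return [
            DoseEvent(
                route=d.get("route", "oral"),
                amount=d["amount"],
                per_kg=d.get("per_kg", False),
                time_h=d.get("time_h", 0.0),
                formulation=d.get("formulation", "solution"),
            )
            for d in items
        ]

    victim = load_compound(cfg["victim"]["compound"])
    perp = load_compound(cfg["perpetrator"]["compound"]) if "perpetrator" in cfg else None
    solver = SolverOptions(**cfg.get("solver", {}))
    return Scenario(
        victim=victim,
        victim_doses=_doses(cfg["victim"]["doses"]),
        species=cfg["species"],
        body_weight_kg=cfg["body_weight_kg"],
        duration_h=cfg["duration_h"],
        perpetrator=perp,
        perpetrator_doses=_doses(cfg["perpetrator"]["doses"]) if perp else [],
        inhibitor_source=cfg.get("inhibitor_source", "liver_intracellular_unbound"),
        physiology_overrides=cfg.get("physiology_overrides", {}),
        solver=solver,
    )
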