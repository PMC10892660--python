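"""Drug-specific parameters and the derived distribution inputs.

A :class:`Compound` mirrors the model parameter tables field-for-field (one value per
species where they differ) and provides the two derived quantities the simulation engine
needs: tissue-plasma partition coefficients and the dissolved fraction of an oral
formulation over time.

Partitioning method ("composition-v1", recorded in output metadata): the intracellular
unbound partition coefficient of each organ is built from its bulk composition,

    Kpu_cell = trap * f_water + K_lip * f_lipid + RA * f_protein / f_protein_plasma

where ``K_lip = 10^(1.115*logD7.4 - 1.35)`` is the vegetable-oil-scaled lipid partition
coefficient, ``RA = 0.5*(1/fu - 1)`` assumes tissue protein binds in proportion to plasma
protein binding, and ``trap`` is the pH-partitioning factor for the ionizable fraction
between plasma pH 7.4 and intracellular pH 7.0 (Henderson-Hasselbalch, single pKa).
The whole-tissue coefficient reported to users is
``Kp = f_vascular + f_interstitial + fu * f_intracellular * Kpu_cell`` so that a
water-only tissue with fu = 1 and logD = 0 has Kp = 1. Per-organ overrides may replace
Kp directly (the engine back-solves Kpu_cell from them).
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from dataclasses import dataclass, field, asdict

import yaml

from .physiology import PhysiologyModel

__all__ = [
    "Compound",
    "FormulationSpec",
    "ClearanceProcess",
    "InhibitionSpec",
    "load_compound",
    "partition_coefficients",
    "dissolved_fraction",
    "PartitionResult",
    "CompoundError",
]

PH_PLASMA = 7.4
PH_CELL = 7.0
PH_BLOOD_CELL = 7.2
F_PROTEIN_PLASMA = 0.074  # plasma protein volume fraction used to normalize tissue protein

# blood-cell composition used for the blood-cell:plasma-unbound partition
BC_F_WATER = 0.63
BC_F_LIPID = 0.003


class CompoundError(ValueError):
    """Invalid compound parameter or formulation."""


@dataclass
class FormulationSpec:
    """Oral formulation; tablets dissolve along a Weibull CDF anchored at 50%
    dissolved at ``dissolution_time_min`` (convention recorded here)."""

    name: str
    kind: str  # 'solution' | 'tablet'
    dissolution_shape: float | None = None
    dissolution_time_min: float | None = None
    anchor_fraction: float = 0.5

    def __post_init__(self):
        if self.kind not in ("solution", "tablet"):
            raise CompoundError(f"formulation kind must be solution or tablet, got {self.kind!r}")
        if self.kind == "tablet":
            if not self.dissolution_shape or self.dissolution_shape <= 0:
                raise CompoundError("tablet dissolution_shape must be > 0")
            if not self.dissolution_time_min or self.dissolution_time_min <= 0:
                raise CompoundError("tablet dissolution_time_min must be > 0")
            if not (0 < self.anchor_fraction < 1):
                raise CompoundError("anchor_fraction must be in (0, 1)")


@dataclass
class ClearanceProcess:
    kind: str  # 'enzyme_mediated' | 'renal' | 'total_hepatic_halflife'
    species: str
    enzyme: str | None = None
    clint_ul_min_pmol: float | None = None
    clearance_ml_min_kg: float | None = None
    hepatic_t_half_min: float | None = None

    def __post_init__(self):
        required = {
            "enzyme_mediated": ("enzyme", "clint_ul_min_pmol"),
            "renal": ("clearance_ml_min_kg",),
            "total_hepatic_halflife": ("hepatic_t_half_min",),
        }
        if self.kind not in required:
            raise CompoundError(f"unknown clearance kind {self.kind!r}")
        for f_ in required[self.kind]:
            v = getattr(self, f_)
            if v is None or (isinstance(v, (int, float)) and v <= 0 and f_ != "enzyme"):
                raise CompoundError(f"clearance {self.kind}: field {f_} must be positive")


@dataclass
class InhibitionSpec:
    enzyme: str
    species: str
    ki_um: float
    mechanism: str = "competitive"

    def __post_init__(self):
        if self.ki_um <= 0:
            raise CompoundError("K_i must be > 0")
        if self.mechanism != "competitive":
            raise CompoundError("only competitive inhibition is supported")


@dataclass
class Compound:
    name: str
    molecular_weight_g_mol: float
    lipophilicity_logd74: float
    pka: float
    pka_type: str  # 'acid' | 'base' | 'neutral'
    solubility_mg_ml: float
    solubility_ref_ph: float
    fraction_unbound: dict[str, float]
    specific_intestinal_permeability_cm_s: float
    cellular_permeability: float
    cellular_permeability_unit: str = "1e-6 cm/s"
    clearance: list[ClearanceProcess] = field(default_factory=list)
    formulations: list[FormulationSpec] = field(default_factory=list)
    inhibition: list[InhibitionSpec] = field(default_factory=list)

    def __post_init__(self):
        if self.molecular_weight_g_mol <= 0:
            raise CompoundError("molecular weight must be > 0")
        if self.solubility_mg_ml <= 0:
            raise CompoundError("solubility must be > 0")
        if self.specific_intestinal_permeability_cm_s <= 0:
            raise CompoundError("intestinal permeability must be > 0")
        if self.cellular_permeability <= 0:
            raise CompoundError("cellular permeability must be > 0")
        if self.pka_type not in ("acid", "base", "neutral"):
            raise CompoundError(f"pka_type must be acid/base/neutral, got {self.pka_type!r}")
        for sp, fu in self.fraction_unbound.items():
            if not (0 < fu <= 1):
                raise CompoundError(f"fraction unbound for {sp} must be in (0, 1]")

    # -- species-resolved views -----------------------------------------
    def fu(self, species: str) -> float:
        try:
            return self.fraction_unbound[species]
        except KeyError:
            raise CompoundError(f"{self.name}: no fraction unbound for species {species!r}")

    @property
    def cellular_permeability_cm_s(self) -> float:
        unit = self.cellular_permeability_unit.replace(" ", "")
        if unit in ("1e-6cm/s", "1e-6_cm_s", "1e-6cms", "um/s·1e0"):
            return self.cellular_permeability * 1e-6
        if unit in ("cm/s", "cm_s", "cms"):
            return self.cellular_permeability
        raise CompoundError(f"unknown cellular permeability unit {self.cellular_permeability_unit!r}")

    def clearances(self, species: str) -> list[ClearanceProcess]:
        return [c for c in self.clearance if c.species == species]

    def inhibitions(self, species: str) -> list[InhibitionSpec]:
        return [i for i in self.inhibition if i.species == species]

    def formulation(self, name: str) -> FormulationSpec:
        for f_ in self.formulations:
            if f_.name == name:
                return f_
        raise CompoundError(f"{self.name}: no formulation named {name!r}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Compound":
        d = copy.deepcopy(d)
        d["clearance"] = [ClearanceProcess(**c) for c in d.get("clearance", [])]
        d["formulations"] = [FormulationSpec(**f_) for f_ in d.get("formulations", [])]
        d["inhibition"] = [InhibitionSpec(**i) for i in d.get("inhibition", [])]
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "Compound":
        return cls.from_dict(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def load_compound(name_or_path: str) -> Compound:
    """Load a compound definition: a bundled name ('saxagliptin', 'nicardipine')
    or a path to a YAML file in the same schema."""
    bundled = importlib.resources.files("pbpkddi") / "data" / "compounds" / f"{name_or_path}.yaml"
    try:
        text = bundled.read_text()
    except (FileNotFoundError, OSError):
        with open(name_or_path) as fh:
            text = fh.read()
    return Compound.from_yaml(text)


# ---------------------------------------------------------------------------
# ionization and partitioning


def neutral_fraction(pka: float, pka_type: str, ph: float) -> float:
    """Henderson-Hasselbalch neutral fraction at the given pH (single pKa)."""
    if pka_type == "neutral":
        return 1.0
    if pka_type == "base":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def ph_trap_factor(pka: float, pka_type: str, ph_from: float, ph_to: float) -> float:
    """Equilibrium total-concentration ratio across a membrane permeable only to the
    neutral species (pH partitioning)."""
    return neutral_fraction(pka, pka_type, ph_from) / neutral_fraction(pka, pka_type, ph_to)


def lipid_partition(logd74: float) -> float:
    """Neutral-lipid partition coefficient on the vegetable-oil scale."""
    return 10.0 ** (1.115 * logd74 - 1.35)


@dataclass
class PartitionResult:
    """Per-organ partition coefficients with the intermediate quantities the engine uses."""

    kp: dict[str, float]  # whole tissue : total plasma
    kpu_cell: dict[str, float]  # intracellular : unbound plasma
    kpu_blood_cell: float
    method: str
    fu: float


def partition_coefficients(
    cmp: Compound,
    phys: PhysiologyModel,
    overrides: dict[str, float] | None = None,
) -> PartitionResult:
    """Tissue-plasma partition coefficients for every organ of ``phys``.

    ``overrides`` maps organ name -> whole-tissue Kp injected verbatim (the matching
    intracellular coefficient is back-solved so the engine honors the override).
    """
    fu = cmp.fu(phys.species)
    klip = lipid_partition(cmp.lipophilicity_logd74)
    trap = ph_trap_factor(cmp.pka, cmp.pka_type, PH_PLASMA, PH_CELL)
    ra = 0.5 * (1.0 / fu - 1.0)

    kp: dict[str, float] = {}
    kpu: dict[str, float] = {}
    for o in phys.organs:
        kpu_cell = (
            trap * o.f_water
            + klip * o.f_lipid
            + ra * o.f_protein / F_PROTEIN_PLASMA
        )
        if kpu_cell <= 0:
            raise CompoundError(f"non-positive partition coefficient for organ {o.name}")
        kp_total = o.f_vascular + o.f_interstitial + fu * o.f_intracellular * kpu_cell
        kpu[o.name] = kpu_cell
        kp[o.name] = kp_total

    if overrides:
        for organ, kp_val in overrides.items():
            o = phys.organ(organ)
            if kp_val <= 0:
                raise CompoundError(f"Kp override for {organ} must be > 0")
            kp[organ] = kp_val
            kpu[organ] = max(
                (kp_val - o.f_vascular - o.f_interstitial) / (fu * o.f_intracellular), 1e-6
            )

    trap_bc = ph_trap_factor(cmp.pka, cmp.pka_type, PH_PLASMA, PH_BLOOD_CELL)
    kpu_bc = trap_bc * BC_F_WATER + klip * BC_F_LIPID
    return PartitionResult(kp=kp, kpu_cell=kpu, kpu_blood_cell=kpu_bc, method="composition-v1", fu=fu)


# ---------------------------------------------------------------------------
# dissolution


def dissolved_fraction(form: FormulationSpec, t_min: float) -> float:
    """Fraction of the dose dissolved at ``t_min`` minutes after administration.

    Tablets follow the Weibull CDF ``F(t) = 1 - exp(ln(1/(1-a)) * -(t/T)^s)`` anchored so
    that ``F(T) = a`` (default a = 0.5); solutions are dissolved instantly.
    """
    if t_min < 0:
        raise CompoundError("time must be >= 0")
    if form.kind == "solution":
        return 1.0
    if t_min == 0:
        return 0.0
    rate = -math.log(1.0 - form.anchor_fraction)  # ln 2 for the 50% anchor
    return 1.0 - math.exp(-rate * (t_min / form.dissolution_time_min) ** form.dissolution_shape)


def dissolution_hazard(form: FormulationSpec, t_min: float, cap_per_min: float = 100.0) -> float:
    """Instantaneous dissolution rate constant (1/min) at time ``t_min`` since dosing,
    i.e. the hazard of the Weibull CDF; capped for solver robustness with shape < 1."""
    if form.kind == "solution":
        return cap_per_min
    if t_min <= 0:
        return 0.0 if form.dissolution_shape > 1 else cap_per_min
    rate = -math.log(1.0 - form.anchor_fraction)
    s, tt = form.dissolution_shape, t_min / form.dissolution_time_min
    h = rate * s / form.dissolution_time_min * tt ** (s - 1.0)
    return min(h, cap_per_min)
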