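"""Species anatomy and physiology for whole-body PBPK models.

Assembles organ volumes, blood flows, sub-compartment fractions, tissue composition and
enzyme abundances for rat and human from bundled reference tables, scaled to body weight
and modifiable through flat dotted-key overrides.

Conventions
-----------
* volumes in mL, flows in mL/min, masses in g (tissue density 1 g/mL), time in min;
* organ volumes scale linearly with body weight, blood flows allometrically
  (cardiac output = coef * BW^exp);
* the liver's ``blood_flow`` is the hepatic artery only; portal inflow is the sum of the
  gut-wall and spleen outflows;
* the ``rest_of_body`` organ closes volume and flow balance exactly, so venous return
  equals cardiac output by construction.
"""

from __future__ import annotations

import copy
import importlib.resources
import io
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

__all__ = [
    "OrganSpec",
    "GISpec",
    "PhysiologyModel",
    "load_physiology",
    "organ_enzyme_abundance",
    "PhysiologyError",
]

SPECIES = ("rat", "human")

PORTAL_ORGANS = ("gut_wall", "spleen")


class PhysiologyError(ValueError):
    """Invalid species, parameter override, or physiological value."""


@dataclass
class OrganSpec:
    """A perfused organ with four sub-compartments (plasma, blood cells, interstitial,
    intracellular) and the composition data needed for partitioning."""

    name: str
    total_volume_ml: float
    blood_flow_ml_min: float
    f_vascular: float
    f_interstitial: float
    f_intracellular: float
    f_water: float
    f_lipid: float
    f_protein: float
    sa_endothelial_cm2_per_ml: float
    sa_cell_cm2_per_ml: float
    drains_to: str  # 'venous' | 'portal' | 'arterial'
    enzyme_relative_expression: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.total_volume_ml <= 0:
            raise PhysiologyError(f"organ {self.name}: total_volume_ml must be > 0")
        if self.blood_flow_ml_min <= 0:
            raise PhysiologyError(f"organ {self.name}: blood_flow_ml_min must be > 0")
        fsum = self.f_vascular + self.f_interstitial + self.f_intracellular
        if not (0 < fsum <= 1.0 + 1e-9):
            raise PhysiologyError(
                f"organ {self.name}: sub-compartment fractions sum to {fsum:.3f}, not in (0, 1]"
            )
        for enz, expr in self.enzyme_relative_expression.items():
            if expr < 0:
                raise PhysiologyError(f"organ {self.name}: expression of {enz} is negative")

    @property
    def mass_g(self) -> float:
        return self.total_volume_ml  # density 1 g/mL


@dataclass
class GISpec:
    """Gut-lumen geometry and transit: stomach plus a chain of small-intestine segments."""

    stomach_volume_ml: float
    gastric_emptying_thalf_min: float
    si_volumes_ml: list[float]
    si_segment_mrt_min: list[float]
    si_surface_areas_cm2: list[float]

    @property
    def n_segments(self) -> int:
        return len(self.si_volumes_ml)


@dataclass
class PhysiologyModel:
    species: str
    body_weight_kg: float
    organs: list[OrganSpec]
    hematocrit: float
    mppgl_mg_per_g: float
    enzyme_reference_concentration_pmol_per_mg: dict[str, float]
    gfr_ml_min_kg: float
    cardiac_output_ml_min: float
    arterial_volume_ml: float
    venous_volume_ml: float
    gi: GISpec
    provenance: dict[str, str] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise PhysiologyError(f"unknown organ: {name!r}")

    @property
    def organ_names(self) -> list[str]:
        return [o.name for o in self.organs]

    @property
    def plasma_volume_ml(self) -> float:
        """Total plasma: arterial + venous pools + organ vascular plasma."""
        vasc = sum(o.total_volume_ml * o.f_vascular for o in self.organs)
        return (self.arterial_volume_ml + self.venous_volume_ml + vasc) * (1.0 - self.hematocrit)

    def venous_return_ml_min(self) -> float:
        """Flow collected into the venous pool: direct drainers plus liver outflow."""
        direct = sum(
            o.blood_flow_ml_min
            for o in self.organs
            if o.drains_to == "venous" and o.name != "liver"
        )
        if "liver" in self.organ_names:
            liver_out = self.organ("liver").blood_flow_ml_min + sum(
                self.organ(n).blood_flow_ml_min for n in PORTAL_ORGANS if n in self.organ_names
            )
            direct += liver_out
        return direct

    def check_flow_balance(self, rtol: float = 1e-9) -> None:
        ret = self.venous_return_ml_min()
        if abs(ret - self.cardiac_output_ml_min) > rtol * self.cardiac_output_ml_min:
            raise PhysiologyError(
                f"flow imbalance: venous return {ret:.6f} vs cardiac output "
                f"{self.cardiac_output_ml_min:.6f} mL/min"
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysiologyModel":
        d = copy.deepcopy(d)
        d["organs"] = [OrganSpec(**o) for o in d["organs"]]
        d["gi"] = GISpec(**d["gi"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhysiologyModel":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# loading


def _read_package_text(name: str) -> str:
    return (importlib.resources.files("pbpkddi") / "data" / name).read_text()


def _parse_enzymes(cell) -> dict[str, float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return {}
    out = {}
    for item in str(cell).split(";"):
        enz, expr = item.split(":")
        out[enz.strip()] = float(expr)
    return out


def _load_tables(species: str) -> tuple[pd.DataFrame, dict]:
    if species not in SPECIES:
        raise PhysiologyError(f"unknown species: {species!r} (expected one of {SPECIES})")
    organs = pd.read_csv(io.StringIO(_read_package_text(f"physiology_{species}.csv")), comment="#")
    scalars = yaml.safe_load(_read_package_text(f"species_{species}.yaml"))
    return organs, scalars


def _apply_override(model_dict: dict, key: str, value, provenance: dict) -> None:
    """Apply a flat dotted-key override onto the nested model dict, verbatim."""
    parts = key.split(".")
    node = model_dict
    for i, part in enumerate(parts[:-1]):
        if isinstance(node, list):
            matches = [o for o in node if isinstance(o, dict) and o.get("name") == part]
            if not matches:
                raise PhysiologyError(f"override {key!r}: no element named {part!r}")
            node = matches[0]
        elif isinstance(node, dict):
            if part not in node:
                raise PhysiologyError(f"override {key!r}: unknown parameter group {part!r}")
            node = node[part]
        else:
            raise PhysiologyError(f"override {key!r}: cannot descend into {part!r}")
    leaf = parts[-1]
    if isinstance(node, list):
        raise PhysiologyError(f"override {key!r}: ends on a list, name an element")
    if leaf not in node:
        raise PhysiologyError(f"override {key!r}: unknown parameter {leaf!r}")
    if isinstance(value, (int, float)) and not isinstance(value, bool) and value < 0:
        raise PhysiologyError(f"override {key!r}: negative value {value}")
    node[leaf] = value
    provenance[key] = "override"


def load_physiology(
    species: str, body_weight_kg: float, overrides: dict | None = None
) -> PhysiologyModel:
    """Build a flow-balanced :class:`PhysiologyModel` scaled to ``body_weight_kg``.

    Organ volumes scale linearly with body weight; blood flows follow the allometric
    cardiac-output rule. ``overrides`` is a flat map of dotted keys
    (e.g. ``{"mppgl_mg_per_g": 44.8, "organs.liver.total_volume_ml": 11.0}``) applied
    verbatim after scaling; every value's provenance (default vs override) is recorded.
    """
    if body_weight_kg <= 0:
        raise PhysiologyError("body_weight_kg must be > 0")
    table, scalars = _load_tables(species)

    co = scalars["co_allometric_coef"] * body_weight_kg ** scalars["co_allometric_exp"]
    bw_g = body_weight_kg * 1000.0

    rows = table.to_dict("records")
    named = {r["organ"]: r for r in rows}
    # rest_of_body closes volume and flow balance exactly
    others_v = sum(r["volume_fraction_bw"] for r in rows if r["organ"] != "rest_of_body")
    others_v += scalars["arterial_blood_fraction_bw"] + scalars["venous_blood_fraction_bw"]
    others_q = sum(
        r["flow_fraction_co"] for r in rows if r["organ"] not in ("rest_of_body", "lung")
    )
    named["rest_of_body"]["volume_fraction_bw"] = 1.0 - others_v
    named["rest_of_body"]["flow_fraction_co"] = 1.0 - others_q

    organs = []
    for r in rows:
        flow_frac = r["flow_fraction_co"]
        organs.append(
            OrganSpec(
                name=r["organ"],
                total_volume_ml=r["volume_fraction_bw"] * bw_g,
                blood_flow_ml_min=flow_frac * co,
                f_vascular=r["f_vascular"],
                f_interstitial=r["f_interstitial"],
                f_intracellular=r["f_intracellular"],
                f_water=r["f_water"],
                f_lipid=r["f_lipid"],
                f_protein=r["f_protein"],
                sa_endothelial_cm2_per_ml=r["sa_endothelial_cm2_per_ml"],
                sa_cell_cm2_per_ml=r["sa_cell_cm2_per_ml"],
                drains_to=r["drains_to"],
                enzyme_relative_expression=_parse_enzymes(r.get("enzymes")),
            )
        )

    model = PhysiologyModel(
        species=species,
        body_weight_kg=body_weight_kg,
        organs=organs,
        hematocrit=scalars["hematocrit"],
        mppgl_mg_per_g=scalars["mppgl_mg_per_g"],
        enzyme_reference_concentration_pmol_per_mg=dict(
            scalars["enzyme_reference_concentration_pmol_per_mg"]
        ),
        gfr_ml_min_kg=scalars["gfr_ml_min_kg"],
        cardiac_output_ml_min=co,
        arterial_volume_ml=scalars["arterial_blood_fraction_bw"] * bw_g,
        venous_volume_ml=scalars["venous_blood_fraction_bw"] * bw_g,
        gi=GISpec(
            stomach_volume_ml=scalars["gi"]["stomach_volume_ml"],
            gastric_emptying_thalf_min=scalars["gi"]["gastric_emptying_thalf_min"],
            si_volumes_ml=list(scalars["gi"]["si_volumes_ml"]),
            si_segment_mrt_min=list(scalars["gi"]["si_segment_mrt_min"]),
            si_surface_areas_cm2=list(scalars["gi"]["si_surface_areas_cm2"]),
        ),
        provenance={"*": f"bundled {species} reference tables v1"},
    )

    if overrides:
        d = model.to_dict()
        prov = d["provenance"]
        for key, value in overrides.items():
            _apply_override(d, key, value, prov)
        model = PhysiologyModel.from_dict(d)

    for o in model.organs:
        o.validate()
    if model.mppgl_mg_per_g <= 0:
        raise PhysiologyError("mppgl_mg_per_g must be > 0")
    if not (0 < model.hematocrit < 1):
        raise PhysiologyError("hematocrit must be in (0, 1)")
    model.check_flow_balance()
    return model


def organ_enzyme_abundance(phys: PhysiologyModel, enzyme: str, organ: str) -> float:
    """Total enzyme amount in an organ, pmol.

    abundance = reference concentration (pmol/mg microsomal protein)
              x relative expression (organ vs liver)
              x microsomal protein density (mg/g)
              x organ mass (g).
    """
    ref = phys.enzyme_reference_concentration_pmol_per_mg.get(enzyme)
    if ref is None:
        raise PhysiologyError(f"unknown enzyme: {enzyme!r}")
    org = phys.organ(organ)
    expr = org.enzyme_relative_expression.get(enzyme, 0.0)
    return ref * expr * phys.mppgl_mg_per_g * org.mass_g
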