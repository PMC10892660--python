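"""Whole-body permeability-limited PBPK simulation engine.

Every perfused organ carries four sub-compartments (vascular plasma, blood cells,
interstitial, intracellular). Blood flow convects drug from the arterial pool through
organ vascular plasma to the venous pool; the lung sits in series between the venous and
arterial pools; the liver receives the hepatic artery plus the portal outflow of gut
wall and spleen. Passive exchange across the endothelial (plasma <-> interstitial) and
cell-membrane (interstitial <-> intracellular) barriers is driven by unbound
concentration gradients: each sub-compartment ``x`` stores amount ``A_x`` and exposes
``u_x = A_x / (V_x * k_x)`` where ``k_x`` is its equilibrium total:unbound ratio
(``1/fu`` for plasma and interstitial, the blood-cell partition for blood cells, the
organ's intracellular coefficient for cells), so at equilibrium without elimination the
unbound concentration is uniform.

Oral dosing enters a gut-lumen transit chain (stomach + three small-intestine segments);
tablets dissolve along the formulation's Weibull hazard; dissolved drug is absorbed into
the gut-wall interstitial space with flux = specific intestinal permeability x segment
surface area x dissolved lumen concentration; material leaving the last segment is
counted as fecal loss.

Elimination processes: enzyme-mediated metabolism (CL_int x organ enzyme abundance x
unbound intracellular concentration, with optional competitive inhibition), hepatic
plasma-referenced half-life clearance applied at the liver intracellular space, and
renal plasma clearance applied at the kidney vascular plasma.

Internal units: amounts nmol, volumes mL, time min, flows mL/min, concentrations
nmol/mL (= uM). Reported plasma concentrations are venous plasma in ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .compound import (
    PH_CELL,
    PH_PLASMA,
    Compound,
    FormulationSpec,
    PartitionResult,
    dissolution_hazard,
    partition_coefficients,
    ph_trap_factor,
)
from .physiology import PORTAL_ORGANS, PhysiologyModel, organ_enzyme_abundance

__all__ = [
    "DoseEvent",
    "PBPKModel",
    "SimulationResult",
    "CompoundTrajectory",
    "build_model",
    "metabolism_flux",
    "simulate",
    "simulate_coupled",
    "EngineError",
    "SolverOptions",
]

ENDOTHELIAL_PERMEABILITY_CM_S = 1e-4  # default small-molecule transcapillary permeability
BLOOD_CELL_SA_CM2_PER_ML = 15000.0  # erythrocyte membrane area per mL packed cells

SUBCOMPARTMENTS = ("plasma", "blood_cells", "interstitial", "intracellular")


class EngineError(RuntimeError):
    """Model assembly or integration failure."""


@dataclass
class DoseEvent:
    """A single administration. ``amount`` is mg (or mg/kg when per_kg is True)."""

    route: str  # 'iv_bolus' | 'oral'
    amount: float
    per_kg: bool = False
    time_h: float = 0.0
    formulation: str = "solution"

    def __post_init__(self):
        if self.route not in ("iv_bolus", "oral"):
            raise EngineError(f"unknown route {self.route!r}")
        if self.amount < 0:
            raise EngineError("dose amount must be >= 0")
        if self.time_h < 0:
            raise EngineError("dose time must be >= 0")

    def amount_nmol(self, mw: float, body_weight_kg: float) -> float:
        mg = self.amount * (body_weight_kg if self.per_kg else 1.0)
        return mg * 1e6 / mw  # mg -> ng -> nmol


@dataclass
class SolverOptions:
    rtol: float = 1e-8
    atol: float = 1e-10
    output_dt_h: float = 0.01
    method: str = "BDF"


class PBPKModel:
    """Assembled ODE system for one compound in one physiology.

    State layout (amounts, nmol)::

        [0 : 4*n_organs)            organ blocks, per organ: plasma, blood cells,
                                    interstitial, intracellular
        [.. +4)                     arterial plasma, arterial cells, venous plasma,
                                    venous cells
        [.. +2*(1+n_segments))      gut lumen: (undissolved, dissolved) for stomach
                                    then each small-intestine segment
        [.. +4)                     cumulative bins: metabolized, hepatic, renal, fecal

    i.e. n_states = 4*n_organs + 4 blood-pool states + 2*(1+n_segments) lumen states
    + 4 elimination bins.
    """

    def __init__(self, compound: Compound, phys: PhysiologyModel, kps: PartitionResult | None = None):
        self.compound = compound
        self.phys = phys
        species = phys.species
        self.fu = compound.fu(species)
        self.kps = kps if kps is not None else partition_coefficients(compound, phys)

        names = phys.organ_names
        if "lung" not in names:
            raise EngineError("physiology must include a lung (pulmonary circulation)")
        self.organ_names = names
        n = self.n_organs = len(names)
        self.i_lung = names.index("lung")
        self.i_liver = names.index("liver") if "liver" in names else None
        self.i_kidney = names.index("kidney") if "kidney" in names else None
        self.i_gut = names.index("gut_wall") if "gut_wall" in names else None
        portal_idx = [names.index(o) for o in PORTAL_ORGANS if o in names]
        self.portal_idx = np.array(portal_idx, dtype=int)

        hct = phys.hematocrit
        V = np.array([o.total_volume_ml for o in phys.organs])
        self.V_pl = V * np.array([o.f_vascular for o in phys.organs]) * (1 - hct)
        self.V_bc = V * np.array([o.f_vascular for o in phys.organs]) * hct
        self.V_int = V * np.array([o.f_interstitial for o in phys.organs])
        self.V_cell = V * np.array([o.f_intracellular for o in phys.organs])
        Q = np.array([o.blood_flow_ml_min for o in phys.organs])
        self.Q_pl = Q * (1 - hct)
        self.Q_bc = Q * hct
        # total outflow per organ (liver carries hepatic artery + portal inflow)
        self.Q_out_pl = self.Q_pl.copy()
        self.Q_out_bc = self.Q_bc.copy()
        if self.i_liver is not None and len(portal_idx):
            self.Q_out_pl[self.i_liver] += self.Q_pl[self.portal_idx].sum()
            self.Q_out_bc[self.i_liver] += self.Q_bc[self.portal_idx].sum()
        self.venous_mask = np.array(
            [(o.drains_to == "venous") for o in phys.organs], dtype=bool
        )

        # pH partitioning: the state-variable "unbound" is the neutral-equivalent
        # concentration that equilibrates across membranes; the total unbound
        # concentration inside cells (neutral + ionized unbound, what the enzyme sees)
        # is trap_cell times larger for ionizable compounds
        self.trap_cell = ph_trap_factor(compound.pka, compound.pka_type, PH_PLASMA, PH_CELL)

        # partition normalization per sub-compartment (total : unbound)
        missing = [o.name for o in phys.organs if o.name not in self.kps.kpu_cell]
        if missing:
            raise EngineError(f"missing partition coefficients for organs: {missing}")
        self.k_cell = np.array([self.kps.kpu_cell[o.name] for o in phys.organs])
        self.k_bc = self.kps.kpu_blood_cell

        # permeability-surface-area products, mL/min
        p_cell = compound.cellular_permeability_cm_s
        sa_end = np.array([o.sa_endothelial_cm2_per_ml for o in phys.organs]) * V
        sa_cell = np.array([o.sa_cell_cm2_per_ml for o in phys.organs]) * V
        self.PS_end = ENDOTHELIAL_PERMEABILITY_CM_S * sa_end * 60.0
        self.PS_cell = p_cell * sa_cell * 60.0
        self.PS_bc = p_cell * BLOOD_CELL_SA_CM2_PER_ML * self.V_bc * 60.0
        self.V_art_pl = phys.arterial_volume_ml * (1 - hct)
        self.V_art_bc = phys.arterial_volume_ml * hct
        self.V_ven_pl = phys.venous_volume_ml * (1 - hct)
        self.V_ven_bc = phys.venous_volume_ml * hct
        self.PS_bc_art = p_cell * BLOOD_CELL_SA_CM2_PER_ML * self.V_art_bc * 60.0
        self.PS_bc_ven = p_cell * BLOOD_CELL_SA_CM2_PER_ML * self.V_ven_bc * 60.0

        # clearance processes
        self.met_cl: dict[str, np.ndarray] = {}  # enzyme -> per-organ mL/min (unbound cell)
        self.hep_cl_u = 0.0
        self.renal_cl = 0.0
        for proc in compound.clearances(species):
            if proc.kind == "enzyme_mediated":
                cl = np.zeros(n)
                for i, o in enumerate(phys.organs):
                    ab = organ_enzyme_abundance(phys, proc.enzyme, o.name)
                    cl[i] = proc.clint_ul_min_pmol * ab / 1000.0  # uL -> mL
                self.met_cl[proc.enzyme] = self.met_cl.get(proc.enzyme, 0) + cl
            elif proc.kind == "total_hepatic_halflife":
                if self.i_liver is None:
                    raise EngineError("hepatic clearance declared but physiology has no liver")
                # plasma-referenced half-life: at systemic equilibrium this eliminates
                # plasma with rate ln2/t_half * V_plasma (see docs/methods.md)
                self.hep_cl_u += (
                    math.log(2.0) / proc.hepatic_t_half_min * phys.plasma_volume_ml / self.fu
                )
            elif proc.kind == "renal":
                if self.i_kidney is None:
                    raise EngineError("renal clearance declared but physiology has no kidney")
                self.renal_cl += proc.clearance_ml_min_kg * phys.body_weight_kg

        # gut lumen
        gi = phys.gi
        self.n_seg = gi.n_segments
        self.k_ge = math.log(2.0) / gi.gastric_emptying_thalf_min
        self.k_si = 1.0 / np.asarray(gi.si_segment_mrt_min, dtype=float)
        self.V_lumen = np.asarray(gi.si_volumes_ml, dtype=float)
        self.CL_abs = (
            compound.specific_intestinal_permeability_cm_s
            * np.asarray(gi.si_surface_areas_cm2, dtype=float)
            * 60.0
        )

        # state indexing
        self.off_pools = 4 * n
        self.off_lumen = self.off_pools + 4
        self.off_bins = self.off_lumen + 2 * (1 + self.n_seg)
        self.n_states = self.off_bins + 4

    # -- documentation ---------------------------------------------------
    def describe(self) -> dict:
        return {
            "n_organs": self.n_organs,
            "n_lumen_states": 2 * (1 + self.n_seg),
            "n_blood_pool_states": 4,
            "n_elimination_bins": 4,
            "n_states": self.n_states,
            "state_names": self.state_names(),
            "partition_method": self.kps.method,
        }

    def state_names(self) -> list[str]:
        names = []
        for o in self.organ_names:
            names += [f"{o}.{s}" for s in SUBCOMPARTMENTS]
        names += ["arterial.plasma", "arterial.blood_cells", "venous.plasma", "venous.blood_cells"]
        names += ["lumen.stomach.undissolved", "lumen.stomach.dissolved"]
        for s in range(self.n_seg):
            names += [f"lumen.si{s + 1}.undissolved", f"lumen.si{s + 1}.dissolved"]
        names += ["eliminated.metabolized", "eliminated.hepatic", "eliminated.renal", "eliminated.fecal"]
        return names

    # -- right-hand side -------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, dy: np.ndarray, k_diss: float,
            inhibition_factors: dict[str, float] | None = None) -> None:
        """Accumulate dA/dt for this compound's block into ``dy`` (same layout as y)."""
        n = self.n_organs
        A = y[: 4 * n].reshape(n, 4)
        dA = dy[: 4 * n].reshape(n, 4)
        a_art_pl, a_art_bc, a_ven_pl, a_ven_bc = y[self.off_pools : self.off_pools + 4]

        C_pl = A[:, 0] / self.V_pl
        C_bc = A[:, 1] / self.V_bc
        C_art_pl = a_art_pl / self.V_art_pl
        C_art_bc = a_art_bc / self.V_art_bc
        C_ven_pl = a_ven_pl / self.V_ven_pl
        C_ven_bc = a_ven_bc / self.V_ven_bc

        # convection
        out_pl = self.Q_out_pl * C_pl
        out_bc = self.Q_out_bc * C_bc
        in_pl = self.Q_pl * C_art_pl
        in_bc = self.Q_bc * C_art_bc
        in_pl[self.i_lung] = self.Q_pl[self.i_lung] * C_ven_pl
        in_bc[self.i_lung] = self.Q_bc[self.i_lung] * C_ven_bc
        if self.i_liver is not None and len(self.portal_idx):
            in_pl[self.i_liver] += out_pl[self.portal_idx].sum()
            in_bc[self.i_liver] += out_bc[self.portal_idx].sum()

        dA[:, 0] += in_pl - out_pl
        dA[:, 1] += in_bc - out_bc
        ven_in_pl = out_pl[self.venous_mask].sum()
        ven_in_bc = out_bc[self.venous_mask].sum()
        dy[self.off_pools + 2] += ven_in_pl - self.Q_pl[self.i_lung] * C_ven_pl
        dy[self.off_pools + 3] += ven_in_bc - self.Q_bc[self.i_lung] * C_ven_bc
        sys_pl = self.Q_pl.sum() - self.Q_pl[self.i_lung]
        sys_bc = self.Q_bc.sum() - self.Q_bc[self.i_lung]
        dy[self.off_pools + 0] += out_pl[self.i_lung] - sys_pl * C_art_pl
        dy[self.off_pools + 1] += out_bc[self.i_lung] - sys_bc * C_art_bc

        # unbound-gradient exchange
        u_pl = C_pl * self.fu
        u_bc = C_bc / self.k_bc
        u_int = A[:, 2] / self.V_int * self.fu
        u_cell = A[:, 3] / (self.V_cell * self.k_cell)
        J_bc = self.PS_bc * (u_pl - u_bc)
        J_end = self.PS_end * (u_pl - u_int)
        J_cell = self.PS_cell * (u_int - u_cell)
        dA[:, 0] += -J_bc - J_end
        dA[:, 1] += J_bc
        dA[:, 2] += J_end - J_cell
        dA[:, 3] += J_cell
        J_art = self.PS_bc_art * (C_art_pl * self.fu - C_art_bc / self.k_bc)
        J_ven = self.PS_bc_ven * (C_ven_pl * self.fu - C_ven_bc / self.k_bc)
        dy[self.off_pools + 0] -= J_art
        dy[self.off_pools + 1] += J_art
        dy[self.off_pools + 2] -= J_ven
        dy[self.off_pools + 3] += J_ven

        # elimination; intracellular processes act on the total intracellular unbound
        # concentration trap_cell * u_cell (ionized unbound included)
        u_cell_tot = self.trap_cell * u_cell
        for enzyme, cl in self.met_cl.items():
            factor = 1.0
            if inhibition_factors and enzyme in inhibition_factors:
                factor = inhibition_factors[enzyme]
            rate = cl * factor * u_cell_tot
            dA[:, 3] -= rate
            dy[self.off_bins + 0] += rate.sum()
        if self.hep_cl_u > 0:
            rate = self.hep_cl_u * u_cell_tot[self.i_liver]
            dA[self.i_liver, 3] -= rate
            dy[self.off_bins + 1] += rate
        if self.renal_cl > 0:
            rate = self.renal_cl * C_pl[self.i_kidney]
            dA[self.i_kidney, 0] -= rate
            dy[self.off_bins + 2] += rate

        # gut lumen: dissolution, transit, absorption
        lo = self.off_lumen
        st_u, st_d = y[lo], y[lo + 1]
        dy[lo] += -(k_diss + self.k_ge) * st_u
        dy[lo + 1] += k_diss * st_u - self.k_ge * st_d
        prev_u_out = self.k_ge * st_u
        prev_d_out = self.k_ge * st_d
        for s in range(self.n_seg):
            iu, idx = lo + 2 + 2 * s, lo + 3 + 2 * s
            a_u, a_d = y[iu], y[idx]
            # without a gut wall (reduced test models) nothing is absorbed
            abs_rate = self.CL_abs[s] / self.V_lumen[s] * a_d if self.i_gut is not None else 0.0
            dy[iu] += prev_u_out - (k_diss + self.k_si[s]) * a_u
            dy[idx] += prev_d_out + k_diss * a_u - self.k_si[s] * a_d - abs_rate
            if self.i_gut is not None:
                dA[self.i_gut, 2] += abs_rate
            prev_u_out = self.k_si[s] * a_u
            prev_d_out = self.k_si[s] * a_d
        dy[self.off_bins + 3] += prev_u_out + prev_d_out  # fecal loss

    # -- dosing ----------------------------------------------------------
    def apply_dose(self, y: np.ndarray, dose: DoseEvent) -> None:
        amt = dose.amount_nmol(self.compound.molecular_weight_g_mol, self.phys.body_weight_kg)
        if dose.route == "iv_bolus":
            y[self.off_pools + 2] += amt
        else:
            if self.i_gut is None:
                raise EngineError("oral dosing requires a gut_wall organ")
            form = self.compound.formulation(dose.formulation)
            if form.kind == "solution":
                y[self.off_lumen + 1] += amt
            else:
                y[self.off_lumen] += amt


def build_model(cmp: Compound, phys: PhysiologyModel, kps: PartitionResult | None = None) -> PBPKModel:
    """Assemble the whole-body ODE system for one compound."""
    return PBPKModel(cmp, phys, kps)


def metabolism_flux(enzyme_abundance_pmol: float, clint_ul_min_pmol: float, unbound_conc_um: float) -> float:
    """First-order enzymatic elimination flux, nmol/min.

    flux = CL_int (uL/min/pmol) x abundance (pmol) x unbound concentration (uM),
    with uL/min x nmol/mL reconciled to nmol/min.
    """
    if enzyme_abundance_pmol < 0 or clint_ul_min_pmol < 0 or unbound_conc_um < 0:
        raise EngineError("metabolism_flux inputs must be non-negative")
    return clint_ul_min_pmol * enzyme_abundance_pmol / 1000.0 * unbound_conc_um


# ---------------------------------------------------------------------------
# integration


@dataclass
class CompoundTrajectory:
    compound: str
    plasma_conc_ng_ml: np.ndarray
    states_nmol: np.ndarray  # (n_times, n_states)
    state_names: list[str]
    administered_nmol: np.ndarray
    mass_balance_rel_err: np.ndarray

    def eliminated(self, bin_name: str) -> np.ndarray:
        return self.states_nmol[:, self.state_names.index(f"eliminated.{bin_name}")]


@dataclass
class SimulationResult:
    time_h: np.ndarray
    compounds: dict[str, CompoundTrajectory]
    metadata: dict = field(default_factory=dict)

    def profile(self, compound: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(time_h, plasma concentration ng/mL) for one compound."""
        if compound is None:
            compound = next(iter(self.compounds))
        return self.time_h, self.compounds[compound].plasma_conc_ng_ml


class _Coupling:
    """Competitive inhibition of victim enzymes by the perpetrator's free concentration."""

    def __init__(self, victim_idx: int, perp_idx: int, pairs: list[tuple[str, float]], source: str):
        if source not in ("liver_intracellular_unbound", "plasma_unbound"):
            raise EngineError(f"unknown inhibitor concentration source {source!r}")
        self.victim_idx = victim_idx
        self.perp_idx = perp_idx
        self.pairs = pairs  # (enzyme, ki_um)
        self.source = source

    def inhibitor_conc(self, model: PBPKModel, y_block: np.ndarray) -> float:
        if self.source == "liver_intracellular_unbound":
            if model.i_liver is None:
                raise EngineError("inhibitor source needs a liver")
            # free concentration at the site of metabolism, by the same convention the
            # static screen uses at the plasma site: plasma fu x total site
            # concentration (the conventional surrogate when tissue binding is unknown)
            a_cell = y_block[4 * model.i_liver + 3]
            return model.fu * max(a_cell, 0.0) / model.V_cell[model.i_liver]
        a_ven = y_block[model.off_pools + 2]
        return max(a_ven, 0.0) / model.V_ven_pl * model.fu


def _negative_guard(y: np.ndarray, total_dose: float, atol: float) -> None:
    floor = -max(1e-6 * max(total_dose, 1.0), 1e4 * atol)
    if y.min() < floor:
        raise EngineError(f"negative state excursion beyond tolerance: min={y.min():.3e} nmol")


def _integrate(
    models: list[PBPKModel],
    doses: list[list[DoseEvent]],
    duration_h: float,
    options: SolverOptions,
    coupling: _Coupling | None,
) -> SimulationResult:
    duration = duration_h * 60.0
    for dl in doses:
        for d in dl:
            if d.time_h * 60.0 > duration:
                raise EngineError("duration must cover all dose times")
    offsets = np.cumsum([0] + [m.n_states for m in models])
    n_tot = offsets[-1]

    grid = np.arange(0.0, duration + 1e-9, options.output_dt_h * 60.0)
    if grid[-1] < duration - 1e-9:
        grid = np.append(grid, duration)

    # per-leg last oral dose time (min) per compound, for the dissolution clock
    dose_times = sorted({d.time_h * 60.0 for dl in doses for d in dl})
    breakpoints = [t for t in dose_times if 0.0 < t < duration]
    legs = [0.0] + breakpoints + [duration]

    y = np.zeros(n_tot)
    totals = [0.0] * len(models)
    last_oral: list[tuple[float, FormulationSpec] | None] = [None] * len(models)

    def dose_at(t: float) -> None:
        for ci, dl in enumerate(doses):
            for d in dl:
                if abs(d.time_h * 60.0 - t) < 1e-9 and d.amount > 0:
                    models[ci].apply_dose(y[offsets[ci] : offsets[ci + 1]], d)
                    totals[ci] += d.amount_nmol(
                        models[ci].compound.molecular_weight_g_mol,
                        models[ci].phys.body_weight_kg,
                    )
                    if d.route == "oral":
                        form = models[ci].compound.formulation(d.formulation)
                        last_oral[ci] = (t, form)

    out_y = np.zeros((len(grid), n_tot))
    out_adm = np.zeros((len(grid), len(models)))
    written = 0

    def rhs(t, yv):
        dy = np.zeros_like(yv)
        factors: dict[str, float] | None = None
        if coupling is not None:
            pm = models[coupling.perp_idx]
            block = yv[offsets[coupling.perp_idx] : offsets[coupling.perp_idx + 1]]
            conc = coupling.inhibitor_conc(pm, block)
            factors = {enz: 1.0 / (1.0 + conc / ki) for enz, ki in coupling.pairs}
        for ci, m in enumerate(models):
            if last_oral[ci] is not None:
                t0, form = last_oral[ci]
                k_diss = dissolution_hazard(form, t - t0)
            else:
                k_diss = 0.0
            inh = factors if (coupling is not None and ci == coupling.victim_idx) else None
            m.rhs(t, yv[offsets[ci] : offsets[ci + 1]], dy[offsets[ci] : offsets[ci + 1]], k_diss, inh)
        return dy

    for leg_start, leg_end in zip(legs[:-1], legs[1:]):
        dose_at(leg_start)
        if leg_end - leg_start < 1e-12:
            continue
        mask = (grid >= leg_start - 1e-9) & (grid <= leg_end + 1e-9) & (np.arange(len(grid)) >= written)
        t_eval = grid[mask]
        sol = solve_ivp(
            rhs,
            (leg_start, leg_end),
            y,
            method=options.method,
            t_eval=t_eval if t_eval.size else None,
            rtol=options.rtol,
            atol=options.atol,
        )
        if not sol.success:
            raise EngineError(f"solver failed on [{leg_start:.2f}, {leg_end:.2f}] min: {sol.message}")
        if t_eval.size:
            k = sol.y.shape[1]
            out_y[written : written + k] = sol.y.T
            out_adm[written : written + k] = totals
            written += k
        y = sol.y[:, -1].copy()
        _negative_guard(y, sum(totals), options.atol)

    if written < len(grid):  # trailing grid point coincides with leg end
        out_y[written:] = y
        out_adm[written:] = totals

    compounds: dict[str, CompoundTrajectory] = {}
    for ci, m in enumerate(models):
        block = out_y[:, offsets[ci] : offsets[ci + 1]]
        conc = np.clip(block[:, m.off_pools + 2], 0.0, None) / m.V_ven_pl  # nmol/mL
        ngml = conc * m.compound.molecular_weight_g_mol
        total_in_system = block.sum(axis=1)
        adm = out_adm[:, ci]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(adm > 0, np.abs(total_in_system - adm) / np.where(adm > 0, adm, 1.0), 0.0)
        compounds[m.compound.name] = CompoundTrajectory(
            compound=m.compound.name,
            plasma_conc_ng_ml=ngml,
            states_nmol=block,
            state_names=m.state_names(),
            administered_nmol=adm,
            mass_balance_rel_err=rel,
        )
    meta = {
        "solver": options.method,
        "rtol": options.rtol,
        "atol": options.atol,
        "output_dt_h": options.output_dt_h,
        "partition_method": models[0].kps.method,
        "species": models[0].phys.species,
        "body_weight_kg": models[0].phys.body_weight_kg,
    }
    return SimulationResult(time_h=grid / 60.0, compounds=compounds, metadata=meta)


def simulate(
    model: PBPKModel,
    doses: list[DoseEvent],
    duration_h: float,
    options: SolverOptions | None = None,
) -> SimulationResult:
    """Simulate one compound; deterministic given inputs. Supports single and repeated dosing."""
    return _integrate([model], [doses], duration_h, options or SolverOptions(), None)


def simulate_coupled(
    victim: PBPKModel,
    victim_doses: list[DoseEvent],
    perpetrator: PBPKModel,
    perpetrator_doses: list[DoseEvent],
    duration_h: float,
    inhibited: list[tuple[str, float]],
    source: str = "liver_intracellular_unbound",
    options: SolverOptions | None = None,
) -> SimulationResult:
    """Co-simulate victim and perpetrator; at every solver step the victim's
    enzyme-mediated intrinsic clearance for each (enzyme, Ki) pair is scaled by
    1/(1 + [I]/Ki) using the perpetrator's current free concentration at ``source``."""
    coupling = _Coupling(0, 1, inhibited, source)
    return _integrate(
        [victim, perpetrator],
        [victim_doses, perpetrator_doses],
        duration_h,
        options or SolverOptions(),
        coupling,
    )
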