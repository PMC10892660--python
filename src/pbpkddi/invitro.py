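"""In vitro assay analysis and IVIVE conversions.

Substrate-depletion half-life -> intrinsic clearance normalized per pmol CYP, IC50 by
nonlinear regression of a percent-of-control inhibition curve, and IC50 -> Ki scaling
utilities (cross-species ratio rule and the Cheng-Prusoff correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DepletionAssay",
    "InhibitionAssay",
    "DepletionFit",
    "IC50Fit",
    "clint_from_halflife",
    "fit_depletion",
    "fit_ic50",
    "ki_from_ic50",
    "ki_cheng_prusoff",
    "AssayError",
]


class AssayError(ValueError):
    """Assay data unsuitable for the requested fit."""


@dataclass
class DepletionAssay:
    """Substrate-depletion time course: fraction of parent remaining per timepoint per
    replicate, with the incubation's enzyme concentration (pmol CYP/mL)."""

    time_min: np.ndarray
    fraction_remaining: np.ndarray  # same length; replicates as repeated timepoints
    enzyme_conc_pmol_ml: float
    incubation_volume_ul: float = 200.0

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.fraction_remaining = np.asarray(self.fraction_remaining, dtype=float)
        if self.time_min.min() != 0:
            raise AssayError("depletion timepoints must start at 0")
        if self.enzyme_conc_pmol_ml <= 0:
            raise AssayError("enzyme concentration must be > 0")
        if np.any(self.fraction_remaining <= 0) or np.any(self.fraction_remaining > 1.2):
            raise AssayError("remaining fractions must lie in (0, 1.2]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.time_min, "fraction_remaining": self.fraction_remaining})


@dataclass
class InhibitionAssay:
    """Inhibition curve: metabolite formation as percent of the no-inhibitor control."""

    inhibitor_um: np.ndarray
    pct_control: np.ndarray

    def __post_init__(self):
        self.inhibitor_um = np.asarray(self.inhibitor_um, dtype=float)
        self.pct_control = np.asarray(self.pct_control, dtype=float)
        if np.any(self.inhibitor_um < 0):
            raise AssayError("inhibitor concentrations must be >= 0")
        if 0.0 not in self.inhibitor_um:
            raise AssayError("assay must include the 0 uM control defining 100%")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"inhibitor_uM": self.inhibitor_um, "pct_control": self.pct_control})


@dataclass
class DepletionFit:
    t_half_min: float
    k_per_min: float
    r_squared: float
    n_points: int


@dataclass
class IC50Fit:
    ic50_um: float
    hill_slope: float
    r_squared: float
    top: float = 100.0
    bottom: float = 0.0
    bounds_fixed: bool = True
    covariance: np.ndarray | None = field(default=None, repr=False)


def clint_from_halflife(t_half_min: float, enzyme_conc_pmol_ml: float) -> float:
    """Intrinsic clearance from a depletion half-life, uL/min/pmol CYP.

    CL_int = (ln 2 / t_half) x (1000 uL/mL / enzyme concentration).
    """
    if t_half_min <= 0 or enzyme_conc_pmol_ml <= 0:
        raise AssayError("half-life and enzyme concentration must be > 0")
    return math.log(2.0) / t_half_min * 1000.0 / enzyme_conc_pmol_ml


def fit_depletion(assay: DepletionAssay, exclude_t0: bool = False) -> DepletionFit:
    """Log-linear least-squares fit of remaining fraction vs time.

    Rejects non-decaying data ("no measurable depletion"). ``exclude_t0`` drops the
    normalization point at t = 0 from the regression.
    """
    t, f = assay.time_min, assay.fraction_remaining
    if exclude_t0:
        keep = t > 0
        t, f = t[keep], f[keep]
    if len(np.unique(t)) < 3:
        raise AssayError("need at least 3 distinct timepoints")
    res = stats.linregress(t, np.log(f))
    if res.slope >= 0:
        raise AssayError("no measurable depletion (non-negative log-linear slope)")
    k = -res.slope
    return DepletionFit(
        t_half_min=math.log(2.0) / k,
        k_per_min=k,
        r_squared=res.rvalue**2,
        n_points=len(t),
    )


def _hill(conc, ic50, h, top, bottom):
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** h)


def fit_ic50(assay: InhibitionAssay, fix_bounds: bool = True) -> IC50Fit:
    """Nonlinear regression of response = bottom + (top - bottom)/(1 + (I/IC50)^h).

    Default constrains top = 100 and bottom = 0 with the Hill slope floating
    (identifiable with a 9-concentration design); ``fix_bounds=False`` floats all four
    parameters.
    """
    conc, resp = assay.inhibitor_um, assay.pct_control
    if len(np.unique(conc)) < 5:
        raise AssayError("need at least 5 concentration levels")
    if np.all(resp <= 0):
        raise AssayError("all-zero response")
    pos = conc > 0
    slope_check = stats.linregress(np.log10(conc[pos]), resp[pos])
    if slope_check.slope > 0 and slope_check.rvalue**2 > 0.5:
        raise AssayError("response increases with inhibitor concentration: not an inhibition curve")

    guess_ic50 = float(np.exp(np.interp(50.0, resp[pos][::-1], np.log(conc[pos][::-1]))))
    guess_ic50 = min(max(guess_ic50, conc[pos].min()), conc[pos].max())
    try:
        if fix_bounds:
            popt, pcov = optimize.curve_fit(
                lambda c, ic50, h: _hill(c, ic50, h, 100.0, 0.0),
                conc, resp, p0=[guess_ic50, 1.0],
                bounds=([1e-6, 0.1], [1e6, 10.0]), maxfev=10000,
            )
            ic50, h = popt
            top, bottom = 100.0, 0.0
        else:
            popt, pcov = optimize.curve_fit(
                _hill, conc, resp, p0=[guess_ic50, 1.0, 100.0, 0.0],
                bounds=([1e-6, 0.1, 50.0, -20.0], [1e6, 10.0, 150.0, 50.0]), maxfev=10000,
            )
            ic50, h, top, bottom = popt
    except RuntimeError as err:
        raise AssayError(f"IC50 regression did not converge: {err}") from err
    pred = _hill(conc, ic50, h, top, bottom)
    ss_res = float(np.sum((resp - pred) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return IC50Fit(
        ic50_um=float(ic50), hill_slope=float(h), r_squared=r2,
        top=float(top), bottom=float(bottom), bounds_fixed=fix_bounds, covariance=pcov,
    )


def ki_from_ic50(ic50_target_um: float, ic50_reference_um: float, ki_reference_um: float) -> float:
    """Cross-species Ki scaling: the target Ki preserves the reference Ki/IC50 ratio,
    Ki_target = IC50_target x (Ki_ref / IC50_ref)."""
    if min(ic50_target_um, ic50_reference_um, ki_reference_um) <= 0:
        raise AssayError("all inputs must be > 0")
    return ic50_target_um * ki_reference_um / ic50_reference_um


def ki_cheng_prusoff(ic50_um: float, substrate_um: float, km_um: float) -> float:
    """Cheng-Prusoff conversion for a competitive inhibitor: Ki = IC50 / (1 + [S]/Km)."""
    if min(ic50_um, substrate_um, km_um) <= 0:
        raise AssayError("all inputs must be > 0")
    return ic50_um / (1.0 + substrate_um / km_um)
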