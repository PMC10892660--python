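"""Noncompartmental analysis of concentration-time profiles.

Cmax/Tmax by direct maximum, AUC by linear-up/log-down trapezoids (pure linear
selectable), terminal slope by log-linear regression over the terminal window that
maximizes adjusted R^2 (minimum 3 points, Tmax excluded; manual window override
supported), AUC_inf = AUC_last + C_last/lambda_z, CL/F = dose/AUC_inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ConcProfile", "PKParameters", "GroupSummary", "nca_single", "nca_group", "NCAError"]


class NCAError(ValueError):
    """Profile unsuitable for the requested NCA computation."""


@dataclass
class ConcProfile:
    """One subject's plasma concentration-time profile.

    ``dose`` pairs with ``dose_per_kg``: when True, dose is mg/kg and CL/F is reported
    per kg (L/h/kg), otherwise dose is mg and CL/F is L/h.
    """

    subject: str
    time_h: np.ndarray
    conc_ng_ml: np.ndarray
    dose: float
    dose_per_kg: bool = True
    role: str = "observed"  # 'observed' | 'predicted'
    group: str = ""
    lloq_ng_ml: float | None = None

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.conc_ng_ml = np.asarray(self.conc_ng_ml, dtype=float)
        if self.time_h.shape != self.conc_ng_ml.shape:
            raise NCAError("time and concentration arrays must have the same length")
        if np.any(np.diff(self.time_h) <= 0):
            raise NCAError("times must be strictly increasing")
        if np.any(self.conc_ng_ml < 0):
            raise NCAError("concentrations must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "group": self.group,
                "time_h": self.time_h,
                "conc_ng_per_ml": self.conc_ng_ml,
            }
        )


@dataclass
class PKParameters:
    cmax_ng_ml: float
    tmax_h: float
    auc_last_ng_h_ml: float
    auc_inf_ng_h_ml: float
    t_half_h: float
    cl_f: float  # L/h/kg if dose was per kg, else L/h
    lambda_z_per_h: float
    n_lambda_points: int
    extrapolated_fraction: float
    lambda_z_adj_r2: float = math.nan
    computable: bool = True  # False when no terminal decline was found

    def as_dict(self) -> dict[str, float]:
        return {
            "cmax_ng_ml": self.cmax_ng_ml,
            "tmax_h": self.tmax_h,
            "auc_last_ng_h_ml": self.auc_last_ng_h_ml,
            "auc_inf_ng_h_ml": self.auc_inf_ng_h_ml,
            "t_half_h": self.t_half_h,
            "cl_f": self.cl_f,
            "lambda_z_per_h": self.lambda_z_per_h,
        }


def _auc_segments(t: np.ndarray, c: np.ndarray, method: str) -> float:
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = (c1 + c2) / 2.0 * dt
    if method == "linear":
        return float(lin.sum())
    down = (c2 < c1) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logdown = (c1 - c2) / np.log(np.where(down, c1 / np.where(c2 > 0, c2, 1.0), math.e)) * dt
    return float(np.where(down, logdown, lin).sum())


def _lambda_z(t: np.ndarray, c: np.ndarray, i_tmax: int, window: int | None):
    """Log-linear terminal fit; returns (lambda_z per h, n_points, adj_r2) or None."""
    pos = c > 0
    idx = np.nonzero(pos & (np.arange(len(t)) > i_tmax))[0]
    if len(idx) < 3:
        return None
    tt, lc = t[idx], np.log(c[idx])
    n = len(idx)
    if window is not None:
        if not (3 <= window <= n):
            raise NCAError(f"lambda_z window of {window} points not available ({n} usable)")
        candidates = [window]
    else:
        ks = np.arange(3, n + 1)
        if len(ks) > 200:  # dense simulated profiles: thin the candidate set
            ks = np.unique(np.linspace(3, n, 200).astype(int))
        candidates = list(ks)
    best = None
    for k in candidates:
        res = stats.linregress(tt[-k:], lc[-k:])
        if res.slope >= 0:
            continue
        r2 = res.rvalue**2
        adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or adj > best[2] + 1e-12:
            best = (-res.slope, k, adj)
    return best


def nca_single(
    profile: ConcProfile,
    auc_method: str = "lin_up_log_down",
    lambda_window: int | None = None,
) -> PKParameters:
    """Noncompartmental parameters for one profile.

    Requires >= 4 positive concentrations and >= 3 usable terminal points. When no
    terminal decline exists, the parameters that need lambda_z are returned as NaN
    with ``computable=False``.
    """
    t, c = profile.time_h, profile.conc_ng_ml
    if np.count_nonzero(c > 0) < 4:
        raise NCAError("need at least 4 positive concentrations")
    i_tmax = int(np.argmax(c))
    cmax, tmax = float(c[i_tmax]), float(t[i_tmax])

    last_pos = np.nonzero(c > 0)[0][-1]
    auc_last = _auc_segments(t[: last_pos + 1], c[: last_pos + 1], auc_method)

    fit = _lambda_z(t, c, i_tmax, lambda_window)
    if fit is None:
        return PKParameters(
            cmax_ng_ml=cmax, tmax_h=tmax, auc_last_ng_h_ml=auc_last,
            auc_inf_ng_h_ml=math.nan, t_half_h=math.nan, cl_f=math.nan,
            lambda_z_per_h=math.nan, n_lambda_points=0,
            extrapolated_fraction=math.nan, computable=False,
        )
    lz, npts, adj_r2 = fit
    c_last = float(c[last_pos])
    auc_inf = auc_last + c_last / lz
    dose_ng = profile.dose * 1e6
    cl_f = dose_ng / auc_inf / 1000.0  # mL/h -> L/h (per kg if dose was per kg)
    return PKParameters(
        cmax_ng_ml=cmax,
        tmax_h=tmax,
        auc_last_ng_h_ml=auc_last,
        auc_inf_ng_h_ml=auc_inf,
        t_half_h=math.log(2.0) / lz,
        cl_f=cl_f,
        lambda_z_per_h=lz,
        n_lambda_points=npts,
        extrapolated_fraction=(auc_inf - auc_last) / auc_inf,
        lambda_z_adj_r2=adj_r2,
    )


@dataclass
class GroupSummary:
    """Per-group arithmetic mean +/- SD of each NCA parameter, with an optional
    unpaired two-sided t-test between two named groups."""

    per_subject: pd.DataFrame
    summary: pd.DataFrame  # index (group, parameter), columns mean/sd/n
    comparison: dict[str, float] = field(default_factory=dict)  # parameter -> p-value
    compared_groups: tuple[str, str] | None = None
    degenerate: list[str] = field(default_factory=list)  # parameters with zero variance


def nca_group(
    profiles: list[ConcProfile],
    compare: tuple[str, str] | None = None,
    **nca_kwargs,
) -> GroupSummary:
    """Group-level NCA: per-subject parameters, mean +/- SD per group, and an unpaired
    two-sided Student's t-test per parameter between the two groups in ``compare``."""
    rows = []
    for p in profiles:
        pk = nca_single(p, **nca_kwargs)
        rows.append({"subject": p.subject, "group": p.group, **pk.as_dict()})
    df = pd.DataFrame(rows)
    counts = df.groupby("group").size()
    small = counts[counts < 2]
    if not small.empty:
        raise NCAError(f"each group needs >= 2 subjects, got {dict(small)}")
    params = [c for c in df.columns if c not in ("subject", "group")]
    summary = df.groupby("group")[params].agg(["mean", "std", "count"])

    comparison: dict[str, float] = {}
    degenerate: list[str] = []
    if compare is not None:
        g1, g2 = compare
        for g in compare:
            if g not in counts.index:
                raise NCAError(f"comparison group {g!r} not present (need two groups)")
        if g1 == g2:
            raise NCAError("comparison requires two distinct groups")
        for param in params:
            a = df.loc[df.group == g1, param].dropna()
            b = df.loc[df.group == g2, param].dropna()
            scale = max(abs(a.mean()), abs(b.mean()), 1e-300)
            if a.std(ddof=1) <= 1e-9 * scale and b.std(ddof=1) <= 1e-9 * scale:
                degenerate.append(param)
                comparison[param] = 1.0 if a.mean() == b.mean() else 0.0
            else:
                comparison[param] = float(stats.ttest_ind(a, b).pvalue)
    return GroupSummary(
        per_subject=df,
        summary=summary,
        comparison=comparison,
        compared_groups=compare,
        degenerate=degenerate,
    )
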