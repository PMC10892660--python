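"""Model-performance metrics and Monte-Carlo prediction intervals.

MRD (mean relative deviation) is the multiplicative RMS of log10 concentration
residuals, 10^sqrt(mean((log10 Cobs - log10 Cpred)^2)); GMFE (geometric mean fold
error) is 10^mean(|log10(pred/obs)|). Both are >= 1 by construction and values <= 2 are
the conventional adequacy criterion. Fold classification bins predicted/observed pairs
into <=1.25-fold, <=2-fold and >2-fold bands, symmetric in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ddi import Scenario, set_param
from .nca import ConcProfile, PKParameters

__all__ = [
    "mrd",
    "gmfe",
    "ddi_ratios",
    "fold_classification",
    "FoldClassification",
    "EvaluationReport",
    "evaluation_report",
    "PopulationSpec",
    "prediction_interval",
    "PredictionInterval",
    "EvaluationError",
]


class EvaluationError(ValueError):
    """Invalid evaluation input."""


def _aligned(observed: ConcProfile, predicted: ConcProfile) -> tuple[np.ndarray, np.ndarray]:
    t_obs, t_pred = observed.time_h, predicted.time_h
    idx_pred = np.searchsorted(t_pred, t_obs)
    idx_pred = np.clip(idx_pred, 0, len(t_pred) - 1)
    # nearest-grid match, required within a tolerance
    left = np.clip(idx_pred - 1, 0, len(t_pred) - 1)
    use_left = np.abs(t_pred[left] - t_obs) < np.abs(t_pred[idx_pred] - t_obs)
    idx_pred = np.where(use_left, left, idx_pred)
    ok = np.abs(t_pred[idx_pred] - t_obs) <= 1e-6 + 1e-3 * np.maximum(t_obs, 1.0)
    if not np.any(ok):
        raise EvaluationError("profiles share no common timepoints")
    return observed.conc_ng_ml[ok], predicted.conc_ng_ml[idx_pred[ok]]


def mrd(observed: ConcProfile, predicted: ConcProfile) -> float:
    """Mean relative deviation of predicted vs observed concentrations:
    10^sqrt(mean of squared log10 residuals); 1.0 for identical profiles."""
    c_obs, c_pred = _aligned(observed, predicted)
    if np.any(c_obs <= 0) or np.any(c_pred <= 0):
        raise EvaluationError("MRD requires strictly positive concentrations")
    x = math.sqrt(float(np.mean((np.log10(c_obs) - np.log10(c_pred)) ** 2)))
    return 10.0**x


def gmfe(pred_obs_ratios) -> float:
    """Geometric mean fold error 10^mean(|log10 ratio|); symmetric under inversion."""
    r = np.asarray(list(pred_obs_ratios), dtype=float)
    if r.size == 0:
        raise EvaluationError("GMFE of an empty ratio list")
    if np.any(r <= 0):
        raise EvaluationError("GMFE requires positive ratios")
    return 10.0 ** float(np.mean(np.abs(np.log10(r))))


def ddi_ratios(alone: PKParameters, combo: PKParameters) -> tuple[float, float]:
    """(AUC_inf ratio, Cmax ratio), co-administration over single administration."""
    for pk in (alone, combo):
        if not pk.computable or math.isnan(pk.auc_inf_ng_h_ml):
            raise EvaluationError("both parameter sets must be complete")
    return (
        combo.auc_inf_ng_h_ml / alone.auc_inf_ng_h_ml,
        combo.cmax_ng_ml / alone.cmax_ng_ml,
    )


@dataclass
class FoldClassification:
    within_1_25: int
    within_2: int  # within 2-fold but outside 1.25-fold
    outside_2: int
    ratios: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.within_1_25 + self.within_2 + self.outside_2

    @property
    def all_within_2(self) -> bool:
        return self.outside_2 == 0


def fold_classification(pairs) -> FoldClassification:
    """Classify (predicted, observed) pairs by fold deviation, symmetric in log space."""
    c125 = c2 = cout = 0
    ratios = []
    for pred, obs in pairs:
        if pred <= 0 or obs <= 0:
            raise EvaluationError("fold classification requires positive values")
        r = pred / obs
        ratios.append(r)
        fold = max(r, 1.0 / r)
        if fold <= 1.25:
            c125 += 1
        elif fold <= 2.0:
            c2 += 1
        else:
            cout += 1
    return FoldClassification(c125, c2, cout, ratios)


@dataclass
class EvaluationReport:
    mrd_values: dict[str, float]
    gmfe_values: dict[str, float]
    fold: FoldClassification
    mrd_pass: bool
    gmfe_pass: bool

    def as_dict(self) -> dict:
        return {
            "mrd": self.mrd_values,
            "gmfe": self.gmfe_values,
            "fold_counts": {
                "within_1.25_fold": self.fold.within_1_25,
                "within_2_fold": self.fold.within_2,
                "outside_2_fold": self.fold.outside_2,
            },
            "mrd_pass": self.mrd_pass,
            "gmfe_pass": self.gmfe_pass,
        }


def evaluation_report(
    profile_pairs: dict[str, tuple[ConcProfile, ConcProfile]],
    parameter_ratios: dict[str, list[float]],
) -> EvaluationReport:
    """Assemble MRD per profile pair, GMFE per parameter, fold classification of all
    ratios, and the <=2 adequacy flags."""
    mrds = {name: mrd(obs, pred) for name, (obs, pred) in profile_pairs.items()}
    gmfes = {name: gmfe(rs) for name, rs in parameter_ratios.items()}
    all_ratios = [(r, 1.0) for rs in parameter_ratios.values() for r in rs]
    fold = fold_classification(all_ratios)
    return EvaluationReport(
        mrd_values=mrds,
        gmfe_values=gmfes,
        fold=fold,
        mrd_pass=all(v <= 2.0 for v in mrds.values()),
        gmfe_pass=all(v <= 2.0 for v in gmfes.values()),
    )


# ---------------------------------------------------------------------------
# Monte-Carlo prediction intervals


@dataclass
class PopulationSpec:
    """Virtual population: lognormal inter-individual variability around the point
    estimates. ``parameter_cv`` maps scenario parameter paths to coefficients of
    variation; the default varied set (clearances, fu, dissolution) is scenario-
    specific and supplied by the caller."""

    n_subjects: int
    parameter_cv: dict[str, float]
    seed: int
    interval_level: float = 0.95

    def __post_init__(self):
        if self.n_subjects < 2:
            raise EvaluationError("population needs n_subjects >= 2")
        if any(cv < 0 for cv in self.parameter_cv.values()):
            raise EvaluationError("CVs must be >= 0")
        if not (0 < self.interval_level < 1):
            raise EvaluationError("interval level must be in (0, 1)")


@dataclass
class PredictionInterval:
    time_h: np.ndarray
    point: np.ndarray  # ng/mL, point-estimate prediction
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    seed: int


def draw_multipliers(pop: PopulationSpec, rng: np.random.Generator) -> dict[str, float]:
    """One subject's lognormal parameter multipliers (median 1, sd from CV)."""
    out = {}
    for path, cv in pop.parameter_cv.items():
        if cv == 0:
            out[path] = 1.0
        else:
            sigma = math.sqrt(math.log(1.0 + cv * cv))
            out[path] = float(rng.lognormal(mean=0.0, sigma=sigma))
    return out


def _perturbed(scenario: Scenario, multipliers: dict[str, float]) -> Scenario:
    from .ddi import get_param

    sc = scenario
    for path, m in multipliers.items():
        if m != 1.0:
            sc = set_param(sc, path, get_param(sc, path) * m)
    return sc


def prediction_interval(
    scenario: Scenario,
    pop: PopulationSpec,
    co_administration: bool = False,
) -> PredictionInterval:
    """Empirical per-timepoint prediction interval of the victim's plasma profile from
    ``pop.n_subjects`` simulations with lognormally drawn parameters; deterministic
    given the seed."""
    rng = np.random.default_rng(pop.seed)

    def run(sc: Scenario) -> tuple[np.ndarray, np.ndarray]:
        res = sc.simulate_co() if co_administration else sc.simulate_victim_alone()
        return res.profile(sc.victim.name)

    t, point = run(scenario)
    sims = np.empty((pop.n_subjects, len(t)))
    for i in range(pop.n_subjects):
        mult = draw_multipliers(pop, rng)
        _, c = run(_perturbed(scenario, mult))
        sims[i] = c
    alpha = (1.0 - pop.interval_level) / 2.0
    return PredictionInterval(
        time_h=t,
        point=point,
        mean=sims.mean(axis=0),
        lower=np.quantile(sims, alpha, axis=0),
        upper=np.quantile(sims, 1.0 - alpha, axis=0),
        level=pop.interval_level,
        seed=pop.seed,
    )
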