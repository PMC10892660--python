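# Methods

This note describes the models implemented in `pbpkddi`, the conventions and defaults
they use, and what the bundled tests do and do not establish.

## Whole-body model structure

Each species model comprises 13 perfused organs (lung, heart, brain, muscle, adipose,
skin, bone, liver, spleen, gut wall, kidney, gonads, rest-of-body) plus arterial and
venous blood pools. The rest-of-body organ closes volume and flow balance exactly, so
venous return equals cardiac output by construction. Every organ carries four
sub-compartments: vascular plasma, vascular blood cells, interstitial space and
intracellular space. Internal units are nmol, mL, min; reported profiles are venous
plasma in ng/mL over an output grid of 0.01 h (configurable).

**Convection.** Arterial blood perfuses every systemic organ; the lung sits in series
between the venous and arterial pools and carries full cardiac output. Gut wall and
spleen drain into the liver (portal vein); the liver outflow carries hepatic artery
plus portal flow. Plasma and blood cells are convected separately
(haematocrit-weighted flows).

**Permeability-limited exchange.** Each sub-compartment `x` stores an amount `A_x` and
exposes a neutral-equivalent unbound concentration `u_x = A_x/(V_x k_x)`, where `k_x`
is its equilibrium total:unbound ratio — `1/fu` for plasma and interstitial space, the
blood-cell partition coefficient for cells in blood, and the organ's intracellular
coefficient `Kpu_cell` for tissue cells. Fluxes are `PS · (u_donor − u_receiver)`
across the endothelial barrier (plasma ↔ interstitial) and the cell membrane
(interstitial ↔ intracellular; blood plasma ↔ blood cells). At equilibrium without
elimination the unbound concentration is uniform — a property the test suite asserts.

PS products are permeability × surface area. The cell-membrane permeability is the
compound's cellular permeability (its unit is carried explicitly in the compound file;
for nicardipine the value 0.09 is used in cm/s as printed — the alternative 10⁻⁶ cm/s
reading is selectable but makes the cells practically inaccessible to a drug whose
elimination and inhibitory action are intracellular, which is inconsistent with its
observed kinetics). Endothelial permeability defaults to 10⁻⁴ cm/s — effectively
non-limiting for small molecules — against per-organ surface-area densities. Liver and
spleen sinusoids and kidney capillaries are fenestrated and are therefore assigned
large area densities (25 000 / 25 000 / 15 000 cm²/mL), making those barriers
negligible; continuous capillary beds (muscle, adipose, skin, brain) keep ordinary
densities.

**Ionization.** Compounds carry one pKa (acid/base/neutral). The state-variable
"unbound" concentration is the species that equilibrates across membranes; inside
cells (pH 7.0 vs plasma 7.4) the *total* unbound concentration of a base exceeds it by
the Henderson–Hasselbalch trapping factor (~2.2 for pKa ≈ 8). All intracellular
processes — metabolism, hepatic clearance, and the free inhibitor concentration — act
on the total intracellular unbound concentration.

## Partitioning ("composition-v1")

The intracellular:unbound partition coefficient per organ is built from bulk tissue
composition:

    Kpu_cell = trap·f_water + K_lip·f_lipid + 0.5·(1/fu − 1)·f_protein/0.074

with `K_lip = 10^(1.115·logD7.4 − 1.35)` (vegetable-oil scale) and the protein term
assuming tissue protein binds in proportion to plasma protein binding. The
whole-tissue coefficient reported to users is
`Kp = f_vasc + f_inter + fu·f_cell·Kpu_cell`, so a water-only tissue with fu = 1 and
logD = 0 has Kp = 1. Per-organ Kp overrides are accepted verbatim (the engine
back-solves `Kpu_cell`), so platform-exported coefficients can be injected. The method
name is recorded in the output metadata.

## Oral absorption

The gut lumen is a stomach plus three small-intestine transit segments. Tablets
dissolve along a Weibull CDF anchored at 50 % dissolved at the formulation's
dissolution time (the anchor is configurable); dissolution enters the ODE as the
Weibull hazard evaluated on time since the latest oral dose, capped at 100 min⁻¹ for
solver robustness with shape < 1. Solutions enter the lumen dissolved. Dissolved drug
is absorbed with flux = specific intestinal permeability × segment surface area ×
lumen concentration, deposited into the gut-wall interstitium (the enterocyte passage
is lumped into the permeability); material leaving the last segment is fecal loss.

GI geometry defaults: rat — 3.4 mL stomach (gastric-emptying t½ 10 min), three 1.7 mL
segments of 20 min mean residence each, villi-amplified absorptive areas 800/480/320
cm²; human — 50 mL stomach (t½ 15 min), 35 mL segments of 66 min, areas
50 000/30 000/20 000 cm². The rat values were calibrated within anatomical ranges so
that the victim's simulated absorption phase matches its observed time-to-peak
(~0.4–0.5 h) and the predicted-exposure band of the reference study; they are package
defaults, overridable per scenario.

## Elimination processes

* **Enzyme-mediated metabolism** — flux = CL_int (µL/min/pmol) × organ enzyme
  abundance (pmol) × total intracellular unbound concentration (µM). Abundance =
  reference concentration (pmol/mg microsomal protein) × organ relative expression ×
  MPPGL (mg/g) × organ mass. Rat: MPPGL 44.8 mg/g, CYP3A2 101 pmol/mg (experimental
  values); human: MPPGL 40 mg/g, CYP3A4 137 and CYP3A5 24 pmol/mg (literature
  population means). Expression is liver-only by default. Metabolism is strictly
  first-order (no saturation).
* **Hepatic half-life clearance** — the perpetrator's "total hepatic clearance"
  half-life is plasma-referenced: the implied clearance is `ln2/t½ · V_plasma`, applied
  as an unbound intracellular clearance `CL_u = ln2/t½ · V_plasma/fu` at the liver.
  Read literally as a rate on the liver's intracellular water, a t½ of 0.62 min would
  produce a whole-body clearance of well under 1 mL/min in the rat — orders of
  magnitude below the drug's observed oral clearance — so the plasma-referenced
  convention is the one consistent with the compound's kinetics.
* **Renal clearance** — a plasma clearance (mL/min/kg × body weight) applied to the
  kidney vascular plasma. When the nominal value exceeds kidney plasma flow, the
  realized organ clearance is flow-limited; this is a physical consequence of the
  perfusion model, not an input error.

## Drug–drug interaction coupling

Both compounds are co-simulated in one ODE system. At every right-hand-side evaluation
the victim's enzyme-mediated CL_int for each inhibited enzyme is multiplied by
`1/(1 + [I]/K_i)` (competitive inhibition; mechanism-based inactivation and induction
are out of scope). Inhibition pairs are formed from the perpetrator's inhibition
constants matching a victim enzyme in the scenario's species — in the human model
CYP3A4 is inhibited while CYP3A5 metabolism continues unimpeded.

**Free inhibitor concentration.** Two sources are selectable. `plasma_unbound` uses
fu × venous plasma concentration — the same quantity the static screen
`1 + (Cmax·fu/MW)/K_i` uses. The default, `liver_intracellular_unbound`, applies the
identical fu × (total concentration) convention at the site of metabolism:
[I] = fu_plasma × total liver intracellular concentration. This deliberate convention
(plasma fu as the surrogate unbound fraction, standard when tissue binding is not
separately measured) is what gives the dynamic model its distinct content: with a
strictly passive unbound concentration the liver site could never exceed
trap × plasma-unbound, and the dynamic prediction would be algebraically pinned to the
static index — contradicting the empirical finding that the rat interaction is strong
while the static rat screen is ~1.03. Under the site convention the rat scenario
produces a pronounced exposure increase while the human scenario stays near unity,
reproducing the species asymmetry; both quantities are computed by the test suite, not
asserted as constants.

## Noncompartmental analysis

Cmax/Tmax by direct maximum; AUC by linear-trapezoid on rising and log-trapezoid on
falling segments (pure linear selectable); λz by log-linear regression over the
terminal window (≥ 3 points after Tmax) that maximizes adjusted R², with a manual
window override; on dense simulated grids the candidate windows are thinned to ≤ 200.
AUC_inf = AUC_last + C_last/λz; CL/F = dose/AUC_inf (L/h/kg when the dose is per kg).
Profiles without terminal decline return the λz-dependent parameters as NaN with a
flag. Group analysis reports arithmetic mean ± SD and unpaired two-sided t-tests;
zero-variance comparisons are flagged degenerate with p = 1.

## Model evaluation

MRD = `10^sqrt(mean (log10 Cobs − log10 Cpred)²)` over aligned timepoints (the
displayed radical is read as a root-mean-square of log residuals); GMFE =
`10^mean|log10 (pred/obs)|`; both ≥ 1 by construction, ≤ 2 conventionally adequate.
Fold classification bins pred/obs pairs into ≤ 1.25-, ≤ 2- and > 2-fold, symmetric in
log space. Monte-Carlo prediction intervals draw per-subject lognormal multipliers
(median 1, σ = sqrt(ln(1+CV²))) for a configurable parameter set — clearances, fu and
dissolution parameters being the intended defaults — and report empirical 2.5/97.5
percentiles at a fixed 95 % level; runs are deterministic given the seed.

## Sensitivity analysis

One-at-a-time forward perturbation (+10 % default; central difference optional) of any
dotted-path-addressable scalar; SC = (ΔPK/PK)/(Δp/p) for victim Cmax and AUC_inf under
co-administration, ranked by |SC|, with |SC| > 0.1 flagged sensitive.

## Synthetic data

The generator emulates the reference study design: a three-group parallel rat study
(perpetrator 15 mg/kg n = 7, victim 5 mg/kg n = 6, co-administration n = 7) sampled at
0.25–24 h, lognormal inter-individual variability (default CV 30 % on clearances,
15 % on fu), residual error 10 % proportional + 1 ng/mL additive, optional LLOQ
truncation; and the in vitro designs (depletion 0/5/10/20/30 min in triplicate;
inhibition at 9 concentrations spanning 0–100 µM with the control fixed at 100 %).
Ground-truth logs carry the seed, per-subject multipliers and noise-free curves, so
every observation is re-derivable. The generator does *not* emulate correlated
parameter variability, time-dependent clearance, chromatographic artifacts or
dropout — recovery tests therefore establish estimator correctness under the stated
error model, not robustness to real bioanalytical pathology.

## Numerical choices

Stiff BDF integration (scipy `solve_ivp`), rtol 10⁻⁸, atol 10⁻¹⁰ nmol, integrated in
legs between dose times; state excursions below −max(10⁻⁶·dose, 10⁴·atol) abort with a
diagnostic; reported concentrations are clipped at zero. Mass balance (system +
eliminated bins vs administered) is tracked at every output time and tested to < 10⁻⁶
relative. Simulations in the test suite use a coarser 0.05 h output grid where only
integral metrics matter; the default remains 0.01 h.

## Known limitations

* Rat perpetrator exposure is over-predicted (~4-fold in Cmax/AUC): near-complete
  hepatic first-pass extraction combined with very deep lipophilic distribution is
  only partly captured by the composition-based partitioning and plasma-referenced
  hepatic clearance. The interaction ratios, which depend on relative liver exposure,
  are much less affected.
* Human victim exposure is under-predicted (~6-fold): recombinant-enzyme intrinsic
  clearances are scaled without an inter-system extrapolation factor, overstating
  human hepatic extraction.
* No transporters, no saturable metabolism, no enterohepatic recycling, no lymphatic
  circulation, single pKa per compound, solubility is not rate-limiting in the lumen.
* The IC50 → K_i species-scaling rule is shipped as a utility but the bundled rat K_i
  (0.39 µM) is taken from the source parameter table, which the rule's printed inputs
  do not reproduce; the table value is treated as authoritative.
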