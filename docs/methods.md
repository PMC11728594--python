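# Methods

## Scope and model structure

`gwrisk` evaluates chronic health risks to an adult resident using
untreated groundwater as the household supply, for ten chlorinated
hydrocarbons through four exposure routes. The dose algebra follows the
standard contaminated-site guideline forms (RAGS-style intake equations;
risk-based corrective-action volatilization factors). All metrics are
products of a concentration term and a rate/toxicity term, hence linear in
the water concentration and in exposure duration — a structure the package
exploits for concentration-invariant pathway shares and closed-form
control-value inversion, each cross-checked numerically by bisection.

Pathways:

* **Ingestion** — CDI = Cw·GWCR·EF·ED/(BW·AT); CR = CDI·SF, HQ = CDI/RfD.
* **Dermal** — steady-state event model DAD = Cw·Kp·t_event·EV·SA·CF/(BW·AT)
  with CF = 10⁻³ L/cm³; CR = DAD·SF/ABS_gi, HQ = DAD/(RfD·ABS_gi). No
  lag-time correction: dermal contributes <0.2% of every total here, so the
  refinement cannot change any conclusion.
* **Inhalation** — EC = Cw·VF·ET·EF·ED/(24·AT); CR = EC·1000·IUR (the
  single point where mg/m³ converts to µg/m³), HQ = EC/RfC. Indoor and
  outdoor are separate routes with separate exposure times and
  volatilization factors.

Volatilization couples a Millington–Quirk effective diffusion coefficient,
D_eff = D_air·θa^3.33/θt² + (D_water/H′)·θw^3.33/θt², to

* an ambient mixing box: VF_out = 1000·H′/(1 + u·δ·L_gw/(D_eff·W));
* a steady-state enclosed space with diffusive crack entry:
  VF_in = 1000·H′·r/(1 + r + L_crack/(η·L_gw)), r = (D_eff/L_gw)/(ER·LB).

To first order in the (small) ratio r, VF_in/VF_out ≈
u·δ/(ER·LB·W·(1 + L_crack/(η·L_gw))) — independent of the compound — so
indoor factors exceed outdoor ones uniformly under the defaults, matching
the observation that enclosed spaces accumulate vapours. The VF sub-model
sits behind a two-method protocol (`indoor`/`outdoor`) so an alternative
formulation (e.g. a full Johnson–Ettinger model with convection) can be
swapped in without touching the risk engine.

Boiling removes a fixed fraction (default 60%) of the volatile solute from
drinking water and therefore rescales the ingestion pathway only; vapour
inhalation during boiling is not modelled.

## Parameter defaults

Exposure (packaged `exposure.yaml`): GWCR 2.5 L/d (conservative resident
tap-water rate), EF 365 d/y, ED 24 y, BW 60 kg, AT_c 25,550 d (70-year
lifetime), ET_in 20 h/d and ET_out 4 h/d. AT_nc is a fixed constant of
8,760 d (365 × the default ED) and deliberately does **not** track a
varied ED: if it did, HQ would be invariant to exposure duration,
contradicting the observed strong HQ sensitivity to ED. Dermal contact is
parameterized as brief hand-only contact (SA 1,000 cm², 0.1 h/event,
1 event/d): with literature permeability coefficients, any full-body
bathing scenario would put dermal shares far above the <0.2% level this
receptor population exhibits, so the receptors' direct water contact is
evidently minimal.

Site (`site.yaml`): θa 0.28, θw 0.15, θt 0.43, depth to groundwater 3 m,
wind 2 m/s across a 10 m source with a 2 m mixing height, air exchange
0.5 h⁻¹, building volume/area ratio 2 m, crack fraction 10⁻³, slab 15 cm —
typical vadose-zone and residential-building values.

Toxicity (`chemicals.csv`): SF/IUR/RfD/RfC from standard databases
(IRIS/RSL conventions), H′ and diffusivities at 25 °C, Kp from the dermal
guidance literature, drinking-water limits from the Chinese national
standard. Three entries are pinned by the study's stated qualitative
orderings rather than database values: vinyl chloride and
1,2-dichloroethylene share RfD 2×10⁻³ mg/kg·d (the study asserts equality;
published values differ between the two), and the slope factors of carbon
tetrachloride, 1,2-dichloroethane and 1,1,2-trichloroethane sit just below
trichloroethylene's so that vinyl chloride and trichloroethylene carry the
two largest oral slope factors, as the survey reports. These three
compounds have site means of 0.00–0.09 mg/L, so the pinning moves no
concentration-weighted result materially. Neither dichloroethylene has an
oral slope factor or inhalation unit risk: their carcinogenic metrics are
reported as absent, never zero.

## Survey statistics and censoring

Detection rate is the fraction of uncensored rows; exceedance rate the
fraction of reported values above the standard limit. Censored rows carry
the detection limit as their reported value but contribute zero to means by
default (matching survey tables in which a heavily censored compound prints
a mean of 0.00); DL/2 and DL substitution are available as a switch.
Compound shares of the site total use the survey mean concentrations
directly (per-well risk aggregation is available via `summarize` over any
concentration mapping).

## Synthetic site generator

Each compound's concentration field is i.i.d. zero-inflated lognormal per
well: with probability p₀ the compound is absent (non-detect); otherwise a
lognormal draw, censored at the detection limit. Calibration to a survey
row solves three moment equations — censored mean
(1−p₀)·e^{μ+σ²/2}·Φ((μ+σ²−ln DL)/σ), detection probability
(1−p₀)·Φ((μ−ln DL)/σ), and the median of the sample maximum
μ+σ·Φ⁻¹(0.5^{1/n}) — by bounded weighted least squares (σ ∈ [0.1, 4],
p₀ ∈ (0, 1) via logit). The three targets are generally not exactly
consistent, so the mean and detection rate carry full weight and the
maximum 0.3: it is a single order statistic and the noisiest constraint. A
compound whose survey mean prints 0.00 is calibrated to detection rate and
maximum only with σ pinned at 1.5.

What the generator does *not* emulate: spatial correlation, hotspots or
plume structure (no coordinates are modelled), inter-compound correlation
from shared sources, temporal trends, or measurement error above the
censoring mechanism. Passing tests therefore demonstrate correctness of
the statistical machinery under the declared marginal model, not fidelity
to any site's spatial contamination pattern.

## Monte Carlo sensitivity

Inputs (cw, GWCR, EF, ED, BW) are sampled independently — averaging times
are fixed constants — with defaults: cw lognormal with the site-calibrated
log-parameters per compound; ED triangular(1, 24, 40) y; EF
triangular(200, 365, 365) d/y; GWCR lognormal (median 2.39 L/d, σ_log 0.3,
truncated to [0.5, 8]); BW normal(60, 10) truncated to [40, 100] kg. The
sensitivity measure is the signed normalized squared Spearman correlation,
sign(r)·r²/Σr², whose absolute values sum to one; point-mass inputs are
excluded. With the site-calibrated concentration fields (σ_log ≈ 1.5–2.5)
concentration dominates the ranking and body weight is negatively signed,
reproducing the qualitative sensitivity structure; exact percentage
contributions depend on distribution parameters that the original survey
drew from uncited local reports, and are not a reproduction target.

## Numerical choices

* Control values: closed form (threshold over the unit-concentration or
  per-year metric); the bisection cross-check brackets at ±6 decades and
  agrees to ~10⁻¹⁰ relative. Zero-toxicity compounds raise an explicit
  unsupported-value error.
* Shares: undefined (explicit error) when every metric in the group is
  zero or absent; otherwise normalized to sum to 1 within 10⁻¹².
* Truncated sampling: rejection resampling against the declared support.
* Reports: floats serialized at 6 significant digits; JSON keys sorted, so
  a rerun with the same seed is byte-identical.
* Acceptability is classified as unacceptable at CR ≥ 10⁻⁶ or HQ ≥ 1
  (boundary inclusive).

## Problem sizes

The shipped tests and the acceptance script are deliberately small: the
deterministic reproduction surface (shares, control values) is exact
algebra over ten compounds and runs in milliseconds; stochastic checks use
10,000 Monte Carlo iterations, 10,000-well parameter-recovery sites and
1,000 simulated 76-well surveys, sizes at which the relevant Monte Carlo
standard errors are a few percent.

## Known limitations

* Single adult receptor; no child/adult stratification or early-life
  potency adjustment.
* Mixture toxicity by simple addition across compounds and pathways.
* Steady-state volatilization only; no transient vapour intrusion, soil
  sources, or shower volatilization.
* The reconstructed toxicity/exposure set reproduces the survey's
  percentages to within a few points and control values to within a factor
  of ~2–3; exact agreement would require the survey's unpublished
  parameter table. The boiled-water hazard-quotient share of
  trichloroethylene is structurally bounded below ~82% under
  ingestion-only boiling with any parameter set matching the unboiled
  shares, so the survey's lower printed value likely reflects a different
  boiling treatment or parameter set.
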