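# Methods

`glimtwin` is a whole-body physiologically based pharmacokinetic (PBPK)
model of glimepiride (GLI) and its sequential metabolites M1
(hydroxy-glimepiride, pharmacologically active) and M2
(carboxy-glimepiride, inactive), built as a "digital twin": a single
calibrated parameter set plus patient-factor scaling rules that together
predict exposure across dose, CYP2C9 genotype, renal function, cirrhosis
severity, bodyweight and food state.

## Model structure

Amounts are tracked in µmol in the following compartments, connected by
plasma flow (flow-limited organs) or permeability-limited exchange:

* **Gut lumen** — solid and dissolved GLI. Tablet dissolution
  (`k_diss`, 1/h) feeds the dissolved pool; first-order absorption
  (`k_abs`, 1/h) feeds the portal inflow. With the bioavailable fraction
  `f_absorption` < 1, the complementary fraction of the absorbed flux is
  routed to feces unabsorbed. Oral solutions bypass dissolution.
* **Venous and arterial plasma** (1.8 + 1.2 L at 75 kg). Arterial plasma
  is fed from venous plasma by the cardiac plasma flow (180 L/h); no lung
  compartment is modeled since no represented PK feature depends on
  pulmonary transit. Non-eliminating "rest organs" are a direct
  arterio-venous flow path.
* **Liver** — a liver-plasma sub-compartment perfused by the hepatic
  artery (11.7 L/h) plus portal flow (32.4 L/h, carrying freshly absorbed
  drug), and a hepatocyte compartment exchanging with liver plasma via
  bidirectional permeability–surface products `ps_li_*` (L/h),
  flux = PS·(C_plasma − C_cell).
* **Kidney plasma** — renal excretion of M1/M2 at
  `f_renal_function · CLren · C_kidney-plasma`. Unchanged glimepiride is
  not excreted renally.
* **Rest tissue** (30 L effective) — a single distribution compartment
  for all three substances exchanging with venous plasma at rate
  `ftissue_gli` (L/h) against the partition coefficient `Kp_gli`
  (shared by parent and metabolites for parsimony).
* **Cumulative urine (M1, M2) and feces (M1, M2, unabsorbed GLI)** —
  irreversible sinks. M1/M2 reach feces by plasma→gut-lumen secretion
  (`k_sec_m1/m2`, 1/h on the venous amount); there is no enterohepatic
  recirculation and no reabsorption of secreted metabolite.

Metabolism happens only in the hepatocyte: Michaelis–Menten CYP2C9
conversion GLI→M1, v1 = f_cyp2c9·(1 − f_cirrhosis)·Vmax·C/(Km + C),
followed by first-order M1→M2, v2 = (1 − f_cirrhosis)·k_m12m2·A. M1→M2 is
kept first-order because public data on the responsible enzymes are too
limited to support a saturable form. Plasma protein binding is not
modeled; all concentrations are total plasma. There is no M1→GLI or
M2→M1 back-conversion.

**Uptake-limited hepatic clearance.** The GLI membrane exchange capacity
`ps_li_gli` is deliberately of the same magnitude as the intrinsic
metabolic clearance Vmax/Km. Hepatic clearance is then a series
combination of exchange and metabolism, so scaling Vmax by a genotype
activity f changes exposure sub-proportionally: with CL_int/PS ≈ 1.9 the
AUC ratio for f = 0.23 (the *3/*3 homozygote) is ≈ 2.1 rather than the
naive 1/0.23 ≈ 4.3, matching the clinically observed ≤ 2.5-fold. This is
a structural property, not a tuned exception: the same mechanism shapes
the cirrhosis response.

## Patient-factor scaling

Scaling factors are stored on the parameter set and resolved into
effective rates in one canonical order at simulation time, which makes
the `apply_*` operations exactly commutative (eager multiplication would
not be, by floating-point non-associativity).

* **CYP2C9 genotype** — allele activities *1 = 1.0, *2 = 0.68,
  *3 = 0.23 (in-vitro derived); diplotype activity is the mean of the two
  allele activities; `f_cyp2c9` multiplies Vmax only (Km unchanged).
* **Renal function** — KDIGO-style GFR classes (mL/min/1.73 m²):
  normal (> 90), mild [50, 90], moderate [35, 50), severe (0, 35); the
  published 49/50 gap is closed by a lower-inclusive moderate interval.
  Factors: 1.0 / 0.69 / 0.32 / 0.19, multiplying CLren_m1 and CLren_m2
  only.
* **Cirrhosis** — `f_cirrhosis` (0 = healthy) multiplies the
  functional-parenchyma processes (Vmax, k_m12m2) by (1 − f) and shunts
  the same fraction f of liver-directed flow (including absorbed drug)
  directly to venous plasma. CTP mapping: A = 0.35, B = 0.65 (monotone
  anchors, configurable) and C calibrated against the 3.5-fold AUC
  increase at 1 mg (fitted value shipped in
  `data/reference_calibration.json`, ≈ 0.87).
* **Bodyweight** — volumes scale with (BW/75)^0.8; flows and all
  metabolic/excretory capacities with (BW/75)^0.75. Matched-in-practice
  exponents keep the terminal half-life nearly weight-independent
  (< 8 % over 40–170 kg) while reproducing the inverse Cmax/AUC–weight
  relation; with strictly linear volumes the half-life would vary ≈ 44 %
  over that range, contradicting the observed stability. The published
  bodyweight series itself implies Cmax ∝ BW^−0.83 and AUC ∝ BW^−0.76,
  i.e. near-matched exponents.
* **Food** — `f_absorption` (fasted 1.0; fed default 0.85, a documented
  placeholder: the food effect is represented only as a scalar
  bioavailable fraction and is excluded from all quantitative checks).

## Numerics

LSODA with rtol 1e-8, atol 1e-10 µmol (population runs use 1e-6/1e-9);
dose events are applied exactly by restarting the integrator at event
times, ties in listed order. Output on a uniform grid (default 0.1 h,
49 h span) plus event boundaries. Mass balance (total moles in all
compartments + sinks vs administered) holds to < 1e-12 relative;
the acceptance requirement is < 1e-6. Michaelis–Menten and secretion
terms clamp negative round-off amounts at zero; reported concentrations
are clipped at zero.

Km is fixed at 50 µM (config): only CL_int = Vmax/Km is identified by
plasma data, and at therapeutic doses hepatocyte concentrations stay
≲ 2 % of this Km, preserving the observed dose linearity (1–8 mg within
1 %) while keeping a saturable form for high-concentration use.

## Non-compartmental analysis

Cmax/Tmax from the grid maximum (first occurrence on ties); linear
trapezoid AUC (log-linear differs by < 0.5 % on the dense simulation
grids); λz by log-linear regression over the last k post-Tmax samples
with k ≥ 3 chosen to maximize adjusted R², flagged if no window reaches
adjusted R² ≥ 0.8 with negative slope; AUC(0–∞) = AUC(0–t) + C_last/λz;
t½ = ln 2/λz; CL/F = dose/AUC(0–∞).

**Apparent metabolite clearance** is defined as cumulative urinary
(M1 + M2) recovery divided by the metabolite's plasma AUC over the
simulated span (≥ 72 h recommended). The naive alternative — *renal* M1
amount over AUC — algebraically equals f_renal·CLren_m1 for every
parameterization, forcing the severe/normal clearance ratio to 0.19 and
making the published 140 → 50 mL/min pair unreachable; it is also
incompatible with the ~43 % urinary dose recovery. Under the definition
used here, the calibrated renal (≈ 90 mL/min), fecal-secretion
(≈ 170 mL/min) and hepatic M2-conversion pathways reproduce the
published normal and severe clearances, the 7 µmol 48-h urinary recovery
at 8 mg, and the 3 → 1 µmol renal-study amounts simultaneously.

## Calibration

The shipped reference set is produced by weighted least squares against a
bundled table of published summary pharmacokinetics (Cmax at 1 mg and at
8 mg/40 kg, AUC at 8 mg, Tmax, t½, 48-h urinary recovery, metabolite
clearances at normal/severe renal function, genotype and cirrhosis AUC
fold-changes) with relative residuals. Because the reference Cmax
(≈ 100 ng/mL) and the 40-kg Cmax (≈ 1000 ng/mL) pull a strictly linear
model in opposite directions, the optimizer settles both near ∓15 %; the
published pair is slightly off-linear, so no single linear
parameterization can center both. The fit is staged — glimepiride
kinetics (absorption, CL_int, exchange, distribution, CTP-C factor)
first, then metabolite disposition (CLren_m1, k_sec_m1, k_m12m2), then a
joint polish — exploiting the triangular dependence structure; features
use parabola-refined peaks and fixed-window terminal slopes so they stay
smooth for the derivative-based optimizer.

The generic dataset calibration (`calibration.fit`) minimizes
J(θ) = Σ_s w_s Σ_i ((ŷ_i − y_i)/σ_i)² with study weights w_s ∝ group
size (normalized to Σw = 1) and σ_i the reported SD, else 20 % of the
observation floored at an LLOQ-equivalent; optimization is multi-start
(Latin hypercube in log-parameter space, deterministic under seed) TRF
least squares with bounds, tolerance 1e-8, ≤ 500 iterations per start.
Simulation failures map to a large-but-finite penalty cost (1e8) so
optimizers continue. Km is fixed during fitting.

## Population simulation

Within-genotype variability of CYP2C9 activity follows a lognormal whose
shape (log-SD σ, default 0.35, config) mimics the intrinsic-clearance
spread observed for the probe substrate diclofenac, and whose per-allele
scale satisfies µ_a = ln(activity_a) − σ²/2 so the mean equals the fixed
allele activity exactly. Individual activity is the average of two
independent allele draws; genotypes are drawn from per-population
frequency tables, optionally Hardy–Weinberg-expanded from allele
frequencies. Sampled activities are not truncated (values > 1 represent
an ultra-rapid tail). Population runs use a 4 mg oral dose at reference
covariates, n = 1000 by default. Of the nine bundled biogeographical
groups, the European *2 frequency (12.7 %) and the Central/South Asian
pair (*2 11.4 %, *3 11.0 %) are published values; the remaining entries
are clearly labeled illustrative placeholders (the Oceanian *3 frequency
is tuned to the published group mean activity of 0.98) and can be
replaced by full published tables via JSON. Pairwise comparisons use
two-sample Kolmogorov–Smirnov tests with Holm-adjusted p-values reported
alongside raw ones, plus the symmetric relative mean difference
|m_A − m_B| / ((m_A + m_B)/2).

## Synthetic studies

The study generator emulates the *structure* of curated clinical data —
arm-wise mean ± SD time courses with group sizes — not any real study's
values. Concentrations get mean-one multiplicative lognormal noise;
urinary amounts proportional plus additive noise; inter-individual
variability perturbs selected parameters lognormally per virtual
subject. What passing recovery tests show is therefore internal
consistency (the fitting machinery recovers known truth under the
generator's error model), not fidelity to real inter-study
heterogeneity, assay error structure, or sparse clinical sampling.

## Known limitations

* No plasma-protein-binding model: the apparent clearance increase seen
  clinically in chronic kidney disease (via reduced albumin binding) is
  not reproduced; glimepiride exposure is exactly renal-independent here.
* Fixed adult physiology; no sex-specific parameters, pediatrics,
  pregnancy or dialysis.
* The M1/M2 fecal secretion rates and the M2 hepatic export are weakly
  identified by summary-level targets; bounds are design choices.
* Food effect is a scalar bioavailability placeholder.
* Alleles beyond *1/*2/*3 are out of scope; frequency tables for most
  biogeographical groups are illustrative placeholders.
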