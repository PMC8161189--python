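# Methods

## Scope and intent

`cyclopbpk` re-implements, in open scientific Python, a whole-body PBPK model
for intravenous and oral cyclosporine together with the evaluation workflow
used in clinical pharmacometrics: calibrate against single-dose healthy
volunteer profiles, predict steady-state troughs for virtual renal-transplant
patients, and score predictions against observed trough levels. The compound
parameterisation (physico-chemistry, nine saturable binding sites, CYP3A4 and
P-glycoprotein kinetics) is taken as published, with its printed units; the
anatomical/absorption platform around it is our own and is documented here.

## Virtual individuals

The reference individual is an average European male (30 y, 73 kg, 176 cm,
hematocrit 0.45). His organ volumes, regional blood flows and tissue
water/lipid/protein fractions are an embedded reference-human table of the
kind used by whole-body PBPK platforms (ICRP-style values; cardiac output
5.6 L/min, total tissue volume ≈ BW/1.05 kg/L).

Patients are built from sex, age, body weight and height:

* lean-tissue and blood volumes scale with the ratio of Boer lean body
  weights; adipose volume absorbs the remaining mass so that total volume
  equals BW/1.05 exactly (volume conservation holds for every patient by
  construction, and organ volumes are monotone in body weight);
* flows scale with cardiac output ∝ BW^0.75, with a 0.4 %/year decline past
  age 30 (clipped to [0.75, 1.08]);
* hematocrit 0.45 (male) / 0.40 (female);
* missing heights are imputed from an embedded sex × age-band table of German
  population averages (male 176–181 cm, female 164–168 cm, decreasing with
  age band).

GI geometry (segment surfaces, luminal fluid volumes, transit rates) is a
fixed adult parameter set: gastric emptying t½ ≈ 12 min, small-intestinal
transit ≈ 3.3 h over five segments, colonic residence ≈ 23 h, luminal fluid
0.30 L stomach / 0.05–0.08 L per small-intestinal segment / 0.15 L colon.

## Distribution

Organs are well-stirred compartments exchanging with blood at their regional
flow. Passive tissue affinity comes from tissue composition,

    Kp = fu_plasma · (f_water + s · 10^logP · f_lipid),

with a single global scalar `s` on the membrane-affinity term (octanol
overestimates membrane partitioning); `s` is calibrated once (below).

Two refinements reflect cyclosporine specifically:

* **Blood-cell binding.** Whole blood is plasma plus a saturable blood-cell
  pool (K_M 0.15 µmol/L, B_C 3.86 µmol/L per litre of cells). The
  whole-blood/plasma relation is inverted in closed form inside the solver;
  the resulting blood:plasma ratio is ≈ 1.9 at trough-like concentrations
  and falls with saturation — the familiar non-linearity of whole-blood
  cyclosporine assays.
* **Transcapillary permeation limit.** For a 1203 Da cyclic peptide,
  distribution into organs with continuous capillaries (heart, bone, skin,
  muscle, brain, adipose) is not purely flow-limited. These organs exchange
  at Q·PS/(Q+PS) with PS = 0.02 L/min per litre of tissue (calibrated once);
  sinusoidal/fenestrated beds (liver, spleen, kidney, lung, gut) remain
  flow-limited. This slows early distribution and sets C_MAX without
  affecting clearance.

### Saturable tissue binding

Nine binding pools with published (K_M, K_OFF, B_C). The kinetic closure is
mass action with k_on = K_OFF/K_M, so every pool's stationary state is the
isotherm B_C·C_u/(K_M + C_u). The printed K_OFF units split the pools into
two regimes, and the engine treats them accordingly:

* per-second sites (lung, heart, bone, skin, blood cells) relax within
  seconds — they are held at local equilibrium inside the compartment amount
  (the singular-perturbation limit; integrating ~10⁵/min modes explicitly
  would add stiffness without changing the solution at solver tolerance);
* per-hour sites (kidney, spleen, liver, intestine) are explicit ODE states
  and fill over days, as printed (their flux is small over a 4-day protocol;
  whether the source intended these literally is unknowable, so they are
  implemented as printed).

## Elimination

No renal or biliary excretion of parent drug is modelled; elimination is
purely metabolic. Systemic CYP3A4 follows Michaelis–Menten kinetics on the
unbound tissue concentration with V_MAX per gram of tissue scaled by each
organ's abundance relative to liver (liver 1.0, large intestine 0.71, small
intestine 0.4, stomach 0.35, kidney 0.03, muscle and brain 0.01).

## Absorption and gut-wall first pass

Oral dosing is a solution bolus into the stomach lumen. Dissolved and
precipitated material transit together; luminal concentration is capped at
the 190 µg/ml solubility, with excess precipitating and redissolving
instantaneously (a fast relaxation, 1/min, numerically). Passive uptake is
P_eff·A·C per segment with P_eff = 4.5·10⁻⁵ cm/min and A the cylindrical
surface times an effective enlargement factor (folds/villi/microvilli).

The mucosa of each segment is a small permeability-limited compartment:
drug enters apically, is metabolised by Cl_II (50 L/h, split across segments
in proportion to the segmental CYP3A4 concentration), effluxed back to the
lumen by saturable P-gp (K_M 0.09 µmol/L, V_MAX 2.14 nmol/ml/min, aboral
distribution 0.07/0.38/0.55, colon baseline 1 µmol/L), or permeates
basolaterally into portal blood through a clearance CL_b on the unbound
concentration. The competition Cl_II vs CL_b sets the gut escape fraction
F_I, exactly as in mucosal submodels of commercial platforms. With a purely
flow-limited mucosa the printed Cl_II would give a gut extraction of only
~3 % — a permeability-limited mucosa is the only structure consistent with
the published F_I ≈ 0.4–0.5.

Bookkeeping: F_A is the net apically absorbed fraction (gross uptake minus
P-gp return — gross alone can exceed 1 through recycling); F_I is gross
portal escape over total mucosal throughput (net absorption plus basolateral
re-entry from arterial blood, which faces the same escape-vs-clearance
competition); F is the dose-normalised AUC ratio against a matched
1.5 mg/kg IV infusion run over the same study window. In the linear regime
F agrees with F_A·F_I·F_H within a few percent, F_H estimated from the IV
run's hepatic clearance.

## Dosing, solver, output

IV infusions are constant-rate source terms into venous blood; oral doses
are state jumps of the stomach lumen. Integration is piecewise between dose
boundaries with SciPy's BDF (rtol 1e-8, atol 1e-10 µmol, conservative
Jacobian sparsity pattern). The output grid is 0.05 h for single-dose
studies and 0.25 h for multi-dose trough protocols; trough values are read
exactly at interval boundaries, so they are grid-independent (verified to
<1 %). Mass balance (body + lumen + metabolised + excreted vs dosed) holds
to ~10⁻¹² relative; the engine aborts with a diagnostic on non-finite or
substantially negative states. Whole-blood concentration is venous amount /
venous volume × 1203 ng/ml per µmol/L.

The single-dose evaluation arms (IV 1.5/2/2.1/2.5/3/5 mg/kg with their
infusion durations, oral 100/300/600 mg) are simulated in the reference
individual over a 24 h window — the typical sampling duration of the
underlying studies; per-arm windows are configurable. mg/kg doses resolve
against the reference 73 kg. The trough protocol is 8 oral doses q12h with
the read-out at t = 96 h, immediately before the would-be 9th dose.

## One-time calibration

Four platform constants are not determined by the published compound table
and were calibrated once against the IV and oral arms, then frozen in the
bundled compound file:

| parameter | value | anchored to |
|---|---|---|
| partition scalar `s` | 0.12 | IV 1.5 mg/kg AUC (terminal phase/V_ss) |
| basolateral mucosa clearance | 34.7 L/h | F_I of the 100 mg arm |
| SI surface enlargement | 80 | F_A at 100 vs 600 mg, t_MAX |
| tissue permeation PS | 0.02 L/min/L | IV and oral C_MAX |

With these values the nine-arm AUC prediction folds against the observed
study values lie in [0.96, 1.20], and the model reproduces the
solubility-limited fall of F_A from 0.96 (100 mg) to 0.75 (600 mg). One
consequence of realistic luminal fluid volumes is brief, fully redissolving
supersaturation even at 100 mg; the dose-dependent F_A fall, not the absence
of transient precipitation, is the constrained behaviour.

## Synthetic TDM cohorts

The clinical trough dataset (32 renal-transplant outpatients, 356 troughs,
q12h doses 25–225 mg, 1–11 dose levels per patient) is unpublished, so the
comparison pipeline is exercised on synthetic cohorts: biometrics uniform
over the cohort's ranges with heights imputed; dose counts from a truncated
geometric distribution (right-skewed, median ≈ 2) on the 12.5 mg clinical
dose grid; noise-free truths from the model's own trough predictions
(cached per patient × dose); observations truth·10^(δ_patient + ε) with
ε ~ N(0, sd²) and an optional between-patient offset δ mimicking
patient-clustered residua. The default sd = 0.204 is the value whose
lognormal error alone reproduces an 86 % within-twofold fraction
(sd = log10 2 / z_(1+0.86)/2); zero-noise cohorts close the pipeline exactly
(MRD 1, MPE 0, bias 0).

What passing on synthetic cohorts shows — and what it does not: the
statistics, matching, stratification and plotting are verified end-to-end,
and the noise calibration behaves as designed; it says nothing about how
well the model captures real patients' dose–exposure relationship, drug–drug
interactions, adherence or assay error structure, none of which the
generator emulates.

## Agreement statistics

Signed deviation (C0_pred − C0_obs); residuum R = log10(C0_pred/C0_obs) with
twofold/threefold bands at |R| < 0.30/0.48; bias B = mean(C_obs − C_pred);
precision P = RMS(C_obs − C_pred); MRD = 10^RMS(log10 C_obs − log10 C_pred);
MPE = mean((C_pred − C_obs)/C_obs)·100. All RMS/variance terms use the
population (divide-by-n) form, matching the defining formulas; logs are
base 10 throughout (the 0.30/0.48 band constants force this). Stratification
is by patient or by body-weight-normalised dose in 0.25 mg/kg bins (no
published bin edges exist). Pairs missing either member are dropped with a
logged count. The signed deviation quartiles are reported as a signed IQR.

## Numerical and design choices, degenerate inputs

* t_MAX ties resolve to the earliest grid time; zero doses yield all-zero
  profiles and a zero trough without integration.
* The amount→plasma-concentration inversion is a closed-form quadratic,
  exact for compartments with one equilibrium binding site; negative solver
  excursions are clipped at zero before rate evaluation.
* Solver-tolerance halving changes AUC and C_MAX by < 0.5 %; dose scaling by
  10⁻³ in the first-order regime scales trajectories linearly within 1 %
  (P-gp saturates near K_M = 0.09 µmol/L, so "linear regime" means sub-mg
  doses).
* Test and cohort runs use reduced problem sizes — fewer synthetic patients
  with cached truths at the published observation counts (356; 1000 for
  noise-recovery) — chosen so the full suite exercises every pathway in a
  couple of minutes.

## Known limitations

* Anatomy is a generic reference table; the original model's (commercial)
  anatomy database is not published, so single-dose metrics are expected to
  agree to tens of percent, not exactly.
* No metabolite kinetics, lipoprotein-fraction dynamics, enterohepatic
  recirculation, drug–drug interactions or disease (CKD) physiology.
* The per-hour binding pools imply days-long tissue equilibration as
  printed; their contribution over 4-day protocols is minor.
* F_A/F_I are read at the end of the simulation window; late recirculation
  is corrected for via the mucosal-throughput definition but a small
  window-length sensitivity remains.
* Brain P-gp is included (toggleable in the compound file) but is of minor
  systemic importance.
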