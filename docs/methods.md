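# Methods

## Model structure

The body is represented by perfusion-limited, well-stirred compartments —
venous and arterial plasma, lung (in series with the full cardiac output),
heart, brain, muscle, adipose, skin, bone, liver (receiving hepatic
arterial flow plus the gut and spleen outflows), and a rest compartment —
connected by plasma flows.  Amounts are tracked in µmol, volumes in L and
time in minutes internally; the external interface uses mg, mg/L and
hours.

The kidney is mechanistic rather than perfusion-limited.  It comprises a
vascular plasma space, a lumped proximal-tubule-cell space and a tubular
lumen:

- filtration: `gfr_fraction · GFR · f_u · C_kidney-plasma` into the lumen;
- OAT3: saturable uptake of unbound drug from kidney plasma into the cell;
- NPT1: saturable efflux from cell to lumen;
- DPEP1: saturable metabolism inside the cell (to a metabolite sink);
- the lumen drains irreversibly to a urine sink with the filtrate flow
  (floored at 0.1 mL/min so severe oliguria stays defined).

There is no reabsorption and no passive tubular-cell permeability: drug
reaches the cell only through OAT3.  Elimination is exclusively renal
(urinary + DPEP1 metabolites), matching a drug whose non-renal clearance
is attributed to renal dehydropeptidase.  An optional dialyzer clearance
drains arterial plasma to a dialyzed sink during hemodialysis sessions.

All saturable processes use Michaelis–Menten kinetics with the Km and
Vmax values of the packaged parameter table.  Vmax (µmol/L/min) is
referenced to a per-process effective volume so that `Vmax·V_ref/Km` is
the linear-range intrinsic clearance.  A single shared reference volume
cannot reconcile the table's uptake:efflux Vmax ratio (≈ 315:1) with
finite cell concentrations, so the per-process volumes absorb the
tissue-expression scaling implicit in the source convention (uptake side
6.5 mL; cell side 0.47 L).  The Vmax values themselves — flagged as
optimized quantities in their source — are the calibration handles.

## Tissue distribution

Partition coefficients come from a composition-based scheme (neutral
lipid + 0.3·phospholipid partitioning at the olive-oil surrogate
10^logD(7.4), the remaining phospholipid behaving as water, and a small
plasma/tissue binding correction).  For strongly ionized hydrophilic
drugs (logD(7.4) < −1) the accessible aqueous space is restricted to
extracellular water plus a 20% slowly-equilibrating share of cell water.
That restriction reproduces the extracellular-like distribution of
β-lactams — measured muscle interstitium:plasma ratios around 0.25 and a
carbapenem steady-state volume near 0.27 L/kg (19.7 L for the reference
adult here) — which full-tissue-water schemes overestimate several-fold.
Coefficients are scale-free in organ volumes.

## Reference physiology and populations

The reference adult male (30 y, 176 cm, 73 kg, hematocrit 0.45, blood
cardiac output 6.5 L/min, eGFR 106.78 mL/min/1.73 m²) is shipped as a
documented table assembled from standard reference-man compilations;
organ flows are fractions of cardiac output and sum to it exactly, which
the ODE system relies on for mass conservation.  eGFR converts to
absolute GFR through the individual Du Bois body surface area.

Virtual individuals rescale volumes and flows linearly with body weight
(lognormal, CV 15% around 73 kg; height normal, SD 7 cm) and carry
multiplicative lognormal between-subject variability (default CV 30%,
mean-preserving) on each renal Vmax and on the distribution volume.  eGFR
is uniform within the assigned CKD stage interval (stage 3: 31–60,
stage 4: 16–30, stage 5: 1–15 mL/min/1.73 m²).  The variability model is
a documented stand-in chosen from standard pharmacometric practice; the
underlying study pipeline did not publish its distributions.

## CKD and hemodialysis scaling

Renal secretion follows the intact nephron hypothesis: the OAT3 and NPT1
activity multipliers are both scaled by `eGFR/106.78`.  DPEP1 activity
falls to 69% (stage 3) or 64% (stages 4–5).  Pathophysiology deltas are
deliberately minimal and exposed in code: kidney sub-volumes and renal
plasma flow shrink with the eGFR ratio (floored at 5%; the freed flow is
rerouted to the rest compartment so cardiac output is conserved), and
stage 5 adds 4 L of excess extracellular water in rapid equilibrium with
plasma, representing the interdialytic fluid gain of dialysis patients
(typically 2–4 kg); with it the end-stage distribution volume is 23.6 L
(0.32 L/kg), inside the 0.3–0.45 L/kg range reported for meropenem in
hemodialysis patients.

Dialyzer clearance uses the Michaels countercurrent relation with the
analytic limit `BFR·KoA/(KoA+BFR)` at equal flows.  The clearance is
applied to arterial blood entering the dialyzer with a documented
blood:plasma ratio of 1 (a drug residing in plasma/blood water with
f_u = 0.98).  Session schedules are explicit lists of start times; the
daily dose on a dialysis day starts at session start by default
(configurable offset), a choice flagged as influential because completing
the infusion before dialysis strips much of the dose.

## Calibration

The objective is the sum of squared log10 plasma-concentration residuals,
optionally plus log10 residuals on cumulative urinary amounts, plus a
weighted squared deviation of the simulated 24-h urinary excretion
fraction from the literature constraint of 0.70 (weight 50; evaluated on
the first dataset's design).  The search runs in log-parameter space:
seeded uniform random exploration (35% of the budget) followed by
Nelder–Mead refinement, with a smooth out-of-bounds penalty; every
simulation failure scores a large penalty and is counted.  Defaults:
budget 150–250 evaluations, Vmax bounds 0.2–5× the packaged values.

Identifiability: plasma kinetics pin the OAT3 uptake capacity but are
blind to the NPT1/DPEP1 split (drug leaving through either route has left
plasma); the urinary fraction identifies the split, and the cumulative
urine time-course at a high dose identifies the absolute NPT1/DPEP1
levels through the onset of NPT1 saturation.  On noise-free synthetic
data the fit recovers a perturbed Vmax triplet essentially exactly.  A
probenecid-style arm (OAT3 activity 0) isolates the filtration pathway —
its profile is insensitive to every transporter Vmax — so the
control/inhibited contrast separates secretion from filtration; it adds
no information about the intracellular split in this architecture.

## Pharmacodynamic evaluation

`fT>MIC` is the measure of the evaluation window in which free
concentration (f_u × total) strictly exceeds the MIC; crossings between
samples are located by linear interpolation (exactly, per segment, in the
reduced engine).  PTA is the percentage of subjects reaching the target
threshold (100% fT>MIC for CKD, 40% for IHD, following the respective
bactericidal-exposure conventions).  The IHD evaluation runs over the
first simulated week with Mon/Wed/Fri 4-h sessions; "on-dialysis" is the
24-h dosing day containing the mid-week session (48–72 h, so accumulation
history is included) and "off-dialysis" the following inter-dialytic day
(72–96 h).  A regimen is optimal at PTA ≥ 90%, preferring lowest total
daily dose, then fewest administrations, then shortest infusion; if none
qualifies the result is the explicit "no regimen attains target".

Large Monte-Carlo runs (n = 20,000) use a reduced per-subject simulation:
each subject collapses to one compartment with volume `V_p + Σ V_t·K_p`
and well-stirred renal clearance
`Q_k (CL_filt + CL_up)/(Q_k + CL_filt + CL_up)`, plus the dialyzer
clearance during sessions.  Concentrations are then piecewise
mono-exponential and time-above-MIC has a closed form, vectorized across
the population.  The surrogate tracks the full ODE model closely
(per-subject fT>MIC median deviation < 0.05 in the cross-check test);
it slightly underestimates dialysis-day attainment because it lacks the
post-dialysis redistribution rebound, making it conservative.

## Synthetic data

Because the observed clinical profiles behind the original qualification
are digitized from literature and cannot be shipped, a generator emulates
their structure: archetype simulations sampled on sparse grids
(0.25–24 h), multiplicative lognormal observation noise (CV 15%) and
±0.05 h digitization jitter, over healthy designs (500/1000 mg, 0.5/3-h
infusions), CKD stages 3–5 and two dialysis settings.  With noise off the
datasets equal model output exactly, so round-trip MRD = GMFE = 1.
Passing these tests demonstrates internal consistency of the pipeline,
not agreement with any real patient data; the generator reproduces the
sampling structure of digitized studies, not assay error correlation,
inter-study heterogeneity or real between-subject kinetics.

## Numerical choices

LSODA with rtol 1e-8 / atol 1e-10 µmol (population cross-checks use
1e-6/1e-8); integration restarts at every infusion and dialysis on/off
boundary; output on a 0.05-h grid plus all boundaries.  Mass balance
(body + urine + metabolites + dialyzed vs infused) holds to ~1e-14 and is
asserted below 1e-6 throughout.  Tiny negative solver excursions are
clipped at zero on output.  Cmax ties report the earliest time; the
terminal half-life regression window is the points after the last dose
end, or the final three points.  Problem sizes in the shipped drivers —
20,000 subjects for the IHD table, 5,000 per CKD stage, calibration
budgets of 150–250 evaluations — were chosen so each driver completes in
well under a minute while leaving Monte-Carlo error far below the
decision thresholds (saturated PTA cells vary by < 0.1 percentage point
across seeds).

## Known limitations

- Residual non-renal clearance in end-stage disease is under-predicted:
  DPEP1 sits strictly inside the tubule cell and is reached only through
  OAT3, so intact-nephron scaling suppresses metabolism along with
  secretion, and the off-dialysis half-life at eGFR ≤ 8 (≈ 20 h) exceeds
  clinical reports (≈ 7–10 h).  This shifts the borderline inter-dialytic
  PTA cells upward; dialysis-day cells, dominated by the dialyzer, are
  unaffected.  A passive tubular permeability path would restore the
  metabolic route but would break the structural property that zero OAT3
  activity plus zero GFR implies zero urinary flux.
- The terminal urinary fraction is not monotone in OAT3 activity: more
  uptake routes more drug through the cell where DPEP1 takes its share.
  Monotonicity holds for early-time cumulative urine and, at all times,
  with metabolism off.
- One virtual sex (male reference); no pediatric, pregnancy or
  covariate-correlation structure beyond weight–BSA.
- The reduced PTA engine is one-compartmental and linear; it is validated
  against the full model per-subject but does not capture distribution
  phases or transporter saturation at supratherapeutic doses.
- Stages are static snapshots; no disease progression, no continuous
  renal replacement therapies, no dialyzer adsorption/saturation.
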