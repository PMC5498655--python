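# Methods

## The disposition model

`irinosim` simulates the whole-body disposition of irinotecan (CPT-11) and
its four circulating metabolites — the active SN-38, its glucuronide
SN-38G, and the CYP3A-derived NPC and APC — after a 90-minute intravenous
infusion. Each compound has its own physiologically-based sub-model:

* **central blood** (volume `V_central`, a fitted apparent volume larger
  than blood volume),
* three perfusion-limited tissues (**muscle, skin, adipose**) with fixed
  tissue-to-blood partition coefficients,
* a **segregated-flow gut**: the portal flow is split into a serosal stream
  perfusing gut serosal tissue and a mucosal stream (default 80% of portal
  flow) perfusing a small mucosal-blood compartment that exchanges with the
  **enterocyte** across the basolateral membrane,
* a **liver** of five sequential units, each an extrahepatic (sinusoidal
  blood) / hepatocyte pair — the tanks-in-series surrogate of the
  dispersion model that captures permeability-limited hepatic uptake,
* three **bile transit compartments** in series carrying hepatocyte biliary
  output to the **intestinal lumen** (enterohepatic recirculation), and
* the lumen itself, with first-order absorption into the enterocyte
  (`k_a`), fecal loss (`k_feces`) and — for SN-38G only — bacterial
  deconjugation back to luminal SN-38 (`k_dec`).

Hepatocellular handling distinguishes sinusoidal active uptake
(`PS_act_inf_h`, OATP1B1; only SN-38 and SN-38G are substrates), passive
influx/efflux (`PS_dif_inf_h = PS_dif_eff_h`, a stated model assumption),
pathway-resolved metabolic clearance and biliary excretion. Apical
enterocyte efflux combines passive diffusion (basolateral passive clearance
scaled by the apical/basolateral area ratio AR = 20) with active transport
(ABCB1/ABCG2/ABCC2). Metabolite formed in hepatocyte unit *i* enters the
metabolite's hepatocyte unit *i*; enterocyte metabolism feeds the
metabolite's enterocyte compartment (co-localisation). Irinotecan's hepatic
metabolism splits into SN-38, NPC, APC and an "others" sink; SN-38 is
glucuronidated (fraction `f_glu` of its hepatic intrinsic elimination, with
`f_bile = 1 - f_glu`); SN-38G and APC are eliminated in bile only
(`f_bile = 1`). Back-conversion of NPC/APC to SN-38 by carboxylesterase is
structurally supported but defaults to zero clearance, since no parameters
constrain it. Renal elimination acts on central blood with the clearance
described below.

States are molar amounts (nmol), concentrations nM, time hours. Per-kg
clearances, flows and volumes scale linearly with body weight.

### Hybrid parameterization

Only certain combinations of the hepatic elementary clearances are
identifiable from plasma data (extended clearance concept). The package
converts losslessly between the elementary set and the hybrid set

    CL_int_all = (PS_act_inf_h + PS_dif_inf_h) (CL_met_h + CL_bile)
                 / (PS_dif_eff_h + CL_met_h + CL_bile)
    R_dif_h    = PS_dif_inf_h / PS_act_inf_h
    beta       = (CL_met_h + CL_bile) / (PS_dif_eff_h + CL_met_h + CL_bile)
    f_bile     = CL_bile / (CL_met_h + CL_bile)
    R_dif_ent  = AR PS_dif_eff_ent / PS_act_eff_ent

with explicit errors at the two degeneracies (`beta = 1` with non-zero
passive diffusion; `PS_dif = 0` with `beta < 1`). Round-trip identity holds
to 1e-10 relative and is property-tested.

### Numerical solution

Every transfer is first order, so the coupled 105-state system is linear
and time-invariant with a constant infusion input. The package therefore
offers two routes and tests their agreement:

* `IrinotecanPBPK.simulate()` — stiff ODE integration (LSODA, default
  rtol 1e-8 / atol 1e-10, default horizon 100 h) returning full
  trajectories plus cumulative urine/feces/metabolic sinks. Molar mass
  balance holds to integrator precision (measured ~1e-14 of dose).
* `IrinotecanPBPK.exposures()` — exact solution: AUC(0–∞) of every state
  from one linear solve (`-M^{-1} u T`), end-of-infusion amounts from one
  matrix exponential. This route costs ~3 ms per subject and powers the
  optimizer and the virtual studies, where 10^4–10^5 subjects are
  simulated.

An isolated compartment (possible in limiting configurations) makes the
rate matrix singular; a guarded least-squares solve accepts the
minimum-norm AUC only when it exactly satisfies the linear system,
otherwise a missing elimination route is reported.

Exposure metrics: plasma concentrations are blood concentrations scaled by
`f_b/f_p`; unbound plasma AUC uses `f_b` directly; enterocyte unbound AUC
uses `f_gut`; the biliary index is
`AUC_irinotecan x AUC_SN-38 / AUC_SN-38G` on total plasma AUCs. The
end-of-infusion SN-38 concentration is reported dose-normalized (nM/mg) so
genotype contrasts are invariant to the per-BSA dose.

## Cluster Newton method

The fitting data (a mean five-compound concentration–time profile)
under-determine the 46 unknown parameters, so the estimator is
multi-solution by design:

1. **Stage 1.** N parameter vectors are sampled log-uniformly inside the
   per-parameter ranges (ranges span 1–2 decades, so a log-uniform prior is
   scale-neutral; reciprocal quantities such as 1/beta are sampled on their
   tabulated 1.1–10 ranges). The residual is the log of each compound's
   plasma AUC against targets derived from the observed profile by
   trapezoid plus standard log-linear tail extrapolation. An affine
   surrogate `r ~ A x + b` is fitted across the cloud by least squares; each
   member moves by the minimum-norm Newton step `A dx = -r` plus a uniform
   random perturbation (default 5% of the log-range, decaying by 0.7 per
   iteration to a floor of 1%) that preserves cloud diversity; members are
   clamped to the ranges; failed members are resampled. Stage 1 stops at a
   median relative AUC error below 5% or after 10 iterations.
2. **Pooling and WSS ranking.** Independent clouds (different seeds) are
   pooled; the weighted sum of squared relative errors
   `WSS = sum (y - y')^2 / y^2` of each member's simulated profile against
   the observed points ranks the pool; ties resolve by batch then member
   index, so campaigns are reproducible.
3. **Elite local polish.** The best-WSS members are refined by the same
   surrogate machinery applied locally: a small cloud (default 55 points)
   in a shrinking trust region around the elite supplies a regression
   Jacobian of the log-concentration residuals, and damped Gauss–Newton
   steps (step halving, trust-region contraction by 0.6 on failure)
   descend the WSS. This is the desk-scale substitute for the profile
   agreement that pooling ~10^6 members buys at production scale; measured
   on the synthetic fixture it brings the best WSS from ~5 to below the
   10%-CV noise floor. No analytic gradients are used anywhere.

Stage 2 (member-wise refinement of the original method) is deliberately
omitted to avoid over-fitting. The campaign returns a results object whose
table lists each retained set (ID in ascending WSS) with all 46 parameters
on their conventional scales.

## Virtual patients

A patient is a fully resolved parameter set sampled around the population
means:

* **Genotypes** at six loci (UGT1A1\*28, SLCO1B1 c.521T>C and c.388A>G,
  ABCG2 c.421C>A, ABCB1 c.3435C>T, ABCC2 c.-24C>T) drawn independently
  under Hardy–Weinberg equilibrium. A locus scales each affected parameter
  by `(1 - c) + c a`, where `c` is the fraction of the process the protein
  carries (UGT1A1 100% of SN-38 glucuronidation, hepatic and enteric;
  SLCO1B1 100% of SN-38/SN-38G active uptake; ABCG2 33% of SN-38 biliary
  and apical efflux; ABCB1 50% irinotecan / 33% SN-38; ABCC2 50%
  irinotecan / 33% SN-38 / 100% SN-38G) and `a` the diplotype activity
  ratio (wild = 1). The convex combination is the natural reading of
  "contribution": a transporter carrying 33% of a flux, fully abolished,
  leaves 67%.
* **Reference correction.** The fitted SN-38 glucuronidation clearance
  represents a cohort recruited half *1/*1 and half *1/*28, so the
  wild-type base value is the fitted value divided by `(1 + a_het)/2`,
  applied once at population construction.
* **Body size.** BW ~ normal(78.8 kg, CV 11.7%); BSA from
  `4.688 BW^(0.8168 - 0.0154 log10 BW)` (BW in grams, BSA in cm^2) times
  multiplicative normal noise of CV 5.5%; the resulting BSA distribution
  (mean 1.97 m^2, CV 9.6%) is an acceptance check. The dose is
  180 mg/m^2 x BSA by default.
* **Binding.** `f_p = 1/(1 + n[Pt]/K_d)`; variability enters only through
  the protein concentration, with one draw per protein (AGP for the basic
  compounds irinotecan/NPC/APC, albumin for SN-38/SN-38G) shared among its
  compounds. Blood unbound fraction
  `f_b = f_p / (1 - (1 - f_p/f_r) Hct)`; SN-38G does not enter blood cells,
  so `f_b = f_p/(1 - Hct)`.
* **Renal clearance.** `CL_r = f_b GFR + CL_sec` with dispersion-model
  secretion (dispersion number 0.17) bounded by the tubular blood flow
  `Q_rtb = GFR/FF/(1 - Hct) - GFR`. The intrinsic secretion clearance
  varies with CV 34.2% (lognormal) for all compounds except SN-38G, whose
  minor secretory route is held fixed.
* **Kinetic variability.** Each elementary parameter is perturbed
  multiplicatively (lognormal, mean 1) with its configured CV; the two
  passive-symmetry constraints are re-imposed after sampling. Normal draws
  (BW, Hct, GFR, FF) are truncated at ±4 SD and at zero by resampling.

## Virtual clinical studies

One replicate generates `n` patients (default 127), simulates each, and:

* flags the `n_neutropenia` (21) highest unbound plasma SN-38 AUCs as
  neutropenia and the `n_diarrhea` (8) highest unbound enterocyte SN-38
  AUCs as diarrhea (ties broken by patient index; counts scale as
  `round(k n/127)` for other population sizes);
* Welch-tests (Bonferroni within locus, two pairwise comparisons) the
  dose-normalized SN-38 end-of-infusion concentration against UGT1A1*28
  and SLCO1B1 521 diplotypes, in linear scale by default (log optional);
* Fisher-exact-tests each side effect against each locus under dominant
  and recessive codings;
* Wilcoxon rank-sum-tests the biliary index against diarrhea (exact for
  group sizes <= 25, tie-corrected normal approximation otherwise).

A test with an empty or single-member comparison group is "not evaluable"
and counts as non-significant — the conservative choice. By default an
association counts as reproduced only when significant *and* in the
clinically expected direction (variant/higher-index groups higher);
significance-only counting is available (`require_direction=False`).
Replicate `r` uses seed `base + r`, recorded per replicate.

Aggregation over replicates yields significance counts per association,
the seven reproduction criteria (thresholds 75/75/75/25/25/25/25 of 100,
scaled proportionally for other replicate counts; a set "reproduces" the
reference findings when >= 5 of 7 hold), the population-size sweep of
reproduction frequency (the Monte-Carlo analogue of power), and streaming
large-population side-effect probabilities at fixed exposure thresholds.

## The synthetic fixture

All study inputs regenerate programmatically. The search ranges of the 46
unknowns and the genotype contribution fractions are the established
values for this model class; the
base ("truth") parameter set, allele frequencies, activity ratios,
variability CVs/shapes, binding constants, partition coefficients and
fixed physiology are package-chosen placeholders at literature-typical
magnitudes, exported with `provenance: placeholder` and overridable through
the YAML interface without code changes. The base set was chosen inside
every search range to give the clinically observed exposure ordering
(irinotecan >> APC > SN-38G > SN-38 ~ NPC) and plausible absolute SN-38
exposure; this is a fixture property, not a fitted result.

Two deliberate features of the base configuration shape the intestinal
toxicity phenotype. First, enterocyte SN-38 arises chiefly from in-situ
carboxylesterase conversion of irinotecan delivered across the basolateral
membrane from mucosal blood, with smaller contributions from luminal
absorption of biliary SN-38 and from luminal deconjugation of SN-38G
(`k_dec` modest). Enterocyte exposure therefore tracks the systemic
quantities the biliary index integrates — irinotecan exposure and the
SN-38/SN-38G conjugation balance — which is what makes the continuous
index a stronger diarrhea marker than any single genotype dichotomy in
this configuration, reproducing the qualitative marker ordering seen
clinically. Second, inter-individual CVs are 30% for hepatic
uptake/biliary clearances and binding, but 15% for intestinal rate
constants and metabolic clearances; large independent intestinal noise
would decouple enterocyte exposure from every systemic marker and is not
supported by the clinical behaviour of the index. Reference
profiles multiply the simulated truth by mean-1 lognormal noise, so the
expected WSS of truth against its own observations is ~ n_points x CV^2 —
the "noise floor" used in the optimizer checks.

Because the placeholder tables are not the original ones, passing tests
demonstrate that the machinery (model structure, optimizer, population
generator, statistics) behaves correctly under realistic conditions; they
do not certify the clinical parameter values themselves. A user supplying
the original supplementary tables gets the calibrated behaviour through
the same interfaces.

## Problem sizes and numerical choices

Default test/acceptance scales: Cluster-Newton campaigns run 2 batches x
300–500 members with 2–4 refined elites (production scale: 100 x 10,000
with a 10^6-member pool); virtual studies run 40–100 replicates; the
large-population probability estimate streams 2 x 10^4 patients in chunks.
The stiff solver uses rtol 1e-8 / atol 1e-10; the exact route has no
tolerance. Not-evaluable statistics propagate as NaN and never count as
significant. Known limitations: no linkage disequilibrium between the two
SLCO1B1 sites; single-compartment lumen (no segmental geometry); no
pharmacodynamic neutrophil model; Kp and tissue unbound fractions are
config inputs, not predicted from structure.
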