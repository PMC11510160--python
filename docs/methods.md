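# Methods

## Scope and model structure

`oxypbpk` implements a minimal parent–metabolite PBPK model of cholesterol
and 4β-hydroxycholesterol (4β-OHC) for evaluating hepatic CYP3A induction.
Each analyte occupies a single well-mixed systemic compartment of volume
V_ss × body weight; the liver is not a separate kinetic compartment (liver
concentrations are reported through K_p). This is justified by the low
distribution volumes involved (0.10 and 0.05 L/kg) and by the fact that all
quantities of interest are steady-state plasma levels and their ratios, for
which distribution kinetics are marginal.

Hepatic elimination uses the well-stirred model,
CL_H = Q_H·fu_p·CLuint / (Q_H + fu_p·CLuint/(B/P)), with CLuint the sum of
the compound's scaled pathway intrinsic clearances. Competing pathways share
the extraction in proportion to their scaled CLint; the CYP3A
(CYP3A4/5/7) share of cholesterol elimination forms 4β-OHC with mass
conversion by the molecular-weight ratio 402.35/386.65. 4β-OHC itself is
cleared by CYP27A1 and an aggregate microsomal (HLM) pathway; the HLM
pathway stands in for CYP7A1, whose hepatic abundance is not available, so
CYP7A1 regulation (e.g. its suppression by rifampicin) is out of scope.
Intestinal CYP3A is omitted: its contribution to plasma 4β-OHC is negligible.

## Units and scaling

Internal units are h, L, mg, pmol. In vitro intrinsic clearances are carried
as µL/min/pmol enzyme (CYP pathways) or µL/min/mg microsomal protein (HLM)
and scaled to whole-liver L/h by liver weight (1737.11 g) × MPPGL
(39.79 mg/g) × abundance, with the exact factor 60/10⁶. The unit round-trip
is tested to 1e-12 relative.

## Reverse translation

The clearance chain runs: t½ → CLiv (0.693·V_ss·W/t½) → CLmet,H (well-stirred
inversion) → per-pathway split by fm → per-enzyme CLint. Inputs: cholesterol
t½ 46.05 d, V_ss 0.1 L/kg; 4β-OHC t½ 62 h, V_ss 0.05 L/kg; fu_p 0.0021 /
0.0051; B/P 0.55; Q_H 90 L/h. The body weights behind the published worked
values are not stated beyond "average subject weight"; the defaults here are
back-derived — **67.5 kg** for the cholesterol-side chain and **63.5 kg**
for the 4β-OHC side — so that the chain reproduces every printed elimination
entry within 2%. Both are prominently configurable and all translated
clearances scale linearly with W. Because both analytes are very
low-extraction, the results are insensitive to Q_H over 80–100 L/h
(tested: < 0.1%).

The residual HLM fraction is computed as fm_HLM = 1 − (fm_CYP27A1 +
fm_CYP3A), the only reading consistent with mass balance and with the
published HLM value. The initial CYP3A fraction (2.1 × 10⁻⁵) is attributed
entirely to CYP3A4; the CYP3A5/CYP3A7 sibling split (5.6% / 2.8% of the
CYP3A total) is applied only to the optimized CLint of 4.17 × 10⁻⁷
µL/min/pmol, which reproduces the published sibling values and the
back-calculated fm_CYP3A4 of 1.17 × 10⁻⁴.

## Induction and inhibition

CYP3A activity is one relative level E(t) shared by CYP3A4/5/7 (perpetrator
induction parameters are shared across the isoforms; CYP3A7's inclusion is a
package choice, numerically negligible). Turnover is dE/dt = k_deg(F − E)
with k_deg defaulting to 0.0193 h⁻¹ (≈36 h half-life, the conventional
hepatic CYP3A value; the source analysis ran induction inside a commercial
simulator and does not print k_deg). F is the Emax fold
1 + (Ind_max − 1)·C_u/(IndC50 + C_u) of unbound liver perpetrator exposure;
rifampicin uses Ind_max 16, IndC50 0.32 µM. Competitive inhibition divides
the CYP3A intrinsic clearances by (1 + C_u/K_i) without turnover lag.
CYP27A1 and HLM are never induced.

Perpetrator PK is one compartment with first-order absorption; unbound liver
exposure is fu × K_p,liver × plasma concentration. The shipped rifampicin
PK values (ka 1 h⁻¹, V/F 53 L, CL/F 7 L/h, fu 0.15) are literature-informed
conveniences, not model ground truth. For population protocols the default
"analytic" route converts the perpetrator's steady-state dosing cycle into a
**cycle-averaged** activity factor: because turnover is linear in the fold
signal, the cycle-mean enzyme level equals the cycle-mean fold, so averaging
the Emax fold over the closed-form multiple-dose concentration profile
matches the dynamic ODE route (tested to 5%), whereas evaluating the fold at
the average concentration would overstate induction for this saturating
curve.

## Numerics

The coupled ODEs (parent, metabolite, enzyme level, perpetrator PK, plus
cumulative-mass bookkeeping states) are integrated with LSODA at rtol 1e-8 /
atol 1e-12, piecewise between dosing discontinuities. A 700-day baseline run
takes ~20 ms per subject. Steady-state summaries average the last 30 days of
the relevant phase; against the closed form the ODE route agrees to < 0.5%
once the horizon covers ≥ 25 parent half-lives (sampled individuals with low
MPPGL can have multi-month cholesterol half-lives, so the fixed 700-day
horizon is not asymptotic for every subject). Mass balance holds to
integrator tolerance. The post-perturbation half-life estimator regresses
log lagged-differences |C(t) − C(t+Δ)|, which cancels the unknown asymptote
exactly for a single exponential phase, on the tail of the relaxation.

Calibration of CLint,CYP3A4 to a baseline 4β-OHC target is a bracketed root
search in log space; siblings stay tied by their percentages and the HLM
pathway is rebalanced so total parent CLmet,H is preserved, which makes the
objective strictly monotone. The retrograde genotype calculation solves, by
bracketed root search on CYP3A4 abundance, for the abundance at which a
CYP3A4/CYP3A5 probe substrate's forward well-stirred hepatic clearance falls
by the stated fraction (20% / 50%). The published genotype abundances
(100.86 / 51.27 pmol/mg) are not jointly consistent with a single linear
CYP3A4 share, so the default probe (CYP3A4 CLint 0.3, CYP3A5 0.076
µL/min/pmol; share ≈0.84 with moderate extraction at the 137/103 pmol/mg
reference) was chosen to recover both within ~2%; the probe is fully
configurable.

## Virtual populations

Templates hold lognormal distributions (mean, CV) for body weight, liver
weight, MPPGL, hepatic blood flow, hematocrit and enzyme abundances —
lognormal because these are strictly positive and that is the standard
convention. Published values shipped: CYP3A4 137 pmol/mg CV 41%
(Caucasian-like), +24% multiplicative shift in females, genotype means
100.86 / 51.27 (CV 41% retained), RA overrides (CYP3A4 82.07 pmol/mg,
cardiac output ×1.05, hematocrit ×0.83), CYP3A5
extensive-metabolizer frequency 0.48 (Asian-like) vs 0.17 (Caucasian-like),
and a 16%-lower CYP3A4 mean for the Asian-like template. Everything else
(weight/liver/MPPGL/Q_H CVs, CYP3A5 abundance per phenotype, CYP3A7 mean) is
a documented placeholder: the underlying population library is proprietary.
The CYP3A5 expresser mean of 103 pmol/mg was set once so the simulated
EM/PM baseline ratio (≈1.05) falls inside the reported 1.04–1.13 range; it
is not an authoritative abundance.

All sampling is driven by spawned `numpy` SeedSequences, so every stochastic
result is bit-reproducible from (seed, design).

## Synthetic data

The study-table generator emulates the meta-analysis input structure:
per-study n uniform in 20–200, study means lognormal around the true mean
(29.85 ng/mL) with between-study SD 4.5 ng/mL, per-study SD from a
within-study CV of 45%, optional strata with multiplicative mean shifts
(e.g. 1.31× for females). The variance split was chosen so the pooled SD
lands near the reported ≈14.9 ng/mL overall scale (√(13.4² + 4.5²) ≈ 14.2);
it is a modelling choice, since only the pooled summary is public. Observed
profiles and calibration fixtures add mean-preserving multiplicative
lognormal noise. Passing tests on these fixtures demonstrate that the
pipeline recovers known generating truths under idealized noise; they cannot
show robustness to real-data pathologies (reporting heterogeneity, assay
bias, non-lognormal outliers).

## Statistics

The pooled SD combines within-study variance and the n-weighted dispersion
of study means (law of total variance), equal to the variance of the
concatenated pseudo-sample; whether the original pooling included the
between-study component is not stated, so a within-only mode is provided.
AFE = 10^mean(log10 P/O) and AAFE = 10^mean(|log10 P/O|). Guest limits use
L = (δ + 2(R′−1))/R′ with R′ = max(R, 1/R) and δ defaulting to 1.25.

## Known limitations

- Absolute predicted concentrations (≈1.16 mg/mL cholesterol, ≈17 ng/mL
  4β-OHC at 1.73 mg/kg/day) sit below typical clinical means (~1.7 mg/mL,
  ~26 ng/mL): the full plasma-binding treatment (apolipoprotein B reference
  concentration) of the original implementation is not public. Fold-changes
  — the quantities this package asserts — are insensitive to this scale.
- The post-induction 4β-OHC recovery half-life from this linear cascade
  (days) is shorter than the reported 23.81 ± 5.32 days; the mechanism
  behind the longer value is not printed, so the estimator reports without
  asserting it.
- No CYP7A1 mechanism, no cholesterol feedback, no intestinal CYP3A, no
  ontogeny/pediatrics; predicted population variability is wider than
  clinically observed because homeostatic regulation is absent.
- The six clinical rifampicin verification studies and non-Caucasian system
  parameters live in a proprietary appendix/library; the verification
  *workflow* (DDI protocol, AFE/AAFE/Guest scoring) is provided and
  exercised on synthetic stand-ins instead.
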