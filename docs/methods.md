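# Methods

This note documents the models, estimators and numerical choices behind
`qivive`, in the order the pipeline runs them.

## Kinetic model

PFOA kinetics in an adult human are described by an eight-compartment
flow-limited model: stomach, intestinal lumen, liver, plasma (central),
rest of body, kidney tissue, kidney filtrate and proximal tubule cells
(PTC).  All amounts are µg, volumes L, time h.

Routing: oral input enters the stomach; the stomach empties to the
intestinal lumen (GEC) and absorbs directly to the liver (K0C); the lumen
absorbs to the liver (Kabsc) or is lost to faeces (Kunabsc); bile (KbileC,
acting on the liver amount) returns to the lumen, closing the
enterohepatic loop.  Tissue exchange is driven by the free plasma
concentration with partition coefficients defined on totals,

    flux_t = Q_t · Free · (CA − C_t/P_t),

so at steady state C_t → P_t · CA.  We use this form (free fraction on
both directions of the gradient) rather than applying `Free` to uptake
only: with liver:blood partitioning near 1 it makes the steady-state liver
concentration track the serum concentration, which is the regime in which
liver-targeted reverse dosimetry of hundreds of µg/L is attainable from
µg/L-range drinking water; the alternative convention would cap liver
concentrations near `Free·CA` (~2% of serum) and could not reproduce that
regime.

Renal handling: glomerular filtration moves `GFR·Free·CA` into the
filtrate (GFR scales with kidney mass at density 1 kg/L); filtrate drains
to urine (KurineC) or is reabsorbed into PTC by a saturable apical
transporter (Michaelis–Menten in the filtrate concentration); a
basolateral transporter moves free plasma PFOA into PTC; PTC loses to
plasma by first-order efflux (Keffluxc) and back to filtrate by passive
diffusion (Kdif, L/h, acting on the PTC concentration).  Near-complete
tubular reabsorption is what produces the multi-year human half-life; the
model's apparent half-life at central parameters is ~2 years, within the
reported 2–5-year range for humans, and knocking the transporters out
collapses the steady-state serum concentration (a directional test).

Scaling: plasma flow `QC = QCC·BW^0.75·(1−Htc)` (the single blood↔plasma
conversion); first-order rates scale as `kC·BW^−0.25`; transporter
capacities convert from pmol/mg protein/min via the total PTC protein
mass, 60 min/h and the molar mass 414.07 g/mol.  Two constants the
parameter tables do not pin down are config-exposed: the PTC cell density
(default 6×10⁷ cells/g kidney, needed by the per-cell protein content) and
the perfused fraction of body weight closing the volume balance (default
0.93).  Kvoid (daily urine volume) is carried for urine-concentration
output only.

### Numerics

Transient simulation uses LSODA at rtol 1e-6 / atol 1e-9 µg with
integration restarted at forcing discontinuities.  Three forcing modes:
`daily_average` (water dose spread over 24 h — one smooth solve),
`events` (four 15-min drinking events per day resolved exactly) and
`hybrid` (averaged outside a window, events inside).  Resolving every
event over the full 120,100 h horizon would mean ~40,000 integration
segments; the hybrid mode exists so the within-day sawtooth can be studied
at steady state at a reasonable cost.  The dose metric (trapezoidal AUC
over a window divided by its width) changes by <1% under event-phase
shifts and <0.1% under output-grid refinement.

Mass balance — cumulative input minus (stored + eliminated) — closes to
~1e-12 relative, checked against 1e-6 in tests across prior-supported
draws.

### Fast mode: algebraic steady state

Sensitivity analysis, calibration and ABC need ~10⁵–10⁶ dose-metric
evaluations.  Under daily-averaged forcing the 100,000–120,000 h window
average is, to within the residual approach to steady state (<2%, verified
against the transient integrator), the steady state itself — which this
package computes algebraically: given a trial plasma concentration CA, the
stomach/gut/liver subsystem is linear (2×2 solve), the filtrate/PTC
subsystem reduces to one quadratic (the apical Michaelis–Menten term is
the only nonlinearity), and total elimination is monotone in CA, so a
bracketed 1-D root (Brent) finishes the job in ~0.05 ms.  This replaces a
coarse-tolerance ODE fast mode: it is faster and exact rather than
approximate at the window of interest.

## Priors

34 parameters with truncated normal, truncated lognormal or uniform
priors.  Lognormal rows are specified on the natural-log scale (location
4.36 for body weight means a median of exp(4.36) = 78.3 kg); the
convention is validated by the published prior summary for body weight.
Truncation is by inverse-CDF restriction — deterministic, exact at the
bounds, no rejection loops.  Each parameter draws from its own stream,
derived from the root seed by hashing the parameter name, so extending the
roster never shifts existing draws.  A `loguniform` family (uniform in log
space) is available for search priors.

Two cells of the published prior-summary table are inconsistent with this
convention even though every other cell matches within 2%: the plasma
unbound fraction's 2.5th percentile (printed 0.0106, which equals the
*untruncated* 2.5th percentile exp(lower bound); the truncated value is
0.0117) and the apical RAF's 97.5th percentile (printed 0.0012 =
exp(upper bound); truncated value 0.00109).  Tests check the 28
self-consistent cells.

Physiological closure: rest-of-body flow fraction = 1 − QLC − QKC;
rest-of-body volume fraction = 0.93 − (liver + kidney + plasma + filtrate
fractions).  Draws violating positivity raise a typed error signalling
resampling (within the tabulated bounds this cannot occur).

## Global sensitivity analysis

**Morris.**  Randomised one-at-a-time trajectories on a 4-level unit-cube
grid (step Δ = levels/(2(levels−1))), 10 trajectories by default, mapped
through the prior inverse CDFs; elementary effects are normalised by Δ.
Because single screens are noisy, the screen repeats 6 times and the
consensus rank is the per-parameter mode of ranks, ties broken by mean
rank.  The retained set defaults to the top 13; a `mu_star >= frac·max`
rule is available.  On the PFOA model both dose metrics put the exposure
parameters (ExposedDW, DWtotal) and the renal-clearance cluster
(Vmax_apical, RAFapi, Protein, Free, GFRC, KurineC, VfilC) in the top
ranks.  Body weight ranks lower here than one might expect: its effect on
a *concentration* metric partially cancels (intake/BW against volumes×BW).

**eFAST.**  Each parameter in turn is driven at frequency
ω ≈ (N−1)/(2M) along the interference search curve
x = 0.5 + arcsin(sin(ωs+φ))/π with random phases, the others spread over
[1, ω/(2M)].  First-order indices sum spectral power at pω (p ≤ M = 4);
total-order indices subtract the complementary band [1, ω/2].  One
non-standard refinement: the triangular search curve has slowly decaying
harmonics beyond order M, which alias across the Nyquist bin and, for
unlucky (N, ω) pairs, land exactly on the measured harmonics (e.g. N=2001,
ω=250: 8ω ≡ −1, 6ω → 501).  The driving frequency is therefore chosen as
the largest value below the ceiling whose aliases keep clear of the
measured bins.  With this choice the Ishigami first-order indices are
reproduced within 0.007 at N=2000.  The total-order estimator retains the
known small positive bias (~0.03 on the Ishigami x2 at this N) caused by
complementary-interaction energy above the band cutoff; first-order
indices are the quantity tested tightly.

## Calibration

Lognormal error model: observed serum y at prediction m(θ) contributes
log LN(y | log m, σ).  The error SD σ is estimated jointly under a
half-normal(1) prior.  The sampler is component-wise Metropolis on each
parameter's internal scale (log for lognormals), step sizes adapted every
50 iterations toward 20–40% acceptance during the first-half burn-in.
Because the transporter capacity enters only as the product
Vmax·RAF·Protein, the posterior has ridge directions; each sweep therefore
adds one joint multivariate-normal move whose covariance is adapted from
the burn-in history (frozen afterwards, preserving detailed balance).
Convergence is split-chain Gelman–Rubin; the recovery experiment (4 chains
× 3,000 iterations, 30 synthetic observations) gives R̂ < 1.1 and medians
within 20% of truth for the identifiable clearance parameters.

The calibrated subset defaults to the ten-parameter roster (BW,
Vmax_apical, VfilC, Free, PR, Protein, RAFapi, GFRC, KurineC, PL); the
list is a config entry, so the nine-parameter variant without PL is one
edit away.  The "mode fit" is the highest-log-posterior retained draw
(joint mode), not per-parameter marginal modes.  Credible bands are
pointwise empirical 2.5/97.5 percentiles of predicted curves over retained
draws.  CSAFs are empirical 95th/50th percentile quotients.

## Reverse dosimetry (two-stage ABC)

Accepting simulations within a relative tolerance of the target — rather
than matching it exactly — encodes a finite degree of belief in the
kinetic model.  Phase 1 draws 500 parameter sets (calibrated parameters:
uniform over their posterior 95% intervals; DWtotal: its population
prior), keeps those within ±7.5% of the target, and computes the retained
covariance on the log scale.  Phase 2 runs 4 ABC-MCMC chains × 2,500
iterations from random phase-1 survivors, with multivariate-normal
proposals scaled 2.4/√d on the transformed scale; a move must be
prior-supported (Metropolis prior ratio with the transform Jacobian) *and*
within ±5%.  Chains are pooled after a 10% burn-in; both tolerance
predicates are hard filters holding for 100% of retained samples by
construction.

ExposedDW, the unknown of interest, cannot keep its population prior
(1.9–6.0 µg/L), which does not span the exposures implied by most targets.
It instead gets a log-uniform prior scaled to the target:
[target/600, target/15] µg/L, bracketing the plausible steady-state
concentration-to-water ratio (~40–120 across the population priors) with
an order-of-magnitude margin either side; explicit bounds are accepted
wherever the default is wrong.  If a rejection batch retains fewer than 5
samples, additional batches are drawn (up to 10) before the run aborts
with guidance to widen the prior.

Intake (ng/kg BW/day) = ExposedDW·DWtotal/BW per retained sample (µg/L ×
L/day ÷ kg = µg/kg/day, ×1000).  Per-target summaries are the Gaussian-KDE
mode computed on the log scale (Silverman bandwidth, back-transformed —
the posteriors are right-skewed) plus empirical 2.5/97.5 percentiles.

## Benchmark dose

Candidate models: exp1 y=a; exp2 a·e^{bx}; exp3 a·e^{bx^d};
exp4 a(c−(c−1)e^{−bx}); exp5 a(c−(c−1)e^{−bx^d}); hill
a(1+(c−1)x^d/(k^d+x^d)).  Responses are lognormal, so fitting is
least-squares on log responses (multi-start Nelder–Mead; σ profiled out).
BMD: the dose with a 5% relative change from the fitted background, in
closed form per family where possible, bracketed otherwise; the direction
follows the data trend.  BMDL/BMDU: profile likelihood with the BMD pinned
(the rate parameter is eliminated analytically per family, remaining
nuisance parameters re-optimised), bound where the deviance rises by
χ²₁(0.90) = 2.71, giving one-sided 95% bounds.  Coverage is verified by
simulation: over 200 noisy replicates the BMDL falls below the true BMD in
≥90%.

Selection: a model is adequate if its log-likelihood is within the
likelihood-ratio χ² criterion of the best candidate and its AIC is within
2 of the minimum; if the flat model is itself adequate the verdict is "no
dose-response"; otherwise the lowest BMDL among adequate models is
selected (the conservative rule).  The extrapolated table has a single
fold-induction per concentration, so the residual SD is profile-estimated
from those few points — a flagged limitation, not a substitute for
replicate-level data.  Credible intervals on the BMDL come from refitting
the lower/upper-bound dose vectors, not bootstrapping.

Adjustments: BMDL/CSAF (kinetic CSAF 1.4 from the transporter posterior
quantile ratio) or BMDL/10 (default kinetic+dynamic factor); reference
comparisons are plain ratios or fold-differences.

## Synthetic data

The generators emulate the pipeline's two external inputs.  Biomonitoring:
three exposure groups at 0.04, 1.0 and 4.9 µg/L drinking water (the
community water-district levels), observations = steady-state serum at a
known truth vector × lognormal noise (log-SD 0.3, the scatter typical of
cross-sectional serum data), sampled at times inside the quasi-steady-state
window.  In vitro: Hill curves (baseline 1, top 3, AC50 50 µg/L free,
slope 1.5, 5% CV multiplicative noise) on the assays' free-concentration
grids — seven points for the hepatocyte (CL-targeted) design, four for the
endothelial (CA-targeted) one.  A toy surrogate metric
ExposedDW·DWtotal·k/(BW·CL_eff) with a closed-form inverse validates the
ABC and GSA estimators analytically.

What passing these tests shows: the estimators are correct on data whose
generating process is known.  What it does not show: robustness to
inter-individual kinetic variability (observations share one truth
vector), assay artifacts (cytotoxicity, fluorescence interference), or
model-structure error beyond the ABC tolerance band.

## Problem sizes

Defaults are the study-scale settings: 10⁶ prior draws for summaries,
Morris 10 trajectories × 6 repeats, eFAST N=1041/M=4 per parameter,
calibration 4×3,000 (recovery experiment), ABC 500 + 4×2,500 per target.
The algebraic steady-state evaluator makes all of these run in seconds to
a few minutes on one core; the end-to-end test therefore keeps study-scale
ABC rather than a scaled-down variant (at 4×250 iterations the KDE mode of
ExposedDW is noisy enough that adjacent targets can cross — an estimator
artifact, not a property of the method).

## Known limitations

- Single population-level parameter vector: no hierarchical
  inter-individual effects.
- The bile-routing, diffusion-direction, PTC cell density and
  perfused-fraction choices follow the minimal structure consistent with
  the parameter roster; all four are config-exposed.
- 2.3% in vitro bioavailability is a log-P-based estimate ignoring
  solubility and ionisation.
- The serum:water concentration ratio at central parameters (~45) sits at
  the low end of the reported community ranges; reverse-dosimetry outputs
  scale accordingly.
- Dermal/inhalation routes, metabolism and gestational transfer are out of
  scope.
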