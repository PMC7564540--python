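# Methods

## Model

`epibalance` treats the methylation state of a genomic region with N CpG
sites, observed across a large population of cells, as the stationary state
of a continuous-time birth–death Markov chain over methylation classes
n ∈ {0, …, N} (n = number of methylated sites on a molecule). Transitions
occur only between adjacent classes — single-site gain or loss; simultaneous
multi-site flips have rate zero, which is the process actually solved by the
detailed-balance recursion. Per-site rates are mean-field and linear in the
molecule's own state:

- methylation: P_n = P + α·n (each of the N−n unmethylated sites),
- demethylation: Q_n = Q + β·(N−n) (each of the n methylated sites).

P and Q are configuration-independent rates; α and β couple a site's rate to
the number of methylated (resp. unmethylated) sites on the same molecule.
Site identity is ignored (the model is site-exchangeable); per-site rate
heterogeneity, hydroxymethylation intermediates and out-of-equilibrium
dynamics are outside the model.

The stationary distribution follows from detailed balance,
C_n (N−n) P_n = C_{n+1}(n+1) Q_{n+1}, giving the weight recursion
w_{n+1} = w_n (N−n)P_n / ((n+1)Q_{n+1}) with w_0 = 1, then normalisation.
The recursion is accumulated in log space so extreme rate ratios or large N
cannot overflow; at N ≤ 10 this is numerically indistinguishable from the
direct product. If some class has zero demethylation rate but nonzero
inbound flux the chain has an absorbing boundary and no finite equilibrium;
this is reported as an error. (Parameter sets with q + β = 0 are allowed at
the type level because they are legitimate inputs for trajectory
simulations of absorbing dynamics.)

Key structural facts used throughout:

- α = β = 0 gives exactly Binomial(N, P/(P+Q));
- the stationary law depends only on rate ratios (scale invariance), so a
  common rescaling of (P, α, Q, β) is unidentifiable from distribution data;
- the flux ratio r_n = (N−n)P_n/((n+1)Q_{n+1}) equals C_{n+1}/C_n, so the
  distribution rises where r_n > 1 and falls where r_n < 1; one crossing
  direction yields a unimodal law, a fall-then-rise profile yields two modes
  (the bimodal regime). Mode detection compares r_n to 1 with a relative
  tolerance of 1e−9, and plateaus are assigned to the lower class index —
  a deterministic tie-break for parameter sets where r_n is algebraically 1.

## Data model and class counting

An epiallele matrix holds one binary site-state vector per sequenced
molecule. Reads with characters outside {0,1} (ambiguous or missing site
calls) are rejected at parse time rather than imputed: silent imputation
would bias class counts, and upstream quality control is out of scope.
Sites are indexed 1-based, 5′→3′ along the amplicon. Class counting is a
histogram of per-read methylated-site counts; condition distributions
average replicate frequencies with the standard error convention
σ_n = SD(sample, m−1 denominator)/√m over the m individuals (σ = 0 for
m = 1).

## Fitting

The chi-square objective L = Σ (D_n − C_n)²/max(σ_n, σ_floor)² is minimised
over the non-negative orthant intersected with the gauge constraint
P + α + Q + β = 1. The flat scale direction makes an unconstrained
4-parameter fit degenerate; the simplex gauge removes it exactly. Internally
the optimiser works on three free logits mapped through a softmax onto the
simplex (smooth and unconstrained), with Nelder–Mead local search from 16
seeded Dirichlet(1,1,1,1) starts plus a restarted-simplex polish;
convergence is declared when the two best restarts agree in L within 1e−10.
Multi-start matters in the bimodal regime, where the likelihood can have
local minima.

- σ_floor defaults to 1e−3 (frequency scale): it only guards classes where
  all replicates coincide and σ_n = 0.
- Degrees of freedom for the reduced chi-square are (N+1) − 4, counting the
  four named parameters even though only three directions are identifiable
  after gauge fixing; this convention is flagged here deliberately.
- 68% half-widths come from the Gaussian approximation of the likelihood
  exp(−L/2): covariance = inverse of ½·Hessian of L, with the Hessian
  computed by central differences (step 1e−5) along an orthonormal basis of
  the sum-zero tangent space of the simplex. Evaluations that step a
  boundary parameter slightly negative clip it at 0. A singular constrained
  Hessian yields +∞ half-widths and a warning flag. The 2σ significance
  flags apply to the gauge-fixed parameters and are convention-dependent.
- Ratio intervals (α/P, β/Q) use first-order error propagation from the
  parameter covariance; near-zero denominators report +∞.
- The objective contains no Poisson/multinomial sampling term: replicate
  scatter is assumed to dominate counting noise at the read depths modeled.

## Pattern classification

Peaks are local maxima of D_n with frequency ≥ `min_peak` (default 0.05);
adjacent peaks are kept separate only if the valley between them drops at
least `min_valley_drop` (default 0.2) times the smaller peak below it.
One surviving peak below N/2 → A, above N/2 → B; two peaks → C; more than
two → "unresolved" (an explicit label, not an error). A single peak exactly
at N/2 is resolved by comparing the mass below and above, tie → A. The
defaults were chosen so the three canonical shapes (monotone-low,
monotone-high, two-peaked) classify as A, B and C; they are exposed on the
CLI and the API.

## Rank-sum comparison

`rank_sum_test` reports the first-sample Mann–Whitney U (pairs with
x_i > y_j plus ½ per tie — the statistic R's `wilcox.test` calls W), with an
exact two-sided p-value when n₁·n₂ ≤ 400 and there are no ties, otherwise
the normal approximation with tie correction (scipy backend). The default
significance threshold in reports is 0.01. Degenerate all-tied input, where
the tie-corrected variance is zero, returns p = 1.

## Synthetic data

The generator emulates post-alignment epiallele matrices from deep amplicon
bisulfite sequencing at the study's scale: regions of N ∈ {6, 9, 10} CpGs
(default 9), m = 3 individuals per condition, 10⁴ molecules per individual,
and inter-individual variability as independent lognormal multiplicative
jitter on each of (P, α, Q, β) with median 1 and relative SD `jitter_sd`
(default 0.1) — lognormal preserves positivity; the literature asserts
parameter fluctuation between individuals without specifying a law.
Molecule classes are drawn from the analytic stationary law and methylated
sites are placed uniformly at random given the class (the unique placement
consistent with a site-exchangeable model). A Gillespie simulator of the
per-molecule dynamics provides an independent brute-force oracle for the
stationary solution and for relaxation behaviour. All randomness flows from
explicit seeds through `numpy.random.Generator`; fixed seeds give
byte-identical outputs.

What the generator does **not** emulate: sequence-level reads (no FASTQ,
bisulfite-conversion failures, PCR duplicates), per-site rate heterogeneity,
read-depth variation between individuals, and any deviation from
equilibrium. Passing tests therefore validate the inference machinery under
the model's own assumptions, not the upstream read processing or the
adequacy of the mean-field model for real regions.

## Verification scale and statistical checks

The test suite validates the stationary solution termwise against detailed
balance (1e−10 relative) for random parameter sets at N ∈ {3, 6, 9, 10} and
against Gillespie stationary occupancy within 3 Monte-Carlo standard errors,
using 400 molecules × 250 checkpoints (10⁵ molecule-time samples) per set
with burn-in set to 10 relaxation times from the chain's spectral gap
(parameter sets whose burn-in would exceed 250 time units are redrawn to
keep simulations compact). Parameter-ratio recovery is checked over 50
seeded conditions at the default study scale, and goodness-of-fit
calibration over 100 seeded fits of model-generated data with Gaussian
noise of SD σ_n = 0.15·C_n + 0.002 (a relative-plus-floor profile on the
scale of m = 3 inter-individual standard errors).

Two calibration caveats, measured with this package: with σ_n estimated
from only three replicates the standardized errors are heavy-tailed
(t-like with 2 degrees of freedom), so nominal "2σ" intervals undercover
somewhat — joint coverage of both cooperativity ratios is ≈86–88% rather
than ≈95% — and the 10% parameter jitter biases the fitted β/Q slightly
upward because a mixture of equilibria is not itself an equilibrium. Both
effects are properties of the study design (three individuals, jittered
parameters), not of the optimizer or the interval construction, which are
verified against closed-form oracles.

## Known limitations

- Only rate ratios are identified; reported parameter values are
  gauge-dependent (P + α + Q + β = 1) and should be compared across
  conditions only through gauge-invariant quantities.
- dof = (N+1) − 4 slightly misstates the effective degrees of freedom
  (three identifiable parameters plus the normalisation constraint), so the
  reduced chi-square is conservative by a factor ≈ 7/6 at N = 9.
- The classifier thresholds are calibrated on canonical shapes; distributions
  with shallow secondary structure near the thresholds may be labelled
  "unresolved".
- Linear cooperativity is an approximation; saturating or distance-dependent
  neighbour effects are not representable.
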