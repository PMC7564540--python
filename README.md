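# epibalance

Equilibrium birth–death modeling of DNA methylation heterogeneity from
deep bisulfite-amplicon (epiallele) data.

## The problem

Deep amplicon bisulfite sequencing reads out the methylation state of every
CpG on every sequenced molecule. Each molecule's binary methylation vector
is an **epiallele**; grouping the epialleles of a region with N CpGs by
their number n of methylated sites yields N+1 **methylation classes
(MCs)**. Across tissues and genomic regions the class distributions D_n
take a few recognisable shapes — unimodal at low methylation (pattern A),
unimodal at high methylation (pattern B), or bimodal (pattern C) — and are
strikingly reproducible between individuals, suggesting a cell-population
steady state maintained by ongoing methylation and demethylation.

`epibalance` is for researchers who want to infer the kinetics behind such
distributions: how much of a site's methylation (demethylation) rate is
intrinsic, and how much is **cooperative**, i.e. driven by the methylation
state of the rest of the molecule.

## The model

Molecules move between adjacent classes. A molecule in class n gains
methylation at each of its N−n unmethylated sites with per-site rate

    P_n = P + α·n

and loses it at each of its n methylated sites with per-site rate

    Q_n = Q + β·(N − n),

where P, Q are the independent rates and α, β the cooperative
contributions. The stationary class distribution C_n satisfies detailed
balance,

    C_n (N − n) P_n = C_{n+1} (n + 1) Q_{n+1},

solved by a one-term recursion and normalised to Σ C_n = 1. With α = β = 0
it reduces exactly to Binomial(N, P/(P+Q)); strong cooperativity makes the
up/down fluxes balance in the interior and produces the bimodal regime.

The four rates are fitted to an observed condition distribution (mean D_n
over replicate individuals with standard errors σ_n) by minimising

    L = Σ_n (D_n − C_n(P, α, Q, β))² / σ_n²,

with 68% confidence half-widths from the Gaussian approximation of the
likelihood exp(−L/2) at the optimum and goodness-of-fit via the reduced
chi-square L/((N+1)−4). Because the stationary law depends only on rate
ratios, the fit fixes the gauge P+α+Q+β = 1; the scientific outputs — the
cooperativity ratios **α/P** and **β/Q**, the fitted distribution, L, and
the reduced chi-square — are gauge-invariant. Ratios across conditions are
compared with the Mann–Whitney rank-sum test.

## Worked example

`examples/03_fit_and_cooperativity.py` generates a three-individual
condition (N = 9 CpGs, 10⁴ molecules per individual, 10% inter-individual
parameter jitter) from known rates with α/P = 4 and β/Q = 0.5, then fits it:

```
converged: True   L_min = 0.4065   reduced chi-square = 0.0678

gauge-fixed parameters (P + alpha + Q + beta = 1), 68% half-widths:
      p = 0.0993 +/- 0.0376 (non-zero at 2 sigma: True)
  alpha = 0.4045 +/- 0.0210 (non-zero at 2 sigma: True)
      q = 0.3216 +/- 0.0233 (non-zero at 2 sigma: True)
   beta = 0.1745 +/- 0.0095 (non-zero at 2 sigma: True)

cooperativity ratios (gauge-invariant):
  alpha/P = 4.073 +/- 1.749   (truth 4.0)
  beta/Q  = 0.543 +/- 0.064   (truth 0.5)
```

The fit recovers the generating ratios within their intervals: methylation
is strongly cooperative (α/P ≈ 4), demethylation mostly independent
(β/Q ≈ 0.5). The other examples cover the bimodality mechanism and balance
points (`01`), class counting from epiallele files (`02`), pattern
classification plus the rank-sum comparison (`04`), and the Gillespie
simulation used as a brute-force oracle for the detailed-balance solution
(`05`).

A thin CLI wraps the same pipeline:

```bash
epibalance simulate --p 0.1 --alpha 0.4 --q 0.333 --beta 0.167 \
    --n-sites 9 --seed 1 --output-dir out/
epibalance classes --input out/synthetic_ind1.txt ... --output-dir out/
epibalance fit --input out/synthetic_condition.tsv --output-dir out/
epibalance rates | classify | compare ...
```

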