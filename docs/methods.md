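# Methods

## The model

`raoeb` implements a two-step inference framework for the historical and
demographic parameters of recent human evolution, built around the RAOEB
model — *Recent African Origin with Expansion and Bottleneck*. Forward in
time, the model is:

1. An archaic hominin population of constant (diploid) size *N′* leaves
   Africa at *T_E* (prior 1.2–2.5 My); thereafter Africa and the archaic
   deme exchange migrants at the ancestral rate *m₀*.
2. Modern humans leave Africa at *T_OoA* (prior 45–87.5 ky), founding a
   Eurasian population of size *N_OoA* = *N′*/*β_OoA*; the bottleneck
   intensity *β_OoA* is the pre/post-exodus size ratio. A fraction *δ*
   (the replacement rate) of present-day non-African lineages traces to
   these modern migrants, 1 − *δ* to the archaic deme.
3. The ancestral Eurasian population splits into Europeans and East
   Asians at *T_E-EA*; each daughter stays at *N_OoA* until its Neolithic
   expansion onset (*t_E*, *t_EA*), after which it grows exponentially at
   rate *α_E* (*α_EA*) per generation to its present size *N_E* (*N_EA*).
4. Africa grows exponentially from *N′* starting at *t_A* at rate *α_A*
   to *N_A* = *N′*·exp(*α_A* *t_A*/g); draws implying *N_A* > 10⁹ are
   rejected. Symmetric migration at rate *m* connects the modern demes
   after the exodus.

All times are in years and converted with a generation time g = 25 y;
sizes are diploid individuals; *m*, *m₀* are migrant proportions per
generation. Composite sizes (*N_A*, *N_OoA*, *N_E*, *N_EA*) are never
drawn; they derive from the drawn parameters. Four dispersal variants
are supported: a single exodus followed by the Eurasian split (A), two
concomitant independent exoduses (B), and two exoduses at different
times with Europe (C) or East Asia (D) founded by the earlier one; for
C/D the earlier exodus time is drawn from the older half of the
*T_OoA* prior and the later from the recent half, and both apply the
same *δ* and *β_OoA*.

The demography is realised as an msprime event graph. Two engine
subtleties are load-bearing: sampling is diploid (`ploidy=2`) so that
sizes are diploid Nₑ and θ = 4Nₑμ, and migration rates of a deme
removed by an admixture event are zeroed explicitly (msprime only does
this automatically for population splits).

## Data and statistics

The data unit is a panel of 20 unlinked noncoding loci (~1.4 kb),
phased, in 118 sub-Saharan African, 47 European and 48 East-Asian
diploids, with ancestral alleles annotated. Per locus and population
the package computes the number of haplotypes *K*, segregating sites
*S*, nucleotide diversity π, Tajima's *D*, Fu's *Fs* (Ewens-formula
tail probability at θ̂ = π per locus, Stirling numbers cached in log
space), Fu & Li's *F** (total singletons, corrected variance
coefficients) and the unnormalised Fay & Wu's *H* (θ_H over
derived-allele counts). Cross-locus means and SDs per population and
pooled, plus haplotype-frequency F_ST (haploid Weir–Cockerham variance
components summed over loci), form the summary vector. Statistics
undefined at *S* = 0 are excluded from the means with counts recorded.

Folded (MAF) spectra are tested against the constant-size expectation
θ_W(1/i + 1/(n−i)) with a two-class χ² (singletons vs rest, 1 df);
unfolded (DAF) spectra against constant-size simulation expectations
(fixed-derived vs rest). Empirical null p-values are two-sided with
add-one correction, maximised over three recombination treatments
(none; gamma-distributed around 10⁻⁸/bp; fixed 10⁻⁷/bp). The
constant-size null simulates the three populations independently (an
isolated-demes joint model has no common ancestor), stacking their
private variants.

## Step 1 — best-fit screening

Candidate models are compared by ψ_ξ: the proportion of a model's
simulated summary vectors whose normalised Euclidean distance
D(S′,S) = ‖(S′−S)/scales‖ to the observation falls below ξ. Scales are
the pooled simulation SDs (MAD optional); ξ is the 1% quantile of the
pooled distances (configurable), recorded in output. Significance uses
100 resamples of the simulation tables, Welch t-tests on mean ψ and
Bonferroni correction over all pairs; every model indistinguishable
from the best is retained. Model-assignment validation simulates
pseudodatasets under each model of a pair and counts how often the
generating model attains the higher ψ (ties count as incorrect).

Three screening grids mirror the staged analysis: 24 archaic models
(8 replacement-rate windows × 3 ancestral-migration regimes, modern
demes held at constant size, scored on pooled statistics + global
F_ST); 15 African-expansion models (3 onset × 5 growth windows, scored
on African means); 5 bottleneck-intensity windows (scored on European
and East-Asian means).

## Step 2 — ABC co-estimation

Rejection keeps the n_accept smallest distances; posteriors come from
locally weighted linear regression (Epanechnikov weights
w = 1 − (d/d_max)²) of each transformed parameter on the normalised
statistic deviations, θ* = θ − b(s − s_obs). Transforms keep the
adjustment inside the prior support: logit over the box for uniform
priors, logit on the log scale for log-uniform rates, log for gamma
priors and composite sizes; raw-scale regression is available. Point
estimates are the weighted mean, median or KDE mode (Gaussian kernel,
Silverman bandwidth — the mode's main tuning knob); intervals are
weighted 2.5/97.5% quantiles. Dispersal-model posterior probabilities
are accepted-label frequencies in a merged equal-proportion table; the
dispersal stage uses the three pairwise F_ST as its statistic set,
since the divergence structure (a shared ancestral-Eurasian branch
lowers EUR–EAS differentiation) is what separates the topologies —
per-population means dilute that signal at moderate table sizes.

Accuracy is evaluated by re-estimating pseudodatasets of known truth:
relative bias B, relative SE, relative RMSE (RMSE² = B² + SE²·(n−1)/n)
and 95% CI coverage (CI_hits), per parameter × statistic set ×
estimator, the winner per parameter chosen by lowest RMSE. Prior
sensitivity re-estimates under one modified prior at a time and reports
CI overlap, flagging moves beyond half the base CI width. The
replacement rate δ is expected to track its prior (known weakly
identified); the present-day African size N_A is the least accurate
parameter, consistent with its composite, heavy-tailed construction.

## Synthetic data

`make_pseudo_observed` generates study-shaped datasets under any
parameter draw; the default truth is the co-estimated point values
(N′ = 13,800; β_OoA = 5.1; T_OoA = 60 ky; T_E-EA = 22.5 ky;
t_A = 27.5 ky; α_A = 0.007; m = 1.3×10⁻⁵; δ = 0.9949). The Eurasian
onsets/rates are not individually reported, so α_E and α_EA are
back-solved from N_E = 31,200 and N_EA = 14,500 with t_E = 12,500 and
t_EA = 8,750 y, keeping both inside their prior boxes. Generated data
reproduce the qualitative signatures of the real panel (negative
African Tajima's D, reduced non-African between-locus SDs, global
F_ST ≈ 0.1–0.2) but not its locus-specific idiosyncrasies: no
sequencing or phasing error, no missing-data pattern beyond optional
uniform N-masking, uniform mutation rate within a locus. Passing tests
therefore validate the inference machinery, not the fit of any
particular real dataset.

## Numerical and engineering choices

* Finite-site JC69 mutations on a discrete 1,400-bp genome; multiply
  hit sites keep all states and count once in *S*.
* `run_batch` draws one recombination rate per dataset so the 20 loci
  share a single batched ancestry call (~4× throughput; per-call engine
  overhead dominates at these locus sizes); mutation rates are still
  drawn per locus. `simulate_dataset` keeps full per-locus control.
* One master seed per batch; row seeds are spawned, so any row can be
  reproduced in isolation. Checkpointing appends completed rows and
  resumes partial tables.
* Ewens probabilities and the Tajima/Fu–Li constants are cached per
  sample size; Stirling rows up to n = 426 are computed once by a
  log-space recurrence (sums verified to 1 within 1e-10).
* Sites containing N drop out of the affected pairwise comparisons; a
  haplotype with missing calls merges into a compatible fully resolved
  haplotype when one exists (configurable).

## Problem sizes of the shipped validation runs

The reference analyses are scaled down from the original design
(10⁵–10⁶ simulations, 100+100 pseudodatasets) to sizes a single CPU
handles in minutes; all are package defaults recorded in
`scripts/acceptance.py`:

* model-assignment comparisons: 1,000 simulated datasets per model,
  40 + 40 pseudodatasets per pair (binomial SE ≈ 5 points);
* ABC coverage: a 2,500-row reference, 50 pseudodatasets, 300 accepted
  (the 21-covariate weighted regression needs well over 21 accepted
  rows; 1% acceptance would leave 25);
* the test suite uses further-reduced sizes with correspondingly wider
  Monte-Carlo tolerance bands.

At these sizes the out-of-Africa time is only weakly identified per
dataset (posteriors close to the prior), which the coverage evaluation
reflects honestly: CI coverage ~0.92–0.94 rather than the 0.98
attainable with two to three orders of magnitude more simulations.

## Known limitations

* The archaic phase is a single constant-size deme; no archaic
  substructure.
* Migration is symmetric and epoch-constant; no spatial structure,
  selection or gene conversion.
* The continuous-time coalescent replaces a generation-per-generation
  algorithm; differences are negligible at the simulated sizes but
  untested for β_OoA near its upper bound with very small N_OoA.
* δ and N_A are reported but known unreliable (prior-driven and
  heavy-tailed respectively); the prior-sensitivity tooling exists to
  demonstrate exactly that.
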