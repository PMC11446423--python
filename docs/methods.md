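# Methods

`dominfer` infers how deleterious nonsynonymous mutations are distributed
over selection strength (the DFE) and dominance (h) from site frequency
spectra, and propagates the fitted models into forward simulations of
genetic and inbreeding load.  This note records the model, the numerical
choices, and what the reduced-scale defaults do and do not demonstrate.

## Model and conventions

**Selection.** The inference side uses the convention in which a mutant
homozygote has fitness 1 − 2s and a heterozygote 1 − 2sh, with s ∈ [0, 0.5]
(s = 0.5 is a recessive lethal when h = 0).  The population-scaled strength
is γ = 2·N_anc·s.  The forward simulator uses the common alternative
(homozygote 1 − s, heterozygote 1 − sh, s ∈ [0, 1]); conversion doubles s
and the bin edges and leaves h and the mixture proportions untouched.

**Sign convention in the diffusion.** The sojourn density

f(q; γ, h) = e^{4γhq + 2γ(1−2h)q²} / (q(1−q)) ·
             ∫_q^1 e^{−4γhε − 2γ(1−2h)ε²} dε / ∫_0^1 e^{−4γhε − 2γ(1−2h)ε²} dε

is the classical Wright–Fisher result with γ *signed*, positive when the
derived allele is favored (at h = ½ it reduces to the textbook genic form
(1 − e^{−2γ(1−q)}) / (q(1−q)(1 − e^{−2γ}))).  Deleterious mutations in the
inference convention therefore enter the diffusion with γ = −2·N_anc·s.
All code in `dominfer.diffusion` takes signed γ; the DFE layer applies the
negation.

**Likelihood.** Independent sites give Poisson-distributed SFS entries
(Poisson random field).  `poisson_loglik` includes the −log(x_i!) constant —
it is the full Poisson log-pmf — so absolute log-likelihoods are comparable
to tools reporting full likelihoods.  All fits use folded spectra over
minor-allele classes 1..⌊n/2⌋ with no extra masking; the central class of an
even-n fold receives no special weighting.

**DFE families.** A gamma distribution over s (shape α, scale β; 2 free
parameters) and a discrete mixture of uniforms over the five |s| bins
(0, 1e−5], (1e−5, 1e−4], (1e−4, 1e−3], (1e−3, 1e−2], (1e−2, 0.5] with 4 free
parameters.  Mass with s > 0.25 is treated as non-segregating (it
contributes no expected variants); mass below 1e−5 uses the neutral
expectation.  The within-bin E[s] used by the h·s summaries is the
arithmetic midpoint of the bin (configurable via `bin_mean_s`); this matters
mostly for the strong bin, whose midpoint 0.255 dominates unweighted h·s
averages.

**Dominance scan and averaging.** Per-bin h from
{0, 0.05, 0.10, 0.15, 0.25, 0.35, 0.45, 0.50}, neutral bin pinned at h = 0.5
(8⁴ = 4096 models).  Models within 4.74 LL units of the maximum form the
"high-LL" set (asymptotic 95% region for 4 free parameters); the monotone
subset additionally requires h non-increasing from the neutral to the
strongly deleterious bin.  Parameter estimates are combined with Akaike
weights w_i ∝ e^{−ΔAIC_i/2}; AIC = 2k − 2·LL with k = 2 (gamma) or 4
(discrete).  Ties at the maximum LL break by lower AIC, then lexicographic
h order, for determinism.

## Numerics

**Frequency grid.** A sigmoid-spaced grid on [0, 1] (crowding factor 8)
concentrates points near both boundaries, where the density behaves like
1/q and where binomial sampling at large n needs resolution.  A warning
fires if the first interior point exceeds 1/n.

**Equilibrium density.** The two exponential integrals are evaluated by
piecewise-exponential quadrature in log space (each interval treats the
quadratic exponent as locally linear and integrates exactly), so arbitrarily
large |γ| cannot overflow; against adaptive quadrature the relative error is
below 1e−8 for |γ| ≤ 1e3 at default resolution.

**Transient integration.** The forward equation
∂φ/∂t = −∂_q(Mφ) + ∂²_q(Dφ), with D = q(1−q)/(2ν(t)) and
M = 2γ q(1−q)(h + (1−2h)q), is discretized in conservative flux form.  The
diffusive part differences the product Dφ — which stays smooth where φ
itself diverges as 1/q — making the neutral equilibrium an exact discrete
steady state of the scheme together with the standard boundary mutation
influx (θ/2 per unit time at the first interior node).  The advective part
uses Chang–Cooper exponential-fitting weights, which reduce to central
differencing for weak selection and upwind automatically for strong
selection, preserving positivity.  Time stepping is implicit Euler with
dt = dt_fac/(1 + |γ|/25) (dt_fac = 0.02), at least 10 steps per epoch, and
ν(t) refreshed every step during exponential growth.  Boundary cells absorb;
their mass is discarded.

**Richardson extrapolation.** Expected spectra are computed on three grids
(default 300/450/600 points) and extrapolated quadratically in the first
grid step to the zero-spacing limit, the standard device for making coarse
diffusion grids accurate.  Measured against the analytic equilibrium, the
extrapolated transient solver is accurate to ~0.1% up to |γ| = 1000; mass-
bearing entries move by < 0.1% when the default grids are doubled.

**Sampling to an SFS.** Entry i is ∫ C(n,i) q^i (1−q)^{n−i} φ(q) dq by
trapezoid over the interior grid plus analytic tail corrections that model
φ ~ c/q near 0 and φ ~ c′/(1−q) near 1 (incomplete-beta closed forms).  The
neutral constant-size expectation θ/i is reproduced to better than 1e−4
relative at 1000 grid points.

**Validity regime of the diffusion.** Against an independent discrete
Wright–Fisher transition-matrix computation, folded expectations agree to
within 5% per entry wherever an entry carries at least 1e−4 of the
spectrum's mass and the per-generation coefficients are small
(roughly s·h ≲ 0.01 at the matrix's population size).  Vanishingly small
high-frequency entries can disagree by tens of percent — a genuine property
of the diffusion limit (the discrepancy shrinks like 1/N at fixed γ), not of
this implementation — which is immaterial for fitting because those entries
contribute negligibly to the Poisson likelihood.

**Expectation grids.** Per h, folded expected spectra (θ = 1) at 1000 (or
fewer, at reduced scale) log-spaced s values in [1e−5, 0.25], plus a neutral
row, cached as an `.npz` container keyed by a hash of (h, demography, n,
N_anc, grid settings); a cached grid reloads bit-identically and any
metadata mismatch triggers a rebuild under a different key.

**Optimization.** The demographic model (bottleneck N1/T1, recovery N2/T2,
exponential growth N2→NC over TC; growth starts from the recovery size) is
fit by bounded L-BFGS-B on log-parameters with multiplicative start
perturbations (factors up to 2), θ_S profiled out analytically
(θ̂ = Σ observed / Σ unit-θ expected).  The discrete-DFE likelihood is
*concave* in the proportions — the expected SFS is linear in them and the
Poisson log-likelihood is concave in its mean — so a single SLSQP start
(with analytic gradient, simplex constraints) finds the global optimum;
multiple starts remain available as insurance.  The gamma DFE is fit on
log(α, β) with multi-start L-BFGS-B (default 25 starts).  The gamma
quadrature over the s grid renormalizes to the exact gamma mass of the grid
range, which keeps sharply peaked DFEs exact in total mass.

## Forward simulator

Diploid Wright–Fisher with multiplicative fitness across sites (1, 1 − sh,
1 − s per genotype).  Coding sequence is modeled as equal-length genes
(1340 bp) on autosomes: no recombination within genes, crossover probability
0.001 between adjacent genes, free assortment between chromosomes.
Haplotypes are sorted arrays of (gene, mutation-id) keys, so homozygosity
detection is a linear merge and recombination walks only the mutated genes,
flipping source haplotype with probability (1 − (1 − 2r)^d)/2 across d gene
boundaries.  New mutations arrive Poisson(U/2) per gamete with
U = 2 × 30.16 Mb × 1.05e−8 = 0.63 at full scale (1.05e−8 = 1.5e−8 × 2.31/3.31,
the nonsynonymous fraction of the coding mutation rate).  Mutations fixed
within a population move to a per-population registry (their fitness cost
persists; they no longer contribute to the inbreeding load).

Reported per replicate and population from a 100-individual sample:
genetic load 1 − mean(Π_sites w); inbreeding load
B = Σ s·q(1−q)(1−2h) over segregating sites, truncated at zero per site —
the first-order difference in expected log fitness between fully inbred and
outbred genotype proportions ("haploid lethal equivalents"); and the mean
count of derived deleterious alleles per individual (fixed sites count
twice).  Half-genome runs project to a full genome by squaring mean fitness
and doubling B and the allele counts.

The two-population history is the standard out-of-Africa parameterization:
ancestral N = 7,310; African growth to 14,474 (placed 3,880 generations
before the split by default); European split 2,040 generations ago at
N = 1,861; exponential growth over the final 204 generations to 424,000
(Africa) and 512,000 (Europe).  The published epoch lengths leave
2,040 − 1,120 − 204 = 716 generations unaccounted; the default keeps the
bottleneck size through that gap.  No migration is modeled.  The optional
variable-dominance mode draws h per mutation uniformly on [0, 2h̄] of its
bin.

## Reduced-scale defaults and what they show

Full-scale runs (N up to 5·10⁵) are cluster work.  The package's default
study conditions are chosen for a single workstation CPU:

* Poisson-sampled inference datasets: n = 40 chromosomes, θ_S = 4000 (the
  order of the human synonymous data, so fit power is comparable),
  N_anc = 5000, 150-point γ grids.
* Forward-simulated validation data: N_anc = 350, 8,000 genes (10.7 Mb),
  the bottleneck–recovery–growth history scaled to generations, burn-in
  5 × 2N (sufficient for all but the most weakly selected class, whose
  equilibration is irrelevant to the validation target).
* Load study: 3,000 genes on 11 autosomes, all demographic sizes and times
  divided by 24 with final growth capped at N = 1,500, 25 replicates.
  Selection coefficients are deliberately *not* rescaled — a full
  rescaling would push the strongly deleterious bin past the lethal bound —
  so these runs preserve the *relative* size history but not the scaled
  parameters, and their outputs are qualitative.

Consequences worth stating plainly:

* The desk-scale scan validation shows the generative dominance model is
  statistically indistinguishable from the scan optimum (ΔLL well under the
  4.74 cut-off), mirroring the full-scale experiment; at this power most of
  the 4096 models fit comparably, so the *counts* of high-LL and monotone
  models are much larger than at full scale.
* The load study reproduces the ordering of inbreeding load across the
  three dominance models and the direction of purging (European B below
  African B) robustly for the strongly and moderately recessive models.
  For the weakly recessive model the published effect is ~4%, which at this
  scale is within replicate noise; only the sign of the mean is meaningful.
  Absolute B values scale with U and N and are far below the full-scale
  predictions by construction.
* Identifiability limits are intrinsic, not numerical: the neutral and
  nearly-neutral proportions of the discrete DFE trade off along a
  likelihood ridge (their h·s products are nearly identical), as does
  bottleneck depth against duration in the demographic model.  Tests
  therefore assert recovery of pooled/identifiable functionals.

## Known limitations

* Single 1-D diffusion only; the two-population analysis runs through the
  forward simulator.
* No beneficial mutations, epistasis, X chromosome, or migration.
* The Poisson random field ignores linkage; the forward-simulated
  validation data deliberately violates that assumption (as real data do),
  which is part of what the scan validation exercises.
* The strongly deleterious bin (s up to 0.5 in the inference convention) is
  constrained almost entirely through its effect on the mixture, not by
  segregating variants, and the diffusion is least accurate there; fine
  structure within that bin is not identifiable from SFS data.
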