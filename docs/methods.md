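# Methods

## Model

A biallelic X-linked locus with alleles M1/M2. Males are hemizygous:
`n1m ~ Binomial(Nm, p_m)` counts male M1 alleles. Female genotype counts
`(n2f, n1f, n0f) ~ Multinomial(Nf; P(M1M1), P(M1M2), P(M2M2))` with

    P(M1M1) = p_f² + ρ p_f q_f,   P(M1M2) = 2(1−ρ) p_f q_f,   P(M2M2) = q_f² + ρ p_f q_f,

where ρ ∈ [0, 1] is the female inbreeding coefficient. ρ is restricted to
be nonnegative: the QC question is excess homozygosity, every alternative
of interest has ρ > 0, and the latent-variable construction below splits
homozygote classes into an "independent alleles" part and an
"identical-by-descent" part, which only makes sense for ρ ≥ 0.
Heterozygote excess (mathematically ρ < 0) is out of scope; the moment
estimator (below) still reports negative values so that it can be compared
with the constrained maximum-likelihood estimators on equal terms.

Four hypotheses: `H0` (p_m = p_f and ρ = 0), `H01` (p_m = p_f, ρ free),
`H02` (ρ = 0), `H1` (unconstrained). All likelihoods are computed in log
space with multinomial coefficients dropped — they are common to every
hypothesis and cancel in each likelihood ratio. Zero-count cells
contribute 0 via the `0·ln 0 = 0` convention; a positive count on a
zero-probability cell yields −∞.

## Estimation

Closed forms:

* H0: pooled frequency `p̂ = (n1m + 2 n2f + n1f) / (Nm + 2 Nf)` (one X per
  male, two per female).
* H02: `p̂_m = n1m/Nm`, `p̂_f = (2 n2f + n1f)/(2 Nf)`.
* Moment estimator of ρ from the homozygote excess:
  `ρ̂_z = (n2f/Nf − p̂_f²)/(p̂_f q̂_f)`, reported unclipped (possibly
  negative); undefined for monomorphic females.

Under H1 and H01 the female block needs an EM algorithm. Augment `n2f`
into latent `w1` (two independent M1 copies, probability ∝ p_f²) and `w2`
(one identical-by-descent copy, ∝ ρ p_f q_f), and `n0f` into `w3`/`w4`
analogously. The E-step takes conditional expectations of the `w`'s at
the current parameters; the M-step is a weighted allele count:

    p_f ← [E(2w1 + w2) + n1f + E(w4)] / (2 Nf)
    ρ   ← [E(w2) + E(w4)] / [E(w2) + E(w4) + n1f]

Under H01 the pooled update adds the male terms:
`p ← [E(2w1 + w2) + E(w4) + n1f + n1m] / (Nm + 2 Nf)`. `p̂_m = n1m/Nm` is
exact at every H1 iteration. Initial values are the moment estimates of
the frequencies and ρ₀ = 0.02; iteration stops when every parameter moves
by less than 1e-7, with a cap of 1000 iterations; all three are
configurable through `EMConfig`.

Numerical choices worth knowing:

* **Boundary polish.** When the maximizer sits on the ρ = 0 boundary, the
  EM map contracts at a rate that approaches 1, so the iteration can stop
  (or hit its cap) a tolerance-level distance short of the optimum. After
  the loop, the fit is compared with the exact ρ = 0 closed form and the
  better log-likelihood is kept. This also guarantees LRT2 ≥ 0 exactly.
  Residual negative LRT values within 1e-6 (10× the parameter tolerance)
  are clipped to zero; anything larger raises, since it would indicate a
  real inconsistency.
* **Degenerate female configurations** bypass EM with their analytic
  boundary MLEs: no heterozygotes but both homozygote classes present →
  ρ̂ = 1 (under H01, p̂ = (n1m + n2f)/(Nm + Nf): homozygotes act as single
  draws); all heterozygotes → ρ̂ = 0, p̂_f = 1/2; monomorphic females →
  ρ is non-identifiable, reported as 0 with `rho_identifiable=False`.
  These rules keep the LRTs defined (statistic 0 when null and alternative
  coincide) so batch runs survive awkward loci.
* Moment starting frequencies of exactly 0 or 1 are nudged into
  [1e-6, 1−1e-6] to avoid 0/0 in the E-step ratios.
* The EM core is vectorized: one numpy array element per locus or
  Monte-Carlo replicate, with converged elements retired from the active
  set each iteration. This is what makes 10⁴-replicate experiments with
  nested bootstrap (10⁶–10⁷ EM fits) run in seconds to minutes on one
  core. The scalar `fit_*` API wraps length-1 arrays of the same code.

## Test statistics

Moment tests (variance estimates as printed in their definitions):
`Z1 = (p̂_m − p̂_f)² / [p̂_m q̂_m/Nm + (p̂_f − 2p̂_f² + n2f/Nf)/(2Nf)]`,
`Z2 = Nf[Δ̂_f + p̂_f q̂_f/(2Nf)]²/(p̂_f² q̂_f²)` with
`Δ̂_f = n2f/Nf − p̂_f²`, and `Z0 = Z1 + Z2` (the components are
asymptotically independent under the joint null). χ² reference with 1, 1
and 2 df; upper tail, no continuity correction.

LRTs: `LRT_k = 2[ℓ(θ̂_1) − ℓ(θ̂_constrained)]` with χ²(2) for LRT0 and
χ²(1) for LRT1/LRT2. Z2 and LRT2 depend only on the female counts (the
male terms cancel), which is asserted by fuzzing male counts in the tests.
Statistics that are undefined at monomorphic loci raise
`UndefinedStatisticError`; the batch front ends catch it and report the
locus as missing rather than aborting.

Because ρ = 0 is a boundary point, LRT0 and LRT2 are *conservative* under
the χ² reference (simulated sizes ≈ 3% and ≈ 2% at the nominal 5%). The
parametric bootstrap restores the level: fit the null model, redraw the
data from it B times (males Binomial, females Multinomial at the fitted
frequencies; for LRT2b the males are held fixed — they cancel anyway),
recompute the statistic on each resample, and report
`p = (1/B)·#{LRT* > LRT_obs}`. The strict inequality is kept as stated —
ties do not count toward significance — and B = 1000 by default.
Per-resample EM fits that hit the iteration cap are counted in the result
but still used.

Dosage compensation: X-inactivation equalizes X-linked dosage between the
sexes; in allele counting it corresponds to weighting each male allele
twice (equivalently each female allele by half). `dc_variants` recomputes
LRT0 and LRT1 under that convention (pooled
`p̂ = (2n1m + 2n2f + n1f)/(2Nm + 2Nf)`, male likelihood exponents
doubled). Z1, Z2, Z0 and LRT2 estimate sex-specific quantities separately
and are unaffected by construction. Only the statistics change — the
generator is never reweighted — so experiments under this flag probe how
the allele-counting convention shifts the pooled-frequency tests.

## Simulation engine

`Scenario` fixes (p_m, ε, ρ, N, r, n_reps, α) with `p_f = p_m + ε`, and the
male:female ratio r maps to `Nm = round(N·r_m/(r_m+r_f))`, `Nf = N − Nm` —
unambiguous for the even splits used in the experiments and deterministic
otherwise. The stratification block defines a two-subpopulation mixture:
each individual independently draws a subpopulation (probability 0.5 each
by default) and a sex (female with probability 0.5); subpopulation k has
male frequency p_m[k] and female frequency p_m[k] + ε_k with ρ = 0 inside
each subpopulation. Pooling then induces apparent inbreeding (Wahlund
effect); e.g. at p_m = (0.3, 0.5), ε = (−0.05, −0.05) the pooled female
population has P(M1M1) = 0.1325 against p̄_f² = 0.1225, i.e. a population
ρ of 0.044. Binomial sex assignment is the default, matching the stated
design; a fixed 50/50 split is available as an option.

`run_experiment` draws `n_reps` datasets, computes the requested
statistics (all EM fits vectorized across replicates; bootstrap p-values
computed with one RNG substream per replicate, flattened into chunked EM
calls of 200×B resamples), and aggregates rejection rates at level α with
Monte-Carlo SE `sqrt(r(1−r)/n)`, plus mean/SD/bias/RMSE for ρ̂₁, ρ̂₀₁,
ρ̂_z, p̂_m, p̂_f₁, p̂₀₁. Rejection uses `p ≤ α`. SDs use the population
convention (ddof = 0) so that RMSE² = bias² + SD² holds exactly; bias and
RMSE are omitted under stratification, where no single true parameter
value exists. Replicates with undefined statistics are excluded per test
and counted — they are never redrawn, which would bias the null
distribution. Results are reproducible and order-independent for a given
seed (per-replicate SeedSequence children). Any experiment can run at
reduced (n_reps, B); the reported SE makes the widened Monte-Carlo band
explicit.

`sample_size_search` finds the smallest Nf on a grid reaching a target
power by coarse doubling then bisection, assuming power is monotone in Nf,
with the male count held at the scenario's Nm (zero for the female-only
tests).

### What the generator does and does not emulate

The generator produces exactly the sampling model the tests assume:
independent individuals, binomial/multinomial sampling, at most two
subpopulations, no genotyping error, no missingness, no linkage between
loci. Passing the simulation checks therefore validates the statistics
under their own model (size, power, boundary behavior, Wahlund
inflation); it says nothing about robustness to genotype-calling artifacts
or family structure in real data — which is why the PED front end uses
founders only.

## Problem sizes and observed behavior

The packaged experiments use 10000 Monte-Carlo replications for the
asymptotic tests and 3000 replications × B = 500 for the nested-bootstrap
experiments (rejection-rate SE ≤ 0.5 percentage points); both scales are
plain parameters, and the full 10⁴ × 10³ runs are supported through the
same interface.

Two distributional facts surfaced by the test suite are worth recording:

* LRT2's null distribution has roughly half its mass at exactly 0 (the
  boundary), so LRT2b's bootstrap p-values are *not* uniform over [0, 1]:
  all zero-statistic replicates map to p ≈ P*(LRT2* > 0) ≈ 0.5. The
  p-values remain valid (P(p ≤ u) ≈ u for small u, which is what rejection
  uses). The uniformity property test therefore uses LRT0b, whose
  statistic is almost surely positive.
* Under stratification the EM estimate ρ̂₁ averages slightly above the
  population mixture value (maximum-likelihood, not moment, weighting);
  both EM estimators have smaller RMSE than ρ̂_z throughout the tested
  grid, at the cost of a small upward bias near the boundary.

## PED input

Whitespace-delimited linkage format: six leading columns (family,
individual, father, mother, sex = 1/2, phenotype) then two allele codes
per marker, `0` = missing. Founders are records whose father and mother
fields are both `0`; only genotyped founders are counted, per marker. PED
has no haploid encoding, so male X genotypes are expected as homozygous
pairs; a male with two different alleles is treated as a genotyping error
at that marker and excluded with a warning. M1 defaults to the minor
allele among founders (ties broken lexicographically) — the choice only
flips count labels, and every p-value is invariant to the swap. The
results table layout (counts, per-hypothesis estimates, statistics,
p-values, one marker per row, Bonferroni threshold in the header) is this
package's own documented format.

## Known limitations

* Biallelic markers only; loci with three or more founder alleles raise.
* ρ < 0 (heterozygote excess) is not modeled; ρ̂_z is the only quantity
  that reports it.
* Asymptotic p-values rely on large Nm, Nf; for small samples use the
  bootstrap variants.
* The stratification model covers exactly two subpopulations with equal
  default mixing; more general structure is out of scope.
* Bootstrap p-values have resolution 1/B; with the strict-inequality
  convention the smallest attainable p-value is 0.
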