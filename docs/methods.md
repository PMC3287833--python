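# Methods

## The model

All stages share one generative view of a quantitative trait in pedigrees:

    Y = μ + Xβ + Σᵢ Qᵢαᵢ + e,          e ~ N(0, σ²ₑ I)

`X` holds the covariates (Sex as 0/1, Age in years, Smoking as 0/1), `Qᵢ`
the additive and dominance coding of the *i*-th QTL's genotypes
(`a(g−1) + d·1[g=1]` with g the count of the variant allele), and the
residual is independent normal.  The three analysis engines differ in what
they treat as latent:

* **Segregation analysis** (no marker data): the QTL genotypes themselves
  are latent, constrained only by Mendelian transmission, and the number
  of QTLs k is a parameter.
* **Variance-components linkage**: genotypes are integrated out into
  covariance kernels, `Ω = 2Φ σ²ₐ + Π σ²_q + I σ²ₑ`, with Φ the kinship
  matrix and Π the locus-specific IBD-sharing matrix.
* **Measured-genotype association**: one specific variant is observed and
  enters as a fixed covariate, the polygenic kernel 2Φ stays in the model
  so relatedness cannot inflate the test.

## Segregation sampler

Latent genotypes use a descent-graph representation: two founder-allele
indicators per founder (Bernoulli(qᵢ)) and one segregation indicator per
meiosis (uniform).  Any setting of these variables is a valid inheritance
pattern, so Mendelian consistency is structural and never needs checking.
Per sweep the sampler performs (a) a joint conjugate Gaussian update of
μ, β and all QTL effects, (b) a conjugate inverse-gamma update of σ²ₑ,
(c) a full Metropolis sweep over the latent descent configuration of every
QTL — one proposal per founder allele (prior ratio q/(1−q)) and per
non-founder segregation slot (symmetric), each accepted on the phenotype
likelihood, (d) a conjugate Beta update of each allele frequency from the
founder-allele counts, and (e) several (default 4) birth/death
reversible-jump attempts with prior-draw proposals.  With exchangeable
components the birth acceptance is `LR·λ/(k+1)` and death `LR·k/λ`; with
the likelihood held constant the chain provably reproduces its
truncated-Poisson prior on k, which the test suite verifies by a χ²
goodness-of-fit at 10⁴ thinned samples.

Full sweeps in step (c) matter: early versions updated only a random
subset of descent sites per iteration, which left the latent configuration
under-mixed — posterior QTL counts were biased and strongly chain-seed
dependent, and pure-noise traits appeared to carry one to two QTLs.  With
full sweeps the sampler is calibrated: a pure-noise trait in a 128-member
family yields a posterior mean QTL count of about 0.6–0.7.

Priors are weakly informative and scale-adapted to the trait: effects
a, d ~ N(0, τ²) with τ² = Var(Y) (a separate width for the dominance
effect is available via ``tau2_dom_scale`` for mostly-additive
architectures); σ²ₑ ~ Inv-Gamma(½, Var(Y)/2); q ~ Beta(1,1) restricted to
(0.005, 0.995); k ~ Poisson(λ=2) truncated to {0,…,8}; μ, β flat.  The
width of the effect prior sets the per-QTL Occam penalty in the marginal
likelihood (wider = fewer spurious QTLs but slower detection of modest
ones); all of these are plain fields of `Priors`.

Because the chain's priors are scale-adapted and proposals consume
randomness in a fixed order, the sampler is exactly equivariant under trait
rescaling: Y → 2Y reproduces identical k samples and variance shares at
the same seed (a regression test asserts this bitwise).

"Expected number of QTLs" is the posterior mean of k — the fractional
per-family counts a mean implies, not a mode.  Variance shares are
empirical (realized) per posterior sample: Var(xⱼβⱼ)/Var(Y) per covariate,
Var(ΣQᵢαᵢ)/Var(Y) for the QTLs, σ²ₑ/Var(Y) for the residual, averaged over
samples and reported in percent.  Realized variances are used instead of
theoretical Hardy-Weinberg variances because genotype frequencies inside a
single family need not match population frequencies.  Heritability is
defined as the QTL share of the variance not explained by the covariates,
`100·QTL%/(QTL%+Residual%)`.

Per-family analysis reruns the sampler on each family's members alone;
every family uses the same chain seed, so structurally identical families
with identical traits receive identical counts.  A family's *excess* is
its expected count minus the mean of the other families' counts; families
with excess ≥ 1 (default threshold) are prioritized.  Multiple chains
(`n_chains`) are run sequentially and pooled.

## Variance-components linkage

Maximum likelihood (not REML), so nested log-likelihood differences are
valid: LOD = (ℓ_full − ℓ_null)/ln 10, floored at 0, with the null fixing
σ²_q = 0.  Fixed effects are profiled by GLS inside the variance
optimization; Ω is block-diagonal across families and every likelihood
evaluation works per family block (Cholesky).  Optimization is on the
log-variance scale (L-BFGS-B, bounds ±30 in log units) from two
variance-fraction starts, followed by explicit boundary fits with each
kernel (and all kernels) removed; the best likelihood wins.  This guards
against misconvergence when a component's ML estimate is 0 — exactly the
situation the LOD's null distribution lives on.

Because one variance component is tested on the boundary of its space, the
pointwise p-value uses the half-and-half mixture:
p = ½·P(χ²₁ > 2 ln 10·LOD), p = 1 at LOD = 0.  Under this convention
LOD 0.60 ⇔ p = 0.048 ≈ 0.05 (reported to 2 d.p.), LOD 5.3 ⇔ 4×10⁻⁷,
LOD 2.02 ⇔ 0.001.  The calibration test confirms both the 5% tail (LOD ≥
0.588) and the χ²₁ shape of the positive part on 500 unlinked-locus
replicates.

Covariate screening fits the polygenic-only model with all covariates and
retains those with Wald p < 0.10.  Π matrices come from the simulator's
recorded descent — the fully-informative-IBD premise — never from marker
data; multipoint IBD estimation is out of scope.

## Rare-variant filtering

Linked regions are 1-Mbp windows centred at genes with family-specific
LOD ≥ 0.60, half-open `[center−500kb, center+500kb)` in 1-based
coordinates, clipped at position 1.  Within a window, candidates must
(i) enter the family through at most 2 founders (founder carriers counted
once each; a carrier pattern with no founder carrier triggers a data-
inconsistency warning), (ii) show at least 5 copies of the rare allele
among family members — copies are allele counts, a homozygote contributes
two, and carrier counts are reported alongside since the two coincide when
all carriers are heterozygous — and (iii) be globally rare (combined-sample
MAF < 5%, configurable).  The rare allele is defined per family as that
family's minor allele, falling back to the global minor allele on a tie.

## Association and attribution

The SNP test is a 1-df likelihood-ratio test of the additive genotype
fixed effect in the polygenic VC model; dominance of the SNP is not
modelled.  Scopes are the prioritized family, all other families pooled,
and everyone; a scope where the variant is monomorphic reports NA
throughout.  "Variation due to SNP (%)" is `100·b̂²·Var(g)/Var(Y)` within
scope, against total phenotypic variance (the natural denominator when
comparing with covariate shares; a covariate-adjusted denominator would
only rescale all entries).  The linkage LOD at the candidate's gene is
recomputed with the SNP as fixed covariate in both the null and full
fits; adjusted ≈ unadjusted means the variant is incidental, adjusted ≈ 0
means it explains the peak.  Bonferroni correction divides α = 0.05 by the
number of candidate tests actually performed for that trait.  Candidate
pairs within a family whose carrier sets overlap by at least half of the
smaller set are automatically disentangled by conditional tests (each
variant tested with the other as covariate); identical genotype vectors
are collinear and flagged instead of tested.

## Synthetic studies

`simulate_study` builds: 8 extended pedigrees (default sizes 73–128, four
generations, founders marrying in at every generation, founder fraction
constrained to 20–40% for families of ≥20 members — a trio cannot satisfy
it), covariates (Sex from the pedigree; Age uniform in generation bands
spanning 20–80 years so older generations are older; Smoking
Bernoulli(0.3)), one segregation-indicator drop per family per gene
(~50 genes over 3 chromosomes, 2.5 Mbp apart), and variants that reuse
their gene's drop — variants within a window are completely linked, genes
are unlinked.  Functional variants follow the scenario: family "7"
privately carries two Q1 variants (additive effects 2.8 and 1.6 trait SD,
entering through single founders, forced by bounded redraws to reach ≥22
and ≥18 copies — emulating variants that entered the family several
generations ago and segregated widely, the regime the design targets) and
one Q2 variant; every family shares one common QTL per trait (frequency
0.3, effects 0.45).  The two private effects are deliberately and markedly
unequal: two private variants with similar effects are nearly
non-identifiable in a segregation analysis, because one latent QTL with
two founder alleles can represent the union of both carrier sets (double
carriers fit as homozygotes) at a per-carrier misfit of only half the
effect difference — the pair is countable as two loci only when that
misfit is decisive.
Entering founders for private variants are drawn among founders with
enough descendants to reach the copy floor.  Roughly 40 nonfunctional rare
variants (mostly family-private, some shared at frequency 0.02) populate
the windows and the space between them.  All randomness flows from a
single seed through named substreams (pedigree, covariates, genotypes,
traits).

What the generator does *not* emulate: genotyping error, sequencing reads,
population stratification, ascertainment, polygenic background beyond the
explicit shared QTLs, and linkage disequilibrium other than the
complete-linkage-within-window rule.  Passing recovery tests therefore
show that the chain of methods is internally sound on idealized data with
fully informative IBD — not that it attains the same power on real exome
data with estimated IBD and confounded covariates.

## Problem sizes and numerical conventions

Test and example runs use chains of 600 burn-in + 1800 kept iterations
(thinning 3, full sweeps) per family, which the scale of the seeded
effects makes sufficient for stable posterior-mean counts; the
null-calibration studies use 2 families × ~60 members (500 locus
replicates) and 50 replicate studies of 4 families × 30–45 members for
family-wise error control.
Defaults in `McmcSettings` are longer (2000/10000/5) for production use.
Reports round counts and percentages to 1 decimal, p-values to 3
significant figures, LODs to 2 decimals; the family-count table annotates
only prioritized families with their "(+x.x)" excess.  Degenerate inputs
fail loudly: zero trait variance, non-finite traits, empty posteriors
(iterations < thinning), negative LODs, and m = 0 Bonferroni tests all
raise; monomorphic genotypes return NA rather than raising, mirroring how
zero-copy scopes are reported.

## Known limitations

* Two co-segregating QTLs of similar effect in one family tend to be
  counted as one (the merged two-founder-allele representation fits their
  union almost as well); split/merge moves that would target this
  degeneracy directly are not implementable with discrete per-meiosis
  segregation indicators, because a split must duplicate the parent QTL's
  descent pattern deterministically, leaving an uncompensated prior factor
  in the acceptance ratio.  Expected QTL counts are therefore conservative
  when a family's loci have comparable effects.
* Per-family expected QTL counts carry realization-level noise of roughly
  ±0.5 at family sizes near 100: chance alignment of residuals with
  descent patterns moves individual families' counts.  The excess-over-
  other-families statistic inherits this noise, so prioritization at the
  one-extra-QTL threshold is reliable for families whose true excess is
  clearly above one and borderline near the threshold.
* Expected QTL counts depend visibly on the k prior and effect prior;
  conclusions should be drawn from *excess* counts (differences between
  families under the same prior), which is what prioritization uses.
* LOD asymptotics (the ½χ² mixture) are accurate at the tested family
  sizes but not guaranteed for very small families.
* X-linked inheritance, half-sib dialects with unknown single parents,
  binary traits, and burden/collapsing tests are out of scope.
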