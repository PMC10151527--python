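# Methods

## Genome and meiosis

Genes are abstract biallelic loci placed equally spaced (endpoints
included) on identical chromosomes; the default genome is 10 chromosomes
of 200 cM with 40 genes each (400 genes).  Map distance maps to a
recombination fraction with the Haldane function
`r = (1 − e^(−2d/100))/2` — the single-parameter `r_ab` used throughout
the closed forms presumes no interference, and Haldane is the matching
mapping.  Meiosis is simulated as a two-state Markov chain of parental
origin along each chromosome with switch probability equal to the
adjacent-gene recombination fraction; for gene positions this is
distributionally identical to drawing a Poisson(length/100) number of
crossovers with uniform positions.  Gene placement (equal spacing versus
random) is configurable; equal spacing is the default because only the
count and map length are design quantities.

## Populations and linkage disequilibrium

A population in LD is constructed from two linkage-equilibrium founder
populations: an F1 is formed (one haplotype per founder) and one round of
random mating follows.  The gametic LD of the pool forming generation 0 is

    Δ_ab(−1) = [(1 − 2 r_ab)/4](p_a1 − p_a2)(p_b1 − p_b2),

and every further round of meiosis multiplies it by (1 − r_ab).  Per-gene
target frequencies are drawn from a beta distribution with the requested
mean; the concentration parameter defaults to 4 (moderate spread without
piling up near the boundaries) and is configurable.  Founder frequencies
straddle the target symmetrically (`p ± div/2`, clipped at the
boundaries), so the divergence parameter sets the LD level without moving
the mean.

Individuals are always the random union of one gamete from each pool;
selfing is tracked as a generation count and resolved exactly.  Doubled
haploids double one meiotic product of a random individual, so they are
fully homozygous with expected allele frequency equal to the population
frequency.

## Trait architecture

Per gene, the three genotypes take values `m − a`, `m + d`, `m + a`
(g/plant).  The per-gene `a_i` are equal by default (gamma-distributed
optional) and scaled so the worst and best full homozygotes are exactly
the configured range, default 30 and 160 g/plant.  Degrees of dominance
`d_i/a_i` are drawn from a beta distribution rescaled to [0.1, 1.2] with
mean exactly 0.6 and concentration 2 — the mean and range are design
quantities, the law is a package choice (a uniform on that range would
have mean 0.65).  Dominance is positive; a no-dominance variant sets all
`d_i = 0` before epistasis is built.

Epistatic pairs are a uniformly random disjoint pairing of a configured
fraction of the genes (default grid: 25 % and 100 %).  For each pair the
target epistatic variance is `V(I) = ratio × (V(A) + V(D))` with the
additive and dominance variances evaluated at the linkage-equilibrium
reference frequencies p = q = 0.5 (the trait is fixed once, not per
population).  The double-homozygote deviation is drawn `I22 ~ N(0, V(I))`;
the class of the genotypic table containing AABB takes the value
`N22 + I22` (N being the additive-dominance baseline) and every other
equality class of the type takes the unweighted mean of N over its cells,
which is the minimum-norm solution of the pattern constraints.  A draw
that collides the anchored class with another class is resampled (bounded
retries); two *free* classes may legitimately coincide — e.g. the 9:3:3:1
pattern collapses to 9:6:1 when both genes have identical effects, which
is classical genetics, not an error.  With `V(I) = 0` no table exists
unless the baseline already satisfies the pattern, and the constructor
raises.

## Effects and parametric means

A 3×3 genotypic table is decomposed with frequency-weighted orthogonal
projections (Hardy–Weinberg, linkage-equilibrium weights): mean, additive
and dominance terms per locus, and four epistatic surfaces (αα, αδ, δα,
δδ) whose frequency-weighted marginal sums vanish.  The composites
`(aa)` and `(dd)` are the coefficients entering the mean components
`E(AA) = 2Δ(aa)` and `E(DD) = Δ²(dd)` per pair.  Because the epistatic
surfaces have zero weighted margins, the expectations of the αδ and δα
surfaces are exactly zero in any non-inbred population, whatever the LD.

Total means are computed as exact expectations of G over the two-locus
genotype distributions (gamete-pool convolution), not by summing printed
component formulas; the component bookkeeping is layered on top, so
`M = m + v + d + E(AA) + E(AD) + E(DA) + E(DD)` holds to machine
precision by construction, and M itself is validated against Monte-Carlo
simulation (3-standard-error tests at 10^5 individuals for all seven
epistasis types).  Two consequences of this design are worth noting:

* The variety effect `v` absorbs the reference-weighted mean of the
  epistatic tables (μ_I) and their induced single-locus shifts.  A purely
  additive-dominance reading of `v` applies only when μ_I = 0, which the
  minimum-norm construction does not enforce; without LD the *epistatic
  components* of the mean are exactly zero but the mean itself still
  shifts with the epistasis type through μ_I.
* For interpopulation crosses the effects are defined on the ordered
  (maternal, paternal) allele space with pool-specific frequencies.  This
  makes E(AD) = E(DA) = 0 exact for any cross and reduces to the standard
  single-population decomposition when the parents coincide.  The
  closed-form decay identities E(AA)_F1 = (1 − r)(E(AA)_j + E(AA)_j')/2
  and E(DD)_F1 = (1 − r)² Δ_j Δ_j' (dd) hold exactly for parents sharing
  gene frequencies (the composites are then population-independent); with
  unequal frequencies the attribution of the epistatic locus-mean shift
  between `v` and the AA component is convention-dependent, while the
  total mean remains exact.

Selfed populations use the exact recursion of the phased two-locus
genotype distribution (16 ordered haplotype-pair states) under selfing
with recombination.  The printed closed forms — the `c1` coefficient of
the AA component, the AD component, and the probability `p1` (which
equals the selfing-induced change of the double-homozygote class
frequency) — are unit-test cross-checks of the recursion, all agreeing to
1e-10.  The non-epistatic inbreeding change `d` is reported as the
residual of the component identity and reduces to the classical
`−F·2pqd` per gene without epistasis.

## Diallel analyses

Gardner–Eberhart analysis II partitions the heterosis table into average
heterosis, zero-sum variety heteroses `H_j* = (N−1)/(N−2)(H̄_j. − H*)`
and specific heteroses with zero row sums; the partition is saturated, so
reconstruction is exact.  The plain row-mean variant of the variety
heterosis is exposed separately, because the zero-sum definition is the
one that makes the restriction set and the reconstruction identity hold
simultaneously.  Griffing method 2 uses the full-table mean (diagonal
included); method 4 solves the least-squares normal equations
`g_j = (N−1)(rowmean_j − mean)/(N−2)` under Σg = 0, verified against a
brute-force constrained projection.  Because the method-4 model carries
an intercept, the mean epistatic offset of the crosses is absorbed in the
grand mean rather than left inside the SCA effects.

Correlation metrics (Pearson) relate the decomposition effects to allele
frequency summaries: mean frequency versus variety/GCA effects, mean
absolute pairwise frequency difference versus heterosis/specific
heterosis/SCA, parent-versus-rest frequency divergence versus variety
heterosis and |SCA with itself|, and |mean frequency − 0.5| versus the
inbreeding change.  Zero-variance inputs are flagged as undefined rather
than silently dropped.  With no epistasis *and* no dominance the
GCA–frequency correlation is exactly 1 (GCA is then linear in allele
content); with dominance a frequency-product term enters the cross means
and the correlation is very high (≈0.9999 at the default design) but not
exactly 1 — the identification of superior parents remains perfect in
rank terms.

## Study design and defaults

The default study reproduces the reference design sizes: nine populations
(36 crosses, 9 selfed populations), 20 DHs per population (180 lines,
16,110 single crosses) and 100 subsets of 20 DHs (190 crosses each).
Population mean frequencies default to (0.1, 0.2, 0.3, 0.5, 0.6, 0.5,
0.7, 0.8, 0.9); the two populations at 0.5 differ in founder divergence
(0.5 versus 0.1; all others 0.25), so they share means but not LD.
Selfed populations use one selfing generation.  The scenario grid crosses
{no epistasis, seven types, admixture} × {25 %, 100 %} × {ratio 1, 10},
optionally duplicated without dominance; every scenario re-samples the
epistatic effects from its own derived seed stream, and a full run is
bit-identical given the master seed.  Heritabilities (10 % plant-level for
populations, 30 %/70 % for DHs and crosses) apply to phenotype simulation
only; all analyses here use parametric genotypic values, so no estimation
error enters the decompositions.

The full default study (population and DH experiments, 33 scenarios each)
runs in well under a minute on a single core; the Monte-Carlo oracle
tests use 10^5 individuals on a 20-gene genome, which keeps the standard
errors a factor ~100 below the effects being checked.

## What the generator does and does not emulate

The simulator emulates finite biallelic architectures with LD generated
by admixture-style founder crosses, digenic epistasis of the seven
classical types with variance-controlled magnitude, selfing and
DH-derivation.  It does not model mutation, migration, selection,
genotype×environment interaction, multi-trait pleiotropy, higher-order
epistasis, marker genotypes, or interference in meiosis.  Passing tests
therefore demonstrate the internal consistency of theory and simulation
under this architecture, not the behaviour of real breeding data, where
allelic series, directional LD from selection, and G×E would all
intervene.

## Known limitations

* The minimum-norm completion of the epistatic table given `I22` is one
  of infinitely many solutions of the pattern constraints.  It is
  canonical and reproducible, but the *systematic* part of the resulting
  epistatic deviations (the class-mean shifts) behaves like
  allele-masking gene action for the duplicate, dominant and recessive
  types and therefore *increases* average population heterosis as the
  epistatic fraction grows; dominant-and-recessive epistasis strongly
  decreases it, and the DH average heterosis is maximised under duplicate
  genes with cumulative effects and non-epistatic genic interaction
  (≈32 and ≈33 g/plant at the defaults).  Alternative completions that
  redistribute the class values differently can reverse some of these
  directions; the package exposes the construction in one place
  (`build_epistasis_table`) to make such variants easy to add.
* Component attribution (not totals) for crosses between populations with
  unequal gene frequencies depends on the reference-frequency convention,
  as described above.
* The beta-sampled population frequencies make extreme frequencies
  possible; they are clipped away from 0 and 1 (1e-4) so that effect
  decompositions at population frequencies stay well-conditioned.
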