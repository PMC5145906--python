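# Methods

## Pedigree model

Individuals are nodes of a directed acyclic graph with at most one sire
and one dam each. Founders — individuals without recorded parents,
including auto-created stubs for parents referenced but absent from the
input — are assumed mutually unrelated and non-inbred. Kinship is
computed by the classic recursion, expanding at each step the pair
member furthest from the founders (by longest-path rank, which
guarantees that an ancestor of the other member is never expanded) and
memoizing over canonically ordered pairs, so repeated queries against
one pedigree are cheap.

**Generation counting.** Depth is measured in ancestor generations
above a focal individual: parents are generation 1, grandparents 2.
A "complete three-generation pedigree" in the studbook literature
(focal + parents + grandparents) therefore corresponds to
`ancestor_complete_depth >= 2`, a four-generation pedigree to `>= 3`.
All APIs take the ancestor-generation depth.

**Truncation.** A depth-limited coefficient is computed on a pruned
view of the pedigree in which any node whose minimum generation distance
from the focal individual(s) equals the limit loses its parent links,
i.e. ancestors beyond the limit become fresh unrelated founders. Because
raising the limit only ever adds inbreeding loops with positive
contributions, F is non-decreasing in depth, and a population's count of
individuals with F > 0 is non-decreasing too — the qualitative signature
of moving from grandparent- to great-grandparent-complete data.
Completeness is metadata: F is also computable for individuals whose
pedigrees are incomplete at the requested depth, and callers decide
whether to filter on `ancestor_complete_depth`.

**Classification.** For an inbred individual the inbreeding loops
connecting its parents are enumerated as pairs of ascending paths that
meet at a common ancestor and share no other node; each loop contributes
(1/2)^(n_up + n_down + 1) (1 + F_ancestor) and the contributions sum
exactly to F (verified by property test). Loops are labelled by path
lengths — shared parent: half- or full siblings; one breeder the other's
parent: parent-offspring; lengths (1,2): uncle-niece or aunt-nephew by
the sex of the closer breeder; (2,2): first cousins; anything else
"other" with the raw path description retained. The kin line (maternal /
paternal / both) follows from each breeder's first step toward the
ancestor, using only the descendant's step for ancestor-descendant
pairs.

**Gene-dropping oracle.** F estimates are cross-checked by Monte-Carlo
transmission of globally distinct founder alleles down the full
pedigree, vectorized across replicates; the IBD frequency at the focal
individual is an unbiased estimator of F with binomial standard error.
The oracle shares no code with the recursion.

## Marker estimators

SH, IR and HL are computed from per-locus sample allele frequencies
obtained by counting both allele copies of every typed individual, the
focal individual included (the convention of the estimators' reference
implementations); an option recomputes frequencies with the focal
individual excluded. The SH denominator averages the *observed*
population heterozygosity over the individual's typed loci — the phrase
"mean heterozygosity of all loci typed" is ambiguous between observed
and expected, observed was chosen and expected is available via a flag.
Degenerate cases (all typed loci monomorphic, too few typed loci) yield
NaN with the individual retained in the output, never silently dropped.
No Hardy-Weinberg or null-allele correction is applied. Minimum loci
default: 10, matching the lower edge of typical STR panels (11–42 loci).

## Avoidance permutation test

The test conditions on the observed offspring (their mothers, birth
dates and groups) and re-assigns only sires. Candidate sires for an
offspring are the males alive at its conception (birth date 166 days
before birth — rhesus gestation; configurable), aged at least 4.0 years
(configurable; captive maturation estimates are 3–3.5 y), and passing
the same pedigree-completeness filter as the tested pairs. Pools are
split by the mother's group at conception into natal (living in their
birth group, which is the mother's group), within-group non-natal, and
extra-group males.

Each simulated dataset partitions offspring into categories with exact
counts round(p·n) (24% extra-group, 16% natal, 60% within-group by
default; a Bernoulli per-offspring mode is available), then draws a sire
uniformly from the category pool. The within-group pool is first thinned
to a "skew subsample" of max(1, round(0.2·|pool|)) males, drawn once per
(group, birth-cohort) per simulation — optionally restricted to an age
window such as 9–11 years, falling back to the full pool when the window
is empty. An offspring whose category pool is empty falls back to the
within-group subsample (logged and counted); an offspring with no pool
at all is excluded with a warning. Mothers may be re-paired with their
true sire: the observed dataset is explicitly one of the n_sim.

P = (number of datasets with mean parental relatedness ≤ observed) /
n_sim, observed included, hence P ∈ [1/n_sim, 1] and never 0. The test
is one-sided: small P means the realized pairs are less related than
the mating structure predicts. Observed relatedness histograms are
reported over the classes {0, 1/16, 1/8, 1/4, 1/2} attainable in
shallow pedigrees, with intermediate values in an "other" class.
Relatedness is computed on the full recorded pedigree by default
(a truncation depth is configurable); values are memoized per pair
across all simulations.

## Synthetic populations

The generator emulates the founding structure of an island macaque
colony: 409 founders (183 adult females, 40 adult males, the remainder
immatures of random sex) spread over 7 social groups (defaults;
everything is configurable), with highly polymorphic codominant markers
(30 loci, 8 alleles each, per-locus frequencies drawn from a symmetric
Dirichlet, founder genotypes Hardy-Weinberg). Years proceed as discrete
birth seasons: each adult female gives birth with probability 0.5; sires
are assigned by exactly the null scheme above (extra/natal/within with
skew subsampling), then filtered through a tunable kin-avoidance rule —
a candidate related to the mother at r ≥ 0.0625 is rejected with
probability θ and redrawn. θ = 0 reproduces the null scheme; θ = 1
rejects every related candidate (after a redraw budget the least-related
candidate is taken). Newborn males draw a dispersal age of 3 years plus
an exponential with overall median 4.5 years (the field range is
3–5.5 y) and move to a uniformly chosen other group; females are
philopatric. Mortality is 14.4% in the first year of life and 4%/year
thereafter (the first value is documented for the emulated colony, the
second is an order-of-magnitude choice giving realistic age structure);
optional culling of juveniles caps population size. Founder males carry
no birth group — they were introduced, not born, into their groups — so
none counts as natal.

Genotypes are produced by Mendelian gene dropping from the founder
genotypes, with optional whole-genotype missingness. One seeded
generator drives founding, demography, mating and gene dropping, so a
seed fully determines every output file.

**What the generator does not emulate**: hurricanes and epidemics,
group fission, dominance hierarchies, genotyping error beyond
missingness, mutation, multiple male group transfers. Tests passing on
these populations show that the pipeline's logic is sound under its own
assumptions, not that any particular wild population satisfies them.

## Calibration and power experiments

`replicate_avoidance_pvalues` simulates many independent populations and
runs the test on each. For the type-I-error experiment the generator
uses θ = 0 and the test is configured so that the observed dataset is
exchangeable with the simulated ones: the completeness filter is
disabled (early-cohort parents are founders and would otherwise be
filtered asymmetrically) and both generator and test use the Bernoulli
category partition. Under these conditions P is uniform on
{1/n_sim, …, 1} up to ties and the α = 0.05 rejection rate over 200
replicate populations falls within the binomial 95% CI of 0.05.
The power experiment uses θ = 1, where the observed mean is typically
below every simulated mean and the test rejects in well over 90% of
runs. Replicate populations use 80 founders in 3 groups over 12 years
(~300 breeding pairs) and 100 simulations per test — sizes chosen to
make the experiments cheap while keeping the P-value granularity (0.01)
fine enough for an α = 0.05 decision.

## Numerical and design notes

* Ages are computed as days/365.25; group-membership intervals are
  half-open [start, end); dates are ISO-8601 throughout.
* Subset sizes use round-half-up (floor(x + 0.5)), so a 20% subsample of
  10 males has exactly 2 and of 3 males has 1 (the minimum-one rule).
* Missing parents are encoded NA (0 also accepted on read); a missing
  parent makes F undefined (reported as such), never 0.
* Parent/offspring date-order violations warn by default and fail in
  strict mode; sex-inconsistent parent links and cyclic parentage always
  fail with the offenders named.
* Kinship values are exact binary fractions for the canonical
  configurations, so equality assertions in the tests are exact.
* The avoidance machinery is organised in the model/results idiom
  (`MateChoiceNullModel.fit() -> AvoidanceResults` with `summary()` and
  `plot_null()`); the pedigree and estimator layers are plain functions
  and small frozen dataclasses, as they compute coefficients rather than
  fit models.

## Known limitations

* Path enumeration for classification is exponential in depth and meant
  for the shallow depths (≤ 5) where classification is scientifically
  meaningful; F itself uses the recursion and has no such limit.
* The "once per group per cohort" skew subsample is drawn from the union
  of the cohort's per-offspring within-group pools; offspring conceived
  at slightly different dates may have slightly different individual
  pools, and the subsample is intersected with each offspring's own pool
  (falling back to that pool when the intersection is empty).
* With the exact-count partition, category counts are fixed per dataset
  while the generator fixes them per cohort; the Bernoulli mode makes
  the two match exactly and is used in the calibration experiment.
* The test measures avoidance of *reproduction* with kin; it cannot
  distinguish pre- from post-copulatory mechanisms.
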