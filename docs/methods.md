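# Methods

## Setting and assumptions

`spawnrs` analyses a supportive-breeding system in which anadromous
spawners are exhaustively trapped at a barrier, genotyped at a small panel
of highly polymorphic microsatellites, and compared with a sample of the
river-born fry of the following spring. The analysis assumes:

- candidate parents and offspring are genotyped at the same loci, with
  alleles recorded as fragment sizes in base pairs;
- scoring errors displace an allele by whole repeat units (±1 unit far
  more often than ±2, never more than 2);
- parents with any failed locus are excluded from allocation (the engine
  requires complete parental genotypes; offspring rows with failed loci
  are flagged, not silently dropped);
- a substantial fraction of true parents — mature resident parr above
  all — is never sampled, and the method must say so rather than force an
  assignment;
- a spawner's reproductive success (RS) is proxied by the number of
  sampled fry allocated to it. Sampling effort varies by year, which is
  why year enters the count models as a fixed factor, and the yearly RS
  is treated as a lifetime proxy (iteroparity is rare in this system).

## Allocation model

For offspring allele *x* and candidate parent *P*, the supply cost is
`d(P, x) = min over alleles a of P of round(|x − a| / motif)`, admissible
only if `d ≤ max_offset` (default 2 units). At one locus a parent pair
(A, B) must supply one offspring allele each; the locus is scored by the
assignment minimising, lexicographically, (number of unattributable
alleles, summed supply cost). A locus with an unattributable allele is
*incompatible*; the per-locus bad-allele minimum is what the origin
classifier later counts, so "at most one incompatible allele" means: over
all loci, at most one offspring allele cannot be drawn from the allocated
pair within tolerance (one incompatible locus may contribute one or two).

A pair is admissible if its incompatible-locus count is at most
`max_incompatible_loci` (0 for fry allocation, 1 when screening returning
adults against the broodstock) and its summed cost is at most
`offset_budget`. The unique admissible pair minimising (incompatible
loci, cost) wins; an exact tie leaves the offspring unallocated with
status `ambiguous`. The two configured tie rules coincide under this
lexicographic key (a tie at the minimum is unallocated either way); both
are accepted for interface compatibility and documented here.

**Offset budget.** The default budget is `2 × max_offset = 4` units.
Under the conservative error model (±1 unit at 5%, ±2 at 1% per
transmitted allele, 16 transmitted alleles over 8 loci) the summed cost of
a *true* pair is approximately Poisson-binomial with mean ≈ 1.1, and a
budget of 2 would reject a true pair about 12% of the time, visibly
inflating the uncollected-parent estimate (≈ +0.06 even with every parent
collected). A budget of 4 keeps that rejection rate below ~2% while a
random pair still has to match at every locus within tolerance, which the
panel's polymorphism makes improbable.

**Single-parent allocation** is attempted only after pair allocation
fails: a lone candidate is admissible if at every locus at least one
offspring allele is within tolerance of one of its alleles, with the
summed attributed cost inside the same budget. This realises the
"one collected + one uncollected parent" outcome without modelling the
missing genotype; sexes are deliberately ignored throughout (sex calls
from external morphology are unreliable in this system).

**Uncollected parents.** Allocation is repeated on locus prefixes
*l* = 1…*L* (input order by default; optionally ordered by Monte-Carlo
estimated single-locus exclusion power). The pair-allocation rate settles
as loci accumulate; a plateau is declared when the relative change over
the last step is below 0.01. The share of parental slots attributed to
uncollected parents is estimated at the full panel as
`1 − (2·pairs + singles) / (2·offspring)`. Without a detected plateau the
estimate is still reported, flagged as possibly overestimated — the
estimate declines as informative loci are added.

**Correct-allocation rate.** Virtual parents are built by i.i.d. allele
resampling from empirical frequencies, a configured number of them
withheld; 1000 pseudo-offspring per round are bred with fair-coin
Mendelian transmission, errors injected on transmitted alleles only
(scoring-error semantics), re-allocated, and scored: both-collected truth
requires the exact pair, one-collected truth requires the single, and
none-collected truth requires an unallocated outcome. The point estimate
is the mean over rounds (10 by default).

## Origin classification

Precedence: (1) a true scale-growth smolt flag → smolt-stocked; (2) else
an allocation to two broodstock parents with ≤ 1 incompatible allele →
fry-stocked; (3) else, with a known scale flag and a complete genotype,
wild; (4) else unknown. Adults born before the broodstock pool was
genotyped can only fall into the wild class, so early-year hatchery
counts are underestimates and summaries should be read per year with that
caveat.

## RRS and contingency statistics

RRS is the ratio of group mean RS (focal over reference). Confidence
intervals are percentile bootstrap over individuals resampled with
replacement within each group independently (10 000 resamples by
default); resamples with a zero reference mean are redrawn and logged.
The multi-year summary is the weighted geometric mean
`exp(Σ wᵢ ln rᵢ / Σ wᵢ)` with yearly focal-group spawner counts as
default weights — with the published yearly ratios and hatchery counts
(15/86/142) this weighting reproduces the published ≈ 0.53, which is why
it is the default; the original weighting is not stated.

Representation (hatchery share among known-origin spawners) and
contribution (hatchery share among collected-parent dyads) are compared
by Pearson χ² without continuity correction on the two count pairs. Two
caveats are deliberate:

- The χ² variant behind some published test statistics is not
  recoverable: on counts reconstructed from the published tables this
  implementation gives 10.27 where 9.63 was printed; neither corrected
  nor uncorrected Pearson reproduces the printed value, so the choice is
  fixed, stated, and surfaced rather than matched.
- The test treats the spawner sample and the dyad sample as independent
  draws from a common superpopulation. When the very spawner pool that
  was scored for representation also generates the dyads, the samples are
  coupled and the test's size deviates from nominal (its calibration
  tests therefore simulate the independent-samples null the statistic
  assumes). On real data the p-values should be read with this in mind.

## Count models

Individual RS is modelled as Poisson with log link on year, sea-winter
class, stocking stage and sex (treatment coding against year 2002, MSW,
fry-stocked, female), optionally with all two-way interactions among the
last three factors. Rows with an undetermined level of any term *in the
model* are excluded, with the count logged — a model without sex can
legitimately use more rows, but model comparisons require a shared row
set and the analysis-of-deviance helper enforces equal n. Fitting is
IRLS via statsmodels (deviance tolerance 1e-8, 100 iterations); no
overdispersion adjustment is applied, but the Pearson dispersion is
reported for diagnostics. Nested fits are compared by the χ² distribution
of the deviance difference.

## Scenario simulator

The generator emulates the study conditions end to end: eight loci with
14–51 alleles (Dirichlet(1) frequencies over a contiguous repeat ladder,
giving expected heterozygosities around 0.85–0.95); yearly spawner pools
with the observed wild / fry-stocked / smolt-stocked counts; a
broodstock of ~20 founders whose offspring (the hatchery-born returnees)
are therefore full- and half-sibs — this is what makes
misassignments concentrate among stocked fish mechanistically rather
than by construction; per-stage MSW proportions and a male-biased sex
ratio with a 31% unknown-sex rate; per-locus amplification failures on
adults at a rate giving ~10% incomplete genotypes; and uncollected parr
sires holding each parental slot independently with probability 0.275
(the middle of the observed 25–30% dyad range), with parr allele
frequencies defaulting to the wild pool's (no parr genotype data exist;
the assumption is flagged here).

Offspring counts arise by drawing, for each of the year's sampled fry,
two distinct parents with probability proportional to a multiplicative
fitness weight (origin × sea-winter × sex × year effort). The hatchery
multiplier is calibrated analytically at generation time so that the
*expected* pooled hatchery:wild mean-RS ratio equals the configured
`true_rrs` (default 0.55) despite composition differences between
origins; the *realised* ratio of a single replicate still fluctuates by
roughly ±0.05 at these sample sizes, so estimator checks compare the
pipeline estimate against the realised true ratio of the same replicate.

What the simulator does not emulate — and what passing tests therefore do
not establish about field data: genuine allele-frequency structure
(mutation ladders, null alleles, large-allele dropout beyond two units),
scale-reading errors, non-independent mate choice, multi-generation
introgression, and sampling that is spatially biased along the river.

## Numerical and degenerate-input choices

- Offset distances use `round()`; allele sizes not congruent modulo the
  motif trigger a single off-ladder warning at table construction.
- All randomness flows from one integer seed through named
  `SeedSequence` sub-streams per stage, so any stage is reproducible in
  isolation; identical inputs and seed give byte-identical outputs.
- Empty candidate sets, empty offspring sets, single-allele loci,
  single-individual bootstrap groups and all-zero reference groups
  degrade to flagged results or explicit errors, never silent numbers.
- With fully related candidates (e.g. full sibs of a true parent carrying
  identical transmitted alleles at every locus) the evidence is genuinely
  ambiguous and the engine says so; this is conservative and is why the
  zero-noise "100% recovery" property is stated for unrelated candidate
  pools.
- JSON reports round to 6 significant digits with fixed key order for
  diff-stable regression tests.

## Problem sizes

The validation suite runs the arithmetic checks at the published table
values; the simulation checks use 300-parent virtual pools with 1000
pseudo-offspring (allocation properties), 500 replicates of 200-spawner
groups (bootstrap coverage), 2000 replicates of the contingency null, 200
replicates at n = 539 (GLM recovery), and 5 full-pipeline replicates at
the study's sample sizes — sizes chosen so the whole suite completes in
well under a minute per property while keeping Monte-Carlo error small
against each tolerance.

## Known limitations

- Exclusion-based allocation reports hard categories; it does not weigh
  likelihoods, so it cannot rank two imperfect-but-admissible pairs other
  than by offset cost, and genuinely ambiguous cases reduce the assigned
  sample instead of being resolved probabilistically.
- The uncollected-parent estimate inherits any residual budget-induced
  demotion of true pairs (kept below ~2% by the default budget) and the
  upward bias of an undetected plateau.
- RS from a partial fry sample is a relative, not absolute, fitness
  measure; between-year comparisons are meaningful only through the year
  factor in the count models.
- The origin classifier cannot see hatchery-born adults whose broodstock
  parents predate genotyping; wild-class counts absorb them.
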