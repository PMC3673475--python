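# spawnrs

Parentage-based estimation of the **relative reproductive success (RRS)**
of hatchery-born versus wild-born spawners in supportive-breeding salmonid
programs.

Supportive breeding — supplementing a wild population with captive-bred
offspring of locally caught breeders — is widespread in Atlantic salmon
(*Salmo salar*) management, yet fish reared even a single generation in a
hatchery often reproduce poorly once released. Quantifying that deficit
requires reconstructing who parented whom from multilocus microsatellite
genotypes, in a setting where a quarter or more of true parents (notably
mature resident parr) are never sampled. `spawnrs` is a tested, reusable
implementation of that whole analysis chain for population geneticists and
fisheries scientists:

- **Offset-tolerant exclusion parentage.** An offspring allele may be
  attributed to a candidate parent if it lies within `max_offset` tandem
  repeat units (default ±2) of one of the parent's alleles, absorbing
  microsatellite scoring errors. A candidate pair is admissible when its
  incompatible-locus count and summed offset cost stay within caps, and
  the unique admissible pair minimising (incompatible loci, cost) is
  retained; exact ties are conservatively left unallocated. Failing a
  pair, a single-parent allocation realises the "one collected + one
  uncollected parent" outcome.
- **Uncollected-parent estimation** from cumulative allocation over locus
  prefixes *l* = 1…*L*: the collected fraction of parental slots at the
  full panel estimates the share of slots held by unsampled parents.
- **Correct-allocation rate** by simulation: pseudo-offspring are bred
  from virtual parents resampled from empirical allele frequencies, with
  ±1-unit errors at 5% and ±2-unit errors at 1% per transmitted allele
  (deliberately conservative), then re-allocated and scored against truth.
- **Spawner origin classification**: smolt-stocked adults carry a scale
  growth-pattern flag; fry-stocked adults are detected genetically as
  allocations to two hatchery broodstock parents with at most one
  incompatible allele.
- **RRS statistics**: RRS = mean RS(focal) / mean RS(reference), where RS
  is the number of sampled juveniles allocated to a spawner; percentile
  bootstrap CIs (10 000 resamples of individuals within group); weighted
  geometric means across years; Pearson χ² comparisons of hatchery
  *representation* among spawners against hatchery *contribution* among
  offspring–parent dyads.
- **Poisson log-linear GLMs** of individual RS on year, sea-winter class
  (SSW/MSW), stocking stage (wild/fry/smolt) and sex, with all two-way
  interactions among the last three, compared by χ² analysis of deviance.
- **A forward scenario simulator** that generates genotypes, metadata,
  true pedigree and true fitness parameters with the structure the
  analysis assumes (few-founder broodstock relatedness, uncollected parr
  sires, amplification failures), so every stage is testable end to end.

## Worked example

```python
from spawnrs import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=1))
est = bundle["rrs_report"]["pooled_hatchery_vs_wild"]
truth = bundle["truth"]
print(f"collected-pair allocations : {(bundle['allocations']['status'] == 'pair').sum()} of {len(bundle['allocations'])} fry")
print(f"single-parent allocations  : {(bundle['allocations']['status'] == 'single').sum()}")
print(f"classified hatchery-born   : {(bundle['origins']['origin'].isin(['fry_stocked','smolt_stocked'])).sum()} adults")
print(f"pooled RRS (hatchery/wild) : {est['point']:.3f} (95% CI {est['ci_low']:.3f}-{est['ci_high']:.3f})")
print(f"true RRS in this scenario  : {truth.true_rrs():.3f}")
```

prints

```
collected-pair allocations : 456 of 1141 fry
single-parent allocations  : 556
classified hatchery-born   : 235 adults
pooled RRS (hatchery/wild) : 0.565 (95% CI 0.470-0.678)
true RRS in this scenario  : 0.569
```

The default scenario emulates a three-year monitoring program of a small
anadromous population (spawner pools of 135–348 adults per year, 1141
sampled fry, eight loci with 14–51 alleles each, ~27.5% of parental slots
held by unsampled parr, true pooled RRS 0.55): 456 fry are allocated to
two collected parents and 556 to one collected + one uncollected parent,
and the pipeline's RRS estimate (0.565) agrees with the realised true
ratio (0.569) well inside the bootstrap interval.

The same stages are available from the shell:

```sh
spawnrs run --seed 1 --out results/
spawnrs simulate --seed 1 --out data/
spawnrs rrs --rs rs_table.csv --group origin --reference wild --nboot 10000 --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `spawnrs.genotypes` | genotype tables, CSV/GenePop I/O, allele frequencies, heterozygosity |
| `spawnrs.allocation` | pair costs, allocation engine, cumulative allocation, pseudo-offspring simulations |
| `spawnrs.origins` | wild / fry-stocked / smolt-stocked classification |
| `spawnrs.rrs` | RS counting, bootstrap RRS, contingency comparisons |
| `spawnrs.glm` | Poisson log-linear RS models, analysis of deviance |
| `spawnrs.simulate` | scenario generator with true pedigree |
| `spawnrs.datasets` | published count/mean-RS/deviance tables used as fixtures |
| `spawnrs.pipeline`, `spawnrs.cli` | orchestration and command-line interface |

See `docs/methods.md` for the statistical model, numerical choices and
known limitations.
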