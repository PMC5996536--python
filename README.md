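# pedlink

Posterior probability of linkage (PPL) analysis for extended multiplex
pedigrees — built for family studies of autism spectrum disorder (ASD) and
the broad autism phenotype (BAP), but generic over any dichotomous trait
segregating in large, loop-free pedigrees.

Genome-wide association has explained little of the strongly familial,
heritable component of ASD. An alternative strategy collects extended
pedigrees dense in ASD and subclinical BAP cases and asks, at each genomic
position, how strongly the data support a trait locus there. `pedlink`
implements that analysis end to end at desk scale: LINKAGE-format I/O and
validation, the genotype-cleaning protocol (missingness, Mendelian-error
repair, founder Hardy–Weinberg, LD thinning), exact trait–marker two-locus
pedigree likelihoods by Elston–Stewart peeling, Bayes-ratio integration over
trait models, pooled and sequential evidence accumulation across pedigrees
and cohorts, peak calling, and a gene-dropping simulator that produces
ascertained multiplex cohorts with known ground truth.

## The statistic

At each marker the Bayes ratio integrates the admixture likelihood ratio
over the trait-parameter grid — recombination fraction θ, Smith's admixture
proportion α of linked pedigrees, disease-allele frequency p, and the
penetrance vector f₁ ≥ f₂ ≥ f₃ (phenocopies allowed):

    BR = E[ (α·L(θ, p, f) + (1 − α)·L(½, p, f)) / L(½, p, f) ]
    PPL = π·BR / (π·BR + 1 − π),        π = 0.02 by default

PPL is on the probability scale: PPL > π supports a trait gene at the
position, PPL ≤ π is evidence against, and no multiple-testing correction is
ever applied. Per-pedigree BRs multiply under Bayesian sequential updating —
the same rule that combines independently collected cohorts. See
`docs/methods.md` for the model, grids, numerics and limitations.

## Worked example

```python
from pedlink import (
    LinkageScanModel, PplConfig, SimConfig, MapSpec, TraitModel,
    simulate_cohort,
)

cfg = SimConfig(
    n_pedigrees=15, generations=4, true_alpha=1.0,
    asd_given_affected=1.0, unknown_rate=0.0,
    true_trait_model=TraitModel(0.1, 1.0, 1.0, 0.0),   # dominant, no phenocopies
    map_spec=MapSpec(n_chromosomes=10, markers_per_chromosome=10, spacing_cm=10.0),
)
pedigrees, marker_map, truth = simulate_cohort(cfg, seed=1)

model = LinkageScanModel(pedigrees, marker_map, trait="ASD",
                         config=PplConfig.coarse())
results = model.fit()
print(results.summary())
```

Output (seed 1; the causal locus is the middle of chromosome 1):

```
Posterior Probability of Linkage — scan summary
========================================================
trait:            ASD
mode:             SEQUENTIAL
prior pi:         0.02
pedigrees:        15 (865 members, 219 ASD, 0 BAP)
positions:        100 markers, 10 chromosomes
grid points:      3150
max PPL:          0.9803 at rs1_7
evidence against: 69.0% of positions (PPL <= 0.02)
--------------------------------------------------------
salient peaks (PPL >= 0.20):
chrom  peak_cM    PPL    narrow        intermed      broad
    1    60.00  0.980  [30.00,70.00]  [20.00,70.00]  [20.00,70.00]
```

Reading it: the scan recovers the simulated locus. The causal marker sits
at 50 cM on chromosome 1 (`rs1_6`); the track peaks one marker over at
60 cM with PPL 0.98 — a 49-fold lift over the 2% prior — and the narrow
support interval [30, 70] cM brackets the true position, the ~1 cM-at-best
localisation of two-point linkage writ large. Meanwhile 69% of positions
(all on the nine unlinked chromosomes) fall at or below the prior, i.e.
accumulate evidence *against* linkage as pedigrees multiply.
`results.call_peaks()` returns the peak objects, `results.plot(prefix)`
writes per-chromosome tracks, and `results.update(other)` sequentially
merges a second cohort's scan.

A `pedlink` console script exposes the same pipeline
(`simulate`, `qc`, `scan`, `update`, `peaks`, `plot` subcommands).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a seeded simulate → QC → scan → peak-call pipeline as an end-to-end
exercise, then recomputes, through the package's Bayes-ratio → PPL
transform, the calibration fold-ratio of posterior to prior at a combined
Bayes ratio of 12.25 under the default 2% prior, and writes it as JSON.
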