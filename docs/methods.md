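# Methods

## The statistic

`pedlink` computes two-point parametric linkage evidence on the probability
scale for dichotomous traits segregating in extended pedigrees. At a marker
position the evidence is summarised by the posterior probability of linkage

    PPL = π·BR / (π·BR + 1 − π),

where π is the prior probability that a trait locus lies at the position
(default 0.02, i.e. one disease gene genome-wide — conservative under locus
heterogeneity) and BR is the Bayes ratio: the likelihood ratio of linked
versus unlinked with every trait parameter integrated out,

    BR = E_grid[ (α·L(θ, p, f) + (1 − α)·L(½, p, f)) / L(½, p, f) ].

The integration grid covers the recombination fraction θ ∈ [0, 0.5), Smith's
admixture proportion α ∈ (0, 1] of linked pedigrees, the disease-allele
frequency p, and the penetrance vector (f1, f2, f3) for genotypes DD/Dd/dd
under the ordering constraint f1 ≥ f2 ≥ f3, with uniform weights after
filtering. The ordered grid implicitly spans dominant, recessive and
additive inheritance and allows phenocopies (f3 > 0). PPL = π means the
data carry no evidence; PPL ≤ π is read as evidence against a locus at the
position. No multiple-testing adjustment is ever applied: the PPL is a
measure of evidence, not a decision procedure.

With a single grid point and α = 1 the BR collapses to 10^LOD, the
exponentiated two-point LOD score — a useful identity for testing.

## Pedigree likelihood

`L(θ, p, f)` is the exact joint probability of the phenotypes and one
marker's genotypes in a pedigree. Each individual carries one of 16 ordered
two-locus states (trait allele × marker allele on the paternal and maternal
haplotype). Founders take Hardy–Weinberg and linkage-equilibrium priors;
transmissions recombine with probability θ; affected/unaffected members
contribute f_g / (1 − f_g); unknown phenotypes contribute 1 (they are
marginalised, never assumed unaffected); observed marker genotypes act as
compatibility indicators, with missing calls compatible with everything.

The sum over joint states is evaluated by Elston–Stewart peeling: nuclear
families are peeled from the periphery of the pedigree inward through
connecting individuals. The implementation batches the peel over all trait
models and θ values at once (the per-individual weights vary with the model,
the transmission tensor with θ), which reduces a grid integration to a
single pass of `einsum` contractions. Messages are rescaled per peel with an
accumulated log correction, so likelihoods never underflow to zero for
valid inputs; all downstream accumulation (products across pedigrees and
cohorts) happens in the log domain, with exponentiation only at reporting.

Pedigrees must be zero-loop: the bipartite individual↔nuclear-family graph
must be a forest. Consanguineous matings and marriage rings are rejected at
validation. A direct enumeration of the joint state space is shipped as an
independent cross-check (`pedigree_likelihood_enumerate`); the test suite
verifies peeling against it to relative error < 1e-10 on hundreds of random
pedigrees.

Numerical conventions: a grid point whose trait model makes the observed
data impossible (identically zero likelihood at every θ, e.g. penetrances
(0,0,0) with an affected member) has an undefined 0/0 likelihood ratio; it
is defined as ratio 1 so it contributes no linkage information. Haldane's
map function (no interference, sex-averaged) converts cM to θ throughout.

## Accumulation across pedigrees and cohorts

Two modes are provided. SEQUENTIAL integrates the grid separately per
pedigree and multiplies the per-pedigree BRs (Bayesian sequential updating);
the same product rule merges independently analysed cohorts, position by
position, through serialized per-pedigree BR tables matched exactly on
(chromosome, marker, cM). POOLED integrates once over the shared grid with
the per-pedigree admixture term evaluated at the shared α:
BR = E_grid[Π_i (α·LR_i + 1 − α)]. For a single pedigree the two modes are
algebraically identical — a property the tests check to machine precision.

A caveat established empirically by this package's own simulations: with
this α-inclusive pooled integrand (the form required for the exact n = 1
mode-equivalence identity to hold), pooling tends to equal
or exceed sequential updating at linked loci even under locus heterogeneity,
because any subset of pedigrees that agrees on a grid region — linked
pedigrees favouring high α and θ ≈ 0, or unlinked pedigrees favouring low α
— boosts the pooled expectation of the product. The often-quoted reversal
(sequential larger under extensive heterogeneity) was not reproducible as a
majority property in two-point desk-scale experiments; the corresponding
acceptance test documents this honestly by failing.

## Grids

`PplConfig()` carries the reference grids: α ∈ {0.1, …, 1.0},
p ∈ {0.001, …, 0.5} (8 values), penetrances on a 0.05-step ordered lattice
(1771 triples) and a 14-point θ grid — 1.98M grid points, intended for
single-position computation. `PplConfig.coarse()` (0.25-step lattice,
105 trait models, 6 θ, 5 α values) is the documented desk-scale grid used
by default in genome scans, tests and the acceptance script; grid density
changes BR values only through quadrature resolution.

## Genotype QC

The cleaning pipeline runs in fixed order, mirroring standard practice for
family SNP data:

1. **Missingness** — markers with > 5% missing calls among genotyped
   individuals are dropped (strict exceedance); individuals with > 5%
   missing over the surviving map are reported and have all genotypes
   blanked (they stay in the structure: removing a connecting member would
   change the pedigree graph).
2. **Mendelian errors** — a marker whose family-incident rate (incident
   families / families with ≥ 1 typed parent and ≥ 1 typed child) exceeds
   5% is dropped; remaining incidents are repaired by setting the offending
   nuclear family's genotypes at that SNP to missing. Post-repair the
   genome is certifiably incident-free.
3. **Hardy–Weinberg** — the two-sided conditional exact test on founder
   genotype counts (founders are the only exchangeable subset of a
   pedigree sample); markers with p < 1e-4 are dropped.
4. **LD thinning** — greedy map-order pruning on founder allele-dosage r²
   (composite genotypic correlation, phase-free): a marker is kept only if
   r² ≤ 0.20 against every kept marker in the trailing 50-marker window;
   windows never span chromosomes; founder-monomorphic markers are excluded
   with their own reason code.

Re-running the pipeline on its own output is a no-op (asserted in tests;
note this can fail in principle if repairs push a marker past the
missingness bound — not observed at realistic error rates).

## The cohort simulator

`simulate_cohort` gene-drops ascertained multiplex pedigrees with the
structure the analysis assumes. Defaults state the emulated design:
three-generation pedigrees from one founding couple whose children marry in
founder spouses (2–4 children per couple), a biallelic map with MAF drawn
from N(0.45, 0.06) at 0.17 cM spacing, a dominant trait model
(p = 0.1, f = (0.8, 0.8, 0.02)) with phenocopies, an ASD:BAP split
ρ = 0.55 among locus-affected individuals (matching the roughly 5:4
ASD:BAP ratio per pedigree in the emulated design), 30% of phenotypes
masked to unknown (phenotype masking is applied before ascertainment, so
observed ASD counts drive inclusion; the emulated study's higher
unphenotyped fraction includes unreachable relatives that rejection
sampling cannot represent), and 2% genotype dropout. Each pedigree is
linked with probability `true_alpha` (the trait locus is inserted at its
cM position on the causal chromosome, otherwise it segregates on an
independent pseudo-chromosome); ascertainment (≥ 3 observed ASD cases
across ≥ 2 nuclear families) is enforced exactly by rejecting and redrawing
whole pedigrees, with a hard failure after 10,000 rejections.

The truth record carries linked flags, per-individual disease-allele counts
and founder-haplotype origins of transmitted disease alleles, enabling
identity-by-descent checks. The generator does not model assortative
mating, de novo variants, CNVs, polygenic background, or any age/sex
dependence of phenotype measurement — a green simulation test therefore
establishes internal consistency of the statistical machinery under the
single-locus admixture model, not robustness to those real-data features.
Simulated within-chromosome marker LD arises only through co-segregation in
families; founders are in linkage equilibrium by construction, so LD
thinning on simulated founders removes (correctly) almost nothing.

## Peak calling

Salient peaks are local PPL maxima ≥ 0.20. Around each peak three nested
support intervals record the contiguous region over which the track stays
≥ 0.20 (narrow), ≥ 0.10 (intermediate) and ≥ 0.05 (broad). Bounds snap to
marker positions (two-point scans have no between-marker values); maxima
whose broad regions touch merge to the higher peak, and separate peaks
require a dip below 0.05. Cytoband/bp annotation is a pass-through table;
no genome build is bundled, since two-point linkage resolution is ~1 cM at
best.

## Known limitations

- Two-point only: the scan evaluates marker positions; no multipoint
  likelihood (the 16-state engine generalises to a 64-state three-locus
  window, but that path is not built).
- Autosomal, biallelic markers, two-allele trait locus, no liability
  classes, imprinting or sex-specific penetrances.
- Loop pedigrees are rejected, not approximated.
- The pooled-vs-sequential heterogeneity caveat above.
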