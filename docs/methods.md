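# Methods

This note documents the models, statistics and design choices behind
`svpanel`, in the order the pipeline runs them: cohort simulation,
consensus merging, panel characterization, SNP–SV linkage disequilibrium,
and imputation evaluation.  It also states what the synthetic cohorts do
and do not emulate, and therefore what a passing test suite does and does
not demonstrate about real data.

## Coordinates and variant model

All in-memory coordinates are 0-based half-open `[start, end)`; VCF's
1-based inclusive `POS`/`END` are converted only at the I/O boundary.
Insertions (`INS`, mobile-element insertions `MEI`) are anchored points
with `start == end` and `length` = inserted bp; this makes reciprocal
overlap well-defined for every reference-consuming type and lets
insertions be counted by inserted length.  Size classes partition lengths
into short (1–20 bp), mid (21–100 bp) and large (>100 bp).

One htslib subtlety is worth recording: for symbolic `<DEL>`, `<DUP>` and
`<INV>` alleles htslib derives the record length from `SVLEN`, overriding
an explicit `END`.  The writer therefore emits `SVLEN` only for
insertion-like types (where it is the only carrier of length) and encodes
spans purely through `END`.

## Synthetic family cohorts

The generator produces a trio-structured cohort (father, mother, child per
family, plus optional unrelated singletons used as held-out imputation
targets) with known truth at every level.

**Allele frequencies.** Founder allele frequencies are drawn from a
discrete spectrum with `P(AF = j/H) ∝ 1/j` for `j = 1 … H/2`, `H` the
number of founder haplotypes.  This is the shape of an equilibrium neutral
site-frequency spectrum: rare-heavy, with half the mass far below 10%.  It
is a stand-in, not a demographic fit.

**Linkage disequilibrium.** Within blocks of `ld_block_bp` (default
50 kb), every founder haplotype copies one of a pool of
`ld_pool_haplotypes` (default 12) ancestral block haplotypes.  A
configurable fraction of SVs (`sv_tag_fraction`, default 0.3)
additionally ride the ancestral haplotype of their nearest same-block SNP,
creating the high-r² SNP–SV pairs (tag SNPs) the LD stage looks for.  Two
consequences are deliberate and matter for testing: tagged SVs inherit the
tag SNP's frequency rather than their own nominal draw, and pool copying
inflates the sampling variance of founder frequencies above binomial.
The founder-AF-recovery property is therefore asserted in the independent
mode (`ld_pool_haplotypes = 0`, `sv_tag_fraction = 0`), where founder
haplotypes are i.i.d. Bernoulli and recovery is exactly binomial.

**Transmission.** Children are Mendelian recombinants: per chromosome and
meiosis, crossover counts are Poisson(`recomb_rate` × length in Mb;
default 0.01/Mb ≈ 1 cM/Mb) with uniform positions.  Mendelian consistency
of every child allele is structural, not statistical.

**Caller error model.** Each simulated caller has a strategy (split-read,
read-pair, read-depth, assembly), a tabulated sensitivity per size class,
rounded-Gaussian breakpoint jitter (`breakpoint_sd`), and a false-call
rate: false calls are added at Poisson(fdr/(1−fdr) × #true calls) so the
expected false fraction of the call set equals `fdr`.  Truth insertions
are placed with at least their merge tolerance between anchors so that
distinct truth events remain distinguishable after merging.

**Genotype likelihoods.** Per sample×site, read depth is Poisson(depth);
each read reports the alternate allele with probability `g/2` flipped at
`error_rate`.  The emitted triplet is the normalized likelihood product —
the posterior under a uniform genotype prior — hence calibrated by
construction when true genotypes are uniform, which the calibration test
exploits (at depth 12 and 5% read error, calls with max probability
≥ 0.999 are empirically ≥ 99.9% correct over 10⁵ draws).  Zero-depth
sites return the uniform triplet.

**What the simulator does not emulate:** reference sequence and alignment
artifacts, repeat-mediated breakpoint ambiguity, genotyping error that
correlates across samples or with variant class, population structure,
multi-generation pedigrees and twins.  Green tests show the *machinery* is
correct and calibrated under its stated assumptions, not that real-data
error modes are handled.

## Consensus merging

Calls are merged per variant type.  Events larger than 20 bp cluster by
single-linkage under reciprocal overlap
`RO(a,b) = min(|a∩b|/|a|, |a∩b|/|b|) ≥ 0.5`; insertion anchors link when
their distance is at most half the smaller inserted length (reciprocal
overlap is undefined for points).  A cluster becomes a consensus variant
only with support from ≥2 distinct detection strategies; its boundaries
are copied from the supporter whose caller has the best (lowest)
breakpoint-accuracy rank, default order assembly < split-read < read-pair
< read-depth, ties broken by caller name for determinism.  Events of
20 bp and smaller must match exactly on (chrom, start, end, length,
alt sequence) and require ≥2 distinct *callers* — small-indel callers are
all alignment-based, so a distinct-strategy requirement would be vacuous.

Single-linkage was chosen over clique merging because it is invariant
under input order; the trade-off (chains can bridge calls that do not
mutually overlap) is accepted and tested.  A naive O(n²) all-pairs oracle
re-derives the consensus independently (explicit linkage graph, connected
components via networkx); the production sweep must agree with it
record-for-record on a thousand random instances.

## Panel characterization

**Allele frequencies** use founders only by default — offspring alleles
are copies of founder alleles, and counting them would double-weight
transmitted chromosomes; an all-samples mode exists.  MAF quartiles are
per variant class, with boundaries at the empirical 25/50/75 percentiles
and ties assigned downward; the boundaries are reported so statements
like "first-quartile events" are reproducible.

**Novelty** reuses the merge matching rule against user-supplied known
sets (exact for ≤20 bp, RO ≥ 0.5 above).

**Annotation enrichment** compares the observed count of variants
intersecting an annotation with `n_perm` (default 10,000) null sets of
length-matched intervals placed uniformly in a mappable-region mask
(segments weighted by placeable positions).  The empirical p-value uses
the add-one rule `(1+k)/(n_perm+1)`, so its sharp lower bound is
`1/(n_perm+1)`; values below `1/n_perm` print as an inequality
(`P<0.0001`) while the exact value stays in machine output.  A resampling
mode (size-class-matched draws from a variant universe) is provided as an
alternative null.

**Load** sums affected bp per haplotype (deletions by deleted bp,
insertions by inserted bp, complex indels by the larger segment,
duplications/inversions by span), split into indels (≤20 bp simple events
plus complex indels) versus SVs; homozygous load sums variants carried on
both haplotypes and can never exceed either haplotype load.

**TDT** is the McNemar-form transmission disequilibrium test: over all
trios, `b` transmissions and `c` non-transmissions of the minor allele
from heterozygous parents give `χ² = (b−c)²/(b+c)` against χ²(1).
Double-het parents are resolved through the child's genotype (child
hom-alt ⇒ two transmissions, het ⇒ one each).  Mendelian-inconsistent
trio-sites are excluded and counted.  Under fair transmission the test's
type-I error at α = 0.05 is within 3 s.e. of 5% over 10⁴ variants.

## SNP–SV linkage disequilibrium

From phased haplotype frequencies, `D = p_AB − p_A p_B` and
`r² = D²/(p_A(1−p_A) p_B(1−p_B))`; monomorphic loci are flagged undefined
rather than zero.  Unphased input is rejected, not approximated — the
panel is phased by construction.  Pair significance is a two-sided
Fisher's exact test on the 2×2 haplotype-count table, with
Benjamini–Hochberg FDR control (q = 0.05) per analyzed pair set.
Candidate pairs are all same-chromosome SNP–SV pairs within 1 Mb
(point-to-interval distance).  Tag-SNP tables list, for every SV above a
MAF threshold (default 4%), the SNPs with r² ≥ 0.8 within 1 Mb.

**Matched resampling.** The observed statistic is the share of GWAS
SNP–SV pairs significant after Fisher+BH.  Each of 1,000 repetitions
draws, per GWAS pair, one non-GWAS pair from the same confounder bin
(default: SNP MAF in bins of 0.05 × distance in bins of 100 kb; the
matcher is pluggable), without replacement within a repetition; BH is
rerun on every matched set.  Empty bins fall back to the nearest bin and
are counted.  The z-score is (observed − null mean)/null s.d.

Two intrinsic limits of this design were measured on exchangeable
synthetic p-values and shape the calibration study.  First, when many
pairs share a SNP or an SV, the observed fraction has clustered variance
that per-pair-independent matched draws understate, inflating |z|.
Second, when the GWAS pairs are a sizeable share of the pool, the matched
draws come from the complement of the observed set and are anti-correlated
with it (amplification factor N/(N−n)), and without-replacement draws
from a small pool are further underdispersed.  The calibration study
therefore pairs each deletion with its nearest SNP (each SNP used once,
so pairs share no loci) and flags ~4% of ~2,000 pairs — the regime of the
original design, where ~100 GWAS pairs sit in a pool of tens of
thousands.  Under randomized labels the z-score is then calibrated
(|z| > 1.96 in ≈5% of 200 replicate label draws), while an injected
enrichment (high-LD SNPs flagged 10× more often) drives z > 3 in
essentially all replicates.

## Imputation evaluation

The workflow mirrors a panel-imputation experiment: genotype SVs in
held-out samples from reads; keep calls whose genotype probability clears
a per-class threshold (0.999 everywhere except MEIs at 0.85, whose
likelihoods are calibrated differently) as the gold standard; reduce the
held-out samples to array-like SNP genotypes (every second panel SNP);
impute SV genotype distributions from the phased panel; sweep the six GL
cutoffs 0.33, 0.75, 0.9, 0.95, 0.99, 0.999.

Genotype probabilities are regularized before thresholding by an exact
water-filling floor at ε = 10⁻⁴: entries below ε are pinned to ε and the
remaining mass is rescaled, so the result is a true distribution with
every entry ≥ ε (a plain floor-then-renormalize leaves floored entries
just below ε).  ε = 10⁻⁴ caps −log₁₀ probabilities near typical PL caps.

The bundled imputer is a deliberately simple haplotype-copying model: for
each SV and target it scores every unordered pair of panel haplotypes by
agreement between the pair's summed alleles and the target's genotypes at
the `window_snps` (default 12) nearest array SNPs; one mismatch costs a
factor `e/(1−e)` (default e = 0.05), and the posterior over SV genotypes
is the normalized sum of pair weights by the pair's SV allele count.
With `e = 0` only minimum-mismatch pairs carry weight, so a target whose
haplotypes are present in the panel recovers its SV genotypes exactly —
the degenerate case the tests pin down.  The evaluation functions accept
genotype-probability arrays from any external imputation tool unchanged;
the simple imputer exists to exercise the workflow, and its absolute
discordance (≈20% unfiltered at desk scale, with ~60 panel haplotypes) is
far above what a production imputer achieves on a 1,000-haplotype panel —
only the shape of the trade-off is meaningful.

**Metrics.** The headline metric is the expected discordance
`1 − Σ_g p_imputed(g) · p_gold(g)` (concordance = 1 − discordance),
defined directly on the two probability triplets; a dosage-r² concordance
(squared Pearson correlation between imputed dosage `p₁ + 2p₂` and gold
dosage) is reported in a separate column since both conventions exist.
Per cutoff and class the sweep reports the missing fraction (gold calls
whose imputed max probability falls below the cutoff — non-decreasing in
the cutoff by construction), the discordance over retained calls, and the
relative reduction between the first and last cutoff, rounded
half-away-from-zero to an integer percent.  MAF stratification uses 20
bins of width 0.025 over (0, 0.5] on panel frequencies (bin =
⌊MAF/0.025⌋+1, capped at 20), optionally restricted to gold genotypes
carrying at least one copy of the rare allele.

## Problem sizes and determinism

The verification studies use desk-scale cohorts chosen to make each
property conclusive: ~5,200 truth variants for perfect-caller recovery,
1,000 random instances (≤200 calls) for oracle equivalence, 200 replicate
label draws for matched-sampling calibration, ~2,050 SVs × 2 held-out
targets for the imputation sweep, 10⁴ null variants × 300 trios for TDT
calibration.  Every random draw descends from a single seed
(`numpy.random.SeedSequence`, one spawned generator per operation with
vectorized draws in fixed sample-major order), and an end-to-end rerun
with the same configuration is byte-identical; the run manifest records
every seed and parameter.

## Known limitations

- The merge never re-genotypes: consensus records carry support and
  boundaries only, and interchromosomal breakends are out of scope.
- The matched-sampling z-score is anti-conservative outside the
  disjoint-pair / small-GWAS-fraction regime (see above); on heavily
  overlapping pair sets its null should be built at the SNP level instead.
- The enrichment null placements are uniform within the mask; real
  mappability and GC structure are not modeled.
- The haplotype-copying imputer has no recombination model inside the
  window and no pre-phasing of the target; it is plumbing for the
  evaluation, not a competitive imputer.
- Allele-frequency quartiles are per variant class; a global-quartile
  variant is a one-line change but alters the reported boundaries.
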