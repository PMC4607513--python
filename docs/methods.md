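# Methods

This note documents the models, statistical conventions, and design choices
behind `snpcontext`, and what the synthetic-data validation does and does
not demonstrate about real panels.

## Data model and filtering

Coordinates are 0-based half-open throughout; VCF input is converted at
parse time.  A genome is a set of contigs over {A,C,G,T,N} plus a
compartment partition (exonic / intronic / intergenic) from BED intervals.
Intervals with conflicting labels are rejected; overlapping intervals of the
same label are merged, so every annotated position has exactly one label.

Site calls carry per-strain genotypes, read depth, and three Phred-scaled
qualities (SNP, mapping, consensus).  Because quality-field dialects differ
between pipelines, the mapping from these names to VCF INFO keys is a
configuration dictionary (defaults DP/SQ/MQ/CQ).  Retention thresholds
default to depth ≥ 30 and all three qualities ≥ 60.  A *homosite*
additionally requires the minor allele (the rarer allele among homozygous
strains; ties resolved to the alternate allele) homozygous in ≥ 2 strains
in exonic DNA or ≥ 4 strains in noncoding DNA; a *heterosite* requires at
least one heterozygous strain.  Raising any threshold can only shrink the
retained set (tested as a property).

**Strand folding.**  The six unordered substitution classes reduce to four:
C⇔T folds onto A⇔G and G⇔T onto A⇔C by reverse complement; A⇔T and C⇔G are
self-complementary and never folded.  The convention is that the canonical
class is reported in the orientation whose alphabetically-first allele is A
or C on the plus strand; folding reverse-complements and swaps the two
50-bp flanks.  Folding is involutive: the same molecule viewed from the
other strand produces the identical folded record (tested; for
self-complementary classes only the class itself, not flank orientation, is
strand-invariant).  Records within 50 bp of a contig end or with any N in a
flank are excluded from context analyses with an explicit signal and
logged counts, rather than silently dropped.

## Bias % profiles

For records of one canonical class and compartment, the observed base
frequency at each relative position j ∈ [−50,−1] ∪ [+1,+50] is compared to
the *position-independent* compartment-wide base frequency (N excluded):
`bias(b, j) = 100·(f_obs(b, j) − f_bg(b))`.  A position-matched background
was considered and rejected: the background is deliberately the overall
compartment composition, so that genuine neighborhood composition effects
(e.g. CpG structure) appear in the profile rather than being normalised
away.  Σ_b bias(b, j) = 0 at every position by construction.

Bootstrap SDs resample whole records (not individual cells) with
replacement at the original sample size, 2,000 replicates by default,
implemented as multinomial weighting so the cost is one matrix product per
replicate batch.  At survey scale (tens of thousands of records) the SDs
land in the 0.1–0.3% range; they scale as n^−1/2.  Controls are uniformly
sampled non-SNP positions whose plus-strand base matches one of the class's
two center bases, excluding known polymorphic positions.

A note on multiplicity: a null profile has 100 positions × 4 bases = 400
cells whose z-scores are approximately standard normal, so the expected
maximum |z| is ≈ 3.2 and "every cell within 3 SD" fails for about two
thirds of null panels by chance alone.  Calibration is therefore asserted
as: ≈ 5% of cells beyond 1.96 SD, at most 1% beyond 3 SD, none beyond
4.5 SD.

## Quartet enrichment

A dinucleotide quartet is the four bases X₁X₂|X₃X₄ two positions either
side of the focal base (the focal base itself excluded).  Genomic tallies
count, for each center base of the class, every compartment position with a
complete non-N window; for folded classes, positions carrying the
complementary center base are tallied under the reverse-complement quartet,
keeping genome counts and folded SNP records in one orientation.

For each quartet q and center base b the 2×2 table
{SNPs with q, SNPs without q} × {genome b-positions with q, without q}
is tested by chi-square with Yates's continuity correction (clamped at
zero), at the Bonferroni level α/256 within each class × compartment
family.  The published rule specifies that both center-base tests must be
significant but not the table construction; two independent 2×2 tests per
quartet is the most literal reading and is what is implemented.  Verdicts:
*permissive* if both tests significant with the observed quartet fraction
above the genomic fraction for both bases; *shielded* for joint depletion;
*untestable* if any expected cell is below 5 or a margin is empty; else
*neutral*.  Expected counts E(q) = n·(G_b1(q)+G_b2(q))/(T_b1+T_b2) sum to n
over all quartets; testable rows are ranked by descending O/E with
lexicographic tie-break.

Because the two center-base tests share the same observed SNP count, they
are highly correlated, and the family-wise false-positive rate under the
null approaches the Bonferroni level α as an equality rather than a strict
bound.  The validation measures it at ≈ 4.5% over 200 seeded null panels.

The ORF scanner counts a quartet set's occurrences among all overlapping
4-mers (len − 3 windows) of a coding sequence and tests the total against
the product-of-mononucleotide-frequencies expectation with a 1-df
Yates-corrected goodness-of-fit chi-square.  A mononucleotide null was
chosen over a dinucleotide null deliberately: the quartet signal of
interest is itself a dinucleotide-level structure, which a dinucleotide
null would absorb.

## Coding metrics

A⇔G and C⇔T are transitions; the other four classes transversions; the two
percentages are computed as exact complements.  NS/S classification builds
the codon containing the site from ordered CDS intervals (strand-aware,
alleles complemented for minus-strand genes), substitutes the alternate
allele, and compares translations under the standard genetic code
(configurable hook); stop gain/loss counts as nonsynonymous.  Agreement
with brute-force whole-protein translation of the mutant CDS is tested on
randomized spliced genes on both strands.  The NS:S ratio is reported in
the conventional "1:x" form with x = S/NS to two decimals.  The chi-square
against a "stochastic formation" NS:S expectation requires the expected
synonymous fraction as a configuration input, since no canonical
expectation model is implied by the counts themselves.

CG-codon usage: for each amino acid with ≥ 2 codons, the fraction of usage
on codons containing CG as a substring, against the expectation that
weights each codon by the product of the pooled CDS's mononucleotide
frequencies.  CG dinucleotides spanning codon junctions are a genomic
dinucleotide-depletion question, not a codon-usage one, and are excluded
here.

## Inbreeding model

The survival probability of an ancestral heterozygous locus under full-sib
mating follows P_t = P_{t−1}/2 + P_{t−2}/4 with P₀ = 1 and P₁ = 3/4,
equivalent to F_t = (1 + 2F_{t−1} + F_{t−2})/4 with the first sib-mated
offspring generation at F = 1/4.  This initialisation reproduces the
standard results for inbred lines: 99.998% fixation (≈ 2.4 surviving loci
per 100,000) at generation 50 and > 90% at generation 40; the alternative
convention (first offspring at F = 0) gives ≈ 3 per 100,000 and is
rejected.  The decay factor converges to (1+√5)/4 per generation.

Equilibrium heterozygosity is π_s = 4·N_e·μ with N_e = 2 for a sib line;
expected heterosite counts are π_s·L per strain.  The residual ancestral
heterozygosity bound multiplies a conservative founder heterozygosity
(default 1/1500) by P_50; using the conventional rounded residual 2×10⁻⁵
gives "1 in 75 million", while the unrounded recursion value gives 1 in
63 million — both are reported, and the rounded form is used when quoting
the conservative bound.  The miscall bound is the independence bound
(10^(−Phred/10))^n over n minor-allele calls.

Parallel-mutation concordance: for each strain, the fraction of its
heterosites that coincide at the identical position with (a) a minor-allele
homosite or (b) a heterosite in at least one other strain, against the
uniform-placement expectation (qualifying target positions / L) aggregated
over strains; fold enrichment is observed/expected, defined as 0 when
nothing is observed.

## Synthetic-data generator

The generator's defaults are the package's study conditions: a
compartmentalised genome (exonic GC 0.52, noncoding GC 0.42; i.i.d. bases
by default, first-order Markov chain when dinucleotide weights such as CpG
suppression are supplied); ancestral polymorphism planted at rate 1/1500
per eligible position (Poisson count, or pinned exactly), with per-position
rate μ·m(q) where m is the quartet multiplier; substitution classes drawn
from a transition-rich spectrum (77.7% transitions) conditioned on the
reference base; de-novo mutation at μ = 30×10⁻⁹ per bp per gamete per
generation; 16 strains; 50 filial generations; depth = 20 + Poisson(15)
and constant Phred 99 qualities, with a knob to inject low-quality sites
for filter tests.

Multipliers are keyed on the quartet in a *purine-center frame*: a
position whose center base is C or T is looked up under its
reverse-complement quartet.  This makes the planted signal exactly
congruent with the folded transition class (A⇔G ∪ C⇔T) that the recovery
validation analyses; for the folded transversion class the frame matches
on half the centers.  A per-position multiplier cannot be orientation-exact
for every class simultaneously, and the transition class is both the most
abundant and the one used for recovery checks.

Breeding is mechanistic, not a bookkeeping shortcut: each strain is a
two-individual line (N_e = 2) founded by two full sibs; every generation
each offspring receives one gamete from each parent, and each gamete picks
one parental chromosome per locus independently and acquires
Poisson(μ·L) new mutations.  Ancestral alleles are tracked as four founder
*tokens* per locus, so autozygosity (identity by descent) arises from the
pedigree itself, and the per-generation count of non-autozygous loci is
the quantity the recursion predicts — the simulator matches it within
binomial noise at every generation (validated at 10/25/50 with 10⁵ loci).
Emitted genotypes map tokens to the two allelic states (tokens from each
founder alternate ref/alt), so observed state heterozygosity is *lower*
than non-autozygosity: two distinct founder tokens can carry the same
base at a biallelic site.  No biallelic founder-state configuration can
reproduce the recursion at the state level (both-het founders yield
1, 1/2, 1/2, 3/8, …), which is why the truth set preserves the token-level
view alongside the emitted genotypes.  De-novo alternate alleles are keyed
deterministically by position, so independent hits in different strains
recreate the same variant — the parallel-evolution signal the concordance
statistics measure.

One seed drives everything through named child streams (genome, planting,
breeding with per-strain substreams, emission); reruns are byte-identical.

### What the synthetic validation does and does not show

It shows that the estimators are correct and calibrated: planted quartet
multipliers ≥ 5× are recovered as exactly the permissive set in ≥ 95% of
panels of ≥ 5,000 transition SNPs; null panels produce no calls in ≥ 95%
of seeds; bias profiles are conserved and calibrated against their
bootstrap SDs; the breeding simulator and the analytic recursion agree.
It does not emulate alignment artifacts, repeat-driven miscalls, linkage
(loci assort independently), selection, or population structure among
founders — so passing these checks validates the statistical machinery,
not the upstream variant calling of any real compendium, whose headline
tables would require the original strain data.

### Problem sizes used in validation

Validation runs are scaled so the full suite completes in about a minute:
300-kb single-compartment genomes with ~5,200 transition-class records for
recovery and null-calibration sweeps (100 and 200 seeds), a 900-kb run
with ~30,000 records for the bootstrap-SD magnitude check, and 10⁵
ancestral loci × 50 generations for the breeding cross-check.  These sizes
put per-quartet expected counts near 20 — comfortably inside the
all-expected-cells ≥ 5 validity rule — while keeping every quantity's
Monte-Carlo error well below its assertion tolerance.

## Known limitations

* Quartet multipliers are position-frame exact only for transition
  classes (see above).
* The NS:S "stochastic expectation" and the parallel-enrichment null are
  deliberately simple (config-supplied fraction; uniform placement); richer
  nulls (codon-composition NS:S expectation, mutability-weighted placement)
  would be natural extensions.
* The Markov sequence sampler targets the compartment composition as the
  conditional base distribution; with strong dinucleotide weights the
  realised stationary composition shifts accordingly (the analytic
  stationary distribution is exposed for exact expectations).
* `filter_sites` classifies a site as homosite and heterosite
  independently; a site may appear in both sets, mirroring how redundant
  homozygous and heterozygous evidence are interrogated separately.
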