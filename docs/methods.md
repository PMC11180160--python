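# Methods

## Scope and model

The package analyses a fully recessive, single-locus seed trait in a
diploid perennial, together with the structural variant believed to cause
it: a multi-kilobase clean deletion spanning the *INO* locus.  Five
analysis stages share a small set of domain types (cross families, progeny
records, references, alignments, band matrices); a sixth module generates
synthetic counterparts of every input so that the whole chain can be
exercised without field populations or sequencing runs.

## Segregation testing

Goodness of fit uses the uncorrected Pearson statistic with
df = classes − 1 and the upper-tail chi-square probability.  No Yates
continuity correction is applied anywhere: the uncorrected statistic is
the one that reproduces standard plant-breeding segregation tables
(e.g. 48:10 against 3:1 gives 1.862, not the corrected 1.47).  A p-value
exactly equal to alpha is reported as non-significant ("at the 5% level"
convention); the choice only matters on exact boundary ties.

Ratio hypotheses may contain structural zeros (1:1:0 for a backcross to
the dominant homozygote).  Zero expectations are invalid for the
chi-square itself, so `drop_structural_zeros` removes those classes first
and treats a nonzero observation in a structurally absent class as an
outright falsification rather than a chi-square contribution.  This
reproduces the conventional df-1 backcross statistics.

The heterogeneity partition is the classical one: summed per-family
chi-square = pooled chi-square (on element-wise summed counts) +
heterogeneity, with df_het = (families − 1)(classes − 1).  The identity
holds by construction and is asserted to 1e-9 on random tables.

The default hypothesis panel for two-class counts is {3:1} for one gene,
{9:7, 13:3, 15:1} for two, {37:27, 63:1} for three.  It is a reasonable
stand-in set of classical epistatic ratios, explicitly user-overridable;
nothing downstream depends on its composition.  Note that a 48:10 family
cannot discriminate 3:1 from 13:3 (chi-square 0.087) — panels of nearby
ratios need larger samples than panels of distant ones.

Chi-square p-values are approximations.  A test compares them against the
exact multinomial (binomial) tail at totals ≤ 12 and ratio 3:1; the
discrepancy there can reach ~0.25, and the documented approximation-error
bound used in that comparison is 0.3.  At the sample sizes of real
segregation tables (n ≥ 50) the approximation is excellent.

## Informative chromosomes and the distance bound

For a fully recessive trait, recombination between a codominant marker
and the trait locus is phenotypically visible only on chromosomes
transmitted through a heterozygous parent where the recombinant haplotype
flips the phenotype class: 1 chromosome per F2 heterozygote, 2 per F2
homozygous mutant, 1 per backcross-to-mutant progeny, 0 for backcrosses
to the dominant parent (uniformly seeded).  A genotype–phenotype
discordant plant is counted as one observed recombinant chromosome — the
minimum the discordance implies; double crossovers are ignored, which is
safe at the few-cM distances at issue.

The rejection test uses, by default, only the recombinant-class term
(O − E)²/E at df 1 with E = n·d/100.  This single-term form is the field
convention for rare-class tests and, with O = 0, reduces to the expected
count itself (e.g. 114 × 0.035 = 3.99).  A `two_class` variant adds the
non-recombinant term (giving 4.13 in the same configuration) for users
who prefer the full binomial chi-square.

`min_rejectable_distance` returns the infimum distance: the statistic
sits exactly on the critical value there, so under the strict p < alpha
convention the infimum itself is retained and every strictly larger
distance is rejected.  With observed recombinants the boundary is found
by 200-step bisection above the point estimate; with none, by the closed
form 100·χ²crit/n, which a test cross-checks against bisection.  When no
distance below 50 cM is rejectable the function returns None rather than
raising — small data sets simply carry no bound.

A Monte Carlo companion (`recombination_power_mc`) simulates binomial
recombinant counts and reports the rejection fraction; tested against the
exact enumerated size of the discrete test, not against the nominal 5%
(the attained size of a discrete test is not 0.05).

## Deletion discovery

Coordinates are 0-based half-open throughout; 1-based coordinates appear
only in the junction report and the VCF record.

*Depth and gaps.*  Depth counts aligned (not clipped) bases.  Gaps are
maximal runs with depth ≤ `max_internal_depth` (default 2), merged across
high-depth runs strictly shorter than `max_spike_len` (default 500 bp) —
the tolerance for reads mis-mapped to repeats inside a deletion, which
produce narrow spikes of arbitrary depth.  Merging is by spike *width*
only, deliberately depth-blind: a repeat spike can be deep.  Runs shorter
than `min_gap_len` (default 100 bp) are noise at ≥15× and discarded.
These defaults assume the study's coverage regime; at ≤5× random
coverage fluctuations themselves produce qualifying runs and the
thresholds must be tightened.

*Junction reads and assembly.*  Reads whose alignment ends within
`window` (100 bp) of a gap boundary with ≥ `min_clip` (20) soft-clipped
bases are collected and assembled by greedy exact suffix–prefix overlap
(minimum 20 bp), ties broken lexicographically by read id, contained
reads absorbed.  Exact overlap is the default because the generator's
error-free regime and low error rates leave exact 20-mers abundant; a
mismatch-tolerant mode exists but is not needed for the shipped analyses.
Assembly failure is a returned result, not an exception — it is an
expected outcome at low coverage.

*Calling.*  The contig's maximal exact prefix and suffix matches on the
reference are its anchors; a seed of `min_anchor` (30) bases locates
candidates and the anchor is the candidate with the longest extension,
ambiguous only on a tie (this matters in repetitive references).  Bases
between anchors are inserted sequence; anchor overlap on the contig is
microhomology, within which the breakpoint placement is inherently
ambiguous.  Pure deletions are canonicalized by maximal left-shift
through identical flanking bases (idempotent, and the synthetic truth
intervals are left-aligned the same way so recovery can be asserted
base-exactly).  Insertions are reported at the anchor boundary without
shifting.  Classification: clean (no insertion), with_duplication
(insertion equal to an adjacent flank copy), with_insertion otherwise.
Note that maximal anchors legitimately absorb insertion-boundary bases
that coincide with reference bases; the resulting call is an equivalent
representation of the same allele.

*In-silico PCR.*  Plus-strand matching of the forward primer and of the
reverse primer's reverse complement, amplicon length inclusive of both
primer footprints, cutoff `max_amplicon` (default 3000 bp — a standard
Taq-range ceiling).  No thermodynamics, degenerate bases, or
minus-strand products: the assay being modelled is presence/absence of a
short product.

## Genotyping and SSR diversity

Band calling is a total, deterministic map from (wild-type band,
deletion band) booleans to the three genotypes, with (absent, absent) a
no-call.  No-calls and unknown phenotypes are excluded from ratios and
cosegregation and reported separately; how real assay failures were
handled upstream is not modelled.  The dominant assay's absence call is
flagged as absence-based inference (`putative_hom_del`).

Jaccard distances are computed directly (shared presences via a single
matrix product) so that pairs with no bands at all can be flagged as
undefined rather than silently coerced; scipy's `pdist` is used as an
independent cross-check in tests.  Monomorphic means constant across
genotypes (all present or all absent); the amplified count (≥1 presence)
is reported alongside.  All-zero columns are permitted but excluded from
"amplified", mirroring the default exclusion of null-amplification
primers.

## Synthetic data

The cross simulator uses a single chromosome with two loci (marker and
trait) in coupling phase; heterozygous parents emit recombinant gametes
with probability d/100, no interference (irrelevant for single-interval
distances).  Defaults mirror the study design: homozygous parental
lines, F1/F2/backcross generations, fully recessive phenotype.  The
recombination calibration (slope of estimated recombinant fraction on
true d over 1–20 cM at n = 100,000) is asserted at 1 ± 0.05.

Genome pairs are i.i.d. base sequences at configurable GC (default 0.40,
a typical plant-genome value); the deletion allele is the reference
minus one interval, and the truth call is left-aligned.  Alignments are
produced by truth projection, not by a read mapper: the subject of the
pipeline is deletion calling, and projection yields exactly the
soft-clip/coverage-gap signal a mapper would, without unverifiable
mapping behavior.  Reads are single-end 150 b by default (paired-end
geometry adds nothing to the junction signal), uniformly placed,
junction-spanning reads split at the breakpoint and assigned to their
longer side (ties keep the left).  Quality strings are constant;
realistic error profiles are out of scope.

Band matrices place all-present monomorphic columns and redrawn
non-constant polymorphic columns; by construction the polymorphism
summary recovers the requested (monomorphic, polymorphic) counts.

What passing synthetic tests does *not* show: performance on real reads
with indel errors, adapter contamination or mapping ambiguity in
repetitive regions; the generators contain no repeats beyond chance
k-mer collisions, so the repeat-spike tolerance and ambiguous-anchor
paths are exercised with constructed fixtures rather than emergent ones.

## Problem sizes and numerics

The shipped analyses use: 100 synthetic genomes of 50–200 kb with
deletions of 500–20,000 bp at 20× error-free coverage for end-to-end
recovery (exact interval match, every junction clean); F2 families of
n = 100,000 over 150 seeds for type-I-rate checks; 10,000 Monte Carlo
replicates for power estimates.  Tolerances: partition identity 1e-9;
published statistics to the printed precision; stochastic rates to three
binomial standard errors.  Chi-square statistics below 1e-12 are clamped
to exactly zero so that an exact fit reports statistic 0, p 1.

## Known limitations

Single deletion per genome (the largest gap is characterized); no
inversions, duplications or translocations; plus-strand-only PCR; no
primer thermodynamics; no multi-gene or polyploid inheritance; the
map-distance bound assumes complete penetrance and correct phenotyping —
a misphenotyped plant would appear as a recombinant and weaken the bound
rather than break the method.
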