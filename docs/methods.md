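# Methods

This document describes the statistical procedures implemented by each
module, in processing order.  Notation: the *gene* and *pseudogene* are the
two members of a segmental duplication; *differentiating sites* are the
positions where their sequences differ; the *unique region* is a stretch
present in one copy per chromosome that is not part of the duplication.

## Region model (`region_model`)

A `ParalogModel` is a declarative JSON document: the paralog intervals, the
unique copy-number region, the homology (phasing) region, the coding region,
every differentiating site with its gene/pseudogene bases (including one
indel-type site handled as a binary presence/absence allele), the known
target variants, and the named recombinant alleles defined as sets of
pseudogene-base sites.  Validation enforces strictly increasing site
coordinates, the unique region lying strictly between the paralogs, phasing
sites exactly covering the homology region, and nesting of the named
recombinant site sets.  Coordinates map between paralogs by linear
interpolation between site anchors; positions inside the gene-only insertion
have no pseudogene image and raise `NoMappingError`.

## Aggregate copy number (`coverage_cn`)

Depth is collected in 500 bp bins across the unique region and a baseline
region, GC-corrected by 2 %-wide GC strata (each stratum's bin medians are
scaled to the global median; correction is skipped with a warning when there
are too few bins or strata), and summarized by 5 %-trimmed means.  The
normalized depth `d = 2 × unique / baseline` has diploid expectation 2.0.
Integer copy number is the MAP component of a one-dimensional Gaussian
mixture over components `k = 0..10` with component scale
`σ_k = σ0 √max(k, 1)` (default `σ0 = 0.12`); a posterior below 0.95 yields
`no_call` while the MAP value is still reported so downstream stages can
proceed with a warning.  Total copy number of the pair adds the two
pseudogene copies: `cn_total = cn_unique + 2`.  `cnv_class` is CNL (loss)
for `cn_unique ≤ 1`, NONE for 2, CNG (gain) for ≥ 3.

## Per-site gene copy number (`site_cn`)

At every differentiating site, reads are pooled across the gene and
pseudogene alignment positions, so paralog misalignment does not change the
counts.  With pooled gene-base count `k` out of `n` and total copy number
`c_t`, the gene copy number at the site is the argmax over `c ∈ {0..c_t}` of
the binomial likelihood with `p = clamp(c/c_t, 0.01, 0.99)`; sites below
depth 10 are no-calls.  The resulting series is median-filtered (width 3)
with low-posterior sites masked, and transitions in the series are typed by
`cnv_class`: a drop on CNL samples marks a fusion-deletion breakpoint
interval, a rise/fall pair on copy-neutral samples marks a gene-conversion
segment, and gains mark duplication breakpoints; an unterminated segment is
flagged UNRESOLVED.  A CNL breakpoint interval is pathogenic when its open
interval intersects the gene coding region.

## Haplotype phasing and recombinant calling (`recombinant_phaser`)

Fragments are built from reads and mate pairs covering the ten phasing
sites (mate conflicts drop the site).  Assembly is greedy: seed with the
pattern whose overlap-consistent full-agreement cluster is largest, extend
site by site by majority linkage — a voter must cover the new site, share at
least one covered site with the partial haplotype, and agree with it
everywhere; when voters conflict only those with the deepest overlap count.
With no usable linkage the nearest covered allele is continued (unless that
source site is an allele island contradicted by every covered neighbor, in
which case a surviving voter is trusted).  Because assembly rounds run on
the pool of fragments no committed haplotype explains, a handful of
sequencing errors can vote unopposed at sites where the novel haplotype
matches a committed one, so any vote that switches away from the
continuation allele — including a lone well-linked voter — must reach ~15%
of the per-copy fragment depth at that site.  A candidate is committed only
if it differs from every committed haplotype at a site covered by that same
depth-scaled number of its supporting fragments; otherwise it is discarded
as sequencing noise and its fragments are explained away.  Committed haplotypes (support ≥ 3)
absorb their consistent fragments and assembly repeats up to `cn_total`
haplotypes.  Per-haplotype integer copy numbers maximize a multinomial
likelihood of fragment-support counts with expected proportions
`c_h / cn_total`, by exhaustive enumeration over compositions.  The scenario
test compares profile likelihoods of one vs at-least-two wild-type gene
copies; genotypes are WT, HET, HOM (gene base absent at a variant site), or
COMPOUND_HET.  Each non-wild-type gene-origin haplotype is mapped to the
named recombinant whose site set matches its pseudogene-base sites, with the
mechanism fusion-CNL (when `cnv_class` is CNL with a matching breakpoint),
conversion, or point SNV.  Pseudogene-side hybrids — including the
reverse-conversion decoys that cause false positives in naive callers —
produce warnings, never calls, and any hybrid call is suppressed when the
sample has two wild-type gene copies and no CNV.

## Targeted variants (`targeted_variant_caller`)

Known variants outside the homology region are genotyped from local
alt/ref counts by the same binomial MAP rule with local copy number 2,
yielding ABSENT/HET/HOM with a posterior; sites below depth 10 are no-calls.

## Amplicon tools (`amplicon_tools`)

For long-read amplicon panels: (1) primer-pair presence/absence patterns
classify alleles as wild-type-or-conversion, CNL, CNG or MIXED, and
impossible patterns raise `InconsistentEvidenceError`; (2) sentinel-site
gene/pseudogene calls localize a fusion breakpoint to the interval between
the last gene-side and first pseudogene-side sentinel, skipping no-calls and
flagging non-canonical (multi-transition) patterns; (3) homopolymer variants
are detected per run as leave-one-out robust z-scores of flank-normalized
depth (median/MAD with the 1.4826 consistency factor, |z| > 5; when the MAD
is zero a 20 % relative-deviation fallback is used and flagged): depth loss
flags DELETION, gain flags SNV; (4) variant lists are filtered at genotype
quality ≥ 650, passing calls without a score while counting them.

## Cohort statistics (`cohort_stats`)

Cohorts are per-sample tables with boolean carrier flags.  Carrier exclusion
removes carriers of a flag from both cohorts and logs the counts.  The odds
ratio is the cross-product of the 2×2 table — identical to the
logistic-regression MLE — with a Haldane–Anscombe 0.5 correction on zero
cells (flagged) and `UndefinedOddsRatioError` on zero margins; 95 %
confidence intervals are Wald intervals on the log scale.  Proportions are
compared by Fisher's exact test (default) or chi-squared; prevalences print
at one decimal place (two below 1 %).

## Synthetic data (`synthetic_data`)

A deterministic mini-genome (~52 kb) contains a gene copied into a
pseudogene at ~96 % identity (~98 % in the 3′ homology block), with ten
clustered phasing sites 14–315 bp apart, one 55 bp gene-only insertion, a
unique copy-number region between the paralogs, and known target variants.
Haplotypes for any allele class (conversions, fusion CNLs, duplication CNGs,
SNVs, reverse-conversion decoys) are built literally from allele specs;
reads are fragmented at configurable depth/insert/error, then placed by a
paralog-ambiguity rule — each read aligns to both homologs and is assigned
to the fewer-mismatch position, ties going to the gene with mapping quality
0 — reproducing the misalignment behavior of real aligners.  Output is a
sorted indexed BAM plus a truth record (copy numbers, breakpoints, variants)
for recovery testing.  `simulate_run_depths` generates per-run homopolymer
depth matrices with planted anomalies for the amplicon detector.
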