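# Methods

## Repeat catalog and the family-median filter

Every annotation row is treated as an independent locus (fragmented copies of
one insertion are not re-joined; RepeatMasker row identity is the unit of
counting). Families are mapped from class/family strings onto the six-group
scheme (LTR/ERVL-MaLR → MaLR, LTR/ERV1|ERVK|ERVL → the matching ERV group,
LINE/\* → LINE, SINE/\* → SINE); everything else is `other` and is excluded
from all downstream analysis. Medians are computed per family over all of
that family's loci, with the even-count median taken as the mean of the two
central order statistics. The filter is strict in both comparisons
("longer than" the median length, milliDiv "below" the median), so loci
sitting exactly at a median are excluded. Internally all coordinates are
0-based half-open; RepeatMasker `.out` 1-based inclusive coordinates and
percent divergence (×10 → milliDiv) are converted at the parse boundary, and
UCSC rmsk TSV coordinates are taken as already 0-based. Element identity is
the repName string, so loci of one element aggregate across chromosomes.

## Alignment handling

Secondary records (FLAG 0x100) are dropped and the first remaining record
per (read id, mate) in file order is kept. Supplementary records (0x800) are
retained by default for fidelity to plain `-F256` filtering; a
`drop_supplementary` switch exists. The library size used for per-million
normalisation (`mapped_reads`) is the number of retained primary mapped
records in the whole library, not just repeat-overlapping ones. Mates are
counted individually as reads (not collapsed into fragments) for repeat
counting; gene-level counting collapses mates into fragments. A read's
transcribed strand depends on the protocol: `forward` (mate1 carries the
transcript strand), `reverse` (dUTP-style, the default — the most common
stranded kit, and explicit because input strandedness cannot be inferred),
or `unstranded` (everything counts as sense). Overlap uses the full
reference span of a record (CIGAR M/D/N/=/X), so a spliced read's intronic
gap still overlaps loci beneath it — interval semantics, documented as a
dialect choice. A record overlapping *k* retained loci increments *k*
counters, each by the ≥ 1 bp rule.

## Quantification

Element RPKM divides the summed read count over the element's *retained*
loci by the summed retained length (kb) and by mapped reads per million;
restricting the length denominator to retained loci matches the restriction
of counting to them. Per-locus RPKM uses the same formula with single-locus
count and length. The family representative is the sum of member-element
RPKMs; composition shares are each element's fraction of that sum (top-5
highlighted by default). Gene FPKM is deliberately simple: fragments
(mate pairs collapsed, unpaired reads count once) touching a gene's merged
exon intervals by ≥ 1 bp, per union-exon kilobase, per million mapped
fragments. There is no isoform deconvolution; gene values only feed the
ratio/clustering stage, where a monotone per-gene quantity suffices.

## Paired statistics

The per-subject change statistic is `pct = 100 · pre/post` RPKM. The test is
a one-sample two-tailed Student's *t* of the pct values against 100 with
n − 1 degrees of freedom, matching the per-subject-percentage presentation
of the headline figures; a paired *t* on log2 ratios is available as an
alternative flavor. A zero-variance pct vector reports t undefined and
p = 1 (no evidence against the null) instead of failing. Ranking uses
log2((mean_post + c)/(mean_pre + c)) with pseudocount c (default 0; the
simulator guarantees positive expression), ties broken lexicographically,
and +inf (zero pre, no pseudocount) ranked first.

Calibration note: for two equally noisy positive measurements the ratio
pre/post has expectation above 1, so one might expect the pct-vs-100 test to
over-reject under a no-change simulation. Empirically it does not at the
default conditions — the mean bias is offset by the ratio's right skew
inflating the sample SD — and the measured type-I rate at α = 0.05 is ≈0.05
(see `null_rejection_rate`). The log-ratio flavor, whose null holds exactly
under exchangeability, is retained for users who prefer an assumption-free
calibration.

## Clustering and grouping

The ratio matrix is elementwise Post14d/Pre FPKM over a user-supplied ISG
panel (the panel is an input; choosing it biologically is out of scope).
Clustering is Ward's method on squared Euclidean distances via the
Lance–Williams recurrence; reported merge heights are the increase in
within-cluster error sum of squares (so external implementations reporting
Euclidean-scale heights h satisfy h² = 2·height here). Ties break on the
smallest cluster-id pair; heights are provably non-decreasing. Ratios are
clustered untransformed (whether to log-transform ratios first is genuinely
open; callers preferring log scale pass the transformed matrix — the
clustering is agnostic to it); rows/columns are not standardised.
Subjects are grouped by representative MLT-int expression = mean RPKM over
the three timepoints; the threshold is the arithmetic mean ("average" taken
literally) of representatives, and a representative equal to the threshold
labels High (deterministic tie rule). Dendrograms export as Newick with
branch lengths derived from merge-height differences.

## Synthetic cohorts

The generator emulates the statistical structure of a vaccination-style
induction cohort at desk scale; a second arm (e.g. 5 low-dose subjects) is a
second config. Defaults: 3 chromosomes of 300 kb plus a repeat-free background
chromosome; six families × 8 elements × 4 loci with per-family length and
milliDiv ranges echoing genome-wide medians, drawn anti-correlated (young &
long vs old & short) so roughly half of each family passes the median
filter; 10 subjects ("high-dose" arm) × {pre, post24h, post14d}; 50,000
mapped 100-bp paired-end reads per sample (insert 250 bp); per-element
fragment counts negative binomial with mean = baseline × fold and variance
μ + αμ², α = 0.1; background element baselines log-uniform on [20, 200]
expected fragments, the induced element ("MLT-int", a MaLR) at baseline 200
with fold 5 at 24 h, fold 2 at 14 d, and sense fraction 0.95 (background
0.5). Half the subjects are planted "High" by scaling the MLT-int baseline
×6. Eight ISG-like panel genes (two 600-bp exons around a 2-kb intron; the
first gene's intron hosts one induced MLT-int locus, the HERC5-like
scenario) have baseline 100 fragments, fold 3 at 24 h, and a class-dependent
14-day fold (0.6 High / 1.4 Low — the below-baseline signature direction).
Reads are placed uniformly within a uniformly chosen *retained* locus of
their element and never straddle locus boundaries, so truth counts map
exactly onto pipeline counts; fragments too long for a locus stack both
mates inside it. Sequence content is a constant filler ('A'×100) because
quantification never inspects bases. A 5% fraction of decoy secondary
records exercises first-primary selection. All draws derive from the config
seed; identical configs give byte-identical files.

What the simulator does **not** model: sequence-level realism (errors, GC
bias), mappability and multi-mapping ambiguity between repeat copies (the
dominant real-data difficulty — here every read is placed at its true
locus), fragmented insertions, inter-gene correlation, and library-size
variation. Passing recovery tests therefore certifies the pipeline's
arithmetic and inference on correctly assigned reads, not robustness to
alignment ambiguity.

## Problem sizes and numerical conventions

The Monte-Carlo experiments use 100 seeds for induction recovery (expected
mean pct 100/5 = 20; observed ≈22 due to ratio bias at CV ≈ 0.3), 500
panels × 20 elements for the null rejection rate (a +1 count offset guards
low-mean ratios against zero denominators), and 100 seeds of two-population
representatives (Normal(8, 0.5) vs Normal(1, 0.2) — deliberately
well-separated to test the rule, not the noise) for grouping recovery. The
end-to-end file-based run uses the default cohort (30 SAM files). Ward
heights are compared to brute-force ESS evaluation at 1e-9; t-test p-values
to an independent continued-fraction incomplete-beta evaluation at 1e-8.
Degenerate inputs are errors rather than silent defaults: empty locus sets,
zero mapped reads, missing timepoints (named subject), NaN matrices,
unknown protocols/dialects.
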