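# retroscope

Retroelement expression profiling from stranded RNA-seq alignments.

Endogenous retroelements — ERVs, LINEs, SINEs and MaLR LTR-retrotransposons —
make up close to half of the mammalian genome, and transcripts containing them
respond to immune stimulation in element-specific ways. Quantifying them is
awkward with gene-centric tools: each element exists as hundreds of scattered
genomic copies of varying age, so expression has to be aggregated across loci,
counted strand-specifically, and restricted to copies young and complete
enough to be meaningfully assigned. `retroscope` implements that pipeline for
researchers profiling retroelement induction in longitudinal (pre/post
stimulation) cohort designs, together with a fully seeded synthetic-data
generator so every stage can be validated against known ground truth without
any external download.

## The method

1. **Catalog filtering.** From a RepeatMasker annotation (UCSC rmsk TSV or
   native `.out`), compute per-family medians of locus length and milliDiv
   (mismatches to consensus per thousand bases) over the six retroelement
   families MaLR, ERV1, ERVK, ERVL, LINE, SINE. A locus enters the analysis
   catalog iff

   `length > median_length(family)  AND  milliDiv < median_milliDiv(family)`

   (both strict) — the long, weakly diverged copies.

2. **Read assignment.** Reproduce first-primary alignment selection
   (`samtools view -F256` semantics plus first-in-file-order per read/mate),
   resolve each read's transcribed strand from the library protocol
   (forward / reverse-dUTP / unstranded), and count every retained read
   against every filtered locus it overlaps by ≥ 1 bp, split into sense and
   antisense relative to the locus strand.

3. **Multi-locus RPKM.** For element *e* with retained loci *L(e)*:

   `RPKM(e) = reads(L(e)) / (len(L(e))/10^3) / (mapped_reads/10^6)`

   The family representative is `Σ_e RPKM(e)` over its members; family
   composition reports each element's share of that sum. Genes get a simple
   union-exon fragment FPKM (no isoform deconvolution — a deliberate
   simplification, documented in `docs/methods.md`).

4. **Paired induction statistics.** Per subject,
   `pct_i = 100 · RPKM_pre,i / RPKM_post,i`, summarised as mean ± SD and
   tested with a one-sample two-tailed Student's *t* against 100
   (*p* < 0.05). Elements/loci rank by log2 fold change of group means.

5. **Ratio clustering and grouping.** Per-gene Post14d/Pre expression ratios
   over an ISG panel are Ward-clustered (Lance–Williams updates on squared
   Euclidean distances; merge heights are ESS increases). Subjects split into
   "High MLT-int" / "Low MLT-int" groups by comparing each subject's mean
   MLT-int RPKM across the three timepoints to the cohort mean of those
   representatives.

## Worked example

Simulate the default cohort (10 subjects × {pre, post24h, post14d}, one
MaLR element "MLT-int" induced five-fold at 24 h with 0.95 sense bias,
negative-binomial dispersion 0.1) and run the pipeline:

```python
import pandas as pd
from retroscope.synthdata import SimConfig, make_annotation, simulate_reads
from retroscope.alignments import (SampleLibrary, count_overlaps, parse_sam,
                                   select_first_primary)
from retroscope.repeat_catalog import build_catalog
from retroscope import diffstats, quantify

config = SimConfig(seed=1)
annotation = make_annotation(config, "cohort")
sim = simulate_reads(config, annotation, "cohort")

catalog = build_catalog(annotation.loci)        # family-median filter
print(f"retained {len(catalog.filtered_ids)} of {len(catalog.loci)} loci")

rpkm = {}
for row in sim.sample_sheet.itertuples():
    records, mapped = select_first_primary(parse_sam(sim.sam_paths[row.sample_id]))
    library = SampleLibrary(row.subject, row.timepoint, row.dose,
                            protocol=config.protocol, mapped_reads=mapped)
    counts = count_overlaps(records, catalog, protocol=config.protocol)
    expr = quantify.element_rpkm(counts, catalog, library)
    sense = expr[expr["orientation"] == "sense"]
    rpkm[row.sample_id] = pd.Series(sense["rpkm"].values,
                                    index=sense["element_name"].values)

subjects = config.subjects()
pre = pd.DataFrame({s: rpkm[f"{s}_pre"] for s in subjects})
post = pd.DataFrame({s: rpkm[f"{s}_post24h"] for s in subjects})

print(diffstats.rank_induction(pre, post).head(3).round(2))
change = diffstats.paired_percentage(pre.loc["MLT-int"], post.loc["MLT-int"])
print(f"MLT-int pre/post pct = {change.mean_pct:.1f} +/- {change.sd_pct:.1f} "
      f"(n={change.n}, p={change.p_value:.2e})")
```

Output:

```
retained 84 of 192 loci
         mean_pre  mean_post  log2fc  rank
MLT-int  10511.36   48894.48    2.22     1
SINE_e6    399.62     542.88    0.44     2
ERV1_e1   2235.99    2879.06    0.36     3
MLT-int pre/post pct = 23.2 +/- 8.8 (n=10, p=5.42e-10)
```

The planted element tops the induction ranking (log2FC ≈ 2.2, close to the
planted log2 5 ≈ 2.32 less the background), and the mean pre/post percentage
of ~23% reflects the five-fold induction (100/5 = 20%, plus the upward bias
of a noisy ratio), rejected against the no-change value of 100 at
p ≈ 5×10⁻¹⁰.

The same stages are available from the shell: `retroscope simulate | catalog |
count | quantify | diff | cluster | group` (see `retroscope --help`).

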