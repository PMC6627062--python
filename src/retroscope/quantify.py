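"""Expression quantification: multi-locus RPKM, family composition, gene FPKM.

Repeat elements are multicopy, so the element-level value aggregates over
every retained locus of an element before normalising:

    RPKM(element) = total reads on all retained loci
                    / total retained locus length (kb)
                    / (mapped reads / 1e6)

The family representative is the sum of its member elements' RPKM. Gene
expression uses a deliberately simple union-exon FPKM (fragments, i.e.
mate pairs collapsed, per kilobase of merged exon per million mapped
fragments) — no isoform deconvolution, since gene values feed only the
downstream ratio/clustering stage.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from gffutils import DataIterator
from intervaltree import IntervalTree

from .alignments import AlignmentRecord, LocusCounts, SampleLibrary
from .repeat_catalog import RepeatCatalog

ORIENTATIONS = ("sense", "antisense")


def _check_library(library: SampleLibrary) -> None:
    if library.mapped_reads <= 0:
        raise ValueError("library has zero mapped reads; RPKM undefined")


def element_rpkm(
    locus_counts: LocusCounts,
    catalog: RepeatCatalog,
    library: SampleLibrary,
) -> pd.DataFrame:
    """Per-(element, orientation) aggregated RPKM.

    Counts and locus lengths are summed over the element's retained loci
    first, then normalised. Elements with zero retained length do not
    appear. Returns a frame with columns: element_name, family,
    orientation, read_count, total_length_kb, rpkm.
    """
    _check_library(library)
    per_million = library.mapped_reads / 1e6
    element_family: dict[str, str] = {}
    element_counts: dict[tuple[str, str], int] = defaultdict(int)
    for locus in catalog.retained_loci():
        element_family[locus.element_name] = locus.family
        for orientation in ORIENTATIONS:
            element_counts[(locus.element_name, orientation)] += locus_counts.get(
                locus.locus_id, orientation
            )
    rows = []
    for element in sorted(element_family):
        length_kb = catalog.element_total_length[element] / 1000.0
        for orientation in ORIENTATIONS:
            count = element_counts[(element, orientation)]
            rows.append(
                {
                    "element_name": element,
                    "family": element_family[element],
                    "orientation": orientation,
                    "read_count": count,
                    "total_length_kb": length_kb,
                    "rpkm": count / length_kb / per_million,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "element_name",
            "family",
            "orientation",
            "read_count",
            "total_length_kb",
            "rpkm",
        ],
    )


def per_locus_rpkm(
    locus_counts: LocusCounts,
    catalog: RepeatCatalog,
    library: SampleLibrary,
) -> pd.DataFrame:
    """Same normalisation at single-locus resolution (for ranking loci)."""
    _check_library(library)
    per_million = library.mapped_reads / 1e6
    rows = []
    for locus in sorted(catalog.retained_loci(), key=lambda l: l.locus_id):
        length_kb = locus.length / 1000.0
        for orientation in ORIENTATIONS:
            count = locus_counts.get(locus.locus_id, orientation)
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "element_name": locus.element_name,
                    "family": locus.family,
                    "chrom": locus.chrom,
                    "orientation": orientation,
                    "read_count": count,
                    "length_kb": length_kb,
                    "rpkm": count / length_kb / per_million,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "element_name",
            "family",
            "chrom",
            "orientation",
            "read_count",
            "length_kb",
            "rpkm",
        ],
    )


@dataclass
class FamilyComposition:
    """Element shares of a family's summed RPKM."""

    family: str
    family_total_rpkm: float
    shares: pd.Series  # element_name -> share, descending
    top: pd.Series  # leading top_k shares
    defined: bool  # False when the family total is zero


def family_composition(
    expressions: pd.DataFrame,
    family: str,
    orientation: str = "sense",
    top_k: int = 5,
) -> FamilyComposition:
    """Composition of one family: per-element share of the family RPKM sum.

    ``top_k`` defaults to 5 — the number of leading elements highlighted in
    composition charts.
    """
    sub = expressions[
        (expressions["family"] == family)
        & (expressions["orientation"] == orientation)
    ]
    if sub.empty:
        raise ValueError(f"no elements of family {family!r}")
    total = float(sub["rpkm"].sum())
    if total == 0.0:
        shares = pd.Series(
            float("nan"), index=sub["element_name"].tolist(), name="share"
        )
        return FamilyComposition(family, 0.0, shares, shares.head(top_k), False)
    shares = (
        pd.Series(sub["rpkm"].values, index=sub["element_name"].values, name="share")
        / total
    )
    shares = shares.sort_values(ascending=False, kind="mergesort")
    return FamilyComposition(family, total, shares, shares.head(top_k), True)


def family_totals(expressions: pd.DataFrame, orientation: str = "sense") -> pd.Series:
    """Summed RPKM per family (the family representative value)."""
    sub = expressions[expressions["orientation"] == orientation]
    return sub.groupby("family")["rpkm"].sum()


# ---------------------------------------------------------------------------
# gene-level FPKM
# ---------------------------------------------------------------------------


def union_exon_intervals(gtf_path: str) -> dict[str, list[tuple[str, int, int]]]:
    """Merged (union) exon intervals per gene_id, 0-based half-open.

    Genes annotated with a ``gene`` feature but no exons are skipped with a
    warning.
    """
    exons: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
    gene_ids: set[str] = set()
    for feature in DataIterator(gtf_path):
        if feature.featuretype == "gene":
            gene_ids.add(feature.attributes["gene_id"][0])
        elif feature.featuretype == "exon":
            gene_id = feature.attributes["gene_id"][0]
            exons[gene_id].append((feature.seqid, feature.start - 1, feature.end))
    for gene_id in gene_ids - set(exons):
        warnings.warn(f"gene {gene_id} has no exons; skipped", stacklevel=2)
    merged: dict[str, list[tuple[str, int, int]]] = {}
    for gene_id, ivs in exons.items():
        ivs.sort()
        out: list[tuple[str, int, int]] = []
        for chrom, start, end in ivs:
            if out and out[-1][0] == chrom and start <= out[-1][2]:
                out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
            else:
                out.append((chrom, start, end))
        merged[gene_id] = out
    return merged


def group_fragments(
    records: Iterable[AlignmentRecord],
) -> dict[str, list[AlignmentRecord]]:
    """Collapse mate pairs: records sharing a read_id form one fragment."""
    fragments: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        if rec.mapped:
            fragments[rec.read_id].append(rec)
    return dict(fragments)


def gene_fpkm(
    gtf_path: str,
    records: Sequence[AlignmentRecord],
    mapped_fragments: int | None = None,
) -> pd.DataFrame:
    """Union-exon gene FPKM.

    A fragment (mate pair, or a single unpaired read) increments a gene
    once if any of its reads overlaps the gene's merged exons by >= 1 bp.
    ``mapped_fragments`` defaults to the number of distinct mapped
    fragments among ``records``.
    """
    merged = union_exon_intervals(gtf_path)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    lengths: dict[str, int] = {}
    for gene_id, ivs in merged.items():
        lengths[gene_id] = sum(end - start for _, start, end in ivs)
        for chrom, start, end in ivs:
            trees[chrom][start:end] = gene_id
    fragments = group_fragments(records)
    if mapped_fragments is None:
        mapped_fragments = len(fragments)
    if mapped_fragments <= 0:
        raise ValueError("no mapped fragments; FPKM undefined")
    counts: dict[str, int] = defaultdict(int)
    for reads in fragments.values():
        hit: set[str] = set()
        for rec in reads:
            tree = trees.get(rec.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(rec.start, rec.end):
                hit.add(iv.data)
        for gene_id in hit:
            counts[gene_id] += 1
    per_million = mapped_fragments / 1e6
    rows = []
    for gene_id in sorted(lengths):
        kb = lengths[gene_id] / 1000.0
        n = counts[gene_id]
        rows.append(
            {
                "gene_id": gene_id,
                "union_exon_kb": kb,
                "fragment_count": n,
                "fpkm": n / kb / per_million,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "union_exon_kb", "fragment_count", "fpkm"]
    )
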