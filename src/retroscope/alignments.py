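"""SAM alignment handling and strand-specific repeat counting.

The pipeline starts from existing alignments. Three steps happen here:

1. first-primary selection — secondary records (FLAG 0x100) are dropped and,
   for every (read, mate) pair, only the first remaining record in file
   order is kept, mirroring ``samtools view -F256`` followed by first-hit
   extraction;
2. fragment-strand resolution — the transcribed strand a read reports
   depends on the library protocol (``forward``/``reverse`` dUTP-style/
   ``unstranded``) and on which mate it is;
3. overlap counting — every retained read is assigned to every filtered
   repeat locus it overlaps by at least ``min_overlap_bp`` (default 1 bp),
   incrementing that locus's sense or antisense counter.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam
from intervaltree import IntervalTree

from .repeat_catalog import RepeatCatalog, RepeatLocus

UNPAIRED = 0  # mate code for single-end records

PROTOCOLS = ("forward", "reverse", "unstranded")


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    mate: int  # 1, 2, or UNPAIRED
    chrom: str | None
    start: int | None  # 0-based half-open reference span
    end: int | None
    read_strand: str  # '+' or '-'
    flag_secondary: bool
    flag_supplementary: bool
    mapped: bool


@dataclass
class SampleLibrary:
    """One subject x timepoint alignment set."""

    subject_id: str
    timepoint: str  # pre | post24h | post14d
    dose: str  # high | low
    protocol: str = "reverse"
    mapped_reads: int = 0


@dataclass
class LocusCounts:
    """Per-(locus, orientation) read counts."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def get(self, locus_id: str, orientation: str) -> int:
        return self.counts.get((locus_id, orientation), 0)

    def increment(self, locus_id: str, orientation: str, by: int = 1) -> None:
        key = (locus_id, orientation)
        self.counts[key] = self.counts.get(key, 0) + by

    def total(self) -> int:
        return sum(self.counts.values())

    def write_tsv(self, path: str, catalog: RepeatCatalog) -> None:
        by_id = catalog.locus_by_id()
        with open(path, "w") as fh:
            fh.write("locus_id\telement_name\tfamily\tsense\tantisense\n")
            for locus_id in sorted(catalog.filtered_ids):
                locus = by_id[locus_id]
                fh.write(
                    f"{locus_id}\t{locus.element_name}\t{locus.family}"
                    f"\t{self.get(locus_id, 'sense')}\t{self.get(locus_id, 'antisense')}\n"
                )

    @classmethod
    def read_tsv(cls, path: str) -> "LocusCounts":
        counts = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                for orientation in ("sense", "antisense"):
                    n = int(fields[idx[orientation]])
                    if n:
                        counts.increment(fields[idx["locus_id"]], orientation, n)
        return counts


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_sam(path: str) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM (or BAM) file.

    FLAG bits are decoded via pysam; the reference span covers all
    reference-consuming CIGAR operations (M, D, N, =, X).
    """
    try:
        sam = pysam.AlignmentFile(path, "r", check_sq=False)
    except ValueError as exc:
        raise ValueError(f"cannot open SAM {path!r}: {exc}") from None
    with sam:
        for aln in sam.fetch(until_eof=True):
            try:
                mapped = not aln.is_unmapped
                if aln.is_paired:
                    mate = 1 if aln.is_read1 else 2
                else:
                    mate = UNPAIRED
                yield AlignmentRecord(
                    read_id=aln.query_name,
                    mate=mate,
                    chrom=aln.reference_name if mapped else None,
                    start=aln.reference_start if mapped else None,
                    end=aln.reference_end if mapped else None,
                    read_strand="-" if aln.is_reverse else "+",
                    flag_secondary=aln.is_secondary,
                    flag_supplementary=aln.is_supplementary,
                    mapped=mapped,
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"invalid record {aln.query_name!r}: {exc}"
                ) from None


def parse_bed_alignments(path: str) -> Iterator[AlignmentRecord]:
    """Lightweight 6-column BED alignment dialect for fixtures.

    Columns: chrom, start, end, name, score, strand. The name carries the
    read id, optionally suffixed ``/1`` or ``/2`` for the mate.
    """
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {line_no}: BED alignment needs 6 columns")
            name = fields[3]
            mate = UNPAIRED
            if name.endswith(("/1", "/2")):
                mate = int(name[-1])
                name = name[:-2]
            yield AlignmentRecord(
                read_id=name,
                mate=mate,
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                read_strand=fields[5],
                flag_secondary=False,
                flag_supplementary=False,
                mapped=True,
            )


# ---------------------------------------------------------------------------
# selection and strand logic
# ---------------------------------------------------------------------------


def select_first_primary(
    records: Iterable[AlignmentRecord], drop_supplementary: bool = False
) -> tuple[list[AlignmentRecord], int]:
    """Apply the first-primary-alignment rule.

    Secondary records are dropped outright; among the remainder, only the
    first record in file order per (read_id, mate) survives. Supplementary
    records are kept by default (the literal -F256 behaviour) unless
    ``drop_supplementary``. Unmapped survivors are discarded from counting.

    Returns (retained mapped records, mapped_reads total).
    """
    seen: set[tuple[str, int]] = set()
    retained: list[AlignmentRecord] = []
    for rec in records:
        if rec.flag_secondary:
            continue
        if drop_supplementary and rec.flag_supplementary:
            continue
        key = (rec.read_id, rec.mate)
        if key in seen:
            continue
        seen.add(key)
        if rec.mapped:
            retained.append(rec)
    return retained, len(retained)


def fragment_strand(record: AlignmentRecord, protocol: str) -> str:
    """Transcribed strand implied by a record under a library protocol.

    forward: mate1 (or unpaired) reports the transcript strand directly,
    mate2 reports the opposite; reverse (dUTP): the mirror image;
    unstranded: orientation is meaningless and '+' matching is forced by
    the caller (counting reports everything as sense).
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    flip = {"+": "-", "-": "+"}
    if record.mate not in (1, 2, UNPAIRED):
        raise ValueError(f"record {record.read_id}: bad mate {record.mate}")
    if protocol == "unstranded":
        return record.read_strand
    first = record.mate in (1, UNPAIRED)
    if protocol == "forward":
        return record.read_strand if first else flip[record.read_strand]
    return flip[record.read_strand] if first else record.read_strand


def build_locus_trees(catalog: RepeatCatalog) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for locus in catalog.retained_loci():
        trees[locus.chrom][locus.start:locus.end] = locus
    return dict(trees)


def count_overlaps(
    records: Iterable[AlignmentRecord],
    catalog: RepeatCatalog,
    protocol: str = "reverse",
    min_overlap_bp: int = 1,
) -> LocusCounts:
    """Strand-specific overlap counting against the filtered catalog.

    A record overlapping k retained loci by >= min_overlap_bp increments k
    counters; the counter is 'sense' when the fragment strand matches the
    locus strand (always, for the unstranded protocol), else 'antisense'.
    Records on chromosomes absent from the catalog contribute nothing here
    (they still count toward the library's mapped total upstream).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees = build_locus_trees(catalog)
    counts = LocusCounts()
    for rec in records:
        if not rec.mapped:
            continue
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        strand = fragment_strand(rec, protocol)
        for iv in tree.overlap(rec.start, rec.end):
            overlap = min(rec.end, iv.end) - max(rec.start, iv.begin)
            if overlap < min_overlap_bp:
                continue
            locus: RepeatLocus = iv.data
            if protocol == "unstranded" or strand == locus.strand:
                counts.increment(locus.locus_id, "sense")
            else:
                counts.increment(locus.locus_id, "antisense")
    return counts
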