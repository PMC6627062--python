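"""Repeat-annotation catalog: parsing, family medians, and locus filtering.

A catalog holds every annotated genomic copy (*locus*) of transposable
elements, binned into six retroelement families: MaLR, ERV1, ERVK, ERVL,
LINE and SINE (anything else is ``other`` and is excluded from analysis).
Expression analysis is restricted to loci that are strictly longer than
their family's median length and strictly less diverged than the family's
median milliDiv — the long, young copies whose transcription is least
likely to be annotation noise.

Coordinates are 0-based half-open everywhere inside the package; the
1-based inclusive convention of RepeatMasker ``.out`` files is converted at
the parse boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

FAMILIES = ("MaLR", "ERV1", "ERVK", "ERVL", "LINE", "SINE")

#: UCSC rmsk columns this parser requires (extra columns are ignored).
UCSC_COLUMNS = (
    "genoName",
    "genoStart",
    "genoEnd",
    "strand",
    "repName",
    "repClass",
    "repFamily",
    "milliDiv",
)


class AnnotationError(ValueError):
    """Malformed repeat annotation input."""


def classify_family(rep_class: str, rep_family: str) -> str:
    """Map RepeatMasker class/family strings onto the six-family scheme.

    LTR/ERVL-MaLR -> MaLR, LTR/ERV1 -> ERV1, LTR/ERVK -> ERVK,
    LTR/ERVL -> ERVL, LINE/* -> LINE, SINE/* -> SINE, everything else
    -> "other".  Trailing '?' qualifiers (uncertain calls) are stripped.
    """
    cls = rep_class.rstrip("?")
    fam = rep_family.rstrip("?")
    if cls == "LTR":
        if fam == "ERVL-MaLR":
            return "MaLR"
        if fam in ("ERV1", "ERVK", "ERVL"):
            return fam
        return "other"
    if cls == "LINE":
        return "LINE"
    if cls == "SINE":
        return "SINE"
    return "other"


@dataclass(frozen=True)
class RepeatLocus:
    """One genomic copy of a repeat element."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    element_name: str
    family: str
    milli_div: int  # base mismatches per thousand
    locus_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise AnnotationError(
                f"locus {self.locus_id}: invalid interval [{self.start}, {self.end})"
            )
        if not 0 <= self.milli_div <= 1000:
            raise AnnotationError(
                f"locus {self.locus_id}: milliDiv {self.milli_div} outside [0, 1000]"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"locus {self.locus_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FamilyThresholds:
    family: str
    median_length: float
    median_millidiv: float
    n_loci: int


@dataclass
class RepeatCatalog:
    """Filtered repeat catalog plus the per-element locus aggregates.

    ``element_total_length`` and ``element_n_loci`` are computed over the
    *retained* loci only, because counting (and hence the RPKM denominator)
    is restricted to them.
    """

    loci: tuple[RepeatLocus, ...]
    thresholds: Mapping[str, FamilyThresholds]
    filtered_ids: frozenset[str]
    element_total_length: dict[str, int] = field(default_factory=dict)
    element_n_loci: dict[str, int] = field(default_factory=dict)

    def retained_loci(self) -> list[RepeatLocus]:
        return [l for l in self.loci if l.locus_id in self.filtered_ids]

    def locus_by_id(self) -> dict[str, RepeatLocus]:
        return {l.locus_id: l for l in self.loci}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _make_locus(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    name: str,
    family: str,
    milli_div: int,
    idx: int,
    line_no: int,
) -> RepeatLocus:
    if start < 0 or end <= start:
        raise AnnotationError(
            f"line {line_no}: negative or inverted coordinates ({start}, {end})"
        )
    try:
        return RepeatLocus(
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            element_name=name,
            family=family,
            milli_div=milli_div,
            locus_id=f"rl{idx:06d}",
        )
    except AnnotationError as exc:
        raise AnnotationError(f"line {line_no}: {exc}") from None


def parse_repeat_annotation(path: str, dialect: str) -> list[RepeatLocus]:
    """Parse a repeat annotation file into RepeatLocus records.

    Parameters
    ----------
    path
        Annotation file.
    dialect
        ``"ucsc_tsv"`` — tab-separated with a header naming at least the
        columns in :data:`UCSC_COLUMNS`; genoStart is already 0-based.
        ``"rmsk_out"`` — native RepeatMasker ``.out`` layout (whitespace
        aligned, banner header); 1-based inclusive coordinates and percent
        divergence are converted to 0-based half-open and milliDiv.
    """
    if dialect == "ucsc_tsv":
        return _parse_ucsc_tsv(path)
    if dialect == "rmsk_out":
        return _parse_rmsk_out(path)
    raise AnnotationError(f"unknown annotation dialect: {dialect!r}")


def _parse_ucsc_tsv(path: str) -> list[RepeatLocus]:
    loci: list[RepeatLocus] = []
    header: dict[str, int] | None = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.lstrip("#").split("\t") if header is None else line.split("\t")
            if header is None:
                header = {name: i for i, name in enumerate(fields)}
                missing = [c for c in UCSC_COLUMNS if c not in header]
                if missing:
                    raise AnnotationError(
                        f"line {line_no}: header missing columns {missing}"
                    )
                continue
            try:
                chrom = fields[header["genoName"]]
                start = int(fields[header["genoStart"]])
                end = int(fields[header["genoEnd"]])
                strand = fields[header["strand"]]
                name = fields[header["repName"]]
                family = classify_family(
                    fields[header["repClass"]], fields[header["repFamily"]]
                )
                milli_div = int(fields[header["milliDiv"]])
            except (IndexError, ValueError) as exc:
                raise AnnotationError(f"line {line_no}: malformed row ({exc})") from None
            loci.append(
                _make_locus(chrom, start, end, strand, name, family, milli_div,
                            len(loci), line_no)
            )
    return loci


def _parse_rmsk_out(path: str) -> list[RepeatLocus]:
    loci: list[RepeatLocus] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            first = line.split(None, 1)[0]
            if first in ("SW", "score"):  # banner header lines
                continue
            fields = line.split()
            if len(fields) < 11:
                raise AnnotationError(f"line {line_no}: expected >=11 fields")
            try:
                perc_div = float(fields[1])
                chrom = fields[4]
                begin_1based = int(fields[5])
                end = int(fields[6])
                strand = "-" if fields[8] == "C" else fields[8]
                name = fields[9]
                clsfam = fields[10]
            except ValueError as exc:
                raise AnnotationError(f"line {line_no}: malformed row ({exc})") from None
            cls, _, fam = clsfam.partition("/")
            family = classify_family(cls, fam)
            milli_div = int(round(perc_div * 10))
            loci.append(
                _make_locus(chrom, begin_1based - 1, end, strand, name, family,
                            milli_div, len(loci), line_no)
            )
    return loci


# ---------------------------------------------------------------------------
# thresholds and filtering
# ---------------------------------------------------------------------------


def compute_family_thresholds(
    loci: Sequence[RepeatLocus],
) -> dict[str, FamilyThresholds]:
    """Median length and milliDiv per family.

    Even-count medians are the mean of the two central order statistics.
    Families with zero loci are simply absent from the result.
    """
    if not loci:
        raise AnnotationError("cannot compute thresholds on an empty locus set")
    by_family: dict[str, list[RepeatLocus]] = {}
    for locus in loci:
        by_family.setdefault(locus.family, []).append(locus)
    out: dict[str, FamilyThresholds] = {}
    for family, members in by_family.items():
        lengths = np.array([m.length for m in members], dtype=float)
        divs = np.array([m.milli_div for m in members], dtype=float)
        out[family] = FamilyThresholds(
            family=family,
            median_length=float(np.median(lengths)),
            median_millidiv=float(np.median(divs)),
            n_loci=len(members),
        )
    return out


def filter_catalog(
    loci: Iterable[RepeatLocus],
    thresholds: Mapping[str, FamilyThresholds],
) -> RepeatCatalog:
    """Retain loci strictly longer than the family median length with
    milliDiv strictly below the family median; drop family "other".

    Both comparisons are strict: a locus sitting exactly at either median
    is excluded.
    """
    loci = tuple(l for l in loci if l.family != "other")
    missing = {l.family for l in loci} - set(thresholds)
    if missing:
        raise AnnotationError(f"no thresholds for families: {sorted(missing)}")
    retained: list[str] = []
    total_length: dict[str, int] = {}
    n_loci: dict[str, int] = {}
    for locus in loci:
        thr = thresholds[locus.family]
        if locus.length > thr.median_length and locus.milli_div < thr.median_millidiv:
            retained.append(locus.locus_id)
            total_length[locus.element_name] = (
                total_length.get(locus.element_name, 0) + locus.length
            )
            n_loci[locus.element_name] = n_loci.get(locus.element_name, 0) + 1
    return RepeatCatalog(
        loci=loci,
        thresholds=dict(thresholds),
        filtered_ids=frozenset(retained),
        element_total_length=total_length,
        element_n_loci=n_loci,
    )


def build_catalog(loci: Sequence[RepeatLocus]) -> RepeatCatalog:
    """Convenience: thresholds from the full locus set, then filter."""
    return filter_catalog(loci, compute_family_thresholds(loci))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_catalog_bed(loci: Iterable[RepeatLocus], path: str) -> None:
    """Write loci as BED6 plus a 7th family column.

    Name is ``element_name|locus_id``; score carries milliDiv.
    """
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.element_name}|{l.locus_id}"
                f"\t{l.milli_div}\t{l.strand}\t{l.family}\n"
            )


def read_catalog_bed(path: str) -> list[RepeatLocus]:
    loci: list[RepeatLocus] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(f"line {line_no}: BED needs >=6 columns")
            name, _, locus_id = fields[3].rpartition("|")
            if not name:
                raise AnnotationError(
                    f"line {line_no}: BED name must be element|locus_id"
                )
            family = fields[6] if len(fields) > 6 else "other"
            loci.append(
                RepeatLocus(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    strand=fields[5],
                    element_name=name,
                    family=family,
                    milli_div=int(fields[4]),
                    locus_id=locus_id,
                )
            )
    return loci


def catalog_from_bed(path: str) -> RepeatCatalog:
    """Rebuild a catalog from a BED written by :func:`write_catalog_bed`.

    Every locus in the file is treated as retained (the BED is assumed to
    be the already-filtered catalog), so thresholds are not reconstructed.
    """
    loci = tuple(read_catalog_bed(path))
    total_length: dict[str, int] = {}
    n_loci: dict[str, int] = {}
    for l in loci:
        total_length[l.element_name] = total_length.get(l.element_name, 0) + l.length
        n_loci[l.element_name] = n_loci.get(l.element_name, 0) + 1
    return RepeatCatalog(
        loci=loci,
        thresholds={},
        filtered_ids=frozenset(l.locus_id for l in loci),
        element_total_length=total_length,
        element_n_loci=n_loci,
    )


def write_thresholds_tsv(
    thresholds: Mapping[str, FamilyThresholds], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("family\tmedian_length\tmedian_millidiv\tn_loci\n")
        for family in sorted(thresholds):
            t = thresholds[family]
            fh.write(
                f"{t.family}\t{t.median_length:g}\t{t.median_millidiv:g}\t{t.n_loci}\n"
            )
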