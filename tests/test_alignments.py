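import numpy as np
import pytest

from retroscope.alignments import (
    UNPAIRED,
    AlignmentRecord,
    count_overlaps,
    fragment_strand,
    parse_bed_alignments,
    parse_sam,
    select_first_primary,
)
from retroscope.repeat_catalog import FamilyThresholds, filter_catalog
from .conftest import random_loci


def _rec(read_id="r", mate=1, chrom="chr1", start=0, end=100, strand="+",
         secondary=False, supplementary=False, mapped=True):
    return AlignmentRecord(read_id, mate, chrom, start, end, strand,
                           secondary, supplementary, mapped)


class TestParseSam:
    def test_forward_record_span(self, write_sam):
        path = write_sam(["r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*"])
        (rec,) = list(parse_sam(path))
        assert (rec.start, rec.end) == (100, 150)
        assert rec.read_strand == "+"
        assert rec.mate == UNPAIRED
        assert rec.mapped

    def test_deletion_consumes_reference(self, write_sam):
        path = write_sam(["r1\t16\tchr1\t1\t60\t10M5D10M\t*\t0\t0\t" + "A" * 20 + "\t*"])
        (rec,) = list(parse_sam(path))
        assert rec.end - rec.start == 25
        assert rec.read_strand == "-"

    def test_secondary_flag_decoded(self, write_sam):
        path = write_sam(["r1\t256\tchr1\t1\t60\t10M\t*\t0\t0\t" + "A" * 10 + "\t*"])
        (rec,) = list(parse_sam(path))
        assert rec.flag_secondary

    def test_mate_flags_decoded(self, write_sam):
        path = write_sam([
            "r1\t99\tchr1\t1\t60\t10M\t=\t50\t59\t" + "A" * 10 + "\t*",
            "r1\t147\tchr1\t50\t60\t10M\t=\t1\t-59\t" + "A" * 10 + "\t*",
        ])
        recs = list(parse_sam(path))
        assert [r.mate for r in recs] == [1, 2]

    def test_unmapped_record_carries_no_coordinates(self, write_sam):
        path = write_sam(["r1\t4\t*\t0\t0\t*\t*\t0\t0\t" + "A" * 10 + "\t*"])
        (rec,) = list(parse_sam(path))
        assert not rec.mapped and rec.chrom is None and rec.start is None

    def test_missing_file_errors(self):
        with pytest.raises((ValueError, OSError)):
            list(parse_sam("/nonexistent.sam"))

    def test_bed_alignment_dialect(self, tmp_path):
        path = tmp_path / "aln.bed"
        path.write_text("chr1\t100\t150\tR7/2\t0\t-\nchr2\t0\t50\tR8\t0\t+\n")
        recs = list(parse_bed_alignments(str(path)))
        assert (recs[0].read_id, recs[0].mate, recs[0].read_strand) == ("R7", 2, "-")
        assert (recs[1].read_id, recs[1].mate) == ("R8", UNPAIRED)


class TestFirstPrimary:
    def test_first_primary_survives_among_duplicates(self):
        records = [
            _rec("R", 1, start=0, end=50, secondary=True),
            _rec("R", 1, start=100, end=150),
            _rec("R", 1, start=200, end=250),
        ]
        retained, mapped = select_first_primary(records)
        assert [(r.start, r.end) for r in retained] == [(100, 150)]
        assert mapped == 1

    def test_both_mates_retained(self):
        records = [_rec("R", 1), _rec("R", 2)]
        retained, mapped = select_first_primary(records)
        assert len(retained) == 2 and mapped == 2

    def test_supplementary_kept_by_default_and_droppable(self):
        records = [_rec("R", 1, supplementary=True), _rec("Q", 1)]
        retained, _ = select_first_primary(records)
        assert len(retained) == 2
        retained, _ = select_first_primary(records, drop_supplementary=True)
        assert [r.read_id for r in retained] == ["Q"]

    def test_matches_grouping_oracle_on_random_streams(self):
        # oracle: group by (read_id, mate), drop 0x100, take first in order
        for seed in range(20):
            rng = np.random.default_rng(seed)
            records = [
                _rec(
                    f"R{int(rng.integers(60))}",
                    mate=int(rng.integers(1, 3)),
                    start=int(rng.integers(1000)) * 10,
                    end=int(rng.integers(1000)) * 10 + 100,
                    secondary=bool(rng.random() < 0.4),
                    mapped=bool(rng.random() < 0.9),
                )
                for _ in range(500)
            ]
            seen, expected = set(), []
            for r in records:
                if r.flag_secondary:
                    continue
                key = (r.read_id, r.mate)
                if key in seen:
                    continue
                seen.add(key)
                if r.mapped:
                    expected.append(r)
            retained, mapped = select_first_primary(records)
            assert retained == expected
            assert mapped == len(expected)


class TestFragmentStrand:
    @pytest.mark.parametrize(
        "protocol,mate,read_strand,expected",
        [
            ("forward", 1, "+", "+"),
            ("forward", 1, "-", "-"),
            ("forward", 2, "+", "-"),
            ("forward", UNPAIRED, "+", "+"),
            ("reverse", 1, "+", "-"),
            ("reverse", 2, "+", "+"),
            ("reverse", UNPAIRED, "-", "+"),
        ],
    )
    def test_protocol_table(self, protocol, mate, read_strand, expected):
        assert fragment_strand(_rec(mate=mate, strand=read_strand), protocol) == expected

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            fragment_strand(_rec(), "rf-stranded")


def _brute_force_counts(records, loci, protocol, min_overlap=1):
    counts = {}
    for rec in records:
        if not rec.mapped:
            continue
        strand = fragment_strand(rec, protocol)
        for locus in loci:
            if locus.chrom != rec.chrom:
                continue
            overlap = min(rec.end, locus.end) - max(rec.start, locus.start)
            if overlap < min_overlap:
                continue
            sense = protocol == "unstranded" or strand == locus.strand
            key = (locus.locus_id, "sense" if sense else "antisense")
            counts[key] = counts.get(key, 0) + 1
    return counts


class TestCountOverlaps:
    def test_single_base_overlap_counts(self):
        from retroscope.repeat_catalog import FamilyThresholds, RepeatLocus, filter_catalog

        locus = RepeatLocus("chr1", 149, 300, "+", "E", "MaLR", 10, "rl000000")
        cat = filter_catalog([locus], {"MaLR": FamilyThresholds("MaLR", 0, 1001, 1)})
        rec = _rec(start=100, end=150)  # read [100,150) vs locus [149,300)
        counts = count_overlaps([rec], cat, protocol="forward")
        assert counts.get("rl000000", "sense") == 1

    def test_half_open_adjacency_is_zero_overlap(self):
        from retroscope.repeat_catalog import FamilyThresholds, RepeatLocus, filter_catalog

        locus = RepeatLocus("chr1", 149, 300, "+", "E", "MaLR", 10, "rl000000")
        cat = filter_catalog([locus], {"MaLR": FamilyThresholds("MaLR", 0, 1001, 1)})
        rec = _rec(start=100, end=149)
        counts = count_overlaps([rec], cat, protocol="forward")
        assert counts.total() == 0

    @pytest.mark.parametrize("protocol", ["forward", "reverse", "unstranded"])
    def test_matches_all_pairs_oracle(self, protocol):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            loci = random_loci(rng, 50)
            from retroscope.repeat_catalog import FamilyThresholds, filter_catalog

            thresholds = {
                f: FamilyThresholds(f, 0, 1001, 1) for f in ("MaLR", "LINE")
            }
            cat = filter_catalog(loci, thresholds)
            records = [
                _rec(
                    f"r{i}",
                    mate=int(rng.integers(1, 3)),
                    chrom=str(rng.choice(["chr1", "chr2"])),
                    start=int(rng.integers(0, 51_000)),
                    end=0,
                    strand="+" if rng.random() < 0.5 else "-",
                )
                for i in range(200)
            ]
            records = [
                AlignmentRecord(r.read_id, r.mate, r.chrom, r.start, r.start + 100,
                                r.read_strand, False, False, True)
                for r in records
            ]
            counts = count_overlaps(records, cat, protocol=protocol)
            assert counts.counts == _brute_force_counts(
                records, cat.retained_loci(), protocol
            )

    def test_flipping_read_strands_swaps_sense_antisense(self):
        rng = np.random.default_rng(42)
        loci = random_loci(rng, 40)
        from retroscope.repeat_catalog import FamilyThresholds, filter_catalog

        thresholds = {f: FamilyThresholds(f, 0, 1001, 1) for f in ("MaLR", "LINE")}
        cat = filter_catalog(loci, thresholds)
        records = [
            _rec(f"r{i}", mate=1, chrom=str(rng.choice(["chr1", "chr2"])),
                 start=s, end=s + 100, strand="+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(0, 51_000, 300))
        ]
        flipped = [
            AlignmentRecord(r.read_id, r.mate, r.chrom, r.start, r.end,
                            "-" if r.read_strand == "+" else "+", False, False, True)
            for r in records
        ]
        a = count_overlaps(records, cat, protocol="forward")
        b = count_overlaps(flipped, cat, protocol="forward")
        swap = {"sense": "antisense", "antisense": "sense"}
        assert b.counts == {(lid, swap[o]): n for (lid, o), n in a.counts.items()}

    def test_min_overlap_threshold(self):
        from retroscope.repeat_catalog import FamilyThresholds, RepeatLocus, filter_catalog

        locus = RepeatLocus("chr1", 100, 300, "+", "E", "MaLR", 10, "rl000000")
        cat = filter_catalog([locus], {"MaLR": FamilyThresholds("MaLR", 0, 1001, 1)})
        rec = _rec(start=50, end=110)  # 10 bp overlap
        assert count_overlaps([rec], cat, "forward", min_overlap_bp=10).total() == 1
        assert count_overlaps([rec], cat, "forward", min_overlap_bp=11).total() == 0

    def test_record_on_unknown_chromosome_is_ignored(self):
        from retroscope.repeat_catalog import FamilyThresholds, RepeatLocus, filter_catalog

        locus = RepeatLocus("chr1", 100, 300, "+", "E", "MaLR", 10, "rl000000")
        cat = filter_catalog([locus], {"MaLR": FamilyThresholds("MaLR", 0, 1001, 1)})
        rec = _rec(chrom="chrZ", start=100, end=200)
        assert count_overlaps([rec], cat, "forward").total() == 0

    def test_mapped_total_is_independent_of_catalog(self):
        records = [_rec(f"r{i}") for i in range(10)]
        retained, mapped = select_first_primary(records)
        assert mapped == 10  # counting never feeds back into the library size

    def test_counts_invariant_under_stream_permutation(self):
        rng = np.random.default_rng(9)
        loci = random_loci(rng, 30)
        thresholds = {f: FamilyThresholds(f, 0, 1001, 1) for f in ("MaLR", "LINE")}
        cat = filter_catalog(loci, thresholds)
        records = [
            _rec(f"r{i}", chrom=str(rng.choice(["chr1", "chr2"])),
                 start=s, end=s + 100, strand="+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(0, 51_000, 200))
        ]
        shuffled = [records[i] for i in rng.permutation(len(records))]
        assert (
            count_overlaps(records, cat, "reverse").counts
            == count_overlaps(shuffled, cat, "reverse").counts
        )
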