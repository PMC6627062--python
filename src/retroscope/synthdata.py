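"""Seeded synthetic-data generator with ground truth.

Emulates the statistical structure of a vaccination-style induction study
on a toy genome: multicopy repeat loci in the six retroelement families, a
small panel of interferon-stimulated genes (ISGs) — one of which hosts an
induced repeat locus in an intron (the HERC5-like scenario) — and, per
subject, stranded paired-end libraries at three timepoints (pre, 24 h
post, 14 d post induction). Per-element fragment counts follow a negative
binomial with mean mu = baseline x fold(timepoint) and variance
mu + alpha mu^2; a configurable induced element carries a post/pre fold
change and a sense-polarity bias. Subjects are planted into High/Low
classes by scaling the induced element's baseline, and ISG 14-day
trajectories depend on the class (High-class ISGs fall below baseline).

Reads are fixed-length (100 bp) proper pairs placed entirely inside a
uniformly chosen retained locus of their element, so truth counts are
exact; base content is a constant filler because quantification never
inspects sequence. Identical configurations (including the seed) produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffstats, quantify
from .alignments import (
    SampleLibrary,
    count_overlaps,
    parse_sam,
    select_first_primary,
)
from .cluster_group import build_ratio_matrix, mlt_grouping, ward_cluster
from .repeat_catalog import (
    FAMILIES,
    RepeatCatalog,
    build_catalog,
    parse_repeat_annotation,
)

_FLIP = {"+": "-", "-": "+"}

#: rmsk class/family strings written for each simulated family.
_FAMILY_RMSK = {
    "MaLR": ("LTR", "ERVL-MaLR"),
    "ERV1": ("LTR", "ERV1"),
    "ERVK": ("LTR", "ERVK"),
    "ERVL": ("LTR", "ERVL"),
    "LINE": ("LINE", "L1"),
    "SINE": ("SINE", "Alu"),
}


@dataclass(frozen=True)
class FamilySpec:
    n_elements: int = 8
    loci_per_element: int = 4
    length_range: tuple[int, int] = (150, 600)
    millidiv_range: tuple[int, int] = (40, 400)


def default_family_specs() -> dict[str, FamilySpec]:
    """Length/divergence ranges loosely echoing genome-wide family medians."""
    return {
        "MaLR": FamilySpec(length_range=(160, 700), millidiv_range=(60, 420)),
        "ERV1": FamilySpec(length_range=(180, 760), millidiv_range=(40, 330)),
        "ERVK": FamilySpec(length_range=(300, 1300), millidiv_range=(20, 180)),
        "ERVL": FamilySpec(length_range=(140, 580), millidiv_range=(80, 480)),
        "LINE": FamilySpec(length_range=(130, 570), millidiv_range=(50, 430)),
        "SINE": FamilySpec(length_range=(140, 590), millidiv_range=(40, 240)),
    }


@dataclass(frozen=True)
class InducedElement:
    element_name: str
    fold_post24h: float = 5.0
    fold_post14d: float = 2.0
    sense_fraction: float = 0.95


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults model the high-dose arm: 10 subjects, three timepoints, one
    MaLR element ("MLT-int") induced five-fold at 24 h with strong sense
    bias, negative-binomial dispersion 0.1, and desk-scale libraries of
    50,000 mapped 100-bp reads per sample.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 300_000
    background_chrom_length: int = 100_000
    families: dict[str, FamilySpec] = field(default_factory=default_family_specs)
    n_subjects: int = 10
    dose: str = "high"
    timepoints: tuple[str, ...] = ("pre", "post24h", "post14d")
    library_size: int = 50_000  # mapped reads per sample
    dispersion: float = 0.1  # NB alpha: var = mu + alpha mu^2
    baseline_range: tuple[float, float] = (20.0, 200.0)  # background fragments
    induced: tuple[InducedElement, ...] = (InducedElement("MLT-int"),)
    induced_baseline: float = 200.0  # expected pre fragments, induced element
    background_sense_fraction: float = 0.5
    high_class_multiplier: float = 6.0  # MLT-int baseline scaling, High subjects
    class_element: str = "MLT-int"
    n_panel_genes: int = 8
    gene_baseline: float = 100.0  # expected fragments per gene per sample
    gene_fold_post24h: float = 3.0
    isg_post14d_fold_high: float = 0.6  # below baseline in High-class subjects
    isg_post14d_fold_low: float = 1.4
    read_length: int = 100
    insert_size: int = 250
    decoy_secondary_fraction: float = 0.05
    protocol: str = "reverse"

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, *key])

    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def fold(self, element_name: str, timepoint: str) -> float:
        for ind in self.induced:
            if ind.element_name == element_name:
                if timepoint == "post24h":
                    return ind.fold_post24h
                if timepoint == "post14d":
                    return ind.fold_post14d
        return 1.0

    def sense_fraction(self, element_name: str) -> float:
        for ind in self.induced:
            if ind.element_name == element_name:
                return ind.sense_fraction
        return self.background_sense_fraction


def nb_draw(rng: np.random.Generator, mu, alpha: float):
    """Negative binomial with mean mu and variance mu + alpha mu^2.

    alpha <= 0 degenerates to Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("negative binomial mean must be positive")
    if alpha <= 0:
        return rng.poisson(mu)
    n = 1.0 / alpha
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


@dataclass
class SimAnnotation:
    rmsk_path: str
    gtf_path: str
    loci: list  # RepeatLocus, canonical ids from parsing the written file
    genes: dict[str, dict]  # gene_id -> {chrom, strand, exons [(start, end)]}
    host_gene: str  # gene whose intron carries an induced locus
    chrom_lengths: dict[str, int]


def _element_names(config: SimConfig, family: str) -> list[str]:
    spec = config.families[family]
    names = [f"{family}_e{k + 1}" for k in range(spec.n_elements)]
    if family == "MaLR" and spec.n_elements >= 2:
        names[0] = "MLT-int"
        names[1] = "MLT1A0"
    return names


def make_annotation(config: SimConfig, out_dir: str | Path) -> SimAnnotation:
    """Write the toy rmsk TSV and GTF; return parsed loci and gene models.

    Loci are placed left-to-right with random gaps so nothing overlaps;
    roughly half of each family is drawn "young and long" (passing the
    median filter) and half "old and short". Induced elements get their
    first two loci forced to the family's extreme length/divergence so the
    filter always retains them; the very first induced locus sits inside
    the host gene's intron.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = config.rng(1)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chrom_length for c in chroms}
    chrom_lengths["chrBG"] = config.background_chrom_length
    cursors = {c: 1000 for c in chroms}

    # gene models: 2 exons of 600 bp around a 2 kb intron
    exon_len, intron_len = 600, 2000
    genes: dict[str, dict] = {}
    for i in range(config.n_panel_genes):
        gene_id = f"ISG{i + 1:02d}"
        chrom = chroms[i % len(chroms)]
        start = cursors[chrom]
        exons = [
            (start, start + exon_len),
            (start + exon_len + intron_len, start + 2 * exon_len + intron_len),
        ]
        genes[gene_id] = {"chrom": chrom, "strand": "+", "exons": exons,
                          "intron": (start + exon_len, start + exon_len + intron_len)}
        cursors[chrom] = exons[-1][1] + int(rng.integers(200, 501))
    host_gene = "ISG01"

    induced_names = {ind.element_name for ind in config.induced}
    rows: list[tuple] = []  # (chrom, start, end, strand, name, family, div)
    chrom_cycle = 0
    host_intron_used = False
    for family in FAMILIES:
        spec = config.families[family]
        lo, hi = spec.length_range
        dlo, dhi = spec.millidiv_range
        mid = (lo + hi) // 2
        dmid = (dlo + dhi) // 2
        for name in _element_names(config, family):
            for j in range(spec.loci_per_element):
                forced = name in induced_names and j < 2
                good = forced or bool(rng.random() < 0.5)
                if forced:
                    length, div = hi, dlo
                elif good:
                    length = int(rng.integers(mid + 1, hi + 1))
                    div = int(rng.integers(dlo, dmid))
                else:
                    length = int(rng.integers(lo, mid + 1))
                    div = int(rng.integers(dmid, dhi + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                if forced and j == 0 and not host_intron_used:
                    g = genes[host_gene]
                    istart, iend = g["intron"]
                    if length > iend - istart - 200:
                        raise ValueError("induced locus does not fit host intron")
                    start = istart + 100
                    chrom = g["chrom"]
                    host_intron_used = True
                else:
                    chrom = chroms[chrom_cycle % len(chroms)]
                    chrom_cycle += 1
                    start = cursors[chrom] + int(rng.integers(100, 401))
                    cursors[chrom] = start + length
                    if cursors[chrom] >= config.chrom_length:
                        raise ValueError(
                            "loci do not fit; increase chrom_length or reduce counts"
                        )
                rows.append((chrom, start, start + length, strand, name, family, div))

    rmsk_path = out_dir / "repeats.rmsk.tsv"
    with open(rmsk_path, "w") as fh:
        fh.write(
            "genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\tmilliDiv\n"
        )
        for chrom, start, end, strand, name, family, div in rows:
            cls, fam = _FAMILY_RMSK[family]
            fh.write(
                f"{chrom}\t{start}\t{end}\t{strand}\t{name}\t{cls}\t{fam}\t{div}\n"
            )

    gtf_path = out_dir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for gene_id, g in genes.items():
            gstart = g["exons"][0][0] + 1
            gend = g["exons"][-1][1]
            attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.1";'
            fh.write(
                f"{g['chrom']}\tsim\tgene\t{gstart}\t{gend}\t.\t{g['strand']}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g['chrom']}\tsim\ttranscript\t{gstart}\t{gend}\t.\t{g['strand']}\t.\t{attrs}\n"
            )
            for start, end in g["exons"]:
                fh.write(
                    f"{g['chrom']}\tsim\texon\t{start + 1}\t{end}\t.\t{g['strand']}\t.\t{attrs}\n"
                )

    loci = parse_repeat_annotation(str(rmsk_path), "ucsc_tsv")
    return SimAnnotation(
        rmsk_path=str(rmsk_path),
        gtf_path=str(gtf_path),
        loci=loci,
        genes=genes,
        host_gene=host_gene,
        chrom_lengths=chrom_lengths,
    )


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    elements: pd.DataFrame  # element, family, subject, timepoint, mu, fragments, sense_fragments
    genes: pd.DataFrame  # gene, subject, timepoint, mu, fragments
    subjects: pd.DataFrame  # subject, mlt_class

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        self.elements.to_csv(out_dir / "truth_elements.tsv", sep="\t", index=False)
        self.genes.to_csv(out_dir / "truth_genes.tsv", sep="\t", index=False)
        self.subjects.to_csv(out_dir / "truth_subjects.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, out_dir: str | Path) -> "SimTruth":
        out_dir = Path(out_dir)
        return cls(
            elements=pd.read_csv(out_dir / "truth_elements.tsv", sep="\t"),
            genes=pd.read_csv(out_dir / "truth_genes.tsv", sep="\t"),
            subjects=pd.read_csv(out_dir / "truth_subjects.tsv", sep="\t"),
        )


@dataclass
class SimOutput:
    annotation: SimAnnotation
    truth: SimTruth
    sample_sheet: pd.DataFrame
    sam_paths: dict[str, str]  # sample_id -> path
    catalog: RepeatCatalog
    out_dir: str


def _assign_classes(config: SimConfig) -> dict[str, str]:
    subjects = config.subjects()
    rng = config.rng(2)
    order = rng.permutation(len(subjects))
    n_high = len(subjects) // 2
    high = {subjects[i] for i in order[:n_high]}
    return {s: ("High" if s in high else "Low") for s in subjects}


def _element_baselines(config: SimConfig) -> dict[str, float]:
    rng = config.rng(3)
    induced_names = {ind.element_name for ind in config.induced}
    lo, hi = config.baseline_range
    baselines: dict[str, float] = {}
    for family in FAMILIES:
        for name in _element_names(config, family):
            if name in induced_names:
                baselines[name] = config.induced_baseline
            else:
                baselines[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return baselines


def element_mu(
    config: SimConfig,
    element: str,
    baselines: dict[str, float],
    subject_class: str,
    timepoint: str,
) -> float:
    mu = baselines[element] * config.fold(element, timepoint)
    if element == config.class_element and subject_class == "High":
        mu *= config.high_class_multiplier
    return mu


def _sam_pair_lines(
    read_id: str,
    chrom: str,
    pos: int,
    span: int,
    transcript_strand: str,
    config: SimConfig,
) -> list[str]:
    """Two proper-pair SAM lines for a fragment at [pos, pos+span)."""
    L = config.read_length
    if config.protocol == "reverse":
        r1 = _FLIP[transcript_strand]
    else:  # forward and unstranded write mate1 on the transcript strand
        r1 = transcript_strand
    r2 = _FLIP[r1]
    left_pos, right_pos = pos, pos + span - L
    seq = "A" * L
    cigar = f"{L}M"
    lines = []
    for mate, strand in ((1, r1), (2, r2)):
        flag = 0x1 | 0x2 | (0x40 if mate == 1 else 0x80)
        if strand == "-":
            flag |= 0x10
        other = r2 if mate == 1 else r1
        if other == "-":
            flag |= 0x20
        mypos = left_pos if strand == "+" else right_pos
        otherpos = right_pos if strand == "+" else left_pos
        tlen = span if strand == "+" else -span
        lines.append(
            f"{read_id}\t{flag}\t{chrom}\t{mypos + 1}\t60\t{cigar}\t=\t{otherpos + 1}"
            f"\t{tlen}\t{seq}\t*"
        )
    return lines


def simulate_reads(
    config: SimConfig, annotation: SimAnnotation, out_dir: str | Path
) -> SimOutput:
    """Write one SAM per subject x timepoint plus truth tables.

    Per (element, sample): fragments ~ NB(baseline x fold, dispersion),
    each placed in a uniformly chosen retained locus of the element, sense
    with the element's sense probability. Panel-gene fragments land in
    exons; filler fragments on a repeat-free background chromosome top the
    library up to exactly ``library_size`` mapped reads. A fraction of
    reads is duplicated as decoy secondary (FLAG 0x100) records.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = build_catalog(annotation.loci)
    retained_by_element: dict[str, list] = {}
    for locus in catalog.retained_loci():
        retained_by_element.setdefault(locus.element_name, []).append(locus)
    element_family = {l.element_name: l.family for l in annotation.loci}
    for ind in config.induced:
        if not retained_by_element.get(ind.element_name):
            raise ValueError(
                f"induced element {ind.element_name} has no retained loci"
            )

    classes = _assign_classes(config)
    baselines = _element_baselines(config)
    subjects = config.subjects()
    L, insert = config.read_length, config.insert_size
    bg_len = annotation.chrom_lengths["chrBG"]

    elem_rows, gene_rows, sheet_rows = [], [], []
    sam_paths: dict[str, str] = {}
    header_lines = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{chrom}\tLN:{length}"
        for chrom, length in annotation.chrom_lengths.items()
    ]

    for si, subject in enumerate(subjects):
        for ti, timepoint in enumerate(config.timepoints):
            rng = config.rng(4, si, ti)
            sample_id = f"{subject}_{timepoint}"
            lines: list[str] = []
            n_frag = 0

            # repeat-derived fragments
            for family in FAMILIES:
                for element in _element_names(config, family):
                    loci = retained_by_element.get(element)
                    mu = element_mu(config, element, baselines, classes[subject],
                                    timepoint)
                    if not loci:
                        continue
                    frags = int(nb_draw(rng, mu, config.dispersion))
                    p_sense = config.sense_fraction(element)
                    n_sense = int(rng.binomial(frags, p_sense))
                    for k in range(frags):
                        locus = loci[int(rng.integers(len(loci)))]
                        sense = k < n_sense
                        tstrand = locus.strand if sense else _FLIP[locus.strand]
                        span = insert if locus.length >= insert else L
                        pos = locus.start + int(
                            rng.integers(0, locus.length - span + 1)
                        )
                        lines.extend(
                            _sam_pair_lines(
                                f"{sample_id}.r{n_frag}", locus.chrom, pos, span,
                                tstrand, config,
                            )
                        )
                        n_frag += 1
                    elem_rows.append(
                        {
                            "element": element,
                            "family": element_family[element],
                            "subject": subject,
                            "timepoint": timepoint,
                            "mu_fragments": mu,
                            "fragments": frags,
                            "sense_fragments": n_sense,
                        }
                    )

            # panel-gene fragments (exonic)
            for gene_id, g in annotation.genes.items():
                if timepoint == "pre":
                    factor = 1.0
                elif timepoint == "post24h":
                    factor = config.gene_fold_post24h
                else:
                    factor = (
                        config.isg_post14d_fold_high
                        if classes[subject] == "High"
                        else config.isg_post14d_fold_low
                    )
                mu = config.gene_baseline * factor
                frags = int(nb_draw(rng, mu, config.dispersion))
                for _ in range(frags):
                    estart, eend = g["exons"][int(rng.integers(len(g["exons"])))]
                    span = insert if eend - estart >= insert else L
                    pos = estart + int(rng.integers(0, eend - estart - span + 1))
                    lines.extend(
                        _sam_pair_lines(
                            f"{sample_id}.r{n_frag}", g["chrom"], pos, span,
                            g["strand"], config,
                        )
                    )
                    n_frag += 1
                gene_rows.append(
                    {
                        "gene": gene_id,
                        "subject": subject,
                        "timepoint": timepoint,
                        "mu_fragments": mu,
                        "fragments": frags,
                    }
                )

            # background filler on the repeat-free chromosome
            deficit = config.library_size - 2 * n_frag
            if deficit < 0:
                raise ValueError(
                    f"sample {sample_id}: {2 * n_frag} reads exceed library_size "
                    f"{config.library_size}; increase library_size"
                )
            for _ in range(deficit // 2):
                pos = int(rng.integers(0, bg_len - insert))
                tstrand = "+" if rng.random() < 0.5 else "-"
                lines.extend(
                    _sam_pair_lines(
                        f"{sample_id}.r{n_frag}", "chrBG", pos, insert, tstrand,
                        config,
                    )
                )
                n_frag += 1
            if deficit % 2:
                pos = int(rng.integers(0, bg_len - L))
                lines.append(
                    f"{sample_id}.r{n_frag}\t0\tchrBG\t{pos + 1}\t60\t{L}M\t*\t0\t0"
                    f"\t{'A' * L}\t*"
                )
                n_frag += 1

            # decoy secondary records exercising first-primary selection
            n_decoys = int(config.decoy_secondary_fraction * config.library_size)
            for _ in range(n_decoys):
                frag = int(rng.integers(n_frag))
                pos = int(rng.integers(0, bg_len - L))
                flag = 0x1 | 0x40 | 0x100
                lines.append(
                    f"{sample_id}.r{frag}\t{flag}\tchrBG\t{pos + 1}\t0\t{L}M\t*\t0\t0"
                    f"\t{'A' * L}\t*"
                )

            sam_path = out_dir / f"{sample_id}.sam"
            with open(sam_path, "w") as fh:
                fh.write("\n".join(header_lines + lines) + "\n")
            sam_paths[sample_id] = str(sam_path)
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "subject": subject,
                    "timepoint": timepoint,
                    "dose": config.dose,
                    "protocol": config.protocol,
                    "sam": sam_path.name,
                    "library_size": config.library_size,
                }
            )

    truth = SimTruth(
        elements=pd.DataFrame(elem_rows),
        genes=pd.DataFrame(gene_rows),
        subjects=pd.DataFrame(
            {"subject": subjects, "mlt_class": [classes[s] for s in subjects]}
        ),
    )
    truth.write(out_dir)
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
    return SimOutput(
        annotation=annotation,
        truth=truth,
        sample_sheet=sheet,
        sam_paths=sam_paths,
        catalog=catalog,
        out_dir=str(out_dir),
    )


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        return x

    return clean(d)


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "families" in d:
        d["families"] = {
            k: FamilySpec(
                n_elements=v.get("n_elements", 8),
                loci_per_element=v.get("loci_per_element", 4),
                length_range=tuple(v["length_range"]),
                millidiv_range=tuple(v["millidiv_range"]),
            )
            for k, v in d["families"].items()
        }
    if "induced" in d:
        d["induced"] = tuple(InducedElement(**v) for v in d["induced"])
    for key in ("timepoints", "baseline_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)


# ---------------------------------------------------------------------------
# fast statistic-level experiments (no file I/O)
# ---------------------------------------------------------------------------


def simulate_count_matrices(
    config: SimConfig,
    rng: np.random.Generator,
    timepoints: tuple[str, ...] = ("pre", "post24h"),
) -> dict[str, pd.DataFrame]:
    """Element x subject realized fragment-count matrices per timepoint.

    Counts are drawn from the same NB model as the read simulator but
    skip read placement; because every element's locus length and the
    library size are constant across samples, count matrices are
    RPKM matrices up to a per-element constant, which leaves percentage
    and fold-change statistics untouched.
    """
    baselines = _element_baselines(config)
    classes = _assign_classes(config)
    subjects = config.subjects()
    elements = [n for fam in FAMILIES for n in _element_names(config, fam)]
    out = {}
    for timepoint in timepoints:
        mat = np.zeros((len(elements), len(subjects)))
        for j, subject in enumerate(subjects):
            mu = np.array(
                [
                    element_mu(config, e, baselines, classes[subject], timepoint)
                    for e in elements
                ]
            )
            mat[:, j] = nb_draw(rng, mu, config.dispersion)
        out[timepoint] = pd.DataFrame(mat, index=elements, columns=subjects)
    return out


def induction_experiment(
    config: SimConfig, n_seeds: int = 100, base_seed: int = 0
) -> pd.DataFrame:
    """Repeated recovery of the induced element across simulation seeds.

    Per seed: fresh count matrices at pre and post24h, the pre/post
    percentage test for the induced element, and the rank of the induced
    element in the log2 fold-change ranking. Returns one row per seed with
    columns induced_rank, mean_pct, p_value, significant.
    """
    induced = config.induced[0].element_name
    rows = []
    for s in range(n_seeds):
        cfg = dataclasses.replace(config, seed=(base_seed + 7919 * s) & 0x7FFFFFFF)
        rng = cfg.rng(5)
        mats = simulate_count_matrices(cfg, rng)
        ranking = diffstats.rank_induction(mats["pre"], mats["post24h"])
        change = diffstats.paired_percentage(
            mats["pre"].loc[induced], mats["post24h"].loc[induced]
        )
        rows.append(
            {
                "seed": cfg.seed,
                "induced_rank": int(ranking.loc[induced, "rank"]),
                "mean_pct": change.mean_pct,
                "p_value": change.p_value,
                "significant": change.significant,
            }
        )
    return pd.DataFrame(rows)


def null_rejection_rate(
    config: SimConfig,
    n_panels: int = 500,
    n_elements: int = 20,
    base_seed: int = 0,
    flavor: str = "pct",
) -> float:
    """Empirical type-I rate of the paired induction test under no change.

    Simulates panels of elements whose pre and post counts are i.i.d.
    negative binomial (all fold changes 1) and applies the paired test at
    alpha = 0.05: ``flavor="pct"`` is the default percentage-vs-100 t-test,
    ``flavor="log"`` the paired log-ratio t-test. A +1 count offset guards
    the ratio against zero denominators at low means.
    """
    rng = np.random.default_rng([base_seed & 0x7FFFFFFF, 6])
    lo, hi = config.baseline_range
    subjects = [f"S{i}" for i in range(config.n_subjects)]
    rejections = 0
    total = 0
    for _ in range(n_panels):
        baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_elements))
        for mu in baselines:
            pre = pd.Series(
                nb_draw(rng, np.full(len(subjects), mu), config.dispersion) + 1.0,
                index=subjects,
            )
            post = pd.Series(
                nb_draw(rng, np.full(len(subjects), mu), config.dispersion) + 1.0,
                index=subjects,
            )
            if flavor == "log":
                _, p = diffstats.paired_log_ttest(pre, post)
            else:
                p = diffstats.paired_percentage(pre, post).p_value
            rejections += p < diffstats.ALPHA
            total += 1
    return rejections / total


def grouping_experiment(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_subjects: int = 10,
    high_pop: tuple[float, float] = (8.0, 0.5),
    low_pop: tuple[float, float] = (1.0, 0.2),
) -> float:
    """Fraction of seeds where High/Low grouping recovers planted classes.

    Draws per-subject representative expression from two well-separated
    normal populations, expands them into a flat three-timepoint profile,
    and checks that the mean-threshold rule reproduces the planted labels
    exactly.
    """
    perfect = 0
    for s in range(n_seeds):
        rng = np.random.default_rng([base_seed & 0x7FFFFFFF, 7, s])
        n_high = n_subjects // 2
        reps = np.concatenate(
            [
                rng.normal(high_pop[0], high_pop[1], n_high),
                rng.normal(low_pop[0], low_pop[1], n_subjects - n_high),
            ]
        )
        truth = ["High"] * n_high + ["Low"] * (n_subjects - n_high)
        order = rng.permutation(n_subjects)
        subjects = [f"S{i:02d}" for i in range(n_subjects)]
        frame = pd.DataFrame(
            {t: reps[order] for t in ("pre", "post24h", "post14d")}, index=subjects
        )
        grouping = mlt_grouping(frame)
        labels = grouping.table["label"].tolist()
        if labels == [truth[i] for i in order]:
            perfect += 1
    return perfect / n_seeds


# ---------------------------------------------------------------------------
# end-to-end recovery
# ---------------------------------------------------------------------------


def end_to_end_recovery(config: SimConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline on one simulated cohort and score it.

    catalog -> count -> quantify -> diff -> cluster/group, compared against
    the generator's truth: (a) the induced element ranks first by
    induction; (b) the mean pre/post percentage is near 100/fold; (c) the
    planted High/Low classes are recovered. Returns a report dict with the
    measured values and pass/fail booleans.
    """
    annotation = make_annotation(config, out_dir)
    sim = simulate_reads(config, annotation, out_dir)
    loci = parse_repeat_annotation(annotation.rmsk_path, "ucsc_tsv")
    catalog = build_catalog(loci)
    induced = config.induced[0].element_name

    sense_rpkm: dict[str, pd.Series] = {}
    sense_counts = {"sense": 0, "antisense": 0}
    gene_fpkm_cols: dict[str, pd.Series] = {}
    mapped_ok = True
    for row in sim.sample_sheet.itertuples():
        records, mapped = select_first_primary(parse_sam(sim.sam_paths[row.sample_id]))
        mapped_ok &= mapped == config.library_size
        library = SampleLibrary(
            subject_id=row.subject,
            timepoint=row.timepoint,
            dose=row.dose,
            protocol=config.protocol,
            mapped_reads=mapped,
        )
        counts = count_overlaps(records, catalog, protocol=config.protocol)
        expr = quantify.element_rpkm(counts, catalog, library)
        sense = expr[expr["orientation"] == "sense"]
        sense_rpkm[row.sample_id] = pd.Series(
            sense["rpkm"].values, index=sense["element_name"].values
        )
        if row.timepoint == "post24h":
            for orientation in ("sense", "antisense"):
                sel = (expr["element_name"] == induced) & (
                    expr["orientation"] == orientation
                )
                sense_counts[orientation] += int(expr.loc[sel, "read_count"].sum())
        genes = quantify.gene_fpkm(annotation.gtf_path, records)
        gene_fpkm_cols[row.sample_id] = pd.Series(
            genes["fpkm"].values, index=genes["gene_id"].values
        )

    subjects = config.subjects()

    def matrix(timepoint: str, table: dict[str, pd.Series]) -> pd.DataFrame:
        return pd.DataFrame(
            {s: table[f"{s}_{timepoint}"] for s in subjects}
        )

    expr_pre = matrix("pre", sense_rpkm)
    expr_post = matrix("post24h", sense_rpkm)
    change = diffstats.paired_percentage(expr_pre.loc[induced], expr_post.loc[induced])
    ranking = diffstats.rank_induction(expr_pre, expr_post)
    induced_rank = int(ranking.loc[induced, "rank"])

    total_induced = sense_counts["sense"] + sense_counts["antisense"]
    sense_share = sense_counts["sense"] / total_induced if total_induced else float("nan")

    mlt = pd.DataFrame(
        {
            t: pd.Series(
                {s: sense_rpkm[f"{s}_{t}"].get(induced, 0.0) for s in subjects}
            )
            for t in config.timepoints
        }
    )
    grouping = mlt_grouping(mlt)
    truth_class = sim.truth.subjects.set_index("subject")["mlt_class"]
    grouping_accuracy = float(
        (grouping.table["label"] == truth_class.reindex(grouping.table.index)).mean()
    )

    panel = list(annotation.genes)
    ratios = build_ratio_matrix(
        matrix("pre", gene_fpkm_cols), matrix("post14d", gene_fpkm_cols), panel
    )
    dendro = ward_cluster(ratios, axis="subjects")
    cut = dendro.cut(2)
    truth_bits = (truth_class.reindex(cut.index) == "High").astype(int)
    agree = float((cut == truth_bits).mean())
    cluster_agreement = max(agree, 1.0 - agree)

    expected_pct = 100.0 / config.fold(induced, "post24h")
    report = {
        "induced_element": induced,
        "induced_rank": induced_rank,
        "mean_pct": change.mean_pct,
        "sd_pct": change.sd_pct,
        "p_value": change.p_value,
        "significant": bool(change.significant),
        "expected_pct": expected_pct,
        "sense_share": sense_share,
        "planted_sense_fraction": config.induced[0].sense_fraction,
        "grouping_accuracy": grouping_accuracy,
        "cluster_agreement": cluster_agreement,
        "n_retained_loci": len(catalog.filtered_ids),
        "mapped_reads_ok": bool(mapped_ok),
        "rank1_ok": induced_rank == 1,
        "pct_ok": abs(change.mean_pct - expected_pct) <= 5.0,
        "grouping_ok": grouping_accuracy == 1.0,
    }
    return report
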