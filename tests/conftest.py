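import dataclasses

import numpy as np
import pytest

from retroscope.repeat_catalog import RepeatLocus
from retroscope.synthdata import FamilySpec, SimConfig, end_to_end_recovery

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n@SQ\tSN:chr2\tLN:100000\n"


@pytest.fixture
def write_sam(tmp_path):
    """Write SAM body lines under a fixed two-chromosome header."""

    def _write(lines, name="fixture.sam"):
        path = tmp_path / name
        path.write_text(SAM_HEADER + "\n".join(lines) + "\n")
        return str(path)

    return _write


def random_loci(rng, n, chroms=("chr1", "chr2"), families=("MaLR", "LINE")):
    """Random RepeatLocus set for oracle-equality property tests."""
    loci = []
    for i in range(n):
        start = int(rng.integers(0, 50_000))
        length = int(rng.integers(50, 2_000))
        loci.append(
            RepeatLocus(
                chrom=str(rng.choice(list(chroms))),
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                element_name=f"E{int(rng.integers(8))}",
                family=str(rng.choice(list(families))),
                milli_div=int(rng.integers(0, 500)),
                locus_id=f"rl{i:06d}",
            )
        )
    return loci


def small_sim_config(seed=0, **overrides) -> SimConfig:
    """Scaled-down cohort for fast unit tests (not the study conditions)."""
    families = {
        fam: FamilySpec(n_elements=3, loci_per_element=3,
                        length_range=spec.length_range,
                        millidiv_range=spec.millidiv_range)
        for fam, spec in SimConfig().families.items()
    }
    defaults = dict(
        seed=seed,
        families=families,
        n_subjects=2,
        library_size=12_000,
        n_panel_genes=2,
        induced_baseline=60.0,
        baseline_range=(10.0, 50.0),
        gene_baseline=40.0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def e2e_report(default_config, tmp_path_factory):
    """One full pipeline run on the default simulated cohort (shared)."""
    out = tmp_path_factory.mktemp("cohort")
    return end_to_end_recovery(dataclasses.replace(default_config), out)
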