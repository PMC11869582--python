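import numpy as np
import pandas as pd
import pytest

from paleokin import simulate
from paleokin.genotype_io import build_panel
from paleokin.simulate import SimConfig


@pytest.fixture(scope="session")
def small_cohort():
    """20 founders, 10k autosomal / 2k X SNPs, equal male/female WHG input."""
    conf = SimConfig(n_snps_autosome=10_000, n_snps_x=2_000, n_individuals=20,
                     missing_rate=0.05, seed=42)
    return simulate.simulate_cohort(conf)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    rng = np.random.default_rng(43)
    matrix, meta = simulate.pseudo_haploid_matrix(small_cohort, rng)
    return matrix, meta


def tiny_panel(positions_by_chrom: dict[str, list[int]]) -> pd.DataFrame:
    """Hand-built panel for unit fixtures: {chrom: [pos, ...]}."""
    rows = []
    for chrom, positions in positions_by_chrom.items():
        for p in positions:
            rows.append((f"snp_{chrom}_{p}", chrom, p * 1e-8, p, "A", "G"))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "genetic_pos",
                                     "physical_pos", "ref_allele", "alt_allele"])
    return build_panel(df)
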