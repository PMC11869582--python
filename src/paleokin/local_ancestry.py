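"""Local-ancestry summaries: mean tracks, Z-scores, MHC enrichment, carrier tests.

Consumes per-SNP, per-haplotype posterior probabilities of hunter-gatherer
origin (as produced by chromosome-painting tools).  The per-SNP mean A_i
averages over both haplotypes of every individual; the Z-score standardises
A_i by the genome-wide mean and population standard deviation,

    Z_i = (A_i - mu) / sigma.

Region enrichment compares the mean ancestry inside a region (by default
the extended MHC, chr6:28,477,797-33,448,354, hg19) with the genome-wide
mean.  The carrier test splits individuals by presence of an HLA allele and
compares their mean region ancestry with a two-sided Mann-Whitney test under
Holm-Sidak correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import config
from .genotype_io import AncestryTrack
from .hla import holm_sidak_adjust


@dataclass
class RegionSpec:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    @classmethod
    def mhc(cls) -> "RegionSpec":
        return cls(config.MHC_CHROM, config.MHC_START, config.MHC_END)

    def mask(self, panel: pd.DataFrame) -> np.ndarray:
        return ((panel["chrom"].astype(str) == self.chrom)
                & (panel["physical_pos"] >= self.start)
                & (panel["physical_pos"] <= self.end)).to_numpy()


def mean_ancestry_and_z(track: AncestryTrack) -> tuple[pd.DataFrame, float, float]:
    """Per-SNP mean ancestry A_i and Z-score; returns (table, mu, sigma).

    A_i averages haplotypes within individuals and then across individuals,
    which with equal weights equals pooling all 2N haplotypes.  sigma is the
    population standard deviation over SNPs (the score is descriptive).
    """
    a = track.prob_whg.mean(axis=1).mean(axis=0)
    mu = float(a.mean())
    sigma = float(a.std())
    if sigma <= 1e-12:
        raise ValueError("degenerate track: per-SNP means are constant")
    stats = track.panel.copy()
    stats["a_i"] = a
    stats["z_i"] = (a - mu) / sigma
    return stats, mu, sigma


def region_enrichment(stats: pd.DataFrame, mu: float,
                      region: RegionSpec | None = None,
                      flank: int = config.MHC_FLANK) -> dict:
    """Mean ancestry inside a region versus the genome-wide mean.

    Also emits the per-SNP table for the region plus its flanks, for
    plotting against the genome-wide dashed line.
    """
    region = region or RegionSpec.mhc()
    mask = region.mask(stats)
    if not mask.any():
        raise ValueError(f"no SNPs inside {region}")
    wide = RegionSpec(region.chrom, max(1, region.start - flank), region.end + flank)
    table = stats[wide.mask(stats)].copy()
    table["in_region"] = region.mask(table)
    return {
        "region_mean": float(stats.loc[mask, "a_i"].mean()),
        "genome_mean": mu,
        "mean_z_in_region": float(stats.loc[mask, "z_i"].mean()),
        "n_snps_in_region": int(mask.sum()),
        "table": table.reset_index(drop=True),
    }


def per_individual_region_ancestry(track: AncestryTrack,
                                   region: RegionSpec | None = None) -> pd.Series:
    """Mean WHG probability over region SNPs and both haplotypes, per sample."""
    region = region or RegionSpec.mhc()
    mask = region.mask(track.panel)
    if not mask.any():
        raise ValueError(f"no SNPs inside {region}")
    means = track.prob_whg[:, :, mask].mean(axis=(1, 2))
    return pd.Series(means, index=track.samples, name="region_ancestry")


def carrier_comparison(track: AncestryTrack, hla_table: pd.DataFrame,
                       alleles: list[str],
                       region: RegionSpec | None = None,
                       alpha: float = config.ALPHA) -> pd.DataFrame:
    """Carrier vs non-carrier mean MHC ancestry, per HLA allele.

    Carriers are individuals with at least one copy of the allele
    (homozygotes count once).  Individuals untyped at the allele's locus are
    excluded from that allele's comparison.  Alleles with fewer than two
    individuals in either class are skipped with a warning.  Two-sided
    Mann-Whitney p-values are Holm-Sidak adjusted over the tested alleles.
    """
    region = region or RegionSpec.mhc()
    anc = per_individual_region_ancestry(track, region)
    rows = []
    for allele in alleles:
        locus = allele.split("*")[0]
        typed = hla_table[hla_table["locus"] == locus]
        typed = typed[typed["sample_id"].isin(anc.index)]
        carriers = set(typed.loc[(typed["allele1"] == allele)
                                 | (typed["allele2"] == allele), "sample_id"])
        noncarriers = set(typed["sample_id"]) - carriers
        c = anc[anc.index.isin(carriers)]
        nc = anc[anc.index.isin(noncarriers)]
        if len(c) < 2 or len(nc) < 2:
            warnings.warn(f"allele {allele}: carrier/non-carrier class too small; skipped")
            rows.append({"allele": allele, "n_carriers": len(c),
                         "n_noncarriers": len(nc), "carrier_mean": np.nan,
                         "noncarrier_mean": np.nan, "p_raw": np.nan,
                         "skipped": True,
                         "carrier_values": c.to_numpy(),
                         "noncarrier_values": nc.to_numpy()})
            continue
        pooled = np.concatenate([c.to_numpy(), nc.to_numpy()])
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (tie_free and len(pooled) <= 40) else "asymptotic"
        p = float(mannwhitneyu(c, nc, alternative="two-sided", method=method).pvalue)
        rows.append({"allele": allele, "n_carriers": len(c),
                     "n_noncarriers": len(nc),
                     "carrier_mean": float(c.mean()),
                     "noncarrier_mean": float(nc.mean()),
                     "p_raw": p, "skipped": False,
                     "carrier_values": c.to_numpy(),
                     "noncarrier_values": nc.to_numpy()})
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    out["p_adjusted"] = np.nan
    if tested.any():
        out.loc[tested, "p_adjusted"] = holm_sidak_adjust(
            out.loc[tested, "p_raw"].to_numpy())
    out["significant"] = out["p_adjusted"] <= alpha
    return out
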