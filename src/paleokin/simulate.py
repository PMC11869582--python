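"""Synthetic cohorts with sex-biased two-source admixture.

The generator emulates the statistical structure the downstream analyses
assume, without claiming demographic realism:

* two source populations ("WHG" hunter-gatherers and "AN" Anatolian-derived
  farmers) whose allele frequencies drift independently from a common
  ancestral frequency under the Balding–Nichols model;
* a single admixture pulse G generations ago in which males contribute a
  fraction ``c_m`` and females ``c_f`` of WHG ancestry, so the expected WHG
  fraction is (c_m + c_f)/2 on autosomes and (c_m + 2 c_f)/3 on the X;
* local-ancestry tracts along each haplotype, generated as a stationary
  renewal process with switch rate G per Morgan (2G/3 on the X, which only
  recombines in females), giving near-exponential tract lengths with mean
  100/G cM;
* pseudo-haploid observation: one randomly sampled allele per site per
  individual, with independent missingness;
* relatives by gene dropping (recombined gametes from stored haplotypes);
* HLA haplotypes drawn from ancestry-specific pools according to the true
  local ancestry of each MHC haplotype.

Every generator takes an explicit :class:`numpy.random.Generator`, so runs
are reproducible from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config as cfg
from .genotype_io import (MISSING, AncestryTrack, PseudoHaploidMatrix,
                          build_panel, make_sample_meta)

# Ancestry labels along haplotypes.
AN_LABEL = 0
WHG_LABEL = 1
NO_HAP = -9   # second X haplotype slot of a male

# Synthetic ancestry-specific DRB1-DQB1 pools and a shared, ancestry-neutral
# HLA-A pool.  Loosely inspired by published Neolithic frequency tables but
# entirely synthetic; no claim of historical accuracy.
DEFAULT_WHG_POOL = [("DRB1*08:01", "DQB1*04:02", 0.60),
                    ("DRB1*13:01", "DQB1*06:03", 0.10),
                    ("DRB1*01:01", "DQB1*05:01", 0.30)]
DEFAULT_AN_POOL = [("DRB1*13:01", "DQB1*06:03", 0.50),
                   ("DRB1*01:01", "DQB1*05:01", 0.35),
                   ("DRB1*07:01", "DQB1*02:02", 0.15)]
DEFAULT_A_POOL = [("A*02:01", 0.35), ("A*01:01", 0.30),
                  ("A*03:01", 0.20), ("A*24:02", 0.15)]


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults follow the scales of the analyses they feed: 50,000 autosomal
    and 5,000 X SNPs (the X panel the sex-bias analysis actually had), 40
    individuals, admixture pulse G = 22 generations ago, 10% missing calls.
    """

    n_snps_autosome: int = 50_000
    n_snps_x: int = 5_000
    fst_whg: float = 0.15
    fst_an: float = 0.10
    c_m: float = 0.35
    c_f: float = 0.35
    generations: int = 22
    n_individuals: int = 40
    missing_rate: float = 0.10
    sex_ratio: float = 0.5          # probability an individual is male
    hla_missing_rate: float = 0.0
    whg_pool: list[tuple[str, str, float]] = field(default_factory=lambda: list(DEFAULT_WHG_POOL))
    an_pool: list[tuple[str, str, float]] = field(default_factory=lambda: list(DEFAULT_AN_POOL))
    a_pool: list[tuple[str, float]] = field(default_factory=lambda: list(DEFAULT_A_POOL))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("c_m", "c_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("fst_whg", "fst_an"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        for pool in (self.whg_pool, self.an_pool):
            if abs(sum(f for *_, f in pool) - 1.0) > 1e-9:
                raise ValueError("haplotype pool frequencies must sum to 1")

    @property
    def alpha_autosome(self) -> float:
        return (self.c_m + self.c_f) / 2.0

    @property
    def alpha_x(self) -> float:
        return (self.c_m + 2.0 * self.c_f) / 3.0


def make_panel(n_auto: int, n_x: int) -> pd.DataFrame:
    """Evenly spaced synthetic SNP panel over 22 autosomes plus X.

    Autosomal SNPs are split evenly across chromosomes 1–22 (each 130 Mb);
    X SNPs span 3–154 Mb, clear of both pseudo-autosomal regions.  The
    genetic map is uniform at 1 cM/Mb.
    """
    if n_auto <= 0:
        raise ValueError("need at least one autosomal SNP")
    rows = []
    per_chrom = np.full(22, n_auto // 22)
    per_chrom[: n_auto % 22] += 1
    for c in range(22):
        n = int(per_chrom[c])
        if n == 0:
            continue
        pos = np.linspace(1_000_000, 129_000_000, n).astype(np.int64)
        pos = np.unique(pos)
        for p in pos:
            rows.append((f"rs{c + 1}_{p}", str(c + 1), p * 1e-8, int(p), "A", "G"))
    if n_x > 0:
        pos = np.unique(np.linspace(3_000_000, 154_000_000, n_x).astype(np.int64))
        for p in pos:
            rows.append((f"rsX_{p}", "X", p * 1e-8, int(p), "A", "G"))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "genetic_pos",
                                     "physical_pos", "ref_allele", "alt_allele"])
    return build_panel(df)


def simulate_sources(panel: pd.DataFrame, fst_whg: float, fst_an: float,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Balding–Nichols source frequencies for every SNP of the panel.

    Ancestral frequency p ~ Uniform(0.05, 0.95); each source draws its
    frequency from Beta(p (1-F)/F, (1-p)(1-F)/F), which has mean p and
    variance F p (1-p).
    """
    for f in (fst_whg, fst_an):
        if not 0.0 < f < 1.0:
            raise ValueError("drift F must be in (0, 1)")
    n = len(panel)
    p = rng.uniform(0.05, 0.95, size=n)

    def draw(fval: float) -> np.ndarray:
        k = (1.0 - fval) / fval
        return rng.beta(p * k, (1.0 - p) * k)

    return pd.DataFrame({
        "snp_id": panel["snp_id"].to_numpy(),
        "f_anc": p,
        "f_whg": np.clip(draw(fst_whg), *cfg.FREQ_CLIP),
        "f_an": np.clip(draw(fst_an), *cfg.FREQ_CLIP),
    })


def _tract_labels(gpos: np.ndarray, alpha: float, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Ancestry labels at SNP positions from a stationary renewal process.

    Renewal points arrive at ``rate`` per Morgan; each segment draws WHG with
    probability ``alpha`` independently, so the marginal is exactly alpha and
    the switch probability over distance d is (1 - e^{-rate d}) scaled by the
    stationary probabilities.
    """
    if alpha <= 0.0:
        return np.zeros(len(gpos), dtype=np.int8)
    if alpha >= 1.0:
        return np.ones(len(gpos), dtype=np.int8)
    length = gpos[-1] - gpos[0]
    n_exp = max(8, int(rate * length * 2) + 8)
    gaps = rng.exponential(1.0 / rate, size=n_exp)
    breaks = gpos[0] + np.cumsum(gaps)
    while breaks[-1] < gpos[-1]:
        more = rng.exponential(1.0 / rate, size=n_exp)
        breaks = np.concatenate([breaks, breaks[-1] + np.cumsum(more)])
    seg = np.searchsorted(breaks, gpos, side="right")
    states = (rng.random(seg[-1] + 1) < alpha).astype(np.int8)
    return states[seg]


@dataclass
class SimulatedCohort:
    """A simulated cohort with full haplotype-level ground truth."""

    config: SimConfig
    panel: pd.DataFrame
    sources: pd.DataFrame
    samples: list[str]
    sex: dict[str, str]
    hap_ancestry: np.ndarray   # int8 (n, 2, n_snps); NO_HAP marks absent male X hap
    hap_allele: np.ndarray     # int8, same shape (0=REF, 1=ALT)
    pedigree: dict[str, tuple[str, str] | None] = field(default_factory=dict)
    relative_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def auto_mask(self) -> np.ndarray:
        return ~self.panel["is_x"].to_numpy()

    @property
    def x_mask(self) -> np.ndarray:
        return self.panel["is_x"].to_numpy()

    def n_haps(self, sample: str) -> np.ndarray:
        """Number of haplotypes carried per SNP (2, or 1 on the male X)."""
        i = self.samples.index(sample)
        return (self.hap_ancestry[i] != NO_HAP).sum(axis=0)

    def true_ancestry(self, sample: str, compartment: str) -> float:
        """Mean WHG label over the carried haplotypes of a compartment."""
        i = self.samples.index(sample)
        mask = self.auto_mask if compartment == "autosome" else self.x_mask
        labels = self.hap_ancestry[i][:, mask]
        ok = labels != NO_HAP
        return float(labels[ok].mean())

    def truth_record(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append({
                "sample_id": s,
                "sex": self.sex[s],
                "q_auto_true": self.true_ancestry(s, "autosome"),
                "q_x_true": self.true_ancestry(s, "X") if self.x_mask.any() else np.nan,
                "parents": ",".join(self.pedigree.get(s) or ()),
            })
        return pd.DataFrame(rows)


def _simulate_haplotypes(panel: pd.DataFrame, sources: pd.DataFrame,
                         config: SimConfig, sex: str,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One individual's (2, n_snps) ancestry-label and allele arrays."""
    n_snps = len(panel)
    anc = np.full((2, n_snps), NO_HAP, dtype=np.int8)
    allele = np.full((2, n_snps), NO_HAP, dtype=np.int8)
    g = config.generations
    is_x = panel["is_x"].to_numpy()
    f = {WHG_LABEL: sources["f_whg"].to_numpy(), AN_LABEL: sources["f_an"].to_numpy()}
    for chrom, sub in panel.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        gpos = sub["genetic_pos"].to_numpy()
        on_x = bool(is_x[idx[0]])
        alpha = config.alpha_x if on_x else config.alpha_autosome
        rate = (2.0 * g / 3.0) if on_x else float(g)
        n_hap = 1 if (on_x and sex == "male") else 2
        for h in range(n_hap):
            labels = _tract_labels(gpos, alpha, rate, rng)
            anc[h, idx] = labels
            pw = np.where(labels == WHG_LABEL, f[WHG_LABEL][idx], f[AN_LABEL][idx])
            allele[h, idx] = (rng.random(len(idx)) < pw).astype(np.int8)
    return anc, allele


def simulate_cohort(config: SimConfig,
                    rng: np.random.Generator | None = None,
                    panel: pd.DataFrame | None = None,
                    sources: pd.DataFrame | None = None) -> SimulatedCohort:
    """Simulate founders under the one-pulse sex-biased admixture model."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if panel is None:
        panel = make_panel(config.n_snps_autosome, config.n_snps_x)
    if len(panel) == 0:
        raise ValueError("cannot simulate a cohort on an empty panel")
    if sources is None:
        sources = simulate_sources(panel, config.fst_whg, config.fst_an, rng)
    samples = [f"sim{i:03d}" for i in range(config.n_individuals)]
    sexes = {}
    anc = np.full((config.n_individuals, 2, len(panel)), NO_HAP, dtype=np.int8)
    allele = np.full_like(anc, NO_HAP)
    for i, s in enumerate(samples):
        sex = "male" if rng.random() < config.sex_ratio else "female"
        sexes[s] = sex
        anc[i], allele[i] = _simulate_haplotypes(panel, sources, config, sex, rng)
    return SimulatedCohort(config=config, panel=panel, sources=sources,
                           samples=samples, sex=sexes,
                           hap_ancestry=anc, hap_allele=allele,
                           pedigree={s: None for s in samples})


def _gamete(cohort: SimulatedCohort, parent_idx: int, x_from_single: bool,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A recombined gamete (ancestry, allele) from a stored parent.

    Crossovers are a Poisson process at 1 per Morgan along each chromosome.
    ``x_from_single`` marks a father: his single X passes without
    recombination (and is absent from gametes destined for sons; the caller
    handles that case).
    """
    panel = cohort.panel
    n_snps = len(panel)
    g_anc = np.full(n_snps, NO_HAP, dtype=np.int8)
    g_all = np.full(n_snps, NO_HAP, dtype=np.int8)
    is_x = panel["is_x"].to_numpy()
    for chrom, sub in panel.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        gpos = sub["genetic_pos"].to_numpy()
        on_x = bool(is_x[idx[0]])
        if on_x and x_from_single:
            g_anc[idx] = cohort.hap_ancestry[parent_idx, 0, idx]
            g_all[idx] = cohort.hap_allele[parent_idx, 0, idx]
            continue
        length = gpos[-1] - gpos[0]
        n_x = rng.poisson(length)
        cuts = np.sort(rng.uniform(gpos[0], gpos[-1], size=n_x))
        seg = np.searchsorted(cuts, gpos, side="right")
        start = rng.integers(0, 2)
        hap_of_snp = (start + seg) % 2
        g_anc[idx] = cohort.hap_ancestry[parent_idx, hap_of_snp, idx]
        g_all[idx] = cohort.hap_allele[parent_idx, hap_of_snp, idx]
    return g_anc, g_all


def _add_child(cohort: SimulatedCohort, mother: str, father: str, child_id: str,
               rng: np.random.Generator, sex: str | None = None) -> str:
    mi, fi = cohort.samples.index(mother), cohort.samples.index(father)
    sex = sex or ("male" if rng.random() < 0.5 else "female")
    m_anc, m_all = _gamete(cohort, mi, x_from_single=False, rng=rng)
    f_anc, f_all = _gamete(cohort, fi, x_from_single=True, rng=rng)
    is_x = cohort.panel["is_x"].to_numpy()
    if sex == "male":   # sons take no paternal X
        f_anc = f_anc.copy()
        f_all = f_all.copy()
        f_anc[is_x] = NO_HAP
        f_all[is_x] = NO_HAP
    child_anc = np.stack([m_anc, f_anc])
    child_all = np.stack([m_all, f_all])
    cohort.samples.append(child_id)
    cohort.sex[child_id] = sex
    cohort.hap_ancestry = np.concatenate([cohort.hap_ancestry, child_anc[None]], axis=0)
    cohort.hap_allele = np.concatenate([cohort.hap_allele, child_all[None]], axis=0)
    cohort.pedigree[child_id] = (mother, father)
    return child_id


def simulate_relatives(cohort: SimulatedCohort, degree: str, n_pairs: int,
                       rng: np.random.Generator) -> list[tuple[str, str, str]]:
    """Extend a founder cohort with relative pairs by gene dropping.

    ``degree`` is ``identical`` (a duplicated genome re-observed),
    ``first`` (parent–offspring) or ``second`` (grandparent–grandchild).
    Returns the appended (sample_a, sample_b, degree) truth tuples.
    """
    if degree not in ("identical", "first", "second"):
        raise ValueError(f"unknown degree {degree!r}")
    founders = [s for s in cohort.samples if cohort.pedigree.get(s) is None]
    females = [s for s in founders if cohort.sex[s] == "female"]
    males = [s for s in founders if cohort.sex[s] == "male"]
    need = {"identical": 1, "first": 2, "second": 3}[degree]
    if degree != "identical" and (len(females) < 1 or len(males) < max(1, need - 1)):
        raise ValueError("insufficient founders for the requested relatives")
    pairs: list[tuple[str, str, str]] = []
    for k in range(n_pairs):
        tag = f"{degree[:3]}{k:03d}"
        if degree == "identical":
            src = founders[int(rng.integers(len(founders)))]
            dup_id = f"dup_{tag}_{src}"
            i = cohort.samples.index(src)
            cohort.samples.append(dup_id)
            cohort.sex[dup_id] = cohort.sex[src]
            cohort.hap_ancestry = np.concatenate(
                [cohort.hap_ancestry, cohort.hap_ancestry[i][None]], axis=0)
            cohort.hap_allele = np.concatenate(
                [cohort.hap_allele, cohort.hap_allele[i][None]], axis=0)
            cohort.pedigree[dup_id] = None
            pairs.append((src, dup_id, "identical"))
        elif degree == "first":
            mother = females[int(rng.integers(len(females)))]
            father = males[int(rng.integers(len(males)))]
            child = _add_child(cohort, mother, father, f"child_{tag}", rng)
            pairs.append((mother, child, "first"))
        else:
            grandma = females[int(rng.integers(len(females)))]
            grandpa = males[int(rng.integers(len(males)))]
            parent = _add_child(cohort, grandma, grandpa, f"par_{tag}", rng, sex="female")
            mate = males[int(rng.integers(len(males)))]
            grandchild = _add_child(cohort, parent, mate, f"gchild_{tag}", rng)
            pairs.append((grandma, grandchild, "second"))
    cohort.relative_pairs.extend(pairs)
    return pairs


def pseudo_haploid_matrix(cohort: SimulatedCohort,
                          rng: np.random.Generator,
                          missing_rate: float | None = None,
                          ) -> tuple[PseudoHaploidMatrix, pd.DataFrame]:
    """Observe the cohort pseudo-haploidly: one random allele per site."""
    missing_rate = (cohort.config.missing_rate if missing_rate is None
                    else missing_rate)
    n, _, m = cohort.hap_allele.shape
    pick = rng.integers(0, 2, size=(n, m))
    # where the picked haplotype is absent (male X slot 1), fall back to slot 0
    picked = np.take_along_axis(cohort.hap_allele, pick[:, None, :], axis=1)[:, 0, :]
    fallback = cohort.hap_allele[:, 0, :]
    calls = np.where(picked == NO_HAP, fallback, picked).astype(np.int8)
    calls[calls == NO_HAP] = MISSING  # sites with no haplotype at all (none in practice)
    miss = rng.random((n, m)) < missing_rate
    calls[miss] = MISSING
    matrix = PseudoHaploidMatrix(samples=list(cohort.samples),
                                 panel=cohort.panel, calls=calls)
    meta = make_sample_meta(matrix, group={s: "SIM" for s in cohort.samples},
                            sex=cohort.sex)
    return matrix, meta


# ---------------------------------------------------------------------------
# Local-ancestry track and HLA genotypes
# ---------------------------------------------------------------------------

def truth_track(cohort: SimulatedCohort, snp_mask: np.ndarray | None = None
                ) -> AncestryTrack:
    """Local-ancestry track from the true haplotype labels (probabilities 0/1).

    Restricted to autosomal SNPs (both haplotypes always present), optionally
    further subset by ``snp_mask``.
    """
    mask = cohort.auto_mask if snp_mask is None else (cohort.auto_mask & snp_mask)
    idx = np.flatnonzero(mask)
    prob = cohort.hap_ancestry[:, :, idx].astype(float)
    panel = cohort.panel.iloc[idx][["snp_id", "chrom", "physical_pos"]].reset_index(drop=True)
    return AncestryTrack(panel=panel, samples=list(cohort.samples), prob_whg=prob)


def mhc_haplotype_ancestry(cohort: SimulatedCohort,
                           region: tuple[str, int, int] | None = None) -> np.ndarray:
    """Majority ancestry label of each haplotype over the MHC region, (n, 2)."""
    chrom, start, end = region or (cfg.MHC_CHROM, cfg.MHC_START, cfg.MHC_END)
    panel = cohort.panel
    mask = ((panel["chrom"] == chrom) & (panel["physical_pos"] >= start)
            & (panel["physical_pos"] <= end)).to_numpy()
    if not mask.any():
        raise ValueError("no SNPs inside the MHC region of the panel")
    lab = cohort.hap_ancestry[:, :, mask]
    return (lab.mean(axis=2) >= 0.5).astype(np.int8)


def _draw_from_pool(pool: list[tuple], rng: np.random.Generator) -> tuple:
    freqs = np.array([p[-1] for p in pool], dtype=float)
    freqs = freqs / freqs.sum()
    return pool[int(rng.choice(len(pool), p=freqs))]


def simulate_hla(cohort: SimulatedCohort, rng: np.random.Generator,
                 missing_rate: float | None = None,
                 region: tuple[str, int, int] | None = None,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """HLA genotypes whose DRB1–DQB1 pool depends on MHC local ancestry.

    Each MHC haplotype draws a DRB1–DQB1 haplotype from the pool of its true
    ancestry; HLA-A alleles come from a shared ancestry-neutral pool.
    Returns (genotype table, per-haplotype truth table).
    """
    conf = cohort.config
    missing_rate = conf.hla_missing_rate if missing_rate is None else missing_rate
    if not conf.whg_pool or not conf.an_pool:
        raise ValueError("empty HLA haplotype pool")
    anc = mhc_haplotype_ancestry(cohort, region=region)
    pools = {WHG_LABEL: conf.whg_pool, AN_LABEL: conf.an_pool}
    rows, truth = [], []
    for i, s in enumerate(cohort.samples):
        geno: dict[str, list[str]] = {"DRB1": [], "DQB1": [], "A": []}
        for h in (0, 1):
            drb, dqb, _ = _draw_from_pool(pools[int(anc[i, h])], rng)
            a_allele, _ = _draw_from_pool(conf.a_pool, rng)
            geno["DRB1"].append(drb)
            geno["DQB1"].append(dqb)
            geno["A"].append(a_allele)
            truth.append({"sample_id": s, "hap": h, "mhc_ancestry": int(anc[i, h]),
                          "drb1": drb, "dqb1": dqb, "a": a_allele})
        for locus in ("A", "DRB1", "DQB1"):
            if rng.random() < missing_rate:
                continue
            a1, a2 = sorted(geno[locus])
            rows.append({"sample_id": s, "locus": locus,
                         "allele1": a1, "allele2": a2})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def simulate_hla_from_haplotypes(haplo_freqs: dict[tuple[str, str], float],
                                 n_individuals: int,
                                 rng: np.random.Generator) -> pd.DataFrame:
    """Random-mating two-locus genotypes from known haplotype frequencies.

    Utility for EM recovery experiments: each individual draws two DRB1–DQB1
    haplotypes i.i.d. from ``haplo_freqs``.
    """
    haps = list(haplo_freqs)
    probs = np.array([haplo_freqs[h] for h in haps], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    rows = []
    for i in range(n_individuals):
        h1, h2 = (haps[j] for j in rng.choice(len(haps), size=2, p=probs))
        drb = sorted([h1[0], h2[0]])
        dqb = sorted([h1[1], h2[1]])
        rows.append({"sample_id": f"em{i:03d}", "locus": h1[0].split("*")[0],
                     "allele1": drb[0], "allele2": drb[1]})
        rows.append({"sample_id": f"em{i:03d}", "locus": h1[1].split("*")[0],
                     "allele1": dqb[0], "allele2": dqb[1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wright–Fisher split (for the Q-statistic calibration)
# ---------------------------------------------------------------------------

def wright_fisher_split_samples(n_loci: int, n_copies: int, generations: int,
                                n_sample: int, rng: np.random.Generator,
                                p0: np.ndarray | None = None,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Drift a population of ``n_copies`` haploid genomes from a source.

    Returns (source_sample, derived_sample) 0/1 call matrices of shape
    (n_sample, n_loci): the source sampled at the ancestral frequencies, the
    derived population sampled after ``generations`` of binomial resampling.
    """
    p0 = rng.uniform(0.05, 0.95, size=n_loci) if p0 is None else p0
    p = p0.copy()
    for _ in range(generations):
        p = rng.binomial(n_copies, p) / n_copies
    src = (rng.random((n_sample, n_loci)) < p0).astype(np.int8)
    der = (rng.random((n_sample, n_loci)) < p).astype(np.int8)
    return src, der
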