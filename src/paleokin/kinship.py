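"""Pairwise-mismatch kinship estimation for pseudo-haploid genotypes.

For a pair of individuals, ``x`` is the fraction of discordant calls among
jointly non-missing autosomal SNPs.  With ``b`` the expected mismatch rate of
two unrelated individuals from the same population, the relatedness
coefficient is

    r = 1 - 2 (x - b/2) / b

so that x = b gives r = 0 (unrelated) and x = b/2 gives r = 1 (identical
genomes; pseudo-haploid sampling of the same diploid genotype still
mismatches at heterozygous sites, hence b/2 rather than 0).  ``b`` is
self-estimated as the median mismatch rate over well-covered pairs.

Degrees are assigned by binning r at the midpoints of the expected values
(identical 1, first degree 0.5, second 0.25, unrelated 0); pairs with too few
overlapping SNPs or with a bootstrap CI spanning three or more bins are left
unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import config
from .genotype_io import MISSING, PseudoHaploidMatrix

# Lower edges of the degree bins (midpoints between expected r values).
DEGREE_BINS = [
    ("unrelated", -np.inf, 0.1875),
    ("second", 0.1875, 0.375),
    ("first", 0.375, 0.75),
    ("identical", 0.75, np.inf),
]


@dataclass
class MismatchRecord:
    pair: tuple[str, str]
    x: float
    n_overlap: int
    x_ci: tuple[float, float]


@dataclass
class KinshipResult:
    pair: tuple[str, str]
    x: float
    n_overlap: int
    r: float
    r_ci: tuple[float, float]
    degree: str
    b_used: float


def pairwise_mismatch(matrix: PseudoHaploidMatrix, pair: tuple[str, str],
                      n_bootstrap: int = config.N_BOOTSTRAP,
                      rng: np.random.Generator | None = None) -> MismatchRecord:
    """Mismatch rate over jointly called autosomal SNPs, with bootstrap CI.

    The 95% CI resamples SNPs with replacement (percentile method).  For a
    0/1 discordance vector this is equivalent to drawing the discordant count
    from Binomial(n, x), which avoids materialising index arrays.
    """
    auto = matrix.autosomes()
    i, j = auto.sample_index(pair[0]), auto.sample_index(pair[1])
    a, b_ = auto.calls[i], auto.calls[j]
    joint = (a != MISSING) & (b_ != MISSING)
    n = int(joint.sum())
    if n == 0:
        raise ValueError(f"pair {pair} has no jointly called autosomal SNPs")
    x = float((a[joint] != b_[joint]).mean())
    if n_bootstrap > 0:
        rng = rng if rng is not None else np.random.default_rng()
        boot = rng.binomial(n, x, size=n_bootstrap) / n
        lo, hi = np.percentile(boot, [2.5, 97.5])
    else:
        lo = hi = x
    return MismatchRecord(pair=pair, x=x, n_overlap=n, x_ci=(float(lo), float(hi)))


def all_pairwise_mismatch(matrix: PseudoHaploidMatrix,
                          n_bootstrap: int = 0,
                          rng: np.random.Generator | None = None,
                          ) -> list[MismatchRecord]:
    """Mismatch records for every unordered sample pair.

    Counts are accumulated with matrix products over the autosomal calls, so
    the all-pairs pass is a handful of GEMMs rather than O(n^2) python loops;
    bootstrap CIs (if requested) are then drawn per pair from the binomial
    equivalence used in :func:`pairwise_mismatch`.
    """
    auto = matrix.autosomes()
    called = (auto.calls != MISSING)
    V = called.astype(np.float32)
    A = np.where(called, auto.calls, 0).astype(np.float32)  # ALT indicator
    n_joint = V @ V.T
    n_both_alt = A @ A.T
    n_alt_i = A @ V.T               # i ALT, j called
    # discordant = (i ALT, j REF) + (i REF, j ALT)
    n_disc = (n_alt_i - n_both_alt) + (n_alt_i.T - n_both_alt)
    rng = rng if rng is not None else np.random.default_rng()
    records = []
    for i in range(auto.n_samples):
        for j in range(i + 1, auto.n_samples):
            n = int(round(n_joint[i, j]))
            if n == 0:
                continue
            x = float(n_disc[i, j]) / n
            if n_bootstrap > 0:
                boot = rng.binomial(n, x, size=n_bootstrap) / n
                lo, hi = np.percentile(boot, [2.5, 97.5])
            else:
                lo = hi = x
            records.append(MismatchRecord(
                pair=(auto.samples[i], auto.samples[j]),
                x=x, n_overlap=n, x_ci=(float(lo), float(hi))))
    return records


def estimate_baseline_b(records: list[MismatchRecord],
                        min_overlap: int = config.MIN_OVERLAP_BASELINE) -> float:
    """Median mismatch rate over pairs with at least ``min_overlap`` joint SNPs."""
    xs = [r.x for r in records if r.n_overlap >= min_overlap]
    if not xs:
        raise ValueError(
            f"no pair has >= {min_overlap} overlapping SNPs; cannot estimate b")
    return float(np.median(xs))


def relatedness_coefficient(x: float, b: float) -> float:
    if b <= 0:
        raise ValueError("baseline mismatch rate b must be positive")
    return 1.0 - (2.0 * (x - b / 2.0)) / b


def _bin_of(r: float) -> str:
    for name, lo, hi in DEGREE_BINS:
        if lo <= r < hi:
            return name
    return "unrelated"


def classify_degree(record: MismatchRecord, b: float,
                    min_overlap: int = config.MIN_OVERLAP_CALL) -> KinshipResult:
    """Assign a kinship degree from a mismatch record and baseline b.

    r decreases in x, so the CI endpoints swap when mapped through the
    relatedness formula.  Pairs with fewer than ``min_overlap`` SNPs or a CI
    touching three or more degree bins stay ``unassigned``.
    """
    r = relatedness_coefficient(record.x, b)
    r_lo = relatedness_coefficient(record.x_ci[1], b)
    r_hi = relatedness_coefficient(record.x_ci[0], b)
    if record.n_overlap < min_overlap:
        degree = "unassigned"
    else:
        n_bins = sum(1 for _, lo, hi in DEGREE_BINS if r_hi >= lo and r_lo < hi)
        degree = "unassigned" if n_bins >= 3 else _bin_of(r)
    return KinshipResult(pair=record.pair, x=record.x, n_overlap=record.n_overlap,
                         r=r, r_ci=(r_lo, r_hi), degree=degree, b_used=b)


def kinship_table(results: list[KinshipResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_a": k.pair[0], "sample_b": k.pair[1],
        "x": k.x, "n_overlap": k.n_overlap, "r": k.r,
        "r_ci_low": k.r_ci[0], "r_ci_high": k.r_ci[1],
        "degree": k.degree, "b_used": k.b_used,
    } for k in results])


def run_kinship(matrix: PseudoHaploidMatrix,
                n_bootstrap: int = config.N_BOOTSTRAP,
                min_overlap_b: int = config.MIN_OVERLAP_BASELINE,
                min_overlap_call: int = config.MIN_OVERLAP_CALL,
                b: float | None = None,
                rng: np.random.Generator | None = None) -> list[KinshipResult]:
    """All-pairs kinship: mismatch rates, self-estimated b, degree calls."""
    records = all_pairwise_mismatch(matrix, n_bootstrap=n_bootstrap, rng=rng)
    if b is None:
        b = estimate_baseline_b(records, min_overlap=min_overlap_b)
    return [classify_degree(rec, b, min_overlap=min_overlap_call) for rec in records]


def first_degree_clusters(results: list[KinshipResult]) -> list[set[str]]:
    """Connected components of the first-degree (and identical) relation."""
    parent: dict[str, str] = {}

    def find(s: str) -> str:
        parent.setdefault(s, s)
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for k in results:
        if k.degree in ("first", "identical"):
            ra, rb = find(k.pair[0]), find(k.pair[1])
            if ra != rb:
                parent[ra] = rb
    clusters: dict[str, set[str]] = {}
    for s in list(parent):
        clusters.setdefault(find(s), set()).add(s)
    return [c for c in clusters.values() if len(c) > 1]
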