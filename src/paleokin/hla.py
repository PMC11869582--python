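"""HLA allele frequencies, group comparisons, diversity, and haplotype EM.

All analyses work at two-field allele resolution on a long-format genotype
table (sample_id, locus, allele1, allele2).  Frequencies count two alleles
per typed individual; individuals untyped at a locus are excluded from that
locus only.

Between-group frequency differences use Fisher's exact test on allele
counts with two-stage Benjamini–Hochberg (TSBH) FDR control; an allele is
called significant when the adjusted p is at most alpha AND the absolute
frequency difference is at least 0.1.  A resampling Mann–Whitney comparison
guards against sample-size artefacts.  Diversity is Shannon's H' computed on
frequency-weighted resamples of equal size, compared with Kruskal–Wallis and
Dunn post-hoc tests.  Two-locus haplotype frequencies come from the
gametic-phase EM algorithm for unphased multi-allelic genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, kruskal, mannwhitneyu, norm

from . import config
from .kinship import KinshipResult, first_degree_clusters


# ---------------------------------------------------------------------------
# Relative exclusion and allele frequencies
# ---------------------------------------------------------------------------

def typed_locus_counts(table: pd.DataFrame) -> pd.Series:
    """Number of typed loci per sample."""
    return table.groupby("sample_id")["locus"].nunique()


def exclude_first_degree(table: pd.DataFrame,
                         kinship_results: list[KinshipResult]) -> pd.DataFrame:
    """Keep one individual per first-degree cluster.

    From each connected cluster of first-degree (or identical) pairs the
    individual with the most typed HLA loci is retained (ties broken by the
    lexicographically smallest sample id).
    """
    counts = typed_locus_counts(table)
    drop: set[str] = set()
    for cluster in first_degree_clusters(kinship_results):
        members = sorted(cluster)
        # highest typed-locus count wins, ties go to the smallest id
        best = sorted(members, key=lambda s: (-counts.get(s, 0), s))[0]
        drop.update(m for m in members if m != best)
    return table[~table["sample_id"].isin(drop)].reset_index(drop=True)


def allele_frequencies(table: pd.DataFrame,
                       samples: list[str] | None = None) -> pd.DataFrame:
    """Per-locus allele counts and frequencies (2 alleles per typed sample).

    Returns a table with columns locus, allele, count, frequency,
    n_alleles_typed.  Loci with no typed individual are omitted with a
    warning.
    """
    sub = table if samples is None else table[table["sample_id"].isin(samples)]
    rows = []
    for locus in config.HLA_LOCI:
        loc = sub[sub["locus"] == locus]
        if loc.empty:
            if (table["locus"] == locus).any() or samples is not None:
                warnings.warn(f"locus {locus} has no typed individual; omitted")
            continue
        alleles = pd.concat([loc["allele1"], loc["allele2"]])
        counts = alleles.value_counts().sort_index()
        n = int(counts.sum())
        for allele, k in counts.items():
            rows.append({"locus": locus, "allele": allele, "count": int(k),
                         "frequency": k / n, "n_alleles_typed": n})
    return pd.DataFrame(rows, columns=["locus", "allele", "count",
                                       "frequency", "n_alleles_typed"])


# ---------------------------------------------------------------------------
# Multiple-testing control
# ---------------------------------------------------------------------------

def tsbh_adjust(p_values, alpha: float = config.ALPHA) -> np.ndarray:
    """Two-stage Benjamini–Hochberg adjusted p-values.

    Stage 1 runs the BH linear step-up at alpha' = alpha/(1+alpha) and counts
    r1 rejections; the number of true nulls is estimated as m0 = m - r1.
    Stage 2 is BH with m replaced by m0: adjusted p for the i-th order
    statistic is min over j >= i of p_(j) * m0 / j, clipped to [0, 1].  The
    output is monotone in the input ranks and invariant to input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    alpha1 = alpha / (1.0 + alpha)
    ranks = np.arange(1, m + 1)
    passed = np.flatnonzero(ps <= ranks / m * alpha1)
    r1 = int(passed[-1] + 1) if passed.size else 0
    m0 = max(m - r1, 1)
    adj = np.minimum.accumulate((ps * m0 / ranks)[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def holm_sidak_adjust(p_values) -> np.ndarray:
    """Holm–Šidák step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    adj = 1.0 - (1.0 - ps) ** (m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Frequency comparisons
# ---------------------------------------------------------------------------

def fisher_comparison(freq_a: pd.DataFrame, freq_b: pd.DataFrame,
                      alpha: float = config.ALPHA,
                      min_freq_diff: float = config.MIN_FREQ_DIFF,
                      family: str = "all") -> pd.DataFrame:
    """Per-allele Fisher exact comparison of two frequency tables.

    Each allele contributes a 2x2 table of (this allele vs all others) by
    group, on allele counts.  Adjustment families: ``all`` corrects across
    every allele of every locus in one family; ``per-locus`` corrects within
    each locus separately.
    """
    if family not in ("all", "per-locus"):
        raise ValueError("family must be 'all' or 'per-locus'")
    a_idx = freq_a.set_index(["locus", "allele"])
    b_idx = freq_b.set_index(["locus", "allele"])
    n_a = dict(freq_a.groupby("locus")["n_alleles_typed"].first())
    n_b = dict(freq_b.groupby("locus")["n_alleles_typed"].first())
    rows = []
    for locus in config.HLA_LOCI:
        if locus not in n_a or locus not in n_b:
            continue
        alleles = sorted({al for (lo, al) in a_idx.index if lo == locus}
                         | {al for (lo, al) in b_idx.index if lo == locus})
        for allele in alleles:
            k1 = int(a_idx["count"].get((locus, allele), 0))
            k2 = int(b_idx["count"].get((locus, allele), 0))
            if k1 == 0 and k2 == 0:
                continue
            n1, n2 = int(n_a[locus]), int(n_b[locus])
            _, p = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")
            rows.append({"locus": locus, "allele": allele,
                         "k1": k1, "n1": n1, "k2": k2, "n2": n2,
                         "freq_a": k1 / n1, "freq_b": k2 / n2,
                         "freq_diff": k2 / n2 - k1 / n1, "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if family == "all":
        out["p_adjusted"] = tsbh_adjust(out["p_raw"].to_numpy(), alpha=alpha)
    else:
        out["p_adjusted"] = np.nan
        for locus in out["locus"].unique():
            mask = out["locus"] == locus
            out.loc[mask, "p_adjusted"] = tsbh_adjust(
                out.loc[mask, "p_raw"].to_numpy(), alpha=alpha)
    out["significant"] = (out["p_adjusted"] <= alpha) & \
        (out["freq_diff"].abs() >= min_freq_diff)
    return out


def _per_sample_allele_counts(table: pd.DataFrame, locus: str
                              ) -> tuple[list[str], list[str], np.ndarray]:
    """(samples typed at locus, allele labels, sample x allele count matrix)."""
    loc = table[table["locus"] == locus]
    samples = loc["sample_id"].tolist()
    alleles = sorted(set(loc["allele1"]) | set(loc["allele2"]))
    a_index = {a: j for j, a in enumerate(alleles)}
    counts = np.zeros((len(samples), len(alleles)), dtype=np.int64)
    for i, (_, row) in enumerate(loc.iterrows()):
        counts[i, a_index[row["allele1"]]] += 1
        counts[i, a_index[row["allele2"]]] += 1
    return samples, alleles, counts


def downsampled_comparison(table_a: pd.DataFrame, table_b: pd.DataFrame,
                           n_resamples: int = config.N_HLA_RESAMPLES,
                           rng: np.random.Generator | None = None,
                           alpha: float = config.ALPHA) -> pd.DataFrame:
    """Resampling Mann–Whitney comparison robust to unequal group sizes.

    Both groups are resampled with replacement ``n_resamples`` times at the
    size of the smaller group (in individuals); allele frequencies are
    recomputed per resample and compared per allele with a two-sided
    Mann–Whitney U test (average ranks, tie-corrected normal approximation),
    then TSBH-adjusted.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n_ind_a = table_a["sample_id"].nunique()
    n_ind_b = table_b["sample_id"].nunique()
    if min(n_ind_a, n_ind_b) < 2:
        raise ValueError("each group needs at least two individuals")
    n = min(n_ind_a, n_ind_b)

    def resample_freqs(table: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
        ids = sorted(table["sample_id"].unique())
        out: dict[tuple[str, str], np.ndarray] = {}
        per_locus = {}
        for locus in config.HLA_LOCI:
            sub = _per_sample_allele_counts(table, locus)
            if sub[0]:
                per_locus[locus] = sub
        draws = rng.integers(0, len(ids), size=(n_resamples, n))
        for locus, (samples, alleles, counts) in per_locus.items():
            s_index = {s: i for i, s in enumerate(samples)}
            row_of_id = np.array([s_index.get(ids[j], -1) for j in range(len(ids))])
            for r in range(n_resamples):
                chosen = row_of_id[draws[r]]
                chosen = chosen[chosen >= 0]   # untyped individuals excluded
                if len(chosen) == 0:
                    freqs = np.zeros(len(alleles))
                else:
                    tot = counts[chosen].sum(axis=0)
                    freqs = tot / tot.sum()
                for j, allele in enumerate(alleles):
                    out.setdefault((locus, allele), np.zeros(n_resamples))[r] = freqs[j]
        return out

    fa = resample_freqs(table_a)
    fb = resample_freqs(table_b)
    keys = sorted(set(fa) | set(fb))
    rows = []
    for locus, allele in keys:
        x = fa.get((locus, allele), np.zeros(n_resamples))
        y = fb.get((locus, allele), np.zeros(n_resamples))
        if np.all(x == y[0]) and np.all(y == y[0]):
            p = 1.0
        else:
            p = float(mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic").pvalue)
        rows.append({"locus": locus, "allele": allele,
                     "mean_freq_a": float(x.mean()), "mean_freq_b": float(y.mean()),
                     "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = tsbh_adjust(out["p_raw"].to_numpy(), alpha=alpha)
    return out


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def shannon_index(frequencies) -> float:
    """H' = -sum p ln p; zero-frequency classes contribute nothing."""
    p = np.asarray(frequencies, dtype=float)
    if (p < 0).any():
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def dunn_test(groups: dict[str, np.ndarray],
              alpha: float = config.ALPHA) -> pd.DataFrame:
    """Dunn's post-hoc pairwise tests on pooled ranks with tie correction.

    z for groups i, j is (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i +
    1/n_j)) with T = sum(t^3 - t) / (12 (N-1)) over tie groups; two-sided
    normal p-values are TSBH-adjusted.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    N = len(values)
    ranks = pd.Series(values).rank(method="average").to_numpy()
    _, tie_counts = np.unique(values, return_counts=True)
    T = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1)))
    mean_rank = {g: ranks[labels == g].mean() for g in names}
    n_of = {g: int((labels == g).sum()) for g in names}
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gi, gj = names[i], names[j]
            se = np.sqrt((N * (N + 1) / 12.0 - T) * (1.0 / n_of[gi] + 1.0 / n_of[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else 0.0
            p = 2.0 * float(norm.sf(abs(z))) if se > 0 else 1.0
            rows.append({"group_a": gi, "group_b": gj, "z": float(z), "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = tsbh_adjust(out["p_raw"].to_numpy(), alpha=alpha)
    return out


@dataclass
class ShannonResult:
    population: str
    h_values: np.ndarray
    n_resample: int


def shannon_resampling_compare(pop_freqs: dict[str, dict[str, float]],
                               pop_allele_counts: dict[str, int],
                               n_resamples: int = config.N_HLA_RESAMPLES,
                               rng: np.random.Generator | None = None,
                               alpha: float = config.ALPHA) -> dict:
    """Equal-size weighted resampling of H' plus Kruskal–Wallis and Dunn tests.

    Per population, ``n_resamples`` samples of ``n`` alleles are drawn with
    replacement, weighted by the population's allele frequencies, where n is
    the smallest population's typed-allele count (2 per typed individual);
    H' is computed on each resample's frequencies.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = min(pop_allele_counts[p] for p in pop_freqs)
    results: dict[str, ShannonResult] = {}
    for pop, freqs in pop_freqs.items():
        probs = np.array(list(freqs.values()), dtype=float)
        probs = probs / probs.sum()
        h = np.empty(n_resamples)
        for r in range(n_resamples):
            counts = rng.multinomial(n, probs)
            h[r] = shannon_index(counts / counts.sum())
        results[pop] = ShannonResult(population=pop, h_values=h, n_resample=n_resamples)
    hs = {p: results[p].h_values for p in results}
    if len(hs) >= 2 and any(np.ptp(v) > 0 for v in hs.values()):
        kw_p = float(kruskal(*hs.values()).pvalue)
    else:
        kw_p = 1.0
    dunn = dunn_test(hs, alpha=alpha) if len(hs) >= 2 else pd.DataFrame()
    return {"shannon": results, "kruskal_p": kw_p, "dunn": dunn, "n": n}


# ---------------------------------------------------------------------------
# Two-locus haplotype EM
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeEMResult:
    locus_a: str
    locus_b: str
    frequencies: dict[tuple[str, str], float]
    loglik: float
    n_iterations: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)


def _genotype_configs(a1, a2, b1, b2):
    """Phase configurations of a two-locus genotype with multiplicities.

    Returns [(hap1, hap2, mult)]: the multinomial coefficient is 1 when the
    two haplotypes coincide and 2 otherwise.  Only double heterozygotes have
    two distinct configurations.
    """
    c1 = ((a1, b1), (a2, b2))
    c2 = ((a1, b2), (a2, b1))
    configs = [c1]
    if a1 != a2 and b1 != b2:
        configs.append(c2)
    out = []
    for h1, h2 in configs:
        out.append((h1, h2, 1.0 if h1 == h2 else 2.0))
    return out


def haplotype_em(table: pd.DataFrame, locus_a: str, locus_b: str,
                 tol: float = 1e-8, max_iter: int = 1_000) -> HaplotypeEMResult:
    """Excoffier–Slatkin gametic-phase EM for two multi-allelic loci.

    The E-step distributes each double heterozygote across its two phase
    configurations in proportion to the current haplotype frequencies; the
    M-step re-estimates frequencies from expected haplotype counts.  Starts
    from linkage-equilibrium product frequencies; the observed-data
    log-likelihood is asserted non-decreasing at every iteration.
    """
    ga = table[table["locus"] == locus_a].set_index("sample_id")
    gb = table[table["locus"] == locus_b].set_index("sample_id")
    shared = sorted(set(ga.index) & set(gb.index))
    if not shared:
        raise ValueError(f"no individual typed at both {locus_a} and {locus_b}")
    genotypes = []
    for s in shared:
        genotypes.append((ga.loc[s, "allele1"], ga.loc[s, "allele2"],
                          gb.loc[s, "allele1"], gb.loc[s, "allele2"]))
    configs = [_genotype_configs(*g) for g in genotypes]
    haps = sorted({h for cfgs in configs for h1, h2, _ in cfgs for h in (h1, h2)})
    h_index = {h: i for i, h in enumerate(haps)}

    # linkage-equilibrium initialisation from marginal allele frequencies
    fa: dict[str, float] = {}
    fb: dict[str, float] = {}
    for a1, a2, b1, b2 in genotypes:
        for a in (a1, a2):
            fa[a] = fa.get(a, 0.0) + 1.0
        for b in (b1, b2):
            fb[b] = fb.get(b, 0.0) + 1.0
    tot = 2.0 * len(genotypes)
    f = np.array([fa[h[0]] / tot * fb[h[1]] / tot for h in haps])
    f = f / f.sum()

    def loglik_of(freqs: np.ndarray) -> float:
        ll = 0.0
        for cfgs in configs:
            lik = sum(mult * freqs[h_index[h1]] * freqs[h_index[h2]]
                      for h1, h2, mult in cfgs)
            ll += np.log(max(lik, 1e-300))
        return float(ll)

    path = [loglik_of(f)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = np.zeros(len(haps))
        for cfgs in configs:
            w = np.array([mult * f[h_index[h1]] * f[h_index[h2]]
                          for h1, h2, mult in cfgs])
            tot_w = w.sum()
            if tot_w <= 0:
                w = np.full(len(cfgs), 1.0 / len(cfgs))
            else:
                w = w / tot_w
            for (h1, h2, _), wc in zip(cfgs, w):
                counts[h_index[h1]] += wc
                counts[h_index[h2]] += wc
        new_f = counts / counts.sum()
        new_ll = loglik_of(new_f)
        if new_ll < path[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        delta = float(np.abs(new_f - f).max())
        f = new_f
        path.append(new_ll)
        if delta < tol:
            converged = True
            break
    return HaplotypeEMResult(
        locus_a=locus_a, locus_b=locus_b,
        frequencies={h: float(v) for h, v in zip(haps, f)},
        loglik=path[-1], n_iterations=it, converged=converged,
        loglik_path=path)
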