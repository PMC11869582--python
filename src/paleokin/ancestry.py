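"""Two-source ancestry estimation and sex-biased admixture statistics.

Ancestry proportions are estimated by maximum likelihood under a two-source
binomial model for pseudo-haploid calls: given per-SNP ALT frequencies
``f_whg`` and ``f_an`` in the two sources, the probability that a sampled
allele at SNP i is ALT for an individual with WHG fraction q is
``q f_whg,i + (1-q) f_an,i``.  With the source frequencies fixed the
log-likelihood is concave in q, so the supervised two-source problem reduces
to a one-dimensional bounded optimisation.

Sex bias is read from two complementary statistics:

* Q = ln(1 - 2 Fst_A) / ln(1 - 2 Fst_X), which equals 3/4 when male and
  female effective sizes are equal (three X chromosomes circulate for every
  four autosomes);
* R_X/A, the per-individual ratio of WHG ancestry on the X chromosome to
  that on autosomes, with autosomal SNPs repeatedly down-sampled to the X
  SNP count so both compartments face the same estimation noise.  Equal
  male/female contributions give R_X/A = 1; values below 1 indicate
  male-biased WHG input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binomtest, pearsonr, wilcoxon

from . import config
from .genotype_io import ALT, MISSING, PseudoHaploidMatrix

logger = logging.getLogger(__name__)


@dataclass
class AncestryEstimate:
    sample_id: str
    compartment: str          # "autosome" or "X"
    q_whg: float
    n_snps_used: int
    loglik: float
    identifiable: bool = True


@dataclass
class SexBiasRecord:
    sample_id: str
    q_x: float
    q_a_reps: np.ndarray      # per-replicate autosomal estimates
    rxa: float                # q_x / mean(q_a_reps)
    rxa_replicates: np.ndarray


def source_frequencies(matrix: PseudoHaploidMatrix,
                       whg_samples: list[str], an_samples: list[str],
                       pseudocount: float = config.FREQ_PSEUDOCOUNT,
                       clip: tuple[float, float] = config.FREQ_CLIP,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ALT frequencies of the two source panels.

    A pseudocount per allele class keeps monomorphic reference panels off the
    log(0) boundary; frequencies are then clipped.
    """
    def freqs(sample_ids: list[str]) -> np.ndarray:
        idx = [matrix.sample_index(s) for s in sample_ids]
        sub = matrix.calls[idx]
        n_alt = (sub == ALT).sum(axis=0)
        n_called = (sub != MISSING).sum(axis=0)
        f = (n_alt + pseudocount) / (n_called + 2 * pseudocount)
        return np.clip(f, *clip)

    return freqs(whg_samples), freqs(an_samples)


def _observed_allele_probs(calls: np.ndarray, f_whg: np.ndarray, f_an: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP probability of the observed allele under each source."""
    use = calls != MISSING
    is_alt = calls[use] == ALT
    a = np.where(is_alt, f_whg[use], 1.0 - f_whg[use])
    b = np.where(is_alt, f_an[use], 1.0 - f_an[use])
    return a, b


def _fit_q(a: np.ndarray, b: np.ndarray, xatol: float = 1e-6) -> tuple[float, float]:
    """Maximise sum(log(q a + (1-q) b)) over q in [0, 1]."""
    diff = a - b

    def nll(q: float) -> float:
        return -float(np.log(b + q * diff).sum())

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": xatol})
    return float(res.x), -float(res.fun)


def estimate_ancestry(calls: np.ndarray, f_whg: np.ndarray, f_an: np.ndarray,
                      sample_id: str = "", compartment: str = "autosome",
                      ) -> AncestryEstimate:
    """ML WHG ancestry proportion for one individual's pseudo-haploid calls."""
    use = calls != MISSING
    n_used = int(use.sum())
    if n_used == 0:
        raise ValueError("all calls missing; cannot estimate ancestry")
    a, b = _observed_allele_probs(calls, f_whg, f_an)
    if np.allclose(a, b):
        loglik = float(np.log(a).sum())
        return AncestryEstimate(sample_id=sample_id, compartment=compartment,
                                q_whg=0.5, n_snps_used=n_used, loglik=loglik,
                                identifiable=False)
    q, loglik = _fit_q(a, b)
    return AncestryEstimate(sample_id=sample_id, compartment=compartment,
                            q_whg=q, n_snps_used=n_used, loglik=loglik)


def rxa_per_individual(matrix: PseudoHaploidMatrix,
                       f_whg: np.ndarray, f_an: np.ndarray,
                       n_reps: int = config.N_DOWNSAMPLE_REPS,
                       min_x_snps: int = config.MIN_X_SNPS,
                       rng: np.random.Generator | None = None,
                       ) -> list[SexBiasRecord]:
    """R_X/A per individual with autosomal down-sampling to the X SNP count.

    q_X uses all non-missing X SNPs; each replicate estimates q_A on an
    equally sized autosomal SNP subset drawn without replacement.  The
    reported ratio divides q_X by the mean replicate q_A; per-replicate
    ratios are retained for the paired tests.  Individuals with fewer than
    ``min_x_snps`` called X SNPs are excluded.
    """
    rng = rng if rng is not None else np.random.default_rng()
    is_x = matrix.panel["is_x"].to_numpy()
    records: list[SexBiasRecord] = []
    for i, s in enumerate(matrix.samples):
        calls = matrix.calls[i]
        x_idx = np.flatnonzero(is_x & (calls != MISSING))
        m = len(x_idx)
        if m < min_x_snps:
            logger.info("excluding %s: only %d called X SNPs (< %d)", s, m, min_x_snps)
            continue
        a_x, b_x = _observed_allele_probs(calls[x_idx], f_whg[x_idx], f_an[x_idx])
        q_x, _ = _fit_q(a_x, b_x)
        auto_idx = np.flatnonzero(~is_x & (calls != MISSING))
        a_full = np.where(calls[auto_idx] == ALT, f_whg[auto_idx], 1 - f_whg[auto_idx])
        b_full = np.where(calls[auto_idx] == ALT, f_an[auto_idx], 1 - f_an[auto_idx])
        take = min(m, len(auto_idx))
        q_reps = np.empty(n_reps)
        for rep in range(n_reps):
            sel = rng.choice(len(auto_idx), size=take, replace=False)
            q_reps[rep], _ = _fit_q(a_full[sel], b_full[sel])
        mean_qa = float(q_reps.mean())
        records.append(SexBiasRecord(
            sample_id=s, q_x=q_x, q_a_reps=q_reps,
            rxa=q_x / mean_qa if mean_qa > 0 else np.inf,
            rxa_replicates=np.where(q_reps > 0, q_x / q_reps, np.inf)))
    return records


def sexbias_tests(records: list[SexBiasRecord]) -> dict:
    """Binomial and Wilcoxon tests for male-biased WHG admixture.

    The right-tailed exact binomial test asks whether more individuals than
    expected under H0: P = 0.5 have R_X/A < 1 (ties at exactly 1 count as
    "not below").  Per down-sampling replicate, a paired Wilcoxon signed-rank
    test compares X against that replicate's autosomal ancestry across
    individuals; the median p over replicates is reported.
    """
    if len(records) < 2:
        raise ValueError("need at least two individuals")
    n = len(records)
    k = sum(1 for r in records if r.rxa < 1.0)
    binomial_p = float(binomtest(k, n, 0.5, alternative="greater").pvalue)
    n_reps = len(records[0].q_a_reps)
    qx = np.array([r.q_x for r in records])
    wilcoxon_p = np.empty(n_reps)
    for rep in range(n_reps):
        qa = np.array([r.q_a_reps[rep] for r in records])
        d = qx - qa
        if np.all(d == 0):
            wilcoxon_p[rep] = 1.0
            continue
        method = "exact" if (n <= 25 and np.all(d != 0)
                             and len(np.unique(np.abs(d[d != 0]))) == np.count_nonzero(d)) else "approx"
        wilcoxon_p[rep] = float(wilcoxon(qx, qa, zero_method="wilcox",
                                         correction=True, method=method).pvalue)
    return {
        "n_total": n,
        "n_below_1": k,
        "binomial_p": binomial_p,
        "mean_rxa": float(np.mean([r.rxa for r in records])),
        "median_rxa": float(np.median([r.rxa for r in records])),
        "wilcoxon_p_per_replicate": wilcoxon_p,
        "median_wilcoxon_p": float(np.median(wilcoxon_p)),
    }


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst (haploid) and the Q statistic
# ---------------------------------------------------------------------------

def wc_fst_counts(alt1: np.ndarray, n1: np.ndarray,
                  alt2: np.ndarray, n2: np.ndarray) -> float:
    """Weighted Weir–Cockerham Fst from per-SNP haploid allele counts.

    The 1984 ANOVA estimator adapted to haploid samples (no within-individual
    component): per SNP, with group sizes n_i and frequencies p_i,

        MSP = sum n_i (p_i - pbar)^2          (between groups, r-1 = 1 df)
        MSG = sum n_i p_i (1-p_i) / (n-2)     (within groups)
        n_c = n - (n_1^2 + n_2^2)/n

    and theta = (MSP - MSG) / (MSP + (n_c - 1) MSG).  The weighted
    multi-SNP estimate is the ratio of summed numerators to summed
    denominators.  SNPs without at least one call in each group, or
    monomorphic over both groups, contribute nothing.
    """
    alt1, n1 = np.asarray(alt1, float), np.asarray(n1, float)
    alt2, n2 = np.asarray(alt2, float), np.asarray(n2, float)
    ntot = n1 + n2
    ok = (n1 >= 1) & (n2 >= 1) & (ntot > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / n1
        p2 = alt2 / n2
        pbar = (alt1 + alt2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
        nc = ntot - (n1 ** 2 + n2 ** 2) / ntot
        num = msp - msg
        den = msp + (nc - 1) * msg
    ok &= np.nan_to_num(den) != 0
    if not ok.any():
        raise ValueError("no SNP informative for Fst")
    return float(num[ok].sum() / den[ok].sum())


def wc_fst(matrix: PseudoHaploidMatrix, group_a: list[str], group_b: list[str],
           snp_mask: np.ndarray | None = None) -> float:
    """Weighted haploid WC Fst between two sample groups of a call matrix."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ia = [matrix.sample_index(s) for s in group_a]
    ib = [matrix.sample_index(s) for s in group_b]
    calls_a, calls_b = matrix.calls[ia], matrix.calls[ib]
    if snp_mask is not None:
        calls_a, calls_b = calls_a[:, snp_mask], calls_b[:, snp_mask]
    return wc_fst_counts((calls_a == ALT).sum(axis=0), (calls_a != MISSING).sum(axis=0),
                         (calls_b == ALT).sum(axis=0), (calls_b != MISSING).sum(axis=0))


def q_statistic(fst_a: float, fst_x: float) -> float:
    """Q = ln(1 - 2 Fst_A) / ln(1 - 2 Fst_X); 3/4 under equal sex sizes."""
    for name, v in (("fst_a", fst_a), ("fst_x", fst_x)):
        if v >= 0.5:
            raise ValueError(f"{name} >= 0.5: Q undefined")
    if fst_x == 0.0:
        raise ValueError("fst_x = 0: Q undefined")
    return float(np.log(1 - 2 * fst_a) / np.log(1 - 2 * fst_x))


def x_robustness(matrix: PseudoHaploidMatrix,
                 f_whg: np.ndarray, f_an: np.ndarray,
                 min_x_snps: int = config.MIN_X_SNPS_ROBUSTNESS,
                 down_to: int = 1_000,
                 n_reps: int = config.N_DOWNSAMPLE_REPS,
                 rng: np.random.Generator | None = None) -> dict:
    """Consistency of X-chromosome ancestry estimates under down-sampling.

    For individuals with more than ``min_x_snps`` called X SNPs, builds the
    empirical distribution of q_X estimated on ``down_to`` SNPs and reports
    the squared Pearson correlation between mean down-sampled and full-data
    estimates across individuals.
    """
    rng = rng if rng is not None else np.random.default_rng()
    is_x = matrix.panel["is_x"].to_numpy()
    full, down = [], []
    used_samples = []
    for i, s in enumerate(matrix.samples):
        calls = matrix.calls[i]
        x_idx = np.flatnonzero(is_x & (calls != MISSING))
        if len(x_idx) <= min_x_snps:
            continue
        a, b = _observed_allele_probs(calls[x_idx], f_whg[x_idx], f_an[x_idx])
        q_full, _ = _fit_q(a, b)
        take = min(down_to, len(x_idx))
        qs = np.empty(n_reps)
        for rep in range(n_reps):
            sel = rng.choice(len(x_idx), size=take, replace=False)
            qs[rep], _ = _fit_q(a[sel], b[sel])
        used_samples.append(s)
        full.append(q_full)
        down.append(qs.mean())
    if len(full) < 3:
        raise ValueError("fewer than 3 individuals qualify for the robustness check")
    r = pearsonr(down, full).statistic
    return {"samples": used_samples, "q_full": np.array(full),
            "q_downsampled_mean": np.array(down), "r2": float(r * r)}
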