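"""Simulation calibrations of the sex-bias statistics.

These experiments verify, under the generator's study conditions, the two
theoretical anchors of the sex-bias analysis:

* under equal male/female effective sizes, Q = ln(1-2FstA)/ln(1-2FstX)
  should average 3/4, because three X chromosomes circulate for every four
  autosomes;
* under equal male/female admixture contributions, the X-to-autosome
  ancestry ratio R_X/A should average 1 (and 2/3 when all hunter-gatherer
  ancestry enters through males).
"""

from __future__ import annotations

import numpy as np

from . import ancestry, simulate
from .rng import substream
from .simulate import SimConfig


def q_calibration(n_loci: int = 5_000, n_per_sex: int = 500,
                  generations: int = 50, n_sample: int = 100,
                  n_replicates: int = 50,
                  rng: np.random.Generator | None = None) -> dict:
    """Mean Q over replicate Wright–Fisher splits with equal sex sizes.

    Each replicate drifts one population from a common source for
    ``generations`` generations: 2N haploid copies for autosomal loci and
    1.5N for X-linked loci (2 per female, 1 per male).  Fst between a sample
    of the source and of the derived population is computed per compartment
    with the haploid Weir–Cockerham estimator, and Q is averaged over
    replicates.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n_auto_copies = 4 * n_per_sex      # 2 per individual, both sexes
    n_x_copies = 3 * n_per_sex         # 2 per female, 1 per male
    n_called = np.full(n_loci, n_sample)
    qs = np.empty(n_replicates)
    for rep in range(n_replicates):
        src_a, der_a = simulate.wright_fisher_split_samples(
            n_loci, n_auto_copies, generations, n_sample, rng)
        src_x, der_x = simulate.wright_fisher_split_samples(
            n_loci, n_x_copies, generations, n_sample, rng)
        fst_a = ancestry.wc_fst_counts(der_a.sum(0), n_called, src_a.sum(0), n_called)
        fst_x = ancestry.wc_fst_counts(der_x.sum(0), n_called, src_x.sum(0), n_called)
        qs[rep] = ancestry.q_statistic(fst_a, fst_x)
    return {"mean_q": float(qs.mean()), "sd_q": float(qs.std(ddof=1)),
            "replicates": qs, "n_replicates": n_replicates}


def rxa_experiment(c_m: float, c_f: float, seed: int,
                   n_cohorts: int = 8, n_individuals: int = 40,
                   n_snps_autosome: int = 50_000, n_snps_x: int = 5_000,
                   n_reps: int = 1_000, label: str = "rxa") -> dict:
    """Across-individual mean R_X/A, averaged over replicate cohorts.

    Each cohort is an independent draw of the one-pulse admixture model at
    the given male/female contributions; ancestry is estimated with the true
    source frequencies of that cohort's drifted sources.  Averaging over
    cohorts separates estimator bias from the tract-level sampling noise of
    a single 40-individual cohort.
    """
    cohort_means = []
    all_rxa = []
    for k in range(n_cohorts):
        conf = SimConfig(n_snps_autosome=n_snps_autosome, n_snps_x=n_snps_x,
                         n_individuals=n_individuals, c_m=c_m, c_f=c_f)
        rng = substream(seed, f"{label}-cohort{k}")
        cohort = simulate.simulate_cohort(conf, rng=rng)
        matrix, _ = simulate.pseudo_haploid_matrix(cohort, rng)
        f_whg = cohort.sources["f_whg"].to_numpy()
        f_an = cohort.sources["f_an"].to_numpy()
        records = ancestry.rxa_per_individual(matrix, f_whg, f_an,
                                              n_reps=n_reps, rng=rng)
        rxa = [r.rxa for r in records]
        cohort_means.append(float(np.mean(rxa)))
        all_rxa.extend(rxa)
    return {"mean_rxa": float(np.mean(cohort_means)),
            "cohort_means": cohort_means,
            "n_individuals_total": len(all_rxa),
            "per_individual": np.array(all_rxa)}
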