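"""End-to-end orchestration from a single YAML-style configuration.

Stages run in dependency order — simulate (when no input paths are given),
qc, kinship, sexbias, hla, local_ancestry — and write TSV/JSON outputs
under a run directory, together with a log and a report that records the
package version, the master seed, and a hash of the configuration so that
identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ancestry, config as defaults, hla, kinship, local_ancestry, simulate
from .genotype_io import (filter_samples_by_snp_count, maf_filter, read_eigenstrat,
                          read_hla_table, remove_par, write_ancestry_track,
                          write_eigenstrat, write_hla_table, write_metadata)
from .rng import substream

logger = logging.getLogger("paleokin.pipeline")

ALL_STAGES = ("simulate", "qc", "kinship", "sexbias", "hla", "local_ancestry")


@dataclass
class RunConfig:
    """Every threshold of the analysis, defaulted to the published values."""

    # inputs: either an EIGENSTRAT prefix (+ optional HLA table), or simulate
    geno_prefix: str | None = None
    hla_table: str | None = None
    whg_samples: list[str] = field(default_factory=list)
    an_samples: list[str] = field(default_factory=list)

    # simulation conditions (used when geno_prefix is None)
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    n_reference_per_source: int = 25

    # QC
    min_snps_per_sample: int = defaults.MIN_SNPS_PER_SAMPLE
    min_maf: float = defaults.MIN_MAF
    ld_r2: float = defaults.LD_R2_THRESHOLD
    ld_window: int = defaults.LD_WINDOW_SNPS
    ld_step: int = defaults.LD_STEP_SNPS
    apply_ld_prune: bool = False          # expensive; off by default for small runs

    # kinship
    min_overlap_b: int = defaults.MIN_OVERLAP_BASELINE
    min_overlap_call: int = defaults.MIN_OVERLAP_CALL
    n_bootstrap: int = defaults.N_BOOTSTRAP

    # sex bias
    min_x_snps: int = defaults.MIN_X_SNPS
    n_downsample_reps: int = defaults.N_DOWNSAMPLE_REPS

    # HLA
    alpha: float = defaults.ALPHA
    n_hla_resamples: int = defaults.N_HLA_RESAMPLES

    # local ancestry
    mhc_chrom: str = defaults.MHC_CHROM
    mhc_start: int = defaults.MHC_START
    mhc_end: int = defaults.MHC_END
    mhc_flank: int = defaults.MHC_FLANK
    carrier_alleles: list[str] = field(
        default_factory=lambda: ["A*02:01", "DRB1*08:01", "DQB1*04:02"])

    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        conf = cls(**raw)
        if sim_raw:
            conf.sim = simulate.SimConfig(**sim_raw)
        return conf

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def run(conf: RunConfig, out_dir, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the requested stages and return the report dictionary."""
    stages = tuple(stages) if stages is not None else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("paleokin")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report: dict = {
        "version": __version__,
        "seed": conf.seed,
        "config_hash": conf.config_hash(),
        "stages_run": list(stages),
    }
    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in stages:
                continue
            logger.info("stage %s started", stage)
            try:
                _STAGE_FUNCS[stage](conf, out, state, report)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s finished", stage)
        _write_json(report, out / "report.json")
    finally:
        root.removeHandler(handler)
        handler.close()
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(conf: RunConfig, out: Path, state: dict, report: dict) -> None:
    if conf.geno_prefix is not None:
        matrix, meta = read_eigenstrat(f"{conf.geno_prefix}.geno",
                                       f"{conf.geno_prefix}.snp",
                                       f"{conf.geno_prefix}.ind")
        state["matrix"], state["meta"] = matrix, meta
        if conf.hla_table:
            state["hla"] = read_hla_table(conf.hla_table)
        state["whg_samples"] = list(conf.whg_samples)
        state["an_samples"] = list(conf.an_samples)
        report["simulate"] = {"source": "files", "n_samples": matrix.n_samples,
                              "n_snps": matrix.n_snps}
        return
    rng = substream(conf.seed, "simulate")
    cohort = simulate.simulate_cohort(conf.sim, rng=rng)
    # pure-source reference panels for supervised frequency estimation
    n_ref = conf.n_reference_per_source
    ref_whg = simulate.simulate_cohort(
        dataclasses.replace(conf.sim, c_m=1.0, c_f=1.0, n_individuals=n_ref),
        rng=substream(conf.seed, "simulate-ref-whg"),
        panel=cohort.panel, sources=cohort.sources)
    ref_an = simulate.simulate_cohort(
        dataclasses.replace(conf.sim, c_m=0.0, c_f=0.0, n_individuals=n_ref),
        rng=substream(conf.seed, "simulate-ref-an"),
        panel=cohort.panel, sources=cohort.sources)
    matrix, meta = simulate.pseudo_haploid_matrix(cohort, substream(conf.seed, "observe"))
    mw, _ = simulate.pseudo_haploid_matrix(ref_whg, substream(conf.seed, "observe-whg"))
    ma, _ = simulate.pseudo_haploid_matrix(ref_an, substream(conf.seed, "observe-an"))
    hla_table, hla_truth = simulate.simulate_hla(cohort, substream(conf.seed, "hla"))

    sim_dir = out / "simulated"
    sim_dir.mkdir(exist_ok=True)
    write_eigenstrat(matrix, meta, sim_dir / "cohort")
    write_hla_table(hla_table, sim_dir / "hla.tsv")
    write_metadata(meta, sim_dir / "meta.tsv")
    cohort.truth_record().to_csv(sim_dir / "truth.tsv", sep="\t", index=False)
    track = simulate.truth_track(
        cohort, (cohort.panel["chrom"] == conf.mhc_chrom).to_numpy())
    write_ancestry_track(track, sim_dir / "track.tsv")

    state.update(matrix=matrix, meta=meta, cohort=cohort, hla=hla_table,
                 hla_truth=hla_truth, track=track,
                 ref_whg_matrix=mw, ref_an_matrix=ma)
    report["simulate"] = {"source": "synthetic", "n_samples": matrix.n_samples,
                          "n_snps": matrix.n_snps,
                          "alpha_autosome": conf.sim.alpha_autosome,
                          "alpha_x": conf.sim.alpha_x}


def _stage_qc(conf: RunConfig, out: Path, state: dict, report: dict) -> None:
    matrix, meta = state["matrix"], state["meta"]
    n0_samples, n0_snps = matrix.n_samples, matrix.n_snps
    matrix, meta, dropped = filter_samples_by_snp_count(
        matrix, meta, min_snps=min(conf.min_snps_per_sample, matrix.n_snps))
    matrix = maf_filter(matrix, conf.min_maf)
    matrix = remove_par(matrix)
    if conf.apply_ld_prune:
        from .genotype_io import ld_prune
        keep = set(ld_prune(matrix, conf.ld_r2, conf.ld_window, conf.ld_step))
        matrix = matrix.take_snps(matrix.panel["snp_id"].isin(keep).to_numpy())
    state["matrix"], state["meta"] = matrix, meta
    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    attrition = {"samples_in": n0_samples, "samples_out": matrix.n_samples,
                 "samples_dropped": dropped,
                 "snps_in": n0_snps, "snps_out": matrix.n_snps}
    _write_json(attrition, qc_dir / "attrition.json")
    logger.info("qc attrition: %s", attrition)
    report["qc"] = {k: v for k, v in attrition.items() if k != "samples_dropped"}


def _stage_kinship(conf: RunConfig, out: Path, state: dict, report: dict) -> None:
    matrix = state["matrix"]
    rng = substream(conf.seed, "kinship")
    n_snps_auto = int((~matrix.panel["is_x"]).sum())
    min_b = min(conf.min_overlap_b, max(n_snps_auto // 2, 1))
    results = kinship.run_kinship(matrix, n_bootstrap=conf.n_bootstrap,
                                  min_overlap_b=min_b,
                                  min_overlap_call=min(conf.min_overlap_call, n_snps_auto),
                                  rng=rng)
    state["kinship"] = results
    kin_dir = out / "kinship"
    kin_dir.mkdir(exist_ok=True)
    table = kinship.kinship_table(results)
    table.to_csv(kin_dir / "kinship.tsv", sep="\t", index=False, float_format="%.6g")
    degrees = table["degree"].value_counts().to_dict()
    report["kinship"] = {"n_pairs": len(table), "b": float(results[0].b_used),
                         "degrees": degrees}


def _stage_sexbias(conf: RunConfig, out: Path, state: dict, report: dict) -> None:
    matrix = state["matrix"]
    if "ref_whg_matrix" in state:
        ref_w, ref_a = state["ref_whg_matrix"], state["ref_an_matrix"]
        # align reference matrices to the QC'd panel of the cohort
        keep = ref_w.panel["snp_id"].isin(matrix.panel["snp_id"]).to_numpy()
        ref_w, ref_a = ref_w.take_snps(keep), ref_a.take_snps(keep)
        merged_calls = np.vstack([ref_w.calls, ref_a.calls])
        merged = type(matrix)(samples=ref_w.samples + [s + "_an" for s in ref_a.samples],
                              panel=matrix.panel, calls=merged_calls)
        f_whg, f_an = ancestry.source_frequencies(
            merged, ref_w.samples, [s + "_an" for s in ref_a.samples])
    else:
        f_whg, f_an = ancestry.source_frequencies(
            matrix, state["whg_samples"], state["an_samples"])
    rng = substream(conf.seed, "sexbias")
    min_x = min(conf.min_x_snps, int(matrix.panel["is_x"].sum()))
    records = ancestry.rxa_per_individual(matrix, f_whg, f_an,
                                          n_reps=conf.n_downsample_reps,
                                          min_x_snps=min_x, rng=rng)
    tests = ancestry.sexbias_tests(records)
    sex_dir = out / "sexbias"
    sex_dir.mkdir(exist_ok=True)
    pd.DataFrame([{
        "sample_id": r.sample_id, "q_x": r.q_x,
        "q_a_mean": float(r.q_a_reps.mean()), "rxa": r.rxa,
        "rxa_median_rep": float(np.median(r.rxa_replicates)),
    } for r in records]).to_csv(sex_dir / "rxa.tsv", sep="\t", index=False,
                                float_format="%.6g")
    summary = {k: v for k, v in tests.items() if k != "wilcoxon_p_per_replicate"}
    _write_json(summary, sex_dir / "summary.json")
    state["sexbias"] = records
    report["sexbias"] = summary


def _stage_hla(conf: RunConfig, out: Path, state: dict, report: dict) -> None:
    if "hla" not in state:
        report["hla"] = {"skipped": "no HLA table available"}
        return
    table = state["hla"]
    if "kinship" in state:
        table = hla.exclude_first_degree(table, state["kinship"])
    freqs = hla.allele_frequencies(table)
    hla_dir = out / "hla"
    hla_dir.mkdir(exist_ok=True)
    freqs.to_csv(hla_dir / "frequencies.tsv", sep="\t", index=False,
                 float_format="%.6g")
    em = hla.haplotype_em(table, "DRB1", "DQB1")
    pd.DataFrame([{"drb1": a, "dqb1": b, "frequency": f}
                  for (a, b), f in sorted(em.frequencies.items())]
                 ).to_csv(hla_dir / "haplotypes_drb1_dqb1.tsv", sep="\t",
                          index=False, float_format="%.6g")
    report["hla"] = {"n_individuals": int(table["sample_id"].nunique()),
                     "em_converged": em.converged,
                     "em_loglik": em.loglik}
    state["hla_filtered"] = table


def _stage_local_ancestry(conf: RunConfig, out: Path, state: dict, report: dict) -> None:
    if "track" not in state:
        report["local_ancestry"] = {"skipped": "no ancestry track available"}
        return
    track = state["track"]
    region = local_ancestry.RegionSpec(conf.mhc_chrom, conf.mhc_start, conf.mhc_end)
    stats, mu, sigma = local_ancestry.mean_ancestry_and_z(track)
    enrich = local_ancestry.region_enrichment(stats, mu, region, conf.mhc_flank)
    la_dir = out / "local_ancestry"
    la_dir.mkdir(exist_ok=True)
    enrich["table"].to_csv(la_dir / "mhc_track.tsv", sep="\t", index=False,
                           float_format="%.6g")
    result = {k: v for k, v in enrich.items() if k != "table"}
    if "hla" in state:
        carriers = local_ancestry.carrier_comparison(
            track, state["hla"], conf.carrier_alleles, region, conf.alpha)
        carriers.drop(columns=["carrier_values", "noncarrier_values"]).to_csv(
            la_dir / "carrier_tests.tsv", sep="\t", index=False, float_format="%.6g")
        result["carrier_tests"] = {
            row["allele"]: {"p_adjusted": None if pd.isna(row["p_adjusted"])
                            else float(row["p_adjusted"]),
                            "significant": bool(row["significant"])}
            for _, row in carriers.iterrows()}
    _write_json(result, la_dir / "enrichment.json")
    report["local_ancestry"] = {k: v for k, v in result.items()}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "kinship": _stage_kinship,
    "sexbias": _stage_sexbias,
    "hla": _stage_hla,
    "local_ancestry": _stage_local_ancestry,
}

REPORT_REQUIRED_KEYS = ("version", "seed", "config_hash", "stages_run")


def validate_report(report: dict) -> bool:
    """Minimal schema check: required bookkeeping keys plus one entry per stage run."""
    for key in REPORT_REQUIRED_KEYS:
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
    for stage in report["stages_run"]:
        if stage not in report:
            raise ValueError(f"report missing section for stage {stage!r}")
    return True
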