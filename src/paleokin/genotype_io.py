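"""I/O and genotype-level QC for pseudo-haploid cohorts.

The on-disk formats are the text ("eigenstrat") dialect of the EIGENSTRAT
geno/snp/ind trio, a TSV HLA genotype table, a TSV local-ancestry track, and
a TSV sample-metadata table.  Pseudo-haploid data carry exactly one sampled
allele per site per individual, so genotypes are never heterozygous: the geno
digit 1 is an error in ``strict`` mode and remapped to missing in ``lenient``
mode.

Internally calls are an int8 sample x SNP array with REF=0, ALT=1,
MISSING=-1.  On disk REF is written as 2, ALT as 0 and MISSING as 9 (the
digit counts copies of the reference allele for a haploid sample carried as
a homozygous diploid, the convention pseudo-haploid pipelines use).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import config

logger = logging.getLogger(__name__)

REF = 0
ALT = 1
MISSING = -1

_GENO_DIGIT = {"2": REF, "0": ALT, "9": MISSING}
_GENO_CHAR = {REF: "2", ALT: "0", MISSING: "9"}

PANEL_COLUMNS = ["snp_id", "chrom", "genetic_pos", "physical_pos",
                 "ref_allele", "alt_allele", "is_x", "in_par"]

HLA_ALLELE_RE = re.compile(r"^(A|B|C|DPB1|DQB1|DRB1)\*\d{2,3}:\d{2,3}[A-Z]?$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def build_panel(df: pd.DataFrame,
                par1: tuple[int, int] = config.PAR1,
                par2: tuple[int, int] = config.PAR2) -> pd.DataFrame:
    """Validate a SNP panel and add the ``is_x`` / ``in_par`` flags.

    Expects columns snp_id, chrom, genetic_pos (Morgans), physical_pos
    (1-based bp), ref_allele, alt_allele.  Positions must be strictly
    increasing within a chromosome and ref must differ from alt.
    """
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].head().tolist()
        raise FormatError(f"duplicated SNP ids, e.g. {dups}")
    if (df["ref_allele"] == df["alt_allele"]).any():
        raise FormatError("SNP with identical ref and alt allele")
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["physical_pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise FormatError(f"positions not strictly increasing on chrom {chrom}")
    df["is_x"] = df["chrom"] == "X"
    pos = df["physical_pos"].to_numpy()
    in_par = df["is_x"].to_numpy() & (
        ((pos >= par1[0]) & (pos <= par1[1])) | ((pos >= par2[0]) & (pos <= par2[1]))
    )
    df["in_par"] = in_par
    return df[PANEL_COLUMNS].reset_index(drop=True)


@dataclass
class PseudoHaploidMatrix:
    """Sample x SNP pseudo-haploid call matrix plus its SNP panel."""

    samples: list[str]
    panel: pd.DataFrame
    calls: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.panel)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.panel)} SNPs")
        bad = ~np.isin(self.calls, (REF, ALT, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {REF, ALT, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.panel)

    def n_snps_called(self) -> np.ndarray:
        """Non-missing call count per sample."""
        return (self.calls != MISSING).sum(axis=1)

    def take_snps(self, mask_or_index) -> "PseudoHaploidMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return PseudoHaploidMatrix(
            samples=list(self.samples),
            panel=self.panel.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
        )

    def take_samples(self, mask_or_index) -> "PseudoHaploidMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return PseudoHaploidMatrix(
            samples=[self.samples[i] for i in idx],
            panel=self.panel,
            calls=self.calls[idx],
        )

    def autosomes(self) -> "PseudoHaploidMatrix":
        return self.take_snps(~self.panel["is_x"].to_numpy())

    def xchrom(self) -> "PseudoHaploidMatrix":
        return self.take_snps(self.panel["is_x"].to_numpy())

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)


def make_sample_meta(matrix: PseudoHaploidMatrix,
                     group: dict[str, str] | None = None,
                     sex: dict[str, str] | None = None) -> pd.DataFrame:
    """Metadata table with per-sample call counts kept in sync with the matrix."""
    group = group or {}
    sex = sex or {}
    return pd.DataFrame({
        "sample_id": matrix.samples,
        "group": [group.get(s, "NA") for s in matrix.samples],
        "genetic_sex": [sex.get(s, "unknown") for s in matrix.samples],
        "n_snps_called": matrix.n_snps_called(),
    })


# ---------------------------------------------------------------------------
# EIGENSTRAT trio
# ---------------------------------------------------------------------------

def read_eigenstrat(geno_path, snp_path, ind_path,
                    mode: str = "strict") -> tuple[PseudoHaploidMatrix, pd.DataFrame]:
    """Read a text-dialect EIGENSTRAT trio into a pseudo-haploid matrix.

    ``mode='strict'`` rejects the heterozygous digit 1 (pseudo-haploid data
    cannot be heterozygous); ``mode='lenient'`` remaps it to missing.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")

    snp_df = pd.read_csv(
        snp_path, sep=r"\s+", header=None,
        names=["snp_id", "chrom", "genetic_pos", "physical_pos", "ref_allele", "alt_allele"],
        dtype={"snp_id": str, "chrom": str},
    )
    snp_df["chrom"] = snp_df["chrom"].replace({"23": "X"})
    panel = build_panel(snp_df)

    ind_df = pd.read_csv(ind_path, sep=r"\s+", header=None,
                         names=["sample_id", "sex_code", "group"],
                         dtype=str)
    sex_map = {"M": "male", "F": "female", "U": "unknown"}
    samples = ind_df["sample_id"].tolist()

    lut = np.full(128, -2, dtype=np.int8)
    for ch, code in _GENO_DIGIT.items():
        lut[ord(ch)] = code
    lut[ord("1")] = MISSING if mode == "lenient" else -2

    rows = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if len(line) != len(samples):
                raise FormatError(
                    f"{geno_path}:{lineno}: {len(line)} genotypes for {len(samples)} samples")
            codes = lut[np.frombuffer(line.encode("ascii"), dtype=np.uint8)]
            if (codes == -2).any():
                bad = line[int(np.flatnonzero(codes == -2)[0])]
                raise FormatError(f"{geno_path}:{lineno}: invalid genotype digit {bad!r}")
            rows.append(codes)
    if len(rows) != len(panel):
        raise FormatError(
            f"geno has {len(rows)} SNP lines but snp file has {len(panel)}")
    calls = (np.vstack(rows).T if rows
             else np.empty((len(samples), 0), dtype=np.int8))

    matrix = PseudoHaploidMatrix(samples=samples, panel=panel, calls=calls)
    meta = make_sample_meta(
        matrix,
        group=dict(zip(ind_df["sample_id"], ind_df["group"])),
        sex={s: sex_map.get(c, "unknown") for s, c in zip(ind_df["sample_id"], ind_df["sex_code"])},
    )
    return matrix, meta


def write_eigenstrat(matrix: PseudoHaploidMatrix, meta: pd.DataFrame, out_prefix) -> None:
    """Write a geno/snp/ind trio that :func:`read_eigenstrat` inverts exactly."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sex_code = {"male": "M", "female": "F", "unknown": "U"}
    meta_idx = meta.set_index("sample_id") if len(meta) else None

    with open(f"{out_prefix}.geno", "w") as fh:
        for j in range(matrix.n_snps):
            fh.write("".join(_GENO_CHAR[int(c)] for c in matrix.calls[:, j]) + "\n")
    with open(f"{out_prefix}.snp", "w") as fh:
        for row in matrix.panel.itertuples(index=False):
            chrom = "23" if row.chrom == "X" else row.chrom
            fh.write(f"{row.snp_id}\t{chrom}\t{row.genetic_pos:.12g}\t"
                     f"{row.physical_pos}\t{row.ref_allele}\t{row.alt_allele}\n")
    with open(f"{out_prefix}.ind", "w") as fh:
        for s in matrix.samples:
            if meta_idx is not None and s in meta_idx.index:
                rec = meta_idx.loc[s]
                fh.write(f"{s}\t{sex_code.get(rec['genetic_sex'], 'U')}\t{rec['group']}\n")
            else:
                fh.write(f"{s}\tU\tNA\n")


# ---------------------------------------------------------------------------
# HLA genotype table
# ---------------------------------------------------------------------------

def validate_hla_table(table: pd.DataFrame) -> pd.DataFrame:
    required = ["sample_id", "locus", "allele1", "allele2"]
    if list(table.columns[:4]) != required:
        raise FormatError(f"HLA table must have columns {required}")
    dup = table.duplicated(subset=["sample_id", "locus"])
    if dup.any():
        pair = table.loc[dup, ["sample_id", "locus"]].iloc[0].tolist()
        raise FormatError(f"duplicate sample x locus row: {pair}")
    for col in ("allele1", "allele2"):
        for val, locus in zip(table[col], table["locus"]):
            if not HLA_ALLELE_RE.match(str(val)):
                raise FormatError(f"malformed HLA allele {val!r}")
            if not str(val).startswith(f"{locus}*"):
                raise FormatError(f"allele {val!r} does not belong to locus {locus}")
    if not table["locus"].isin(config.HLA_LOCI).all():
        bad = sorted(set(table["locus"]) - set(config.HLA_LOCI))
        raise FormatError(f"unknown HLA locus {bad}")
    return table.reset_index(drop=True)


def read_hla_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_hla_table(table)


def write_hla_table(table: pd.DataFrame, path) -> None:
    validate_hla_table(table)
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Local-ancestry track
# ---------------------------------------------------------------------------

@dataclass
class AncestryTrack:
    """Per-SNP, per-haplotype posterior probability of hunter-gatherer origin."""

    panel: pd.DataFrame          # snp_id, chrom, physical_pos (at least)
    samples: list[str]
    prob_whg: np.ndarray         # float, shape (n_samples, 2, n_snps)

    def __post_init__(self) -> None:
        self.prob_whg = np.asarray(self.prob_whg, dtype=float)
        n = (len(self.samples), 2, len(self.panel))
        if self.prob_whg.shape != n:
            raise ValueError(f"prob_whg shape {self.prob_whg.shape}, expected {n}")
        if (self.prob_whg < 0).any() or (self.prob_whg > 1).any():
            raise ValueError("ancestry probabilities outside [0, 1]")


def read_ancestry_track(path) -> AncestryTrack:
    """Read a TSV with columns snp_id, chrom, pos, then ``sample.hap`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    hap_cols = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
    samples: list[str] = []
    for c in hap_cols:
        s, hap = c.rsplit(".", 1)
        if hap not in ("0", "1"):
            raise FormatError(f"track column {c!r} is not of the form sample.hap")
        if s not in samples:
            samples.append(s)
    prob = np.empty((len(samples), 2, len(df)))
    for i, s in enumerate(samples):
        for h in (0, 1):
            col = f"{s}.{h}"
            if col not in df.columns:
                raise FormatError(f"track missing haplotype column {col!r}")
            prob[i, h] = df[col].to_numpy(dtype=float)
    panel = df[["snp_id", "chrom", "pos"]].rename(columns={"pos": "physical_pos"})
    return AncestryTrack(panel=panel.reset_index(drop=True), samples=samples, prob_whg=prob)


def write_ancestry_track(track: AncestryTrack, path) -> None:
    out = {"snp_id": track.panel["snp_id"],
           "chrom": track.panel["chrom"],
           "pos": track.panel["physical_pos"]}
    for i, s in enumerate(track.samples):
        for h in (0, 1):
            out[f"{s}.{h}"] = track.prob_whg[i, h]
    pd.DataFrame(out).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_samples_by_snp_count(matrix: PseudoHaploidMatrix, meta: pd.DataFrame,
                                min_snps: int = config.MIN_SNPS_PER_SAMPLE,
                                ) -> tuple[PseudoHaploidMatrix, pd.DataFrame, list[str]]:
    """Drop samples with fewer than ``min_snps`` non-missing calls.

    Returns the filtered matrix and metadata plus the list of dropped ids.
    """
    if min_snps < 0:
        raise ValueError("min_snps must be >= 0")
    counts = matrix.n_snps_called()
    keep = counts >= min_snps
    dropped = [s for s, k in zip(matrix.samples, keep) if not k]
    if not keep.any():
        warnings.warn("all samples fall below the SNP-count threshold")
    out = matrix.take_samples(keep)
    meta = meta[meta["sample_id"].isin(out.samples)].reset_index(drop=True)
    return out, meta, dropped


def alt_frequencies(matrix: PseudoHaploidMatrix) -> np.ndarray:
    """Per-SNP ALT frequency among non-missing calls (NaN where all missing)."""
    called = matrix.calls != MISSING
    n_called = called.sum(axis=0)
    n_alt = (matrix.calls == ALT).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan)


def maf_filter(matrix: PseudoHaploidMatrix, min_maf: float = config.MIN_MAF
               ) -> PseudoHaploidMatrix:
    """Keep SNPs whose minor-allele frequency among called samples is >= min_maf.

    SNPs with all calls missing have no defined frequency and are dropped with
    a warning.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    freq = alt_frequencies(matrix)
    all_missing = np.isnan(freq)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} SNPs with no calls")
    maf = np.minimum(freq, 1.0 - freq)
    keep = ~all_missing & (maf >= min_maf)
    return matrix.take_snps(keep)


def remove_par(matrix: PseudoHaploidMatrix) -> PseudoHaploidMatrix:
    """Remove X-chromosome SNPs inside the configured pseudo-autosomal regions."""
    return matrix.take_snps(~matrix.panel["in_par"].to_numpy())


def _windowed_r2(X: np.ndarray) -> np.ndarray:
    """Pairwise r^2 between columns of a 0/1 matrix with NaN for missing.

    Each pair uses only the samples non-missing at both SNPs; pairs with
    fewer than 20 joint observations return NaN (treated as uncorrelated).
    """
    V = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X)
    C = V.T @ V               # joint non-missing counts
    Sx = X0.T @ V             # Sx[i, j] = sum of x_i over samples valid at both
    Sxy = X0.T @ X0
    Sxx = (X0 * X0).T @ V     # sum of x_i^2 over jointly valid samples
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = C * Sxy - Sx * Sx.T
        var_i = C * Sxx - Sx * Sx
        r2 = (cov * cov) / (var_i * var_i.T)
    r2[C < 20] = np.nan
    return r2


def ld_prune(matrix: PseudoHaploidMatrix,
             r2_threshold: float = config.LD_R2_THRESHOLD,
             window_snps: int = config.LD_WINDOW_SNPS,
             step_snps: int = config.LD_STEP_SNPS) -> list[str]:
    """Greedy windowed LD pruning; returns the retained SNP ids.

    Within each window SNP pairs are scanned left to right; when a pair
    exceeds the r^2 threshold the SNP with the lower call rate is dropped
    (ties drop the right-hand SNP).  r^2 is the squared Pearson correlation
    of haploid 0/1 calls over jointly non-missing samples.  Deterministic
    and independent of sample order.
    """
    if window_snps < step_snps:
        raise ValueError("window must be at least as large as the step")
    panel = matrix.panel
    calls = matrix.calls.astype(float)
    calls[matrix.calls == MISSING] = np.nan
    call_rate = (matrix.calls != MISSING).mean(axis=0)

    removed = np.zeros(matrix.n_snps, dtype=bool)
    for chrom, sub in panel.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        for start in range(0, len(idx), step_snps):
            win = idx[start:start + window_snps]
            alive = win[~removed[win]]
            if len(alive) > 1:
                r2 = _windowed_r2(calls[:, alive])
                local_alive = np.ones(len(alive), dtype=bool)
                for a in range(len(alive)):
                    for b in range(a + 1, len(alive)):
                        if not (local_alive[a] and local_alive[b]):
                            continue
                        v = r2[a, b]
                        if np.isnan(v) or v < r2_threshold:
                            continue
                        ca, cb = call_rate[alive[a]], call_rate[alive[b]]
                        drop_local = b if cb <= ca else a
                        local_alive[drop_local] = False
                        removed[alive[drop_local]] = True
            if start + window_snps >= len(idx):
                break
    return panel.loc[~removed, "snp_id"].tolist()
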