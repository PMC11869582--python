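"""Shared constants and default thresholds.

All genome coordinates are 1-based inclusive and refer to the hg19 assembly.
Every threshold used by the analysis stages is named here so that deviations
from the defaults are explicit in configuration rather than buried in code.
"""

from __future__ import annotations

# Pseudo-autosomal regions of the X chromosome (hg19).  SNPs inside these
# intervals behave autosomally and are removed before any X-specific analysis.
PAR1 = (60_001, 2_699_520)
PAR2 = (154_931_044, 155_260_560)

# Extended MHC region on chromosome 6 (hg19) used for local-ancestry
# enrichment and the carrier/non-carrier tests.
MHC_CHROM = "6"
MHC_START = 28_477_797
MHC_END = 33_448_354
MHC_FLANK = 5_000_000

# Genotype-level QC defaults.
MIN_SNPS_PER_SAMPLE = 20_000
MIN_MAF = 0.01
LD_R2_THRESHOLD = 0.4
LD_WINDOW_SNPS = 200
LD_STEP_SNPS = 25

# Kinship defaults.
MIN_OVERLAP_BASELINE = 100_000   # pairs entering the unrelated-baseline median
MIN_OVERLAP_CALL = 2_500         # pairs below this are never assigned a degree
N_BOOTSTRAP = 1_000
# Published unrelated-pair baseline mismatch rate for central-European
# Neolithic pseudo-haploid data; usable when a cohort is too small to
# self-estimate b.
PUBLISHED_BASELINE_B = 0.2593

# Sex-bias defaults.
MIN_X_SNPS = 1_000               # individuals below this never enter R_X/A
MIN_X_SNPS_ROBUSTNESS = 4_000
N_DOWNSAMPLE_REPS = 1_000

# HLA defaults.
HLA_LOCI = ("A", "B", "C", "DPB1", "DQB1", "DRB1")
ALPHA = 0.05
MIN_FREQ_DIFF = 0.1              # absolute frequency difference for "significant"
N_HLA_RESAMPLES = 100

# Source-frequency estimation.
FREQ_PSEUDOCOUNT = 0.5
FREQ_CLIP = (0.001, 0.999)
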