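"""Shared locations and study conditions for the analysis scripts.

The simulated study: 5,000 genes across four developmental stages with two
waves of bivalency establishment (gain of both marks at S3, H3K4me3 gain on
pre-existing H3K27me3 at S4), stage depth skews of 0.5-2x, and a unified
threshold calibrated at S4.  top_n is scaled to this universe: the real
procedure anchors on the top 3,000 of ~20,000 promoters, i.e. the
constitutively marked fraction; 600 of 5,000 keeps the anchor inside the
marked population at every stage.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"   # bulky intermediates, not tracked
RESULTS = ROOT / "results"                # small tables and reports

SIM_DIR = SCRATCH / "simulated"
MATRIX_DIR = SCRATCH / "matrices"

SEED = 1
N_GENES = 5000
TOP_N = 600
STAGES = ("S1", "S2", "S3", "S4")
CALIBRATION_STAGE = "S4"
MARKS = ("H3K27me3", "H3K4me3")


def track_path(stage: str, mark: str) -> Path:
    return SIM_DIR / f"{stage}_{mark}.bedgraph"


def peaks_path(stage: str) -> Path:
    return SIM_DIR / f"{stage}_H3K4me3_peaks.bed"


def matrix_path(mark: str, kind: str) -> Path:
    return MATRIX_DIR / f"{mark}.{kind}.tsv"
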