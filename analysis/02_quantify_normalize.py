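#!/usr/bin/env python
"""Quantify promoter signal per stage and make stages comparable.

Reads the simulated bedGraph tracks back through the standard readers,
computes per-gene promoter averages for both marks (normalization window
-1,000/+500 bp, calling window +/-1 kb, max over TSSs), derives saturation
scale factors per mark and applies them.  Scale-factor audit tables go to
results/; raw and normalized matrices to scratch/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import (
    CALIBRATION_STAGE,
    MARKS,
    MATRIX_DIR,
    RESULTS,
    SIM_DIR,
    STAGES,
    TOP_N,
    matrix_path,
    track_path,
)

from bivalink import (
    CALLING_WINDOW,
    NORMALIZATION_WINDOW,
    build_matrix,
    compute_scale_factors,
    normalize,
    read_bedgraph,
    read_tss_annotation,
)


def main() -> None:
    annotation = read_tss_annotation(SIM_DIR / "annotation.tsv")
    print(f"{annotation.n_genes} genes, {len(annotation)} TSS records")
    MATRIX_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    for mark in MARKS:
        tracks = [
            (stage, read_bedgraph(track_path(stage, mark), bin_size=100, mark=mark, stage=stage))
            for stage in STAGES
        ]
        norm_win = build_matrix(tracks, annotation, NORMALIZATION_WINDOW, mark=mark)
        raw = build_matrix(tracks, annotation, CALLING_WINDOW, mark=mark)
        factors = compute_scale_factors(norm_win, CALIBRATION_STAGE, top_n=TOP_N)
        normalized = normalize(raw, factors)

        raw.to_tsv(matrix_path(mark, "raw"))
        normalized.to_tsv(matrix_path(mark, "normalized"))
        factors.to_tsv(RESULTS / f"scale_factors_{mark}.tsv")
        pretty = {s: round(f, 3) for s, f in factors.factors.items()}
        print(f"{mark}: saturated values anchored on {CALIBRATION_STAGE}; factors {pretty}")
    print(f"matrices in {MATRIX_DIR}, factor tables in {RESULTS}")


if __name__ == "__main__":
    main()
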