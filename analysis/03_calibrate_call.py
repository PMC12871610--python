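#!/usr/bin/env python
"""Calibrate the unified bivalency threshold and call bivalent genes per stage.

The reference count comes from the data: regions +/-2 kb around S4 H3K4me3
peak centers whose mean raw H3K27me3 is >= 3 FPKM.  Theta is then matched so
the same number of genes passes min(normK27, normK4) >= theta at S4, and the
same theta is applied to every stage.  Threshold report and count timeline
go to results/; the full call table to scratch/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import (
    CALIBRATION_STAGE,
    RESULTS,
    SCRATCH,
    STAGES,
    matrix_path,
    peaks_path,
    track_path,
)

from bivalink import (
    PromoterSignalMatrix,
    calibrate_threshold,
    call_bivalent,
    count_timeline,
    read_bedgraph,
    read_peaks_bed,
    reference_regions,
    write_call_table,
)


def main() -> None:
    m27 = PromoterSignalMatrix.from_tsv(matrix_path("H3K27me3", "normalized"))
    m4 = PromoterSignalMatrix.from_tsv(matrix_path("H3K4me3", "normalized"))

    peaks = read_peaks_bed(peaks_path(CALIBRATION_STAGE))
    raw_k27 = read_bedgraph(
        track_path(CALIBRATION_STAGE, "H3K27me3"), bin_size=100,
        mark="H3K27me3", stage=CALIBRATION_STAGE,
    )
    refs = reference_regions(peaks, raw_k27, half_width=2000, min_mean=3.0)
    print(
        f"{len(refs)} candidate regions around {CALIBRATION_STAGE} H3K4me3 peak centers, "
        f"{refs.n_ref} with mean raw H3K27me3 >= 3 FPKM"
    )

    threshold = calibrate_threshold(
        m27.column(CALIBRATION_STAGE), m4.column(CALIBRATION_STAGE),
        target=refs.n_ref, calibration_stage=CALIBRATION_STAGE,
    )
    print(
        f"theta = {threshold.theta:.4f} calls {threshold.achieved_count} genes at "
        f"{CALIBRATION_STAGE} (target {threshold.target_count})"
    )

    calls = [
        call_bivalent(m27.column(s), m4.column(s), threshold, stage=s) for s in STAGES
    ]
    timeline = count_timeline(calls)
    print(timeline.to_string(index=False))

    RESULTS.mkdir(parents=True, exist_ok=True)
    with open(RESULTS / "threshold.json", "w") as fh:
        json.dump(threshold.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    timeline.to_csv(RESULTS / "bivalent_counts.tsv", sep="\t", index=False,
                    float_format="%.10g")
    SCRATCH.mkdir(parents=True, exist_ok=True)
    write_call_table(calls, SCRATCH / "bivalent_calls.tsv")
    print(f"threshold and counts in {RESULTS}, call table in {SCRATCH}")


if __name__ == "__main__":
    main()
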