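# bivalink

Bivalent-chromatin analysis across developmental stages: which promoters
carry both repressive H3K27me3 and active H3K4me3, when bivalency is
established, and how it changes between stages.

The package is aimed at epigenomics analysts working with per-stage binned
coverage tracks (bedGraph, FPKM, fixed bin size) of the two marks, H3K4me3
peak intervals (BED) and a TSS annotation. It implements, as a tested
library plus drivers:

* **Promoter quantification** — per-gene signal as the length-weighted mean
  of coverage over a strand-aware window around the TSS, maximum over
  alternative TSSs.
* **Saturation normalization** — per stage s, the median FPKM of the top
  *n* promoters is its saturated value S_s; stage s is scaled by
  f_s = S_ref / S_s so stages become comparable.
* **Count-matched threshold calibration** — regions ±2 kb around H3K4me3
  peak centers with mean raw H3K27me3 ≥ 3 FPKM define a reference count
  N_ref; the unified threshold θ on b_g = min(normK27_g, normK4_g) is
  chosen so exactly N_ref genes pass at the calibration stage, and a gene
  is bivalent at any stage iff normK27 ≥ θ and normK4 ≥ θ.
* **Transition classification** — A-specific / shared / B-specific
  partitions of bivalent sets between stages, count timelines with fold
  changes, descriptive expression summaries of the groups, and
  intersections with external gene lists.
* **Synthetic data with planted truth** — a first-class generator of
  multi-stage annotation/tracks/peaks/expression whose class labels are
  known, including a four-stage "two waves" scenario (gain of both marks,
  then H3K4me3 gain on pre-existing H3K27me3) against which the whole
  pipeline is validated.

See `docs/methods.md` for the model, conventions and design choices.

## Worked example

```python
from bivalink import (
    PipelineParams, generate_dataset, run_bivalency_analysis, scenario_two_waves,
)

dataset = generate_dataset(scenario_two_waves(n_genes=5000, seed=1))
params = PipelineParams(calibration_stage="S4", top_n=600)
result = run_bivalency_analysis(
    dataset.annotation, dataset.tracks, dataset.peaks, params
)
print("theta =", round(result.threshold.theta, 4),
      "from", result.threshold.target_count, "reference regions")
print("bivalent counts:", result.counts())
part = result.partitions[-1]
print("S3->S4:", part.counts, "shared fraction of S4 =",
      round(part.fractions["shared_of_S4"], 3))
```

prints

```
theta = 9.6732 from 1750 reference regions
bivalent counts: {'S1': 250, 'S2': 250, 'S3': 1000, 'S4': 1750}
S3->S4: {'S3_specific': 0, 'shared': 1000, 'S4_specific': 750} shared fraction of S4 = 0.571
```

Reading: 1,750 peak-flanking regions at S4 carry strong raw H3K27me3, so θ
is set where exactly 1,750 genes pass both normalized marks (θ ≈ 9.67
normalized FPKM). Applying that θ everywhere recovers the planted history —
250 constitutively bivalent genes at S1/S2, a 4-fold jump to 1,000 at S3
(wave 1), 1,750 at S4 (wave 2) — and the S3→S4 partition shows all 1,000
S3-bivalent genes retained plus 750 newly bivalent K4-gain genes.

The same run is available stepwise from a shell:

```sh
bivalink simulate --n-genes 5000 --seed 1 --out sim/
bivalink run --config run.yaml      # paths + parameters in one YAML
```

and as a narrated analysis in `analysis/01_simulate.py` …
`analysis/04_transitions.py` (small tables land in `results/`, bulky
intermediates in `scratch/`). On real data, point the YAML at your
bedGraph/BED/TSV files; all published constants (windows −1,000/+500 and
±1 kb, top 3,000 promoters, ±2 kb regions, ≥ 3 FPKM) are the defaults.

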