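import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bivalink import (
    BinnedSignalTrack,
    PipelineParams,
    TssAnnotation,
    generate_dataset,
    run_bivalency_analysis,
    scenario_two_waves,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: problem size and parameters used for pipeline-level checks; top_n is scaled
#: to the synthetic universe so the top promoters are marked at every stage
SCENARIO_N_GENES = 5000
SCENARIO_TOP_N = 600
SCENARIO_SEED = 1


def make_annotation(rows):
    return TssAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))


def make_track(arrays: dict, bin_size=100, mark="", stage=""):
    return BinnedSignalTrack(
        bin_size=bin_size,
        data={c: np.asarray(a, dtype=float) for c, a in arrays.items()},
        mark=mark,
        stage=stage,
    )


@pytest.fixture(scope="session")
def two_wave_dataset():
    """The four-stage two-wave scenario at full study size."""
    return generate_dataset(scenario_two_waves(n_genes=SCENARIO_N_GENES, seed=SCENARIO_SEED))


@pytest.fixture(scope="session")
def two_wave_result(two_wave_dataset):
    """Full pipeline run on the two-wave scenario."""
    params = PipelineParams(calibration_stage="S4", top_n=SCENARIO_TOP_N)
    return run_bivalency_analysis(
        two_wave_dataset.annotation, two_wave_dataset.tracks, two_wave_dataset.peaks, params
    )
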