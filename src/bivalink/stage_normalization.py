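"""Cross-stage saturation normalization of promoter signal.

Coverage units (FPKM) are not comparable across stages when global signal or
effective depth differs.  The scheme anchors each stage on its "saturated
signal value" S_s - the median promoter FPKM of the top ``top_n`` promoters,
which are assumed to be fully marked at every stage - and rescales stages so
the anchors agree.

Two conventions are exposed.  ``equalize`` (default) uses f_s = S_ref / S_s
and multiplies stage s by f_s, which maps every stage's saturated value onto
the reference stage's and thereby removes global depth differences.
``literal`` uses f_s = S_s / S_ref, the inverse reading, kept for
comparability studies: it amplifies rather than removes depth differences
and is not suitable for cross-stage thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateNormalizationError
from .promoter_signal import PromoterSignalMatrix

CONVENTIONS = ("equalize", "literal")


@dataclass(frozen=True)
class SaturationFactors:
    """Per-stage saturated values S_s and scale factors f_s.

    Invariant: ``factors[reference_stage] == 1.0`` exactly.
    """

    saturated: dict[str, float]
    factors: dict[str, float]
    reference_stage: str
    top_n: int
    convention: str = "equalize"

    def __post_init__(self):
        if self.factors.get(self.reference_stage) != 1.0:
            raise ConfigError("reference stage scale factor must be exactly 1")

    def to_frame(self) -> pd.DataFrame:
        stages = list(self.saturated)
        return pd.DataFrame(
            {
                "stage": stages,
                "saturated_value": [self.saturated[s] for s in stages],
                "scale_factor": [self.factors[s] for s in stages],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def saturated_value(column: Sequence[float] | pd.Series, top_n: int = 3000) -> float:
    """Median of the ``top_n`` largest promoter values of one stage.

    When fewer than ``top_n`` promoters exist, the median of all of them is
    used.  A zero result (e.g. an all-zero column) is degenerate: the stage
    carries no signal to anchor on.
    """
    col = np.asarray(column, dtype=float)
    if col.size == 0:
        raise DegenerateNormalizationError("cannot compute saturated value of an empty column")
    k = min(int(top_n), col.size)
    if k <= 0:
        raise ConfigError(f"top_n must be positive, got {top_n}")
    top = np.sort(col)[::-1][:k]
    s = float(np.median(top))
    if s <= 0.0:
        raise DegenerateNormalizationError(
            f"saturated value is {s}; stage has no usable promoter signal"
        )
    return s


def compute_scale_factors(
    matrix: PromoterSignalMatrix,
    reference_stage: str,
    top_n: int = 3000,
    convention: str = "equalize",
) -> SaturationFactors:
    """Saturated values and scale factors for every stage of ``matrix``."""
    if convention not in CONVENTIONS:
        raise ConfigError(f"unknown normalization convention '{convention}'")
    if reference_stage not in matrix.stages:
        raise ConfigError(f"reference stage '{reference_stage}' not in matrix stages {matrix.stages}")
    saturated = {s: saturated_value(matrix.values[s], top_n) for s in matrix.stages}
    s_ref = saturated[reference_stage]
    if convention == "equalize":
        factors = {s: s_ref / saturated[s] for s in matrix.stages}
    else:
        factors = {s: saturated[s] / s_ref for s in matrix.stages}
    factors[reference_stage] = 1.0
    return SaturationFactors(
        saturated=saturated,
        factors=factors,
        reference_stage=reference_stage,
        top_n=top_n,
        convention=convention,
    )


def normalize(matrix: PromoterSignalMatrix, factors: SaturationFactors) -> PromoterSignalMatrix:
    """Multiply each stage column by its scale factor; marks the matrix normalized."""
    missing = [s for s in matrix.stages if s not in factors.factors]
    if missing:
        raise ConfigError(f"no scale factor for stages: {missing}")
    values = matrix.values.copy()
    for s in matrix.stages:
        values[s] = values[s] * factors.factors[s]
    return PromoterSignalMatrix(
        mark=matrix.mark, window=matrix.window, values=values, normalized=True
    )
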