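"""Bivalent-gene calling with a count-matched unified threshold.

The threshold theta is not chosen by eye: a peak-derived reference count
pins it down.  Regions of +/- ``half_width`` around H3K4me3 peak centers
whose mean raw H3K27me3 coverage is at least ``min_mean`` FPKM are "strong
H3K27me3 domains overlapping H3K4me3 peaks"; their count N_ref is the
number of bivalent regions the signal itself supports.  Theta is then the
cutoff on b_g = min(normK27_g, normK4_g) that calls exactly (or as close as
attainable) N_ref genes at the calibration stage, and the same theta is
applied to every stage: a gene is bivalent iff both normalized marks are
>= theta (inclusive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, UniverseMismatchError
from .formats_io import BinnedSignalTrack, PeakSet
from .promoter_signal import window_mean

logger = logging.getLogger(__name__)


@dataclass
class ReferenceRegionSet:
    """Peak-flanking regions scored by mean raw H3K27me3, with keep flags.

    One region per H3K4me3 peak: ``[center - half_width, center + half_width)``
    with ``center = floor((start + end) / 2)``.  Regions are neither merged
    nor deduplicated; N_ref counts regions passing the (inclusive)
    ``min_mean`` filter.
    """

    regions: pd.DataFrame  # chrom, start, end, mean_k27, kept
    half_width: int = 2000
    min_mean: float = 3.0

    @property
    def n_ref(self) -> int:
        if len(self.regions) == 0:
            return 0
        return int(self.regions["kept"].sum())

    def __len__(self) -> int:
        return len(self.regions)


def reference_regions(
    k4_peaks: PeakSet,
    k27_track: BinnedSignalTrack,
    half_width: int = 2000,
    min_mean: float = 3.0,
) -> ReferenceRegionSet:
    """Score +/- half_width regions around K4 peak centers by mean raw K27.

    ``k27_track`` must be the un-normalized (raw FPKM) track of the
    calibration stage.  Returns every region with its mean and keep flag.
    """
    if len(k4_peaks) == 0:
        logger.warning("empty H3K4me3 peak set: reference region count is 0, calibration will fail")
        empty = pd.DataFrame(columns=["chrom", "start", "end", "mean_k27", "kept"])
        return ReferenceRegionSet(empty, half_width=half_width, min_mean=min_mean)
    centers = k4_peaks.centers()
    rows = []
    for rec in centers.itertuples(index=False):
        start = rec.center - half_width
        end = rec.center + half_width
        mean = window_mean(k27_track, rec.chrom, start, end)
        mean = 0.0 if mean is None else mean
        rows.append((rec.chrom, start, end, mean, mean >= min_mean))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_k27", "kept"])
    return ReferenceRegionSet(df, half_width=half_width, min_mean=min_mean)


@dataclass(frozen=True)
class BivalencyThreshold:
    """Calibrated unified cutoff theta on b_g = min(normK27, normK4)."""

    theta: float
    target_count: int
    achieved_count: int
    calibration_stage: str = ""
    source: str = ""

    def as_dict(self) -> dict:
        return {
            "theta": self.theta,
            "target_count": self.target_count,
            "achieved_count": self.achieved_count,
            "calibration_stage": self.calibration_stage,
            "source": self.source,
        }


def _aligned(norm_k27: pd.Series | np.ndarray, norm_k4: pd.Series | np.ndarray):
    """Return (index_or_None, k27 array, k4 array) with universe check."""
    if isinstance(norm_k27, pd.Series) and isinstance(norm_k4, pd.Series):
        if set(norm_k27.index) != set(norm_k4.index):
            extra = sorted(set(norm_k27.index) ^ set(norm_k4.index))
            raise UniverseMismatchError(
                f"mark vectors cover different genes (first offenders: {extra[:10]})"
            )
        norm_k4 = norm_k4.reindex(norm_k27.index)
        return norm_k27.index, norm_k27.to_numpy(float), norm_k4.to_numpy(float)
    a27 = np.asarray(norm_k27, dtype=float)
    a4 = np.asarray(norm_k4, dtype=float)
    if a27.shape != a4.shape:
        raise UniverseMismatchError("mark vectors have different lengths")
    return None, a27, a4


def calibrate_threshold(
    norm_k27: pd.Series | np.ndarray,
    norm_k4: pd.Series | np.ndarray,
    target: int,
    calibration_stage: str = "",
    source: str = "",
) -> BivalencyThreshold:
    """Find theta so that |{g : min(k27_g, k4_g) >= theta}| matches ``target``.

    The count is a non-increasing step function of theta whose attainable
    values occur at the distinct b_g.  When the target is attainable, theta
    is the target-th largest b_g.  Otherwise the candidate minimizing
    |count - target| is returned, ties broken toward the larger count
    (i.e. the smaller theta).  ``target == 0`` places theta just above
    max(b_g).
    """
    _, a27, a4 = _aligned(norm_k27, norm_k4)
    b = np.minimum(a27, a4)
    n = b.size
    if target < 0:
        raise CalibrationError(f"target count must be >= 0, got {target}")
    if target > n:
        raise CalibrationError(f"target count {target} exceeds gene universe size {n}")
    if n == 0:
        raise CalibrationError("cannot calibrate on an empty gene universe")
    b_asc = np.sort(b)
    if target == 0:
        theta = math.nextafter(float(b_asc[-1]), math.inf)
        achieved = 0
    else:
        cand = float(b_asc[n - target])  # target-th largest
        achieved = int(n - np.searchsorted(b_asc, cand, side="left"))
        if achieved != target:
            # ties make the exact target unattainable: sweep all candidates
            distinct = np.unique(b_asc)  # ascending
            counts = n - np.searchsorted(b_asc, distinct, side="left")
            diffs = np.abs(counts - target)
            # ascending candidates have non-increasing counts, so the first
            # minimizer is the one with the larger count (smaller theta)
            i = int(np.argmin(diffs))
            theta, achieved = float(distinct[i]), int(counts[i])
        else:
            theta = cand
    return BivalencyThreshold(
        theta=theta,
        target_count=int(target),
        achieved_count=int(achieved),
        calibration_stage=calibration_stage,
        source=source,
    )


@dataclass
class StageCallSet:
    """Per-stage bivalency calls with each gene's limiting signal b_g."""

    stage: str
    table: pd.DataFrame  # index gene_id; columns norm_k27, norm_k4, b, is_bivalent
    theta: float

    @property
    def bivalent_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["is_bivalent"]])

    @property
    def n_bivalent(self) -> int:
        return int(self.table["is_bivalent"].sum())

    @property
    def gene_universe(self) -> frozenset[str]:
        return frozenset(self.table.index)

    def to_frame(self) -> pd.DataFrame:
        """Rows for the tabular call report (see formats_io.write_call_table)."""
        out = pd.DataFrame(
            {
                "gene_id": self.table.index,
                "stage": self.stage,
                "normK27": self.table["norm_k27"].to_numpy(),
                "normK4": self.table["norm_k4"].to_numpy(),
                "b_g": self.table["b"].to_numpy(),
                "is_bivalent": self.table["is_bivalent"].to_numpy(),
            }
        )
        return out


def call_bivalent(
    norm_k27: pd.Series | np.ndarray,
    norm_k4: pd.Series | np.ndarray,
    theta: float | BivalencyThreshold,
    stage: str = "",
) -> StageCallSet:
    """Call genes with both normalized marks >= theta (inclusive boundary)."""
    if isinstance(theta, BivalencyThreshold):
        theta = theta.theta
    if not math.isfinite(theta):
        raise CalibrationError(f"theta must be finite, got {theta}")
    index, a27, a4 = _aligned(norm_k27, norm_k4)
    b = np.minimum(a27, a4)
    table = pd.DataFrame(
        {"norm_k27": a27, "norm_k4": a4, "b": b, "is_bivalent": b >= theta},
        index=index if index is not None else pd.RangeIndex(a27.size).astype(str),
    )
    table.index.name = "gene_id"
    return StageCallSet(stage=stage, table=table, theta=float(theta))
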