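"""Per-gene promoter signal quantification from binned coverage tracks.

A promoter window is an asymmetric strand-aware interval around a TSS.  The
per-TSS value is the length-weighted mean of track bins over the half-open
window; a gene's value is the maximum over its TSSs (genes frequently have
alternative promoters, and the strongest one carries the mark).

Two windows matter downstream and are kept distinct: the window used to
compute cross-stage scale factors (default -1,000/+500 bp around the TSS)
and the window used for bivalency calling (default +/-1,000 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .formats_io import BinnedSignalTrack, TssAnnotation


@dataclass(frozen=True)
class PromoterWindow:
    """Window of ``upstream`` bp before and ``downstream`` bp after a TSS.

    When ``strand_aware`` (default), "upstream" follows transcription
    direction: for a minus-strand gene the window in genomic coordinates is
    ``[tss - downstream, tss + upstream)``.
    """

    upstream: int
    downstream: int
    strand_aware: bool = True

    def __post_init__(self):
        if self.upstream < 0 or self.downstream < 0:
            raise ConfigError("window extents must be non-negative")
        if self.upstream + self.downstream <= 0:
            raise ConfigError("window must have positive length")

    @property
    def length(self) -> int:
        return self.upstream + self.downstream

    def bounds(self, tss: int, strand: str) -> tuple[int, int]:
        """Genomic half-open [start, end) of the window at this TSS."""
        if self.strand_aware and strand == "-":
            return tss - self.downstream, tss + self.upstream
        return tss - self.upstream, tss + self.downstream


# default windows; see module docstring
NORMALIZATION_WINDOW = PromoterWindow(upstream=1000, downstream=500)
CALLING_WINDOW = PromoterWindow(upstream=1000, downstream=1000)


def window_mean(track: BinnedSignalTrack, chrom: str, start: int, end: int) -> float | None:
    """Length-weighted mean track signal over half-open [start, end).

    Returns 0.0 for chromosomes absent from the track.  The window is
    truncated at coordinate 0 and the mean renormalized by the covered
    length; bins beyond the stored array read as 0 signal but stay in the
    denominator (uncovered = 0 convention).  Returns None when the usable
    window length is zero.
    """
    start0 = max(start, 0)
    if end <= start0:
        return None
    arr = track.data.get(chrom)
    if arr is None:
        return 0.0
    bs = track.bin_size
    i0 = start0 // bs
    i1 = (end - 1) // bs + 1
    n = arr.size
    hi_bin = min(i1, n)
    if hi_bin <= i0:
        return 0.0
    idx = np.arange(i0, hi_bin)
    lo = np.maximum(start0, idx * bs)
    hi = np.minimum(end, (idx + 1) * bs)
    total = float(np.dot(arr[i0:hi_bin], (hi - lo).astype(float)))
    return total / (end - start0)


def promoter_mean_signal(
    track: BinnedSignalTrack,
    annotation: TssAnnotation,
    window: PromoterWindow,
) -> pd.Series:
    """Per-gene promoter signal: mean over the window, max over TSSs.

    Returns a float Series indexed by sorted gene_id.  A TSS on a chromosome
    absent from the track contributes 0; a TSS whose window has zero usable
    length (entirely before coordinate 0) raises ValueError naming the gene.
    """
    values: dict[str, float] = {}
    for rec in annotation.records.itertuples(index=False):
        start, end = window.bounds(rec.tss, rec.strand)
        m = window_mean(track, rec.chrom, start, end)
        if m is None:
            raise ValueError(
                f"gene {rec.gene_id}: promoter window [{start}, {end}) at {rec.chrom}:{rec.tss} "
                "has zero usable length"
            )
        prev = values.get(rec.gene_id)
        if prev is None or m > prev:
            values[rec.gene_id] = m
    out = pd.Series(values, dtype=float).sort_index()
    out.index.name = "gene_id"
    return out


@dataclass
class PromoterSignalMatrix:
    """gene x stage matrix of promoter signal for one mark.

    ``values`` is indexed by gene_id with one float column per stage, in
    pipeline stage order.  ``normalized`` records whether cross-stage scale
    factors have been applied.
    """

    mark: str
    window: PromoterWindow
    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if v.size and ((v < 0).any() or not np.all(np.isfinite(v))):
            raise ValueError(f"promoter matrix for {self.mark} has negative or non-finite entries")

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def column(self, stage: str) -> pd.Series:
        return self.values[stage]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# mark={self.mark} upstream={self.window.upstream} "
                f"downstream={self.window.downstream} strand_aware={self.window.strand_aware} "
                f"normalized={self.normalized}\n"
            )
            self.values.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PromoterSignalMatrix":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ConfigError(f"{path}: missing matrix metadata header")
            meta = dict(tok.split("=", 1) for tok in header[1:].split())
            df = pd.read_csv(fh, sep="\t", index_col="gene_id")
        window = PromoterWindow(
            upstream=int(meta["upstream"]),
            downstream=int(meta["downstream"]),
            strand_aware=meta["strand_aware"] == "True",
        )
        return cls(mark=meta["mark"], window=window, values=df, normalized=meta["normalized"] == "True")


def build_matrix(
    tracks: Mapping[str, BinnedSignalTrack] | Sequence[tuple[str, BinnedSignalTrack]],
    annotation: TssAnnotation,
    window: PromoterWindow,
    mark: str | None = None,
) -> PromoterSignalMatrix:
    """Quantify one mark across stages into a PromoterSignalMatrix.

    ``tracks`` maps stage name to track (insertion order defines column
    order).  All tracks must carry the same mark label when labelled.
    """
    items = list(tracks.items()) if isinstance(tracks, Mapping) else list(tracks)
    stages = [s for s, _ in items]
    if len(set(stages)) != len(stages):
        raise ConfigError(f"duplicate stage names in track set: {stages}")
    marks = {t.mark for _, t in items if t.mark}
    if len(marks) > 1:
        raise ConfigError(f"tracks mix marks: {sorted(marks)}")
    if mark is None:
        mark = marks.pop() if marks else ""
    columns = {stage: promoter_mean_signal(track, annotation, window) for stage, track in items}
    values = pd.DataFrame(columns, columns=stages)
    return PromoterSignalMatrix(mark=mark, window=window, values=values, normalized=False)
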