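"""Readers and writers for the plain-text genomic formats the pipeline touches.

Coordinate conventions are fixed throughout the package: BED and bedGraph
intervals are 0-based half-open, TSS positions are 0-based, and bin ``i`` of a
binned track covers ``[i*bin_size, (i+1)*bin_size)``.  Chromosome names are
compared verbatim; an optional flag on the readers strips/adds no prefixes
unless asked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

_STRANDS = frozenset({"+", "-"})


def _normalize_chrom(chrom: str, chr_prefix: bool | None) -> str:
    if chr_prefix is None:
        return chrom
    has = chrom.startswith("chr")
    if chr_prefix and not has:
        return "chr" + chrom
    if not chr_prefix and has:
        return chrom[3:]
    return chrom


# ---------------------------------------------------------------------------
# TSS annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TssAnnotation:
    """Gene identities with one or more strand-aware TSS positions.

    ``records`` has columns ``gene_id`` (non-empty str), ``chrom`` (str),
    ``tss`` (0-based int, >= 0) and ``strand`` ('+' or '-').  A gene may have
    several TSS records; ``(gene_id, chrom, tss)`` is unique.
    """

    records: pd.DataFrame

    def __post_init__(self):
        df = self.records
        required = ["gene_id", "chrom", "tss", "strand"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"TSS annotation missing columns: {missing}")
        if len(df):
            if (df["gene_id"].astype(str) == "").any():
                raise FormatError("TSS annotation contains empty gene_id")
            if (df["tss"] < 0).any():
                raise ValueError("TSS annotation contains negative coordinates")
            bad = set(df["strand"]) - _STRANDS
            if bad:
                raise FormatError(f"TSS annotation contains invalid strand values: {sorted(bad)}")
            if df.duplicated(subset=["gene_id", "chrom", "tss"]).any():
                raise FormatError("TSS annotation contains duplicate (gene_id, chrom, tss) records")

    @property
    def gene_ids(self) -> list[str]:
        """Sorted unique gene identifiers (the gene universe)."""
        return sorted(self.records["gene_id"].unique())

    @property
    def n_genes(self) -> int:
        return self.records["gene_id"].nunique()

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def read_tss_annotation(path: str | Path, chr_prefix: bool | None = None) -> TssAnnotation:
    """Read a tab/whitespace-separated table of gene_id, chrom, tss, strand.

    A header row is auto-detected (third column not integer-parseable).
    Malformed rows raise :class:`FormatError` naming the row number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and len(fields) >= 3:
                try:
                    int(fields[2])
                except ValueError:
                    continue  # header row
            if len(fields) < 4:
                raise FormatError(
                    f"{path}, row {lineno}: expected 4 columns (gene_id chrom tss strand), got {len(fields)}"
                )
            gene_id, chrom, tss_s, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                tss = int(tss_s)
            except ValueError as exc:
                raise FormatError(f"{path}, row {lineno}: TSS coordinate '{tss_s}' is not an integer") from exc
            if tss < 0:
                raise ValueError(f"{path}, row {lineno}: negative TSS coordinate {tss}")
            if strand not in _STRANDS:
                raise FormatError(f"{path}, row {lineno}: invalid strand '{strand}' (expected + or -)")
            rows.append((gene_id, _normalize_chrom(chrom, chr_prefix), tss, strand))
    if not rows:
        logger.warning("TSS annotation %s is empty", path)
        df = pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand"]).astype(
            {"tss": np.int64}
        )
        return TssAnnotation(df)
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return TssAnnotation(df)


# ---------------------------------------------------------------------------
# Binned signal tracks (bedGraph carrier)
# ---------------------------------------------------------------------------

@dataclass
class BinnedSignalTrack:
    """Fixed-bin FPKM coverage for one histone mark at one stage.

    ``data`` maps chromosome name to a float array of per-bin values; bin i
    covers ``[i*bin_size, (i+1)*bin_size)``.  Bins beyond the stored array
    (and whole chromosomes absent from ``data``) read as 0 signal.
    """

    bin_size: int
    data: dict[str, np.ndarray] = field(default_factory=dict)
    mark: str = ""
    stage: str = ""

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"track {self.mark}/{self.stage} chrom {chrom}: non-finite values")
            if (arr < 0).any():
                raise ValueError(f"track {self.mark}/{self.stage} chrom {chrom}: negative values")
            self.data[chrom] = arr

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def scaled(self, factor: float) -> "BinnedSignalTrack":
        """Return a copy with every bin multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return BinnedSignalTrack(
            bin_size=self.bin_size,
            data={c: a * factor for c, a in self.data.items()},
            mark=self.mark,
            stage=self.stage,
        )

    def total_mass(self) -> float:
        """Sum of value*length over all bins (signal mass)."""
        return float(sum(a.sum() for a in self.data.values())) * self.bin_size


def read_bedgraph(
    path: str | Path,
    bin_size: int,
    mark: str = "",
    stage: str = "",
    chr_prefix: bool | None = None,
) -> BinnedSignalTrack:
    """Rasterize a bedGraph file onto a fixed bin grid.

    Intervals must be non-overlapping per chromosome.  Uncovered bins are 0;
    interval boundaries not aligned to the grid are length-weight averaged
    into the bins they touch, so total signal mass (value*length) is
    conserved.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}, line {lineno}: expected 4 bedGraph columns, got {len(fields)}")
            chrom = _normalize_chrom(fields[0], chr_prefix)
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: unparseable interval/value") from exc
            if start < 0 or start >= end:
                raise FormatError(f"{path}, line {lineno}: invalid interval [{start}, {end})")
            if value < 0:
                raise ValueError(f"{path}, line {lineno}: negative signal value {value}")
            per_chrom.setdefault(chrom, []).append((start, end, value))

    data: dict[str, np.ndarray] = {}
    for chrom, ivals in per_chrom.items():
        ivals.sort(key=lambda t: t[0])
        prev_end = -1
        for start, end, _ in ivals:
            if start < prev_end:
                raise FormatError(f"{path}: overlapping intervals on {chrom} near position {start}")
            prev_end = end
        n_bins = -(-ivals[-1][1] // bin_size)  # ceil
        arr = np.zeros(n_bins, dtype=float)
        for start, end, value in ivals:
            if value == 0.0:
                continue
            i0, i1 = start // bin_size, (end - 1) // bin_size + 1
            if start % bin_size == 0 and end % bin_size == 0:
                arr[i0:i1] += value  # whole-bin fast path
                continue
            for i in range(i0, i1):
                lo = max(start, i * bin_size)
                hi = min(end, (i + 1) * bin_size)
                arr[i] += value * (hi - lo) / bin_size
        data[chrom] = arr
    return BinnedSignalTrack(bin_size=bin_size, data=data, mark=mark, stage=stage)


def write_bedgraph(track: BinnedSignalTrack, path: str | Path) -> None:
    """Write a track as bedGraph, run-length merging equal adjacent bins.

    Zero bins are omitted (uncovered = 0), so reading the file back with the
    same bin size reproduces the track exactly for grid-aligned data.
    """
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in track.chroms():
            arr = track.data[chrom]
            if arr.size == 0:
                continue
            # boundaries of runs of equal value
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0.0:
                    continue
                fh.write(f"{chrom}\t{s * bs}\t{e * bs}\t{v:.17g}\n")


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """0-based half-open peak intervals; overlapping peaks are kept as-is."""

    intervals: pd.DataFrame  # columns chrom, start, end [, name, score, strand]

    def __post_init__(self):
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise FormatError(f"PeakSet missing column {col}")
        if len(df) and (df["start"] >= df["end"]).any():
            raise FormatError("PeakSet contains intervals with start >= end")

    def __len__(self) -> int:
        return len(self.intervals)

    def centers(self) -> pd.DataFrame:
        """Floor midpoints, one row per peak (chrom, center)."""
        out = self.intervals[["chrom"]].copy()
        out["center"] = (self.intervals["start"] + self.intervals["end"]) // 2
        return out

    def to_bed(self, path: str | Path) -> None:
        cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in self.intervals.columns]
        self.intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_peaks_bed(path: str | Path, chr_prefix: bool | None = None) -> PeakSet:
    """Read BED3+ peak intervals verbatim (no merging, strand kept as metadata)."""
    rows = []
    n_fields_seen = 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}, line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: unparseable coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}, line {lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else "."
            score = fields[4] if len(fields) > 4 else "."
            strand = fields[5] if len(fields) > 5 else "."
            n_fields_seen = max(n_fields_seen, min(len(fields), 6))
            rows.append((_normalize_chrom(fields[0], chr_prefix), start, end, name, score, strand))
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.DataFrame(rows, columns=cols)
    if not rows:
        logger.warning("peak file %s is empty", path)
        df = df.astype({"start": np.int64, "end": np.int64})
    return PeakSet(df[cols[:n_fields_seen]] if n_fields_seen >= 3 else df)


# ---------------------------------------------------------------------------
# Expression table and gene lists
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """gene_id x stage FPKM matrix; finite and non-negative."""

    values: pd.DataFrame  # index gene_id, one column per stage

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if v.size and (not np.all(np.isfinite(v)) or (v < 0).any()):
            raise ValueError("expression table contains negative or non-finite values")

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_table(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return ExpressionTable(df)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


# ---------------------------------------------------------------------------
# Call table
# ---------------------------------------------------------------------------

def write_call_table(calls: Iterable, path: str | Path) -> None:
    """Write per-stage bivalency calls as a deterministic TSV.

    ``calls`` is an iterable of StageCallSet-like objects exposing
    ``to_frame()`` with columns gene_id, stage, normK27, normK4, b_g,
    is_bivalent.  Rows are ordered by (stage, gene_id) lexicographically so
    re-running on the same input is byte-identical.
    """
    frames = [c.to_frame() for c in calls]
    if not frames:
        raise ValueError("write_call_table requires at least one stage")
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["stage", "gene_id"], kind="mergesort").reset_index(drop=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_call_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
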