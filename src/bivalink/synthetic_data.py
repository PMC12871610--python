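"""Synthetic multi-stage promoter-mark datasets with planted truth.

Each gene carries one of four chromatin classes per stage - ``bivalent``
(both marks), ``k4_only``, ``k27_only`` or ``silent`` - and per-mark
promoter signal drawn from the class's log-normal.  The generator paints a
signal plateau over the promoter span of every TSS onto fixed-bin tracks,
adds a uniform low background elsewhere, applies a per-stage global depth
multiplier, emits an H3K4me3 peak for every K4-positive gene, and writes an
expression table in which bivalent and silent genes are lowly expressed.

Signal model.  A gene's log-signal deviate z is drawn once per (gene, mark,
TSS): value(gene, stage, mark) = exp(mu[class(gene, stage), mark] + sd * z).
Promoter signal is thus a reproducible gene property - a gene whose class
keeps a mark "on" across stages shows the same underlying FPKM, and stage
dynamics enter only through class changes and depth.  This mirrors the
reproducibility of promoter chromatin levels between adjacent developmental
stages; per-stage independent redraws can be enabled via
``persistent_signal=False``.

Randomness flows from a single generator in a fixed stream order (signal
deviates, secondary-TSS deviates, multi-TSS mask, labels, per-stage
backgrounds, per-stage expression), so identical configs and seeds give
byte-identical outputs, and changing the depth multiplier of a stage
rescales exactly that stage's tracks without touching any draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .formats_io import (
    BinnedSignalTrack,
    ExpressionTable,
    PeakSet,
    TssAnnotation,
    write_bedgraph,
)

MARKS = ("H3K27me3", "H3K4me3")
CLASSES = ("bivalent", "k4_only", "k27_only", "silent")

_LOG_ON = math.log(40.0)    # FPKM of a present promoter mark
_LOG_OFF = math.log(0.25)   # residual level of an absent mark

DEFAULT_CLASS_LOG_MEANS: dict[str, dict[str, float]] = {
    "bivalent": {"H3K27me3": _LOG_ON, "H3K4me3": _LOG_ON},
    "k4_only": {"H3K27me3": _LOG_OFF, "H3K4me3": _LOG_ON},
    "k27_only": {"H3K27me3": _LOG_ON, "H3K4me3": _LOG_OFF},
    "silent": {"H3K27me3": _LOG_OFF, "H3K4me3": _LOG_OFF},
}

# bivalent genes are poised, not expressed; k4_only genes are active
DEFAULT_EXPRESSION_LOG_MEANS: dict[str, float] = {
    "bivalent": math.log(0.5),
    "k4_only": math.log(50.0),
    "k27_only": math.log(0.3),
    "silent": math.log(0.2),
}

DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "bivalent": 0.10,
    "k4_only": 0.20,
    "k27_only": 0.15,
    "silent": 0.55,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``class_fractions`` may be one mapping (applied to every stage) or a
    per-stage mapping; fractions must sum to 1.  ``depth`` is a per-stage
    global multiplier (scalar, or per-mark mapping) applied to the finished
    tracks.  ``label_plan``, when given, fixes every gene's class at every
    stage (shape n_genes x n_stages) and overrides random class draws -
    scenario builders use it to plant stage-to-stage dynamics.
    """

    n_genes: int = 5000
    stages: tuple[str, ...] = ("S1", "S2")
    class_fractions: Mapping = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    class_log_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_CLASS_LOG_MEANS.items()}
    )
    signal_log_sd: float = 0.4
    expression_log_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_LOG_MEANS)
    )
    expression_log_sd: float = 0.6
    depth: Mapping[str, float | Mapping[str, float]] | float = 1.0
    multi_tss_fraction: float = 0.1
    multi_tss_offset: int = 600       # bp between primary and secondary TSS
    secondary_tss_scale: float = 0.5  # secondary promoters are weaker
    bin_size: int = 100
    promoter_span: int = 2000         # painted plateau width, centered on TSS
    peak_width: int = 1000
    peak_min_k4: float = 2.0          # FPKM floor for emitting a K4 peak
    background_level: float = 0.1     # uniform background upper bound (FPKM)
    gene_spacing: int = 6000
    n_chroms: int = 2
    chrom_offset: int = 3000
    persistent_signal: bool = True
    seed: int = 0
    label_plan: np.ndarray | None = None
    trajectory_names: tuple[str, ...] | None = None  # per gene, set by scenarios

    def __post_init__(self):
        self.validate()

    # -- helpers -----------------------------------------------------------
    def fractions_for(self, stage: str) -> dict[str, float]:
        fr = self.class_fractions
        if fr and all(isinstance(v, Mapping) for v in fr.values()):
            fr = fr[stage]
        return {c: float(fr.get(c, 0.0)) for c in CLASSES}

    def depth_for(self, stage: str, mark: str) -> float:
        d = self.depth
        if isinstance(d, Mapping):
            d = d.get(stage, 1.0)
        if isinstance(d, Mapping):
            d = d.get(mark, 1.0)
        return float(d)

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError(f"duplicate stage names: {self.stages}")
        if self.signal_log_sd < 0 or self.expression_log_sd < 0:
            raise ConfigError("log-sd values must be >= 0")
        if not 0.0 <= self.multi_tss_fraction <= 1.0:
            raise ConfigError("multi_tss_fraction must be in [0, 1]")
        if self.bin_size <= 0 or self.promoter_span <= 0 or self.peak_width <= 0:
            raise ConfigError("bin_size, promoter_span and peak_width must be positive")
        if self.background_level < 0:
            raise ConfigError("background_level must be >= 0")
        for stage in self.stages:
            for mark in MARKS:
                if self.depth_for(stage, mark) <= 0:
                    raise ConfigError(f"depth multiplier for {stage}/{mark} must be > 0")
            if self.label_plan is None:
                fr = self.fractions_for(stage)
                total = sum(fr.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"class fractions for stage {stage} sum to {total}, expected 1"
                    )
                if any(v < 0 for v in fr.values()):
                    raise ConfigError(f"negative class fraction for stage {stage}")
        if self.label_plan is not None:
            plan = np.asarray(self.label_plan, dtype=object)
            if plan.shape != (self.n_genes, len(self.stages)):
                raise ConfigError(
                    f"label_plan shape {plan.shape} != (n_genes, n_stages) "
                    f"({self.n_genes}, {len(self.stages)})"
                )
            bad = set(plan.ravel()) - set(CLASSES)
            if bad:
                raise ConfigError(f"label_plan contains unknown classes: {sorted(bad)}")
            self.label_plan = plan


@dataclass(frozen=True)
class PlantedTruth:
    """Per-gene per-stage class labels plus the generating config."""

    labels: pd.DataFrame  # index gene_id, one column per stage (class names)
    config: SimulationConfig

    def genes_of_class(self, stage: str, cls: str) -> frozenset[str]:
        col = self.labels[stage]
        return frozenset(col.index[col == cls])

    def bivalent_genes(self, stage: str) -> frozenset[str]:
        return self.genes_of_class(stage, "bivalent")

    def expected_partition(self, stage_a: str, stage_b: str) -> dict[str, frozenset[str]]:
        a, b = self.bivalent_genes(stage_a), self.bivalent_genes(stage_b)
        return {
            f"{stage_a}_specific": frozenset(a - b),
            "shared": frozenset(a & b),
            f"{stage_b}_specific": frozenset(b - a),
        }

    def to_tsv(self, path: str | Path) -> None:
        self.labels.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class SimulatedDataset:
    """Everything generate_dataset produces, in memory."""

    annotation: TssAnnotation
    tracks: dict[str, dict[str, BinnedSignalTrack]]  # stage -> mark -> track
    peaks: dict[str, PeakSet]                        # stage -> H3K4me3 peaks
    expression: ExpressionTable
    truth: PlantedTruth

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write the dataset in the pipeline's input dialects; returns a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        ann_path = outdir / "annotation.tsv"
        self.annotation.to_tsv(ann_path)
        manifest["annotation"] = str(ann_path)
        for stage, marks in self.tracks.items():
            for mark, track in marks.items():
                p = outdir / f"{stage}_{mark}.bedgraph"
                write_bedgraph(track, p)
                manifest[f"track:{stage}:{mark}"] = str(p)
        for stage, peakset in self.peaks.items():
            p = outdir / f"{stage}_H3K4me3_peaks.bed"
            peakset.to_bed(p)
            manifest[f"peaks:{stage}"] = str(p)
        expr_path = outdir / "expression.tsv"
        self.expression.to_tsv(expr_path)
        manifest["expression"] = str(expr_path)
        truth_path = outdir / "truth.tsv"
        self.truth.to_tsv(truth_path)
        manifest["truth"] = str(truth_path)
        return manifest


def _gene_layout(config: SimulationConfig):
    """Deterministic gene ids, chromosomes, primary TSS positions, strands."""
    n = config.n_genes
    idx = np.arange(n)
    gene_ids = np.array([f"G{i:05d}" for i in idx])
    chrom_idx = idx % config.n_chroms
    chroms = np.array([f"chr{c + 1}" for c in chrom_idx])
    positions = config.chrom_offset + (idx // config.n_chroms) * config.gene_spacing
    strands = np.where(idx % 2 == 0, "+", "-")
    return gene_ids, chroms, positions.astype(np.int64), strands


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate annotation, tracks, peaks, expression and planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    stages = list(config.stages)
    gene_ids, chroms, positions, strands = _gene_layout(config)

    # --- random draws, fixed stream order ---------------------------------
    z_primary = {mark: rng.standard_normal(n) for mark in MARKS}
    z_secondary = {mark: rng.standard_normal(n) for mark in MARKS}
    if not config.persistent_signal:
        z_primary_per_stage = {
            s: {mark: rng.standard_normal(n) for mark in MARKS} for s in stages
        }
        z_secondary_per_stage = {
            s: {mark: rng.standard_normal(n) for mark in MARKS} for s in stages
        }
    multi_mask = rng.random(n) < config.multi_tss_fraction

    if config.label_plan is not None:
        labels = {s: np.asarray(config.label_plan[:, j], dtype=object) for j, s in enumerate(stages)}
    else:
        labels = {}
        for s in stages:
            fr = config.fractions_for(s)
            p = np.array([fr[c] for c in CLASSES], dtype=float)
            p = p / p.sum()
            labels[s] = rng.choice(np.array(CLASSES, dtype=object), size=n, p=p)

    # --- per-TSS signal values --------------------------------------------
    sd = config.signal_log_sd
    mu = {
        c: {m: float(config.class_log_means[c][m]) for m in MARKS} for c in CLASSES
    }

    def signal_values(stage: str, mark: str, secondary: bool) -> np.ndarray:
        mus = np.array([mu[c][mark] for c in labels[stage]], dtype=float)
        if config.persistent_signal:
            z = (z_secondary if secondary else z_primary)[mark]
        else:
            z = (z_secondary_per_stage if secondary else z_primary_per_stage)[stage][mark]
        vals = np.exp(mus + sd * z)
        if secondary:
            vals = vals * config.secondary_tss_scale
        return vals

    # --- chromosome sizes (shared grid across stages) ---------------------
    half_span = config.promoter_span // 2
    bs = config.bin_size
    n_bins: dict[str, int] = {}
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        on_chrom = positions[chroms == chrom]
        if on_chrom.size == 0:
            continue
        end = int(on_chrom.max()) + config.multi_tss_offset + half_span
        n_bins[chrom] = -(-end // bs)  # ceil

    def paint(arr: np.ndarray, pos: int, value: float) -> None:
        i0 = max((pos - half_span) // bs, 0)
        i1 = min(-(-(pos + half_span) // bs), arr.size)
        if i1 > i0:
            np.maximum(arr[i0:i1], value, out=arr[i0:i1])

    tracks: dict[str, dict[str, BinnedSignalTrack]] = {}
    stage_k4_primary: dict[str, np.ndarray] = {}
    for stage in stages:
        tracks[stage] = {}
        for mark in MARKS:
            chrom_arrays = {
                chrom: rng.uniform(0.0, config.background_level, size=nb)
                for chrom, nb in n_bins.items()
            }
            primary = signal_values(stage, mark, secondary=False)
            secondary = signal_values(stage, mark, secondary=True)
            if mark == "H3K4me3":
                stage_k4_primary[stage] = primary
            for i in range(n):
                arr = chrom_arrays[chroms[i]]
                paint(arr, int(positions[i]), primary[i])
                if multi_mask[i]:
                    paint(arr, int(positions[i]) + config.multi_tss_offset, secondary[i])
            d = config.depth_for(stage, mark)
            if d != 1.0:
                for arr in chrom_arrays.values():
                    arr *= d
            tracks[stage][mark] = BinnedSignalTrack(
                bin_size=bs, data=chrom_arrays, mark=mark, stage=stage
            )

    # --- H3K4me3 peaks: one per K4-positive gene, centered on primary TSS --
    half_peak = config.peak_width // 2
    peaks: dict[str, PeakSet] = {}
    for stage in stages:
        sel = stage_k4_primary[stage] >= config.peak_min_k4
        df = pd.DataFrame(
            {
                "chrom": chroms[sel],
                "start": positions[sel] - half_peak,
                "end": positions[sel] + half_peak,
                "name": gene_ids[sel],
            }
        )
        df["start"] = df["start"].clip(lower=0)
        peaks[stage] = PeakSet(df.reset_index(drop=True))

    # --- expression --------------------------------------------------------
    expr_cols = {}
    for stage in stages:
        mus = np.array(
            [float(config.expression_log_means[c]) for c in labels[stage]], dtype=float
        )
        z = rng.standard_normal(n)
        expr_cols[stage] = np.exp(mus + config.expression_log_sd * z)
    expression = ExpressionTable(pd.DataFrame(expr_cols, index=pd.Index(gene_ids, name="gene_id")))

    # --- annotation and truth ----------------------------------------------
    ann_rows = []
    for i in range(n):
        ann_rows.append((gene_ids[i], chroms[i], int(positions[i]), strands[i]))
        if multi_mask[i]:
            ann_rows.append(
                (gene_ids[i], chroms[i], int(positions[i]) + config.multi_tss_offset, strands[i])
            )
    annotation = TssAnnotation(
        pd.DataFrame(ann_rows, columns=["gene_id", "chrom", "tss", "strand"])
    )

    label_df = pd.DataFrame(
        {s: pd.array(labels[s], dtype=object) for s in stages},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    if config.trajectory_names is not None:
        label_df["trajectory"] = list(config.trajectory_names)
    truth = PlantedTruth(labels=label_df, config=config)

    return SimulatedDataset(
        annotation=annotation,
        tracks=tracks,
        peaks=peaks,
        expression=expression,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Two-wave scenario
# ---------------------------------------------------------------------------

#: trajectory name, fraction of genes, class at each of the four stages
TWO_WAVE_TRAJECTORIES: tuple[tuple[str, float, tuple[str, str, str, str]], ...] = (
    ("constitutive_bivalent", 0.05, ("bivalent", "bivalent", "bivalent", "bivalent")),
    ("wave1_gain_both", 0.15, ("silent", "silent", "bivalent", "bivalent")),
    ("wave2_k4_gain", 0.15, ("k27_only", "k27_only", "k27_only", "bivalent")),
    ("constitutive_k4", 0.20, ("k4_only", "k4_only", "k4_only", "k4_only")),
    ("constitutive_k27", 0.15, ("k27_only", "k27_only", "k27_only", "k27_only")),
    ("late_k27", 0.02, ("silent", "silent", "silent", "k27_only")),
    ("always_silent", 0.28, ("silent", "silent", "silent", "silent")),
)

TWO_WAVE_STAGES = ("S1", "S2", "S3", "S4")

#: per-stage global depth multipliers; powers of two so depth scaling is
#: bit-exact, with the calibration stage (S4) left at natural scale
TWO_WAVE_DEPTH = {"S1": 0.5, "S2": 2.0, "S3": 1.0, "S4": 1.0}


def scenario_two_waves(
    n_genes: int = 5000,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    **overrides,
) -> SimulationConfig:
    """Four-stage config with the two waves of bivalency establishment.

    Wave 1: between S2 and S3 a block of previously silent genes gains both
    marks at once.  Wave 2: between S3 and S4 a block of genes that already
    carried H3K27me3 gains H3K4me3 on top, so every gene newly bivalent at
    S4 is of the "K4-gain" type.  Trajectory blocks are allocated by exact
    quota in gene-index order, so planted per-stage class counts are exact.
    """
    counts = [int(round(frac * n_genes)) for _, frac, _ in TWO_WAVE_TRAJECTORIES]
    counts[-1] += n_genes - sum(counts)  # remainder goes to the silent block
    if counts[-1] < 0:
        raise ConfigError(f"n_genes={n_genes} too small for the two-wave trajectory quotas")
    plan = np.empty((n_genes, len(TWO_WAVE_STAGES)), dtype=object)
    names: list[str] = []
    row = 0
    for (name, _, classes), cnt in zip(TWO_WAVE_TRAJECTORIES, counts):
        for _ in range(cnt):
            plan[row, :] = classes
            names.append(name)
            row += 1
    base = base_config if base_config is not None else SimulationConfig()
    return replace(
        base,
        n_genes=n_genes,
        stages=TWO_WAVE_STAGES,
        depth=dict(TWO_WAVE_DEPTH),
        label_plan=plan,
        trajectory_names=tuple(names),
        seed=seed,
        **overrides,
    )
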