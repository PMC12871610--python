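"""End-to-end orchestration: quantify, normalize, calibrate, call, classify.

The in-memory core (:func:`run_bivalency_analysis`) is what tests and the
acceptance machinery drive; :func:`run_pipeline` wraps it with file I/O from
a single YAML config and emits a machine-readable run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import ConfigError, PipelineError
from .formats_io import (
    BinnedSignalTrack,
    PeakSet,
    TssAnnotation,
    read_bedgraph,
    read_peaks_bed,
    read_tss_annotation,
    write_call_table,
)
from .promoter_signal import (
    CALLING_WINDOW,
    NORMALIZATION_WINDOW,
    PromoterWindow,
    build_matrix,
)
from .stage_normalization import compute_scale_factors, normalize
from .bivalency_calling import (
    BivalencyThreshold,
    StageCallSet,
    calibrate_threshold,
    call_bivalent,
    reference_regions,
)
from .transition_analysis import TransitionPartition, classify_transition, count_timeline

logger = logging.getLogger(__name__)

K27, K4 = "H3K27me3", "H3K4me3"


@dataclass
class PipelineParams:
    """All tunable constants of the published procedure, with its defaults.

    The normalization window (-1,000/+500 bp) feeds the scale-factor
    computation; factors are applied to the calling-window (+/-1 kb)
    matrices, which the threshold and calls then operate on.
    """

    normalization_window: PromoterWindow = NORMALIZATION_WINDOW
    calling_window: PromoterWindow = CALLING_WINDOW
    top_n: int = 3000
    convention: str = "equalize"
    calibration_stage: str = ""
    reference_stage: str | None = None  # defaults to the calibration stage
    target_override: int | None = None
    half_width: int = 2000
    min_mean: float = 3.0

    def resolved_reference(self) -> str:
        return self.reference_stage or self.calibration_stage


@dataclass
class RunResult:
    """Everything one analysis run computed, in memory."""

    params: PipelineParams
    stages: list[str]
    factors: dict  # mark -> SaturationFactors
    matrices: dict  # mark -> normalized PromoterSignalMatrix
    raw_matrices: dict  # mark -> raw calling-window PromoterSignalMatrix
    reference: object | None  # ReferenceRegionSet or None when target overridden
    threshold: BivalencyThreshold
    calls: dict[str, StageCallSet]
    partitions: list[TransitionPartition]
    timeline: pd.DataFrame

    @property
    def n_ref(self) -> int:
        return self.threshold.target_count

    def counts(self) -> dict[str, int]:
        return {s: self.calls[s].n_bivalent for s in self.stages}

    def report(self) -> dict:
        """JSON-serializable summary sufficient to re-execute the run."""
        return {
            "params": {
                "normalization_window": vars(self.params.normalization_window),
                "calling_window": vars(self.params.calling_window),
                "top_n": self.params.top_n,
                "convention": self.params.convention,
                "calibration_stage": self.params.calibration_stage,
                "reference_stage": self.params.resolved_reference(),
                "target_override": self.params.target_override,
                "half_width": self.params.half_width,
                "min_mean": self.params.min_mean,
            },
            "stages": self.stages,
            "n_genes": int(len(self.matrices[K27].genes)),
            "threshold": self.threshold.as_dict(),
            "saturation": {
                mark: {
                    "saturated_values": f.saturated,
                    "scale_factors": f.factors,
                    "reference_stage": f.reference_stage,
                }
                for mark, f in self.factors.items()
            },
            "bivalent_counts": self.counts(),
            "transitions": [
                {
                    "stage_a": p.stage_a,
                    "stage_b": p.stage_b,
                    "counts": p.counts,
                    "fractions": p.fractions,
                }
                for p in self.partitions
            ],
        }


def run_bivalency_analysis(
    annotation: TssAnnotation,
    tracks: Mapping[str, Mapping[str, BinnedSignalTrack]],
    peaks: Mapping[str, PeakSet] | None,
    params: PipelineParams,
) -> RunResult:
    """Run the full analysis on in-memory inputs.

    ``tracks`` maps stage -> mark -> track (marks "H3K27me3"/"H3K4me3");
    ``peaks`` maps stage -> H3K4me3 PeakSet and may be None when
    ``params.target_override`` is given.
    """
    stages = list(tracks)
    if params.calibration_stage not in stages:
        raise ConfigError(
            f"calibration stage '{params.calibration_stage}' not among stages {stages}"
        )
    if params.target_override is None and (
        peaks is None or params.calibration_stage not in peaks
    ):
        raise ConfigError(
            "no H3K4me3 peaks for the calibration stage and no target override given"
        )

    def stage_tracks(mark: str):
        return [(s, tracks[s][mark]) for s in stages]

    # promoter quantification on both windows
    try:
        norm_win_mat = {
            mark: build_matrix(stage_tracks(mark), annotation, params.normalization_window, mark=mark)
            for mark in (K27, K4)
        }
        raw_matrices = {
            mark: build_matrix(stage_tracks(mark), annotation, params.calling_window, mark=mark)
            for mark in (K27, K4)
        }
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise PipelineError("quantify", str(exc)) from exc

    # cross-stage scale factors from the normalization window
    try:
        reference_stage = params.resolved_reference()
        factors = {
            mark: compute_scale_factors(
                norm_win_mat[mark], reference_stage, top_n=params.top_n,
                convention=params.convention,
            )
            for mark in (K27, K4)
        }
        matrices = {mark: normalize(raw_matrices[mark], factors[mark]) for mark in (K27, K4)}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("normalize", str(exc)) from exc

    # reference region count and threshold calibration
    try:
        reference = None
        if params.target_override is not None:
            target = int(params.target_override)
            source = "target override"
        else:
            reference = reference_regions(
                peaks[params.calibration_stage],
                tracks[params.calibration_stage][K27],  # raw K27 track
                half_width=params.half_width,
                min_mean=params.min_mean,
            )
            target = reference.n_ref
            source = (
                f"{reference.n_ref} regions +/-{params.half_width} bp around "
                f"H3K4me3 peak centers with mean raw H3K27me3 >= {params.min_mean}"
            )
        threshold = calibrate_threshold(
            matrices[K27].column(params.calibration_stage),
            matrices[K4].column(params.calibration_stage),
            target=target,
            calibration_stage=params.calibration_stage,
            source=source,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("calibrate", str(exc)) from exc

    # per-stage calls and consecutive-stage transitions
    try:
        calls = {
            s: call_bivalent(
                matrices[K27].column(s), matrices[K4].column(s), threshold, stage=s
            )
            for s in stages
        }
        partitions = [
            classify_transition(calls[a], calls[b]) for a, b in zip(stages, stages[1:])
        ]
        timeline = count_timeline([calls[s] for s in stages])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("call", str(exc)) from exc

    logger.info(
        "analysis complete: theta=%.6g target=%d achieved=%d counts=%s",
        threshold.theta, threshold.target_count, threshold.achieved_count,
        {s: calls[s].n_bivalent for s in stages},
    )
    return RunResult(
        params=params,
        stages=stages,
        factors=factors,
        matrices=matrices,
        raw_matrices=raw_matrices,
        reference=reference,
        threshold=threshold,
        calls=calls,
        partitions=partitions,
        timeline=timeline,
    )


# ---------------------------------------------------------------------------
# File-based runner
# ---------------------------------------------------------------------------

@dataclass
class StageInputs:
    name: str
    k27_track: str
    k4_track: str
    k4_peaks: str | None = None


@dataclass
class RunConfig:
    """File-based run description (usually loaded from YAML)."""

    annotation: str
    stage_inputs: list[StageInputs]
    output_dir: str
    bin_size: int = 100
    params: PipelineParams = field(default_factory=PipelineParams)
    log_level: str = "INFO"

    def __post_init__(self):
        names = [s.name for s in self.stage_inputs]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate stage names: {names}")
        if self.params.calibration_stage == "" and names:
            self.params.calibration_stage = names[-1]
        cal = self.params.calibration_stage
        has_peaks = any(s.name == cal and s.k4_peaks for s in self.stage_inputs)
        if not has_peaks and self.params.target_override is None:
            raise ConfigError(
                f"calibration stage '{cal}' has no peak file and no target override is set"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping, base_dir: Path | None = None) -> "RunConfig":
        def resolve(p):
            if p is None:
                return None
            p = Path(p)
            if base_dir is not None and not p.is_absolute():
                p = base_dir / p
            return str(p)

        def window(key, default: PromoterWindow) -> PromoterWindow:
            w = raw.get(key)
            if w is None:
                return default
            return PromoterWindow(
                upstream=int(w["upstream"]),
                downstream=int(w["downstream"]),
                strand_aware=bool(w.get("strand_aware", True)),
            )

        stage_inputs = [
            StageInputs(
                name=str(s["name"]),
                k27_track=resolve(s["k27_track"]),
                k4_track=resolve(s["k4_track"]),
                k4_peaks=resolve(s.get("k4_peaks")),
            )
            for s in raw["stages"]
        ]
        params = PipelineParams(
            normalization_window=window("normalization_window", NORMALIZATION_WINDOW),
            calling_window=window("calling_window", CALLING_WINDOW),
            top_n=int(raw.get("top_n", 3000)),
            convention=str(raw.get("convention", "equalize")),
            calibration_stage=str(raw.get("calibration_stage", "")),
            reference_stage=raw.get("reference_stage"),
            target_override=raw.get("target_override"),
            half_width=int(raw.get("half_width", 2000)),
            min_mean=float(raw.get("min_mean", 3.0)),
        )
        return cls(
            annotation=resolve(raw["annotation"]),
            stage_inputs=stage_inputs,
            output_dir=resolve(raw.get("output_dir", "bivalink_out")),
            bin_size=int(raw.get("bin_size", 100)),
            params=params,
            log_level=str(raw.get("log_level", "INFO")),
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute a file-based run; writes outputs and returns the run report.

    On any stage failure, partially written outputs are removed and a
    :class:`PipelineError` naming the failing stage is raised.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        try:
            annotation = read_tss_annotation(config.annotation)
            tracks: dict[str, dict[str, BinnedSignalTrack]] = {}
            peaks: dict[str, PeakSet] = {}
            for s in config.stage_inputs:
                tracks[s.name] = {
                    K27: read_bedgraph(s.k27_track, config.bin_size, mark=K27, stage=s.name),
                    K4: read_bedgraph(s.k4_track, config.bin_size, mark=K4, stage=s.name),
                }
                if s.k4_peaks:
                    peaks[s.name] = read_peaks_bed(s.k4_peaks)
                logger.info(
                    "stage %s: K27 %d chroms, K4 %d chroms, peaks %s",
                    s.name, len(tracks[s.name][K27].data), len(tracks[s.name][K4].data),
                    len(peaks[s.name]) if s.name in peaks else "-",
                )
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("read-inputs", str(exc)) from exc

        result = run_bivalency_analysis(annotation, tracks, peaks or None, config.params)

        calls_path = outdir / "bivalent_calls.tsv"
        write_call_table([result.calls[s] for s in result.stages], calls_path)
        written.append(calls_path)
        for mark, f in result.factors.items():
            p = outdir / f"scale_factors_{mark}.tsv"
            f.to_tsv(p)
            written.append(p)
        timeline_path = outdir / "bivalent_counts.tsv"
        result.timeline.to_csv(timeline_path, sep="\t", index=False, float_format="%.10g")
        written.append(timeline_path)
        for p_ in result.partitions:
            pth = outdir / f"transition_{p_.stage_a}_vs_{p_.stage_b}.tsv"
            p_.to_frame().to_csv(pth, sep="\t", index=False)
            written.append(pth)

        report = result.report()
        report["inputs"] = {
            "annotation": {"path": config.annotation, "sha256": _sha256(config.annotation)},
            "stages": [
                {
                    "name": s.name,
                    "k27_track": {"path": s.k27_track, "sha256": _sha256(s.k27_track)},
                    "k4_track": {"path": s.k4_track, "sha256": _sha256(s.k4_track)},
                    "k4_peaks": (
                        {"path": s.k4_peaks, "sha256": _sha256(s.k4_peaks)} if s.k4_peaks else None
                    ),
                }
                for s in config.stage_inputs
            ],
            "bin_size": config.bin_size,
        }
        report["outputs"] = [str(p) for p in written]
        report_path = outdir / "run_report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
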