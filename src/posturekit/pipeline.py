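"""End-to-end measurement pipeline: calibrate → measure → select →
aggregate → stabilize."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .calibration import CalibrationModel
from .errors import InsufficientDataError, PostureKitError
from .metrics import LandmarkFrame, MeasuredFrame, measure_frame
from .protocol import ProtocolConfig
from .simulate import FrameSelection, select_frames
from .stats import (
    MetricAggregate,
    StabilizationResult,
    aggregate_metrics,
    percent_error,
    repetitions_needed,
)

__all__ = ["PipelineReport", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("posturekit.pipeline")


class PipelineStageError(PostureKitError):
    """An error raised by a pipeline stage, labelled with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


@dataclass(frozen=True)
class PipelineReport:
    """Everything the pipeline computed, per metric."""

    measured: tuple[MeasuredFrame, ...]
    selection: Optional[FrameSelection]
    aggregates: Mapping[str, Optional[MetricAggregate]]
    stabilization: Mapping[str, StabilizationResult]
    skipped_metrics: Mapping[str, int]
    percent_errors: Mapping[str, float]

    def summary_lines(self) -> list[str]:
        """Human-readable per-metric report."""
        lines = []
        for name in sorted(self.aggregates):
            agg = self.aggregates[name]
            if agg is None:
                lines.append(f"{name}: insufficient data (fewer than 2 frames)")
                continue
            s = agg.summary
            line = (
                f"{name}: n={s.n} mean={s.mean:.2f} sd={s.sd:.2f} "
                f"cv={s.cv:.2f}% min={s.min:.2f} max={s.max:.2f}"
            )
            stab = self.stabilization.get(name)
            if stab is not None:
                line += (
                    f" | stabilized at k={stab.k_stable}" if stab.stabilized
                    else " | not stabilized"
                )
            if name in self.percent_errors:
                line += f" | error vs truth={self.percent_errors[name]:.2f}%"
            lines.append(line)
        return lines


def run_pipeline(
    protocol: ProtocolConfig,
    frames: Sequence[LandmarkFrame],
    model: CalibrationModel,
    truth: Optional[Mapping[str, float]] = None,
) -> PipelineReport:
    """Measure every frame, select the analysis window, aggregate and
    run the stabilization analysis.

    Frame selection (by platform angle, per ``protocol.frame_selection``)
    is applied only when the frames carry rotation angles; plain
    annotation sets without angles are used in full.  ``truth`` maps
    metric names to known reference values; percent errors of the
    aggregated means against them are included in the report.

    Stage failures are re-raised as :class:`PipelineStageError` with the
    stage name attached.
    """
    if not frames:
        raise PipelineStageError("measure", InsufficientDataError("no landmark frames"))

    selection: Optional[FrameSelection] = None
    analysed: Sequence[LandmarkFrame] = frames
    if all(f.rotation_angle is not None for f in frames):
        try:
            sel_cfg = protocol.frame_selection
            selection = select_frames(
                frames, sel_cfg.target_angle, sel_cfg.tolerance, sel_cfg.max_frames
            )
        except Exception as exc:
            raise PipelineStageError("select", exc) from exc
        if selection.empty_warning:
            log.warning(
                "select: no frames within %.3g deg of target %.3g deg",
                sel_cfg.tolerance, sel_cfg.target_angle,
            )
        analysed = [f for f in selection]
        log.info("select: kept %d of %d frames", len(analysed), len(frames))

    try:
        measured = tuple(measure_frame(f, model, protocol) for f in analysed)
    except Exception as exc:
        raise PipelineStageError("measure", exc) from exc
    for m in measured:
        if m.missing:
            log.warning(
                "measure: frame %d missing metrics: %s", m.frame_index, ", ".join(m.missing)
            )

    try:
        aggregates = aggregate_metrics([m.values for m in measured], protocol.rounding)
    except Exception as exc:
        raise PipelineStageError("aggregate", exc) from exc

    stabilization: dict[str, StabilizationResult] = {}
    skipped: dict[str, int] = {}
    stab_cfg = protocol.stabilization
    for name, agg in aggregates.items():
        if agg is None:
            continue
        skipped[name] = agg.n_skipped
        try:
            stabilization[name] = repetitions_needed(
                agg.accumulated,
                rule=stab_cfg.rule,
                decimals=stab_cfg.decimals,
                epsilon=stab_cfg.epsilon,
                window=stab_cfg.window,
                metric_name=name,
            )
        except Exception as exc:
            raise PipelineStageError("stabilize", exc) from exc

    errors: dict[str, float] = {}
    if truth:
        for name, ref in truth.items():
            agg = aggregates.get(name)
            if agg is not None:
                errors[name] = percent_error(agg.summary.mean, ref)

    return PipelineReport(
        measured=measured,
        selection=selection,
        aggregates=aggregates,
        stabilization=stabilization,
        skipped_metrics=skipped,
        percent_errors=errors,
    )
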