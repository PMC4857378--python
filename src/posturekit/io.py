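"""Readers and writers for the package's plain-text interchange formats.

All tables are CSV with dot-decimal output; readers additionally accept
comma decimals (common in Brazilian-locale exports).  Formats:

* calibration marks: ``mark_id,u_px,v_px,x_cm,y_cm``
* landmark frames (long format, one landmark per row):
  ``frame_index,rotation_angle_deg,landmark,u_px,v_px``
* per-frame metrics: ``frame_index,metric,value``
* summary statistics: ``metric,n,mean,sd,cv,min,max``
* accumulated statistics: ``metric,k,mean_accum,sd_accum,cv_accum``
* calibration model and stabilization results: JSON
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .calibration import CalibrationMark, CalibrationModel, PixelPoint, WorldPoint
from .errors import FormatError
from .metrics import LandmarkFrame, MeasuredFrame
from .stats import AccumulatedStatsRow, StabilizationResult, SummaryStats

__all__ = [
    "read_calibration_marks",
    "write_calibration_marks",
    "read_calibration_model",
    "write_calibration_model",
    "read_landmark_frames",
    "write_landmark_frames",
    "read_metric_table",
    "write_metric_table",
    "write_summary_table",
    "write_accumulated_table",
    "read_accumulated_table",
    "write_stabilization_result",
    "read_stabilization_result",
]

PathLike = Union[str, Path]

_MARKS_HEADER = ["mark_id", "u_px", "v_px", "x_cm", "y_cm"]
_FRAMES_HEADER = ["frame_index", "rotation_angle_deg", "landmark", "u_px", "v_px"]
_METRICS_HEADER = ["frame_index", "metric", "value"]
_ACCUM_HEADER = ["metric", "k", "mean_accum", "sd_accum", "cv_accum"]


def _read_csv(path: PathLike, expected_header: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: could not parse CSV: {exc}") from exc
    if list(df.columns) != expected_header:
        raise FormatError(
            f"{path}: unknown header {list(df.columns)}; expected {expected_header}"
        )
    return df


def _num(raw: str, path: PathLike, line: int, column: str, optional: bool = False) -> float:
    text = raw.strip().replace(",", ".")
    if text == "":
        if optional:
            return math.nan
        raise FormatError(f"{path}:{line}: empty value in column {column!r}")
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"{path}:{line}: could not parse {raw!r} in column {column!r}"
        ) from None


# -- calibration marks ----------------------------------------------


def read_calibration_marks(path: PathLike) -> list[CalibrationMark]:
    df = _read_csv(path, _MARKS_HEADER)
    marks = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        marks.append(
            CalibrationMark(
                PixelPoint(_num(row.u_px, path, line, "u_px"),
                           _num(row.v_px, path, line, "v_px")),
                WorldPoint(_num(row.x_cm, path, line, "x_cm"),
                           _num(row.y_cm, path, line, "y_cm")),
            )
        )
    return marks


def write_calibration_marks(path: PathLike, marks: Sequence[CalibrationMark]) -> None:
    df = pd.DataFrame(
        [
            {"mark_id": i, "u_px": m.pixel.u, "v_px": m.pixel.v,
             "x_cm": m.world.x, "y_cm": m.world.y}
            for i, m in enumerate(marks)
        ],
        columns=_MARKS_HEADER,
    )
    df.to_csv(path, index=False)


def read_calibration_model(path: PathLike) -> CalibrationModel:
    return CalibrationModel.from_json(Path(path).read_text())


def write_calibration_model(path: PathLike, model: CalibrationModel) -> None:
    Path(path).write_text(model.to_json(indent=2) + "\n")


# -- landmark frames -------------------------------------------------


def read_landmark_frames(path: PathLike) -> list[LandmarkFrame]:
    """Parse annotated frames, sorted by frame index.

    Raises :class:`FormatError` on an unknown header, a malformed row,
    or a duplicated (frame, landmark) pair — each naming the offending
    line.
    """
    df = _read_csv(path, _FRAMES_HEADER)
    frames: dict[int, dict] = {}
    seen: dict[tuple[int, str], int] = {}
    for i, row in df.iterrows():
        line = i + 2
        try:
            idx = int(row.frame_index)
        except ValueError:
            raise FormatError(
                f"{path}:{line}: frame_index {row.frame_index!r} is not an integer"
            ) from None
        name = row.landmark.strip()
        if not name:
            raise FormatError(f"{path}:{line}: empty landmark name")
        key = (idx, name)
        if key in seen:
            raise FormatError(
                f"{path}:{line}: duplicate record for landmark {name!r} in frame "
                f"{idx} (first seen at line {seen[key]})"
            )
        seen[key] = line
        angle = _num(row.rotation_angle_deg, path, line, "rotation_angle_deg", optional=True)
        u = _num(row.u_px, path, line, "u_px")
        v = _num(row.v_px, path, line, "v_px")
        entry = frames.setdefault(idx, {"angle": None, "landmarks": {}})
        if not math.isnan(angle):
            entry["angle"] = angle
        entry["landmarks"][name] = PixelPoint(u, v)
    return [
        LandmarkFrame(frame_index=idx, landmarks=frames[idx]["landmarks"],
                      rotation_angle=frames[idx]["angle"])
        for idx in sorted(frames)
    ]


def write_landmark_frames(path: PathLike, frames: Iterable[LandmarkFrame]) -> None:
    rows = []
    for frame in frames:
        angle = "" if frame.rotation_angle is None else repr(float(frame.rotation_angle))
        for name in sorted(frame.landmarks):
            p = frame.landmarks[name]
            rows.append(
                {"frame_index": frame.frame_index, "rotation_angle_deg": angle,
                 "landmark": name, "u_px": repr(p.u), "v_px": repr(p.v)}
            )
    pd.DataFrame(rows, columns=_FRAMES_HEADER).to_csv(path, index=False)


# -- metric tables ---------------------------------------------------


def read_metric_table(path: PathLike) -> list[dict[str, float]]:
    """Per-frame metric mappings from a long-format metrics CSV."""
    df = _read_csv(path, _METRICS_HEADER)
    frames: dict[int, dict[str, float]] = {}
    for i, row in df.iterrows():
        line = i + 2
        try:
            idx = int(row.frame_index)
        except ValueError:
            raise FormatError(
                f"{path}:{line}: frame_index {row.frame_index!r} is not an integer"
            ) from None
        metric = row.metric.strip()
        if metric in frames.get(idx, {}):
            raise FormatError(
                f"{path}:{line}: duplicate value for metric {metric!r} in frame {idx}"
            )
        frames.setdefault(idx, {})[metric] = _num(row.value, path, line, "value")
    return [frames[idx] for idx in sorted(frames)]


def write_metric_table(path: PathLike, measured: Sequence[MeasuredFrame]) -> None:
    rows = []
    for frame in measured:
        for metric in sorted(frame.values):
            rows.append(
                {"frame_index": frame.frame_index, "metric": metric,
                 "value": repr(frame.values[metric])}
            )
    pd.DataFrame(rows, columns=_METRICS_HEADER).to_csv(path, index=False)


def write_summary_table(path: PathLike, summaries: Mapping[str, SummaryStats]) -> None:
    rows = [
        {"metric": name, "n": s.n, "mean": repr(s.mean), "sd": repr(s.sd),
         "cv": repr(s.cv), "min": repr(s.min), "max": repr(s.max)}
        for name, s in sorted(summaries.items())
    ]
    pd.DataFrame(rows, columns=["metric", "n", "mean", "sd", "cv", "min", "max"]).to_csv(
        path, index=False
    )


def write_accumulated_table(
    path: PathLike, accumulated: Mapping[str, Sequence[AccumulatedStatsRow]]
) -> None:
    rows = []
    for name, table in sorted(accumulated.items()):
        for r in table:
            rows.append(
                {"metric": name, "k": r.k, "mean_accum": repr(r.mean_accum),
                 "sd_accum": repr(r.sd_accum), "cv_accum": repr(r.cv_accum)}
            )
    pd.DataFrame(rows, columns=_ACCUM_HEADER).to_csv(path, index=False)


def read_accumulated_table(path: PathLike) -> dict[str, list[AccumulatedStatsRow]]:
    df = _read_csv(path, _ACCUM_HEADER)
    out: dict[str, list[AccumulatedStatsRow]] = {}
    for i, row in df.iterrows():
        line = i + 2
        try:
            k = int(row.k)
        except ValueError:
            raise FormatError(f"{path}:{line}: k {row.k!r} is not an integer") from None
        out.setdefault(row.metric.strip(), []).append(
            AccumulatedStatsRow(
                k=k,
                mean_accum=_num(row.mean_accum, path, line, "mean_accum"),
                sd_accum=_num(row.sd_accum, path, line, "sd_accum"),
                cv_accum=_num(row.cv_accum, path, line, "cv_accum"),
            )
        )
    return out


def write_stabilization_result(path: PathLike, result: StabilizationResult) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "metric": result.metric_name,
                "k_stable": result.k_stable,
                "rule": result.criterion,
                "stabilized": result.stabilized,
                "cv_series": list(result.cv_series),
            },
            indent=2,
        )
        + "\n"
    )


def read_stabilization_result(path: PathLike) -> StabilizationResult:
    d = json.loads(Path(path).read_text())
    return StabilizationResult(
        k_stable=d["k_stable"],
        stabilized=d["stabilized"],
        criterion=d["rule"],
        cv_series=tuple(d["cv_series"]),
        metric_name=d.get("metric", ""),
    )
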