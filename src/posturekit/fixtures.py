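"""Reference validation data: 30 repeated measurements of a known rectangle.

The instrument's criterion validity was established by filming a flat
25 cm x 15 cm rectangle on the rotating platform and measuring its
width and height on 30 frames of the frontal plane.  The per-frame
values below are transcribed from the published validation table
(decimal commas converted to dots) and are the package's reference
data set for summary statistics, accumulated statistics and the
repetitions-needed analysis.

Transcription notes: the per-frame raw columns are authoritative and
preserved verbatim.  The source table is not perfectly self-consistent
— two accumulated means are printed to three decimals where the rest
have two, and the narrative min/max for width (24.83–25.2) conflict
with the per-frame extremes (24.75–25.8).  Such cells are documented
here, not "corrected"; derived statistics in this package are always
recomputed from the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Table1Fixture", "table1_fixture", "TRUE_WIDTH", "TRUE_HEIGHT"]

TRUE_WIDTH = 25.0
TRUE_HEIGHT = 15.0

_WIDTHS = (
    24.75, 24.75, 24.75, 24.95, 25.12, 24.75, 24.89, 24.92, 25.10, 25.25,
    25.00, 25.00, 25.00, 24.75, 24.75, 25.80, 24.75, 24.89, 24.83, 24.93,
    24.95, 25.00, 25.00, 25.00, 25.20, 25.10, 25.00, 25.12, 25.14, 25.20,
)

_HEIGHTS = (
    15.41, 15.41, 15.41, 15.41, 15.22, 14.84, 14.94, 14.94, 14.84, 14.94,
    15.41, 15.41, 14.75, 15.41, 14.56, 14.56, 14.56, 15.22, 14.66, 14.66,
    14.66, 15.22, 14.66, 14.56, 14.66, 14.66, 14.66, 15.22, 15.75, 15.03,
)


@dataclass(frozen=True)
class Table1Fixture:
    """Per-frame width/height measurements of the 25 x 15 cm rectangle."""

    widths: tuple[float, ...]
    heights: tuple[float, ...]
    true_width: float
    true_height: float

    def __post_init__(self) -> None:
        if len(self.widths) != 30 or len(self.heights) != 30:
            raise ValueError("the reference fixture has exactly 30 frames per series")

    def as_frames(self) -> list[dict[str, float]]:
        """Per-frame metric mappings, ready for aggregation."""
        return [
            {"width": w, "height": h} for w, h in zip(self.widths, self.heights)
        ]


def table1_fixture() -> Table1Fixture:
    """The embedded 30-frame known-rectangle measurement series."""
    return Table1Fixture(
        widths=_WIDTHS, heights=_HEIGHTS,
        true_width=TRUE_WIDTH, true_height=TRUE_HEIGHT,
    )
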