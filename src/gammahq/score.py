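"""Per-cell gamma-H2AX scoring.

Each segmented cell is scored by the single brightest pixel of the
(background-corrected) signal channel inside its nucleus mask.  The score is
deliberately the plain maximum: positivity is a whole-cell call, not a focus
count, so one saturating pixel anywhere in the nucleus marks the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .segment import LabelMap

__all__ = ["CellRecord", "CellTable", "assign_max_signal", "CELL_COLUMNS"]

CELL_COLUMNS = [
    "image_id",
    "experiment",
    "arm",
    "treatment",
    "field",
    "label",
    "centroid_row",
    "centroid_col",
    "area",
    "max_signal",
]


@dataclass(frozen=True)
class CellRecord:
    image_id: str
    label: int
    centroid: tuple[float, float]
    area: int
    max_signal: float


@dataclass
class CellTable:
    """Per-cell feature rows, one per (image_id, label).

    Carried as a DataFrame with the columns in :data:`CELL_COLUMNS`; condition
    metadata travels per row so tables from different images and conditions
    can be concatenated and pooled freely.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CELL_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"CellTable missing columns: {missing}")
        if len(self.df) and self.df.duplicated(["image_id", "label"]).any():
            raise ValueError("(image_id, label) pairs must be unique")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def max_signals(self) -> np.ndarray:
        return self.df["max_signal"].to_numpy(dtype=float)

    @staticmethod
    def concat(tables: list["CellTable"]) -> "CellTable":
        if not tables:
            return CellTable()
        return CellTable(
            pd.concat([t.df for t in tables], ignore_index=True)
        )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "CellTable":
        return CellTable(pd.read_csv(path))


def assign_max_signal(
    label_map: LabelMap,
    signal: np.ndarray,
    image_id: str = "",
    experiment: str = "",
    arm: str = "",
    treatment: str = "",
    field_index: int = 0,
    percentile: float = 100.0,
) -> CellTable:
    """Score every labeled cell with its brightest signal-channel pixel.

    The signal image must already be background-corrected (the pipeline runs
    :func:`gammahq.segment.subtract_background` on the signal channel before
    scoring).  ``percentile`` below 100 swaps the maximum for a per-cell
    intensity percentile, for sensitivity analysis only; the default is the
    plain maximum.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.shape != label_map.labels.shape:
        raise ValueError(
            f"shape mismatch: labels {label_map.labels.shape} vs signal {sig.shape}"
        )
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    rows = []
    for prop in regionprops(label_map.labels, intensity_image=sig):
        pixels = sig[prop.slice][prop.image]
        score = (
            float(pixels.max())
            if percentile == 100
            else float(np.percentile(pixels, percentile))
        )
        rows.append(
            {
                "image_id": image_id,
                "experiment": experiment,
                "arm": arm,
                "treatment": treatment,
                "field": field_index,
                "label": int(prop.label),
                "centroid_row": float(prop.centroid[0]),
                "centroid_col": float(prop.centroid[1]),
                "area": int(prop.area),
                "max_signal": score,
            }
        )
    df = pd.DataFrame(rows, columns=CELL_COLUMNS).sort_values("label")
    return CellTable(df.reset_index(drop=True))
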