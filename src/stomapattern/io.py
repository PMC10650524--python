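"""Coordinate-table file formats and section metadata.

The pipeline boundary is a pair of plain CSV files: a *coordinate table*
with one row per stoma (window id, section metadata, x/y in μm) and a
companion *window table* with one row per observation window (id, width,
height in μm). Floats are serialized with 6 significant digits; a write →
read → write round trip is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import ObservationWindow, PointPattern

COORD_COLUMNS = ["window_id", "species", "leaf_id", "layer", "position",
                 "x_um", "y_um"]
WINDOW_COLUMNS = ["window_id", "width_um", "height_um"]
_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class SectionLabel:
    """Where on which leaf a window was sampled.

    ``layer`` runs 1 (leaf apex) to at most 4 (base); ``position`` is
    1 near the midrib, 2 near the leaf margin.
    """

    species: str
    leaf_id: str
    layer: int
    position: int

    def __post_init__(self):
        if not (1 <= int(self.layer) <= 4):
            raise ValueError(f"layer must be in 1..4, got {self.layer}")
        if int(self.position) not in (1, 2):
            raise ValueError(f"position must be 1 or 2, got {self.position}")

    @property
    def window_id(self) -> str:
        return (f"{self.species}_{self.leaf_id}_"
                f"L{self.layer}_P{self.position}")


class CoordinateValidationError(ValueError):
    """Raised when a coordinate table fails validation.

    ``errors`` lists (row_number, message) pairs; row numbers refer to the
    data rows of the CSV, 1-based (header excluded).
    """

    def __init__(self, errors: List[Tuple[int, str]]):
        self.errors = errors
        shown = "; ".join(f"row {r}: {m}" for r, m in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"coordinate table invalid: {shown}{more}")


def write_coordinates(patterns: Sequence[PointPattern], points_path,
                      windows_path) -> None:
    """Write labelled patterns to the coordinate + window CSV pair."""
    rows = []
    wrows = []
    for pat in patterns:
        lab = pat.label
        if not isinstance(lab, SectionLabel):
            raise ValueError("every pattern needs a SectionLabel to be "
                             "written to a coordinate table")
        wrows.append({"window_id": lab.window_id,
                      "width_um": pat.window.width,
                      "height_um": pat.window.height})
        for x, y in pat.points:
            rows.append({"window_id": lab.window_id, "species": lab.species,
                         "leaf_id": lab.leaf_id, "layer": lab.layer,
                         "position": lab.position, "x_um": x, "y_um": y})
    pd.DataFrame(rows, columns=COORD_COLUMNS).to_csv(
        points_path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(wrows, columns=WINDOW_COLUMNS).to_csv(
        windows_path, index=False, float_format=_FLOAT_FMT)


def read_coordinates(points_path, windows_path) -> List[PointPattern]:
    """Read a coordinate table back into labelled point patterns.

    Patterns are grouped by ``window_id`` (row order within the file is
    irrelevant; the original window order of the file is preserved).
    Unknown columns, non-numeric coordinates, inconsistent metadata within
    a window, and points outside their window all fail validation with a
    report naming the offending rows.
    """
    pts = pd.read_csv(points_path, dtype={"window_id": str, "species": str,
                                          "leaf_id": str})
    wins = pd.read_csv(windows_path, dtype={"window_id": str})
    errors: List[Tuple[int, str]] = []
    if list(pts.columns) != COORD_COLUMNS:
        raise CoordinateValidationError(
            [(0, f"expected columns {COORD_COLUMNS}, got {list(pts.columns)}")])
    if list(wins.columns) != WINDOW_COLUMNS:
        raise CoordinateValidationError(
            [(0, f"expected columns {WINDOW_COLUMNS}, got {list(wins.columns)}")])
    windows = {}
    for _, row in wins.iterrows():
        try:
            windows[row["window_id"]] = ObservationWindow(
                float(row["width_um"]), float(row["height_um"]))
        except (TypeError, ValueError) as exc:
            errors.append((0, f"window {row['window_id']}: {exc}"))
    for col in ("x_um", "y_um"):
        numeric = pd.to_numeric(pts[col], errors="coerce")
        for i in pts.index[numeric.isna()]:
            errors.append((i + 1, f"non-numeric {col}: {pts.at[i, col]!r}"))
        pts[col] = numeric
    for i in pts.index[~pts["window_id"].isin(windows)]:
        errors.append((i + 1, f"unknown window_id {pts.at[i, 'window_id']!r}"))
    if errors:
        raise CoordinateValidationError(errors)
    for i, row in pts.iterrows():
        win = windows[row["window_id"]]
        if not (0.0 <= row["x_um"] <= win.width
                and 0.0 <= row["y_um"] <= win.height):
            errors.append(
                (i + 1, f"point ({row['x_um']:g}, {row['y_um']:g}) outside "
                        f"window {row['window_id']} "
                        f"({win.width:g} x {win.height:g} μm)"))
    if errors:
        raise CoordinateValidationError(errors)
    patterns = []
    order = pts["window_id"].drop_duplicates().tolist()
    grouped = dict(list(pts.groupby("window_id", sort=False)))
    for wid in order:
        grp = grouped[wid]
        meta = grp[["species", "leaf_id", "layer", "position"]].drop_duplicates()
        if len(meta) != 1:
            raise CoordinateValidationError(
                [(int(grp.index[0]) + 1,
                  f"inconsistent metadata within window {wid!r}")])
        m = meta.iloc[0]
        label = SectionLabel(species=m["species"], leaf_id=m["leaf_id"],
                             layer=int(m["layer"]), position=int(m["position"]))
        patterns.append(PointPattern(grp[["x_um", "y_um"]].to_numpy(float),
                                     windows[wid], label))
    return patterns


def window_stats_table(patterns: Sequence[PointPattern],
                       metric: str = "euclidean") -> pd.DataFrame:
    """Per-window statistics table (one row per window, tidy columns)."""
    from .stats import window_stats

    rows = []
    for pat in patterns:
        st = window_stats(pat, metric=metric)
        lab = pat.label
        rows.append({
            "window_id": lab.window_id if isinstance(lab, SectionLabel) else "",
            "species": getattr(lab, "species", ""),
            "leaf_id": getattr(lab, "leaf_id", ""),
            "layer": getattr(lab, "layer", np.nan),
            "position": getattr(lab, "position", np.nan),
            "n": st.n, "sd": st.sd, "mnnd": st.mnnd, "r_e": st.r_e,
            "sai": st.sai, "dispersion": st.dispersion,
        })
    return pd.DataFrame(rows)
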