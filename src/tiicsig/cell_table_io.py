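"""Read, validate, and write per-cell and per-patient tables.

The per-cell table is a flat delimited export (one row per segmented
nucleus) carrying slide/patient identifiers, ROI membership, nucleus
centroid coordinates in micrometres, binarised marker positivity, and a
tumour-cell flag. Coordinates are nucleus centroids with the origin at
the ROI top-left and y increasing downward (image convention); only
intra-ROI Euclidean distances are ever formed downstream, so no global
frame is needed.

Marker positivity arrives already binarised by the upstream image
analysis; this module never re-thresholds intensities. Cells in
overlapping fields are deduplicated only when ``cell_id`` collides —
there is no geometric deduplication (known limitation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CellTableError, ConfigurationError

#: Markers stained by the default panels.
DEFAULT_MARKERS: tuple[str, ...] = (
    "CD8", "PD-1", "TIM-3", "LAG-3",
    "CD4", "FoxP3", "CTLA-4", "PD-L1",
    "CD68", "CD163", "HLA-DR", "STING",
    "CD20", "CD66b",
)

ROI_CLASSES = ("TC", "IM", "N")
COMPARTMENTS = ("tumour_nest", "stroma")

#: Default stamp geometry (micrometres).
DEFAULT_FIELD_WIDTH_UM = 930.0
DEFAULT_FIELD_HEIGHT_UM = 700.0

MANDATORY_COLUMNS = (
    "cell_id", "patient_id", "roi_id", "roi_class",
    "compartment", "x_um", "y_um", "is_tumour_cell",
)
OPTIONAL_ROI_COLUMNS = (
    "roi_width_um", "roi_height_um", "area_tumour_mm2", "area_stroma_mm2",
)

CLINICAL_COLUMNS = (
    "patient_id", "ebv", "mmr", "cps", "her2", "response",
    "os_months", "os_event", "iros_months", "iros_event",
    "irpfs_months", "irpfs_event", "cohort",
)

RESPONSE_LEVELS = ("CR", "PR", "SD", "PD", "missing")
RESPONDER_LEVELS = ("CR", "PR")


@dataclass(frozen=True)
class PanelConfig:
    """Declares the marker panel and (optionally) remaps input column names."""

    markers: tuple[str, ...] = DEFAULT_MARKERS
    column_map: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ConfigurationError("panel declares duplicate markers")
        if not self.markers:
            raise ConfigurationError("panel declares no markers")

    @classmethod
    def from_file(cls, path: str | Path) -> "PanelConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yaml", ".yml"} else json.load(fh)
        return cls(
            markers=tuple(raw["markers"]),
            column_map=dict(raw.get("column_map", {})),
        )


@dataclass(frozen=True)
class Cell:
    """One segmented nucleus."""

    cell_id: str
    patient_id: str
    roi_id: str
    roi_class: str
    compartment: str
    x_um: float
    y_um: float
    markers: Mapping[str, bool]
    is_tumour_cell: bool


@dataclass(frozen=True)
class Roi:
    """One imaged field."""

    roi_id: str
    patient_id: str
    roi_class: str
    width_um: float = DEFAULT_FIELD_WIDTH_UM
    height_um: float = DEFAULT_FIELD_HEIGHT_UM
    area_tumour_mm2: float | None = None
    area_stroma_mm2: float | None = None

    @property
    def stamp_area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


@dataclass
class CellTable:
    """Validated study substrate: per-cell frame, per-ROI frame, QC report."""

    cells: pd.DataFrame
    rois: pd.DataFrame
    panel: PanelConfig
    qc: dict

    def iter_cells(self) -> Iterable[Cell]:
        marker_cols = list(self.panel.markers)
        for row in self.cells.itertuples(index=False):
            d = row._asdict()
            yield Cell(
                cell_id=d["cell_id"], patient_id=d["patient_id"],
                roi_id=d["roi_id"], roi_class=d["roi_class"],
                compartment=d["compartment"], x_um=d["x_um"], y_um=d["y_um"],
                markers={m: bool(d[m]) for m in marker_cols},
                is_tumour_cell=bool(d["is_tumour_cell"]),
            )


def _infer_sep(path: Path) -> str:
    if path.suffix.lower() in {".tsv", ".txt"}:
        return "\t"
    return ","


def _validate_cells(df: pd.DataFrame, panel: PanelConfig, source: str) -> pd.DataFrame:
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CellTableError(f"{source}: missing mandatory column '{col}'")
    for m in panel.markers:
        if m not in df.columns:
            raise CellTableError(f"{source}: missing marker column '{m}'")

    df = df.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    df["patient_id"] = df["patient_id"].astype(str)
    df["roi_id"] = df["roi_id"].astype(str)

    bad_class = ~df["roi_class"].isin(ROI_CLASSES)
    if bad_class.any():
        i = int(np.flatnonzero(bad_class)[0])
        raise CellTableError(
            f"{source}: row {i}: roi_class '{df['roi_class'].iloc[i]}' not in {ROI_CLASSES}"
        )
    bad_comp = ~df["compartment"].isin(COMPARTMENTS)
    if bad_comp.any():
        i = int(np.flatnonzero(bad_comp)[0])
        raise CellTableError(
            f"{source}: row {i}: compartment '{df['compartment'].iloc[i]}' not in {COMPARTMENTS}"
        )

    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CellTableError(f"{source}: row {i}: {col} = {df[col].iloc[i]!r} is not a finite non-negative length")
        df[col] = vals.astype(float)

    for col in ("is_tumour_cell", *panel.markers):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise CellTableError(
                f"{source}: row {i}: non-binary value {df[col].iloc[i]!r} in column '{col}'"
            )
        df[col] = vals.astype(bool)

    extra = [
        c for c in df.columns
        if c not in MANDATORY_COLUMNS
        and c not in OPTIONAL_ROI_COLUMNS
        and c not in panel.markers
    ]
    if extra:
        raise CellTableError(f"{source}: unknown columns (unexpected markers?): {extra}")

    dup = df["cell_id"].duplicated()
    if dup.any():
        raise CellTableError(f"{source}: duplicate cell_id '{df['cell_id'][dup].iloc[0]}'")
    return df


def _build_rois(df: pd.DataFrame, source: str) -> pd.DataFrame:
    rows = []
    for roi_id, grp in df.groupby("roi_id", sort=True):
        if grp["patient_id"].nunique() > 1:
            raise CellTableError(f"{source}: roi_id '{roi_id}' spans multiple patients")
        if grp["roi_class"].nunique() > 1:
            raise CellTableError(f"{source}: roi_id '{roi_id}' carries conflicting roi_class values")

        def _const(col: str, default: float | None) -> float | None:
            if col not in grp.columns:
                return default
            vals = pd.to_numeric(grp[col], errors="coerce").dropna().unique()
            if len(vals) == 0:
                return default
            if len(vals) > 1:
                raise CellTableError(f"{source}: roi_id '{roi_id}': conflicting values for {col}")
            return float(vals[0])

        width = _const("roi_width_um", DEFAULT_FIELD_WIDTH_UM)
        height = _const("roi_height_um", DEFAULT_FIELD_HEIGHT_UM)
        area_t = _const("area_tumour_mm2", None)
        area_s = _const("area_stroma_mm2", None)
        if area_t is not None and area_s is not None:
            if area_t + area_s > width * height / 1e6 + 1e-9:
                raise CellTableError(
                    f"{source}: roi_id '{roi_id}': segmented areas exceed the stamp area"
                )
        rows.append({
            "roi_id": roi_id,
            "patient_id": grp["patient_id"].iloc[0],
            "roi_class": grp["roi_class"].iloc[0],
            "width_um": width,
            "height_um": height,
            "area_tumour_mm2": area_t,
            "area_stroma_mm2": area_s,
        })
    return pd.DataFrame(rows, columns=[
        "roi_id", "patient_id", "roi_class", "width_um", "height_um",
        "area_tumour_mm2", "area_stroma_mm2",
    ])


def _qc_report(cells: pd.DataFrame, rois: pd.DataFrame) -> dict:
    return {
        "n_cells": int(len(cells)),
        "n_rois": int(len(rois)),
        "n_patients": int(cells["patient_id"].nunique()),
        "cells_per_roi_class": {
            k: int(v) for k, v in cells["roi_class"].value_counts().sort_index().items()
        },
        "cells_per_compartment": {
            k: int(v) for k, v in cells["compartment"].value_counts().sort_index().items()
        },
        "n_tumour_cells": int(cells["is_tumour_cell"].sum()),
        "rois_missing_segmented_area": int(rois["area_tumour_mm2"].isna().sum()),
    }


def read_cell_table(
    path: str | Path | Sequence[str | Path],
    panel: PanelConfig | None = None,
) -> CellTable:
    """Read one or more delimited per-cell tables into a validated :class:`CellTable`.

    Multiple files (e.g. one export per stamp) are concatenated; a
    ``cell_id`` collision across files is a hard failure.
    """
    panel = panel or PanelConfig()
    paths = [Path(path)] if isinstance(path, (str, Path)) else [Path(p) for p in path]
    frames = []
    for p in paths:
        if not p.exists():
            raise CellTableError(f"no such file: {p}")
        raw = pd.read_csv(p, sep=_infer_sep(p), dtype=str)
        frames.append(_validate_cells(raw, panel, p.name))
    cells = pd.concat(frames, ignore_index=True)
    dup = cells["cell_id"].duplicated()
    if dup.any():
        raise CellTableError(f"duplicate cell_id across files: '{cells['cell_id'][dup].iloc[0]}'")
    rois = _build_rois(cells, "/".join(p.name for p in paths))
    cells = cells.drop(columns=[c for c in OPTIONAL_ROI_COLUMNS if c in cells.columns])
    return CellTable(cells=cells, rois=rois, panel=panel, qc=_qc_report(cells, rois))


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table (with per-row ROI geometry) so that it round-trips."""
    df = table.cells.copy()
    for col in ("is_tumour_cell", *table.panel.markers):
        df[col] = df[col].astype(int)
    geo = table.rois.set_index("roi_id")
    df["roi_width_um"] = df["roi_id"].map(geo["width_um"])
    df["roi_height_um"] = df["roi_id"].map(geo["height_um"])
    df["area_tumour_mm2"] = df["roi_id"].map(geo["area_tumour_mm2"])
    df["area_stroma_mm2"] = df["roi_id"].map(geo["area_stroma_mm2"])
    path = Path(path)
    df.to_csv(path, sep=_infer_sep(path), index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-patient clinical table.

    ``response`` may be blank (missing); such patients are excluded from
    response modelling but retained for survival analysis. A derived
    boolean ``responder`` column is added (CR/PR => True, SD/PD => False,
    missing => NA).
    """
    path = Path(path)
    if not path.exists():
        raise CellTableError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_infer_sep(path))
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise CellTableError(f"{path.name}: missing clinical column '{col}'")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["response"] = df["response"].fillna("missing").astype(str)
    bad = ~df["response"].isin(RESPONSE_LEVELS)
    if bad.any():
        raise CellTableError(f"{path.name}: invalid response value {df['response'][bad].iloc[0]!r}")
    dup = df["patient_id"].duplicated()
    if dup.any():
        raise CellTableError(f"{path.name}: duplicate patient_id '{df['patient_id'][dup].iloc[0]}'")
    for col in ("os_event", "iros_event", "irpfs_event"):
        df[col] = df[col].astype(int).astype(bool)
    df["responder"] = pd.array(
        [lvl in RESPONDER_LEVELS if lvl != "missing" else None for lvl in df["response"]],
        dtype="boolean",
    )
    return df


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write a per-patient feature matrix as CSV.

    Missing values are written as empty cells, never as 0, so that the
    missingness contract survives a round-trip.
    """
    path = Path(path)
    features.to_csv(path, index=False, na_rep="")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read back a feature matrix written by :func:`write_features`."""
    path = Path(path)
    if not path.exists():
        raise CellTableError(f"no such file: {path}")
    df = pd.read_csv(path)
    if "patient_id" in df.columns:
        df["patient_id"] = df["patient_id"].astype(str)
    return df
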