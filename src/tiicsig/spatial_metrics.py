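"""Nucleus-to-nucleus distance statistics between immune and tumour cells.

The central quantity is the *effective score*: the fraction of immune
cells of a phenotype with at least one tumour cell within a given radius
(closed interval, d <= r). Counts are pooled over all of a patient's
tumour-core ROIs before the single division, and pairs are never formed
across ROIs. The *effective density* is the absolute number of such
tumour-proximal immune cells per unit area (default radius 20 µm).

Neighbour queries use a KD-tree; tests hold it to exact agreement with
an O(n²) brute force. No edge correction is applied for cells near ROI
borders (matching the upstream analysis; a known bias).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import UndefinedDensityError
from .phenotyping import PhenotypeRegistry, phenotype_matrix

DEFAULT_RADII_UM = (10.0, 20.0, 30.0)
EFFECTIVE_DENSITY_RADIUS_UM = 20.0


@dataclass(frozen=True)
class SpatialResult:
    patient_id: str
    phenotype: str
    radius_um: float
    n_immune: int
    n_paired: int
    area_mm2: float | None = None
    nearest_dist_um: np.ndarray = field(default_factory=lambda: np.array([]), compare=False)

    @property
    def effective_score(self) -> float:
        """n_paired / n_immune; NaN when the patient has no immune cells."""
        if self.n_immune == 0:
            return float("nan")
        return self.n_paired / self.n_immune

    @property
    def effective_density(self) -> float:
        """n_paired per mm² of the pooled ROI area."""
        if self.area_mm2 is None or self.area_mm2 <= 0:
            raise UndefinedDensityError("effective density requires a positive pooled area")
        return self.n_paired / self.area_mm2

    @property
    def nearest_summary(self) -> dict:
        finite = self.nearest_dist_um[np.isfinite(self.nearest_dist_um)]
        if finite.size == 0:
            return {"mean": float("nan"), "median": float("nan"), "n": 0}
        return {"mean": float(finite.mean()), "median": float(np.median(finite)), "n": int(finite.size)}


def pairwise_distances(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between two point sets (µm in, µm out)."""
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if a.size == 0 or b.size == 0:
        return np.empty((a.shape[0], b.shape[0]))
    return cdist(a, b)


def _nearest_per_roi(
    immune: pd.DataFrame, tumour: pd.DataFrame
) -> np.ndarray:
    """Nearest-tumour-cell distance per immune cell (same-ROI pairs only).

    Immune cells in ROIs without any tumour cell get +inf (missing).
    """
    out = np.full(len(immune), np.inf)
    if immune.empty:
        return out
    tumour_by_roi = dict(iter(tumour.groupby("roi_id"))) if not tumour.empty else {}
    pos = 0
    for roi_id, grp in immune.groupby("roi_id", sort=False):
        idx = immune.index.get_indexer(grp.index)
        t = tumour_by_roi.get(roi_id)
        if t is not None and len(t):
            tree = cKDTree(t[["x_um", "y_um"]].to_numpy())
            d, _ = tree.query(grp[["x_um", "y_um"]].to_numpy())
            out[idx] = d
        pos += len(grp)
    return out


def effective_score(
    immune_cells: pd.DataFrame,
    tumour_cells: pd.DataFrame,
    radius_um: float,
    patient_id: str = "",
    phenotype: str = "",
    area_mm2: float | None = None,
) -> SpatialResult:
    """Effective score of one phenotype at one radius, pooled over ROIs.

    ``immune_cells`` / ``tumour_cells`` are frames with ``roi_id``,
    ``x_um``, ``y_um`` already restricted to the ROI set of interest
    (tumour core in the headline analysis). An immune cell is *paired*
    iff a tumour cell of the same ROI lies within ``radius_um``
    (inclusive).
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    nearest = _nearest_per_roi(immune_cells, tumour_cells)
    n_immune = int(len(immune_cells))
    n_paired = int(np.count_nonzero(nearest <= radius_um))
    return SpatialResult(
        patient_id=patient_id,
        phenotype=phenotype,
        radius_um=float(radius_um),
        n_immune=n_immune,
        n_paired=n_paired,
        area_mm2=area_mm2,
        nearest_dist_um=nearest,
    )


def effective_density(
    immune_cells: pd.DataFrame,
    tumour_cells: pd.DataFrame,
    area_mm2: float,
    radius_um: float = EFFECTIVE_DENSITY_RADIUS_UM,
) -> float:
    """Tumour-proximal immune cells per mm² (default 20 µm radius)."""
    if area_mm2 <= 0:
        raise UndefinedDensityError("effective density requires a positive pooled area")
    res = effective_score(immune_cells, tumour_cells, radius_um, area_mm2=area_mm2)
    return res.effective_density


def nearest_tumour_distance(
    immune_cells: pd.DataFrame, tumour_cells: pd.DataFrame
) -> pd.Series:
    """Distance from each immune cell to the closest same-ROI tumour cell.

    NaN where the immune cell's ROI contains no tumour cell.
    """
    d = _nearest_per_roi(immune_cells, tumour_cells)
    return pd.Series(np.where(np.isinf(d), np.nan, d), index=immune_cells.index, name="nearest_dist_um")


def spatial_table(
    cells: pd.DataFrame,
    rois: pd.DataFrame,
    registry: PhenotypeRegistry,
    phenotypes: Iterable[str] | None = None,
    radii_um: Iterable[float] = DEFAULT_RADII_UM,
    roi_class: str = "TC",
) -> pd.DataFrame:
    """Long-format per-patient spatial metrics over phenotypes × radii.

    Effective scores are computed on the tumour-core ROI set by default;
    the pooled area (segmented when available, stamp otherwise) feeds the
    effective density.
    """
    names = [registry.get(p).name for p in phenotypes] if phenotypes else registry.names
    pheno = phenotype_matrix(cells, registry)
    rows = []
    for patient_id in sorted(cells["patient_id"].unique()):
        sel_rois = rois[(rois["patient_id"] == patient_id) & (rois["roi_class"] == roi_class)]
        if sel_rois.empty:
            continue
        seg = sel_rois["area_tumour_mm2"].notna() & sel_rois["area_stroma_mm2"].notna()
        if seg.all():
            area = float((sel_rois["area_tumour_mm2"] + sel_rois["area_stroma_mm2"]).sum())
        else:
            area = float((sel_rois["width_um"] * sel_rois["height_um"]).sum() / 1e6)
        in_rois = cells["roi_id"].isin(sel_rois["roi_id"])
        tumour = cells[in_rois & cells["is_tumour_cell"]]
        for name in names:
            immune = cells[in_rois.to_numpy() & pheno[name].to_numpy()]
            for r in radii_um:
                res = effective_score(immune, tumour, r, patient_id, name, area_mm2=area)
                summ = res.nearest_summary
                rows.append({
                    "patient_id": patient_id,
                    "phenotype": name,
                    "roi_class": roi_class,
                    "radius_um": float(r),
                    "n_immune": res.n_immune,
                    "n_paired": res.n_paired,
                    "effective_score": res.effective_score,
                    "effective_density": res.n_paired / area,
                    "area_mm2": area,
                    "nearest_mean_um": summ["mean"],
                    "nearest_median_um": summ["median"],
                })
    return pd.DataFrame(rows, columns=[
        "patient_id", "phenotype", "roi_class", "radius_um", "n_immune",
        "n_paired", "effective_score", "effective_density", "area_mm2",
        "nearest_mean_um", "nearest_median_um",
    ])
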