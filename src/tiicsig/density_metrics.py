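"""Cell densities per phenotype, ROI class and tissue compartment.

Densities pool counts and areas over all of a patient's ROIs of the
requested class before dividing (cluster-level normalisation), so a
patient with ROIs of unequal area is *not* the mean of per-ROI
densities. The two-thirds dichotomisation used for survival
stratification lives here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, UndefinedDensityError
from .phenotyping import PhenotypeRegistry, phenotype_matrix

COMPARTMENT_CHOICES = ("tumour_nest", "stroma", "all")


@dataclass(frozen=True)
class DensityRecord:
    patient_id: str
    phenotype: str
    roi_class: str
    compartment: str
    count: int
    area_mm2: float
    area_source: str  # "segmented" or "stamp"

    @property
    def density(self) -> float:
        """Cells per mm²."""
        return self.count / self.area_mm2


def _pooled_area(rois: pd.DataFrame, compartment: str) -> tuple[float, str]:
    """Pooled area (mm²) over the given ROI rows for one compartment.

    The "all" compartment uses segmented tumour+stroma area when every
    ROI provides it, falling back to the nominal stamp area otherwise.
    """
    if compartment == "tumour_nest":
        if rois["area_tumour_mm2"].isna().any():
            raise UndefinedDensityError("tumour-nest area missing for one or more ROIs")
        return float(rois["area_tumour_mm2"].sum()), "segmented"
    if compartment == "stroma":
        if rois["area_stroma_mm2"].isna().any():
            raise UndefinedDensityError("stroma area missing for one or more ROIs")
        return float(rois["area_stroma_mm2"].sum()), "segmented"
    if compartment == "all":
        seg = rois["area_tumour_mm2"].notna() & rois["area_stroma_mm2"].notna()
        if seg.all():
            return float((rois["area_tumour_mm2"] + rois["area_stroma_mm2"]).sum()), "segmented"
        return float((rois["width_um"] * rois["height_um"]).sum() / 1e6), "stamp"
    raise ValueError(f"unknown compartment '{compartment}'")


def patient_density(
    cells: pd.DataFrame,
    rois: pd.DataFrame,
    phenotype: str,
    patient_id: str,
    roi_class: str = "TC",
    compartment: str = "all",
    registry: PhenotypeRegistry | None = None,
    phenotype_mask: pd.Series | None = None,
) -> DensityRecord:
    """Density of one phenotype for one patient, pooled over ROIs of a class.

    ``phenotype_mask`` (a boolean Series aligned to ``cells``) may be
    supplied to avoid recomputing rule matches; otherwise the registry
    (default registry when omitted) resolves ``phenotype``.
    """
    sel_rois = rois[(rois["patient_id"] == patient_id) & (rois["roi_class"] == roi_class)]
    if sel_rois.empty:
        raise UndefinedDensityError(
            f"patient '{patient_id}' has no ROI of class '{roi_class}'"
        )
    area, area_source = _pooled_area(sel_rois, compartment)
    if area <= 0:
        raise UndefinedDensityError(
            f"pooled {compartment} area is zero for patient '{patient_id}' / {roi_class}"
        )

    if phenotype_mask is None:
        from .phenotyping import default_registry

        registry = registry or default_registry()
        rule = registry.get(phenotype)
        single = PhenotypeRegistry([rule])
        phenotype_mask = phenotype_matrix(cells, single)[rule.name]
        phenotype = rule.name

    in_rois = cells["roi_id"].isin(sel_rois["roi_id"])
    mask = phenotype_mask.to_numpy() & in_rois.to_numpy()
    if compartment != "all":
        mask &= (cells["compartment"] == compartment).to_numpy()
    return DensityRecord(
        patient_id=patient_id,
        phenotype=phenotype,
        roi_class=roi_class,
        compartment=compartment,
        count=int(mask.sum()),
        area_mm2=area,
        area_source=area_source,
    )


def density_table(
    cells: pd.DataFrame,
    rois: pd.DataFrame,
    registry: PhenotypeRegistry,
    phenotypes: Iterable[str] | None = None,
    roi_classes: Iterable[str] = ("TC", "IM", "N"),
    compartments: Iterable[str] = ("all",),
) -> pd.DataFrame:
    """Long-format density table over patients × phenotypes × regions."""
    names = [registry.get(p).name for p in phenotypes] if phenotypes else registry.names
    pheno = phenotype_matrix(cells, registry)
    rows = []
    for patient_id in sorted(cells["patient_id"].unique()):
        for roi_class in roi_classes:
            has_roi = (
                (rois["patient_id"] == patient_id) & (rois["roi_class"] == roi_class)
            ).any()
            if not has_roi:
                continue
            for compartment in compartments:
                for name in names:
                    rec = patient_density(
                        cells, rois, name, patient_id, roi_class, compartment,
                        phenotype_mask=pheno[name],
                    )
                    rows.append({
                        "patient_id": rec.patient_id,
                        "phenotype": rec.phenotype,
                        "roi_class": rec.roi_class,
                        "compartment": rec.compartment,
                        "count": rec.count,
                        "area_mm2": rec.area_mm2,
                        "density": rec.density,
                        "area_source": rec.area_source,
                    })
    return pd.DataFrame(rows, columns=[
        "patient_id", "phenotype", "roi_class", "compartment",
        "count", "area_mm2", "density", "area_source",
    ])


def dichotomise_tertile(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Split patients at the empirical two-thirds quantile.

    Patients strictly above the type-1 (inverse-CDF) two-thirds order
    statistic are "high"; everyone else — including ties at the
    threshold — is "low". Missing values stay missing.
    """
    s = pd.Series(values, dtype=float)
    obs = s.dropna()
    if len(obs) < 3:
        raise DegenerateDataError("tertile split needs >= 3 non-missing values")
    order = np.sort(obs.to_numpy())
    threshold = order[math.ceil(2 * len(order) / 3) - 1]
    out = pd.Series(pd.NA, index=s.index, dtype=object)
    out[obs.index] = np.where(obs > threshold, "high", "low")
    return out
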