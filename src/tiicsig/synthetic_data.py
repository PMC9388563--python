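"""Synthetic studies with known ground truth.

Generates complete cohorts — spatial cell patterns per ROI plus clinical
tables — in the exact formats the IO layer consumes. Tumour cells follow
a Poisson or Thomas (parent–offspring) process; immune cells are Poisson
with an optional tumour-proximity bias: a fraction ``beta`` of each
population is displaced to within ``r0`` of a random tumour cell, which
makes the true effective score directly controllable. Marker states are
drawn from full-sign population signatures so the phenotyping rules
recover the generating label exactly.

Responder labels come from a logistic model on the realised (z-scaled)
signature features; survival times are exponential with per-feature
log-hazard-ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cell_table_io import (
    DEFAULT_FIELD_HEIGHT_UM,
    DEFAULT_FIELD_WIDTH_UM,
    DEFAULT_MARKERS,
    CellTable,
    PanelConfig,
    _qc_report,
    write_cell_table,
)
from .cohort_stats import compute_cps
from .signature import SIGNATURE_FEATURES, compute_signature_inputs


@dataclass(frozen=True)
class PopulationSpec:
    """One generating immune population: signature + placement behaviour."""

    markers: dict[str, int]            # full-sign over its panel; omitted markers are 0
    intensity: dict[str, float]        # cells/mm² per ROI class
    beta: float = 0.0                  # fraction displaced to within r0 of a tumour cell


def default_populations() -> dict[str, PopulationSpec]:
    """A compact population set covering the four signature components."""

    def tc(v, im=None, n=None):
        return {"TC": v, "IM": im if im is not None else v * 1.2, "N": n if n is not None else v * 0.5}

    return {
        "cd8_pd1neg_lag3neg": PopulationSpec(
            {"CD8": 1, "PD-1": 0, "LAG-3": 0, "TIM-3": 0}, tc(60.0), beta=0.1),
        "cd8_pd1pos_lag3neg": PopulationSpec(
            {"CD8": 1, "PD-1": 1, "LAG-3": 0, "TIM-3": 0}, tc(40.0, 30.0, 10.0), beta=0.4),
        "cd8_pd1pos_lag3pos_tim3pos": PopulationSpec(
            {"CD8": 1, "PD-1": 1, "LAG-3": 1, "TIM-3": 1}, tc(15.0, 10.0, 2.0), beta=0.5),
        "cd4_foxp3neg_pdl1pos": PopulationSpec(
            {"CD4": 1, "FoxP3": 0, "PD-L1": 1, "CTLA-4": 0}, tc(30.0), beta=0.2),
        "cd4_foxp3pos_ctla4pos": PopulationSpec(
            {"CD4": 1, "FoxP3": 1, "CTLA-4": 1, "PD-L1": 0}, tc(20.0, 12.0, 5.0), beta=0.3),
        "cd68_stingpos": PopulationSpec(
            {"CD68": 1, "STING": 1, "CD163": 0, "HLA-DR": 0}, tc(25.0), beta=0.4),
        "m_cd163": PopulationSpec(
            {"CD68": 1, "CD163": 1, "HLA-DR": 0, "STING": 0}, tc(20.0)),
        "m_hladr": PopulationSpec(
            {"CD68": 1, "HLA-DR": 1, "CD163": 0, "STING": 0}, tc(15.0)),
        "b_cells": PopulationSpec({"CD20": 1}, tc(25.0, 40.0, 30.0)),
        "neutrophils": PopulationSpec({"CD66b": 1}, tc(15.0), beta=0.5),
    }


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 20
    rois_per_patient: dict[str, int] = field(
        default_factory=lambda: {"TC": 3, "IM": 1, "N": 1})
    width_um: float = DEFAULT_FIELD_WIDTH_UM
    height_um: float = DEFAULT_FIELD_HEIGHT_UM
    tumour_intensity: dict[str, float] = field(
        default_factory=lambda: {"TC": 400.0, "IM": 150.0, "N": 0.0})
    populations: dict[str, PopulationSpec] = field(default_factory=default_populations)
    clustering: str = "poisson"        # "poisson" | "thomas"
    thomas_parent_intensity: float = 20.0   # parents/mm²
    thomas_sigma_um: float = 40.0
    r0_um: float = 20.0
    nest_area_fraction: float = 0.4
    p_nest: float = 0.3                # immune cells in the tumour nest
    tumour_pdl1_prob: float = 0.3
    #: logistic response model on z-scaled signature features
    response_intercept: float = -0.7
    response_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "d_cd4_foxp3neg_pdl1pos": 0.8,
            "d_cd8_pd1neg_lag3neg": -0.6,
            "d_cd68_stingpos": -0.8,
            "es_cd8_pd1pos_lag3neg": 1.2,
        })
    #: exponential survival model (per-month baseline; log-HRs on z-scaled features)
    baseline_rate: float = 1.0 / 24.0
    log_hrs: dict[str, float] = field(
        default_factory=lambda: {
            "d_cd4_foxp3neg_pdl1pos": -0.2,
            "d_cd8_pd1neg_lag3neg": -0.1,
            "d_cd68_stingpos": 0.5,
            "es_cd8_pd1pos_lag3neg": -0.3,
        })
    censor_months: float = 48.0
    ebv_pos_rate: float = 0.15
    dmmr_rate: float = 0.14
    training_fraction: float = 0.73
    seed: int = 0

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


@dataclass
class SyntheticStudy:
    table: CellTable
    clinical: pd.DataFrame
    features: pd.DataFrame
    truth: dict


def _poisson_points(rng, intensity_per_mm2, width_um, height_um) -> np.ndarray:
    n = rng.poisson(intensity_per_mm2 * width_um * height_um / 1e6)
    xy = np.empty((n, 2))
    xy[:, 0] = rng.uniform(0, width_um, n)
    xy[:, 1] = rng.uniform(0, height_um, n)
    return xy


def _thomas_points(rng, intensity_per_mm2, cfg: SimulationConfig) -> np.ndarray:
    """Parent–offspring clustered pattern with the requested mean intensity."""
    area = cfg.area_mm2
    n_parents = rng.poisson(cfg.thomas_parent_intensity * area)
    if n_parents == 0:
        return np.empty((0, 2))
    mean_offspring = intensity_per_mm2 / cfg.thomas_parent_intensity
    parents = np.column_stack([
        rng.uniform(0, cfg.width_um, n_parents),
        rng.uniform(0, cfg.height_um, n_parents),
    ])
    counts = rng.poisson(mean_offspring, n_parents)
    pts = np.repeat(parents, counts, axis=0)
    pts = pts + rng.normal(0, cfg.thomas_sigma_um, pts.shape)
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= cfg.width_um)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= cfg.height_um)
    )
    return pts[inside]


def _displace_near_tumour(rng, xy, tumour_xy, beta, r0, width_um, height_um) -> np.ndarray:
    """Move a Bernoulli(beta) subset to uniform positions in a tumour-centred disk."""
    if beta <= 0 or len(tumour_xy) == 0 or len(xy) == 0:
        return xy
    xy = xy.copy()
    move = rng.random(len(xy)) < beta
    for i in np.flatnonzero(move):
        for _ in range(100):
            centre = tumour_xy[rng.integers(len(tumour_xy))]
            r = r0 * np.sqrt(rng.random())
            theta = rng.uniform(0, 2 * np.pi)
            cand = centre + [r * np.cos(theta), r * np.sin(theta)]
            if 0 <= cand[0] <= width_um and 0 <= cand[1] <= height_um:
                xy[i] = cand
                break
    return xy


def simulate_roi(
    cfg: SimulationConfig,
    roi_class: str,
    rng: np.random.Generator,
    patient_id: str = "p0",
    roi_id: str = "p0-TC-0",
) -> pd.DataFrame:
    """One field's worth of cell rows (tumour + immune) with ROI geometry."""
    lam_t = cfg.tumour_intensity.get(roi_class, 0.0)
    if cfg.clustering == "thomas":
        tumour_xy = _thomas_points(rng, lam_t, cfg)
    elif cfg.clustering == "poisson":
        tumour_xy = _poisson_points(rng, lam_t, cfg.width_um, cfg.height_um)
    else:
        raise ValueError(f"unknown clustering '{cfg.clustering}'")

    marker_zero = {m: 0 for m in DEFAULT_MARKERS}
    rows: list[dict] = []

    def base_row(x, y, compartment):
        return {
            "patient_id": patient_id, "roi_id": roi_id, "roi_class": roi_class,
            "compartment": compartment, "x_um": float(x), "y_um": float(y),
            "roi_width_um": cfg.width_um, "roi_height_um": cfg.height_um,
            "area_tumour_mm2": cfg.nest_area_fraction * cfg.area_mm2,
            "area_stroma_mm2": (1 - cfg.nest_area_fraction) * cfg.area_mm2,
        }

    for x, y in tumour_xy:
        row = base_row(x, y, "tumour_nest")
        row.update(marker_zero)
        row["PD-L1"] = int(rng.random() < cfg.tumour_pdl1_prob)
        row["is_tumour_cell"] = 1
        rows.append(row)

    for name, pop in cfg.populations.items():
        lam = pop.intensity.get(roi_class, 0.0)
        xy = _poisson_points(rng, lam, cfg.width_um, cfg.height_um)
        xy = _displace_near_tumour(
            rng, xy, tumour_xy, pop.beta, cfg.r0_um, cfg.width_um, cfg.height_um)
        nest = rng.random(len(xy)) < cfg.p_nest
        for (x, y), in_nest in zip(xy, nest):
            row = base_row(x, y, "tumour_nest" if in_nest else "stroma")
            row.update(marker_zero)
            row.update(pop.markers)
            row["is_tumour_cell"] = 0
            rows.append(row)

    df = pd.DataFrame(rows)
    if not df.empty:
        df.insert(0, "cell_id", [f"{roi_id}:c{i}" for i in range(len(df))])
    return df


def _to_cell_table(frames: list[pd.DataFrame]) -> CellTable:
    panel = PanelConfig()
    cells = pd.concat([f for f in frames if not f.empty], ignore_index=True)
    for col in ("is_tumour_cell", *panel.markers):
        cells[col] = cells[col].astype(bool)
    roi_rows = (
        cells.groupby("roi_id", sort=True)
        .agg(
            patient_id=("patient_id", "first"),
            roi_class=("roi_class", "first"),
            width_um=("roi_width_um", "first"),
            height_um=("roi_height_um", "first"),
            area_tumour_mm2=("area_tumour_mm2", "first"),
            area_stroma_mm2=("area_stroma_mm2", "first"),
        )
        .reset_index()
    )
    cells = cells.drop(columns=[
        "roi_width_um", "roi_height_um", "area_tumour_mm2", "area_stroma_mm2"])
    return CellTable(cells=cells, rois=roi_rows, panel=panel, qc=_qc_report(cells, roi_rows))


def simulate_cohort(cfg: SimulationConfig) -> SyntheticStudy:
    """Full study: cells, realised features, clinical covariates, outcomes."""
    rng = np.random.default_rng(cfg.seed)
    frames = []
    patients = [f"p{i:03d}" for i in range(cfg.n_patients)]
    for pid in patients:
        for roi_class, count in cfg.rois_per_patient.items():
            for k in range(count):
                roi_id = f"{pid}-{roi_class}-{k}"
                frames.append(simulate_roi(cfg, roi_class, rng, pid, roi_id))
    table = _to_cell_table(frames)

    features = compute_signature_inputs(table).set_index("patient_id")
    feats = features[list(SIGNATURE_FEATURES)].astype(float)
    mu, sd = feats.mean(), feats.std(ddof=0).replace(0, 1.0)
    z = ((feats - mu) / sd).fillna(0.0)

    logit = cfg.response_intercept + sum(
        cfg.response_coefs.get(f, 0.0) * z[f] for f in z.columns)
    p_resp = 1 / (1 + np.exp(-logit))
    responder = rng.random(cfg.n_patients) < p_resp
    response = np.where(
        responder, rng.choice(["CR", "PR"], cfg.n_patients),
        rng.choice(["SD", "PD"], cfg.n_patients))

    log_rate = np.log(cfg.baseline_rate) + sum(
        cfg.log_hrs.get(f, 0.0) * z[f] for f in z.columns)
    rate = np.exp(log_rate.to_numpy())

    def draw_survival(scale=1.0):
        t = rng.exponential(1 / (rate * scale))
        c = rng.uniform(cfg.censor_months * 0.25, cfg.censor_months, size=len(rate))
        event = t <= c
        return np.minimum(t, c).round(3) + 0.001, event

    os_t, os_e = draw_survival()
    iros_t, iros_e = draw_survival(1.2)
    irpfs_t, irpfs_e = draw_survival(2.0)

    cps_values = []
    for pid in patients:
        tc_rois = table.rois.loc[table.rois["patient_id"] == pid].query("roi_class == 'TC'")
        sub = table.cells[table.cells["roi_id"].isin(tc_rois["roi_id"])]
        cps_values.append(round(compute_cps(sub)[0], 1))

    n_train = int(round(cfg.training_fraction * cfg.n_patients))
    clinical = pd.DataFrame({
        "patient_id": patients,
        "ebv": np.where(rng.random(cfg.n_patients) < cfg.ebv_pos_rate, "pos", "neg"),
        "mmr": np.where(rng.random(cfg.n_patients) < cfg.dmmr_rate, "dMMR", "pMMR"),
        "cps": cps_values,
        "her2": np.where(rng.random(cfg.n_patients) < 0.25, "pos", "neg"),
        "response": response,
        "os_months": os_t, "os_event": os_e.astype(int),
        "iros_months": iros_t, "iros_event": iros_e.astype(int),
        "irpfs_months": irpfs_t, "irpfs_event": irpfs_e.astype(int),
        "cohort": ["training"] * n_train + ["validation"] * (cfg.n_patients - n_train),
    })
    truth = {
        "z_features": z,
        "response_probability": pd.Series(p_resp, index=feats.index),
        "hazard_rate": pd.Series(rate, index=feats.index),
        "config": cfg,
    }
    return SyntheticStudy(
        table=table, clinical=clinical, features=features.reset_index(), truth=truth)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write cells.csv + clinical.csv in the formats the IO layer reads."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells_path = outdir / "cells.csv"
    clinical_path = outdir / "clinical.csv"
    write_cell_table(study.table, cells_path)
    study.clinical.to_csv(clinical_path, index=False)
    return {"cells": str(cells_path), "clinical": str(clinical_path)}
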