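"""The 4-feature immune signature and the HR-weighted prognostic score.

The signature couples three densities (CD4+FoxP3−PD-L1+ T cells,
CD8+PD-1−LAG-3− T cells, CD68+STING+ macrophages) with one spatial
feature (effective score of CD8+PD-1+LAG-3− T cells; radius
configurable, default 20 µm). The combined form appends EBV status,
MMR status and PD-L1 CPS.

The prognostic score weights each signature feature by its univariate
Cox hazard ratio on its raw scale and splits patients at the cohort
median (cut-point configurable; the originating analysis does not state
one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_table_io import CellTable
from .density_metrics import density_table
from .errors import ConfigurationError, DegenerateDataError
from .phenotyping import PhenotypeRegistry, default_registry
from .spatial_metrics import spatial_table
from .survival_stats import cox_fit

#: Canonical feature order: column name -> (source metric, phenotype).
SIGNATURE_FEATURES: dict[str, tuple[str, str]] = {
    "d_cd4_foxp3neg_pdl1pos": ("density", "CD4+FoxP3−PD-L1+"),
    "d_cd8_pd1neg_lag3neg": ("density", "CD8+PD-1−LAG-3−"),
    "d_cd68_stingpos": ("density", "CD68+STING+"),
    "es_cd8_pd1pos_lag3neg": ("effective_score", "CD8+PD-1+LAG-3−"),
}
COMBINED_EXTRAS = ("ebv", "mmr", "cps")

DEFAULT_SIGNATURE_RADIUS_UM = 20.0


@dataclass
class PrognosticScore:
    weights: dict[str, float]             # feature -> hazard ratio
    scores: pd.Series                     # patient -> weighted sum
    groups: pd.Series                     # patient -> {"high", "low"}
    cut_value: float


def compute_signature_inputs(
    table: CellTable,
    registry: PhenotypeRegistry | None = None,
    radius_um: float = DEFAULT_SIGNATURE_RADIUS_UM,
) -> pd.DataFrame:
    """Per-patient signature inputs straight from a cell table.

    Densities are tumour-core, all-compartment, in cells/mm²; the
    spatial feature is the tumour-core effective score at ``radius_um``.
    """
    registry = registry or default_registry()
    phenos = [p for _, (_, p) in SIGNATURE_FEATURES.items()]
    dens = density_table(
        table.cells, table.rois, registry,
        phenotypes=[p for k, (m, p) in SIGNATURE_FEATURES.items() if m == "density"],
        roi_classes=("TC",), compartments=("all",),
    )
    spat = spatial_table(
        table.cells, table.rois, registry,
        phenotypes=[p for k, (m, p) in SIGNATURE_FEATURES.items() if m == "effective_score"],
        radii_um=(radius_um,), roi_class="TC",
    )
    patients = sorted(table.cells["patient_id"].unique())
    out = pd.DataFrame({"patient_id": patients}).set_index("patient_id")
    for col, (metric, pheno) in SIGNATURE_FEATURES.items():
        canon = registry.get(pheno).name
        if metric == "density":
            sub = dens[dens["phenotype"] == canon].set_index("patient_id")["density"]
        else:
            sub = spat[spat["phenotype"] == canon].set_index("patient_id")["effective_score"]
        out[col] = sub
    return out.reset_index()


def build_signature(
    patient_features: pd.DataFrame,
    combined: bool = False,
    clinical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the signature matrix in canonical column order.

    ``patient_features`` must carry ``patient_id`` plus the four core
    columns. With ``combined=True``, EBV/MMR are encoded {0,1}
    (positive / dMMR = 1) and CPS is numeric, pulled from ``clinical``.
    A boolean ``complete`` column marks patients with no missing entry.
    """
    missing_cols = [c for c in SIGNATURE_FEATURES if c not in patient_features.columns]
    if missing_cols:
        raise ConfigurationError(f"missing signature feature columns: {missing_cols}")
    cols = ["patient_id", *SIGNATURE_FEATURES]
    sig = patient_features[cols].copy()
    feature_cols = list(SIGNATURE_FEATURES)
    if combined:
        if clinical is None:
            raise ConfigurationError("combined signature requires the clinical table")
        clin = clinical.set_index("patient_id")
        sig = sig.set_index("patient_id")
        sig["ebv"] = (clin["ebv"] == "pos").astype(float)
        sig["mmr"] = (clin["mmr"] == "dMMR").astype(float)
        sig["cps"] = clin["cps"].astype(float)
        sig = sig.reset_index()
        feature_cols += list(COMBINED_EXTRAS)
    sig["complete"] = sig[feature_cols].notna().all(axis=1)
    return sig


def prognostic_score(
    signature: pd.DataFrame,
    survival: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    cut: str | float = "median",
    z_scale: bool = False,
) -> PrognosticScore:
    """HR-weighted sum of the four signature features with high/low split.

    Each feature's weight is its univariate Cox hazard ratio fitted on
    the supplied cohort; the score is Σ HRᵢ·xᵢ on raw feature scales
    (``z_scale=True`` standardises features first). ``cut`` is "median"
    or an explicit numeric cut-point; scores strictly above it are
    "high".
    """
    feats = list(SIGNATURE_FEATURES)
    df = signature.set_index("patient_id")[feats].astype(float)
    if df.isna().any().any():
        df = df.dropna()
    if df.empty:
        raise DegenerateDataError("no complete signature vectors")
    surv = survival.set_index("patient_id").loc[df.index]
    if z_scale:
        df = (df - df.mean()) / df.std(ddof=1)
    fit_frame = df.copy()
    fit_frame["time"] = surv[time_col].astype(float)
    fit_frame["event"] = surv[event_col].astype(bool)
    univ = cox_fit(fit_frame, feats, adjustment="univariate")
    weights = {f: float(univ.loc[f, "hr"]) for f in feats}
    scores = sum(weights[f] * df[f] for f in feats)
    scores.name = "score"
    cut_value = float(scores.median()) if cut == "median" else float(cut)
    groups = pd.Series(np.where(scores > cut_value, "high", "low"), index=scores.index, name="group")
    return PrognosticScore(weights=weights, scores=scores, groups=groups, cut_value=cut_value)


def score_with_weights(signature: pd.DataFrame, weights: dict[str, float]) -> pd.Series:
    """Apply fixed feature weights (e.g. fitted on the training cohort)."""
    feats = list(SIGNATURE_FEATURES)
    df = signature.set_index("patient_id")[feats].astype(float)
    s = sum(float(weights[f]) * df[f] for f in feats)
    s.name = "score"
    return s
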