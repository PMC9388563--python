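# tiicsig

Multi-dimensional analysis of tumour-infiltrating immune cells (TIICs) in
multiplex-IHC data: single-cell phenotyping from binarised marker panels,
region-resolved density metrics, nucleus-to-nucleus spatial statistics
(effective score / effective density / nearest-tumour distance), a
4-feature immune signature with multi-classifier response prediction, an
HR-weighted prognostic score, and the accompanying survival and cohort
statistics. A synthetic-data generator produces complete studies with
known ground truth in the exact input formats, so the whole pipeline is
testable without any external data.

## Package layout

| module | role |
| --- | --- |
| `tiicsig.cell_table_io` | read/validate/write per-cell, ROI and clinical tables |
| `tiicsig.phenotyping` | boolean marker rule registry; population assignment |
| `tiicsig.density_metrics` | pooled densities per phenotype/region/compartment; two-thirds split |
| `tiicsig.spatial_metrics` | effective score (radii 10/20/30 µm), effective density (20 µm), nearest-tumour distance |
| `tiicsig.signature` | 4-feature signature assembly; HR-weighted prognostic score |
| `tiicsig.response_models` | univariate screening; repeated stratified 3-fold CV harness for ETC/GBC/ABC/MLP |
| `tiicsig.survival_stats` | Kaplan–Meier, log-rank, Cox (Efron ties), PH time-interaction check |
| `tiicsig.cohort_stats` | uncorrected Pearson chi-square, Mann–Whitney, Kruskal–Wallis + Dunn, CPS, reproducibility CV |
| `tiicsig.synthetic_data` | Poisson/Thomas point patterns with planted response and survival effects |
| `tiicsig.cli` | `tiicsig` command chaining all stages with manifests |

## CLI

```bash
# simulate a study, then run every stage end-to-end
tiicsig run-all --patients 20 --seed 1 --out runs/demo

# or stage by stage
tiicsig simulate  --patients 20 --seed 1 --out runs/demo
tiicsig phenotype --cells runs/demo/cells.csv --out runs/demo/phenotype_counts.csv
tiicsig density   --cells runs/demo/cells.csv --out runs/demo/density.csv
tiicsig spatial   --cells runs/demo/cells.csv --out runs/demo/spatial.csv
tiicsig signature --cells runs/demo/cells.csv --clinical runs/demo/clinical.csv \
                  --out runs/demo/signature.csv
tiicsig predict   --signature runs/demo/signature.csv --clinical runs/demo/clinical.csv \
                  --fast --out runs/demo/predict.json
tiicsig survive   --signature runs/demo/signature.csv --clinical runs/demo/clinical.csv \
                  --endpoint irpfs --out runs/demo/survival.json
tiicsig stats     --table contingency.csv --out chi2.json
```

Defaults (radii, folds, repetition counts, split rules) are declared in
`src/tiicsig/data/default_config.yaml`; pass `--config your.yaml` to
override. Every run writes a `manifest.json` (config hash, seed, output
hashes) and is byte-reproducible for a fixed seed.

## Input format

Per-cell tables are CSV/TSV with columns `cell_id, patient_id, roi_id,
roi_class (TC|IM|N), compartment (tumour_nest|stroma), x_um, y_um,
is_tumour_cell` plus one 0/1 column per panel marker, and optional ROI
geometry columns (`roi_width_um, roi_height_um, area_tumour_mm2,
area_stroma_mm2`; the stamp default is 930 × 700 µm). Clinical tables
carry EBV/MMR/CPS/HER2, RECIST response, and OS/irOS/irPFS times and
event flags. `tiicsig simulate` emits both formats.
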