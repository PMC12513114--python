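# immunoprox

Spatial proximity analysis of the tumor-immune microenvironment from
multiplex immunohistochemistry (mIHC) cell tables, with a survival-linked
synthetic cohort generator for validation and power studies.

## The problem

In many solid tumors — hepatocellular carcinoma prominently among them —
PD-L1–expressing tumor-associated macrophages (TAMs) sit close to CD8+
T cells and are suspected of driving them into exhaustion. mIHC platforms
(Opal staining, inForm-style segmentation) reduce each imaged tissue field to
a table of cells with x/y centroids in µm and per-marker intensities. The
scientific question is whether the *spatial proximity* of two phenotype
populations — not merely their abundance — carries prognostic information.

`immunoprox` turns those per-cell tables into patient-level prognosis
analyses:

1. **Phenotype gating** — threshold rules on marker intensities
   (CD3+CD8+ → CD8 T cell; CD68+CD163+ → TAM; + PD-L1 positivity → the
   PD-L1+ TAM anchor population).
2. **Interaction variable** — per image, for a counted population A and an
   anchor population B:

   `value = 100 · #{a ∈ A : min_b ||a − b|| ≤ r} / (n_A + n_B)`,  r = 25 µm,

   i.e. the count of A-cells with at least one anchor within r, normalised by
   the combined population size so that abundance alone does not inflate the
   statistic. Radial profiles bin the nearest-anchor distances at 5 µm
   intervals.
3. **Clinical scores** — IHC H-score (1·%weak + 2·%moderate + 3·%strong) and
   the albumin–bilirubin score `ALBI = 0.66·log10(bil µmol/L) − 0.085·alb g/L`
   with standard and modified (2a/2b split at −2.270) grading.
4. **Survival analysis** — per tissue region (tumor T, subcapsular SC,
   peritumoral stroma PS, adjacent normal A), patients are split at the
   median interaction value (≥ median → "high"); Kaplan–Meier curves and the
   log-rank test compare the groups, and a univariate Cox screen (p < 0.05)
   feeds a multivariate Cox proportional-hazards model.
5. **Synthetic cohorts** — a Thomas-style cluster process with a tunable
   CD8→TAM attraction, lognormal marker intensities, and exponential event
   times whose hazard is `λ0·exp(β·z)` in the standardised patient-level
   interaction value, for calibration, oracle testing and power studies.

## Worked example

```python
import numpy as np
from immunoprox import SpatialParams, interaction_variable, radial_profile

anchors = np.array([[0.0, 0.0], [100.0, 0.0]])           # PD-L1+ TAMs
tcells  = np.array([[10.0, 0.0], [30.0, 0.0],
                    [90.0, 0.0], [200.0, 0.0]])          # CD8+ T cells

res = interaction_variable(tcells, anchors, SpatialParams(radius_r=25))
print(res.k, round(res.value, 2))        # 2 33.33
prof = radial_profile(tcells, anchors)
print(prof.counts, prof.cumulative_fraction(25.0))  # [0 0 2 0 0] 0.5
```

Two of the four T cells have an anchor within 25 µm (distances 10, 30, 10,
100 µm), so the interaction value is 100·2/(4+2) = 33.33; both fall in the
[10, 15) µm bin and half of the counted population lies within 25 µm.

An end-to-end run on a synthetic cohort:

```bash
immunoprox simulate --out sim --seed 4 --n-patients 40
immunoprox validate --cells sim/cells.csv --clinical sim/clinical.csv
immunoprox run --cells sim/cells.csv --clinical sim/clinical.csv \
    --out run --seed 4 --endpoint RFS
immunoprox report --out run
```

which writes per-image interaction tables, per-patient values, high/low
groups, Kaplan–Meier step tables, log-rank summaries, the
univariate/multivariate Cox tables and a reproducibility manifest; a typical
run prints e.g.

```
log-rank RFS_T: chi2=3.402 p=0.0651 (high n=20, low n=20)
screen RFS: selected []
```

(at n = 40 the median-split comparison is underpowered; the power study
below quantifies this at n = 200).

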