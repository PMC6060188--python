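# flucipet

Semiquantitative analysis of **dynamic fluciclovine (anti-[18F]FACBC) brain
PET** for glioma grading, driven by a synthetic 4D phantom generator so the
whole chain runs — and is tested — without patient data.

Amino-acid PET tracers accumulate in gliomas well above normal parenchyma.
Given a dynamic acquisition (15 frames: 6 × 30 s, 4 × 180 s, 5 × 600 s,
ending at 65 min), the package measures, per lesion and per frame:

- **SUV_max** — hottest voxel in a spherical search ROI over the lesion;
- **background** — mean SUV in a 15-mm sphere mirrored to the contralateral
  hemisphere;
- **metabolically active tumor** at minimum thresholds k × background,
  k ∈ {1.3, 1.6, 1.9};
- **TB_max = SUV_max / SUV_mean(background)** and
  **TB_mean_k = SUV_mean(tumor, k) / SUV_mean(background)**.

From these it assesses time-activity-curve **equilibrium** over the 30–60
min window (unbalanced two-way ANOVA, type-II sums of squares, Tukey HSD
within groups), derives **ROC cutoffs** separating high-grade (WHO III–IV)
from low-grade (WHO II) glioma (trapezoidal AUC = Mann–Whitney concordance;
Youden-optimal threshold, ties broken toward sensitivity), runs **Welch
t-tests** of WHO II vs IV uptake, correlates uptake with the **Ki-67**
proliferation index (Pearson r, zero-slope p), and ranks the four metrics'
relevance by **lasso-regularized logistic regression** with a
cross-validated (1-SE) penalty.

Intended for researchers in PET quantification who need a fully specified,
reproducible reference implementation of this analysis style, with every
stage calibrated on phantoms with known ground truth.

## Worked example

Run the end-to-end demo — simulate an 18-lesion synthetic cohort (12 HGG,
6 LGG), segment and measure every scan, then run the TAC, ROC, correlation
and relevance analyses:

```sh
flucipet demo --seed 1 --out out/
```

which prints (abridged from `out/summary.txt`):

```
flucipet pipeline summary
seed=1  lesions: 12 HGG + 6 LGG  metric rows: 265
equilibrium window starts at 30 min; alpha=0.05

Plateau (no significant within-group Tukey pair):
  HGG: True
  LGG: True
  normal: True
  venous: True

ROC (HGG positive, pooled equilibrium observations):
  parameter  threshold  sensitivity_pct  specificity_pct    auc
    suv_max     3.2295            100.0             86.4 0.9828
tb_mean_1.3     1.7617            100.0             86.4 0.9818
tb_mean_1.6     2.3476             84.4            100.0 0.9753
tb_mean_1.9     2.4138             84.4            100.0 0.9533

Ki-67 correlation at 30 min:
  suv_max: r=0.722 p=0.008 n=12
  tb_mean_1.3: r=0.788 p=0.0023 n=12
```

Reading this: all four tissue groups show TAC flattening over 30–60 min
(tracer influx/efflux equilibrium), so pooling late frames is justified;
every uptake metric separates high- from low-grade lesions with AUC > 0.95
on this cohort, with the Youden-optimal TB_mean_1.3 cutoff at 1.76
(sensitivity 100%, specificity 86%); and uptake correlates strongly with
the Ki-67 proliferation index (r ≈ 0.79 for TB_mean_1.3, n = 12 evaluable
lesions). 265 metric rows rather than 18 × 15 = 270 reflects simulated
patient attrition (scans stopped before the 60-min frame).

The same stages are available individually (`flucipet simulate | segment |
tac | discriminate | correlate`) and as library calls:

```python
from flucipet import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(n_hgg=12, n_lgg=6), "out/", seed=1)
res["roc_table"]          # Table-2-style parameter/threshold/sens/spec/AUC
res["equilibrium"].plateau
```

`docs/methods.md` documents the phantom model, the measurement conventions,
the statistical procedures and their calibration, and known limitations.

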