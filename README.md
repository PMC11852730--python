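# parotid-radiomics

MRI-radiomics pipeline for discriminating **Warthin's tumors (WT)** from
**malignant tumors (MT)** of the parotid gland on paired T2-weighted and
ADC-map volumes. Warthin's tumors are benign but mimic malignancy on
imaging (low ADC, heterogeneous texture), so the two entities overlap on
conventional multiparametric MRI; quantitative texture analysis of the
whole 3D lesion is a candidate non-invasive discriminator.

The package implements the full analysis chain as a tested library:

1. **Synthetic cohort generator** — class-conditional Gaussian-random-field
   lesions (66 WT + 40 MT by default, diameters > 1 cm, some patients with
   multiple lesions) with paired T2-like/ADC-like volumes sharing one
   segmentation mask, plus perturbed re-segmentations for stability testing.
2. **Preprocessing** — polynomial bias-field correction, whole-image
   z-score normalization, μ±3σ outlier voxel removal, isotropic 1 mm³
   B-spline resampling, fixed-bin-width (W = 25) gray-level discretization.
3. **Filter bank** — 8 sub-bands of a level-1 undecimated 3D wavelet
   transform (Coiflet-1) and Laplacian-of-Gaussian responses at σ = 3 and
   5 mm.
4. **Feature extraction** — 1037 features per sequence: 14 shape +
   93 intensity/texture features (18 first-order, 24 GLCM, 16 GLRLM,
   16 GLSZM, 14 GLDM, 5 NGTDM) on each of the 11 images (original +
   8 wavelet + 2 LoG); 2074 per lesion over both sequences.
5. **Feature-reduction cascade** — ICC(A,1) stability gate (> 0.85) on
   re-segmented lesions; Mann–Whitney U screen with Benjamini–Hochberg
   adjustment (q < 0.05); Spearman redundancy pruning (|ρ| > 0.9, the
   higher-p member of each pair eliminated); LASSO logistic regression
   with λ chosen by minimum 10-fold cross-validated binomial deviance.
6. **Radiomic Score & evaluation** — the linear score

   *Radiomic Score = I + Σ_y C_y · V_y*

   over the selected z-standardized features (WT scores high), evaluated
   on a class-stratified train/test split with ROC/AUC (DeLong CIs),
   Youden-J cut-off, sensitivity/specificity (Clopper–Pearson CIs) and
   likelihood ratios (log-method CIs), with MT as the positive class.

## Worked example

```python
from parotid_radiomics import CohortSpec, EffectProfile, PipelineConfig, run_pipeline
from parotid_radiomics.selection import SelectionConfig

cfg = PipelineConfig(
    simulate=CohortSpec(
        n_wt=24, n_mt=18, roi_shape=(16, 16, 8), n_reseg=10,
        effect_profile=EffectProfile().scaled(0.65), seed=42,
    ),
    selection=SelectionConfig(cv_folds=5, seed=42),
    seed=42,
)
results = run_pipeline(cfg, "out/demo")
```

prints (via the bundled reporting) the artifacts under `out/demo/` and
returns the diagnostic readout:

```text
features per sequence: 1037
training AUC 0.996 (95% CI 0.984-1.000)
cut-off -0.239 (lt): Se 100.0%, Sp 94.4%
+LR 18.00, -LR 0.00
testing  AUC 0.933 (95% CI 0.779-1.000)
```

Reading: 1037 radiomic features were extracted per MRI sequence; the
cascade distilled them into a sparse LASSO score (here 7 ADC-derived
texture features); malignant lesions are called when the score falls
below −0.239, which on this moderately separable synthetic cohort gives
perfect training sensitivity at 94% specificity and a held-out AUC of
0.93. On a null cohort (`EffectProfile.null()`) the same pipeline returns
an AUC compatible with 0.5 — the cascade does not manufacture signal.

The same run is available from the shell:

```bash
parotid-radiomics run-all --seed 42 --out-dir out/demo
parotid-radiomics simulate --n-wt 10 --n-mt 8 --effect 0.5 --seed 1 --out-dir out/cohort
parotid-radiomics extract --manifest out/cohort/cohort.csv --out out/features.csv
```

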