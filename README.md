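# mriharm

Scanner-effect harmonization and radiomic reproducibility analysis for
brain MRI.

When the same brain (or phantom) is scanned under different acquisition
settings — field strength, FOV, matrix — the radiomic features extracted
from identical regions of interest shift for purely non-biological
reasons. This *scanner effect* undermines multicenter radiomics studies.
`mriharm` implements, end to end, the standard toolbox for measuring and
removing it:

- **synthetic multi-setting studies**: homogeneous (9-tube) and
  heterogeneous (6-tube) phantoms and brain-like WM/GM/CC volumes,
  acquired under configurable settings
  (`observed = gain · bias_field(x) · resample(clean) + offset + noise`),
  with co-registered ROI masks shared across settings so that any feature
  difference is attributable to the injected effect alone;
- **preprocessing**: log-domain bias-field correction and isotropic
  b-spline resampling;
- **six intensity-normalization methods** acting on images: Z-Score and
  WhiteStripe (`I_norm = (I − μ)/σ`), FCM-, GMM- and KDE-based
  white-matter normalization (`I_norm = c · I/μ_WM`), and Nyúl
  piecewise-linear histogram matching;
- **92 radiomic features** per 2D ROI with fixed-bin-number
  discretization (32 bins): 18 first-order, 23 GLCM, 16 GLRLM, 16 GLSZM,
  5 NGTDM and 14 GLDM features, verified against brute-force enumeration
  oracles;
- **ComBat harmonization** acting on feature tables, fitted per tissue
  class with no covariates: the location/scale model
  `y_ijv = α_v + γ_iv + δ_iv ε_ijv`, in standard (no empirical Bayes),
  parametric-EB and non-parametric-EB variants;
- **reproducibility evaluation**: paired Wilcoxon signed-rank (two
  settings) or Friedman (three or more) tests per (tissue class,
  feature), Bonferroni correction over the 92 features, and the summary
  statistic

  ```
  DiffFeatureRatio = #{features with P < 0.05} / #{all features}   ∈ [0, 1]
  ```

  where 0 means perfect harmonization and 1 the worst.

## Worked example

The default study emulates a paired 1.5T-vs-3T acquisition of six
subjects (1.8× gain, noise σ 2 vs 3, 5% bias fields) with 60 circular
ROIs per scan (20 WM + 20 GM + 20 CC, identical geometry in both arms):

```python
from mriharm.pipeline import PipelineConfig, run_pipeline

for norm, combat in [("none", "none"), ("zscore", "none"), ("none", "parametric")]:
    r = run_pipeline(PipelineConfig(seed=7, normalization=norm, combat=combat))
    print(norm, combat, round(r["ratio"], 3))
```

prints

```
none none 0.384
zscore none 0.246
none parametric 0.025
```

Read: in the raw data 38% of the 3 × 92 per-class feature tests detect a
significant difference between the two arms; z-scoring the images first
only brings this to 25% (intensity normalization makes the *images*
comparable but cannot remove feature-level scanner effects); per-class
parametric ComBat on the feature table drives it to 3% — ComBat is the
decisive step. The numbered scripts under `analysis/` run the full
narrative: `01_simulate_study.py` (the study and its intensity gap),
`02_extract_features.py` (the raw feature table),
`03_harmonization_grid.py` (normalization × ComBat grid with bar plot),
`04_biological_information.py` (tube classes stay identifiable after
harmonization). A thin CLI mirrors the pipeline:
`mriharm run --config cfg.yaml --seed 7 --out out/`.

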