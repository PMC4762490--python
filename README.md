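# cervidct

Non-destructive species identification of cervid antler from micro-CT, for
zooarchaeologists and bone-microarchitecture researchers. Red deer
(*Cervus elaphus*) and reindeer (*Rangifer tarandus*) antler — the raw
material of much Upper Palaeolithic osseous industry — are nearly
indistinguishable by eye once worked into artefacts, but their inner
trabecular (spongy) tissue differs: reindeer alveoli form a tighter mesh
than red deer alveoli. `cervidct` quantifies that difference and turns it
into a classifier.

## What it computes

From a grayscale micro-CT stack (isotropic voxels, e.g. 20 µm):

1. **Volume of interest** — a fixed ellipse (default semi-axes 1.07 mm and
   3.86 mm, area 12.98 mm²) replicated across the slice range, so
   VOI volume = area × slices × slice thickness.
2. **Segmentation** — a single global threshold at the arithmetic mean of
   the two modes of the VOI gray-level histogram (the empty-space peak and
   the bone peak).
3. **Six trabecular biomarkers** —
   BV/TV (%), bone volume fraction;
   Tb.Th and Tb.Sp (mm), mean local thickness of the mineralised and
   empty-space phases (largest-inscribed-sphere definition);
   Tb.N (mm⁻¹) = (BV/TV)/Tb.Th;
   SMI = 6·V·S′/S², calibrated to 0/3/4 for ideal plates/rods/spheres;
   Tb.Pf (mm⁻¹) = (S₁−S₂)/(V₁−V₂) under one-voxel dilation.
4. **Statistics** — Shapiro–Wilk normality screen, two-sided Wilcoxon
   rank-sum species comparisons, PCA of the standardized biomarkers.
5. **Classification** — soft-margin SVM with Gaussian kernel
   k(xᵢ,xⱼ) = exp(−γ‖xᵢ−xⱼ‖²), decision h(x) = wᵀφ(x) + w₀ with
   h > 0 ⇔ red deer; (c, γ) tuned over integer powers of two by
   leave-one-out cross-validation; SVM-RFE (Guyon) variable ranking;
   2×2 confusion matrices with per-class and overall percent correct.

Because no public scan corpus exists, the package ships first-class
synthetic generators: geometric phantoms (plates/rods/spheres) with
analytically known morphometry, sponge-like random trabecular volumes,
noisy grayscale renderings for threshold testing, and feature-table
cohorts drawn from the published per-species biomarker moments of the
modern corpus (17 red deer, 22 reindeer) and the archaeological corpus
(23 red deer, 27 reindeer).

## Worked example

```sh
python examples/04_svm_classification.py
```

```
grid search over 21x19 (c, gamma) pairs
selected c = 0.5, gamma = 0.125 (LOOCV accuracy 94.9%)

LOOCV confusion matrix (rows: true, cols: predicted)
             red_deer  reindeer   % correct
  red_deer         16         1    94.1%
  reindeer          1        21    95.4%
  overall accuracy: 94.8%

biomarkers most->least informative (SVM-RFE): tb_sp, tb_pf, bv_tv, tb_n, smi, tb_th

modern rule on an archaeological-moments cohort: 100% of samples called red_deer
```

The simulated modern cohort separates well above chance on the
mesh-density biomarkers; applying that modern decision rule to a cohort
drawn from the archaeological moments collapses toward red deer, because
archaeological reindeer antler has a coarser mesh (lower Tb.N, wider
Tb.Sp) that the modern boundary reads as red deer — the same failure mode
seen with the real corpora.

Other examples: `01_phantom_morphometry.py` (biomarkers on known
geometry), `02_segmentation_threshold.py` (histogram-peak threshold
recovery), `03_cohort_statistics.py` (normality/Wilcoxon/PCA screening),
`05_full_pipeline.py` (stacks → report end to end).

## Command line

```sh
cervidct demo --out demo/ --seed 1        # synthetic rendered cohort + config
cervidct run --config demo/run.toml       # full pipeline -> features.csv, report.json
cervidct morphometry --in stack.tif ...   # one stack -> one feature row
cervidct stats-compare --in features.csv --out comparisons.csv
cervidct classify-loocv --in features.csv --out report.json
```

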