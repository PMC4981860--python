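# hepatexture

Texture analysis of conventional (non-contrast) liver MR images for
non-invasive staging of non-alcoholic fatty liver disease (NAFLD).

Liver biopsy is the reference standard for diagnosing steatohepatitis
(NASH) and for staging fibrosis, but it is invasive, costly, and prone to
sampling error. An alternative is to quantify the subtle textural changes
that inflammation and fibrosis imprint on routine MR images. This package
implements that approach end to end, for researchers who want to apply,
refit, or stress-test grid-sampled MR texture biomarkers:

1. **Imaging I/O** — read single-frame DICOM series, group slices by
   protocol (SSFSE-T2, FAST-STIR, in/out-phase, DYNAMIC), and normalise
   pixels into each slice's intensity window.
2. **Grid sampling** — rasterize a manually drawn liver contour, overlay a
   square grid whose cell size is computed from the field of view, matrix
   size and slice thickness so each cell covers roughly a biopsy-sized
   15–24 mm³ of tissue (clipped to 10–23 px), discard cells with < 70 % of
   pixels inside the parenchyma, and flag cells contaminated by vessels or
   ducts with an automated robust-outlier check.
3. **Estimators** — compute 84 per-sample texture estimators (E1–E84):
   first-order statistics, gray-level co-occurrence (Haralick) features,
   intensity-surface curvature descriptors, and spectral band powers.
4. **Biomarkers** — score patients with the published logistic models
   combining per-protocol estimator aggregates, positive when p > 0.5:

   * **NASHMRI** (steatohepatitis):
     η = β₀ + 0.079·E3(SSFSE-T2) + 0.127·E57(DYNAMIC) + β₃·E73(FAST-STIR),
     p = 1/(1+e^(−η))
   * **FibroMRI** (significant fibrosis, ≥ F2):
     η = β₀ + 1.101·E22(SSFSE-T2) − 1.105·E3(DYN) − 115.737·E6(DYN)
     + 0.696·E31(DYN) − 0.825·E75(DYN)

   The source publication prints only the slope coefficients; intercepts
   (and the third NASHMRI slope) were never published, so the presets ship
   them as explicit free parameters (default 0) that must be calibrated on
   labelled data before the absolute 0.5 cut-off is meaningful. Ranking —
   and therefore AUROC — does not depend on them.
5. **ROC statistics** — AUROC with the Hanley closed-form standard error
   and normal CI, correlated/unpaired curve comparison, Se/Sp/PPV/NPV at a
   threshold, Youden-optimal cut-offs, Spearman correlation, and a sample
   size calculator for detecting an AUROC difference.
6. **Phantom generator** — synthetic multi-protocol DICOM studies with
   liver-shaped contours and controllable texture (noise, skewness, bias
   fields, vessel-like dark tubes), so the whole pipeline is testable with
   no clinical data and a known ground truth.

## Worked example

Generate a small two-class phantom cohort and push it through the whole
chain (load → grid → features → score → ROC):

```bash
hepatexture phantom --out cohort --n-per-class 3 --seed 17
cat > config.json <<'JSON'
{"data_dir": "cohort", "contours": "cohort/contours.json",
 "labels_csv": "cohort/labels.csv", "out_dir": "out", "model": "nashmri"}
JSON
hepatexture run --config config.json
```

which prints

```
wrote 6 patients to cohort
pipeline complete: 6 patients, QC counts {'samples': 2268, 'outside_30pct': 846, 'inhomogeneous': 690, 'passed': 732}
```

Of the 2268 grid squares laid over the six patients' slices, 846 fell
mostly outside the liver contour and 690 were rejected as inhomogeneous
(the phantoms deliberately contain vessel-like structures); 732 clean
parenchyma squares fed the estimators. `out/scores.csv` holds one NASHMRI
probability per patient:

```
patient_id,eta,probability,positive
C0P000,0.06909301523671853,0.5172663854353419,True
C0P001,0.071722865146125,0.5179230336850867,True
C0P002,0.06958094289783963,0.5173882208568424,True
C1P000,0.1919150908548856,0.5478320526248638,True
```

and `out/roc.json` reports `"auroc": 1.0` — the diseased class (higher
harmonic mean, higher co-occurrence contrast) is perfectly separated from
the control class. Note that with the preset's uncalibrated intercept all
probabilities sit just above 0.5, so threshold metrics like specificity
are not meaningful until the intercept is fitted
(`hepatexture fit features.csv labels.csv`); the AUROC, being rank-based,
is unaffected.

Individual stages are also available as subcommands: `load`, `grid`,
`features`, `score`, `fit`, `roc`, `phantom`.

## Layout

```
src/hepatexture/
  protocols.py         MR protocol tags and series-description aliases
  imaging_io.py        DICOM read/write, windowing, slice selection
  roi_grid.py          contour rasterization, grid sampling, QC filters
  estimators.py        the 84-estimator registry and aggregation
  biomarker_models.py  NASHMRI/FibroMRI presets, scoring, (re)fitting
  roc_stats.py         Hanley AUROC machinery and threshold metrics
  phantom.py           synthetic DICOM cohort generator
  pipeline.py          end-to-end orchestration with provenance logging
  cli.py               the `hepatexture` command line
```

See `docs/methods.md` for the underlying models, conventions, parameter
defaults, and known limitations.
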