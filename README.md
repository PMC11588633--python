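# pancradiomics

CT radiomics of pancreatic ductal adenocarcinoma (PDAC) tumor heterogeneity
across pancreatic subregions.

PDAC tumors behave differently depending on where they sit in the pancreas:
head tumors (the majority) tend to be smaller, appear hyperintense on
contrast-enhanced venous-phase CT, and differ in treatment response from
body/tail tumors, which grow larger and darker. This package provides a
reusable, tested pipeline for quantifying those differences from images
alone and for classifying a tumor into **head** vs **body/tail** from its
CT features — for imaging researchers who want a transparent, scriptable
radiomics workflow rather than a black box.

## What it computes

Given a 3D volume (NIfTI-1 or NRRD), an aligned binary tumor mask and a
pancreas mask, the pipeline runs:

1. **Preprocessing** — min–max intensity normalization of the scan to
   [0, 1]; no other filtering (`io_preprocess`).
2. **Subregion partition** — pancreas voxels are ordered by projection onto
   the mask's first principal axis and cut at cumulative voxel fractions
   0.40 / 0.73, yielding head (40%), body (33%) and tail (27%); the head is
   the bulkier end of the axis. A tumor is assigned head vs body/tail by
   voxel plurality (`subregions`).
3. **Feature extraction** — 7 feature families over a parameter grid of
   bin counts b ∈ {2¹, …, 2⁸}, kernel radii k ∈ {1, …, 5} and the four
   in-plane angles θ ∈ {0°, 45°, 90°, 135°}:

   | family | features | swept axes | columns |
   |---|---|---|---|
   | first-order statistics | 15 | — | 15 |
   | shape 2D/3D | 20 | — | 20 |
   | grey-level co-occurrence (GLCM) | 20 | b × d(1..5) × θ | 3200 |
   | grey-level run length (GLRLM) | 15 | b × θ | 480 |
   | grey-level size zone (GLSZM) | 14 | b | 112 |
   | grey-level dependence (GLDM) | 12 | b × k | 480 |
   | neighborhood grey-tone difference (NGTDM) | 5 | b × k | 200 |

   i.e. **4507 provenance-tagged feature columns per tumor** at the full
   default grid, and 101 at a single setting
   (`discretization`, `texture_matrices`, `firstorder_shape`, `feature_grid`).
4. **Screening** — unusable (non-finite or constant) columns are dropped,
   then each feature is compared between head and body/tail tumors with a
   two-sided Welch *t*-test at α = 0.05 (no multiplicity correction by
   default; optional Benjamini–Hochberg flag), with a Manhattan-plot export
   (`screening`).
5. **Classification** — seven classifiers (Gaussian Naïve Bayes, KNN,
   nearest-class-centroid "K-Means", linear SVM, thresholded linear
   regression, 50-tree bagged trees, LDA), each wrapped in recursive
   feature elimination capped at **5 features**, trained on one cohort and
   evaluated on a held-out cohort: confusion matrix, accuracy/sensitivity/
   specificity, ROC and trapezoid AUC (`classification`).

Because the underlying patient scans are not publicly available, the
package ships a **synthetic phantom generator** (`synthetic_data`) that
reproduces the cohort's statistical structure — 58 head / 42 body-tail
cases, head tumors 2.4–3.1 cm equivalent-sphere diameter and hyperintense
(+0.15), body/tail tumors 5.6–6.1 cm and darker, class-specific texture
correlation lengths — plus a *null* cohort (identical process for both
classes) for type-I-error calibration. Every stage runs end-to-end on
phantoms with no external data.

## Worked example

```python
from pancradiomics import (
    PhantomSpec, generate_cohort, extract_cohort, GridSpec,
    filter_features, ttest_screen, ScreeningConfig, run_bank, RFEConfig,
)

train = generate_cohort(PhantomSpec(seed=0, n_head=12, n_bodytail=9))
test = generate_cohort(PhantomSpec(seed=1, n_head=12, n_bodytail=9))
grid = GridSpec(bin_counts=(8, 32), kernels=(1, 3), angles=(0, 90))

train_table = extract_cohort(train, grid)
filtered, dropped = filter_features(train_table)
head = filtered.subset_cases([c.case_id for c in train if c.region_label == "head"])
bt = filtered.subset_cases([c.case_id for c in train if c.region_label == "body_tail"])
screen = ttest_screen(head, bt, ScreeningConfig(alpha=0.05))
print(f"significant: {screen.n_significant}/{screen.n_tested}")

sig = screen.significant_columns()
bank = run_bank(
    filtered.subset_columns(sig), [c.region_label for c in train],
    extract_cohort(test, grid).subset_columns(sig),
    [c.region_label for c in test],
    rfe=RFEConfig(max_features=5), seed=0,
)
rep = bank.best_report
print(f"best method: {bank.best_method}")
print(f"held-out accuracy {rep.rounded['accuracy']}%, "
      f"sensitivity {rep.rounded['sensitivity']}%, "
      f"specificity {rep.rounded['specificity']}%, AUC {rep.auc:.2f}")
print("selected:", list(bank.models[bank.best_method].selected_features))
```

prints

```
significant: 275/351
best method: naive_bayes
held-out accuracy 100%, sensitivity 100%, specificity 100%, AUC 1.00
selected: ['shape__surface_area_mm2', 'shape__minor_axis_length_mm', 'shape__slice_perimeter_mm', 'shape__maximum_2d_diameter_slice_mm', 'shape__equivalent_sphere_diameter_cm']
```

Reading the output: 275 of the 351 grid features differ significantly
between the classes at this (reduced) grid — the phantom's planted size and
intensity contrasts are large, so on synthetic data the classes separate
essentially perfectly, and RFE converges on five size-driven shape
features. Real CT cohorts are far noisier; the phantoms validate the
machinery, not the clinical effect size.

The same run is available from the shell:

```sh
pancradiomics --seed 0 run-all --out results/run0
```

which writes the cohorts, feature tables, screening CSV + Manhattan plot,
per-classifier evaluation JSON and ROC curves, along with the exact config
and a seeded run log.

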