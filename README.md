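# curemetrics

Chemometric quality monitoring of dry-cured, pressed meat slices (pastourma
/ pastirma and similar products) during refrigerated storage.

When an opened package of cured meat sits in a domestic refrigerator, its
surface fades (less red, less yellow), its visual texture fragments, its
moisture drops and its protein secondary structure rearranges.
`curemetrics` implements the complete computational side of monitoring that
deterioration from two cheap, non-destructive measurements — slice
photographs and ATR-FTIR spectra — plus the supporting statistics for
physicochemical and microbiological assay tables.  It is written for food
scientists and analysts who want a reproducible, scriptable version of this
workflow, and it ships a synthetic-data generator so every stage can be
exercised and validated without proprietary study data.

## What it computes

**Image features** (`curemetrics.imaging`).  Each slice photograph is cut
into rectangular regions of interest (default: eight 96×96 ROIs on a 4×2
grid) and each ROI is reduced to an 18-feature vector:

* colour — mean CIELAB *L\**, *a\**, *b\** (D65, 2° observer);
* first order — mean intensity, standard deviation, skewness of the
  BT.601 luma;
* grey-level co-occurrence (Haralick) at distance 1, averaged over the four
  standard angles on 32 quantised levels — contrast = Σ P(i,j)(i−j)²,
  dissimilarity = Σ P|i−j|, homogeneity = Σ P/(1+(i−j)²),
  ASM = Σ P², energy = √ASM, entropy = −Σ P log₂P, correlation;
* grey-level run length, averaged over four directions — SRE, LRE, GLN,
  RLN and run percentage RP = N_runs/N_pixels.

**Discrimination and regression** (`curemetrics.chemometrics`).  Features
are z-scored, a candidate feature subset is compacted into two principal
components (correlation PCA), and a classifier from an extensible registry
(nearest centroid, k-NN, linear discriminant, CART decision tree) is
evaluated by leave-one-out cross-validation with the normalisation, PCA and
classifier refit inside every fold — no leakage.  An exhaustive search over
all feature subsets up to a size cap returns the combination with the best
LOO accuracy.  Storage day is predicted by stagewise gradient boosting
(F₀ = ȳ; F_m = F_{m−1} + ν·tree_m on the residuals) under seeded K-fold R².

**Amide-I deconvolution** (`curemetrics.ftir`).  Spectra are ATR-corrected
(A′ = A·ν/ν_ref), the amide-I region (1600–1700 cm⁻¹) is extracted,
smoothed with a nine-point Savitzky–Golay filter, baseline-corrected, and
band centres are picked from the second-derivative minima (completed with
literature band positions where overlap hides a shoulder).  A constrained
multi-Gaussian least-squares fit then yields the five secondary-structure
percentages — β-parallel sheet, random coil, α-helix, β-turn,
β-antiparallel sheet — as each class's share of the total fitted band area:

    proportion(class) = 100 · Σ area(components in class) / Σ area(all components)

**Statistics** (`curemetrics.stats`).  Mann–Whitney–Wilcoxon U (exact
enumeration for small samples, tie-corrected normal approximation
otherwise), one-way ANOVA, Tukey HSD with studentized-range p-values and a
compact letter display ("a, ab, b…"), and the CIELAB hue angle
h = atan2(b\*, a\*).

**Synthetic data** (`curemetrics.synthetic`).  Seeded generators emulate a
16-day refrigerated storage study (days 1, 4, 8, 11, 14, 16; eight slices
per day): slice images whose redness/yellowness fade linearly and whose
texture fragments with storage day, amide-I spectra as five-Gaussian
mixtures with published secondary-structure percentages, and replicate
assay tables following published moisture / hue / firmness / TBARS /
microbial-count series.

## Worked example

```python
from curemetrics.synthetic import (
    StorageProfile, SpectrumProfile, generate_image_dataset, generate_amide_spectrum,
)
from curemetrics.imaging import extract_feature_table, FEATURE_NAMES
from curemetrics.chemometrics import feature_subset_search
from curemetrics.ftir import deconvolve_amide

# day-1 vs day-16 storage discrimination on synthetic slice photographs
profile = StorageProfile(days=(1, 16))                  # 2 x 8 slices, 512 x 512 px
images = generate_image_dataset(profile, seed=0)
table = extract_feature_table(images)                   # 128 ROI feature vectors
subset, result = feature_subset_search(
    table[list(FEATURE_NAMES)], table["day"], classifier="decision_tree",
    max_subset_size=2,
)
print(subset, result.accuracy)

# amide-I secondary structure from a synthetic lamb day-1 spectrum
spectrum = generate_amide_spectrum(SpectrumProfile(), seed=0)
fit, proportions = deconvolve_amide(spectrum)
print({k: round(v, 2) for k, v in proportions.percentages.items()})
```

Output:

```
('a_star',) 100.0
{'beta_parallel_sheet': 9.42, 'random_coil': 18.64, 'alpha_helix': 10.16,
 'beta_turn': 38.7, 'beta_antiparallel_sheet': 23.08}
```

The search finds that mean redness (*a\**) alone separates day 1 from
day 16 perfectly under the default fade rate (accuracy is the percentage of
the 128 held-out ROI vectors classified to the correct storage day), and
the deconvolution recovers the generating secondary-structure percentages
of the synthetic spectrum exactly at zero noise.

The same pipeline is available from the shell:

```bash
curemetrics run --seed 3 --out runs/demo           # full synthetic pipeline
curemetrics simulate images --seed 0 --out imgs/   # PNGs + manifest.csv
curemetrics extract-features --images imgs/manifest.csv --out features.csv
curemetrics discriminate --features features.csv --classes 1,16 --max-subset 5
curemetrics predict-days --features features.csv --k 5
curemetrics amide-fit --spectrum spectrum.csv --out fit.json
curemetrics stats --assays assays.csv --alpha 0.05
```

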