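# nirauth

Chemometric authentication of protected-origin products from FT-NIR
spectra.

Protected geographical indications (a famous oolong tea, an estate olive
oil, a denomination wine) attract counterfeits that look identical to the
genuine product. Near-infrared spectroscopy fingerprints a sample's
chemistry in under a minute without destroying it; the question is
whether a classifier built on those fingerprints can tell the protected
origin from everything else. `nirauth` implements the standard
chemometric workflow for that question as a tested, reusable Python
package with scikit-learn-style estimators:

1. **Trim** the uninformative high-wavenumber region (default: keep
   4000–9000 cm⁻¹).
2. **Stahel–Donoho outlyingness diagnosis** per class: a sample's score
   is its worst-case robustly standardised distance over projection
   directions,
   `out(xᵢ) = maxₐ |a·xᵢ − med(a·x)| / (1.4826 · MAD(a·x))`,
   and spectra scoring above 3 (≈3 robust standard deviations) are
   removed as aberrant.
3. **Pretreatment** — exactly one of: SNV (per-spectrum standardisation,
   removes multiplicative scatter and additive offsets), Savitzky–Golay
   second derivative D2 (annihilates constant/linear baselines), or
   Savitzky–Golay smoothing.
4. **Kennard–Stone splitting** per class: deterministic maximin
   selection of a training set that spans each class, merged into one
   training and one prediction set.
5. **PLSDA** (SIMPLS): regression of the dummy-coded membership matrix
   Y (rows (+1, −1) for the positive class, (−1, +1) otherwise) on the
   spectral matrix X, assigning a sample to the positive class iff its
   first predicted response exceeds 0. The latent-variable count A is
   chosen by Monte-Carlo cross-validation — T stratified 50/50 splits of
   the training set scoring `MR(A) = (1/T) Σᵢ Mᵢ/Pᵢ × 100%` — and the
   prediction set is scored by sensitivity `TP/(TP+FN)` and specificity
   `TN/(TN+FP)`.

Because public FT-NIR authentication datasets with origin labels are
scarce, the package ships a seeded synthetic generator
(`nirauth.simulate`) that emulates two-class FT-NIR cohorts on the
instrument grid (4000–12000 cm⁻¹ at 1.928 cm⁻¹ spacing): Gaussian
absorption bands with a class-dependent amplitude shift in the
4000–5000 cm⁻¹ combination region, low-rank bounded scatter/baseline/
composition nuisances, and injected aberrant scans (spikes, baseline
jumps, scatter blow-ups) with a ground-truth mask.

## Worked example

Run the full pipeline on the default synthetic study (450 positive /
120 negative samples, 4% aberrant scans) with SNV pretreatment:

```python
import nirauth as na

config = na.PipelineConfig()
config.preprocess = na.PreprocessConfig(method=na.Method.SNV)
report = na.run_pipeline(config)
print(report.n_removed, report.per_class_split)
print(report.chosen_lv, report.sensitivity, report.specificity)
```

prints

```
{'POS': 12, 'NEG': 7} {'POS': (305, 133), 'NEG': (79, 34)}
1 1.0 1.0
```

meaning: the outlyingness diagnosis removed 12 positive and 7 negative
spectra (at a 4% injection rate, 23 of 570 scans were aberrant; the
remainder of the injected set falls in the trimmed 9000–12000 cm⁻¹
region and is harmless after trimming), Kennard–Stone kept 305/133 and
79/34 samples per class for training/prediction, MCCV selected a single
latent variable, and the prediction set was classified perfectly
(sensitivity 1.000, specificity 1.000). On real instrument data the same
entry point accepts a CSV via `config.input_csv`.

The same workflow is scriptable from the shell:

```bash
nirauth generate --n-pos 450 --n-neg 120 --seed 0 --out tea.csv --truth-out truth.csv
nirauth diagnose-outliers --input tea.csv --out outliers.csv
nirauth run --config study.yaml
nirauth compare --config study.yaml       # raw vs SNV vs D2 vs smoothing
```

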