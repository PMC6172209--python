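# ftirmacro

Macromolecular profiling of cultured cells from ATR-FTIR spectra.

Vibrational biospectroscopy reads a cell population's gross biochemistry
from a single absorbance trace: protein secondary structure from the
amide I envelope (α-helix components at 1657/1649 cm⁻¹, β-sheet at
1636/1629 cm⁻¹), total nucleic acids from the PO₂⁻ antisymmetric stretch
(1242–1238 cm⁻¹) and the ribose ring band (915 cm⁻¹), DNA conformation
from the A-form (1240), B-form (1221) and Z-form (1066 cm⁻¹) marker
bands, and membrane lipid state from the olefinic (3009), CH₂ (2921/2852)
and cholesteryl-ester (1172 cm⁻¹) bands. `ftirmacro` implements the full
analysis chain used in dose-response studies of this kind — e.g. probing
what low doses of a "vehicle" solvent such as DMSO (0.1–1.5% v/v) do to
epithelial cells — for spectroscopists and computational biologists who
want the pipeline scripted, tested and reproducible rather than clicked
through vendor software:

* **synthetic spectra** — a generator that emulates replicated cell-film
  spectra (biological × technical replicates, dose-dependent band
  effects, baseline, residual water band, noise), so the whole pipeline
  is testable without instrument data;
* **preprocessing** — PBS background subtraction with free-water
  flattening at ~2125 cm⁻¹, Savitzky–Golay second derivatives, vector
  and min/max normalization, region extraction;
* **band quantification** — marker-band table, percent-of-untreated
  intensities, Z-DNA enhancement ratio I(1066)/(I(1240)+I(1221)), lipid
  unsaturation (olefinic/total lipid), and the α→β conversion
  100·(1 − mean α(dose)/mean α(UT));
* **chemometrics** — NIPALS PCA with Hotelling's T², LDA on PC scores
  (linear / Mahalanobis classifiers), prediction and confusion matrices;
* **statistics** — mean ± SEM, unpaired t tests versus untreated, star
  significance tiers (*p ≤ 0.05 … ****p ≤ 0.0001).

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Recover the protein secondary-structure change from a simulated
experiment (3 biological × 3 technical replicates per group):

```python
import ftirmacro as fm

design = fm.SampleDesign(("HCT116_like",), (0.0, 0.1, 0.5, 1.5),
                         n_bio=3, n_tech=3, seed=1)
spectra, reference = fm.generate_experiment(design)
absorbance, second = fm.preprocess_set(spectra, reference)
table = fm.quantify_bands(absorbance, second)
print(fm.secondary_structure_summary(table)
      [["dose", "conversion_percent", "beta_gain_percent"]].round(2))
```

```
   dose  conversion_percent  beta_gain_percent
0   0.0                0.00               0.00
1   0.1               13.73              32.98
2   0.5               29.61              69.18
3   1.5               39.66              95.54
```

The generator moved 15/30/40% of the α-helix amide-I amplitude into the
β-sheet components at the three doses; the pipeline recovers those
fractions from noisy second-derivative band intensities to within about
one percentage point, and the β gain rises in step — the lost α intensity
reappears as β, it does not vanish.

Classification of the same kind of data:

```python
report = fm.discriminate_groups(absorbance, region=(650, 4000),
                                label_key="dose", seed=7)
print(report.holdout_accuracy)        # 100.0
print(report.confusion_holdout.to_frame())
```

The dose groups separate with 100% held-out accuracy (whole-region PCA +
PC-score LDA), and two cell-line profiles differing
in lipid-band amplitudes separate equally cleanly in the 3030–2830 cm⁻¹
region — the behavior reported for real dose-response data of this type.

The `examples/` directory holds one short script per capability
(simulation, secondary structure, DNA topology and nucleic acids, dose
discrimination, cell-line fingerprinting); each prints the numbers it
computes with a note on what they mean. A thin CLI mirrors the pipeline
stages:

```bash
ftirmacro simulate --out-dir run/          # spectra.csv + reference.csv
ftirmacro run --seed 7 --out-dir run/      # end-to-end with manifest
```

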