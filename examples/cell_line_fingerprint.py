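"""Separate two cell lines by their membrane-lipid spectral fingerprint.

Two untreated cell-line profiles differ in CH₂/CH₃ stretching, olefinic
and cholesteryl-ester band amplitudes; PCA + PC-score LDA restricted to
the lipid region (3030–2830 cm⁻¹) separates them completely.
"""

import warnings

import ftirmacro as fm

warnings.simplefilter("ignore", RuntimeWarning)

design = fm.SampleDesign(("HCT116_like", "SW480_like"), (0.0,), 3, 3,
                         seed=3)
spectra, reference = fm.generate_experiment(design)
absorbance, _ = fm.preprocess_set(spectra, reference)

report = fm.discriminate_groups(absorbance, region=(2830, 3030),
                                label_key="cell_line", seed=3)

print(f"lipid-region PCA: PC1 explains "
      f"{report.pca.explained_variance[0]:.1f}% of variance")
print(f"held-out accuracy: {report.holdout_accuracy:.1f}%")
print("held-out confusion matrix:")
print(report.confusion_holdout.to_frame())
# The lines differ in acyl-chain band amplitudes, so even the narrow
# C-H stretching window is enough for a clean discrimination.
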