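"""Recover the α-helix → β-sheet conversion induced by DMSO dose.

Generates noisy spectra whose amide-I composition encodes conversion
fractions of 15/30/40% at 0.1/0.5/1.5% dose, quantifies the
second-derivative intensities of the 1657/1649 (α) and 1636/1629 cm⁻¹ (β)
components, and reports the conversion the pipeline recovers.
"""

import ftirmacro as fm

design = fm.SampleDesign(("HCT116_like",), (0.0, 0.1, 0.5, 1.5), 3, 3,
                         seed=1)
spectra, reference = fm.generate_experiment(design)
absorbance, second = fm.preprocess_set(spectra, reference)
table = fm.quantify_bands(absorbance, second)
summary = fm.secondary_structure_summary(table)

print("dose (%)  alpha mean  beta mean  conversion %  beta gain %")
for _, row in summary.iterrows():
    print(f"{row['dose']:7.1f}  {row['alpha_mean']:10.5f}  "
          f"{row['beta_mean']:9.5f}  {row['conversion_percent']:12.2f}  "
          f"{row['beta_gain_percent']:11.2f}")
# conversion % is the relative loss of total alpha-helix amide-I intensity
# versus untreated cells; beta gain rising in step confirms the intensity
# moved into the beta-sheet components rather than vanishing.
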