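"""Generate a synthetic DMSO dose-response FTIR experiment.

Builds the default study design — one colon-epithelial-like cell line,
doses 0/0.1/0.5/1.0/1.5% v/v, 3 biological × 3 technical replicates — and
writes the spectra plus the PBS reference to CSV.
"""

from pathlib import Path

import ftirmacro as fm
from ftirmacro.io import write_spectra_csv
from ftirmacro.spectrum import SpectrumSet

out = Path("scratch/example_simulation")
out.mkdir(parents=True, exist_ok=True)

design = fm.SampleDesign(cell_lines=("HCT116_like",),
                         doses=(0.0, 0.1, 0.5, 1.0, 1.5),
                         n_bio=3, n_tech=3, seed=7)
spectra, reference = fm.generate_experiment(design)

write_spectra_csv(spectra, out / "spectra.csv")
write_spectra_csv(SpectrumSet([reference]), out / "reference.csv")

print(f"generated {len(spectra)} spectra on a "
      f"{spectra.wavenumbers[0]:.0f}-{spectra.wavenumbers[-1]:.0f} cm-1 grid "
      f"({spectra.wavenumbers.size} points)")
first = spectra[0]
print(f"first sample: {first.sample_id}, absorbance range "
      f"{first.values.min():.4f}-{first.values.max():.4f}")
print(f"wrote {out / 'spectra.csv'} and {out / 'reference.csv'}")
# Each spectrum is a sum of macromolecular marker bands on a smooth
# baseline with a residual free-water band at 2125 cm-1; dose shifts the
# band amplitudes the way a DMSO treatment would.
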