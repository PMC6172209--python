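# Example end-to-end pipeline configuration.
#
#   ftirmacro run --config examples/pipeline_config.yaml --out-dir run/
#
# Design: one cell line, four doses, 3 biological x 3 technical
# replicates, with a custom effect model instead of the built-in default.

cell_lines: [HCT116_like]
doses: [0.0, 0.1, 0.5, 1.5]
n_bio: 3
n_tech: 3
seed: 7

# Savitzky-Golay second derivative and water-flattening window
sg_window: 9
sg_poly: 3
flatten_window: [2050.0, 2200.0]

regions:
  whole: [650.0, 4000.0]
  lipid: [2830.0, 3030.0]
  nucleic: [1200.0, 1250.0]

lda_kind: linear
lda_split: 0.6666666666666666
t_variant: student
stat_unit: biological

# Custom dose response: only the Z-DNA marker band and the alpha->beta
# conversion change with dose here.
effects:
  HCT116_like:
    multipliers:
      0.0: {}
      0.1: {zdna_1066: 1.2}
      0.5: {zdna_1066: 1.4}
      1.5: {zdna_1066: 1.7}
    conversion:
      0.0: 0.0
      0.1: 0.15
      0.5: 0.30
      1.5: 0.40
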