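# Fish-oil effect on triglycerides, adjusted for degree of unsaturation
# and chain length (double-bond bins as cell means, carbon bins
# reference-coded against [40,45)).
#
# Generate the matching synthetic fixture first:
#   matlm simulate --out examples/data/tg --preset triglyceride --seed 1
# then:
#   matlm fit --config examples/sams_style.toml \
#       --y examples/data/tg/abundance.csv \
#       --samples examples/data/tg/samples.csv \
#       --annotations examples/data/tg/annotations.csv \
#       --out examples/data/tg/fit_adjusted.csv

[x]
covariates = ["fish_oil"]
intercept = true

[z]
mode = "adjusted"

[[z.variables]]
column = "double_bonds"
edges = [3, 6, 9]

[[z.variables]]
column = "total_carbon"
edges = [40, 45, 50, 55, 60, 65, 70]
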