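# Single-annotation (unadjusted) model: one cell-means block over carbon
# bins, so each coefficient is the covariate effect for that carbon range.
#
#   matlm simulate --out examples/data/tg --preset triglyceride --seed 1
#   matlm fit --config examples/tilapia_style.toml \
#       --y examples/data/tg/abundance.csv \
#       --samples examples/data/tg/samples.csv \
#       --annotations examples/data/tg/annotations.csv \
#       --out examples/data/tg/fit_carbon_only.csv

[x]
covariates = ["fish_oil"]
intercept = true

[z]
mode = "unadjusted"

[[z.variables]]
column = "total_carbon"
edges = [40, 45, 50, 55, 60, 65, 70]
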