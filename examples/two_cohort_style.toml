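# Two-cohort comparison: fit the same unadjusted categorical model in two
# independently simulated cohorts, then contrast the shared coefficients.
#
#   matlm simulate --out examples/data/cohort_a --preset categorical --seed 11
#   matlm simulate --out examples/data/cohort_b --preset categorical --seed 22
#   for C in cohort_a cohort_b; do
#     matlm fit --config examples/two_cohort_style.toml \
#         --y examples/data/$C/abundance.csv \
#         --samples examples/data/$C/samples.csv \
#         --annotations examples/data/$C/annotations.csv \
#         --out examples/data/$C/fit.csv
#   done
#   matlm contrast examples/data/cohort_a/fit.csv examples/data/cohort_b/fit.csv \
#       --mode difference --out examples/data/contrast_diff.csv
#   matlm contrast examples/data/cohort_a/fit.csv examples/data/cohort_b/fit.csv \
#       --mode average --out examples/data/contrast_avg.csv

[x]
covariates = ["treatment"]
intercept = true

[z]
mode = "unadjusted"

[[z.variables]]
column = "group"
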