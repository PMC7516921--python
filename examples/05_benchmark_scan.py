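"""A small sample-size scan of the Correct-vs-Alternative benchmark.

Exponential surface 100(x+y)e^-x with Poisson(10) noise, scanned over
three sample sizes with 5 replicates each, then summarised as the rate at
which each criterion ranks the correct model best.
"""

from gofselect import BenchmarkConfig, NoiseSpec, scan_sample_size

cfg = BenchmarkConfig(
    case="exponential",
    noise=NoiseSpec.poisson(10),
    n_grid=(100, 300, 1000),
    reps=5,
    gof_test="chi_squared",
    seed=123,
)
result = scan_sample_size(cfg)

print("mean criterion values (lower = preferred):")
agg = result.aggregate()
sub = agg[agg.criterion.isin(["aic", "aic_gf"])]
print(sub.pivot(index=["n_or_intensity", "criterion"],
                columns="model_label", values="mean").round(1))

print("\nrate at which the Correct model is ranked best:")
for crit in ("aic", "bic", "aic_gf", "bic_gf"):
    rates = result.selection_rate(crit)
    line = "  ".join(f"n={int(r.n_or_intensity)}: {r.rate:.0%}"
                     for r in rates.itertuples())
    print(f"  {crit:<8} {line}")

# Because the exponential fit family cannot reproduce the y e^-x term, the
# Alternative here is a poor fit and every criterion identifies the correct
# model; the GF upgrade matters when the Alternative is competitive (see
# the power-law case) or when differences are marginal.
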