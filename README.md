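# gofselect

Model selection criteria upgraded with goodness-of-fit tests, for data
whose additive noise is **not** zero-mean Gaussian.

## The problem

The workhorse residual forms of the Akaike and Bayesian information
criteria,

```
AIC = n·ln(MSE) + 2k          BIC = n·ln(σ(ε)²) + k·ln(n)
```

summarise everything about the residuals ε with their mean-squared error
and variance.  That is fine when the noise is zero-mean Gaussian.  When it
is asymmetric about zero — Poisson(λ) noise has mean λ, Gamma(k, θ) noise
has mean kθ — a least-squares fit of a *wrong* model will happily absorb
the noise mean into its parameters, driving the residual mean to zero and
its MSE below that of the *true* model (whose residuals reproduce the
noise, mean included).  Classic AIC then rewards the wrong model.

`gofselect` implements two upgraded families of criteria that look at the
whole residual distribution instead:

```
AIC_H  = n·ln(MSE/H) + 2k                    BIC_H  = n·ln(σ(ε)²/H) + k·ln(n)
AIC_GF = n·ln(MSE·(1+Z²)/H) + 2k             BIC_GF = n·ln(σ(ε)²·(1+Z²)/H) + k·ln(n)
```

where `H = −Σᵢ pᵢ ln pᵢ` is the Shannon entropy of the binned residual
distribution (rewarding residuals without leftover structure) and `Z` is a
nonnegative goodness-of-fit discrepancy between the residuals and the
*known* noise distribution — Kolmogorov–Smirnov (`D_n`), Anderson–Darling
(`A²/n`) or Pearson chi-squared (`χ²/n`).  Under a correct model `Z → 0`
as n grows, so the GF criteria converge to the entropy ones; under a wrong
model `Z` stays bounded away from zero and the `(1+Z²)` factor penalises
residuals that do not look like the noise.

The package also ships the complete simulation benchmark that probes this
behaviour: three generating surfaces (exponential, polynomial, power-law)
on `0 < x < 10`, `−10 < y < 10`, four noise laws (Gaussian(0,3),
Uniform(−1,1), Poisson(10), Gamma(3,2)), Correct-vs-fitted-Alternative
comparisons, and scans over sample size and noise intensity with averaged
repetitions.

## Worked example

The power-law benchmark case: data from `z = x³/y` plus Poisson(10) noise,
true model vs a least-squares power-law fit
(`python examples/03_criteria_table.py`):

```
criterion      Correct   Alternative
aic             4692.8        4023.0
bic             2292.9        3556.0  <- correct wins
aic_h           3749.8        2985.3
bic_h           1349.9        2518.3  <- correct wins
aic_gf          3750.2        8392.9  <- correct wins
bic_gf          1350.3        7925.9  <- correct wins

Correct:     MSE=108.5  var=9.7  Z=0.021
Alternative: MSE=55.5  var=34.3  Z=14.903
```

The fitted Alternative halves the MSE by absorbing the noise mean (≈10),
so classic AIC prefers it.  But its residuals sit near 0 while Poisson(10)
noise lives near 10: its chi-squared z-score is ~15 versus ~0.02 for the
true model, and the `(1+Z²)` factor reverses the ranking.  Lower values
win throughout; the k-penalties are identical here (both models have three
parameters), so every difference comes from the residual statistics.

The other scripts in `examples/` walk through the noise models, the
z-scores, the fitting layer and a full sample-size scan.

## Command line

```bash
gofselect bench --case exponential --noise poisson --noise-params '{"lam": 10}' \
    --n-grid 100,300,1000 --reps 10 --gof-test chi2 --seed 1 --out scan.csv
gofselect intensity-scan --noise poisson --grid 2,5,10,20 --n 1000 --out intensity.csv
gofselect criteria --data data.csv --model model.json --noise '{"family":"poisson","params":{"lam":10}}'
```

Scans are deterministic: the same config and seed reproduce the output CSV
byte for byte.

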