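# langdiv

Phylogenetic–spatial generalized least squares for grid-based language
diversity macroecology.

## What problem this solves

The world's languages are distributed extremely unevenly, and the candidate
ecological explanations — productive, aseasonal climates that let small
cultural groups be self-sufficient (*ecological risk*), landscape barriers
that subdivide speaker populations (*isolation*), and covariation with
biodiversity — are themselves spatially clustered.  Grid cells near each
other share climate, species and related languages, so naive regressions of
per-cell language counts on environmental layers are badly
pseudo-replicated: similarity between neighbouring, related cells
manufactures significant-looking correlations.

`langdiv` is for researchers who want to test such hypotheses while
modelling that non-independence explicitly.  It fits, by maximum
likelihood, the regression

    y = X b + e,   e ~ N(0, σ² C),   C = (1 − α) I + α [ β P + (1 − β) D ]

where `y` is log language diversity per equal-area grid cell, `P` is the
PhyloSor phylogenetic similarity between the language sets of two cells
(shared branch length on a taxonomy-derived language tree, star-shaped at
the base because between-family relationships are unknown), and
`D = exp(−(d/γ)²)` is a Gaussian decay of the great-circle distance between
cell centroids.  `α` measures how much residual variance is
spatial+phylogenetic, `β` splits it between phylogeny and space, and `γ`
(km) sets the spatial decay range.  On top of the fitter sit drop-one
likelihood-ratio tests, leave-one-out predicted-R² variance partitioning
(including the GLS-vs-OLS difference that prices the non-independence),
residual hotspot maps at |z| ≥ 1.96, and systematic grid subsampling to
keep the correlation matrix well conditioned.

Because global language-range atlases are license-restricted, the package
ships a first-class synthetic-data generator producing datasets with the
same statistical anatomy — families with spatially clustered ranges,
log-normal speaker counts, autocorrelated covariate fields, responses drawn
from the model at known parameters — so every stage is testable end to end.

## Worked example

```python
import numpy as np
from langdiv import (GLSConfig, SynthConfig, fit_gls, fit_ols,
                     simulate_dataset)

data = simulate_dataset(SynthConfig(seed=1))   # truth: α=0.6, β=0.5, γ=1500 km
gls = fit_gls(data.y, data.X, data.P, data.d, names=data.names)
ols = fit_ols(data.y, data.X, names=data.names)

print(f"alpha={gls.params.alpha:.2f} beta={gls.params.beta:.2f} "
      f"gamma={gls.params.gamma_km:.0f} km")
print(gls.summary_frame().round(3))
print(f"predicted R2: GLS {gls.predicted_r2:.3f} vs OLS {ols.predicted_r2:.3f}")
```

Output:

```
alpha=0.64 beta=0.25 gamma=1655 km
                          coef     se      t      p
intercept                3.449  0.393  8.786  0.000
land_fraction           -0.105  0.425 -0.247  0.805
annual_mean_temperature  0.331  0.111  2.967  0.003
mean_growing_season      0.482  0.123  3.932  0.000
predicted R2: GLS 0.658 vs OLS 0.281
```

The generating truth was α = 0.6, β = 0.5, γ = 1500 km with coefficients
(3.0 intercept, 0.5 land, 0.4 per predictor): in this single draw α and γ
are recovered closely, the coefficients sit within their confidence
intervals, and β — the hardest parameter, since phylogenetic and spatial
similarity partly overlap — lands low but within its typical sampling
spread (across 50 replicates its median absolute error is about 0.1).  The
t value is each coefficient over its standard error under the fitted
correlation structure; the 0.38 gap in predicted R² is explanatory power
carried by spatial autocorrelation and phylogenetic non-independence —
exactly the part an OLS analysis would misattribute to its predictors.

A thin CLI mirrors the pipeline stages (`langdiv simulate`, `langdiv grid
build/overlay/subsample`, `langdiv similarity phylo/distance`, `langdiv
analyze run`); see `langdiv --help`.

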