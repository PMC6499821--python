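# Methods

## The problem

The number of languages per cell of an equal-area grid varies by orders of
magnitude across the globe, and candidate ecological explanations (climate,
landscape barriers, biodiversity) are themselves spatially structured.  Two
cells close in space, or containing related languages, are not independent
observations: nearby cells share climate, flora and speech communities, and
cells sampling the same language families inherit similarity by descent.
Regression that ignores this pseudo-replication produces spurious
associations.  `langdiv` implements a generalized least squares (GLS)
framework in which the residual correlation between two grid cells is an
explicit, jointly estimated function of their spatial proximity and the
phylogenetic similarity of their language sets.

## Model

For log language diversity (or a speaker-population summary) `y` over `n`
retained grid cells,

    y = X b + e,     e ~ N(0, sigma^2 C),
    C = (1 - alpha) I + alpha [ beta P + (1 - beta) D ],

where

* `X` always contains an intercept and the cell's land coverage, plus the
  predictors under test;
* `P` is the PhyloSor similarity between the language sets of two cells:
  `2 BL_shared / (BL_i + BL_j)`, with `BL_i` the total branch length of the
  rooted spanning subtree of cell i's languages and `BL_shared` the length
  of branches common to both spanning subtrees.  Spanning subtrees include
  the path to the root, which makes the documented endpoints exact on the
  star-based tree: 1 for identical language sets, 0 for cells sharing no
  family;
* `D = exp(-(d / gamma)^2)` is a Gaussian decay of the great-circle
  distance `d` (km) between cell centroids (Earth radius 6371 km;
  Euclidean distance in the planar toy mode);
* `alpha` in [0, 1] is the share of residual variance carried by
  spatial-plus-phylogenetic structure, `beta` in [0, 1] the phylogenetic
  (beta) versus spatial (1 - beta) split, and `gamma > 0` the spatial decay
  range in km.

`C` has unit diagonal for every parameter value, so `sigma^2` retains its
usual meaning.

## The language tree

There is no accepted global phylogeny of languages, so the tree is derived
from a tabular taxonomy: tips are languages, internal nodes are taxonomy
groups merged along shared classification-path prefixes, and the root is a
star over families — any two languages from different families sit at the
maximum patristic distance.  Isolates are their own families, attached
directly under the root.  The taxonomy states no branch lengths; the
package uses ultrametric depth-normalisation (every root-to-tip path has
length 1; internal edges take equal shares of the deepest chain, the
pendant edge absorbs the remainder), which guarantees the constant-maximum
cross-family distance and makes PhyloSor scale-free.  A
`unit_branch_lengths` switch supports sensitivity analysis against the
convention.

## Fitting

`b` and `sigma^2` are profiled out of the Gaussian likelihood analytically;
the profiled negative log-likelihood is minimised over
`(alpha, beta, log gamma)` with a bounded Nelder-Mead simplex from multiple
starts (a 3 x 3 x 3 grid of alpha, beta in {0.2, 0.5, 0.8} and gamma in
{0.5, 1, 2} x median inter-cell distance, plus the OLS corner alpha = 0;
the best `n_starts` candidates seed local searches with a seeded jitter).
gamma is searched on the log scale within [1 km, 5 x max distance].
Maximum likelihood (not REML) is used throughout, because likelihood-ratio
tests across fixed-effect structures require it.  Standard errors come
from `sigma^2 (X' C^-1 X)^-1`; t statistics use df = n minus the number of
fixed-effect columns.

Drop-one tests refit the model without one predictor (all dummy columns of
a categorical at once, df = k - 1) and compare twice the log-likelihood
difference to chi-square.  Reduced fits are warm-started at the full
optimum; if a reduced fit nevertheless out-fits the full model (a local
optimum), the full model is refit warm-started from the reduced optima
before the statistic is formed.

### Numerical safeguards

All solves are factor-based (Cholesky; `log|C|` from the factor; never an
explicit inverse), with a 1e-10 ridge and an eigenvalue-clamping repair
(floor 1e-8, diagonal rescaled to 1, perturbation logged) as fallbacks
before a singularity error advising heavier subsampling is raised.

Two degeneracy guards protect the ML search itself:

* **Near-duplicate cells.**  A Cholesky pivot is the conditional standard
  deviation of one cell given the preceding ones; a pivot below 1e-4 at
  unit marginal variance means two cells are effectively duplicates, and
  the parameter point is rejected.  Without this, `(1/2) log|C|` diverges
  to -inf as C approaches singularity and near-singular corners become
  spurious optima — the degeneracy that motivates subsampling.
* **Indefinite similarity inputs.**  With positive semidefinite `P` and
  `D` the construction guarantees `lambda_min(C) >= 1 - alpha`.  The
  Gaussian kernel of great-circle (non-Euclidean) distances can be
  indefinite, letting `lambda_min(C)` collapse toward zero at legal
  parameter values, again earning a spurious log-determinant bonus (in
  testing this produced |t| > 40 on permuted, structureless responses).
  Parameter points with `lambda_min(C) < max((1 - alpha)/2, 1e-6)` —
  impossible under PSD inputs — are rejected; `lambda_min` is estimated by
  inverse power iteration on the Cholesky factor at O(n^2) cost.

## Predicted R^2

The predicted R^2 is leave-one-out and conditional: under GLS the
prediction for cell i borrows the correlated residuals of the other cells,

    yhat_i = x_i b + C[i,-i] C[-i,-i]^-1 (y_-i - X_-i b),

computed for all i at once via the precision-matrix identity
`y_i - yhat_i = (C^-1 r)_i / (C^-1)_ii`.  With `C = I` the conditional
term vanishes and the measure reduces to the classical in-sample R^2, so
the GLS-minus-OLS difference isolates the contribution of spatial
autocorrelation and phylogenetic non-independence.  This conditional
reading is a declared interpretation: it is the one under which a GLS
model can out-predict OLS at all.

## Residual diagnostics

Standardized residuals are raw residuals over sigma-hat (C has unit
diagonal); cells beyond |1.96| are flagged as diversity hotspots or
coldspots.  The Shapiro-Wilk normality check runs on the whitened
residuals `L^-1 r / sigma`, which are iid standard normal under a
correctly specified model.  Both scalings are reported because map-style
hotspot flags belong to the per-cell (standardized) scale while the
normality assumption concerns the whitened scale.

## Gridding and subsampling

Spherical mode uses a cylindrical equal-area projection
(`x = R lon_rad`, `y = R sin(lat_rad)`); the grid tiles the projected
plane exactly, so all cells have identical area.  A language occupies
every cell its range polygon intersects, boundary touches included; cells
no language touches are dropped.  Land coverage below 1% in an occupied
cell is floored at 0.01 (the small-island convention).  Centroid
distances are great-circle on the geographic centroids.

Adjacent cells can be near-duplicates in both predictors and language
composition, degrading the conditioning of `C`.  Systematic subsampling
keeps every `step`-th row and column at a given offset; at `step = 3` the
nine possible offsets partition the cells into nine regimes that can be
analysed in a loop for a consistency summary.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
at desk scale, with every parameter known:

* **Languages.**  Families receive uniform homeland locations; each
  family's dispersion is log-normal around a 400 km median
  (`family_dispersion_log_sd = 1`), mirroring the heavy-tailed spread of
  real family extents — most families are compact, a few span continental
  distances.  That heterogeneity matters: it gives `P` long-range
  structure distinct from the Gaussian kernel, which is what makes
  `beta` identifiable, exactly as widespread families do in real data.
  Language ranges are discs with log-normal radii (median 280 km);
  speaker counts are log-normal (median 7000, log-sd 2), matching the
  strongly right-skewed empirical size distribution of languages.
* **Covariates.**  Gaussian random fields over cell centroids with
  squared-exponential covariance: climate-like layers vary over thousands
  of km, landscape-like layers over hundreds.  Land coverage is a
  logistic-squashed field (mostly-full cells with coherent "coastal"
  patches), floored at 0.01.  An optional categorical biome comes from
  thresholding a long-range field.
* **Response.**  Drawn from the model itself, `y ~ N(Xb, sigma^2 C)` at
  known `(alpha, beta, gamma)`, directly on the log scale the model fits;
  a count layer would add unmodelled noise to recovery tests.  Default
  conditions: a 9000 km planar domain of 500 km cells (roughly 300
  occupied cells), `alpha = 0.6`, `beta = 0.5`, `gamma = 1500 km`,
  `sigma^2 = 0.4`, coefficients (3.0 intercept, 0.5 land, 0.4 per
  predictor).  The domain is large relative to `gamma` for the same
  reason the real analysis is global: with only ~3 decay ranges of
  extent, the correlation parameters are weakly identified.
* **Seeding.**  Separate seed streams for taxonomy/ranges, covariate
  fields and noise, so one component can vary with the others held fixed;
  everything is bit-reproducible from one seed.

What the generator does **not** emulate: realistic coastline/landmass
geometry, range polygons more complex than discs, per-country speaker
splits, covariate derivation from rasters, or any diversification history
(languages do not descend from one another in the generator; the taxonomy
is imposed).  Passing tests therefore validate the statistical machinery
under the model's own assumptions — they do not validate the ecological
conclusions on real data.

## Problem sizes used in checks

Simulation-based checks run at a few hundred grid cells and tens to a few
hundred replicates (e.g. 50 replicates at ~300 cells for parameter
recovery; 200 replicates at ~116 cells for test calibration), sizes at
which the relevant asymptotics are already visible while a full run stays
in the minutes range on one core.

## Known limitations

* The t-test degrees of freedom (n - p) and the plug-in treatment of the
  estimated correlation parameters are approximations; coverage is
  slightly below nominal at small n.
* PhyloSor similarity and the Gaussian kernel are partially confounded
  when all families have similar spatial scale; `beta` is then weakly
  identified (the likelihood is nearly flat in it) even though the fit and
  tests remain valid.
* The spherical overlay does not handle ranges crossing the antimeridian;
  the generator avoids producing them.
* With `alpha` estimated at 0 the fitted model collapses to OLS and
  `beta`, `gamma` are reported at arbitrary values within bounds.
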