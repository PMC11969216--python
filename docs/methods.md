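# Methods

This note documents the statistical models `mutclock` implements, the
choices made where the design was genuinely open, and what the synthetic
data used by the test suite does and does not establish about real data.

## Traits and units

The primary data are one row per species: the germline mutation rate per
site per generation `mu_G` (dimensionless, > 0), the generation time `GT`
in years (> 0, defined as the average age of parents), and a taxonomic
group label. The per-year rate is `mu_y = mu_G / GT` (per site per year).
Because the rates span roughly four orders of magnitude, all regressions
use `log10 mu_y` and `log10 GT`. Log base only shifts intercepts; log-log
slopes are base-invariant when both axes share a base (asserted by a
test). Species names are matched to tree tips by exact comparison after
case-folding and space/underscore normalization — no fuzzy matching, since
a silent mis-join is worse than a dropped species; dropped names are always
reported. Duplicate species rows are a hard error rather than being
averaged: the intended input is one estimate per species. Rows with
missing or non-positive rates or generation times are excluded and listed
with reasons in a rejects table.

## Brownian covariance

For a rooted tree with branch lengths in time units, the expected trait
covariance under Brownian motion is the matrix `C` with `C[i,j]` the
root-to-MRCA path length of tips *i* and *j* and `C[i,i]` the root-to-tip
distance. Polytomies are handled as-is (the matrix is well defined on any
topology; no random resolution). Pruning a tree keeps the retained tips'
depths unchanged: unary nodes are collapsed with branch lengths summed,
and when the kept clade hangs below the original root the shared stem is
retained as a root-edge length that counts toward every depth and every
covariance. This makes pruning commute exactly (to float round-off) with
taking submatrices of `C`, which the per-group fits rely on.
Non-ultrametric trees produce a logged warning, not an error — pruned
subtrees and user-supplied trees may legitimately vary. Zero-length
terminal branches can make `C` singular; that is handled in the
regression, not the tree code.

## PGLS

The fit is `y = b0 + b1 x` with residual covariance `sigma^2 V`,
`V = C(lambda)` keeping the diagonal of `C` and multiplying off-diagonals
by Pagel's `lambda`. Estimation whitens through a lower Cholesky factor of
`V` (solve, never an explicit inverse); coefficients are
`(X' V^-1 X)^-1 X' V^-1 y`, `sigma^2 = RSS_gls / (n - p)`, standard errors
from the diagonal of `sigma^2 (X' V^-1 X)^-1`, two-sided p-values from the
t distribution with `n - p` df. If `V` is numerically singular, a single
jitter of `1e-8 * mean(diag V)` is added with a warning before failing
hard. R-squared is defined against the GLS intercept-only fit under the
same `V`: `R^2 = 1 - RSS_model / RSS_intercept_only`, adjusted as
`1 - (1 - R^2)(n - 1)/(n - p)`; this definition is stated explicitly
because software conventions differ and any mismatch with other tools
should be diagnosable. The default is `lambda = 1` (pure Brownian), the
common default of comparative-methods packages; `lambda` can instead be
estimated by ML with a bounded one-dimensional search on [0, 1]
(tolerance 1e-6), with both boundary values checked explicitly because a
bounded interior search can stall short of an endpoint. With `lambda = 0`
the fit reduces exactly to OLS (tested to 1e-10 against explicit normal
equations); coefficients, SEs and the ML log-likelihood at `lambda = 1`
match an independent GLS implementation (R `nlme::gls` with a Brownian
correlation) on a frozen six-species fixture. Per-group fits prune the
tree to the group and report raw per-group p-values with no
multiple-testing correction, mirroring how such group tables are usually
presented; groups below `min_n = 3` are skipped, not errors.

Comparisons between two groups' slopes or intercepts use
`t = (a - b)/sqrt(SE_a^2 + SE_b^2)` with Welch–Satterthwaite degrees of
freedom built from each fit's residual df. This is one defensible
construction of a "two-sample t-test on two fitted coefficients"; the
quantity being compared is stated in the output so the construction is
auditable.

The doubling effect converts the log-log slope to an interpretable
percentage: `100 * (1 - 2^slope)` is the percent reduction in `mu_y` per
doubling of generation time (a slope of −0.71 gives ≈ 39%).

## Phylogenetic mixed model

The Gaussian mixed model is `y = X beta + u + e`,
`u ~ N(0, sigma_p^2 C)`, `e ~ N(0, sigma_r^2 I)`. Fixed-effect designs:
`base` (intercept + slope), `group` (+ treatment-coded group offsets,
alphabetically first group as reference — this affects printed
coefficients but not model comparison), and `interaction` (+ per-group
slope offsets, each interaction group needing ≥ 3 members). Estimation is
full ML, not REML, so likelihood-ratio tests on fixed effects are valid.
Internally the covariance is parameterized as
`sigma^2 (h * C/mean(diag C) + (1 - h) I)` with `h` in [0, 1]: `sigma^2`
is profiled analytically and `h` found by a deterministic bounded scalar
search (with both endpoints checked). This enforces non-negative variance
components by construction, reaches the boundaries exactly — `h = 1`
reproduces the `lambda = 1` PGLS coefficients (tested to 1e-6), `h = 0`
ordinary regression — and permits pinning `h` for diagnostic fits.
Boundary estimates are flagged, and LRT p-values whose null puts a
variance on the boundary are marked conservative. Model comparison
reports AIC with `k = n_fixed + 2` variance components and chi-square
LRTs with df equal to the difference in fixed-effect counts for declared
nested pairs; AIC ties are broken by stable input order.

## Errors-in-variables simulation

Since `mu_y` is `mu_G` divided by `GT`, error in `GT` enters the observed
log variables with opposite signs: with independent normals
`log mu_y_true`, `log GT_true`, and `e ~ N(0, sigma_e^2)`,

    log GT_obs   = log GT_true + e
    log mu_y_obs = (log mu_y_true + log GT_true) - log GT_obs
                 = log mu_y_true - e

so `Cov(log mu_y_obs, log GT_obs) = -sigma_e^2` and the population slope
is `-sigma_e^2 / Var(log GT_obs)` — a derivation verified in the tests
against a million-species Monte-Carlo replicate. The sweep holds
`Var(log GT_obs)` fixed (matched to the analysed data; the crossing ratio
is invariant to its actual value and to the `mu_y` variance, both
asserted), sweeps the ratio `sigma_e^2 / Var(log GT_true)` over a grid
(default 0–4 by 0.25), runs 100 replicate OLS regressions of
`log mu_y_obs` on `log GT_obs` per grid point at n = 133, and finds the
ratio where the mean slope reaches a target by linear interpolation.
The regression inside the simulation is deliberately ordinary least
squares — the sampled species are i.i.d., there is no tree — even though
the observed slope it is compared against comes from a PGLS; that is the
construction of the artifact model itself. Sampling means default to 0
(slopes are location-invariant; asserted). Seeding uses one master seed
with per-(grid-point, replicate) seed-sequence spawn keys, so any single
replicate is individually reproducible.

The closed form puts the crossing for a target slope `s` at ratio
`-s/(1 + s)`: ≈ 2.45 at `s = -0.71`, with Monte-Carlo runs at 100
replicates per point scattering roughly ±0.1 around it. Published analyses
of this artifact have quoted a ratio of about 2.2 at the same slope; the
package reports its own computed crossing next to the closed form and
flags the difference rather than matching the quoted figure, since under
this generating model the two cannot be reconciled exactly. Either way
the qualitative conclusion is unchanged: the error variance would need to
be more than twice the true variance in log generation time, which is not
a plausible level of measurement error.

## Synthetic data generator

The generator emulates the structure the analysis assumes: a seeded Yule
(pure-birth) tree — crown start with two lineages, so there is no stem
edge; one extra exponential waiting time after the last split so terminal
branches are strictly positive — with `log10 GT` evolving by Brownian
motion on the tree and `log10 mu_y` equal to a linear function of it plus
an independent Brownian residual. Two independent Brownian processes
(predictor and residual) are used rather than a correlated bivariate
process: simpler, and exactly the linear-model generating assumption PGLS
makes. Groups are contiguous blocks of the tree's tip order, so group
labels are confounded with phylogeny roughly the way real taxonomy is.
Optional normal error is injected into observed `log10 GT` only, with
`mu_G` kept consistent with the TRUE generation time, so the artifact
propagates exactly as in the measurement-error model above.

Defaults, chosen once as the study-like conditions: 133 species, 9
groups, generating slope −0.71; intercept −8.5 (`mu_y ≈ 3e-9` per site
per year at `GT` = 1 year, mid-range of observed eukaryote estimates);
birth rate 1 per unit time (time units are arbitrary — PGLS is invariant
to covariance scale, which is tested); Brownian rates 0.15 (log10 GT) and
0.075 (residual) per unit depth, giving a tip spread of log10 GT of
roughly ±1 and an adjusted R² near 0.5–0.6, the magnitudes seen in real
compilations; no GT error by default. What the generator does **not**
emulate: unequal group sizes, non-Brownian (e.g. Ornstein–Uhlenbeck or
rate-shifted) trait evolution, extinction in the tree, heteroscedastic
estimation error in `mu_G`, or correlated errors between `mu_G` and `GT`.
Tests passing on this generator therefore establish the correctness and
calibration of the machinery under its stated assumptions, not the truth
of those assumptions for any particular real dataset.

## Problem sizes and numerical conventions

Stochastic suite sizes, chosen as the package's own accuracy/runtime
trade-off: parameter recovery uses 200 datasets at n = 133; null p-value
calibration 1000 fits on one fixed 133-tip tree; mixed-model AIC behaviour
and LRT null calibration 200 + 400 runs at n = 80 with two groups;
Brownian tip-covariance checks 2000 replicates on a 10-tip tree. All
simulations are seeded and deterministic; optimizer determinism is
asserted (identical inputs give bit-identical variance components).
Degenerate inputs fail early with typed errors: < 3 matched species,
constant predictor, rank-deficient designs (the aliased term is named),
unbracketed sweep targets (the message says to extend the grid).

## Known limitations

- Gaussian traits only; no OU or other non-Brownian covariance models, no
  non-Gaussian mixed models, and a single phylogenetic random effect.
- Generation-time estimation itself (from life-history data) and
  corrections for the difference between experimental parental age and
  wild generation time are out of scope; `mu_y` is taken at face value as
  `mu_G / GT`.
- The adjusted-R² and group-comparison conventions are stated above;
  other software may print slightly different values for the same fit.
- AIC counts both variance components as parameters even when one is
  estimated on the boundary, where the usual asymptotics are conservative.
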