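# mutclock

Phylogenetic comparative analysis of germline mutation rates per year and
generation time across eukaryotes.

## The scientific problem

Rates of molecular evolution vary widely between species and are strongly
correlated with generation time: lineages that reproduce faster tend to
accumulate substitutions faster per year. A direct explanation would be that
the germline mutation rate per site per year,

    mu_y = mu_G / GT,

where `mu_G` is the pedigree- or mutation-accumulation-estimated mutation
rate per site per generation and `GT` the generation time in years, is itself
negatively correlated with generation time. `mutclock` implements the
comparative pipeline needed to test this claim on a table of per-species
estimates and a time-calibrated phylogeny:

- **Trait table handling** — validate per-species `mu_G`, `GT` and taxonomic
  group, derive `mu_y` and the `log10` traits, and reconcile species names
  with the tips of a Newick tree.
- **PGLS** — generalized least squares of `log10 mu_y` on `log10 GT` with
  residual covariance `sigma^2 * C(lambda)`, where `C` is the Brownian-motion
  expected covariance (entry *(i,j)* = shared root-to-MRCA path length) and
  Pagel's `lambda` rescales the off-diagonals (default 1, ML estimation
  available). Fitted globally and within each taxonomic group, with
  Welch-type comparisons of group slopes/intercepts and the "doubling
  effect" reading of the slope: a log-log slope *b* means doubling `GT`
  multiplies `mu_y` by `2^b`.
- **Phylogenetic mixed model** — `y = X beta + u + e` with
  `u ~ N(0, sigma_p^2 C)` and `e ~ N(0, sigma_r^2 I)`, fixed effects
  optionally including group and group-by-slope terms; ML fits compared by
  AIC and likelihood-ratio tests to ask whether the rate/generation-time
  relationship differs among groups.
- **Errors-in-variables simulation** — because `mu_y` is a ratio with `GT`
  in the denominator, measurement error in `GT` alone produces a spurious
  negative slope. The simulation samples independent
  `log mu_y_true`, `log GT_true` and error `e`, forms
  `log mu_y_obs = log mu_y_true - e` and `log GT_obs = log GT_true + e`
  with the total variance of `log GT_obs` held at the data's value, and
  finds how large the error-to-systematic variance ratio
  `sigma_e^2 / Var(log GT_true)` must be for the artifact to reach an
  observed slope. The closed form (population slope
  `-sigma_e^2 / Var(log GT_obs)`) is computed alongside the Monte-Carlo
  sweep.
- **Synthetic data generator** — seeded Yule trees with Brownian traits and
  known ground truth, so every stage is testable without external downloads.

## Worked example

Generate a dataset with the structure the analysis assumes (133 species in
9 groups on an ultrametric tree, generating slope −0.71) and run the full
pipeline — the bundled `examples/fixture` is exactly this, written by
`mutclock simulate`:

```sh
mutclock run-all --table examples/fixture/table.tsv \
                 --tree examples/fixture/tree.nwk \
                 --seed 1 --out runs/example
```

prints (abridged):

```
PGLS fit (lambda = 1, n = 133)
  slope     = -0.74  (SE 0.055, P = 1.34e-26)
  intercept = -8.47  (SE 0.196)
  adjusted R^2 = 0.58
  doubling generation time changes mu_y by -40%

group               n    slope     P-value   adj R2
---------------------------------------------------
group_01           15    -0.55     0.0036b     0.45
...

Generation-time error sweep (n = 133, 100 replicates/point)
  target slope: -0.74
  Monte-Carlo crossing ratio (error var / systematic var): 2.83
  analytic crossing ratio: 2.83
```

Reading this: the global PGLS slope (−0.74) sits within sampling error of
the generating value −0.71 and implies that doubling generation time lowers
the per-year rate by ~40%; every per-group slope is negative (marks `a`/`b`
flag P < 0.05 / P < 0.01); and for measurement error in generation time
alone to fake a slope of −0.74, its variance would have to be ~2.8 times
the true between-species variance in log generation time — far beyond any
plausible level of estimation error, which is the argument that the
correlation is genuine. Full-precision results land in
`runs/example/report.json` plus TSV tables and the pruned tree.

To analyse real data, point `--table` at a TSV/CSV with columns
`species, mu_g, generation_time, group` (rename via a config file) and
`--tree` at a time-calibrated Newick tree whose tip labels match the
species names (case and space/underscore differences are normalized).
Individual stages are exposed as `mutclock fit`, `groups`, `pglmm`,
`error-sim` and `simulate`.

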