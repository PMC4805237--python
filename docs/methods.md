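# Methods

## The problem

A species with many named subspecies poses a statistical question: are the
named forms *diagnosable* — can a specimen be assigned to its population
from the trait alone — or does the trait vary clinally, so that the named
boundaries are arbitrary cuts through a gradient? The package implements
the standard morphometric chain for answering this on museum series: check
that the measurements are repeatable, reduce the correlated bill traits to
a composite size score, describe group structure (clustering, discriminant
analysis), and apply the 75% rule pairwise in both directions.

## Repeatability

One-way ANOVA with specimen as the factor and measurement session as the
replicate. With `a` specimens, `N` total measurements and per-specimen
session counts `n_i`:

```
n0        = (N − Σ n_i² / N) / (a − 1)        (= k for balanced k sessions)
s²_A      = (MS_among − MS_within) / n0
r         = s²_A / (s²_A + MS_within)
```

`r` is the intraclass correlation: the share of measurement variance that
is real among-specimen difference rather than session noise. It is
returned unclamped — `MS_among < MS_within` gives a (flagged) negative
estimate, which is informative about tiny samples and is not cosmetically
truncated. All-identical measurements define `r = 1` with a `degenerate`
flag. Ordinal color scores are entered as numeric values in the same
decomposition; this treats adjacent score steps as equidistant, which is
the conventional compromise and is recorded here as such.

## Composite bill size

PCA of the **correlation** matrix of bill length, width and depth (the
traits differ in scale; correlation weighting keeps the composite from
being dominated by the longest measurement). The covariance alternative is
exposed as `scale="covariance"`. PC1 is oriented so that it correlates
positively with bill depth, making "larger score = deeper bill" stable
across runs. Scores are projections of standardized variables; variance
shares are eigenvalue fractions.

## Sex screen

Sexual size dimorphism would force sex-stratified analyses, so sex is
screened first with a MANOVA adjusted for subspecies: fit the additive
two-factor linear model, form the Type II hypothesis SSCP for sex as the
drop in residual cross-products from the subspecies-only model, take
Pillai's trace `V = tr[H(H+E)⁻¹]` with the standard approximate-F
transformation. Type II is the right adjustment for an additive model with
no interaction term; sequential fitting can be had by passing
`covariate_factor=None`. Specimens of unknown sex are excluded from the
screen only. The pipeline pools sexes when the screen's p-value exceeds
`manova_alpha` (default 0.05) or when `force_pool_sexes` is set; in a
seeded synthetic run the screen is a true null, so roughly one seed in
twenty will trip it by chance — the pipeline records the flag and
continues pooled, matching the analysis design.

## Outlier screen

Squared Mahalanobis distances from the pooled centroid, paired with
chi-square(3) quantiles at plotting positions `(i − 0.5)/n`. This is a
screening table for QQ-style inspection, deliberately without a rejection
rule: on real museum data, apparent outliers are usually data-entry or
label problems that deserve inspection, not automatic deletion.

## Clustering and the number of clusters

Agglomerative complete linkage on Euclidean distances over the three raw
bill traits (scipy linkage). The number of clusters is chosen by a
three-index majority vote over k = 2..10: Calinski–Harabasz (arg-best),
mean silhouette (arg-best), and a Duda–Hart-style stopping rule (smallest k
whose refinement to k+1 is an unjustified split at the normal-theory
critical value, z = 3.20). Ties go to the smaller k. This is an
intentionally small, fully documented ensemble, not a reproduction of any
30-index voting package; on genuinely clinal data the vote can hover
between 2 and 3, which is a fair description of a step cline with
intermediates.

## Discriminant analysis

Canonical LDA (scikit-learn, eigen solver): axes from the between- versus
pooled-within-group eigenproblem, priors proportional to group sizes
(uniform available), classification by largest posterior, confusion matrix
by resubstitution of the training specimens. Resubstitution is reported
because the question is descriptive overlap among the series at hand, not
out-of-sample prediction; cross-validated rates would be slightly lower.
Axes are sign-normalized to a positive bill-depth coefficient — canonical
axis signs are otherwise arbitrary.

## Diagnosability

For continuous characters (by default the PC1 composite, but any single
trait can be passed) the ordered-pair index is

```
D_ij = |x̄_i − x̄_j| − t(p_i, n_i−1)·s_i − t(p_j, n_j−1)·s_j ,
p_i = 0.75 (focal), p_j = 0.99 (reference), one-tailed t quantiles.
```

`D ≥ 0` in one direction means the focal population's inner 75% quantile
(toward the reference) lies beyond the reference's outer 99% bound; the
pair is accepted only reciprocally. The threshold convention is `D ≥ 0`
(an exactly-zero index counts as diagnosable). Degrees of freedom are
n − 1 per group; sd = 0 simply drops that term. The index is strictly
decreasing in either sd and increasing in the mean gap, and converges to
the normal-quantile form (0.6745, 2.3263 multipliers) as n grows.

For ordinal color scores the rule is applied empirically: the fraction of
focal scores strictly outside `[min(ref), max(ref)]`, compared with 3/4 in
exact rational arithmetic. Because the reference range is an extreme
statistic, this rule is brittle — one unusually pale or dark reference
specimen collapses the fraction — and seed-to-seed variation in the
synthetic results reflects that honestly.

## The synthetic world

One locale per subspecies, ordered geographically (Florida, then clockwise
around the Caribbean). Bill means follow
`baseline + amplitude · g(position)` with `g` a logistic step centered
between the Greater and Lesser Antilles (`paper_like`), linear, or flat
(`flat_null`); intermediates (Antigua/Barbuda, the mainland) sit at
half-height. Defaults, chosen once as realistic for a medium-sized cuckoo
and fixed:

| quantity | default | why |
|---|---|---|
| baseline (length, width, depth) | 19.0, 6.0, 7.0 mm | typical nares-to-tip bill of the species group |
| within-locale sd | 0.9, 0.45, 0.40 mm | ~5% CV, usual for skeletal-adjacent traits |
| trait correlation | 0.5 | weakly integrated bill dimensions; gives a dominant but not degenerate PC1 |
| step amplitude | 3.1, 1.55, 1.35 mm (~3.4 within-locale sd) | calibrated so the extreme regions clear the 75%-rule bound (~3.2 sd at n≈25) by ~1 sd while half-cline intermediates stay ~1 sd below it — the designed diagnosability geometry of the world |
| session noise sd | 0.12, 0.27, 0.08 mm | back-solved from target mean repeat differences (≈0.13, 0.31, 0.09 mm) via E&#124;d&#124; = 2σ/√π |
| color model | 4 latent Gaussians, pairwise r = 0.7, thresholds −1,0,1,2,3 → scores 0–5 | ordinal scores with heavy overlap ("exceptions are common"); darkness profile peaks at Dominica |
| sample sizes | the 12 museum-series counts, total 274 | the study conditions |

Sex labels are drawn independently of phenotype (5% unknown), so the sex
screen is a true null. Collection dates are uniform over 1877–1986 and used
only for tabulation. Randomness derives from a single seed with per-stage
substreams (`SeedSequence([seed, stage])`), so re-running one stage
reproduces it without replaying the others.

What the generator does **not** emulate: within-locale geographic
substructure, collection-date/feather-wear effects on color, missing-data
patterns of real museum series (missingness must be injected explicitly),
measurement drift between sessions, and any genetic process — it targets
the statistical structure of the measured phenotypes only. Passing tests
therefore certify the statistical machinery, not the taxonomic conclusion
for any real series.

## Numerical and design notes

- Color ordinal support defaults to 0–5 (six levels, 0 palest) and is
  configurable end-to-end; sources differ on whether such scales are
  written 0–5 or 1–5.
- Complete-case filtering is stage-specific and logged; values are never
  imputed.
- Spearman correlations use average ranks for ties (pandas/scipy
  convention); a constant column yields flagged NaNs.
- Cluster merge heights are non-decreasing by construction of complete
  linkage; partitions are invariant to row order (ties between equal
  heights are resolved by cluster formation order and are measure-zero for
  continuous data).
- Repeatability recovery tolerance: ±0.05 at 500 re-measured specimens,
  ±0.15 at the museum-series size of 17 — the small-sample sd of an ICC
  near 0.9 at n = 17 is roughly 0.05–0.10, so these bands are ~2 se.
- Problem sizes in the test suite (274-row tables, 100-seed recovery loops,
  oracle clustering at n ≤ 8) keep the whole suite around fifteen seconds
  while leaving every statistical check at full strength.

## Known limitations

- The optimal-k vote is a 3-index stand-in; ensembles with many more
  indices can vote differently on borderline clinal data.
- The parametric index assumes within-group normality of the composite
  score; heavy tails inflate sd and deflate D conservatively.
- The empirical color rule inherits the brittleness of range statistics
  (see above); with small reference samples its fraction is noisy.
- MANOVA uses a common error SSCP across subspecies (homoscedasticity);
  no robust or permutation variant is provided.
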