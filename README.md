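# cuckoomorph

Tools for deciding whether named subspecies of a widespread bird are
*diagnosable* from museum-specimen morphometrics, built around the classic
case of Mangrove Cuckoo (*Coccyzus minor*): twelve named island and mainland
forms whose bill size varies clinally around the Caribbean basin, with a
steep step between the small-billed Greater Antilles and the large-billed
Lesser Antilles, bridged by intermediates on Antigua and Barbuda.

The package is aimed at systematists and morphometricians who have a
specimen table (three bill measurements in mm, ordinal ventral color scores)
and want the full chain of analyses that the subspecies question requires:

1. **Measurement repeatability** — intraclass correlation from a one-way
   ANOVA over re-measured specimens:
   `r = s²_A / (s²_A + MS_within)` with `s²_A = (MS_among − MS_within)/n₀`.
2. **Composite bill size** — PC1 of the correlation matrix of bill length,
   width and depth.
3. **Structure** — Pillai's-trace MANOVA sex screen (adjusted for
   subspecies), Mahalanobis outlier screening, complete-linkage clustering
   with an internal-index vote on the number of clusters, and canonical
   discriminant analysis with resubstitution confusion matrices.
4. **Diagnosability under the 75% rule** — for an ordered pair of
   populations (focal *i*, reference *j*):

   `D_ij = |x̄_i − x̄_j| − t(0.75, n_i−1)·s_i − t(0.99, n_j−1)·s_j`

   with one-tailed t quantiles. `D ≥ 0` means ≥75% of the focal distribution
   lies beyond essentially all of the reference distribution; a valid
   subspecies must pass in **both** directions (reciprocal diagnosability).
   For ordinal color scores the rule is applied directly: the fraction of
   focal scores strictly outside the reference's observed range.

A synthetic-cline generator (`cuckoomorph.synthetic_cline`) produces
specimen tables with this exact structure — logistic bill-size step,
unimodal color-darkness profile peaking at Dominica, duplicate measurement
sessions with known repeatability, Table-like sample sizes (274 specimens) —
so every stage can be tested against ground truth.

## Worked example

```sh
$ cuckoomorph simulate --preset paper_like --seed 1 -o demo.csv --repeats-output demo_repeats.csv
wrote 274 specimens to demo.csv
wrote 17 repeat pairs to demo_repeats.csv

$ cuckoomorph repeatability demo_repeats.csv
                       r  ms_among  ms_within   n0  ...  max_abs_diff  mean_abs_diff
bill_depth_mm   0.969934  0.578125   0.008824  2.0  ...           0.3       0.105882
bill_length_mm  0.976548  2.900294   0.034412  2.0  ...           0.5       0.217647
bill_width_mm   0.738027  0.493676   0.074412  2.0  ...           0.9       0.323529

$ cuckoomorph diagnose demo.csv --grouping region
                 florida_bahamas greater_antilles antigua_barbuda lesser_antilles south_america middle_america
florida_bahamas                -            -2.43           -1.20           1.06*         -0.93          -0.90
greater_antilles           -2.65                -           -1.09           1.16*         -0.82          -0.79
antigua_barbuda            -0.83            -0.51               -           -1.11         -2.88          -2.22
lesser_antilles            0.79*            1.11*           -1.75               -         -1.26          -0.60
south_america              -0.75            -0.43           -3.07           -0.82             -          -2.14
middle_america             -1.08            -0.76           -2.76           -0.51         -2.49              -
```

Rows are the focal population, columns the reference; starred cells pass
`D ≥ 0`. Read off the biology: the Lesser Antilles are reciprocally
diagnosable from Florida/Bahamas and from the Greater Antilles (both
directions starred), while the phenotypically intermediate Antigua/Barbuda,
South American and Middle American populations are diagnosable from no one —
the signature of a cline rather than discrete taxa. On this synthetic
series PC1 carries 88% of trait variance and repeatability of the 17
re-measured specimens is 0.74–0.98 depending on trait.

`cuckoomorph run-all --preset paper_like --seed 1 -o out/` writes the whole
bundle (counts, repeatability, PCA scores, confusion matrices,
diagnosability matrices, reciprocal verdicts, `report.json`). The same
commands accept any conforming CSV via `--input-csv`/positional path, with
a YAML column mapping (`--schema`) for third-party tables.

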