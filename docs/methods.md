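# Methods

## Scope and model

`broodmate` operates on diploid codominant genotypes at L unlinked loci.
Alleles are positive integer codes; a genotype is an unordered pair of
codes, called or missing as a unit (half-calls are rejected at parse time).
The missing sentinel on input is 0 or a blank cell, matching common
fragment-table exports and the Genepop `000` convention.

### Pair predictions

All pair statistics are exact expectations over the four equally likely
offspring genotypes of a sire × dam cross at one locus:

| statistic | definition | range |
|---|---|---|
| H_exp | heterozygote fraction of the 4 outcomes | {0, ¼, ½, ¾, 1} |
| ar | distinct alleles among the 4 parental copies | 1–4 |
| weak | parental copies form the 3:1 pattern AAAB | boolean |

Aggregates over loci: H_mean is the unweighted mean of H_exp, ar_total the
sum of ar, and wh_share the mean of (0.5 if weak else 0) — the expected
share of offspring genotype-locus outcomes that are "weak" heterozygotes
(heterozygous, but the parents differ by a single allele copy). A locus
where either parent is uncalled is excluded from all three aggregates; this
keeps the statistics unbiased within the evaluable data at the cost of
comparing pairs over slightly different locus sets when missingness is
uneven.

The group-level "share of weak heterozygotes" has no unambiguous
definition at the cohort scale; this package operationalizes it as the
mean pair-level share over all member sire × dam pairs and labels it as
such wherever it is reported.

### v index

Pairs are ranked by `v = i_H·H/max(H) + i_ar·ar/max(ar) +
i_wh·(1 − wh/max(wh))` with maxima over the enumerated cohort of all
male × female pairs. Defaults i_H = 0.45, i_wh = 0.1, i_ar = 0.45; weights
are normalized to sum to 1 at construction, so only their ratios matter.
Normalizing by the cohort maximum (rather than a cohort mean or a
theoretical maximum) makes v ∈ [0, 1] with the best attainable pair at 1;
if a cohort maximum is 0 (e.g. no pair produces any weak heterozygote) the
corresponding relative term is defined as its best value, avoiding 0/0
while preserving the semantics. The reversed wh term encodes that weak
heterozygotes are undesirable.

### Pair selection

Greedy selection — repeatedly take the highest-v pair whose sire and dam
are both unused — is the default because it guarantees the nesting
property (the K-pair set is always contained in the (K+n)-pair set), which
is what a hatchery manager expanding a breeding plan expects. Ties in v
break by higher ar_total, lower wh_share, then lexicographic male and
female ID, making outputs reproducible. An `exact` method solves the
maximum-total-v assignment of exactly K disjoint pairs via
`scipy.optimize.linear_sum_assignment`, padding with M−K dummy columns
whose bonus (2.0 > any v) forces exactly K real matings; exact total v is
never below greedy's, but exact sets need not nest.

### Group spawning

Objective: lexicographically maximize (alleles transmitted, expected
progeny heterozygosity). Alleles transmitted at a locus is the size of the
union of all selected parents' alleles there; under equal contribution any
parental allele reaches the progeny group. Progeny heterozygosity per
locus is 1 − Σₖ p♂(k)p♀(k), with sex-specific frequencies giving each
*called* parent equal weight (an uncalled parent drops out of that locus's
pool, so frequencies stay normalized); loci with no called parent on one
side are excluded from the H mean but still contribute their one-sided
union to the allele count.

Search: exhaustive enumeration when C(M,m)·C(F,f) ≤ limit (default 10⁷),
implemented with per-individual bitmasks over the (locus, allele)
inventory so subset union is a bitwise OR and the allele count a popcount;
ties on the allele count are re-scored with the full prediction. Above the
limit, greedy construction on the allele-coverage objective (monotone and
submodular, so greedy alone is within 1 − 1/e of optimal) followed by
best-improvement 1-swap exchange until no single-individual replacement
improves the lexicographic key; the result is locally optimal and, on all
small instances tested, equal to the exhaustive optimum. Set-level ties
break by higher H, lower group wh_share, then the smallest sorted ID
tuples. The `seed` argument is recorded for reproducibility but the
default search is fully deterministic.

`list_alternative_sets` enumerates every subset pair meeting an
allele-count floor and a heterozygosity band — useful when the nominal
best set is impractical (a fish dies, a tank is unavailable) — and
requires the space to fit the exhaustive budget.

### Diversity statistics

Ho is the fraction of called genotypes with two distinct alleles; He is
the plug-in gene diversity 1 − Σp² over called allele copies, with an
optional 2n/(2n−1) small-sample correction (off by default; the choice of
estimator variant is not fixed by any external constraint we could
verify). Across loci, Ho and He average unweightedly and allele counts
sum. No rarefaction is applied: `ar` is a raw distinct-allele count, not
allelic richness.

## Synthetic data

`simulate_panel` draws genotypes per locus from specified allele
frequencies with a heterozygote-deficit parameter f_is:
P(het k,l) = 2pₖpₗ(1 − f_is), P(hom k) = pₖ² + f_is·pₖ(1 − pₖ) — f_is = 0
is Hardy–Weinberg, f_is = 1 all-homozygote. Missingness is independent per
genotype (both copies together). Panels are bit-reproducible from the spec
seed.

`study_scale_fixture` emulates the *shape* of the motivating survey: 23
males, 25 females, 13 microsatellite loci (7 tri-allelic + 6 bi-allelic =
33 alleles), skewed frequencies (minor alleles ≥ 0.14 so none is likely to
drop out of a 48-fish sample), f_is = 0.1 and no missing data, chosen to
put realized overall Ho in the depleted-broodstock band 0.30–0.46. The
generator resamples deterministically from the seed until the realized
panel carries all 33 alleles and lands in the Ho band. What it does *not*
emulate: real linkage, null alleles, genotyping error, family structure or
any actual genotype values — so passing tests demonstrate correctness of
the algorithms on panels with realistic marginal structure, not agreement
with any particular real broodstock.

## Numerical and engineering choices

* All combinatorial counts use exact integer arithmetic (`math.comb`);
  printed counts reproduce bit-exactly at any size.
* Pair and group statistics are rational expectations computed in floating
  point from small integer counts; no iterative numerics are involved.
* Monte-Carlo cross-checks in the test suite use 10⁵ offspring draws and a
  3-standard-error acceptance band; brute-force enumeration oracles cover
  all pair genotype shape classes exhaustively and subset search on 6×6
  panels (C(6,3)² = 400 set pairs).
* Problem sizes in tests and the acceptance script (6–8 individuals per
  sex for brute-force comparisons, the 48-fish fixture for pipeline runs,
  greedy_exchange for the 4+4 and 8+8 group searches) were chosen so the
  whole suite completes in seconds while every algorithmic path — parsing,
  closed forms, both selection methods, both search modes — is exercised
  against an independent oracle.

## Limitations

* Equal parental contribution is hard-wired into the group model; in real
  mass spawning, contributions can be highly skewed, which would lower
  realized allele retention below the prediction.
* Loci are treated as independent: no linkage, no gametic correlation.
* The v index is cohort-relative — v values are not comparable across
  panels or candidate pools.
* The greedy_exchange search is heuristic above the exhaustive budget; it
  carries a local-optimality guarantee and a (1 − 1/e) coverage bound, not
  global optimality.
* No kinship/pedigree information is used; selection is purely
  genotype-based.
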