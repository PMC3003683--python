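# Methods

## Model and procedure

`sagemine` implements a threshold-based, set-algebraic screen over SAGE
tag counts. It deliberately contains no statistical significance
machinery: a tag is mined when its normalized fold change crosses a
user-chosen factor in every included case-vs-control screen and in no
excluded one. The pipeline is:

1. **Normalization.** Raw counts become tags per million,
   `s_ij = c_ij · 10⁶ / N_j`, so libraries of different depth compare on
   an equal baseline. TPM is always derived from stored raw counts
   (computed as `(c · 10⁶) / N` so the vectorized matrix agrees bit for
   bit with the scalar definition); the `.matrix` file stores raw
   counts, which also preserves the detected/undetected distinction a
   TPM of zero would blur.
2. **Condition evaluation.** Each condition `(a, op, factor, b)` yields
   a tag set. The `>` and `<` screens use the adjusted fold (below) with
   a non-strict threshold (`fold ≥ factor`) and require detection in
   the up-library, which prevents 0/0 artifacts from qualifying. `!=`
   is pure presence/absence on raw counts and ignores the factor.
3. **Set algebra.** Included conditions intersect; excluded conditions
   subtract as a union. All-included mines common markers; one tissue
   included and the rest excluded mines that tissue's specific markers;
   swapping `>` and `<` everywhere mines suppressor candidates.
4. **Ranking.** Score = sum of fold values over included conditions;
   ties break lexicographically by tag. The report is truncated to the
   top N (default 10, hard maximum 100).

### Fold values and zeros

Fold = TPM(numerator) / TPM(denominator), per condition reading
(`>` and `!=` columns are a/b, `<` columns are b/a). Two rules keep the
table finite and asymmetric on purpose:

* numerator TPM 0 → fold 0 (flags `zero_numerator` / `both_zero`);
* denominator TPM 0 (numerator positive) → divide by the smallest
  positive TPM in the denominator library (flag
  `adjusted_denominator`), so presence-against-absence is large but
  bounded by what the library could have detected.

A fold against an entirely empty library is a domain error. Every fold
cell carries its provenance flag so downstream display can distinguish
measured from adjusted ratios.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `factor` | per condition, ≥ 1 | fold threshold of a screen; 2 is a typical marker screen |
| `top_n` | 10 (max 100) | length of the ranked report |
| `scale` | `linear` | display transform: identity, log2(1+x), log10(1+x), √x; all rank-preserving (log1p keeps tiny values distinct) |
| `PlantSpec.marker_fold` | 8 | planted case/control expression ratio |
| `PlantSpec.library_depth` | 50,000 | tags sequenced per synthetic library |
| `PlantSpec.libs_per_tissue` | (2, 1) | case and control libraries per tissue |
| `PlantSpec.n_background_tags` | 1000 | undifferential background transcripts |

The generated condition pool uses `factor = marker_fold / 2`, i.e. a
screen at half the planted effect.

## The synthetic study

The generator emulates a four-tissue (colon, ovary, pancreas, breast)
case/control SAGE design. Each library is one multinomial draw of
`library_depth` tags from a frequency pool: background tags have
relative abundance Uniform(0.5, 1.5), identical in expectation between
cases and controls; common markers are multiplied by `marker_fold` in
every case pool, tissue-specific markers only in their tissue's case
pools, suppressors divided by `marker_fold` in every case pool. Folds
are applied to expected frequencies *before* sampling, so realized
folds fluctuate around the planted value. Two case libraries per tissue
give the per-case intersection that the multi-pool screening design is
built around.

What this does **not** emulate: the heavy-tailed abundance distribution
of real transcriptomes (real SAGE libraries are dominated by singletons
and a few very abundant tags), sequencing errors, ditag/linker
artifacts, or biological replicate variance beyond multinomial
sampling. Passing recovery tests therefore demonstrates the correctness
of the screening algebra and its behaviour under counting noise at
moderate abundance — not false-positive rates in the singleton regime,
where a threshold-only method is known to be noisy.

With the default design the planted effect (8-fold) sits well above the
screening factor (2), and background tags have expected counts around
24–73, so recovery of every planted marker is the norm. Two noise
effects remain visible and are reported honestly rather than suppressed:
occasional background tags pass a single tissue's screens at factor 2
(a 2-fold Poisson excursion on a low-count tag — the acceptance report
counts these as `specific_screen_false_positives`), and, rarely, a
planted tissue-specific marker is excluded because noise pushes it past
factor 2 in *another* tissue's screen (exclusion-by-union working as
defined). At factor 4 both effects vanish in practice.

## Numerical and design choices

* **Non-strict threshold.** `fold ≥ factor`, stated explicitly because
  "more than" is ambiguous at equality; monotonicity (member sets
  shrink as the factor grows) holds either way.
* **Exclusion = union.** A tag satisfying *any* excluded condition is
  removed; this is what makes tissue-specific sets disjoint from other
  tissues' marker sets.
* **Ranking score.** The sum of folds over included conditions is the
  simplest statistic consistent with "top scores" reporting; it equals
  the fold itself for a single screen. Ties break lexicographically so
  output is deterministic.
* **Clustering.** Average-linkage agglomerative clustering, Euclidean
  distance on scale-transformed fold rows. Rows are canonicalized
  (sorted by tag) before linkage, making leaf order and merge structure
  invariant to input row order; exact-distance ties resolve toward the
  lexicographically smallest tag.
* **Heatmap normalization** is per whole table, not per row or column,
  so color is comparable across libraries and conditions in one panel.
  White = 0, full red = table maximum, gray = raw count 0
  ("undetectable", distinct from a zero-TPM value).
* **Degenerate inputs.** Empty libraries are storable but cannot be a
  fold denominator; an all-zero heatmap renders white; clustering needs
  at least two rows; an empty condition pool or a pool with no included
  condition is a configuration error.
* **File formats.** `.lib` files carry `#key: value` headers (id,
  title, tissue, tag_type, enzyme) over `TAG<TAB>count` lines;
  duplicate tags are summed and lowercase is uppercased, each with a
  warning; the total count is always recomputed from the body. Writers
  sort tags lexicographically, so write→read→write is byte-stable.

## Problem sizes

The test suite runs scaled-down studies (2 tissues, 200 background
tags, depth 20,000) for unit checks and the full four-tissue design
(1000 background tags, depth 50,000, 10 fixed seeds) for the recovery
suite; the acceptance script uses the full design on a seed-derived
10-study panel plus 100 random instances (≤ 50 tags, ≤ 6 libraries,
≤ 6 conditions) for the brute-force cross-check. These sizes were
chosen to exercise every code path with comfortable statistical margins.

## Known limitations

* No p-values, FDR control or count-model tests: mining is purely
  threshold-based, so low-count tags are noisy at small factors.
* One condition compares exactly two libraries; pooled/averaged group
  comparisons are out of scope by design.
* Tag-to-gene mapping scores are treated as opaque ordering keys; no
  attempt is made to interpret or recompute them.
* No network retrieval: all libraries, matrices and mapping tables are
  local files.
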