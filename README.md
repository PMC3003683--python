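# sagemine

Cross-tissue mining of SAGE (serial analysis of gene expression)
libraries: merge tag-count libraries into a tags-per-million expression
matrix, screen it through a pool of pairwise case-vs-control conditions
combined by set algebra, rank and visualize the mined tags, and map tags
to genes and libraries.

## The problem

A SAGE library is one sample's table of short transcript tags (10, 11,
17 or 21 bp, anchored at an NlaIII or Sau3A site) and their counts.
Classical SAGE comparison tools pool all cases against all controls,
which erases tissue identity: a tag that is up in breast tumors only
cannot be told apart from one up in every tumor. `sagemine` instead
screens each case library against its own tissue control individually
and combines the per-screen tag sets with set algebra, so the same
condition pool yields, by toggling inclusion flags, *common* tumor
markers (up in every tissue), *tissue-specific* markers (up in one
tissue and not mined in the others), and, with the operators reversed,
tumor *suppressor* candidates (down in every tissue). The intended users
are transcriptomics researchers doing in-silico marker screens on public
or in-house SAGE data.

## The method

Counts are normalized to tags per million, `s_ij = c_ij · 10⁶ / N_j`,
giving the matrix **S** (rows = tags, columns = libraries). Each
condition *k* in the pool is a tuple
`(Lib_a, op_k, factor_k, Lib_b, inclusion_k)` with `op_k ∈ {>, <, !=}`.
Its tag set `T_k` contains the tags whose adjusted fold reaches
`factor_k`:

* `>` : fold(a/b) ≥ factor and the tag is detected in a,
* `<` : fold(b/a) ≥ factor and the tag is detected in b,
* `!=`: present in a (raw count > 0) and absent from b.

Folds divide TPM by TPM with two zero rules: a zero numerator keeps the
fold at zero, and a zero denominator is replaced by the smallest
positive TPM in the denominator library. The mined set is

```
mined = ⋂ {T_k : inclusion_k} \ ⋃ {T_k : not inclusion_k}
```

ranked by the sum of fold values over the included conditions (top 10 by
default, configurable up to 100). TPM and fold tables render as
white-to-red heatmaps in four scales (linear, log2, log10, square root),
with gray for tags undetectable in a library, and mined tags can be
clustered hierarchically on their fold vectors.

## Worked example

Simulate a four-tissue case/control study with planted markers, then
mine the common tumor-marker candidates:

```sh
sagemine simulate --out-dir demo --seed 1
sagemine extract --matrix demo/study.matrix --pool demo/conditions.tsv \
    --out-prefix demo/common
```

The second command logs
`12 libraries, 8 conditions (8 included), 10 tags mined` and writes
three TSV tables. `demo/common_tags.tsv` begins:

```
tag	score
TTTGTCCTAC	67.2131
CGTTAGTCCT	66.6749
TCCTCCGGAA	63.5958
ACTACCTAGC	62.4368
...
```

Each row is a mined tag with its ranking score — the sum of its fold
values over the eight included case-vs-control screens; with eight
screens and eight-fold planted effects, scores near 8 × 8 = 64 are
exactly what a true common marker should show. All ten tags are planted
common markers listed in `demo/ground_truth.tsv`. Flipping the inclusion
flags in `demo/conditions.tsv` to one tissue (label column) mines that
tissue's specific markers instead; `sagemine heatmap --kind fold
--cluster` renders the fold table. `sagemine tag2gene` and
`sagemine tag2lib` answer annotation queries against a 5-column
tag-to-gene TSV and a set of `.lib` files.

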