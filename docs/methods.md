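# Methods

## Data model

Four RNA classes are analyzed as separate libraries over a two-stage,
three-replicate design (6 samples). Counts are held in feature x sample
matrices tagged with class and unit; annotation carries per-feature
length, the circRNA host (source) gene and the lncRNA cis-gene; a
miRNA -> target map stands in for database-predicted target/sponge
relations; gene sets come in standard GMT.

## Normalization

Each class is normalized against its own library pool, matching the three
library types of a whole-transcriptome experiment:

- **FPKM** (mRNA, lncRNA): `count * 1e9 / (length_nt * T_j)` with `T_j`
  the per-sample column total over the *combined* mRNA+lncRNA pool — both
  classes are quantified from the same rRNA-depleted library, so they
  share a denominator. Whether circRNA-supporting reads should enter this
  total is undefined in principle; this implementation excludes them
  (totals come only from the provided count matrices).
- **RPM** (circRNA): `count * 1e6 / junction-read column total`.
- **TPM** (miRNA): `tag count * 1e6 / clean-tag column total`, with **no
  length term** — for small RNA, "transcripts per million" conventionally
  means tags per million, since each tag is one full-length molecule.

RPM/TPM columns sum to 1e6 by construction; FPKM is invariant to
per-sample depth rescaling. No between-sample scaling factors (TMM/RLE)
are applied; this matters for interpretation (see Limitations).

## Differential expression

A self-contained negative-binomial exact test stands in for an edgeR-style
analysis; the downstream network needs DE sets with controlled error
rates, not parity with any particular tool.

- **Dispersion** (variance = mu + phi mu^2): per-feature method of
  moments, `phi_raw = max(0, (s^2 - mu)/mu^2)` with `s^2` the within-group
  variance pooled over the two groups and `mu` the mean of group means,
  then shrunk 50/50 toward the across-feature **mean** of `phi_raw` and
  floored at 1e-4. The mean, not the median, is the shrinkage center
  because with 3 replicates the MoM estimate is strongly right-skewed: its
  median understates the common dispersion, and an understated dispersion
  makes the exact test anti-conservative. With mean-centering the null
  fraction of p < 0.05 measures 0.044-0.069 across seeds (nominal 0.05);
  with median-centering it measures 0.073-0.078.
- **Exact test**: condition the group-2 count sum on the overall sum.
  Group sums of i.i.d. NB replicates are NB with size n_g/phi, and under
  equal per-sample means the conditional law of the split is free of the
  mean. Unequal library sizes are handled by moment-matching the group-sum
  means to `T * L_g / (L_1 + L_2)` (exact under equal per-sample means,
  an approximation otherwise). Two-sided p doubles the smaller tail
  (observed point included), capped at 1 — conservative but symmetric
  under label swap. For dispersion < 1e-10 the conditional is exactly
  Binomial(T, L_2/(L_1+L_2)).
- **Fold change**: `log2((m2 + 0.5)/(m1 + 0.5))` on library-size-adjusted
  count means; the 0.5 pseudocount keeps zero-mean features finite and
  at 0 when both groups are empty.
- **Screening** (deliberately asymmetric across classes, as is common in
  multi-library transcriptome reports): mRNA/lncRNA `|log2FC| >= 1` and
  `q < 0.05` (BH); circRNA `|log2FC| >= 1` and `p < 0.05` (strict);
  miRNA `|log2FC| >= 1` and `p <= 0.05` (inclusive). Boundary conventions
  are exact: `>=` on the fold change, strict `<` on q and circRNA p,
  inclusive `<=` on miRNA p.

## Enrichment

Gene lists per class: mRNAs themselves; circRNA host genes with
intergenic circRNAs dropped; lncRNA cis-genes; mRNA-class targets of DE
miRNAs. The per-term P-value is the hypergeometric upper tail
`P(X >= m)` with N annotated genes, n source genes, M in the term, m
observed — evaluated by log-space summation of the upper tail (never
`1 - cdf`, which cancels catastrophically for small tails). The
background is per-analysis: all genes carrying any term annotation.
BH FDR across terms is reported; calls default to raw P < 0.05.

## ceRNA network

Only DE features participate. Correlations are computed on the normalized
layer across all six samples pooled: with n = 3 per group, within-group
correlation is meaningless, and cross-stage co-variation is precisely the
signal the ceRNA model predicts. Spearman uses mid-ranks; zero-variance
vectors have no defined correlation and the pair is skipped (counted in
the log).

1. miRNA-target pairs: in the map, both DE, `SCC < -0.7` (strict).
2. Sponge-target candidates: DE lncRNA-mRNA and circRNA-mRNA pairs with
   `PCC > 0.9` (strict).
3. Shared-sponge test: for a candidate pair, `M` and `N` are the miRNAs
   linked to each member by filter 1, `x` their overlap, and
   `p = P(shared >= x)` under Hypergeometric(U, M, N). The universe `U`
   defaults to all distinct miRNAs in the target map; the pipeline uses
   the DE-filtered count (configurable), since only DE miRNAs can enter
   filter 1. `p < 0.05`, uncorrected, admits the pair (an optional BH
   mode exists but is off by default). Each shared miRNA adds
   miRNA-target edges to both members.

Exports are deterministic (lexicographic rows): `network.sif` with
relations `sponges` (validated pair) and `targets` (miRNA support),
plus node (id, class, degree) and edge (coefficient, p) tables.

## Synthetic data

The generator emulates the study conditions end to end: 2,000 mRNAs,
400 lncRNAs, 800 circRNAs (10% intergenic), 150 miRNAs; NB counts with
phi = 0.1 and baseline mean 200 (flat across features); two groups of
three replicates; a miRNA->target map with planted relations plus
Bernoulli background at density 0.01; GMT terms over the mRNA universe
with one term seeded from the planted DE mRNAs. One master seed drives
named substreams, so enabling one component never perturbs another's
draws, and identical configs give byte-identical files.

**Planted DE** (100 features per class): effects of |log2FC| = 6 applied
as a symmetric split — group means `mu * 2^(-lfc/2)` and `mu * 2^(+lfc/2)`
— with extra features' signs chosen to balance up- and down-regulation
within each class. Both choices protect the *null* features: large
one-directional shifts change a class's library total several-fold
between groups, and the resulting compositional bias (the classic
CPM-normalization artifact) would flag most null features as DE. The
symmetric, direction-balanced design keeps both groups' library totals
equal in expectation while preserving each planted log2 ratio exactly.

**Planted triplets** (50): sponge (alternating circRNA/lncRNA) and mRNA
target are planted up, the miRNA down. Each triplet shares a latent
per-replicate factor: three standard-normal draws standardized to zero
mean and SD 1.0, repeated across both groups, entering the NB mean as
`exp(+s z)` for sponge/target and `exp(-s z)` for the miRNA (s = 0.9,
the correlation strength), each rescaled to unit mean. Three properties
motivate this construction over i.i.d. per-sample factors:

- *repetition across groups* means the factor cancels from the
  group-mean ratio, so the planted fold change is observed undistorted
  and the exact test retains power despite the factor's variance;
- *standardization* guarantees within-group spread, so the Pearson filter
  (which needs shared variance to beat the irreducible NB noise — at
  phi = 0.1 the population PCC of two features sharing a multiplicative
  factor cannot exceed ~0.905) passes planted pairs reliably;
- the random orientation per triplet decorrelates distinct triplets.

The large default effect size (64-fold) is what makes factor-carrying
mRNA targets clear the BH q-screen in a 2,000-feature class; the
generator's defaults are chosen for testability of the pipeline's
guarantees, not for biological realism of any one parameter. Under these
conditions the planted structure measures: median SCC(miRNA, sponge)
= -1.0, median PCC(sponge, target) ~ 0.99, triplet recovery 84-92%
across seeds, decoy pass rate 0%.

**Decoys** (500): random (sponge, miRNA, target) triplets over features
with *no* planted effect, whose two map relations are guaranteed present.
They probe the false-positive path: a decoy passes only if null features
survive DE screening *and* both correlation filters *and* the sponge
test.

## What the synthetic data does not emulate

Real libraries have heavy-tailed mean distributions (the generator's
baseline is flat), gene-wise dispersion trends, GC/length biases,
between-sample composition shifts requiring TMM-style correction,
correlated (not independent) background relations, and miRNAs targeting
through shared seed families. Passing the recovery tests shows the
pipeline's machinery is correct and calibrated under its own model
assumptions; it does not certify performance on real data, where the
correlation thresholds (|SCC| > 0.7, PCC > 0.9 at n = 6) are extremely
aggressive and fold-change magnitudes are smaller.

## Numerical choices

- Hypergeometric tails via `gammaln` + `logsumexp` over the upper tail;
  agreement with exact rational enumeration to < 1e-12 for universes up
  to 40.
- The NB conditional is normalized in probability space after a max-log
  shift; totals up to ~10^5 are exact in double precision.
- Ties in Spearman: mid-ranks. Degenerate (constant) vectors: NaN,
  skipped by callers.
- All comparisons against thresholds are strict or inclusive exactly as
  documented; thresholds are configurable with the stated defaults.
- Problem sizes in tests and the acceptance script: 2,000-feature classes
  for calibration/power, the full ~3,350-feature default bundle for
  end-to-end recovery (a few seconds per run).

## Known limitations

- The exact test's library-size handling is exact only under equal
  per-sample means within groups; strongly unequal depths combined with
  high dispersion make it approximate.
- Tail-doubling makes the test conservative at small totals.
- The sponge test treats miRNA links as exchangeable; hub miRNAs violate
  this in real data.
- With three replicates per group, the q-screen for mRNA (2,000-feature
  background) is the power bottleneck of the whole pipeline; features
  with strong sample-level covariation (exactly the ceRNA candidates) pay
  an additional dispersion penalty. This is a property of the design, not
  of the implementation.
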