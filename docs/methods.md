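# Methods notes

## Statistical model for differential expression

Counts are modelled as Poisson per gene and condition.  Replicates are
pooled (summed) before testing; with library sizes N₁, N₂ and pooled
counts k₁, k₂, equality of per-base transcription rates is tested
exactly by conditioning on K = k₁ + k₂, under which k₁ ~
Binomial(K, N₁/(N₁+N₂)).  The two-sided p-value is the
minimum-likelihood sum: all binomial point probabilities not exceeding
the observed one (with a 10⁻¹² relative slack for float round-off);
K = 0 returns p = 1.  This conditional binomial is an exact equivalent
of the two-sample Poisson rate test and stands in for count-model DE
packages built on the same H₀.  Multiplicity is controlled by
Bonferroni over tested genes; selection requires fold change ≥ 1.5 (or
≤ 2/3) *and* corrected p < 0.001.  The fold-change gates are
inclusive, the significance gate strict.

**Known limitation.** Pooling discards replicate-level variance; on
overdispersed data every test statistic is too large and the procedure
is anticonservative.  The stringent α and the fold-change gate
mitigate but do not repair this.  A negative-binomial model is a
deliberate non-goal.

Library size defaults to the column sum of the analysed count table —
"per million reads" is ambiguous between total aligned and
transcriptome-mapped reads, and the column sum is the only
self-contained choice; an override table is accepted.  The RPKM floor
in fold changes is 10⁻⁹, preventing infinities when one condition has
zero signal.  The low-count filter sums reads across *all* samples
(strictly greater than 10); a per-condition variant is a one-line
change in `filter_low_counts` callers.

## Co-expression network and connectivity

Correlation is Pearson on quantile-normalized, replicate-averaged log₂
RPKM over developmental stages (Spearman available via
`method="spearman"`).  Edges require |r| ≥ 0.95 (inclusive); genes
with no qualifying partner are excluded.  The connectivity score of a
gene set is the mean |r| over all C(n,2) pairs.  Its permutation null
draws n_perm same-size subsets, without replacement within a draw,
from the background universe — defined as the genes passing the
low-count filter — and the empirical p is count(null ≥ observed)/n_perm,
so p = 0 is possible at finite n_perm; the (count+1)/(n+1) estimator is
available (`estimator="add_one"`).  Drawn indices are sorted before
scoring so results are invariant to draw order.

Quantile normalization maps each column's sorted values onto the
cross-column mean of sorted values; within-column ties receive the
mean of the target values at their tied ranks (so an entirely tied
column collapses to the grand mean — the "identical sorted columns"
property holds exactly only for tie-free columns).  Z-scores use the
sample (n−1) standard deviation; constant rows map to zero with a
warning instead of NaN.

Hierarchical clustering is agglomerative with Euclidean distance and
complete linkage; the tree is cut to exactly k groups (default 3).
Because cut labels are arbitrary, groups are renumbered by the mean
peak stage of their members (earliest peak = group 1), which makes
labels stable across runs and interpretable as ramp-up / pulse /
ramp-down.

## Motif scanning

Matrix similarity is the information-weighted score
Σᵢ Cᵢ·f(i,bᵢ) / Σᵢ Cᵢ·max_b f(i,b) with Cᵢ = (100/ln 4)(Σ_b f ln f + ln 4)
and the 0·ln 0 = 0 convention; it is 1 exactly on the consensus and
invariant to rescaling the Cᵢ.  Hits are called at ≥ 0.8 on both
strands; windows containing ambiguous bases score 0.  Overlapping hits
are all reported (no greedy masking), and strands are counted
separately, so a site whose reverse complement also clears the
threshold — inevitable for the reverse-complement-palindromic core
TAATTA — contributes two hits at one locus.  No separate
core-similarity sub-threshold is applied.  An optional pseudocount
(default 0) can regularize zero frequencies in scoring.

The bundled matrix (`data/rax_synthetic.transfac`) is a *synthetic*
stand-in: the proprietary RAX matrix could not be shipped, so a
12-position matrix was constructed with the published core consensus
TAATTA strongly conserved (0.97 dominant base) and weakly informative
flanks (0.70 dominant).  With this design every exact core occurrence
scores ≥ 0.82 regardless of flanks, while a single core mismatch falls
below 0.8 unless at least four of six flanking bases match — hit
density in random sequence is therefore close to the exact-core rate
of 4⁻⁶ per position per strand.

Motif enrichment uses two statistics over the query set — number of
genes with ≥ 1 promoter hit, and mean hits per promoter — each
compared against n_perm random same-size draws from the promoter
universe with the same count/n_perm rule as above.  The rank-sum test
for motif-count effects is one-tailed (higher-count bin has larger
|log₂FC|), exact by enumeration when both groups have ≤ 12 untied
observations and otherwise a tie-corrected normal approximation;
fully tied data returns 0.5 (z = 0).

## Gene building

Coordinates are 0-based half-open internally; GTF I/O converts to
1-based inclusive.  Clustering requires same chromosome and strand in
every phase.  "Overlap" means ≥ 1 shared base.  A CDS-less transcript
overlapping several phase-1 genes attaches to the one with the
largest overlap in bases, ties broken by smaller gene id, with a
logged warning.  Gene ids are `g:<smallest member id>`, making the
partition invariant under input order.  Novel transcripts shorter
than 300 summed exon bases are dropped before clustering; known
transcripts are never length-filtered.

## Gene-set enrichment

One-tailed over-representation: p = P(X ≥ k) for X hypergeometric with
the term/query/universe margins, term sets intersected with the
universe first.  The correction across terms defaults to
Benjamini–Hochberg — the enrichment stage reports "q-values" without a
stated method and BH is the field convention for screening many terms
— with Bonferroni available; note this deliberately differs from the
DE stage's Bonferroni.  The universe defaults to the genes passing the
low-count filter.  Gene Ontology ancestor propagation is out of scope:
terms are tested exactly as annotated.

## Synthetic data: what it emulates and what it does not

`make_counts` draws per-gene baselines from a log-normal (σ = 1,
a typical RNA-seq abundance spread), normalizes them to an expected
library of `lib_size` reads per replicate, and plants
floor(n·de_fraction) fold changes split half down-, half
up-in-mutant, symmetric in log space so libraries stay balanced.
Counts are exactly Poisson — the regime where the DE test is exact —
so passing recovery/calibration tests demonstrates correctness of the
inference machinery, *not* robustness to biological overdispersion.

`make_timecourse` uses a 12-point stage grid emulating 2–4-cell
cleavage through 7 dpf, with the regulator's onset at the 10 hpf
index.  The three module templates are a post-onset sigmoid ramp-up, a
Gaussian pulse peaking just after onset (the 10–13 hpf window), and a
mirrored ramp-down, each standardized to unit variance.  Module genes
share their template at amplitude s = noise_sd·√(r/(1−r)), which makes
the expected pairwise correlation equal the requested r (0.97 default,
matching the near-threshold cohesion of a real co-regulated module);
noise_sd = 0 degenerates to identical profiles and r = 1 exactly.
Background genes are independent unit-variance noise — the paper-scale
background correlation structure is unknown, so it is left
uncorrelated and exposed only through the module/background split.

`make_promoters` plants full-width consensus insertions at
non-overlapping recorded positions and random strands in i.i.d.
background.  Chance hits are left in place and recorded into truth by
a reference scan; with `reject_chance_hits` the background is locally
re-drawn until the scan reports exactly the planted loci, which is the
mode to use when a fixture needs an exact zero-hit truth.

`make_genesets` designs one term to overlap a query set at a given
proportion; `make_annotation` computes its expected gene partition
with an independent quadratic union-find oracle, which doubles as the
brute-force reference for the fast sweep-based clustering.

`make_study` composes all generators over one shared gene universe —
DE genes populate the temporal modules, carry the planted promoter
sites and seed the designed term — giving the end-to-end pipeline
recoverable structure at every stage.

## Problem sizes and numerical choices

The test suite exercises the null calibration at 20,000 genes across
20 seeds, DE recovery at 2,000 genes × 5·10⁶ reads/replicate, network
recovery with a 20-gene module in a 2,020-gene correlation matrix at
1,000 permutations, and the background-density computation on 10 Mb of
sequence; these sizes keep every Monte-Carlo band (e.g. the raw-p rate
window [2·10⁻⁴, 2·10⁻³]) well-resolved while the full suite stays in
the minutes range.  Determinism: every stochastic routine takes an
explicit seed; the pipeline derives per-stage seeds from a single
master seed via `numpy.random.SeedSequence.spawn`, so reruns are
byte-identical.  Permutation p-values, linkage heights and correlation
matrices are deterministic given those seeds.
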