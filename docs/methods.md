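# Methods

## Scope and estimand

The pipeline estimates, for every ortholog group aligned across the five
taxa (*D. nigrodunni*, *D. arawakana*, *D. dunni*, *D. similis*,
*D. innubila* outgroup), the synonymous divergence dS, nonsynonymous
divergence dN and their ratio ω = dN/dS at three scopes: each of the eight
branches of the rooted species tree, the whole tree, and (for calibration)
pairwise between taxa. Downstream statistics — percentile outlier scans,
background contrasts, category tests, enrichment — consume only these
per-gene, per-scope values, so any estimator producing the same table
schema (for example a maximum-likelihood codon-model fit) can be substituted
at the `estimate` stage boundary.

## Counting estimator

Site counts follow the NG86 convention. Each codon position contributes a
synonymous-site fraction equal to the number of synonymous single-nucleotide
changes at that position divided by the number of non-stop changes there
(so TTT has S = 1/3, a fourfold Leu codon like CTT has S = 1, and TGG —
whose third-position A/G changes produce stops — has S = 0 with the
stop-producing neighbors removed from the denominator). Differences between
two codons are averaged over all orderings of the single-nucleotide steps
between them, excluding pathways through stop codons; when every pathway is
blocked, each differing position is classified by direct substitution in
isolation, with stop-producing isolated changes counted as nonsynonymous.
Proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits by the
Jukes–Cantor transform d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 makes the
corrected value undefined and the record is flagged saturated. ω is
reported as missing when dS = 0 or either divergence is undefined — never
as infinity or an imputed value — and such genes are excluded from windows,
backgrounds, and tests in that scope.

Branch-specific counts come from Fitch parsimony on the fixed species
topology: a bottom-up intersection/union pass over the observed sense-codon
states of each usable column (a column is usable when every taxon carries a
complete, unambiguous sense codon), then a deterministic top-down
refinement that keeps the parent's state when it lies in the child's Fitch
set and otherwise takes the lexicographically smallest codon. Differences
are counted between the parent- and child-node sequence of each branch;
sites are the mean of the two node sequences' site counts. The whole-tree
record sums dN and dS over branches.

Known properties, measured on simulations with the bundled generator:

- Because site counting is unweighted while the generative process has
  transition bias, pairwise ω estimates at κ = 2 carry the classic NG86
  downward bias of roughly 10–15% in the median (the enumerated
  small-divergence expectation is ω̂ ≈ 0.887·ω at κ = 2); the mean over
  genes sits closer to truth because the per-gene ratio dN/dS is convex in
  its noisy denominator. Whole-tree estimates, built from many short
  branches, recover true ω within a few percent below ω = 1 and compress
  somewhat above it (multiple hits that parsimony cannot see).
- Sister-branch estimates from the same alignment share ancestral-
  reconstruction errors: a misassigned ancestor codon creates compensating
  changes on both child branches, so per-gene rate deviations on
  *nigrodunni* and *arawakana* are weakly positively coupled even when the
  generating processes are independent. Between-branch correlation tests on
  same-alignment deltas therefore see a small genuine positive component;
  the type-I calibration of the Pearson test is verified on deltas drawn
  from independent replicate simulations, where its null holds exactly.

## Saturation filter

Genes with dS > 1 (default threshold) are removed per analysis scope: a
gene saturated on the *dunni* branch leaves only the *dunni*-branch
analyses, and tree-scope analyses filter on tree-scope dS. Undefined
corrected dS (p ≥ 3/4) counts as saturated. Because tree dS sums eight
branches, tree-scope removal is naturally more frequent than branch-scope
removal under the default generator (a long-tailed per-gene rate
multiplier); the removal log records every exclusion with its scope and dS.

## Outlier scan

Windows of width 0.001 dS sliding by 0.001 (a 0.01 preset is provided) tile
[0, max dS] as half-open intervals; a gene joins every window containing
its dS. Windows under 40 genes merge upward until the minimum is met — a
97.5th percentile over fewer points is dominated by a single order
statistic — and a trailing underfull block merges into its predecessor.
The window threshold is the linear-interpolation percentile of member ω;
outlier status requires ω strictly above it, so degenerate windows with
tied ω flag nothing. Two consequences worth knowing: the flagged count per
block of m distinct values is exactly ⌈0.025·(m−1)⌉, so thin dS coverage
(blocks near the 40-gene minimum) overshoots the nominal 2.5% rate —
approaching 4% at m ≈ 42 — while large windows converge to 2.5%; the
calibration test therefore measures the rule on genes exchangeable in dS
as well as ω. For the paired sister-species scan, each species' genes are
windowed by the *partner* species' value — dN/dS by default, matching the
procedure as stated, with dS selectable in config since windowing on a
noisy ratio is unusual — and the percentile is computed on the focal
species' ω.

## Background contrast and category tests

The local background of a focal gene on a branch is every other gene on the
same chromosome within 100 kbp (inclusive, between 1-based start
coordinates; the generator spaces genes ~12 kbp apart so neighborhoods
hold tens of genes) and within 0.01 dS (inclusive) on that branch, with
defined ω. The contrast is Δ = ω(focal) − median(ω(background)) (even-sized
backgrounds take the mean of the central pair), so positive Δ means faster
than the neighborhood; empty backgrounds leave Δ undefined and logged.
Matching on dS serves two purposes: it controls for regional divergence
level, and it removes most of the shared dS estimation noise from the
contrast.

Per category and branch (≥ 2 genes with defined Δ): a one-sample one-sided
t-test of Δ against zero (the degenerate all-equal case is resolved by the
sign, with t = 0 and p = 0.5 at exact zero), and a two-sided Wilcoxon
rank-sum comparing the category genes' ω with the pooled, deduplicated ω of
their background genes (category members are excluded from the pool).
Benjamini–Hochberg correction is applied across the whole category × branch
family. A Shapiro–Wilk statistic on the category's deltas is reported as a
diagnostic only and never gates anything. Per-category Pearson correlations
of Δ between two branches report r, t = r·√(n−2)/√(1−r²), df and a
two-sided p, and are undefined under zero variance.

The t-test's null (mean Δ = 0) holds exactly only when genes are
exchangeable in their *true* rates: with a skewed distribution of true ω
across genes, the focal gene's expectation exceeds the background median
and E[Δ] > 0 — a property of the contrast statistic itself, not an
implementation artifact. Type-I calibration is therefore measured on null
simulations with constant true ω and no category effects (20 replicates ×
10 random pseudo-categories of 30 genes).

## Enrichment

A fixed-cutoff hypergeometric test: with N genes surviving the saturation
filter in the tested scope, K of them in a category, n outliers and k
outlier category genes, p = P(X ≥ k), BH-corrected across categories within
the scope; fold enrichment is (k/n)/(K/N). The universe is the filtered
gene set of that scope, not all annotated genes, because outliers are
defined only within it. Underrepresentation (lower tail) is available by
flag.

## Synthetic-data generator

The generative model is a 61-state codon process in the Goldman–Yang
parameterization: rate(i→j) ∝ π_j · κ^[transition] · ω^[nonsynonymous] for
single-nucleotide changes, zero otherwise, normalized to one expected
substitution per codon per unit branch length. Sequences start at the
stationary frequencies (uniform by default) and evolve by exponential-
waiting-time jump sampling down the tree, so internal-node sequences are
exact ground truth for reconstruction tests. The truth table records each
gene's per-branch true ω and expected dS = branch length × gene rate
multiplier × synonymous rate fraction of that branch's matrix (synonymous
substitutions per codon).

Defaults, chosen once as a study-shaped baseline: 2000 genes of 100–500
codons; κ = 2; baseline ω log-normal with median 0.15 and log-sd 0.8 (the
bulk of genes well under ω = 1, a thin tail above it); per-gene rate
multipliers Gamma(shape 3, mean 1) giving heterogeneous dS; tree
((nigrodunni:0.1,arawakana:0.1):0.05,(dunni:0.1,similis:0.1):0.05) with the
outgroup stem split 0.15/0.15, in expected substitutions per codon; three
designated categories — 50 SFP-like genes ×10 ω on both *nigrodunni* and
*arawakana*, 40 Toll-like ×10 on *arawakana* only, 40 JAK-STAT-like ×10 on
*nigrodunni* only; genes laid on three 30 Mbp chromosomes with exponential
~12 kbp gaps; and 3% of plain background genes scaled past dS saturation on
at least one branch (categories are never saturated so designed signals
stay intact). All of this is configuration, not constants.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: indels and alignment error, within-gene rate or
ω variation (no site classes), codon-usage bias estimated from data, gene
tree/species tree discordance, duplications, and correlated rate variation
along chromosomes beyond the imposed layout. Power numbers on the ×10
multiplier categories are best-case figures for clean alignments.

## Numerical and design choices

- Codon states are integer-encoded in lexicographic sense-codon order;
  Fitch state sets are 61-bit masks, vectorized across columns; the
  lexicographic tie-break is the lowest set bit.
- Percentiles use linear interpolation between order statistics (numpy's
  default); medians of even sets average the central pair.
- Problem sizes in the test suite (e.g. 150–200 genes × 300 codons for
  calibration, 20 null replicates × 600 genes, one 2000-gene study) were
  chosen to make sampling error small relative to the asserted tolerances
  while keeping the suite quick to run end to end.
- Coordinates are 1-based; neighborhood distance uses start coordinates
  only.
- Taxon labels match case-insensitively, with unambiguous prefixes accepted
  (`nig` → `nigrodunni`) and an explicit mapping available in config.
- The `simulate` stage clears stale per-gene FASTA files when rerun into an
  existing directory, so identical config + seed always yields a
  byte-identical output tree.

## Known limitations

- The counting estimator's κ-blind site counts bias pairwise ω downward
  under transition bias (see above); comparisons *between* genes, branches
  and categories — the pipeline's actual use — are unaffected to first
  order because the bias is a common multiplicative factor.
- Parsimony undercounts multiple hits on long branches; the outgroup stem
  (the longest default branch) absorbs most of this, and the dS > 1 filter
  removes the worst cases before any scan.
- The windowed percentile rule's flagged fraction depends weakly on window
  occupancy (the ⌈0.025·(m−1)⌉ sawtooth); results at different window
  widths (0.001 vs 0.01) are not numerically identical, which is why both
  are exposed.
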