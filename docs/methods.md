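# Methods

This note documents the statistical procedures implemented in `funclink`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Gene pairs, networks and gold standards

All associations are unordered pairs of distinct genes; identifiers are
upper-cased and pairs stored lexicographically sorted, so `(x, y)` and
`(y, x)` are one link and self-links are rejected at construction. A
pathway-derived gold standard labels a pair **positive** when the two genes
are co-annotated to at least one gene set and **negative** when both genes
carry annotations but never share a set. This "annotated but never
co-annotated" reading of negatives is the standard one for pathway-derived
benchmarks; pairs involving unannotated genes are simply not evaluable, and
every routine that consumes a gold standard treats them that way rather
than as negatives.

## Raw evidence scorers

Three standard scorers are built in; all are symmetric in gene order and
deterministic.

- **Co-expression (CX).** Pearson correlation over the conditions where
  both genes are observed (complete-pairs handling of missing values).
  Pairs with fewer than `min_pairs` complete observations (default 10) or
  with a zero-variance profile over them are omitted and logged, since the
  correlation is undefined there.
- **Phylogenetic profiles (PG).** Plug-in mutual information (bits)
  between two binary presence/absence vectors across reference genomes,
  computed from the empirical 2×2 joint table. No bias correction is
  applied; the plug-in estimator's positive bias is O(1/n) in the genome
  count and irrelevant after rank-based calibration. Constant profiles
  carry no co-inheritance signal and score 0 by convention.
- **Co-citation (CC).** −log10 of the one-sided hypergeometric probability
  of sharing at least the observed number of citing documents, given each
  gene's document count and the corpus size. The hypergeometric upper tail
  was chosen over pointwise mutual information so that the literature
  scorer and the modulator test share one piece of math. Pairs sharing no
  document are omitted.

The remaining evidence channels of a real build (genetic interactions,
protein–protein interactions, domain co-occurrence, gene neighborhood,
protein structure) are data-acquisition problems, not calibration problems:
they enter as externally supplied evidence tables or pre-calibrated edge
lists in the same TSV dialect and flow through the identical downstream
machinery.

## LLS calibration

`calibrate` sorts evidence pairs by descending raw score (ties broken by
canonical pair order, for reproducibility), walks the gold-evaluable pairs
in consecutive bins of `bin_size` (default 1000; small fixtures use smaller
bins), and scores each bin `LLS = ln(((p+c)/(n+c)) / (P/N))` with a
symmetric pseudocount `c` (default 0.5) keeping zero cells finite without
materially distorting large bins. Natural-log units are used throughout.

Bins count **gold-evaluable pairs only**; otherwise bin composition would
depend on the gold standard's coverage of the evidence, and identical
evidence benchmarked against sparser gold would land in different bins.
Non-evaluable pairs inherit an LLS afterwards through the raw-score map.

Monotonicity is enforced by pool-adjacent-violators on the bin sequence: a
bin whose LLS exceeds its higher-ranked neighbor is merged with it, and the
pooled bin's LLS is recomputed from the summed counts — so pooling
preserves the total contingency and the pooled value is exactly the LLS of
the merged 2×2 table. The final mapping interpolates linearly between the
(count-weighted) mean raw scores of the monotone bins and clamps beyond the
first and last knot. `apply_calibration` scores every pair through this map
and drops edges with LLS ≤ 0, which are no better than a random annotated
pair.

Disjoint consecutive bins (not sliding windows) are used; with monotone
smoothing on top, overlapping windows would add smoothing without changing
the fixed points.

## Weighted-sum integration

For a pair with per-data-type values `L0 ≥ L1 ≥ …`,
`WS = L0 + Σ_{i≥1} Li/(D·i)` with `D ≥ 1` (linear rank decay, the
default; a geometric `Li/D^i` decay is available and the choice is recorded
in output metadata). Each data-type tag may contribute at most one value
per pair; multiple datasets of one type must be pre-integrated within-type
with the same weighted sum, and by default within-type and cross-type
integration share `D`. The retention threshold defaults to `T = 0` because
non-positive LLS edges were already dropped per network. `tune_D` selects
`D` from a grid by maximizing the area under the cumulative
precision–recall curve on a validation gold standard, refusing to run when
the validation set overlaps the supplied training set; ties favor the
smallest `D`.

## Precision–recall evaluation

Edges are ranked by LLS and binned cumulatively. After each bin, precision
is (gold positives so far)/(gold-evaluable pairs so far) and recall is
genome coverage: distinct genes touched by any edge so far divided by the
genome size (default 5887 validated coding genes for yeast; an explicit
parameter everywhere else). Unevaluable edges advance recall but not
precision, which keeps the precision estimate on the independent benchmark
while still crediting network growth. Points are emitted once at least one
evaluable edge has been seen (precision is undefined before that), plus a
terminal point, so terminal recall is always (network genes)/(genome size).

## Leave-one-out guilt-by-association

For a phenotype gene set with `m` members present in the network, the AUC
follows strict leave-one-out cross-validation. In the fold that holds out
member `g`, every gene is scored by its summed edge weights to the
remaining `m−1` members; the held-out member then competes against all
non-member network genes, and pooling every member/non-member comparison
across folds (wins count 1, ties ½) gives the Mann–Whitney AUC.

The fold structure matters: the superficially simpler shortcut of building
one ranking in which each gene is scored against "members other than
itself" compares members (who can link to at most `m−1` members) against
non-members (who can link to all `m`), and is therefore biased *below* 0.5
on an uninformative network — measurably so for small sets on sparse
networks (mean AUC ≈ 0.48 for 10-gene sets at edge density 0.05). Scoring
each fold's competitors against the identical reference set makes held-out
members and non-members exchangeable under the null, so an uninformative
network scores exactly 0.5 in expectation and an isolated positive clique
scores exactly 1. The user-facing `ranked` candidate list still uses the
per-gene sum over all members other than the gene itself, which is the
natural prioritization output; only the AUC is computed fold-wise.

Genes absent from the network are excluded from both ranking and AUC (the
network cannot say anything about them); sets with fewer than two network
members are rejected, or skipped with a logged reason in batch mode.

## Extreme-tail phenotype sets

Quantitative per-gene phenotype measures (morphology parameters,
growth/sensitivity scores) are turned into discrete gene sets by fitting a
normal location/scale to the values and cutting both tails at a per-side
probability threshold (defaults: `p < 1e-4`, the morphology-screen
convention); each side becomes its own candidate set — at most two per
parameter — and sets with fewer than `min_size` members (default 5) are
dropped. An empirical-quantile mode is available for clearly non-normal
measures. Paired AUC distributions from two networks are compared with the
one-sided Wilcoxon signed-rank test: zero differences dropped, exact null
enumeration for ≤ 25 tie-free differences, tie-corrected normal
approximation otherwise.

## Hypothesis-generation tools

All three tools are deterministic given their inputs, with documented tie
breaking (ascending p, then descending overlap, then name).

- **Find new members** scores candidates by the *sum* of LLS weights to the
  query set — not neighbor counts or the maximum edge — so the web-style
  tool and the LOO-GBA benchmark share one scoring contract, and the score
  is additive over disjoint query subsets.
- **Infer functions** tests each annotation term hit by at least one
  neighbor with the hypergeometric upper tail over the universe of
  annotated network genes (configurable), returning the top 30 terms by
  raw p with Benjamini–Hochberg adjusted values reported alongside; the
  adjustment is reported, not used for ranking, mirroring common server
  behavior while exposing modern practice.
- **Find modulators** builds one gene set per network gene from its direct
  neighbors (hub included by default; the construction is ambiguous in
  common usage, so a flag controls it) and tests each set's overlap with
  the DEG query by the same hypergeometric tail. DEGs outside the network
  are ignored, and the universe defaults to the network gene count, with a
  genome-sized universe supported as an explicit argument. The tool's point
  is that a hub need not itself be differentially expressed to rank first.

## Synthetic data

The generators plant known structure so that recovery is checkable:
planted-module networks (within-module edge probability `p_in`, background
`p_out`, weights from normals truncated at 0 — defaults 2.0 ± 0.5 within
modules, 0.5 ± 0.5 background, chosen only to set a weight ordering);
expression matrices where module genes share a latent condition factor
giving expected pairwise correlation `rho`; phyletic profiles where module
genes descend from one ancestral presence pattern with independent
per-genome flips; gold standards derived from the modules; and DEG queries
consisting of a fraction of a hub's neighbors plus noise genes, with the
hub itself excluded. Every generator takes an explicit seed, uses one local
random source, and is byte-reproducible.

What the generators do **not** emulate: scale-free degree structure,
correlated noise and batch effects in expression data, phylogenetic
non-independence of reference genomes, citation bias toward well-studied
genes, and the sheer scale of real corpora. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
signal at the stated noise levels — not performance on real yeast data.

## Problem sizes and tolerances

The test and acceptance workloads use desk-scale sizes chosen to make the
checked effects unambiguous: 200-gene networks with 200 phenotype sets for
ROC boundary checks (chance-level mean AUC asserted within ±0.02);
12-gene modules, 120 conditions and `rho = 0.75` for end-to-end module
recovery (AUC > 0.9); 100 seeds for planted-modulator recovery (top rank in
> 90%); brute-force oracle grids up to universe 60 for the hypergeometric
tail and full pair enumeration for AUC checks. Near-zero assertions on
permuted-gold calibration use bounds of a few sampling standard errors at
the stated bin sizes. Monte-Carlo assertions are seeded and deterministic.

## Known limitations

- The calibration map interpolates on bin mean raw scores; heavily skewed
  raw-score distributions within a bin are represented by a single knot.
- Plug-in MI and the normal tail fit are simple estimators by design;
  both are documented above and replaceable per analysis.
- `wilcoxon_signed_rank` switches from the exact null to the normal
  approximation when ties are present among nonzero differences, even at
  small n, since the exact enumeration assumes tie-free ranks.
- No identifier mapping is performed: inputs must already use one
  consistent gene naming scheme (systematic names, upper-cased).
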