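# Methods

## Model and procedure

`degnet` treats a differential-expression gene list not as a final
answer but as a candidate pool to be refined by two rounds of network
topology before pathway enrichment.

**Kruskal–Wallis similarity.** The similarity between two genes is the p
value of the Kruskal–Wallis rank test applied to their per-sample
expression vectors (two groups whose sizes are the sample counts).  The
test is location-based and non-parametric: a high p value means the two
genes' expression distributions are indistinguishable over the chosen
samples, which is taken as evidence of shared behavior.  The statistic
is computed in the rank-sum form H = 12/(N(N+1)) Σ Rᵢ²/nᵢ − 3(N+1) on
midranks and divided by the tie correction 1 − Σ(t³−t)/(N³−N); the p
value uses the χ² approximation with g−1 degrees of freedom.  The
χ² approximation rather than an exact small-sample table matches
standard practice; with the default 10 case samples per gene it is
adequate, and similarity values are only compared against a coarse
threshold, not interpreted as calibrated tail probabilities.

The samples used are the **case** samples by default (`sample_scope`
config key, also `controls` or `all`): the phenotype under study is the
condition in which co-behavior is biologically meaningful.  Pairs are
computed within the up-regulated gene set and the down-regulated gene
set separately; similarity values below the threshold (default 0.005,
`similarity_threshold`) are zeroed, and the DEG p threshold and the
similarity threshold are deliberately independent config keys even
though both default to 0.005.

**Closeness filtering.** The thresholded matrix is read as an
undirected network (nonzero cell = edge).  Closeness centrality uses
unweighted hop distances — edge weights are retained as annotations but
carry no distance semantics — and the Wasserman–Faust component scaling
CC(v) = ((n_v−1)/Σd(v,u)) · ((n_v−1)/(n−1)), because similarity
networks are frequently disconnected and unscaled per-component
closeness would make one global average meaningless.  Isolated nodes
score 0.  The essential set keeps nodes with CC(v) ≤ average CC.  Note
this rule keeps *peripheral* nodes: the package implements the rule as
stated, and exposes `invert_cc_rule` (default off) to flip the
comparison for sensitivity analysis.  The comparison uses a 1e−12
relative tolerance so that a network in which every node has the same
closeness (e.g. a clique) selects all nodes rather than none when
floating-point summation lands the mean a few ulps below the common
value.

**PPI expansion and Bottleneck selection.**  Essential genes are
intersected with the PPI node set (unmatched genes are reported, not
fatal) and expanded to the radius-1 neighborhood (`radius` key).
Bottleneck centrality follows the cytoHubba-style formulation: for each
root s, grow the BFS shortest-path tree T_s, and give v one point if
more than n/4 of the nodes lie in v's subtree (their tree path from s
passes through or ends at v).  Because BFS trees are not unique, the
neighbor expansion order is pinned to lexicographic symbol order, making
scores deterministic and reproducible.  Scores are computed on the
induced community subgraph (not the full PPI) and averaged over all
community members; members with BN(v) strictly greater than the average
are the relevant genes.  When every member has the same score the strict
rule selects nothing, so the selection falls back to ≥ (keeping all
members) and logs the fallback — the pipeline never silently empties a
branch.

**Enrichment.**  Over-representation uses the upper-tail hypergeometric
probability P[X ≥ k] including the observed overlap, the standard ORA
convention.  The universe defaults to all genes annotated to at least
one pathway; an optional background list (e.g. the array's genes) is
intersected with that universe.  Pathways with no member in the
(restricted) universe are not tested and therefore do not enter the
corrections.  FDR is Benjamini–Hochberg step-up over all tested
pathways; Bonferroni is min(1, m·p).  The |log2 p| presentation columns
are added only when writing the TSV; internal tables keep full
precision.

## Key parameters

| key | default | meaning |
|---|---|---|
| `p_threshold` | 0.005 | adjusted-p cutoff for DEG selection (inclusive) |
| `lfc_threshold` | 1.5 | minimum abs log2 fold change (inclusive) |
| `use_adjusted_p` | true | filter on FDR-adjusted p; raw-p mode provided because upstream exports vary in which column the thresholds were applied to |
| `similarity_threshold` | 0.005 | minimum KW p for a similarity edge |
| `sample_scope` | cases | samples used for pairwise KW tests |
| `invert_cc_rule` | false | select CC ≥ average instead of ≤ |
| `radius` | 1 | PPI neighborhood radius |
| `dedup_policy` | min_p | duplicate-symbol survivor: smallest p, ties by larger abs logFC, then probe id |

## Synthetic data generator

The generator emulates the study design the pipeline expects: a
case/control microarray experiment with two planted disease modules.

- **Expression**: background genes are i.i.d. Normal(8.0, noise_sd) on
  the log2 scale (8.0 is a typical mid-range microarray intensity).
  Each module shares a per-sample latent factor (sd 0.3) so members
  co-vary, and gains ±effect_size in case samples.
- **DEG table**: per-gene two-sample t test with BH adjustment and
  logFC = mean(case) − mean(control).  A plain t test (not a moderated
  one) suffices because the pipeline consumes only the table's schema.
- **PPI**: a Barabási–Albert graph (m = 2) over the same symbols
  supplies scale-free hub structure; each module is chained connected
  and attached to the top non-module hub, mimicking disease modules
  embedded in the dense core of curated interactomes.
- **Pathways**: one planted pathway containing all module genes plus 5
  random decoy members, and 49 decoy pathways of 10–40 genes drawn from
  the non-module pool.

Reference conditions: 300 genes, 25+25 module genes, 10 cases + 10
controls, effect size 3.0, noise sd 0.2, 50 pathways.  All generators
are pure functions of their seed and parameters.

What the generator does **not** model: probe-level effects, batch and
array normalization artifacts, correlated background genes, heavy-tailed
noise, pathway overlap/hierarchy, and PPI false positives.  Passing the
recovery tests therefore shows the pipeline's machinery is correct and
well-calibrated under clean planted structure; it does not certify
performance on real microarray data, where the filtering thresholds and
the similarity scope interact with normalization quality.

## Numerical choices and degenerate inputs

- Threshold comparisons at the DEG filter are inclusive (≤, ≥) exactly
  as specified.
- Kruskal–Wallis returns H = 0, p = 1 when all pooled observations are
  identical (the tie correction would otherwise divide by zero).
- Deduplication tie-breaks are total (p, then |logFC|, then probe id) so
  results never depend on input row order.
- Branches with fewer than two expressed genes, or whose essential genes
  all miss the PPI, are recorded as empty with a reason string; the
  other branch proceeds.
- Enrichment ranking ties are broken by descending overlap then pathway
  id, making output files byte-reproducible.
- Everything downstream of input parsing is deterministic; the only
  randomness in the package lives in the synthetic generators and flows
  from one integer seed.

## Known limitations

- The CC ≤ average rule keeps low-closeness nodes, which is the stated
  selection even though "essential gene" elsewhere usually means hubs;
  `invert_cc_rule` exists precisely to probe this choice.
- The Bottleneck n/4 threshold and the BFS tie-break are conventions;
  other shortest-path tree choices would shift scores on graphs with
  many equal-length paths.
- Pairwise KW similarity at ~10 samples has limited power; with very
  small cohorts (≤4 per group) most pairs exceed the 0.005 threshold and
  the similarity networks approach cliques.
- The pipeline is O(b²·s) in branch size b and sample count s for the
  similarity stage and O(c·(c+e)) per community of c nodes and e edges
  for Bottleneck; branch sizes in the low thousands remain tractable,
  but tens of thousands of DEGs should be pre-filtered harder.
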