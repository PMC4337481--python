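# Methods

`tfregnet` implements a differential co-regulation analysis of
transcription-factor (TF) regulatory networks between two sample groups
(e.g. tumor vs non-tumor). This note records the model, the defaults and
the design choices a maintainer would want justified.

## Pipeline model

The input is a genes × samples log2-scale expression matrix with a
two-group design and a TF → target edge list. Expression values are taken
as already normalized (e.g. RMA output on microarrays); no renormalization
is performed. Group labels are sorted lexicographically and fold changes
are always `groups[1] − groups[0]`.

### 1. Differential expression

Per gene, a moderated two-sample t-statistic with empirical-Bayes variance
shrinkage: pooled residual variances `s²` (df `d = n₁ + n₂ − 2`) are
shrunk toward the mean gene-wise variance `s0²` with `prior_df`
pseudo-observations,

    s̃² = (prior_df·s0² + d·s²) / (prior_df + d),
    t = Δmean / √(s̃²(1/n₁ + 1/n₂)),   p ~ t(d + prior_df), two-sided.

`prior_df = 4` by default — mild moderation of the sort routinely applied
to small-replicate expression data; `prior_df = 0` recovers the classical
pooled t-test exactly (this identity is the oracle test), `prior_df = ∞`
pins all variances to `s0²`. A gene is a DEG iff `p < 0.05` **and**
`|log2FC| > 1.5`, both strict; the raw p is used for the call because the
fold-change cut already controls the practical error rate, and the BH
FDR-adjusted p is reported alongside (the call can be switched to it with
`use_adjusted_p`). Zero-variance genes with `prior_df = 0` get `p = 1`
when the fold change is zero and an infinitesimal-variance guard
otherwise (logged).

### 2. Over-representation

A standard one-sided hypergeometric upper-tail test of the DEG list
against user-supplied GMT sets, BH-adjusted across sets. The universe is
the full post-collapse expression matrix. Depletion and ontology-graph
propagation are out of scope.

### 3. Edge weighting

For each TF → target edge, Spearman's rank correlation (Pearson on
average ranks; ties share midranks; a constant vector yields ρ = 0 with a
warning) is computed separately within each group, giving `r₁` and `r₂`.
Two summaries:

    weight = |r₁ + r₂| / 2     (consistent co-expression)
    delta  = |r₁ − r₂| / 2     (differential co-regulation)

They satisfy `weight + delta ≤ 1`. Edges naming genes absent from the
matrix are dropped with a logged count.

### 4. Permutation filter

The sample → group assignment is reshuffled (group sizes preserved)
`n_permutations` times (default 1,000; minimum 100) and each edge's delta
recomputed, pooling all null deltas into a single empirical distribution.
The threshold is its `quantile` quantile (default 0.90). Default
direction is **keep_above**: an edge passes iff its observed delta
exceeds the threshold, i.e. the ~10% of edges whose between-group
correlation change exceeds the null are retained — this is the
biologically coherent reading for a screen that goes on to interpret
differentially co-regulated subnets; `drop_above` provides the exact
complement for users who want the literal exclusion rule. A pooled
(rather than per-edge) null was chosen for stability at moderate
permutation counts; by symmetry of label shuffling it is calibrated for
the pass-fraction property checked in the tests. Null computation is
restricted to the genes present on edges, so its cost scales with the
network, not the matrix.

### 5. Subnet scoring

TFs with out-degree strictly greater than `min_degree` (default 15) among
*passing* edges are hubs (degree on the unfiltered network is available
via `passing_only=False`). For each hub, the background `E` is all
passing edges ranked by delta descending (ties broken by edge id for
determinism); the objective set `S` is the hub's edges. Walking the
ranking,

    P_hit(i)  = Σ_{j∈S, j≤i} |r_j|^P / N_R,   N_R = Σ_{j∈S} |r_j|^P
    P_miss(i) = Σ_{j∉S, j≤i} 1 / (N − N_H)

with `r_j` the delta and `P = 1`. The enrichment score is the maximum of
`P_hit − P_miss` (positive-deviation convention — the screen looks for
enrichment, and scores below the null mean stay meaningful as negative
Z-values; a signed max-|deviation| variant is available). Members at
ranks up to the maximizing position form the leading edge; the rest do
not contribute and are trimmed. The ES is standardized against `n_null`
(default 1,000) size-matched uniform random subsets of the background:
`Z_s = (ES − mean)/sd`. A zero null sd flags the score degenerate
(`Z = NaN`, ranked last) rather than dividing by zero.

### 6. Gene-level scoring and combined ranking

The trimmed subnet's distinct genes (targets of leading-edge pairs, plus
the TF itself when expressed — configurable) are scored with the same
running-sum engine over the whole expression universe ranked by
`−log10(p)` descending (`p` floored at the smallest positive double).
`−log10(p)` is used as the gene weight because it is a monotone measure
of the magnitude of differential-expression evidence; an
`|log2FC|`-weighted variant can be obtained by passing custom records.
Standardization against size-matched random gene sets gives `Z_trimmed`,
and the final candidate score is the raw sum

    Z_combined = Z_s + Z_trimmed.

An optional mode re-standardizes `Z_s` and `Z_trimmed` across all scored
TFs before summing (`combine_z_standardized`); the raw sum is the default
since both components are already null-standardized. TFs are ranked by
`Z_combined` descending, ties broken by TF id; the top 5 are reported by
default. Each candidate is annotated with its regulated DEGs (trimmed
genes flagged as DEGs, the TF excluded from its own list) and a flag for
whether the TF itself is differentially expressed.

## Synthetic data

The generator emulates a two-condition expression study at desk scale:
log2-Gaussian expression (baseline mean 8), planted DEGs as a group-2 mean
shift, and planted differential co-regulation by a Gaussian-copula
conditional construction (`target_z = ρ·tf_z + √(1−ρ²)·ε` per group), so
the planted population correlation is exact. TF targets are disjoint
across TFs, and planted DEGs are drawn preferentially from the planted
hubs' targets so that differential co-regulation and differential
expression coincide, as they would for a driver TF. Defaults are a
balanced 20+20 design, 1,000 genes plus 10 TFs with 25 targets each,
50 DEGs at log2FC 2.5 over noise sd 0.5, and one hub with ρ flipping
0.8 → −0.2; `paper_shape_config()` switches to an unbalanced 23 vs 77
design to exercise unbalanced code paths.

Not emulated: probe-level artifacts, batch effects, heavy-tailed noise,
correlated null genes, and overlapping TF target sets. Passing tests
therefore demonstrate correctness of the statistical machinery and its
calibration under Gaussian nulls, not performance on real microarray data.
Note that the empirical Spearman correlation of a bivariate Gaussian with
Pearson ρ is (6/π)·asin(ρ/2), slightly below ρ; Monte-Carlo tolerances in
the tests account for this.

## Numerical choices

- Ranks: average ranks for ties throughout; constant vectors give ρ = 0
  with a warning instead of an undefined value.
- Determinism: every stochastic step takes an explicit seed
  (`numpy.random.default_rng`); ranking ties are broken lexicographically;
  repeated runs of the pipeline are byte-identical.
- Text formats only; floats in network exports are written with 17
  significant digits so write-then-read is exact.
- Problem sizes in tests and the acceptance script (1,000 genes, 100–500
  permutations, 100–1,000 null subsets, 100 replicates) were chosen as the
  smallest sizes at which the Monte-Carlo properties are stable.

## Known limitations

- Only the two-group design is supported (no covariates or contrasts).
- The permutation null assumes exchangeable samples under the null of no
  group difference; strong batch structure would violate this.
- Hub degree, filter direction and the ES convention are ambiguous in
  parts of the literature this design follows; all three are configurable
  and the defaults are stated above.
- `score-subnets`/`rank-tfs` CLI subcommands re-run the deterministic
  pipeline from the config rather than consuming intermediate files;
  outputs are identical either way.
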