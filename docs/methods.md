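# Methods

This note records the models, parameter choices and numerical decisions
behind `qsig`, and what the synthetic benchmarks do and do not
demonstrate about real label-retention RNA-seq data.

## Transposed correlation PCA

Expression profiles of label-retention experiments have a handful of
samples and thousands of genes, so PCA is run on the samples × samples
Pearson correlation matrix computed over genes (genes are the
statistical units). Eigenvalues therefore sum to the number of samples.
Gene scores are the projections of the per-sample z-scored gene rows
onto each eigenvector, re-standardized to mean 0 / sd 1 per component;
the "score > |3|" selection operates on these z-scores (the
standardization is this package's decision — score scale is otherwise
arbitrary).

Two loading conventions are emitted side by side: unit-eigenvector
coefficients and correlation loadings (eigenvector × √λ). Published
decomposition tables for this kind of analysis sometimes label
unit-eigenvector entries as correlations (a 10-sample size component
prints entries ≈ 1/√10 ≈ 0.316); providing both, labeled, avoids the
ambiguity.

Numerical conventions:

* Eigenvector sign is arbitrary; each component is oriented so its
  first nonzero loading is ≥ 0. Phenotype orientation (positive gene
  score = up in PKH26+) is applied downstream by the discriminant
  report.
* The discriminant matcher demands a *perfect* sign partition of the
  two phenotype levels; a zero loading is neither sign and breaks a
  match. When several components match, the highest-variance one is
  primary (deterministic, variance-ordered).
* Report tables round half-up to 3 decimals, and the displayed
  cumulative column is the running sum of the *rounded* proportions —
  the convention of the published decomposition tables this package
  validates against — while unrounded values are retained internally.

## Moderated differential expression

Per gene, OLS of log-CPM on an intercept plus the phenotype indicator;
a cell-line covariate is added automatically when the tissue has more
than one line (the line effect is a dominant expression axis and would
otherwise inflate residual variance). The mean–variance trend is a
lowess fit (span 0.5) of log s² on average log-CPM, interpolated at
each gene. The prior df d₀ solves

    trigamma(d₀/2) = var(log(s²/trend)) − trigamma(d/2)

via a trigamma-inverse Newton iteration (the moment identity of the
scaled-F distribution of variance ratios); a non-positive excess
variance means complete shrinkage and d₀ is capped at 10·d so the
posterior df stays finite. Moderated t = logFC/√(s²_post·v) with v the
phenotype coefficient's unscaled variance factor, referred to t on
d + d₀ df. All-constant gene rows are flagged with logFC 0, p 1.

log-CPM uses the library-scaled pseudocount convention,
log2((c + p·L/L̄)/(L + 2p·L/L̄)·10⁶) with p = 0.5 by default: the scaled
prior makes samples with proportional counts map to *identical* columns
(exact scale invariance), which a fixed pseudocount only approximates.
A Bioconductor limma (`lmFit` + `eBayes(trend=TRUE)`) cross-check in
the test suite confirms logFC and residual variances agree to 1e-8 and
p-value rankings to Spearman ρ > 0.99; the d₀ estimate itself differs
slightly (limma fits an F-distribution, this package moment-matches).

Ranking: logFC descending, ties broken by gene id; duplicate symbols
keep the max-|logFC| record; the nominal-p filter (p < α, default 0.05)
applies *within* the selected top/bottom blocks, matching the
"significant if in the first N of the ranking with nominal p < α"
membership rule. The top/bottom size defaults to 6000, or ⌊n_genes/4⌋
when fewer than 12000 genes are measured.

## Overlap statistics

RR = k·N/(a·b) with an explicit universe N (genes measured, post-dedup,
in both experiments being compared — logged in every report). The
permutation test redraws only set B (conditional, matching the
hypergeometric conditioning) and reports (count+1)/(n_perm+1). RR
values depend strongly on the universe; they are comparable only within
one analysis.

## Preranked GSEA

Hits increment the running sum by |metric|^p normalized over the set's
hits (p = 1 default; p = 0 recovers the Kolmogorov–Smirnov form),
misses decrement by 1/(N−N_h); ES is the signed maximum deviation, with
an exact tie broken by the earlier extremum (deterministic). The null
permutes gene labels — equivalently redraws hit positions uniformly —
which matches preranked semantics; sets of equal effective size share
one null sample. NES divides ES by the mean |null ES| of matching sign;
the nominal p is the sign-matched tail frequency with a +1 correction
(its floor is therefore 1/(n_same_sign+1), bounded below by
1/(n_perm+1)); q follows the pooled positive/negative NES scheme.
Leading edge: hits at or before the positive peak (at or after the
negative trough).

## Co-expression networks

Edges require strict |r| > threshold (0.7 conventional, 0.98
quasi-deterministic core) on log-scale expression over the designated
sample subset; zero-variance genes are dropped with a warning, isolated
nodes retained. Betweenness is exact (Brandes accumulation as
implemented in networkx), reported as unnormalized unordered-pair
counts with endpoints excluded and fractional credit across tied
shortest paths, alongside the normalized variant; local clustering is
triangles/C(degree,2) with 0 below degree 2. The test suite verifies
both against exhaustive path/triad enumeration on all random graphs up
to 8 nodes. Giant-component ties break by lexicographically smallest
member. Rewiring discordance is the absolute rank shift of betweenness
between the two state networks; genes at or above the 0.9 quantile of
nonzero discordance are flagged. The range-restriction comparison
builds plus-only, minus-only and pooled networks on one gene list and
flags whether both intra-class counts exceed the pooled count.

## Synthetic-data generator

Expected log2 expression of gene g in sample s is

    x_gs = baseline_g(tissue) + line_offset_g(line) + δ_g·1[PKH26+]
           + w_g(state)·z_s + ε,   ε ~ N(0, noise_sigma)

with counts negative binomial (variance μ + φμ²) around
μ = libsize_s · 2^x / Z_s, where Z_s = Σ_g 2^(baseline+line+ε) is the
sample's *pre-effect* expression sum: the normalizer tracks realized
depth (keeping column sums within the stated tolerance of the library
size) while remaining phenotype-independent, so the planted shift does
not leak into non-signature genes. Dispersion 0 yields deterministic
counts equal to the mean, making noise-free identities exact.

Defaults are the study conditions: two tissues (2 lines × 3 replicates
× 2 states = 12 samples; 5+5 samples), 5000 genes, 300 signature genes
per direction per tissue with 60% shared across tissues, δ = 2 log2
units, NB dispersion 0.1, baseline N(4, 2) log2 units, line offsets
N(0, 0.5), residual noise sd 0.3, library sizes lognormal with mean 10⁶
and CV 0.2 (no depth statistics are published for this kind of
experiment; 10⁶ mapped counts over 5000 genes gives realistic per-gene
coverage at desk scale). The residual-noise field is the package's
addition — the model needs an explicit within-replicate noise scale.

The co-expression module (120 genes, nested in the shared up-signature)
loads on a per-sample N(0,1) latent factor. Per state, each module gene
is active with probability 0.75, with loading ±module_strength
(default 1). The sparse activity pattern is what makes state-specific
wiring *observable*: since |r|-thresholded edges ignore correlation
sign, flipping loading signs alone would leave the edge topology
unchanged — a gene must drop out of the factor in one state for the
network to rewire. Genes active in exactly one state are the rewiring
ground truth.

Gene sets: the full module, overlapping module sub-pathways (emulating
nested morphogenesis-style categories) and size-matched decoy sets of
non-signature genes for null calibration.

What the generator does *not* emulate: batch effects, sample swaps,
transcript-level ambiguity, low-mapping-rate count sparsity,
heavy-tailed outlier samples, and correlation structure outside the one
planted module. Passing benchmarks therefore show the pipeline's
operations are correct and calibrated under the assumed model, not that
real xenograft data satisfy that model.

## Benchmark design and frozen bounds

* **Recovery**: 20 seeds of the default configuration; mean sensitivity
  of the recovered shared-up core against truth ≥ 0.85 (bound frozen
  from a 100-seed pre-build calibration) and mean AUC of the matched
  component's |score| ranking of signature genes > 0.95.
* **Route concordance**: RR > 5 with p < 1e-4 is evaluated at
  signature-scaled lists (n = 300): with lists of ⌊n_genes/4⌋ = 1250 on
  a 5000-gene universe, RR is arithmetically capped at N/max(a,b) = 4,
  so the property is only meaningful for lists comparable to the
  planted signature.
* **Null calibration**: at zero effect size, ≤ 2/40 tissue-runs may
  show a (chance) discriminant match — the analytic chance rate of a
  perfect sign split is ~2/2^(n−1) per component — and the moderated
  p-values must pass per-run KS uniformity (α = 0.01) in ≥ 36/40 runs;
  decoy GSEA p-values must be KS-uniform.
* **Range restriction**: demonstrated deterministically on a
  constructed anti-pooling example (within-state factor with opposed
  loadings plus gene-specific between-state shifts) and statistically
  on generator output with strong wiring. At the default single-tissue
  configuration the planted differential shift itself correlates module
  genes in the pooled data, so intra > pooled holds on average but not
  for every seed — the same caveat the range-restriction argument is
  designed to address in real data.

## Known limitations

* The moment-matched d₀ is cruder than a full F-distribution fit; at
  the default 12-sample design it frequently hits the 10·d cap
  (strong shrinkage), which the null-calibration benchmark shows is
  conservative rather than anti-conservative.
* GSEA's FDR q uses the pooled-NES scheme without the original
  method's per-sign renormalization subtleties; q values are
  comparable within a run.
* Betweenness-based rewiring detection loses power in very dense
  modules (shortest paths vanish in cliques); the benchmark operates
  at a threshold where the state networks are sparse enough to carry
  signal.
* Networks are undirected and unweighted beyond the |r| threshold; no
  partial-correlation or directionality inference is attempted.
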