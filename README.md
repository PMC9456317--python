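# qsig — shared quiescence-signature discovery with network rewiring analysis

Quiescent (dormant, slow-cycling) cancer cells survive chemotherapy and
seed relapse, but they are rare and hard to profile: label-retention
experiments (PKH26 dye dilution) yield a handful of RNA-seq samples per
tumor, with tens of thousands of genes each. `qsig` implements a
dual-route strategy for extracting a quiescence transcriptional
signature from such data and comparing it across tumor types, together
with a synthetic-data generator that reproduces the statistical
structure of these experiments so every stage is testable end to end.

## The method

**Unsupervised route — transposed correlation PCA.** With genes as
statistical units and samples as variables, the eigen-decomposition of
the samples × samples Pearson correlation matrix yields components whose
loadings live in sample space. The first component (all loadings of one
sign, the "tissue attractor") captures the shared average expression
profile; a component whose loading signs perfectly partition the
PKH26+ (label-retaining, quiescent) from PKH26− (proliferating) samples
is an unsupervised discriminant of the phenotype, checked only *a
posteriori* so the number of inferential tests collapses to the few
retained components. Genes are then ranked by their z-standardized
scores on the matched component (|z| > 3 threshold or top/bottom-N).

**Supervised route — moderated logFC.** Per gene, OLS of log-CPM on the
phenotype indicator (plus a cell-line covariate where relevant) gives
the log2 fold change and residual variance s². Variances are shrunk
toward a lowess mean-variance trend by empirical Bayes,

    s²_post = (d₀·trend + d·s²) / (d₀ + d),

with the prior degrees of freedom d₀ moment-matched from the scaled-F
behaviour of s²/trend; moderated t = logFC/√(s²_post·v) on d+d₀ df.
Genes are ranked by logFC (duplicates keep the max-|logFC| record).

**Cross-route and cross-tissue overlap.** Set overlaps are scored by
relative risk RR = k·N/(a·b) (observed over expected intersection within
an explicit universe), exact hypergeometric upper-tail p, and an
optional conditional permutation p.

**Preranked GSEA.** Weighted running-sum enrichment (hits weight
|metric|^p, misses −1/(N−N_h)), gene-label permutation null, NES,
sign-matched nominal p and the pooled positive/negative FDR q.

**Co-expression networks.** On a chosen gene module, Pearson networks at
|r| > 0.7 (conventional) and |r| > 0.98 (quasi-deterministic core) are
built separately from PKH26+, PKH26− and pooled samples; betweenness and
clustering coefficients quantify each gene's role, rank-shift
discordance between states flags rewired "high-traffic" genes, and the
edge-count comparison tests for the range-restriction effect
(within-state correlations outnumbering pooled ones).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1) and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_pca_discriminant.py
python analysis/03_diffexp_rank.py
python analysis/04_overlap.py
python analysis/05_gsea.py
python analysis/06_network.py
```

Output of the run (abridged):

```
seed 1: wrote 2 tissues under results/01_simulated_data/
  lung: 5000 genes x 12 samples (2 line(s), 6 PKH26+)
  colon: 5000 genes x 10 samples (1 line(s), 5 PKH26+)
  planted: 180 shared up, 180 shared down, 120 module genes, 59 gene sets
published lung loadings -> discriminating component PC3 (orientation +1)
published colon loadings -> discriminating component PC4 (orientation +1)
lung: PC1 explains 0.875 (tissue attractor); discriminant=PC3, candidates [3]
colon: PC1 explains 0.898 (tissue attractor); discriminant=PC2, candidates [2]
lung route concordance (up): k=1040/1250, RR=3.33, p_hyper=0, p_perm=0.0001
cross-tissue core: 166 shared up (RR=8.39, p=1.86e-131), 240 shared down (RR=2.08)
  sensitivity vs planted shared-up: 0.917
lung: 59 sets tested, 9 at p<0.05; MODULE_MAIN ES=0.958 NES=3.94 p=0.0059
shared enriched: 9 positive-state, 0 negative-state sets
range restriction: edges plus/minus/all = 2694/2488/1560 (intra > pooled: True)
core (|r|>0.98) classes: 9 plus-only, 2 minus-only, 0 shared
```

Reading the numbers: in each simulated tissue the phenotype surfaces as
a single sign-separating component after the tissue attractor and line
effects (PC3 with two cell lines, PC2 with one); the unsupervised and
moderated-logFC rankings agree far above chance (RR 3.3 with lists of a
quarter of the genome, permutation p = 1/10001); intersecting the two
tissues' significant top-block genes recovers 91.7% of the planted
shared up-signature; the planted module is the top shared enriched gene
set in both tissues; and the module's state-specific networks have
roughly 1.7× the edges of the pooled network — the range-restriction
signature of constitutive, state-internal co-expression.

The same pipeline runs from a single command on packaged or user data:

```bash
qsig run-all --seed 0 --sim-seed 1 --out out/
qsig pca counts.tsv design.tsv --out out/pca
```

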