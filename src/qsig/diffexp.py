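"""Two-group moderated differential expression on log-CPM.

Per gene, an ordinary least-squares fit of log-CPM on the phenotype
indicator (optionally adjusting for cell line) gives the log2 fold
change and a residual variance s2 with d degrees of freedom.  The
gene-wise variances are then shrunk toward a smooth mean-variance
trend by empirical Bayes:

    s2_post = (d0 * trend + d * s2) / (d0 + d)

with the prior degrees of freedom d0 estimated by moment-matching the
log variance ratios log(s2 / trend) against their theoretical
scaled-F behaviour.  The moderated t statistic logFC / sqrt(s2_post*v)
is referred to a t distribution on d + d0 degrees of freedom.  This is
the limma-trend approach for RNA-seq expressed on log-CPM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from qsig.io import ExpressionMatrix


@dataclass
class DiffExpRecord:
    gene: str
    logFC: float
    aveExpr: float
    s2: float
    s2_post: float
    t_mod: float
    p_value: float
    trend: float
    d0: float
    flagged: bool = False  # all-constant row


@dataclass
class RankedGeneList:
    """Ordered unique genes with their ranking metric."""

    genes: list[str]
    metric: np.ndarray
    direction: str  # "up" or "down"
    cutoff: float  # |metric| at the list boundary

    def __len__(self) -> int:
        return len(self.genes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.metric, index=self.genes, name=self.direction)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/y scale)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for the monotone decreasing psi'
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - dif
        if np.all(np.abs(dif / y) < 1e-10):
            break
    return y


def _estimate_d0(s2: np.ndarray, trend: np.ndarray, d: float) -> float:
    """Moment-match the prior df of the scaled-F distribution of s2/trend.

    If z = log(s2/trend), then var(z) ~= trigamma(d/2) + trigamma(d0/2);
    excess variance beyond the chi-square term determines d0.  A
    non-positive excess means complete shrinkage; d0 is then capped at
    10*d to keep the posterior df finite.
    """
    ok = (s2 > 0) & (trend > 0)
    z = np.log(s2[ok] / trend[ok])
    if z.size < 2:
        return 10.0 * d
    evar = np.var(z, ddof=1) - float(special.polygamma(1, d / 2.0))
    if evar <= 0:
        return 10.0 * d
    d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
    return min(d0, 10.0 * d)


def fit_two_group_trend(m: ExpressionMatrix, design: pd.DataFrame,
                        covariate_line: bool | None = None,
                        lowess_frac: float = 0.5) -> list[DiffExpRecord]:
    """Moderated two-group fit of log-CPM on phenotype (PKH26+ vs PKH26-).

    ``covariate_line=None`` adds a cell-line covariate automatically when
    the design has more than one line (the line effect otherwise inflates
    the residual variance).  All-constant gene rows are flagged and get
    logFC 0 / p 1.
    """
    if m.scale == "counts":
        raise ValueError("fit_two_group_trend expects log-scale expression")
    design = design.set_index("sample").loc[m.sample_ids]
    pheno = (design["phenotype"] == "PKH26_plus").to_numpy(dtype=float)
    if pheno.sum() < 2 or (1 - pheno).sum() < 2:
        raise ValueError("need >=2 samples per phenotype")
    cols = [np.ones_like(pheno), pheno]
    lines = sorted(design["line"].unique())
    if covariate_line is None:
        covariate_line = len(lines) > 1
    if covariate_line and len(lines) > 1:
        for line in lines[1:]:
            cols.append((design["line"] == line).to_numpy(dtype=float))
    X = np.column_stack(cols)
    n, p = X.shape
    d = n - p
    if d < 1:
        raise ValueError(f"residual df {d} < 1 with design matrix {X.shape}")
    Y = m.values  # genes x samples
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T  # genes x p
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / d
    logfc = beta[:, 1]
    ave = Y.mean(axis=1)
    v = XtX_inv[1, 1]  # unscaled variance factor of the phenotype coefficient

    constant = Y.std(axis=1) == 0
    # mean-variance trend: lowess of log s2 on average expression
    pos = s2 > 0
    if pos.sum() >= 10:
        fit = lowess(np.log(s2[pos]), ave[pos], frac=lowess_frac, return_sorted=True)
        trend = np.exp(np.interp(ave, fit[:, 0], fit[:, 1]))
    else:
        trend = np.full_like(s2, max(s2.mean(), 1e-12))
    d0 = _estimate_d0(s2, trend, float(d))
    s2_post = (d0 * trend + d * s2) / (d0 + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = logfc / np.sqrt(s2_post * v)
    t_mod = np.where(s2_post > 0, t_mod, 0.0)
    df_total = d + d0
    p_val = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_val = np.clip(p_val, np.finfo(float).tiny, 1.0)
    logfc = np.where(constant, 0.0, logfc)
    t_mod = np.where(constant, 0.0, t_mod)
    p_val = np.where(constant, 1.0, p_val)
    return [
        DiffExpRecord(gene=g, logFC=float(logfc[i]), aveExpr=float(ave[i]),
                      s2=float(s2[i]), s2_post=float(s2_post[i]),
                      t_mod=float(t_mod[i]), p_value=float(p_val[i]),
                      trend=float(trend[i]), d0=float(d0),
                      flagged=bool(constant[i]))
        for i, g in enumerate(m.gene_ids)
    ]


def records_frame(records: list[DiffExpRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "logFC": [r.logFC for r in records],
            "aveExpr": [r.aveExpr for r in records],
            "s2": [r.s2 for r in records],
            "s2_post": [r.s2_post for r in records],
            "t": [r.t_mod for r in records],
            "p_value": [r.p_value for r in records],
        }
    )


def rank_top_bottom(records: list[DiffExpRecord], n: int = 6000,
                    alpha: float | None = None) -> tuple[RankedGeneList, RankedGeneList]:
    """Top/bottom-N logFC ranking with duplicate-symbol removal.

    Duplicate symbols keep the record with max |logFC|.  The ranking is by
    logFC descending (gene id breaks ties); the up list is the first ``n``
    and the down list the last ``n`` (most-negative first).  When ``alpha``
    is given, the nominal-p filter p < alpha is applied *within* the
    selected top/bottom blocks, mirroring "in the first N of the ranking,
    with nominal p < alpha".
    """
    best: dict[str, DiffExpRecord] = {}
    for r in records:
        prev = best.get(r.gene)
        if prev is None or abs(r.logFC) > abs(prev.logFC):
            best[r.gene] = r
    if n > len(best) / 2:
        raise ValueError(f"n={n} exceeds half the unique gene count {len(best)}")
    ordered = sorted(best.values(), key=lambda r: (-r.logFC, r.gene))
    top = ordered[:n]
    bottom = ordered[-n:][::-1]
    up_cut = abs(top[-1].logFC)
    down_cut = abs(bottom[-1].logFC)
    if alpha is not None:
        top = [r for r in top if r.p_value < alpha]
        bottom = [r for r in bottom if r.p_value < alpha]
    up = RankedGeneList([r.gene for r in top], np.array([r.logFC for r in top]),
                        "up", up_cut)
    down = RankedGeneList([r.gene for r in bottom], np.array([r.logFC for r in bottom]),
                          "down", down_cut)
    return up, down


def full_ranking(records: list[DiffExpRecord]) -> pd.Series:
    """Deduplicated full logFC ranking (descending), for preranked GSEA."""
    best: dict[str, DiffExpRecord] = {}
    for r in records:
        prev = best.get(r.gene)
        if prev is None or abs(r.logFC) > abs(prev.logFC):
            best[r.gene] = r
    ordered = sorted(best.values(), key=lambda r: (-r.logFC, r.gene))
    return pd.Series([r.logFC for r in ordered], index=[r.gene for r in ordered],
                     name="logFC")
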