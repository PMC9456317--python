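"""Samples-as-variables correlation PCA and discriminant-component search.

The transposed-PCA trick: with far more genes than samples, treat the
samples (expression profiles) as variables and the genes as statistical
units.  The eigen-decomposition of the samples x samples Pearson
correlation matrix then yields components whose *loadings* live in
sample space — a component whose loading signs perfectly separate the
quiescent (PKH26+) from the proliferating (PKH26-) samples is an
unsupervised discriminant of the phenotype, and its standardized *gene
scores* rank genes by how strongly they follow that contrast.  Because
the check happens only a posteriori, the number of inferential tests
collapses to the handful of retained components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from qsig.io import ExpressionMatrix


def _round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding (0.0025 -> 0.003), as report tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PCAResult:
    """Eigen-decomposition of the sample correlation matrix.

    eigenvalues      : descending, sum = n_samples
    eigenvectors     : samples x components, orthonormal columns
                       (sign convention: first nonzero loading >= 0)
    correlation_loadings : eigenvector * sqrt(eigenvalue) per component,
                       i.e. the sample-component correlation form
    gene_scores      : genes x components, z-standardized per component
    """

    eigenvalues: np.ndarray
    eigenvectors: pd.DataFrame
    correlation_loadings: pd.DataFrame
    gene_scores: pd.DataFrame
    n_samples: int
    n_genes: int


@dataclass
class VarianceTableRow:
    component: int
    eigenvalue: float
    difference: float
    proportion: float
    cumulative: float
    # display values rounded half-up to 3 decimals; cumulative_display is the
    # running sum of the rounded proportions, as decomposition tables print it
    eigenvalue_display: float = field(init=False)
    difference_display: float = field(init=False)
    proportion_display: float = field(init=False)
    cumulative_display: float = field(init=False)

    def __post_init__(self) -> None:
        self.eigenvalue_display = _round_half_up(self.eigenvalue)
        self.difference_display = _round_half_up(self.difference) if np.isfinite(self.difference) else float("nan")
        self.proportion_display = _round_half_up(self.proportion)
        self.cumulative_display = float("nan")  # filled by variance_table


@dataclass
class DiscriminantReport:
    """Outcome of the a posteriori loading-sign scan.

    component   : 1-based index of the primary matching component (or None)
    orientation : +1 if PKH26+ samples load positively on it, else -1
    matched     : whether any component's loading signs perfectly
                  partition the two phenotype levels
    candidates  : 1-based indices of all matching components, variance order
    """

    component: int | None
    orientation: int
    matched: bool
    candidates: list[int]
    factor: str = "phenotype"


def sample_correlation_pca(m: ExpressionMatrix) -> PCAResult:
    """PCA of the samples x samples Pearson correlation matrix over genes.

    Gene scores are the projections of the z-scored gene rows onto each
    eigenvector, re-standardized to mean 0 / sd 1 per component.
    """
    if m.scale == "counts":
        raise ValueError("sample_correlation_pca expects log-scale expression")
    X = m.values  # genes x samples
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValueError(f"need >=3 samples, got {n_samples}")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [s for s, v in zip(m.sample_ids, sd) if v == 0]
        raise ValueError(f"constant sample columns (undefined correlation): {bad}")
    Z = (X - X.mean(axis=0)) / sd  # z-score each sample over genes
    R = (Z.T @ Z) / (n_genes - 1)
    np.fill_diagonal(R, 1.0)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: first nonzero loading of each component >= 0
    for k in range(n_samples):
        col = evecs[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            evecs[:, k] = -col
    comp_names = [f"PC{k + 1}" for k in range(n_samples)]
    ev_df = pd.DataFrame(evecs, index=m.sample_ids, columns=comp_names)
    corr_df = ev_df * np.sqrt(evals)
    raw_scores = Z @ evecs  # genes x components
    mu = raw_scores.mean(axis=0)
    sdev = raw_scores.std(axis=0, ddof=1)
    sdev[sdev == 0] = 1.0
    scores = pd.DataFrame((raw_scores - mu) / sdev, index=m.data.index, columns=comp_names)
    return PCAResult(
        eigenvalues=evals,
        eigenvectors=ev_df,
        correlation_loadings=corr_df,
        gene_scores=scores,
        n_samples=n_samples,
        n_genes=n_genes,
    )


def variance_table(eigenvalues: np.ndarray, n_components: int | None = None,
                   total: float | None = None) -> list[VarianceTableRow]:
    """Eigenvalue / difference / proportion / cumulative decomposition rows.

    ``total`` defaults to the sum of the supplied eigenvalues; for a
    correlation-matrix PCA it equals the number of samples, so pass it
    explicitly when only the leading part of the spectrum is available.
    Display cumulative is the running sum of the 3-dp half-up-rounded
    proportions (the convention of printed decomposition tables);
    unrounded values are retained alongside.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        raise ValueError("empty eigenvalue sequence")
    if (np.diff(ev) > 1e-9).any():
        raise ValueError("eigenvalues must be non-increasing")
    if (ev < -1e-12).any():
        raise ValueError("eigenvalues must be nonnegative")
    if total is None:
        total = float(ev.sum())
    n = ev.size if n_components is None else min(n_components, ev.size)
    rows: list[VarianceTableRow] = []
    cum = 0.0
    cum_disp = 0.0
    for k in range(n):
        diff = ev[k] - ev[k + 1] if k + 1 < ev.size else float("nan")
        prop = ev[k] / total
        cum += prop
        row = VarianceTableRow(component=k + 1, eigenvalue=float(ev[k]),
                               difference=float(diff), proportion=float(prop),
                               cumulative=float(cum))
        cum_disp = round(cum_disp + row.proportion_display, 3)
        row.cumulative_display = cum_disp
        rows.append(row)
    return rows


def variance_table_frame(rows: list[VarianceTableRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "component": [r.component for r in rows],
            "eigenvalue": [r.eigenvalue_display for r in rows],
            "difference": [r.difference_display for r in rows],
            "proportion": [r.proportion_display for r in rows],
            "cumulative": [r.cumulative_display for r in rows],
        }
    )


def find_discriminating_component(loadings: pd.DataFrame, design: pd.DataFrame,
                                  factor: str = "phenotype") -> DiscriminantReport:
    """Scan components (variance order) for a perfect loading-sign partition.

    A component matches iff every sample of one factor level loads with one
    sign and every sample of the other level with the opposite sign — no
    exceptions, and a zero loading is neither sign.  The primary match is
    the highest-variance one; orientation is recorded so that positive gene
    scores mean "up in PKH26+" (respectively, up in the first level).

    ``loadings`` may be a PCAResult's eigenvectors or any printed loading
    matrix with samples as rows and components as columns.
    """
    if isinstance(loadings, PCAResult):
        loadings = loadings.eigenvectors
    col = {"phenotype": "phenotype", "line": "line"}[factor]
    design = design.set_index("sample").loc[loadings.index]
    levels = sorted(design[col].unique(), reverse=(factor == "phenotype"))
    # phenotype: reverse sort puts PKH26_plus first -> orientation anchors on it
    if len(levels) != 2:
        raise ValueError(f"factor {factor!r} must have exactly 2 levels, got {levels}")
    in_first = (design[col] == levels[0]).to_numpy()
    candidates: list[int] = []
    orientations: dict[int, int] = {}
    for k, comp in enumerate(loadings.columns, start=1):
        v = loadings[comp].to_numpy()
        if (v == 0).any():
            continue
        s = np.sign(v)
        if (s[in_first] == 1).all() and (s[~in_first] == -1).all():
            candidates.append(k)
            orientations[k] = 1
        elif (s[in_first] == -1).all() and (s[~in_first] == 1).all():
            candidates.append(k)
            orientations[k] = -1
    if candidates:
        primary = candidates[0]
        return DiscriminantReport(component=primary, orientation=orientations[primary],
                                  matched=True, candidates=candidates, factor=factor)
    return DiscriminantReport(component=None, orientation=1, matched=False,
                              candidates=[], factor=factor)


def select_genes_by_score(pca: PCAResult, component: int, orientation: int = 1,
                          mode: str = "threshold", threshold: float = 3.0,
                          n: int = 6000) -> tuple[pd.Series, pd.Series]:
    """Select genes by standardized score on an (oriented) component.

    threshold mode: genes with |z| > threshold, split by sign.
    top_bottom mode: first / last ``n`` genes of the oriented score ranking.
    Returns (up, down) as Series of oriented scores, sorted by decreasing
    involvement; ties broken by gene id for determinism.
    """
    comp_name = f"PC{component}"
    scores = pca.gene_scores[comp_name] * orientation
    idx = pd.DataFrame({"score": scores.to_numpy(), "gene": scores.index.to_numpy()})
    # one total order (score desc, gene asc); down is read from the other
    # end so that the two lists always partition the genes, and an
    # orientation flip swaps them (exactly so for tie-free scores)
    ordered = idx.sort_values(["score", "gene"], ascending=[False, True])
    desc = pd.Series(ordered["score"].to_numpy(), index=ordered["gene"].to_numpy())
    asc = desc.iloc[::-1]
    if mode == "threshold":
        up = desc[desc > threshold]
        down = asc[asc < -threshold]
    elif mode == "top_bottom":
        if 2 * n > len(desc):
            raise ValueError(f"n={n} exceeds half the gene count {len(desc)}")
        up = desc.iloc[:n]
        down = asc.iloc[:n]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return up, down
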