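"""Published reference PCA tables for the two xenograft experiments.

The published correlation-matrix decomposition of the lung (two cell
lines, 3 replicates per state each; trace 12) and colon (5+5 samples;
trace 10) label-retention experiments ships with the package: the
leading eigenvalue spectra and the full sample-loading matrices.  They
serve as fixed inputs for arithmetic validation of the variance-table
and discriminant-matching operations — the raw expression matrices
behind them are not publicly deposited.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

LUNG_TRACE = 12.0   # number of samples in the lung experiment
COLON_TRACE = 10.0  # number of samples in the colon experiment


def _read(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("qsig") / "data" / name
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def lung_eigenvalues() -> pd.Series:
    df = _read("pca_variance_lung.tsv")
    return pd.Series(df["eigenvalue"].to_numpy(), index=df["component"])


def colon_eigenvalues() -> pd.Series:
    df = _read("pca_variance_colon.tsv")
    return pd.Series(df["eigenvalue"].to_numpy(), index=df["component"])


def lung_loadings() -> pd.DataFrame:
    return _read("pca_loadings_lung.tsv").set_index("sample")


def colon_loadings() -> pd.DataFrame:
    return _read("pca_loadings_colon.tsv").set_index("sample")


def lung_design() -> pd.DataFrame:
    """Design recovered from the published sample naming: 'p'/'m' prefix is
    the PKH26 phenotype, the number block the cell line."""
    rows = []
    for sid in lung_loadings().index:
        pheno = "PKH26_plus" if sid.startswith("p") else "PKH26_minus"
        line = sid[1:].split(".")[0]
        rep = sid.split(".")[1]
        rows.append({"sample": sid, "tissue": "lung", "line": f"lsc{line}",
                     "phenotype": pheno, "replicate": rep})
    return pd.DataFrame(rows)


def colon_design() -> pd.DataFrame:
    rows = []
    for sid in colon_loadings().index:
        pheno = "PKH26_plus" if sid.startswith("plus") else "PKH26_minus"
        rows.append({"sample": sid, "tissue": "colon", "line": "crc1",
                     "phenotype": pheno, "replicate": sid[-1]})
    return pd.DataFrame(rows)
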