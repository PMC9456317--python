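#!/usr/bin/env python
"""Unsupervised route: correlation PCA and discriminant-component search.

First validates the variance-table arithmetic and loading-sign matcher on
the published decomposition tables of the two xenograft experiments
(packaged reference data), then runs samples-as-variables PCA on the
simulated tissues, reports which component separates PKH26+ from PKH26-
by loading sign alone, and writes variance tables, loadings (unit
eigenvector and correlation forms) and standardized gene scores under
results/02_pca/.
"""

from pathlib import Path

from qsig import reference
from qsig.io import log_cpm, read_counts, read_design
from qsig.pca import (find_discriminating_component, sample_correlation_pca,
                      variance_table, variance_table_frame)

DATA = Path("results/01_simulated_data")
OUT = Path("results/02_pca")


def validate_published_tables() -> None:
    lung = variance_table(reference.lung_eigenvalues().to_numpy(),
                          total=reference.LUNG_TRACE)
    print("published lung spectrum: proportions",
          [r.proportion_display for r in lung],
          "cumulative", [r.cumulative_display for r in lung])
    for name, loadings, design in (
            ("lung", reference.lung_loadings(), reference.lung_design()),
            ("colon", reference.colon_loadings(), reference.colon_design())):
        rep = find_discriminating_component(loadings, design)
        print(f"published {name} loadings -> discriminating component "
              f"PC{rep.component} (orientation {rep.orientation:+d})")


def main() -> None:
    validate_published_tables()
    OUT.mkdir(parents=True, exist_ok=True)
    for tissue in ("lung", "colon"):
        counts = read_counts(DATA / f"counts_{tissue}.tsv")
        design = read_design(DATA / f"design_{tissue}.tsv")
        res = sample_correlation_pca(log_cpm(counts))
        vt = variance_table_frame(variance_table(res.eigenvalues))
        vt.to_csv(OUT / f"variance_table_{tissue}.tsv", sep="\t", index=False)
        res.eigenvectors.round(6).to_csv(OUT / f"loadings_{tissue}.tsv", sep="\t")
        res.correlation_loadings.round(6).to_csv(
            OUT / f"correlation_loadings_{tissue}.tsv", sep="\t")
        res.gene_scores.round(6).to_csv(OUT / f"gene_scores_{tissue}.tsv",
                                        sep="\t")
        rep = find_discriminating_component(res.eigenvectors, design)
        lead = vt.iloc[0]
        print(f"{tissue}: PC1 explains {lead['proportion']:.3f} "
              f"(tissue attractor); discriminant="
              f"{'PC%d' % rep.component if rep.matched else 'none'}, "
              f"candidates {rep.candidates}")


if __name__ == "__main__":
    main()
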