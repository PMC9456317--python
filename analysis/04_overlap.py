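#!/usr/bin/env python
"""Overlap analyses: route concordance and the cross-tissue core.

Quantifies (i) agreement between the PCA gene-score ranking and the
moderated-logFC ranking within each tissue (relative risk +
hypergeometric p on the measured-gene universe) and (ii) the shared
up/down cores across the two tissues with the nominal-p filter applied
within the top/bottom blocks, plus per-category counts against the
planted gene sets.  Writes Venn-style summaries under results/04_overlap/.
"""

import json
from pathlib import Path

from qsig.diffexp import fit_two_group_trend, full_ranking, rank_top_bottom
from qsig.io import log_cpm, read_counts, read_design, read_gmt
from qsig.overlap import category_counts, cross_tissue_core, pairwise_overlap
from qsig.pca import (find_discriminating_component, sample_correlation_pca,
                      select_genes_by_score)

DATA = Path("results/01_simulated_data")
OUT = Path("results/04_overlap")
ALPHA = 0.05
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((DATA / "truth.json").read_text())
    per_tissue = {}
    for tissue in ("lung", "colon"):
        counts = read_counts(DATA / f"counts_{tissue}.tsv")
        design = read_design(DATA / f"design_{tissue}.tsv")
        logm = log_cpm(counts)
        records = fit_two_group_trend(logm, design)
        ranking = full_ranking(records)
        n = counts.n_genes // 4
        up, down = rank_top_bottom(records, n=n)
        res = sample_correlation_pca(logm)
        rep = find_discriminating_component(res.eigenvectors, design)
        route = {}
        if rep.matched:
            s_up, s_down = select_genes_by_score(
                res, rep.component, rep.orientation, mode="top_bottom", n=n)
            for tag, de_list, pca_list in (("up", up.genes, s_up.index),
                                           ("down", down.genes, s_down.index)):
                ov = pairwise_overlap(de_list, pca_list, ranking.index,
                                      n_perm=10000, seed=SEED)
                route[tag] = ov.to_dict()
                print(f"{tissue} route concordance ({tag}): k={ov.k}/{ov.a}, "
                      f"RR={ov.RR:.2f}, p_hyper={ov.p_hyper:.3g}, "
                      f"p_perm={ov.p_perm:.4f}")
        (OUT / f"route_concordance_{tissue}.json").write_text(
            json.dumps(route, indent=1))
        pmap = {r.gene: r.p_value for r in records}
        per_tissue[tissue] = {
            "up": {g for g in up.genes if pmap[g] < ALPHA},
            "down": {g for g in down.genes if pmap[g] < ALPHA},
            "universe": set(ranking.index),
        }

    universe = per_tissue["lung"]["universe"] & per_tissue["colon"]["universe"]
    shared_up, shared_down, res, discordant = cross_tissue_core(
        per_tissue["lung"]["up"], per_tissue["colon"]["up"],
        per_tissue["lung"]["down"], per_tissue["colon"]["down"],
        universe, n_perm=10000, seed=SEED)
    print(f"cross-tissue core: {len(shared_up)} shared up "
          f"(RR={res['up'].RR:.2f}, p={res['up'].p_hyper:.3g}), "
          f"{len(shared_down)} shared down (RR={res['down'].RR:.2f}), "
          f"{len(discordant)} discordant")
    tu = set(truth["shared_up"])
    print(f"  sensitivity vs planted shared-up: "
          f"{len(shared_up & tu) / len(tu):.3f}")
    (OUT / "cross_tissue.json").write_text(json.dumps(
        {"shared_up": sorted(shared_up), "shared_down": sorted(shared_down),
         "discordant": sorted(discordant),
         "overlap": {k: v.to_dict() for k, v in res.items()}}, indent=1))
    gene_sets = read_gmt(DATA / "gene_sets.gmt")
    cat = category_counts(shared_up, shared_down, gene_sets)
    cat.to_csv(OUT / "category_counts.tsv", sep="\t", index=False)
    top = cat[cat["category"] != "unassigned"].nlargest(3, "up")
    print("  top categories by shared-up count:",
          ", ".join(f"{r.category}={r.up}" for r in top.itertuples()))


if __name__ == "__main__":
    main()
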