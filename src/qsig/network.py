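"""Condition-specific thresholded Pearson co-expression networks.

Genes are nodes; an undirected edge joins two genes when the Pearson
correlation of their log-scale expression over the designated sample
subset strictly exceeds the threshold in absolute value (|r| > t, with
t = 0.7 as the conventional co-expression cutoff and t = 0.98 isolating
quasi-deterministic "hard-wired" relations).  Centrality analysis uses
betweenness (shortest-path traffic) and the local clustering
coefficient (complete-triad frequency); comparing the quiescent-state
and proliferating-state networks gene by gene exposes rewiring, and
comparing within-state vs pooled edge counts exposes the range
restriction effect (pooled correlations attenuated or inflated by the
between-state mean shift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from qsig.io import ExpressionMatrix, GeneSetCollection
from qsig.overlap import OverlapResult, pairwise_overlap


@dataclass
class GeneNetwork:
    graph: nx.Graph
    threshold: float
    subset_label: str = "all"  # plus / minus / all

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [(min(u, v), max(u, v), d["r"]) for u, v, d in self.graph.edges(data=True)]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r"])


@dataclass
class ComponentClasses:
    plus_only: list[str]
    minus_only: list[str]
    shared: list[str]
    overlap: OverlapResult | None = None


def build_coexpression_network(m: ExpressionMatrix, genes: Iterable[str] | None = None,
                               samples: Iterable[str] | None = None,
                               r_threshold: float = 0.7,
                               subset_label: str = "all") -> GeneNetwork:
    """All-pairs Pearson network on log-scale expression.

    Strict inequality |r| > threshold admits an edge; isolated nodes are
    retained; zero-variance genes are dropped with a warning.
    """
    if m.scale == "counts":
        raise ValueError("build_coexpression_network expects log-scale expression")
    sub = m
    if samples is not None:
        sub = sub.subset_samples(samples)
    if genes is not None:
        genes = list(genes)
        if not genes:
            raise ValueError("empty gene list")
        sub = sub.subset_genes(genes)
    if sub.n_samples < 3:
        raise ValueError(f"need >=3 samples, got {sub.n_samples}")
    X = sub.values
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(sub.gene_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} zero-variance genes", stacklevel=2)
        X = X[keep]
    ids = [g for g, k in zip(sub.gene_ids, keep) if k]
    G = nx.Graph()
    G.add_nodes_from(ids)
    if len(ids) >= 2:
        R = np.corrcoef(X)
        iu, ju = np.triu_indices(len(ids), k=1)
        mask = np.abs(R[iu, ju]) > r_threshold
        for i, j in zip(iu[mask], ju[mask]):
            G.add_edge(ids[i], ids[j], r=float(R[i, j]))
    return GeneNetwork(G, threshold=r_threshold, subset_label=subset_label)


def betweenness_centrality(net: GeneNetwork) -> pd.DataFrame:
    """Exact betweenness (unnormalized unordered-pair counts, endpoints
    excluded, fractional credit over tied shortest paths) plus the
    normalized variant, per node."""
    raw = nx.betweenness_centrality(net.graph, normalized=False)
    norm = nx.betweenness_centrality(net.graph, normalized=True)
    deg = dict(net.graph.degree())
    return pd.DataFrame(
        {
            "gene": sorted(net.graph.nodes),
            "degree": [deg[g] for g in sorted(net.graph.nodes)],
            "betweenness": [raw[g] for g in sorted(net.graph.nodes)],
            "betweenness_norm": [norm[g] for g in sorted(net.graph.nodes)],
        }
    ).set_index("gene")


def clustering_coefficients(net: GeneNetwork) -> pd.DataFrame:
    """Local clustering (triangles / C(degree,2); 0 for degree < 2) and the
    network mean as frame attribute ``mean_clustering``."""
    cc = nx.clustering(net.graph)
    deg = dict(net.graph.degree())
    df = pd.DataFrame(
        {
            "gene": sorted(net.graph.nodes),
            "degree": [deg[g] for g in sorted(net.graph.nodes)],
            "clustering": [cc[g] for g in sorted(net.graph.nodes)],
        }
    ).set_index("gene")
    df.attrs["mean_clustering"] = float(df["clustering"].mean()) if len(df) else 0.0
    return df


def giant_component(net: GeneNetwork) -> tuple[list[str], list[int]]:
    """Largest connected component (ties: lexicographically smallest member)
    and the full component-size list (descending)."""
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    if not comps:
        return [], []
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps[0], [len(c) for c in comps]


def class_partition(net_plus: GeneNetwork, net_minus: GeneNetwork,
                    universe: Iterable[str]) -> ComponentClasses:
    """Giant-component membership classes across the two state networks."""
    U = set(universe)
    if set(net_plus.graph.nodes) - U or set(net_minus.graph.nodes) - U:
        raise ValueError("networks contain genes outside the stated universe")
    gc_plus = set(giant_component(net_plus)[0])
    gc_minus = set(giant_component(net_minus)[0])
    shared = gc_plus & gc_minus
    ov = None
    if gc_plus and gc_minus:
        ov = pairwise_overlap(gc_plus, gc_minus, U, n_perm=0)
    return ComponentClasses(
        plus_only=sorted(gc_plus - gc_minus),
        minus_only=sorted(gc_minus - gc_plus),
        shared=sorted(shared),
        overlap=ov,
    )


def rewiring_report(cent_plus: pd.DataFrame, cent_minus: pd.DataFrame,
                    flag_quantile: float = 0.9) -> pd.DataFrame:
    """Paired betweenness table with a rank-shift discordance score.

    Discordance = |rank of betweenness in plus - rank in minus| (average
    ranks on ties); genes at or above the ``flag_quantile`` of the nonzero
    discordance distribution are flagged as rewired "high traffic"
    candidates.  Mean betweenness of both networks is stored in
    ``attrs['mean_betweenness']``.
    """
    common = sorted(set(cent_plus.index) & set(cent_minus.index))
    bp = cent_plus.loc[common, "betweenness"].to_numpy(dtype=float)
    bm = cent_minus.loc[common, "betweenness"].to_numpy(dtype=float)
    rp = stats.rankdata(bp)
    rm = stats.rankdata(bm)
    disc = np.abs(rp - rm)
    if (disc > 0).any():
        cut = np.quantile(disc[disc > 0], flag_quantile)
        flagged = disc >= cut
    else:
        flagged = np.zeros(len(common), dtype=bool)
    df = pd.DataFrame(
        {
            "betweenness_plus": bp,
            "betweenness_minus": bm,
            "rank_plus": rp,
            "rank_minus": rm,
            "discordance": disc,
            "flagged": flagged,
        },
        index=pd.Index(common, name="gene"),
    )
    df.attrs["mean_betweenness"] = {"plus": float(bp.mean()) if len(bp) else 0.0,
                                    "minus": float(bm.mean()) if len(bm) else 0.0}
    return df


def edge_count_comparison(m: ExpressionMatrix, design: pd.DataFrame,
                          genes: Iterable[str], threshold: float = 0.7
                          ) -> dict:
    """Edge counts of plus-only, minus-only and pooled networks on one
    gene list, with the range-restriction interpretation flag."""
    design = design.set_index("sample")
    plus = [s for s in m.sample_ids if design.loc[s, "phenotype"] == "PKH26_plus"]
    minus = [s for s in m.sample_ids if design.loc[s, "phenotype"] == "PKH26_minus"]
    genes = list(genes)
    nets = {
        "plus": build_coexpression_network(m, genes, plus, threshold, "plus"),
        "minus": build_coexpression_network(m, genes, minus, threshold, "minus"),
        "all": build_coexpression_network(m, genes, None, threshold, "all"),
    }
    n = len(nets["all"].nodes)
    possible = n * (n - 1) / 2 if n > 1 else 1
    counts = {k: v.n_edges for k, v in nets.items()}
    return {
        "edges": counts,
        "densities": {k: c / possible for k, c in counts.items()},
        "intra_exceeds_pooled": counts["plus"] > counts["all"]
        and counts["minus"] > counts["all"],
        "networks": nets,
    }


def pathway_distribution(classes: dict[str, Iterable[str]],
                         collection: GeneSetCollection
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pathway membership counts per class column + the Pearson
    correlation matrix of the count columns (symmetric, unit diagonal)."""
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    class_sets = {k: set(v) for k, v in classes.items()}
    rows = {}
    for name in sorted(collection.sets):
        members = collection.sets[name]
        rows[name] = {k: len(v & members) for k, v in class_sets.items()}
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "pathway"
    corr = counts.corr(method="pearson")
    return counts, corr


def write_sif(net: GeneNetwork, path: str | Path) -> None:
    """Simple interaction format: 'geneA pp geneB' per edge."""
    lines = [f"{a}\tpp\t{b}" for a, b, _ in
             net.edge_frame().itertuples(index=False, name=None)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(net: GeneNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))
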