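"""Preranked gene-set enrichment with a gene-label permutation null.

Given a metric-ranked gene list (e.g. moderated logFC, descending), the
enrichment score of a set is the signed maximum deviation of a weighted
running sum: each hit increments by |metric|^p normalized over the set's
hits, each miss decrements by 1/(N - Nh).  The null distribution permutes
gene labels (equivalently, redraws the hit positions uniformly), which
matches preranked-GSEA semantics.  NES divides ES by the mean |null ES|
of matching sign; the nominal p is the sign-matched tail frequency with
a +1 correction, and the FDR q follows the positive/negative NES pooling
scheme of the original method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qsig.io import GeneSetCollection
from qsig.overlap import OverlapResult, pairwise_overlap


@dataclass
class EnrichmentStat:
    name: str
    size: int
    ES: float
    NES: float
    p_nominal: float
    q_fdr: float
    leading_edge: list[str]
    n_perm: int
    seed: int | None
    curve: np.ndarray | None = field(default=None, repr=False)


def _hit_weights(metric: np.ndarray, hit_pos: np.ndarray, weight_p: float) -> np.ndarray:
    w = np.abs(metric[hit_pos]) ** weight_p
    total = w.sum()
    if total == 0:  # all-zero metrics in the set: fall back to equal weights
        return np.full(hit_pos.size, 1.0 / hit_pos.size)
    return w / total


def _es_from_positions(metric: np.ndarray, hit_pos: np.ndarray,
                       weight_p: float) -> float:
    """Signed max deviation of the running sum, evaluated only at the
    piecewise-linear breakpoints (just before and just after each hit)."""
    N = metric.size
    nh = hit_pos.size
    md = 1.0 / (N - nh)
    pos = np.sort(hit_pos)
    w = _hit_weights(metric, pos, weight_p)
    cumw = np.cumsum(w)
    misses_before = pos - np.arange(nh)
    after = cumw - misses_before * md            # value at each hit
    before = np.concatenate(([0.0], cumw[:-1])) - misses_before * md
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    hi, lo = after[i_max], before[i_min]
    if abs(hi) > abs(lo):
        return float(hi)
    if abs(lo) > abs(hi):
        return float(lo)
    # exact tie: sign of the earlier extremum (before-hit minima sit at
    # position pos-1, after-hit maxima at pos)
    return float(hi) if pos[i_max] <= pos[i_min] - 1 else float(lo)


def enrichment_score(ranked: pd.Series, geneset, weight_p: float = 1.0
                     ) -> tuple[float, np.ndarray]:
    """ES and the full running-sum curve for one gene set.

    ``ranked`` is a metric Series indexed by gene, already in ranking
    order (descending metric).  The curve has one value per list position,
    evaluated after that gene is processed (it ends at 0).
    """
    genes = ranked.index.to_numpy()
    metric = ranked.to_numpy(dtype=float)
    members = set(geneset)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=genes.size)
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has empty intersection with the ranked list")
    if nh == genes.size:
        raise ValueError("gene set covers the entire ranked list")
    hit_pos = np.flatnonzero(hit)
    w = _hit_weights(metric, hit_pos, weight_p)
    step = np.full(genes.size, -1.0 / (genes.size - nh))
    step[hit_pos] = w
    curve = np.cumsum(step)
    curve[-1] = 0.0 if abs(curve[-1]) < 1e-12 else curve[-1]
    es = _es_from_positions(metric, hit_pos, weight_p)
    return es, curve


def _leading_edge(genes: np.ndarray, curve: np.ndarray, hit_pos: np.ndarray,
                  es: float) -> list[str]:
    if es >= 0:
        peak = int(np.argmax(curve))
        return [genes[i] for i in hit_pos if i <= peak]
    trough = int(np.argmin(curve))
    return [genes[i] for i in hit_pos if i >= trough]


def gsea_collection(ranked: pd.Series, collection: GeneSetCollection,
                    n_perm: int = 1000, weight_p: float = 1.0,
                    seed: int | None = 0, min_size: int = 5,
                    max_size: int = 500, keep_curves: bool = False
                    ) -> list[EnrichmentStat]:
    """Run preranked enrichment for every set in a collection.

    Sets are filtered to ``min_size <= |set ∩ list| <= max_size``.  Null ES
    values are drawn once per distinct effective set size (sets of equal
    size share the same gene-label permutation null) with ``n_perm``
    permutations each.  Deterministic for a fixed seed.
    """
    filtered = collection.filter_sizes(ranked.index, min_size, max_size)
    if len(filtered) == 0:
        raise ValueError("all gene sets filtered out")
    genes = ranked.index.to_numpy()
    metric = ranked.to_numpy(dtype=float)
    N = genes.size
    rng = np.random.default_rng(seed)

    names = sorted(filtered.sets)
    sizes = {name: len(filtered.sets[name]) for name in names}
    null_by_size: dict[int, np.ndarray] = {}
    for s in sorted(set(sizes.values())):
        null = np.empty(n_perm)
        for j in range(n_perm):
            pos = rng.choice(N, size=s, replace=False)
            null[j] = _es_from_positions(metric, pos, weight_p)
        null_by_size[s] = null

    es_obs: dict[str, float] = {}
    curves: dict[str, np.ndarray] = {}
    led: dict[str, list[str]] = {}
    for name in names:
        es, curve = enrichment_score(ranked, filtered.sets[name], weight_p)
        members = filtered.sets[name]
        hit_pos = np.flatnonzero(np.fromiter((g in members for g in genes),
                                             dtype=bool, count=N))
        es_obs[name] = es
        curves[name] = curve
        led[name] = _leading_edge(genes, curve, hit_pos, es)

    # normalization: per-set null means of matching sign
    nes_obs: dict[str, float] = {}
    p_nom: dict[str, float] = {}
    null_nes_pos: list[np.ndarray] = []
    null_nes_neg: list[np.ndarray] = []
    for name in names:
        null = null_by_size[sizes[name]]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.nan
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.nan
        es = es_obs[name]
        if es >= 0:
            denom = mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else 1.0
            nes_obs[name] = es / denom
            p_nom[name] = (int((pos_null >= es).sum()) + 1) / (pos_null.size + 1)
        else:
            denom = mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else 1.0
            nes_obs[name] = es / denom
            p_nom[name] = (int((neg_null <= es).sum()) + 1) / (neg_null.size + 1)
        if np.isfinite(mean_pos) and mean_pos > 0:
            null_nes_pos.append(pos_null / mean_pos)
        if np.isfinite(mean_neg) and mean_neg > 0:
            null_nes_neg.append(-np.abs(neg_null) / mean_neg)

    all_null_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.array([])
    all_null_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.array([])
    obs_pos = np.array([v for v in nes_obs.values() if v >= 0])
    obs_neg = np.array([v for v in nes_obs.values() if v < 0])

    results = []
    for name in names:
        nes = nes_obs[name]
        if nes >= 0:
            num = (all_null_pos >= nes).mean() if all_null_pos.size else 0.0
            den = (obs_pos >= nes).mean() if obs_pos.size else 1.0
        else:
            num = (all_null_neg <= nes).mean() if all_null_neg.size else 0.0
            den = (obs_neg <= nes).mean() if obs_neg.size else 1.0
        q = float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))
        results.append(EnrichmentStat(
            name=name, size=sizes[name], ES=es_obs[name], NES=float(nes),
            p_nominal=float(p_nom[name]), q_fdr=q, leading_edge=led[name],
            n_perm=n_perm, seed=seed,
            curve=curves[name] if keep_curves else None))
    return results


def results_frame(results: list[EnrichmentStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "size": [r.size for r in results],
            "ES": [r.ES for r in results],
            "NES": [r.NES for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "q_fdr": [r.q_fdr for r in results],
            "leading_edge": ["|".join(r.leading_edge) for r in results],
        }
    )


def shared_enriched(results_a: list[EnrichmentStat], results_b: list[EnrichmentStat],
                    alpha: float = 0.05, n_perm: int = 0, seed: int | None = None
                    ) -> tuple[set[str], set[str], dict[str, OverlapResult]]:
    """Significantly enriched sets shared by two experiments, split by sign.

    Positive-state sets (enriched toward the top / PKH26+) and
    negative-state sets are intersected separately among sets with
    p_nominal < alpha; overlap significance uses the tested sets as the
    universe.
    """
    universe = {r.name for r in results_a} & {r.name for r in results_b}

    def split(results):
        pos = {r.name for r in results if r.p_nominal < alpha and r.ES >= 0}
        neg = {r.name for r in results if r.p_nominal < alpha and r.ES < 0}
        return pos & universe, neg & universe

    pos_a, neg_a = split(results_a)
    pos_b, neg_b = split(results_b)
    shared_pos = pos_a & pos_b
    shared_neg = neg_a & neg_b
    stats = {}
    if universe:
        if pos_a and pos_b:
            stats["positive"] = pairwise_overlap(pos_a, pos_b, universe,
                                                 n_perm=n_perm, seed=seed)
        if neg_a and neg_b:
            stats["negative"] = pairwise_overlap(neg_a, neg_b, universe,
                                                 n_perm=n_perm, seed=seed)
    return shared_pos, shared_neg, stats
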