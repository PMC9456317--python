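"""Gene-set overlap statistics: relative risk and hypergeometric/permutation p.

The relative risk of an intersection is observed over expected size under
independence within a stated universe, RR = k*N / (a*b); significance is
the exact hypergeometric upper tail P(K >= k), optionally accompanied by a
conditional permutation p that redraws one set uniformly from the universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from qsig.io import GeneSetCollection


@dataclass
class OverlapResult:
    a: int
    b: int
    k: int
    N: int
    RR: float
    expected_k: float
    p_hyper: float
    p_perm: float | None = None
    n_perm: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "k": self.k, "N": self.N,
            "RR": self.RR, "expected_k": self.expected_k,
            "p_hyper": self.p_hyper, "p_perm": self.p_perm,
            "n_perm": self.n_perm, "seed": self.seed,
        }


def pairwise_overlap(set_a: Iterable[str], set_b: Iterable[str],
                     universe: Iterable[str], n_perm: int = 10000,
                     seed: int | None = None) -> OverlapResult:
    """Overlap of two gene sets within a universe.

    p_hyper is the exact hypergeometric upper tail P(K >= k); p_perm (when
    ``n_perm`` > 0 and a seed is given) redraws set B uniformly from the
    universe and reports (count(k_perm >= k) + 1) / (n_perm + 1).
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    if not U:
        raise ValueError("empty universe")
    if not A <= U or not B <= U:
        raise ValueError("sets must be contained in the universe")
    a, b, N = len(A), len(B), len(U)
    k = len(A & B)
    expected = a * b / N
    rr = (k * N / (a * b)) if a and b else 0.0
    # P(K >= k) for K ~ Hypergeom(N, a, b)
    p_hyper = float(stats.hypergeom.sf(k - 1, N, a, b)) if k > 0 else 1.0
    p_hyper = min(p_hyper, 1.0)
    p_perm = None
    if n_perm > 0 and seed is not None and a and b:
        rng = np.random.default_rng(seed)
        in_a = np.zeros(N, dtype=bool)
        order = sorted(U)
        pos = {g: i for i, g in enumerate(order)}
        in_a[[pos[g] for g in A]] = True
        hits = 0
        for _ in range(n_perm):
            draw = rng.choice(N, size=b, replace=False)
            if int(in_a[draw].sum()) >= k:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
    return OverlapResult(a=a, b=b, k=k, N=N, RR=rr, expected_k=expected,
                         p_hyper=p_hyper, p_perm=p_perm,
                         n_perm=n_perm if p_perm is not None else 0, seed=seed)


def cross_tissue_core(up_a: Iterable[str], up_b: Iterable[str],
                      down_a: Iterable[str], down_b: Iterable[str],
                      universe: Iterable[str], n_perm: int = 0,
                      seed: int | None = None):
    """Shared up/down cores across two tissues plus overlap statistics.

    Returns (shared_up, shared_down, {"up": OverlapResult, "down": ...},
    discordant) where discordant genes are up in one tissue and down in the
    other.
    """
    U = set(universe)
    if not U:
        raise ValueError("empty universe intersection")
    up_a, up_b = set(up_a) & U, set(up_b) & U
    down_a, down_b = set(down_a) & U, set(down_b) & U
    shared_up = up_a & up_b
    shared_down = down_a & down_b
    discordant = (up_a & down_b) | (down_a & up_b)
    results = {
        "up": pairwise_overlap(up_a, up_b, U, n_perm=n_perm, seed=seed),
        "down": pairwise_overlap(down_a, down_b, U, n_perm=n_perm,
                                 seed=None if seed is None else seed + 1),
    }
    return shared_up, shared_down, results, discordant


def category_counts(shared_up: Iterable[str], shared_down: Iterable[str],
                    collection: GeneSetCollection) -> pd.DataFrame:
    """Per-category counts of shared genes, split by direction.

    Genes in several categories count in each; genes in none fall into an
    ``unassigned`` bin.  Output is barplot-ready (category, up, down).
    """
    up, down = set(shared_up), set(shared_down)
    annotated = set().union(*collection.sets.values()) if len(collection) else set()
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        rows.append({"category": name, "up": len(up & members),
                     "down": len(down & members)})
    rows.append({"category": "unassigned", "up": len(up - annotated),
                 "down": len(down - annotated)})
    return pd.DataFrame(rows)
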