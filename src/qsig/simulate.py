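"""Negative-binomial RNA-seq simulator with planted quiescence structure.

The generator emulates a two-tissue label-retention experiment: each
tissue has a dominant shared baseline profile (the "tissue attractor"
that surfaces as an all-same-sign first principal component), a
cell-line offset axis, a sign-consistent quiescence axis that shifts a
planted signature (partially shared between tissues) by +/- delta log2
units in the label-retaining (PKH26+) samples, and a densely
co-expressed module driven by a per-sample latent factor whose loading
vector can be drawn independently for the two states (state-specific
wiring, the ground truth for rewiring analysis).  Counts are negative
binomial around library-size-scaled expected expression; dispersion 0
yields deterministic counts equal to the mean so that noise-free
identities hold exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from qsig.io import ExpressionMatrix, GeneSetCollection, write_design, write_gmt


@dataclass
class TissueSpec:
    name: str
    n_lines: int = 1
    replicates_per_state_per_line: int = 3

    @property
    def n_samples(self) -> int:
        return self.n_lines * self.replicates_per_state_per_line * 2


def _default_tissues() -> list[TissueSpec]:
    # one tissue with two cell lines x 3 replicates x 2 states (12 samples),
    # one with a single source and 5+5 samples
    return [TissueSpec("lung", n_lines=2, replicates_per_state_per_line=3),
            TissueSpec("colon", n_lines=1, replicates_per_state_per_line=5)]


@dataclass
class SimConfig:
    n_genes: int = 5000
    tissues: list[TissueSpec] = field(default_factory=_default_tissues)
    signature_size: int = 300          # genes per direction per tissue
    shared_fraction: float = 0.6       # fraction of signature shared across tissues
    effect_size: float = 2.0           # quiescence shift delta, log2 units
    module_size: int = 120             # genes in the correlated module
    module_strength: float = 1.0       # latent-factor loading magnitude
    module_active_prob: float = 0.75   # per-state chance a module gene loads
    baseline_mu: float = 4.0           # per-gene log2 baseline mean
    baseline_sigma: float = 2.0        # per-gene log2 baseline sd
    line_sigma: float = 0.5            # cell-line offset scale (log2)
    noise_sigma: float = 0.3           # residual log2 Normal noise
    dispersion: float = 0.1            # NB dispersion (var = mu + phi*mu^2)
    libsize_mu: float = 1_000_000.0    # mean library size
    libsize_cv: float = 0.2            # library-size coefficient of variation
    state_specific_wiring: bool = True
    n_module_pathways: int = 8         # overlapping subsets of the module
    n_decoy_sets: int = 50             # size-matched decoy gene sets
    seed: int = 1

    @classmethod
    def scaled(cls, n_genes: int = 5000, **overrides) -> "SimConfig":
        """Config with signature/module sizes scaled to ``n_genes`` at the
        default proportions (300 and 120 per 5000 genes)."""
        sig = overrides.pop("signature_size", max(10, round(n_genes * 300 / 5000)))
        mod = overrides.pop("module_size",
                            max(5, min(round(n_genes * 120 / 5000),
                                       round(0.6 * sig))))
        return cls(n_genes=n_genes, signature_size=sig, module_size=mod,
                   **overrides)

    def validate(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for t in self.tissues:
            if t.n_lines < 1 or t.replicates_per_state_per_line < 1:
                raise ValueError(f"non-positive replicate counts for tissue {t.name}")
            if t.n_samples < 6:
                raise ValueError(f"tissue {t.name} needs >=3 samples per state")
        if 2 * self.signature_size + self.module_size > self.n_genes:
            raise ValueError("signature + module exceed n_genes")
        n_shared = round(self.shared_fraction * self.signature_size)
        n_specific = self.signature_size - n_shared
        distinct = 2 * (n_shared + len(self.tissues) * n_specific)
        if distinct > self.n_genes:
            raise ValueError(
                f"distinct signature genes ({distinct}) exceed n_genes ({self.n_genes})")
        if self.module_size > max(n_shared, 1) and self.module_size > 0 and n_shared > 0:
            raise ValueError("module_size exceeds the shared-up signature")


@dataclass
class SimTruth:
    up_genes: dict[str, list[str]]
    down_genes: dict[str, list[str]]
    shared_up: list[str]
    shared_down: list[str]
    module_members: list[str]
    effects: dict[str, dict[str, float]]       # tissue -> gene -> signed delta
    latent_factors: dict[str, float]           # sample -> z value
    module_loadings: dict[str, dict[str, float]]  # state -> gene -> w

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def generate_experiment(config: SimConfig
                        ) -> tuple[dict[str, ExpressionMatrix],
                                   dict[str, pd.DataFrame],
                                   SimTruth, GeneSetCollection]:
    """Generate per-tissue count matrices, designs, ground truth and GMTs.

    Fully reproducible from ``config.seed``.  Expected log2 expression is

        x_gs = baseline_g(tissue) + line_offset + delta_g * 1[PKH26+]
               + w_g(state) * z_s + Normal(0, noise_sigma)

    and counts are NB with mean libsize_s * 2^x_gs / Z_s, where the
    normalizer Z_s = sum_g 2^(baseline + line + noise) is computed from
    the pre-effect expression of the sample: it tracks realized depth but
    is phenotype-independent, so the planted shift does not leak into
    non-signature genes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"G{i + 1:06d}" for i in range(config.n_genes)])

    # --- allocate signature, shared core and module ---------------------
    n_shared = round(config.shared_fraction * config.signature_size)
    n_specific = config.signature_size - n_shared
    n_tissues = len(config.tissues)
    need = 2 * (n_shared + n_tissues * n_specific)
    pool = rng.permutation(config.n_genes)[:need]
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor:cursor + k]
        cursor += k
        return out

    shared_up_idx = take(n_shared)
    shared_down_idx = take(n_shared)
    up_idx = {t.name: np.concatenate([shared_up_idx, take(n_specific)])
              for t in config.tissues}
    down_idx = {t.name: np.concatenate([shared_down_idx, take(n_specific)])
                for t in config.tissues}
    if config.module_size > 0 and n_shared > 0:
        module_idx = rng.choice(shared_up_idx, size=config.module_size, replace=False)
    else:
        module_idx = rng.choice(config.n_genes, size=config.module_size, replace=False)

    # state-specific (or shared) module loading vectors: per state a gene is
    # active (loading +/- strength) with probability module_active_prob, so
    # the |r|-thresholded edge topology genuinely rewires between states
    def _loadings() -> np.ndarray:
        active = rng.random(config.module_size) < config.module_active_prob
        signs = rng.choice([-1.0, 1.0], size=config.module_size)
        return np.where(active, signs * config.module_strength, 0.0)

    w_plus = _loadings()
    w_minus = _loadings() if config.state_specific_wiring else w_plus

    counts: dict[str, ExpressionMatrix] = {}
    designs: dict[str, pd.DataFrame] = {}
    effects: dict[str, dict[str, float]] = {}
    latent: dict[str, float] = {}

    for t in config.tissues:
        baseline = rng.normal(config.baseline_mu, config.baseline_sigma, config.n_genes)
        line_names = [f"{t.name}L{i + 1}" for i in range(t.n_lines)]
        line_offsets = {ln: rng.normal(0.0, config.line_sigma, config.n_genes)
                        for ln in line_names}
        delta = np.zeros(config.n_genes)
        delta[up_idx[t.name]] = config.effect_size
        delta[down_idx[t.name]] = -config.effect_size
        effects[t.name] = {genes[i]: float(delta[i])
                           for i in np.flatnonzero(delta != 0)}

        sample_rows = []
        cols = {}
        for ln in line_names:
            for state, tag in (("PKH26_plus", "p"), ("PKH26_minus", "m")):
                for rep in range(1, t.replicates_per_state_per_line + 1):
                    sid = f"{t.name}_{ln}_{tag}{rep}"
                    z = float(rng.normal())
                    latent[sid] = z
                    # pre-effect expression defines the normalizer: it is
                    # phenotype-independent, so the planted shift is not
                    # leaked into non-signature genes
                    x_base = baseline + line_offsets[ln] \
                        + rng.normal(0.0, config.noise_sigma, config.n_genes)
                    z_norm = float(np.sum(np.exp2(x_base)))
                    x = x_base.copy()
                    if state == "PKH26_plus":
                        x = x + delta
                        w = w_plus
                    else:
                        w = w_minus
                    x[module_idx] = x[module_idx] + w * z
                    if config.libsize_cv > 0:
                        sig2 = np.log(1.0 + config.libsize_cv**2)
                        libsize = float(rng.lognormal(
                            np.log(config.libsize_mu) - sig2 / 2.0, np.sqrt(sig2)))
                    else:
                        libsize = config.libsize_mu
                    mu = libsize * np.exp2(x) / z_norm
                    if config.dispersion > 0:
                        r = 1.0 / config.dispersion
                        col = rng.negative_binomial(r, r / (r + mu)).astype(float)
                    else:
                        col = mu
                    cols[sid] = col
                    sample_rows.append({"sample": sid, "tissue": t.name, "line": ln,
                                        "phenotype": state, "replicate": rep})
        df = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
        counts[t.name] = ExpressionMatrix(df, scale="counts")
        designs[t.name] = pd.DataFrame(sample_rows)

    truth = SimTruth(
        up_genes={k: sorted(genes[v]) for k, v in up_idx.items()},
        down_genes={k: sorted(genes[v]) for k, v in down_idx.items()},
        shared_up=sorted(genes[shared_up_idx]),
        shared_down=sorted(genes[shared_down_idx]),
        module_members=sorted(genes[module_idx]),
        effects=effects,
        latent_factors=latent,
        module_loadings={
            "plus": {genes[g]: float(w) for g, w in zip(module_idx, w_plus)},
            "minus": {genes[g]: float(w) for g, w in zip(module_idx, w_minus)},
        },
    )

    gene_sets = _build_gene_sets(config, rng, genes, module_idx,
                                 up_idx, down_idx)
    return counts, designs, truth, gene_sets


def _build_gene_sets(config: SimConfig, rng: np.random.Generator,
                     genes: np.ndarray, module_idx: np.ndarray,
                     up_idx: dict, down_idx: dict) -> GeneSetCollection:
    """Planted module set, overlapping module sub-pathways and size-matched
    decoy sets of non-signature genes."""
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    if config.module_size > 0:
        sets["MODULE_MAIN"] = frozenset(genes[module_idx])
        labels["MODULE_MAIN"] = "planted co-expression module"
        for i in range(config.n_module_pathways):
            size = max(5, int(round(config.module_size *
                                    rng.uniform(0.4, 0.8))))
            sub = rng.choice(module_idx, size=min(size, config.module_size),
                             replace=False)
            name = f"MODULE_PATHWAY_{i + 1:02d}"
            sets[name] = frozenset(genes[sub])
            labels[name] = "overlapping subset of the planted module"
    sig = set(np.concatenate([*up_idx.values(), *down_idx.values()])) | set(module_idx)
    nonsig = np.array(sorted(set(range(config.n_genes)) - sig))
    decoy_size = config.module_size if config.module_size > 0 else 20
    for i in range(config.n_decoy_sets):
        if nonsig.size < decoy_size:
            break
        pick = rng.choice(nonsig, size=decoy_size, replace=False)
        name = f"DECOY_{i + 1:03d}"
        sets[name] = frozenset(genes[pick])
        labels[name] = "size-matched non-signature decoy"
    return GeneSetCollection(sets, labels)


def make_anti_pooling_example(n_module: int = 10, n_other: int = 10,
                              reps: int = 6, seed: int = 0
                              ) -> tuple[ExpressionMatrix, pd.DataFrame, list[str]]:
    """Constructed range-restriction demonstration.

    Module genes follow a within-state latent factor whose loading flips
    sign between states, on top of gene-specific between-state mean
    shifts: within each state the module is tightly correlated, while
    pooling the two states mixes clouds with different means and opposed
    wiring, destroying the correlations.  State-specific networks on the
    module are therefore strictly denser than the pooled network.
    Returns (log-scale matrix, design, module gene ids).
    """
    rng = np.random.default_rng(seed)
    z_plus = rng.normal(size=reps)
    z_minus = rng.normal(size=reps)
    rows = []
    for g in range(n_module):
        w = 1.0 if g % 2 == 0 else -1.0
        plus = 5.0 + w * z_plus + rng.normal(0, 0.05, reps)
        minus = 5.0 + (2.5 * g) % 3 - w * z_minus + rng.normal(0, 0.05, reps)
        rows.append(np.r_[plus, minus])
    for _ in range(n_other):
        rows.append(rng.normal(5, 1, 2 * reps))
    genes = [f"M{i:02d}" for i in range(n_module)] + \
            [f"O{i:02d}" for i in range(n_other)]
    samples = [f"p{i}" for i in range(reps)] + [f"m{i}" for i in range(reps)]
    m = ExpressionMatrix(pd.DataFrame(np.array(rows), index=genes,
                                      columns=samples), scale="log_generic")
    design = pd.DataFrame({
        "sample": samples, "tissue": "t", "line": "l1",
        "phenotype": ["PKH26_plus"] * reps + ["PKH26_minus"] * reps,
        "replicate": list(range(reps)) * 2,
    })
    return m, design, genes[:n_module]


def write_experiment(counts: dict[str, ExpressionMatrix],
                     designs: dict[str, pd.DataFrame], truth: SimTruth,
                     gene_sets: GeneSetCollection, outdir: str | Path) -> None:
    """Write counts TSV, design TSV, truth JSON and gene-set GMT files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tissue, m in counts.items():
        m.to_tsv(outdir / f"counts_{tissue}.tsv")
        write_design(designs[tissue], outdir / f"design_{tissue}.tsv")
    truth.to_json(outdir / "truth.json")
    write_gmt(gene_sets, outdir / "gene_sets.gmt")
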