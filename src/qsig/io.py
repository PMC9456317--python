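"""Expression-matrix, design-table and gene-set IO plus log-CPM.

In-memory containers are thin dataclasses around pandas/numpy objects:
an :class:`ExpressionMatrix` is a genes x samples frame with an explicit
scale tag (raw counts vs log2 counts-per-million), a design is a pandas
DataFrame with a controlled phenotype vocabulary, and a
:class:`GeneSetCollection` maps set names to member-gene frozensets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: allowed scale tags for an ExpressionMatrix
SCALES = ("counts", "logcpm", "log_generic")

#: controlled phenotype vocabulary: label-retaining (quiescent) vs not
PHENOTYPES = ("PKH26_plus", "PKH26_minus")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale tag."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.scale == "counts" and (self.data.to_numpy() < 0).any():
            raise ValueError("counts-scale matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], scale=self.scale)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], scale=self.scale)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


@dataclass
class GeneSetCollection:
    """Named gene sets, each with a database label and member ids."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def filter_sizes(self, ranked_genes: Iterable[str], min_size: int = 5,
                     max_size: int = 500) -> "GeneSetCollection":
        """Restrict members to a ranked universe and drop out-of-bound sets."""
        universe = set(ranked_genes)
        kept, labels = {}, {}
        for name, members in self.sets.items():
            inter = members & universe
            if min_size <= len(inter) <= max_size and len(inter) < len(universe):
                kept[name] = frozenset(inter)
                labels[name] = self.labels.get(name, "")
        return GeneSetCollection(kept, labels)


def _normalize_gene_ids(ids: Iterable[str]) -> list[str]:
    return [str(g).strip().upper() for g in ids]


def read_counts(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a raw count matrix (genes as rows, samples as columns).

    ``format='tsv'`` expects a header row of sample ids and a leading gene
    column.  ``format='mtx_triplet'`` expects a MatrixMarket file ``path``
    with companion ``<stem>.genes.txt`` / ``<stem>.samples.txt`` index files.

    Gene symbols are whitespace-trimmed and uppercased.  Duplicate sample
    ids are a hard error; duplicate gene ids are retained (they are resolved
    later at ranking time) with a logged count.
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(header) != len(set(header)):
            raise ValueError(f"duplicate sample ids in header of {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx_triplet":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")
        genes = Path(f"{stem}.genes.txt").read_text().split()
        samples = Path(f"{stem}.samples.txt").read_text().split()
        if len(samples) != len(set(samples)):
            raise ValueError(f"duplicate sample ids in {stem}.samples.txt")
        df = pd.DataFrame(np.asarray(mat), index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")
    df.index = pd.Index(_normalize_gene_ids(df.index), name="gene")
    n_dup = int(df.index.duplicated().sum())
    if n_dup:
        logger.info("read_counts: %d duplicate gene ids retained in %s", n_dup, path)
    return ExpressionMatrix(df.astype(float), scale="counts")


def log_cpm(m: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with a library-scaled pseudocount.

    value = log2( (count + prior_s) / (libsize + 2*prior_s) * 1e6 ), with
    prior_s = prior_count * libsize / mean(libsize) and library size the
    sample's column sum (the scaled-prior convention of standard log-CPM
    practice).  Strictly monotone in counts within a sample; samples with
    proportional counts map to identical columns exactly.
    """
    if m.scale != "counts":
        raise ValueError(f"log_cpm expects a counts-scale matrix, got {m.scale!r}")
    libsize = m.values.sum(axis=0)
    if (libsize <= 0).any():
        bad = [s for s, l in zip(m.sample_ids, libsize) if l <= 0]
        raise ValueError(f"zero library size for samples {bad}")
    prior = prior_count * libsize / libsize.mean()
    vals = np.log2((m.values + prior) / (libsize + 2.0 * prior) * 1e6)
    return ExpressionMatrix(pd.DataFrame(vals, index=m.data.index, columns=m.data.columns),
                            scale="logcpm")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read a sample design table (sample, tissue, line, phenotype[, replicate])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "tissue", "line", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design file {path} missing columns {sorted(missing)}")
    bad = sorted(set(df["phenotype"]) - set(PHENOTYPES))
    if bad:
        raise ValueError(f"unknown phenotype labels {bad}; expected {PHENOTYPES}")
    if df["sample"].duplicated().any():
        raise ValueError(f"duplicate sample ids in design {path}")
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file: name, description, members...

    An empty file yields an empty collection with a warning; a line with
    no members is a hard error.
    """
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: gene set with <1 member")
        name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} with no members")
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(_normalize_gene_ids(members))
        labels[name] = desc
    if not sets:
        warnings.warn(f"GMT file {path} contains no gene sets", stacklevel=2)
    return GeneSetCollection(sets, labels)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; members sorted for bit-stable output."""
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.labels.get(name, '')}\t{members}\n")


def write_mtx_triplet(m: ExpressionMatrix, path: str | Path) -> None:
    """Write counts as MatrixMarket triplet + gene/sample index files."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
    stem = path.with_suffix("")
    Path(f"{stem}.genes.txt").write_text("\n".join(m.gene_ids) + "\n")
    Path(f"{stem}.samples.txt").write_text("\n".join(m.sample_ids) + "\n")
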