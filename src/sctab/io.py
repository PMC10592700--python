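"""Core domain types and I/O: expression matrices, ontologies, shard stores.

Conventions used throughout the package: cells are rows and genes are columns,
indices are 0-based, and expression values after `normalize` are natural-log
log1p of size-factor-scaled counts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import obonet
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq
import scipy.sparse as sp

__all__ = [
    "REQUIRED_META_COLUMNS",
    "ExpressionDataset",
    "NormalizedMatrix",
    "OntologyDAG",
    "LabelSpace",
    "ShardStore",
    "read_expression",
    "read_obo",
    "write_obo",
    "normalize",
    "write_shards",
    "stream_batches",
]

REQUIRED_META_COLUMNS = (
    "donor_id",
    "cell_type",
    "assay",
    "tissue",
    "dataset_id",
    "is_primary",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Raw UMI counts (cells x genes) plus per-cell metadata.

    ``counts`` is a dense or CSR integer-valued matrix; ``cell_meta`` carries
    one row per cell with the columns in `REQUIRED_META_COLUMNS`.
    """

    counts: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows but counts has "
                f"{n_cells} cells"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries but counts has "
                f"{n_genes} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell_meta missing required columns: {missing}")
        mn = self.counts.min() if not sp.issparse(self.counts) else self.counts.data.min(initial=0)
        if mn < 0:
            raise ValueError("negative counts")
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense_counts(self) -> np.ndarray:
        x = self.counts
        return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)

    def subset(self, cell_idx: np.ndarray) -> "ExpressionDataset":
        """Row-subset keeping gene space and metadata aligned."""
        cell_idx = np.asarray(cell_idx)
        return ExpressionDataset(
            counts=self.counts[cell_idx],
            gene_ids=list(self.gene_ids),
            cell_meta=self.cell_meta.iloc[cell_idx].reset_index(drop=True),
        )

    def to_anndata(self) -> ad.AnnData:
        obs = self.cell_meta.copy()
        obs.index = obs.index.astype(str)
        adata = ad.AnnData(X=sp.csr_matrix(self.counts), obs=obs)
        adata.var_names = list(self.gene_ids)
        return adata

    def write_h5ad(self, path: str | Path) -> None:
        self.to_anndata().write_h5ad(Path(path))


@dataclass
class NormalizedMatrix:
    """log1p of size-factor-normalized expression (cells x genes)."""

    values: np.ndarray
    target_sum: float = 10_000.0

    def __post_init__(self) -> None:
        if np.min(self.values) < 0:
            raise ValueError("normalized values must be non-negative")


class OntologyDAG:
    """Cell-type ontology as a DAG of is_a edges (child -> parent), rooted.

    Supports the ancestor/descendant queries the corpus filters and the
    ontology-corrected metric need; transitive closures are cached.
    """

    def __init__(self, terms: set[str], is_a_edges: set[tuple[str, str]], root: str):
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(is_a_edges)  # child -> parent
        if root not in terms:
            raise ValueError(f"root term {root!r} not among terms")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        for t in terms:
            if t != root and not nx.has_path(g, t, root):
                raise ValueError(f"term {t!r} has no is_a path to root {root!r}")
        self.graph = g
        self.root = root
        self._anc_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def is_a_edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, OntologyDAG)
            and self.terms == other.terms
            and self.is_a_edges == other.is_a_edges
            and self.root == other.root
        )

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive is_a ancestors of ``term`` (excludes the term itself)."""
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in ontology")
        if term not in self._anc_cache:
            self._anc_cache[term] = frozenset(nx.descendants(self.graph, term))
        return self._anc_cache[term]

    def is_strict_descendant(self, a: str, b: str) -> bool:
        """True when ``a`` is a strict subtype of ``b`` via is_a edges."""
        return a != b and b in self.ancestors(a)

    def n_ancestors(self, term: str) -> int:
        return len(self.ancestors(term))


@dataclass(frozen=True)
class LabelSpace:
    """Stable bijection between cell-type terms and softmax output indices."""

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate classes in label space")

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "LabelSpace":
        return cls(classes=tuple(sorted(set(labels))))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index(self, term: str) -> int:
        return self._index()[term]

    def _index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.classes)}

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        idx = self._index()
        try:
            return np.array([idx[l] for l in labels], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"label {e.args[0]!r} not in label space") from None

    def decode(self, codes: Sequence[int]) -> list[str]:
        return [self.classes[int(c)] for c in codes]


@dataclass
class ShardStore:
    """Ordered list of parquet shards that concatenate to one dataset.

    Each shard holds one column per gene (named by gene id) plus the metadata
    columns; a sidecar ``schema.json`` records gene order and shard layout.
    """

    shard_paths: list[Path]
    rows_per_shard: int
    gene_ids: list[str]
    meta_columns: list[str] = field(default_factory=lambda: list(REQUIRED_META_COLUMNS))

    @property
    def n_shards(self) -> int:
        return len(self.shard_paths)

    @classmethod
    def open(cls, out_dir: str | Path) -> "ShardStore":
        out_dir = Path(out_dir)
        schema = json.loads((out_dir / "schema.json").read_text())
        return cls(
            shard_paths=[out_dir / p for p in schema["shards"]],
            rows_per_shard=schema["rows_per_shard"],
            gene_ids=schema["gene_ids"],
            meta_columns=schema["meta_columns"],
        )

    def read_all(self) -> ExpressionDataset:
        frames = [pq.read_table(p).to_pandas() for p in self.shard_paths]
        df = pd.concat(frames, ignore_index=True)
        counts = df[self.gene_ids].to_numpy(dtype=np.int64)
        meta = df[self.meta_columns].copy()
        return ExpressionDataset(counts=counts, gene_ids=list(self.gene_ids), cell_meta=meta)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str = "h5ad") -> ExpressionDataset:
    """Read an `ExpressionDataset` from H5AD or an MTX directory.

    The MTX directory layout is the 10x-style triplet ``matrix.mtx`` (genes x
    cells or cells x genes, detected from ``barcodes.tsv``/``features.tsv``
    lengths), ``barcodes.tsv`` with the metadata columns, ``features.tsv``
    with gene ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "h5ad":
        adata = ad.read_h5ad(path)
        missing = [c for c in REQUIRED_META_COLUMNS if c not in adata.obs.columns]
        if missing:
            raise ValueError(f"H5AD obs missing required columns: {missing}")
        counts = adata.X
        if sp.issparse(counts):
            counts = counts.tocsr()
        counts = np.asarray(counts.todense()) if sp.issparse(counts) else np.asarray(counts)
        if np.any(counts < 0):
            raise ValueError("negative counts in H5AD")
        meta = adata.obs[list(REQUIRED_META_COLUMNS)].copy()
        return ExpressionDataset(
            counts=counts.astype(np.int64),
            gene_ids=list(adata.var_names),
            cell_meta=meta,
        )
    if format == "mtx_dir":
        import scipy.io as sio

        mtx = sp.csr_matrix(sio.mmread(path / "matrix.mtx"))
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t")
        gene_ids = features[0].tolist()
        if mtx.shape == (len(gene_ids), len(barcodes)):
            mtx = mtx.T.tocsr()  # 10x convention: genes x cells
        if mtx.shape != (len(barcodes), len(gene_ids)):
            raise ValueError(
                f"matrix shape {mtx.shape} inconsistent with {len(barcodes)} "
                f"barcodes and {len(gene_ids)} features"
            )
        missing = [c for c in REQUIRED_META_COLUMNS if c not in barcodes.columns]
        if missing:
            raise ValueError(f"barcodes.tsv missing required columns: {missing}")
        counts = np.asarray(mtx.todense()).astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("negative counts in MTX")
        return ExpressionDataset(counts=counts, gene_ids=gene_ids, cell_meta=barcodes)
    raise ValueError(f"unknown format {format!r}")


def read_obo(path: str | Path, root: str | None = None) -> OntologyDAG:
    """Parse an OBO file into an `OntologyDAG`, dropping obsolete terms.

    Only is_a relations are kept. ``root`` defaults to the unique term with no
    is_a parent.
    """
    g = obonet.read_obo(Path(path))
    # obonet already drops is_obsolete terms; edges point child -> parent
    terms = set(g.nodes)
    edges = {(u, v) for u, v, k in g.edges(keys=True) if k == "is_a"}
    keep = nx.DiGraph()
    keep.add_nodes_from(terms)
    keep.add_edges_from(edges)
    if root is None:
        roots = [t for t in terms if keep.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"cannot infer root: candidates {sorted(roots)}")
        root = roots[0]
    return OntologyDAG(terms=terms, is_a_edges=edges, root=root)


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Serialize a DAG to a minimal OBO file (round-trips through `read_obo`)."""
    lines = ["format-version: 1.2", ""]
    parents: dict[str, list[str]] = {t: [] for t in dag.terms}
    for child, parent in sorted(dag.is_a_edges):
        parents[child].append(parent)
    for term in sorted(dag.terms):
        lines += ["[Term]", f"id: {term}", f"name: {term}"]
        lines += [f"is_a: {p}" for p in sorted(parents[term])]
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(data: ExpressionDataset | np.ndarray, target_sum: float = 10_000.0) -> NormalizedMatrix:
    """Size-factor normalize to ``target_sum`` counts per cell, then log1p.

    Row i of the result is ``log1p(counts_i * target_sum / sum(counts_i))``
    (natural log). Cells with zero total count are an error: they carry no
    expression signal and should have been removed by upstream filters.
    """
    counts = data.dense_counts() if isinstance(data, ExpressionDataset) else np.asarray(data)
    counts = counts.astype(np.float64)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"all-zero cells at indices {zero[:10].tolist()}")
    values = np.log1p(counts * (target_sum / totals)[:, None])
    return NormalizedMatrix(values=values, target_sum=float(target_sum))


# ---------------------------------------------------------------------------
# Shard store
# ---------------------------------------------------------------------------

def write_shards(
    data: ExpressionDataset,
    out_dir: str | Path,
    rows_per_shard: int,
    overwrite: bool = False,
) -> ShardStore:
    """Split a dataset into parquet shards of ``rows_per_shard`` cells each."""
    if rows_per_shard < 1:
        raise ValueError("rows_per_shard must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is non-empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    counts = data.dense_counts()
    n = data.n_cells
    n_shards = math.ceil(n / rows_per_shard)
    shard_names = []
    for s in range(n_shards):
        lo, hi = s * rows_per_shard, min((s + 1) * rows_per_shard, n)
        df = pd.DataFrame(counts[lo:hi], columns=data.gene_ids)
        for c in REQUIRED_META_COLUMNS:
            df[c] = data.cell_meta[c].iloc[lo:hi].to_numpy()
        name = f"shard_{s:05d}.parquet"
        pq.write_table(pa.Table.from_pandas(df, preserve_index=False), out_dir / name)
        shard_names.append(name)

    schema = {
        "shards": shard_names,
        "rows_per_shard": rows_per_shard,
        "gene_ids": list(data.gene_ids),
        "meta_columns": list(REQUIRED_META_COLUMNS),
    }
    (out_dir / "schema.json").write_text(json.dumps(schema))
    return ShardStore(
        shard_paths=[out_dir / n_ for n_ in shard_names],
        rows_per_shard=rows_per_shard,
        gene_ids=list(data.gene_ids),
    )


def stream_batches(
    store: ShardStore,
    batch_size: int,
    shuffle: bool = True,
    seed: int = 0,
    buffer_shards: int = 4,
) -> Iterator[pd.DataFrame]:
    """Stream one epoch of cells in batches of ``batch_size``.

    Shuffling is block-based, mirroring how bigger-than-memory tabular data is
    read from disk: the shard order is permuted, shards are read ``buffer_shards``
    at a time into a buffer, and the buffer is shuffled in memory before
    batches are emitted. Both permutations derive from ``seed``, so an epoch is
    fully reproducible. Without shuffling, rows come in on-disk order.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(seed)
    order = np.arange(store.n_shards)
    if shuffle:
        rng.shuffle(order)

    pending = pd.DataFrame()
    for start in range(0, store.n_shards, buffer_shards):
        block = [pq.read_table(store.shard_paths[i]).to_pandas() for i in order[start:start + buffer_shards]]
        buf = pd.concat([pending] + block, ignore_index=True)
        if shuffle:
            buf = buf.iloc[rng.permutation(len(buf))].reset_index(drop=True)
        n_full = (len(buf) // batch_size) * batch_size
        for lo in range(0, n_full, batch_size):
            yield buf.iloc[lo:lo + batch_size].reset_index(drop=True)
        pending = buf.iloc[n_full:].reset_index(drop=True)
    if len(pending):
        yield pending
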