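"""Seeded synthetic scRNA-seq corpora with the structure the method assumes.

The generator emulates the three ingredients the classifier and the
augmentation scheme rely on: cell-type expression programs (distinct gene
modules up-regulated per type), additive per-donor batch effects in log-mean
space, and Poisson count noise with variable library size. Cell-type labels
live on a toy ontology whose leaves have a configurable number of ancestors,
so corpus filters and ontology-corrected evaluation are exercisable end to
end without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionDataset, OntologyDAG

__all__ = ["SimConfig", "SimOutput", "make_toy_ontology", "simulate", "make_xor_corpus"]

ROOT_TERM = "CT:0000000"  # "native cell" analog


@dataclass
class SimConfig:
    n_genes: int = 200
    n_cell_types: int = 8
    n_donors: int = 20
    cells_per_donor: int = 500
    type_effect_scale: float = 2.0
    donor_effect_scale: float = 0.4
    depth_mean: float = 2000.0
    ontology_depth: int = 7
    overdispersion: float = 0.0  # NB dispersion; 0 = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cell_types, self.n_donors, self.cells_per_donor) < 1:
            raise ValueError("size parameters must be >= 1")
        if min(self.type_effect_scale, self.donor_effect_scale) < 0:
            raise ValueError("effect scales must be >= 0")


@dataclass
class SimOutput:
    dataset: ExpressionDataset
    ontology: OntologyDAG
    truth: dict = field(default_factory=dict)

    @property
    def leaf_terms(self) -> list[str]:
        return self.truth["leaf_terms"]


def leaf_term(j: int) -> str:
    return f"CT:1{j:06d}"


def make_toy_ontology(n_types: int, depth: int = 7, seed: int = 0) -> OntologyDAG:
    """Rooted toy DAG whose leaves (the assignable labels) have >= depth ancestors.

    A backbone chain of ``depth - 1`` internal terms hangs under the root and
    every leaf attaches to the end of the chain, giving each leaf exactly
    ``depth`` ancestors on the chain path. A seeded subset of leaves gets a
    second parent (a side term under the root), producing diamonds so the
    graph is a genuine DAG rather than a tree.
    """
    if n_types < 1 or depth < 1:
        raise ValueError("n_types and depth must be >= 1")
    rng = np.random.default_rng(seed)
    terms = {ROOT_TERM}
    edges: set[tuple[str, str]] = set()
    chain = [ROOT_TERM]
    for k in range(1, depth):
        t = f"CT:2{k:06d}"
        terms.add(t)
        edges.add((t, chain[-1]))
        chain.append(t)
    side = f"CT:3{0:06d}"
    terms.add(side)
    edges.add((side, ROOT_TERM))
    for j in range(n_types):
        leaf = leaf_term(j)
        terms.add(leaf)
        edges.add((leaf, chain[-1]))
        if depth > 1 and rng.random() < 0.3:
            edges.add((leaf, side))  # diamond: two upward paths
    return OntologyDAG(terms=terms, is_a_edges=edges, root=ROOT_TERM)


def _donor_effects(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Additive per-donor offsets in log-mean space on a random 20% gene subset."""
    effects = np.zeros((cfg.n_donors, cfg.n_genes))
    n_hit = max(1, cfg.n_genes // 5)
    for d in range(cfg.n_donors):
        hit = rng.choice(cfg.n_genes, size=n_hit, replace=False)
        effects[d, hit] = cfg.donor_effect_scale * rng.normal(size=n_hit)
    return effects


def _sample_counts(
    log_mean: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson (or NB) counts with per-cell library size around depth_mean."""
    w = np.exp(log_mean)
    p = w / w.sum(axis=1, keepdims=True)
    lib = np.maximum(rng.poisson(cfg.depth_mean, size=log_mean.shape[0]), 1)
    lam = lib[:, None] * p
    if cfg.overdispersion > 0:
        # NB via gamma-Poisson mixture
        shape = 1.0 / cfg.overdispersion
        lam = rng.gamma(shape, lam / shape)
    return rng.poisson(lam).astype(np.int64)


def _metadata(types: np.ndarray, donors: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "donor_id": [f"donor_{d:04d}" for d in donors],
            "cell_type": [leaf_term(t) for t in types],
            "assay": "10x 3' v3",
            "tissue": "synthetic_tissue",
            "dataset_id": "synthetic_0001",
            "is_primary": True,
        }
    )


def simulate(cfg: SimConfig) -> SimOutput:
    """Generate a corpus with type programs, donor batch effects, count noise.

    Each cell type up-regulates its own disjoint gene module by
    ``type_effect_scale`` in log-mean space; each donor adds its offset vector;
    counts are Poisson around a library size drawn per cell.
    """
    rng = np.random.default_rng(cfg.seed)
    base = rng.normal(0.0, 0.3, size=cfg.n_genes)
    module = max(1, cfg.n_genes // (2 * cfg.n_cell_types))
    type_prog = np.zeros((cfg.n_cell_types, cfg.n_genes))
    for t in range(cfg.n_cell_types):
        type_prog[t, t * module:(t + 1) * module] = cfg.type_effect_scale
    donor_eff = _donor_effects(cfg, rng)

    n = cfg.n_donors * cfg.cells_per_donor
    donors = np.repeat(np.arange(cfg.n_donors), cfg.cells_per_donor)
    types = rng.integers(0, cfg.n_cell_types, size=n)
    log_mean = base[None, :] + type_prog[types] + donor_eff[donors]
    counts = _sample_counts(log_mean, cfg, rng)

    dataset = ExpressionDataset(
        counts=counts, gene_ids=[f"ENSG{g:011d}" for g in range(cfg.n_genes)],
        cell_meta=_metadata(types, donors),
    )
    ontology = make_toy_ontology(cfg.n_cell_types, cfg.ontology_depth, seed=cfg.seed)
    truth = {
        "type_index": types,
        "donor_index": donors,
        "type_programs": type_prog,
        "donor_effects": donor_eff,
        "leaf_terms": [leaf_term(j) for j in range(cfg.n_cell_types)],
    }
    return SimOutput(dataset=dataset, ontology=ontology, truth=truth)


def make_xor_corpus(cfg: SimConfig) -> SimOutput:
    """Corpus whose two classes are an XOR of two gene-module activations.

    Modules A and B are each on or off per cell; the label is class 1 iff
    exactly one module is active. No linear decision boundary in gene space
    separates the classes, so the corpus discriminates nonlinear classifiers
    from linear ones.
    """
    rng = np.random.default_rng(cfg.seed)
    base = rng.normal(0.0, 0.3, size=cfg.n_genes)
    module = max(1, cfg.n_genes // 8)
    prog_a = np.zeros(cfg.n_genes)
    prog_a[:module] = cfg.type_effect_scale
    prog_b = np.zeros(cfg.n_genes)
    prog_b[module:2 * module] = cfg.type_effect_scale
    donor_eff = _donor_effects(cfg, rng)

    n = cfg.n_donors * cfg.cells_per_donor
    donors = np.repeat(np.arange(cfg.n_donors), cfg.cells_per_donor)
    a_on = rng.integers(0, 2, size=n)
    b_on = rng.integers(0, 2, size=n)
    types = (a_on ^ b_on).astype(np.int64)
    log_mean = (
        base[None, :]
        + a_on[:, None] * prog_a[None, :]
        + b_on[:, None] * prog_b[None, :]
        + donor_eff[donors]
    )
    counts = _sample_counts(log_mean, cfg, rng)

    dataset = ExpressionDataset(
        counts=counts, gene_ids=[f"ENSG{g:011d}" for g in range(cfg.n_genes)],
        cell_meta=_metadata(types, donors),
    )
    ontology = make_toy_ontology(2, cfg.ontology_depth, seed=cfg.seed)
    truth = {
        "type_index": types, "donor_index": donors,
        "a_on": a_on, "b_on": b_on, "donor_effects": donor_eff,
        "leaf_terms": [leaf_term(0), leaf_term(1)],
    }
    return SimOutput(dataset=dataset, ontology=ontology, truth=truth)
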