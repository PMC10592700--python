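"""Donor-difference data augmentation for expression classifiers.

The augmentation simulates how a cell's expression profile would look had it
been observed in a different donor: differences between per-(cell type, donor)
mean centroids of normalized expression are precomputed into a bank, and
during training a randomly drawn difference vector is added to or subtracted
from each training cell (fair coin), with the result clamped into [0, 9] —
the plausible range of log1p-normalized expression.

Bank construction: (1) subsample up to ``subsample_n`` cells balanced across
cell types; (2) centroids per (cell type, donor); (3) within each cell type,
difference vectors between donor-pair centroids; (4) zero out entries in
[-zero_band, zero_band] to sparsify; (5) clamp entries to [-clamp, clamp];
(6) k-means the vectors into ``n_clusters`` and sample ``sample_size`` of them
uniformly from clusters with more than ``min_cluster_size`` members, which
discards outlier vectors.

`variance_r2` quantifies how much expression variance cell type plus donor
identity explain (a linear fit on one-hot covariates); comparing raw against
augmented data shows the augmentation blurs but does not destroy cell-type
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.preprocessing import OneHotEncoder

from .io import NormalizedMatrix

__all__ = [
    "AugmentationParams", "AugmentationBank", "VarianceDecomposition",
    "build_bank", "augment", "augment_batch", "variance_r2",
]

EXPRESSION_RANGE = (0.0, 9.0)  # clamp interval for augmented log1p expression


@dataclass
class AugmentationParams:
    subsample_n: int = 500_000
    zero_band: float = 0.25
    clamp: float = 1.5
    n_clusters: int = 50
    min_cluster_size: int = 2000
    sample_size: int = 5000
    max_pairs_per_type: int = 1000
    seed: int = 0


@dataclass
class AugmentationBank:
    vectors: np.ndarray  # n_vectors x genes
    params: AugmentationParams = field(default_factory=AugmentationParams)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2:
            raise ValueError("bank vectors must be 2-D (n_vectors x genes)")
        if np.abs(self.vectors).max(initial=0.0) > self.params.clamp + 1e-12:
            raise ValueError("bank vectors exceed the clamp interval")

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]

    def save(self, path: str | Path) -> None:
        np.savez_compressed(Path(path), vectors=self.vectors)
        import json

        Path(str(path) + ".json").write_text(json.dumps(self.params.__dict__))

    @classmethod
    def load(cls, path: str | Path) -> "AugmentationBank":
        import json

        vectors = np.load(Path(path))["vectors"]
        params = AugmentationParams(**json.loads(Path(str(path) + ".json").read_text()))
        return cls(vectors=vectors, params=params)


@dataclass
class VarianceDecomposition:
    r2: float
    design: str = "intercept + onehot(cell_type) + onehot(donor_id)"


def _balanced_subsample(
    meta: pd.DataFrame, n_target: int, rng: np.random.Generator
) -> np.ndarray:
    """Up to n_target cell indices, as evenly across cell types as possible.

    Per-type quota = n_target / n_types, capped at availability; leftover quota
    is redistributed proportionally among types that still have cells.
    """
    groups = {t: np.flatnonzero((meta["cell_type"] == t).to_numpy())
              for t in meta["cell_type"].unique()}
    n_total = len(meta)
    if n_total <= n_target:
        return np.arange(n_total)
    take = {t: 0 for t in groups}
    remaining = n_target
    active = set(groups)
    while remaining > 0 and active:
        quota = max(1, remaining // len(active))
        progress = False
        for t in sorted(active):
            room = len(groups[t]) - take[t]
            grab = min(quota, room, remaining)
            if grab > 0:
                take[t] += grab
                remaining -= grab
                progress = True
            if take[t] == len(groups[t]):
                active.discard(t)
            if remaining == 0:
                break
        if not progress:
            break
    idx = np.concatenate([
        rng.choice(groups[t], size=take[t], replace=False) for t in sorted(groups) if take[t]
    ])
    return np.sort(idx)


def build_bank(
    x: NormalizedMatrix,
    meta: pd.DataFrame,
    params: AugmentationParams | None = None,
) -> AugmentationBank:
    """Precompute donor-difference vectors from normalized expression."""
    params = params or AugmentationParams()
    rng = np.random.default_rng(params.seed)
    values = x.values

    idx = _balanced_subsample(meta, params.subsample_n, rng)
    sub_vals = values[idx]
    sub_meta = meta.iloc[idx].reset_index(drop=True)

    # centroids per (cell type, donor)
    key = pd.MultiIndex.from_frame(sub_meta[["cell_type", "donor_id"]])
    centroids = pd.DataFrame(sub_vals).groupby(key).mean()

    diffs = []
    for ct in sorted(sub_meta["cell_type"].unique()):
        rows = centroids.loc[[k for k in centroids.index if k[0] == ct]]
        donors = list(rows.index)
        pairs = list(combinations(range(len(donors)), 2))
        if len(pairs) > params.max_pairs_per_type:
            chosen = rng.choice(len(pairs), size=params.max_pairs_per_type, replace=False)
            pairs = [pairs[i] for i in chosen]
        arr = rows.to_numpy()
        for i, j in pairs:
            diffs.append(arr[i] - arr[j])
    if not diffs:
        raise ValueError("no cell type is shared by at least two donors")
    d = np.array(diffs)

    d[np.abs(d) <= params.zero_band] = 0.0
    np.clip(d, -params.clamp, params.clamp, out=d)

    if d.shape[0] <= params.n_clusters:
        warnings.warn(
            "fewer difference vectors than clusters; skipping k-means filter",
            stacklevel=2,
        )
        chosen = d
    else:
        km = KMeans(n_clusters=params.n_clusters, random_state=params.seed, n_init=10)
        assign = km.fit_predict(d)
        sizes = np.bincount(assign, minlength=params.n_clusters)
        big = np.flatnonzero(sizes > params.min_cluster_size)
        if big.size:
            pool = np.flatnonzero(np.isin(assign, big))
        else:
            warnings.warn(
                "no k-means cluster exceeds min_cluster_size; falling back to "
                "largest clusters in size order",
                stacklevel=2,
            )
            order = np.argsort(-sizes, kind="stable")  # ties broken by cluster index
            pool_list: list[int] = []
            for c in order:
                pool_list.extend(np.flatnonzero(assign == c).tolist())
                if len(pool_list) >= params.sample_size:
                    break
            pool = np.array(pool_list)
        n_take = min(params.sample_size, pool.size)
        chosen = d[rng.choice(pool, size=n_take, replace=False)]
    return AugmentationBank(vectors=chosen, params=params)


def augment(x_cell: np.ndarray, bank: AugmentationBank, rng: np.random.Generator) -> np.ndarray:
    """clamp(x +/- v, 0, 9) for a uniformly drawn bank vector and fair-coin sign."""
    if bank.n_vectors == 0:
        raise ValueError("augmentation bank is empty")
    if x_cell.shape[-1] != bank.vectors.shape[1]:
        raise ValueError("gene-dimension mismatch between cell and bank")
    v = bank.vectors[rng.integers(bank.n_vectors)]
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return np.clip(x_cell + sign * v, *EXPRESSION_RANGE)


def augment_batch(x: np.ndarray, bank: AugmentationBank, rng: np.random.Generator) -> np.ndarray:
    """Vectorized `augment`: one independent vector and sign per row."""
    if bank.n_vectors == 0:
        raise ValueError("augmentation bank is empty")
    n = x.shape[0]
    v = bank.vectors[rng.integers(bank.n_vectors, size=n)]
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)[:, None]
    return np.clip(x + sign * v, *EXPRESSION_RANGE)


def variance_r2(x: NormalizedMatrix | np.ndarray, meta: pd.DataFrame) -> VarianceDecomposition:
    """R^2 of expression regressed on one-hot cell type and donor.

    Uniform-average multi-output R^2 of an ordinary least-squares fit; rank
    deficiency in the one-hot design is handled by the least-norm solution.
    """
    values = x.values if isinstance(x, NormalizedMatrix) else np.asarray(x)
    if meta["cell_type"].nunique() < 2 or meta["donor_id"].nunique() < 2:
        raise ValueError("need >= 2 cell types and >= 2 donors")
    enc = OneHotEncoder(sparse_output=False)
    design = enc.fit_transform(meta[["cell_type", "donor_id"]])
    fit = LinearRegression().fit(design, values)
    r2 = r2_score(values, fit.predict(design), multioutput="uniform_average")
    return VarianceDecomposition(r2=float(r2))
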