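"""Dataset preparation: quality filters, donor-level splitting, subsampling.

The filters remove cells that would make a cross-donor generalization
benchmark unreliable: secondary (duplicated) data, non-10x assays, labels that
are not proper cell types under the ontology root, rare types, types seen in
too few donors, and over-general labels with few ontology ancestors. They run
once, sequentially, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionDataset, OntologyDAG

__all__ = [
    "TENX_ASSAYS",
    "FilterConfig",
    "FilterStage",
    "FilterReport",
    "SplitAssignment",
    "apply_filters",
    "split_by_donor",
    "subsample",
]

# The seven 10x Genomics assay labels admitted by default.
TENX_ASSAYS = frozenset({
    "10x 5' v2",
    "10x 3' v3",
    "10x 3' v2",
    "10x 5' v1",
    "10x 3' v1",
    "10x 3' transcription profiling",
    "10x 5' transcription profiling",
})


@dataclass
class FilterConfig:
    allowed_assays: frozenset[str] = TENX_ASSAYS
    min_cells_per_type: int = 5000
    min_donors_per_type: int = 30
    min_ancestors: int = 7
    require_primary: bool = True
    root_term: str = "native cell"

    def __post_init__(self) -> None:
        if min(self.min_cells_per_type, self.min_donors_per_type, self.min_ancestors) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class FilterStage:
    name: str
    cells_removed: int
    cell_types_removed: list[str]


@dataclass
class FilterReport:
    stages: list[FilterStage] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "cells_removed": s.cells_removed,
                 "cell_types_removed": s.cell_types_removed}
                for s in self.stages
            ]
        }


class EmptyCorpusError(ValueError):
    def __init__(self, report: FilterReport):
        super().__init__("no cells remain after filtering")
        self.report = report


def apply_filters(
    data: ExpressionDataset,
    ontology: OntologyDAG,
    cfg: FilterConfig | None = None,
) -> tuple[ExpressionDataset, FilterReport]:
    """Apply the six corpus filters sequentially; returns data and a report.

    Stage 0 removes cells whose cell_type does not resolve in the ontology.
    Then: (1) primary data only; (2) allowed assays; (3) strict descendant of
    the root term; (4) >= min_cells_per_type cells per type; (5) type observed
    in >= min_donors_per_type donors; (6) type has >= min_ancestors transitive
    is_a ancestors. Thresholds are inclusive ("at least").
    """
    cfg = cfg or FilterConfig()
    meta = data.cell_meta
    keep = np.ones(data.n_cells, dtype=bool)
    report = FilterReport()

    def types_of(mask: np.ndarray) -> set[str]:
        return set(meta.loc[mask, "cell_type"])

    def record(name: str, new_keep: np.ndarray) -> np.ndarray:
        removed = keep & ~new_keep
        lost_types = types_of(keep) - types_of(new_keep)
        report.stages.append(FilterStage(name, int(removed.sum()), sorted(lost_types)))
        return new_keep

    resolvable = meta["cell_type"].map(lambda t: t in ontology).to_numpy()
    keep = record("unresolvable_terms", keep & resolvable)

    if cfg.require_primary:
        keep = record("primary_only", keep & meta["is_primary"].to_numpy(dtype=bool))
    ok_assay = meta["assay"].isin(cfg.allowed_assays).to_numpy()
    keep = record("allowed_assays", keep & ok_assay)

    is_sub = meta["cell_type"].map(
        lambda t: ontology.is_strict_descendant(t, cfg.root_term)
    ).to_numpy(dtype=bool)
    keep = record("subtype_of_root", keep & is_sub)

    counts = meta.loc[keep, "cell_type"].value_counts()
    big = set(counts[counts >= cfg.min_cells_per_type].index)
    keep = record("min_cells_per_type", keep & meta["cell_type"].isin(big).to_numpy())

    donors = meta.loc[keep].groupby("cell_type", observed=True)["donor_id"].nunique()
    spread = set(donors[donors >= cfg.min_donors_per_type].index)
    keep = record("min_donors_per_type", keep & meta["cell_type"].isin(spread).to_numpy())

    deep = {t for t in types_of(keep) if ontology.n_ancestors(t) >= cfg.min_ancestors}
    keep = record("min_ancestors", keep & meta["cell_type"].isin(deep).to_numpy())

    if not keep.any():
        raise EmptyCorpusError(report)
    return data.subset(np.flatnonzero(keep)), report


@dataclass
class SplitAssignment:
    donor_to_split: dict[str, str]
    fractions: tuple[float, float, float]

    def donors(self, split: str) -> list[str]:
        return [d for d, s in self.donor_to_split.items() if s == split]

    def cell_mask(self, meta: pd.DataFrame, split: str) -> np.ndarray:
        return meta["donor_id"].map(self.donor_to_split).eq(split).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"donor_id": list(self.donor_to_split), "split": list(self.donor_to_split.values())}
        )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_by_donor(
    donors: list[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Assign each donor to train/val/test so no donor crosses splits.

    Donors are permuted seed-deterministically; the first round(f_train * n)
    go to train, the next round(f_val * n) to val, the remainder to test
    (round-half-up, so every split is non-empty for n >= 3 at 70/15/15).
    """
    uniq = list(dict.fromkeys(donors))
    if len(uniq) < len(donors):
        import warnings

        warnings.warn("duplicate donor ids collapsed", stacklevel=2)
    if len(uniq) < 3:
        raise ValueError(f"need >= 3 unique donors, got {len(uniq)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    rng = np.random.default_rng(seed)
    perm = [uniq[i] for i in rng.permutation(len(uniq))]
    n = len(perm)
    n_train = _round_half_up(fractions[0] * n)
    n_val = _round_half_up(fractions[1] * n)
    n_train = min(n_train, n - 2)  # keep val/test non-empty
    n_val = min(max(n_val, 1), n - n_train - 1)
    assignment = {}
    for i, d in enumerate(perm):
        assignment[d] = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
    return SplitAssignment(donor_to_split=assignment, fractions=tuple(fractions))


def subsample(
    data: ExpressionDataset,
    mode: str,
    fraction: float,
    seed: int = 0,
) -> ExpressionDataset:
    """Incrementally nested subsampling by donor or by cell.

    A single seed-deterministic permutation of donors (or cells) is drawn and
    the first round(fraction * n) taken, so for a fixed seed the selection at a
    smaller fraction is always a subset of that at a larger one.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if mode == "donor":
        donors = list(dict.fromkeys(data.cell_meta["donor_id"]))
        perm = [donors[i] for i in rng.permutation(len(donors))]
        chosen = set(perm[: _round_half_up(fraction * len(perm))])
        idx = np.flatnonzero(data.cell_meta["donor_id"].isin(chosen).to_numpy())
    elif mode == "cell":
        perm = rng.permutation(data.n_cells)
        idx = np.sort(perm[: _round_half_up(fraction * data.n_cells)])
    else:
        raise ValueError(f"unknown subsample mode {mode!r}")
    return data.subset(idx)
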