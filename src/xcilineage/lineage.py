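"""Downstream clonal analyses built on XCI assignments and carrier calls.

* Clone-vs-XCI consistency: every cell of a true clone inherits the same
  active-X allele, so an independently derived clone table (e.g. TCR/BCR
  clonotypes) should be unanimous in XCI label; a permutation null
  quantifies how often unanimity arises by chance (for a clone of m
  assigned cells with label frequencies p and q it approaches
  p**m + q**m).
* Mutation burden: fraction of cells per cell type carrying at least one
  selected clonal mutation.
* Fate coupling: similarity of clonal-mutation carrier profiles between
  cell types — the normalized covariance (Pearson correlation over the
  variant axis) of the variants × cell-types carrier-count matrix. High
  coupling between two types suggests shared progenitors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel_io import CellMetadata, CloneTable, UNKNOWN_LABEL
from .xci_deconv import UNASSIGNED, XCIAssignment

__all__ = [
    "clone_xci_consistency",
    "null_consistency_probability",
    "shuffle_null",
    "mutation_burden",
    "fate_coupling",
]


def _labels_series(xci: XCIAssignment | pd.Series) -> pd.Series:
    if isinstance(xci, XCIAssignment):
        return xci.label_of()
    return xci


def clone_xci_consistency(clones: CloneTable, xci: XCIAssignment | pd.Series,
                          min_clone_size: int = 2) -> pd.DataFrame:
    """Per-clone XCI unanimity report.

    A clone is consistent iff all its *assigned* cells share one XCI label
    (strict unanimity); unassigned cells never break consistency. Clones
    with zero assigned cells get a NaN sentinel; clones below
    ``min_clone_size`` (in assigned cells) are reported but flagged.

    Columns: ``size`` (all member cells), ``n_assigned``,
    ``majority_allele``, ``consistent``, ``below_min_size``.
    """
    labels = _labels_series(xci)
    rows = []
    for clone in clones.clone_ids:
        members = clones.members(clone)
        mlabels = labels.reindex(members).dropna()
        mlabels = mlabels[mlabels != UNASSIGNED]
        n_assigned = len(mlabels)
        if n_assigned == 0:
            majority, consistent = None, np.nan
        else:
            counts = mlabels.value_counts()
            majority = counts.index[0]
            consistent = bool(counts.iloc[0] == n_assigned)
        rows.append({
            "clone": clone,
            "size": len(members),
            "n_assigned": n_assigned,
            "majority_allele": majority,
            "consistent": consistent,
            "below_min_size": n_assigned < min_clone_size,
        })
    return pd.DataFrame(rows).set_index("clone")


def null_consistency_probability(m: int, p: float, q: float | None = None) -> float:
    """Chance that a clone of m assigned cells is unanimous under shuffled labels.

    ``p`` and ``q`` are the two label frequencies among assigned cells
    (``q = 1 - p`` when omitted): probability = p**m + q**m. Exact for
    independent label draws, and the large-population limit of permutation
    without replacement.
    """
    if q is None:
        q = 1.0 - p
    return float(p ** m + q ** m)


def shuffle_null(clones: CloneTable, xci: XCIAssignment | pd.Series,
                 n_perm: int = 1000, seed: int = 0,
                 min_clone_size: int = 2) -> np.ndarray:
    """Null distribution of the consistent-clone fraction under label shuffling.

    XCI labels are permuted across all cells without replacement and
    consistency recomputed; returns the per-permutation fraction of clones
    (with >= min_clone_size assigned cells) that are unanimous.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    labels = _labels_series(xci)
    rng = np.random.default_rng(seed)
    values = labels.to_numpy(dtype=object)
    index = labels.index

    clone_member_pos: list[np.ndarray] = []
    for clone in clones.clone_ids:
        pos = index.get_indexer(clones.members(clone))
        clone_member_pos.append(pos[pos >= 0])

    fractions = np.empty(n_perm)
    for b in range(n_perm):
        perm = values[rng.permutation(len(values))]
        n_eval = 0
        n_consistent = 0
        for pos in clone_member_pos:
            mlab = perm[pos]
            mlab = mlab[mlab != UNASSIGNED]
            if len(mlab) < min_clone_size:
                continue
            n_eval += 1
            n_consistent += int(all(l == mlab[0] for l in mlab))
        fractions[b] = n_consistent / n_eval if n_eval else np.nan
    return fractions


def mutation_burden(carriers: pd.DataFrame, meta: CellMetadata) -> pd.DataFrame:
    """Fraction of cells per cell type with >= 1 clonal-mutation carrier flag.

    ``carriers`` is a long table with at least columns ``variant`` and
    ``cell`` (one row per carrier call, PASS variants only). Cell types
    come from ``meta``; cells with unknown type fall under the sentinel
    label. Returns per-type ``n_cells``, ``n_mutated``, ``fraction``.
    """
    types = meta.table["cell_type"]
    mutated = set(carriers["cell"]) if len(carriers) else set()
    rows = []
    for ctype, group in types.groupby(types):
        cells = set(group.index)
        n_mut = len(cells & mutated)
        rows.append({"cell_type": ctype, "n_cells": len(cells),
                     "n_mutated": n_mut, "fraction": n_mut / len(cells)})
    # carriers whose cells are absent from the metadata
    orphan = mutated - set(types.index)
    if orphan:
        rows.append({"cell_type": UNKNOWN_LABEL, "n_cells": len(orphan),
                     "n_mutated": len(orphan), "fraction": 1.0})
    return pd.DataFrame(rows).set_index("cell_type")


def fate_coupling(carriers: pd.DataFrame, meta: CellMetadata, min_cells: int = 2,
                  max_cells: int | None = None,
                  weight: str = "count") -> pd.DataFrame:
    """Cell-type fate-coupling matrix from clonal-mutation carrier profiles.

    Variants are filtered to those carried by more than ``min_cells - 1``
    and (when given) fewer than ``max_cells`` cells (strict bounds). A
    variants × cell-types matrix of carrier counts (or per-type carrier
    fractions with ``weight="fraction"``) is built, and the coupling of two
    types is the Pearson correlation of their columns over the variant
    axis — covariance normalized by the per-type standard deviations.
    Diagonal is 1 wherever defined; zero-variance types yield NaN rows and
    columns.
    """
    if weight not in ("count", "fraction"):
        raise ValueError("weight must be 'count' or 'fraction'")
    types = meta.table["cell_type"]
    type_names = sorted(types.unique())
    df = carriers.copy()
    df["cell_type"] = df["cell"].map(types).fillna(UNKNOWN_LABEL)

    sizes = df.groupby("variant")["cell"].nunique()
    keep = sizes.index[sizes > (min_cells - 1)]
    if max_cells is not None:
        keep = keep.intersection(sizes.index[sizes < max_cells])
    df = df[df["variant"].isin(keep)]

    M = (df.groupby(["variant", "cell_type"]).size().unstack(fill_value=0)
         .reindex(columns=type_names, fill_value=0))
    if weight == "fraction":
        totals = types.value_counts().reindex(type_names).astype(float)
        M = M.divide(totals, axis=1)

    vals = M.to_numpy(dtype=float)
    std = vals.std(axis=0, ddof=1) if len(M) > 1 else np.zeros(vals.shape[1])
    coupling = pd.DataFrame(np.nan, index=type_names, columns=type_names)
    ok = std > 0
    if ok.any() and len(M) > 1:
        sub = np.corrcoef(vals[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        ok_names = [t for t, o in zip(type_names, ok) if o]
        coupling.loc[ok_names, ok_names] = sub
    for t, o in zip(type_names, ok):
        coupling.loc[t, t] = 1.0 if o else np.nan
    return coupling
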