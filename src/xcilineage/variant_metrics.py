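"""Per-variant quality statistics for mitochondrial variant nomination.

Genuine heteroplasmic variants show dispersed per-cell allele fractions
(variance-mean ratio, VMR) and balanced support on both sequencing strands
(strand correlation across cells); strand-specific artefacts do not. The
pre-filter keeps variants with VMR > 0.01 and strand correlation > 0.65
(strict inequalities). Statistics that cannot be computed (no covered
cells, a zero-variance strand) are NaN sentinels and always fail the
filter.

Conventions (configurable upstream of the thresholds): VMR is computed on
per-cell heteroplasmy (allele fractions) over cells with coverage >= 1,
with the unbiased (ddof=1) variance; strand correlation is Pearson on raw
per-strand variant-supporting read counts over cells with at least one
supporting read on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datamodel_io import StrandCountTensor, variant_name

__all__ = [
    "HeteroplasmyResult",
    "heteroplasmy_matrix",
    "variance_mean_ratio",
    "strand_correlation",
    "variant_stats",
    "quality_filter",
]


@dataclass
class HeteroplasmyResult:
    """Cells × variants allele fractions with the underlying k/n counts."""

    af: pd.DataFrame  # NaN where the cell has no coverage at the position
    k: pd.DataFrame   # variant-supporting reads (both strands)
    n: pd.DataFrame   # position coverage

    @property
    def variant_ids(self) -> list[str]:
        return list(self.af.columns)


def heteroplasmy_matrix(t: StrandCountTensor,
                        variants: list[tuple[int, str, str]] | None = None
                        ) -> HeteroplasmyResult:
    """Per-cell heteroplasmy for every candidate variant in the tensor.

    For variant (pos, ref, alt): k = alt-base reads at pos summed over
    strands, n = total coverage at pos, AF = k/n where n > 0 (NaN
    otherwise). ``alt == ref`` is rejected.
    """
    if variants is None:
        variants = t.variants(min_total=1)
    names, k_cols, n_cols, af_cols = [], [], [], []
    for pos, ref, alt in variants:
        if alt == ref:
            raise ValueError(f"alt equals reference base at position {pos}")
        if ref != t.ref_of(pos):
            raise ValueError(f"reference base mismatch at position {pos}")
        k = t.base_counts(pos, alt).astype(float)
        n = t.position_coverage(pos).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = np.where(n > 0, k / np.where(n > 0, n, 1.0), np.nan)
        names.append(variant_name(pos, ref, alt))
        k_cols.append(k)
        n_cols.append(n)
        af_cols.append(af)
    idx = pd.Index(t.cells, name="cell")
    return HeteroplasmyResult(
        af=pd.DataFrame(dict(zip(names, af_cols)), index=idx),
        k=pd.DataFrame(dict(zip(names, k_cols)), index=idx),
        n=pd.DataFrame(dict(zip(names, n_cols)), index=idx),
    )


def variance_mean_ratio(af: pd.Series | np.ndarray, n: pd.Series | np.ndarray,
                        min_coverage: int = 1) -> float:
    """VMR = var(AF) / mean(AF) over cells with coverage >= min_coverage.

    Unbiased (ddof=1) variance. Returns 0.0 when the mean is 0 and NaN when
    fewer than two cells qualify.
    """
    af = np.asarray(af, dtype=float)
    n = np.asarray(n, dtype=float)
    use = (n >= min_coverage) & np.isfinite(af)
    if use.sum() < 2:
        return float("nan")
    x = af[use]
    mean = x.mean()
    if mean == 0.0:
        return 0.0
    return float(x.var(ddof=1) / mean)


def strand_correlation(t: StrandCountTensor, variant: tuple[int, str, str]) -> float:
    """Pearson correlation of plus- vs minus-strand variant support across cells.

    Computed over cells with >= 1 supporting read on either strand; NaN when
    fewer than 3 such cells or when either strand has zero variance.
    """
    pos, ref, alt = variant
    if alt == ref:
        raise ValueError(f"alt equals reference base at position {pos}")
    plus = t.base_counts(pos, alt, "+").astype(float)
    minus = t.base_counts(pos, alt, "-").astype(float)
    use = (plus + minus) >= 1
    if use.sum() < 3:
        return float("nan")
    p, m = plus[use], minus[use]
    if p.std() == 0 or m.std() == 0:
        return float("nan")
    return float(pearsonr(p, m).statistic)


def variant_stats(t: StrandCountTensor, min_coverage: int = 1,
                  variants: list[tuple[int, str, str]] | None = None) -> pd.DataFrame:
    """Quality statistics for every candidate variant.

    Columns: ``variant``, ``pos``, ``ref``, ``alt``, ``mean_coverage``
    (reads/cell at the position), ``vmr``, ``strand_correlation``,
    ``n_cells`` (cells with >= 1 supporting read).
    """
    if variants is None:
        variants = t.variants(min_total=1)
    het = heteroplasmy_matrix(t, variants)
    rows = []
    for (pos, ref, alt), vid in zip(variants, het.variant_ids):
        k = het.k[vid].to_numpy()
        n = het.n[vid].to_numpy()
        rows.append({
            "variant": vid,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "mean_coverage": float(n.mean()),
            "vmr": variance_mean_ratio(het.af[vid], n, min_coverage),
            "strand_correlation": strand_correlation(t, (pos, ref, alt)),
            "n_cells": int((k >= 1).sum()),
        })
    return pd.DataFrame(rows).set_index("variant")


def quality_filter(stats: pd.DataFrame, vmr_min: float = 0.01,
                   strand_min: float = 0.65) -> list[str]:
    """Variant ids with VMR > vmr_min AND strand correlation > strand_min.

    Strict inequalities; NaN statistics fail.
    """
    keep = (stats["vmr"] > vmr_min) & (stats["strand_correlation"] > strand_min)
    return list(stats.index[keep.fillna(False)])
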