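"""Glue running the whole selection workflow on in-memory objects.

Thin orchestration only — every statistic lives in its own module. The CLI
and the end-to-end tests both call these helpers, so the command-line and
library routes cannot drift apart.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clonal_selection import (SelectionResult, SelectionThresholds, Verdict,
                               select_by_xci)
from .datamodel_io import StrandCountTensor
from .variant_metrics import heteroplasmy_matrix, quality_filter, variant_stats
from .xci_deconv import XCIAssignment

__all__ = ["run_selection", "selection_table", "carrier_table"]


def run_selection(tensor: StrandCountTensor, xci: XCIAssignment | pd.Series,
                  thresholds: SelectionThresholds | None = None, *,
                  vmr_min: float = 0.01, strand_min: float = 0.65,
                  call_all_cells: bool = False,
                  seed: int | None = None):
    """Quality-filter candidate variants, then apply the XCI-split selection.

    Returns ``(stats, results)``: the per-variant quality statistics and a
    dict variant id -> :class:`SelectionResult` for quality-passing
    variants. XCI labels are aligned to the tensor's cells by barcode;
    cells missing from the assignment count as unassigned.
    """
    thresholds = thresholds or SelectionThresholds()
    labels = xci.label_of() if isinstance(xci, XCIAssignment) else xci
    labels = labels.reindex(tensor.cells).fillna("unassigned").to_numpy(dtype=object)

    variants = tensor.variants(min_total=1)
    stats = variant_stats(tensor, variants=variants)
    kept = set(quality_filter(stats, vmr_min=vmr_min, strand_min=strand_min))
    het = heteroplasmy_matrix(tensor, variants)

    results: dict[str, SelectionResult] = {}
    for (pos, ref, alt), vid in zip(variants, het.variant_ids):
        if vid not in kept:
            continue
        results[vid] = select_by_xci(
            het.k[vid].to_numpy(), het.n[vid].to_numpy(), labels,
            thresholds, seed=seed, call_all_cells=call_all_cells)
    return stats, results


def selection_table(results: dict[str, SelectionResult]) -> pd.DataFrame:
    """Per-variant summary: verdict, per-allele clonal heteroplasmy, logit gap."""
    rows = []
    for vid, res in results.items():
        row = {"variant": vid, "verdict": res.verdict.value,
               "passing_allele": res.passing_allele,
               "logit_diff": res.logit_diff}
        for allele in ("allele1", "allele2"):
            fit = res.fits.get(allele)
            row[f"theta1_{allele}"] = fit.effective_theta1 if fit else np.nan
            row[f"pi1_{allele}"] = fit.pi1 if fit else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


def carrier_table(results: dict[str, SelectionResult],
                  cells: list[str]) -> pd.DataFrame:
    """Long table of carrier calls (PASS variants only).

    Columns: ``variant``, ``cell``, ``posterior``, ``p_value``.
    """
    rows = []
    for vid, res in results.items():
        if res.verdict is not Verdict.PASS or res.carrier is None:
            continue
        for i in np.flatnonzero(res.carrier):
            rows.append({"variant": vid, "cell": cells[i],
                         "posterior": res.posterior[i],
                         "p_value": res.pvalue[i]})
    return pd.DataFrame(rows, columns=["variant", "cell", "posterior", "p_value"])
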