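"""Synthetic data generation and sensitivity assessment.

Two layers:

* *Per-variant count simulations* (:func:`simulate_variant`,
  :func:`sensitivity_grid`): plant a clonal mutation inside one active-X
  group and measure how often the XCI-split mixture criterion (absolute
  logit gap of the two groups' clonal heteroplasmies above 1.22) detects
  it, across grids of XCI ratio, heteroplasmy, clonal fraction and read
  coverage. An exact Neyman-Pearson power calculation
  (:func:`exact_lrt_power`) characterises the per-cell likelihood-ratio
  call without sampling.

* *Full dataset fixtures* (:func:`simulate_dataset`): an end-to-end bundle
  with planted XCI haplotypes (X-linked allelic counts), planted clones
  nested inside XCI groups, and mitochondrial variants of three classes —
  clonal (carriers confined to one clone, hence one active-X background),
  pre-XCI (carriers spanning both XCI groups) and strand artefacts (all
  variant support on one strand). Every truth fact is recorded so tests
  can compare pipeline output against the generative bookkeeping.

Dataset fixtures draw each carrier's heteroplasmy from a Beta distribution
around the nominal level: with a constant level and Poisson coverage the
plus/minus strand counts would be independent Poisson thinnings and
genuine variants would show no strand correlation; cell-to-cell
heteroplasmy dispersion is both biologically expected and what the
strand-correlation filter exploits. Per-variant simulations keep the level
constant (k ~ Binomial(n, h)), matching the detection-power question they
answer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binom

from .clonal_selection import (MixtureFit, SelectionThresholds,
                               fit_binomial_mixture, logit, lrt_pvalue)
from .datamodel_io import (AllelicCountMatrix, BASES, CellMetadata, CloneTable,
                           StrandCountTensor, variant_name, write_cellsnp,
                           write_strand_counts)

__all__ = [
    "SimulationSpec",
    "simulate_variant",
    "detection_event",
    "sensitivity_grid",
    "exact_lrt_power",
    "DatasetConfig",
    "FixtureBundle",
    "simulate_dataset",
]


@dataclass
class SimulationSpec:
    """Conditions for one per-variant detection simulation.

    Ranges mirror realistic single-cell mutation-discovery scenarios:
    XCI ratio 0.1-0.9, heteroplasmy 0.01-0.99, clonal fraction 0.001-0.1,
    coverage 10-500 reads over the variant site per cell.
    """

    xci_ratio: float = 0.5
    heteroplasmy: float = 0.04
    clonal_fraction: float = 0.05
    coverage: int = 100
    n_cells: int = 1000
    error_theta: float = 0.01
    coverage_law: str = "fixed"  # "fixed" | "poisson"

    def __post_init__(self) -> None:
        checks = [
            ("xci_ratio", self.xci_ratio, 0.1, 0.9),
            ("heteroplasmy", self.heteroplasmy, 0.01, 0.99),
            ("clonal_fraction", self.clonal_fraction, 0.001, 0.1),
            ("coverage", self.coverage, 10, 500),
        ]
        for name, v, lo, hi in checks:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.coverage_law not in ("fixed", "poisson"):
            raise ValueError("coverage_law must be 'fixed' or 'poisson'")


def simulate_variant(spec: SimulationSpec, seed: int | np.random.Generator = 0):
    """Simulate per-cell counts for one planted clonal variant.

    XCI labels are Bernoulli(xci_ratio); the carriers are a fraction
    ``clonal_fraction`` of all cells, drawn entirely from one XCI group
    (chosen uniformly) because clonality implies a shared active X.
    Carriers have k ~ Binomial(n, heteroplasmy), all other cells
    k ~ Binomial(n, error_theta).

    Returns ``(k, n, xci_labels, carrier)`` arrays; ``xci_labels`` holds
    "allele1"/"allele2".
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = spec.n_cells
    group1 = rng.random(S) < spec.xci_ratio
    labels = np.where(group1, "allele1", "allele2").astype(object)

    n_carriers = int(round(spec.clonal_fraction * S))
    if n_carriers < 1:
        warnings.warn("clonal_fraction * n_cells < 1; forcing a single carrier")
        n_carriers = 1
    carrier_group = bool(rng.random() < 0.5)
    members = np.flatnonzero(group1 == carrier_group)
    if len(members) == 0:  # degenerate draw; use the other group
        members = np.flatnonzero(group1 != carrier_group)
    n_carriers = min(n_carriers, len(members))
    carriers_idx = rng.choice(members, size=n_carriers, replace=False)
    carrier = np.zeros(S, dtype=bool)
    carrier[carriers_idx] = True

    if spec.coverage_law == "poisson":
        n = rng.poisson(spec.coverage, size=S)
    else:
        n = np.full(S, spec.coverage, dtype=int)
    theta = np.where(carrier, spec.heteroplasmy, spec.error_theta)
    k = rng.binomial(n, theta)
    return k, n, labels, carrier


def detection_event(fit_allele1: MixtureFit, fit_allele2: MixtureFit,
                    logit_diff_min: float = 1.22) -> bool:
    """Detection = absolute logit gap of the groups' clonal heteroplasmies > cutoff.

    Uses each group's effective (parsimony-checked) clonal heteroplasmy; a
    non-converged fit is never a detection.
    """
    if not (fit_allele1.converged and fit_allele2.converged):
        return False
    gap = abs(logit(fit_allele1.effective_theta1) - logit(fit_allele2.effective_theta1))
    return bool(gap > logit_diff_min)


def _detect_once(spec: SimulationSpec, rng: np.random.Generator,
                 logit_diff_min: float) -> bool:
    k, n, labels, _ = simulate_variant(spec, rng)
    fits = []
    for allele in ("allele1", "allele2"):
        mask = (labels == allele) & (n > 0)
        if mask.sum() < 2:
            return False
        fits.append(fit_binomial_mixture(k[mask], n[mask]))
    return detection_event(fits[0], fits[1], logit_diff_min)


def sensitivity_grid(specs: list[SimulationSpec], reps: int = 200, seed: int = 0,
                     logit_diff_min: float = 1.22) -> pd.DataFrame:
    """Detection rate (with Wilson 95% CI) at each grid point.

    One row per spec: the simulation conditions, the number of detections
    over ``reps`` replicates, the detection rate and its Wilson interval.
    """
    from statsmodels.stats.proportion import proportion_confint

    rows = []
    for i, spec in enumerate(specs):
        rng = np.random.default_rng([seed, i])
        hits = sum(_detect_once(spec, rng, logit_diff_min) for _ in range(reps))
        lo, hi = proportion_confint(hits, reps, alpha=0.05, method="wilson")
        rows.append({
            "xci_ratio": spec.xci_ratio,
            "heteroplasmy": spec.heteroplasmy,
            "clonal_fraction": spec.clonal_fraction,
            "coverage": spec.coverage,
            "n_cells": spec.n_cells,
            "error_theta": spec.error_theta,
            "reps": reps,
            "detections": hits,
            "detection_rate": hits / reps,
            "ci_low": float(lo),
            "ci_high": float(hi),
        })
    return pd.DataFrame(rows)


def exact_lrt_power(n: int, theta_true: float, theta0: float = 0.01,
                    theta1: float = 0.1, alpha: float = 0.05):
    """Exact power and achieved size of the per-cell likelihood-ratio call.

    Enumerates k = 0..n; the rejection region is every k whose LRT p-value
    (null theta0 vs alternative theta1) falls below ``alpha``. Power is the
    rejection probability under Binomial(n, theta_true), achieved size the
    same under Binomial(n, theta0). Exact — no sampling. By the
    Neyman-Pearson lemma this likelihood-ratio region is the most powerful
    test of its size for the simple null vs simple alternative.
    """
    if n > 10_000:
        raise ValueError("n too large for exact enumeration")
    ks = np.arange(n + 1)
    pvals = lrt_pvalue(ks, np.full(n + 1, n), theta0, theta1)
    # the statistic clamp puts an atom at p = 1; a size-1 test rejects it too
    reject = pvals < alpha if alpha < 1.0 else np.ones(n + 1, dtype=bool)
    power = float(binom.pmf(ks[reject], n, theta_true).sum())
    size = float(binom.pmf(ks[reject], n, theta0).sum())
    return power, size


# ---------------------------------------------------------------------------
# Full dataset fixtures
# ---------------------------------------------------------------------------


@dataclass
class DatasetConfig:
    """Configuration of a full synthetic dataset.

    X-linked layer: ``n_x_sites`` heterozygous SNPs; a cell expresses the
    ALT allele of a site with probability ``x_alt_expression`` when its
    active haplotype carries ALT there and ``1 - x_alt_expression``
    otherwise; per-cell-site depth is Poisson(``x_depth_mean``).

    Mitochondrial layer: each variant sits at its own position with
    coverage Poisson(``mito_coverage``); carriers of genuine variants draw
    a per-cell heteroplasmy from Beta with mean ``heteroplasmy`` and
    concentration ``het_concentration``; variant reads split evenly across
    strands (artefact variants place all support on the plus strand).

    Clones: ``clone_sizes`` cells each, nested inside one XCI group; one
    clonal variant marks one clone.
    """

    n_cells: int = 500
    xci_ratio: float = 0.5
    n_x_sites: int = 150
    x_depth_mean: float = 3.0
    x_alt_expression: float = 0.95
    n_clonal: int = 10
    n_pre_xci: int = 5
    n_artefact: int = 5
    clone_sizes: tuple[int, ...] | None = None  # default: 25 cells per clonal variant
    pre_xci_fraction: float = 0.3
    heteroplasmy: float = 0.2
    het_concentration: float = 10.0
    error_theta: float = 0.01
    mito_coverage: float = 100.0
    cell_types: tuple[str, ...] = ("T cell", "B cell", "NK cell")
    donor: str = "donor_synth"

    def resolved_clone_sizes(self) -> list[int]:
        if self.clone_sizes is not None:
            return list(self.clone_sizes)
        return [25] * self.n_clonal


@dataclass
class FixtureBundle:
    """A complete synthetic dataset with generative truth tables."""

    acm: AllelicCountMatrix
    tensor: StrandCountTensor
    clones: CloneTable
    metadata: CellMetadata
    truth_xci: pd.Series            # barcode -> "allele1"/"allele2"
    truth_variants: pd.DataFrame    # variant, class, position, ref, alt
    truth_carriers: dict[str, list[str]]  # variant id -> carrier barcodes

    def write(self, directory) -> None:
        """Serialise everything through the canonical on-disk formats."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_cellsnp(self.acm, directory / "cellsnp")
        write_strand_counts(self.tensor, directory / "strand_counts.tsv")
        self.clones.assignments.rename("clone").rename_axis("cell").reset_index() \
            .to_csv(directory / "clones.tsv", sep="\t", index=False)
        self.metadata.table.rename_axis("cell").reset_index() \
            .to_csv(directory / "metadata.tsv", sep="\t", index=False)
        self.truth_xci.rename("xci").rename_axis("cell").reset_index() \
            .to_csv(directory / "truth_xci.tsv", sep="\t", index=False)
        self.truth_variants.to_csv(directory / "truth_variants.tsv",
                                   sep="\t", index=False)
        rows = [(v, c) for v, cells in sorted(self.truth_carriers.items())
                for c in cells]
        pd.DataFrame(rows, columns=["variant", "cell"]) \
            .to_csv(directory / "truth_carriers.tsv", sep="\t", index=False)


def _simulate_x_layer(cfg: DatasetConfig, truth_state: np.ndarray,
                      barcodes: list[str], rng: np.random.Generator
                      ) -> AllelicCountMatrix:
    # which haplotype carries ALT at each site is itself random
    alt_on_hap1 = rng.random(cfg.n_x_sites) < 0.5
    mu = np.empty((2, cfg.n_x_sites))
    mu[0] = np.where(alt_on_hap1, cfg.x_alt_expression, 1 - cfg.x_alt_expression)
    mu[1] = 1.0 - mu[0]
    dp = rng.poisson(cfg.x_depth_mean, size=(cfg.n_cells, cfg.n_x_sites))
    ad = rng.binomial(dp, mu[truth_state])
    sites = pd.DataFrame({
        "chrom": "chrX",
        "pos": np.sort(rng.choice(np.arange(1_000_000, 150_000_000), size=cfg.n_x_sites,
                                  replace=False)),
        "ref": [BASES[i] for i in rng.integers(0, 4, cfg.n_x_sites)],
    })
    sites["alt"] = [BASES[(BASES.index(r) + int(o)) % 4]
                    for r, o in zip(sites["ref"], rng.integers(1, 4, cfg.n_x_sites))]
    return AllelicCountMatrix(cells=barcodes, sites=sites,
                              ad=sp.csr_matrix(ad), dp=sp.csr_matrix(dp))


def simulate_dataset(cfg: DatasetConfig, seed: int = 0) -> FixtureBundle:
    """Generate a full fixture with planted XCI states, clones and variants.

    Deterministic given ``seed``: the same seed yields byte-identical files
    from :meth:`FixtureBundle.write`.
    """
    rng = np.random.default_rng(seed)
    S = cfg.n_cells
    barcodes = [f"cell{i:05d}" for i in range(S)]
    truth_state = (rng.random(S) < (1 - cfg.xci_ratio)).astype(int)  # 0=allele1
    truth_labels = np.where(truth_state == 0, "allele1", "allele2").astype(object)

    clone_sizes = cfg.resolved_clone_sizes()
    if len(clone_sizes) != cfg.n_clonal:
        raise ValueError("clone_sizes must have one entry per clonal variant")

    # clones nested inside XCI groups, disjoint
    free = {0: list(np.flatnonzero(truth_state == 0)),
            1: list(np.flatnonzero(truth_state == 1))}
    for g in free:
        rng.shuffle(free[g])
    clone_of: dict[str, str] = {}
    clone_members: list[list[int]] = []
    for ci, size in enumerate(clone_sizes):
        g = int(rng.integers(0, 2))
        if len(free[g]) < size:
            g = 1 - g
        if len(free[g]) < size:
            raise ValueError(f"clone of size {size} larger than remaining XCI group")
        members = [free[g].pop() for _ in range(size)]
        clone_members.append(members)
        for m in members:
            clone_of[barcodes[m]] = f"clone{ci + 1}"

    # mitochondrial variant positions, refs, alts
    n_var = cfg.n_clonal + cfg.n_pre_xci + cfg.n_artefact
    positions = np.sort(rng.choice(np.arange(1, 16_570), size=n_var, replace=False))
    refs = [BASES[i] for i in rng.integers(0, 4, n_var)]
    alts = [BASES[(BASES.index(r) + int(o)) % 4]
            for r, o in zip(refs, rng.integers(1, 4, n_var))]
    classes = (["clonal"] * cfg.n_clonal + ["pre_xci"] * cfg.n_pre_xci
               + ["artefact"] * cfg.n_artefact)

    a = cfg.heteroplasmy * cfg.het_concentration
    b = (1 - cfg.heteroplasmy) * cfg.het_concentration

    shape = (n_var, S)
    layers = {(bse, s): np.zeros(shape, dtype=np.int64) for bse in BASES for s in "+-"}
    truth_carriers: dict[str, list[str]] = {}
    var_rows = []
    clonal_i = 0
    for vi in range(n_var):
        pos, ref, alt, klass = int(positions[vi]), refs[vi], alts[vi], classes[vi]
        vid = variant_name(pos, ref, alt)
        cov = rng.poisson(cfg.mito_coverage, size=S)
        carrier = np.zeros(S, dtype=bool)
        if klass == "clonal":
            carrier[clone_members[clonal_i]] = True
            clonal_i += 1
        elif klass == "pre_xci":
            # carriers span both XCI groups (mutation predates inactivation)
            carrier = rng.random(S) < cfg.pre_xci_fraction
            for g in (0, 1):  # guarantee representation in both groups
                grp = np.flatnonzero(truth_state == g)
                if not carrier[grp].any():
                    carrier[rng.choice(grp)] = True
        else:  # artefact: support concentrated in a random cell subset
            carrier = rng.random(S) < 0.1
        h = np.where(carrier, rng.beta(a, b, size=S), cfg.error_theta)
        k = rng.binomial(cov, h)
        k = np.minimum(k, cov)
        if klass == "artefact":
            plus_k = k  # all variant support on one strand
        else:
            plus_k = rng.binomial(k, 0.5)
        minus_k = k - plus_k
        ref_reads = cov - k
        plus_ref = rng.binomial(ref_reads, 0.5)
        layers[(alt, "+")][vi] += plus_k
        layers[(alt, "-")][vi] += minus_k
        layers[(ref, "+")][vi] += plus_ref
        layers[(ref, "-")][vi] += ref_reads - plus_ref
        truth_carriers[vid] = [barcodes[i] for i in np.flatnonzero(carrier)]
        var_rows.append({"variant": vid, "class": klass, "position": pos,
                         "ref": ref, "alt": alt})

    tensor = StrandCountTensor(
        positions=positions,
        cells=barcodes,
        refbase=np.array(refs, dtype=object),
        counts={key: sp.csr_matrix(m) for key, m in layers.items()},
    )
    acm = _simulate_x_layer(cfg, truth_state, barcodes, rng)

    types = np.array(cfg.cell_types, dtype=object)[
        rng.integers(0, len(cfg.cell_types), S)]
    metadata = CellMetadata(table=pd.DataFrame(
        {"cell_type": types, "donor": cfg.donor}, index=pd.Index(barcodes, name="cell")))
    clones = CloneTable(assignments=pd.Series(clone_of, dtype=object))

    return FixtureBundle(
        acm=acm,
        tensor=tensor,
        clones=clones,
        metadata=metadata,
        truth_xci=pd.Series(truth_labels, index=pd.Index(barcodes, name="cell")),
        truth_variants=pd.DataFrame(var_rows),
        truth_carriers=truth_carriers,
    )
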