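"""Data containers and readers/writers for the formats used across the package.

The canonical in-memory objects are:

* :class:`AllelicCountMatrix` — per-cell ALT/total read depths at X-linked
  heterozygous SNPs, as produced by cellSNP-lite (sites VCF + sparse
  MatrixMarket AD/DP matrices + barcode list).
* :class:`StrandCountTensor` — per mitochondrial position × base × strand ×
  cell read counts, ingested from a documented long-format TSV dialect
  (mgatk-style counts re-expressed; see :func:`read_strand_counts`).
* :class:`CloneTable` / :class:`CellMetadata` — thin tables mapping cell
  barcodes to clone ids (e.g. from TCR/BCR clonotyping) and to cell-type /
  donor labels.

All counts are non-negative integers; cell barcodes are opaque strings (no
10x suffix normalisation). Multi-allelic VCF records are split into one site
per ALT allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "AllelicCountMatrix",
    "StrandCountTensor",
    "CloneTable",
    "CellMetadata",
    "read_cellsnp",
    "write_cellsnp",
    "read_strand_counts",
    "write_strand_counts",
    "count_het_x_variants",
    "read_clone_table",
    "read_cell_metadata",
    "variant_name",
]

BASES = ("A", "C", "G", "T")
STRANDS = ("+", "-")
#: chromosome names accepted as the X chromosome
X_CHROM_NAMES = frozenset({"X", "chrX", "x", "chrx"})


def variant_name(pos: int, ref: str, alt: str) -> str:
    """Mitochondrial variant identifier, e.g. ``2860G > A``."""
    return f"{pos}{ref} > {alt}"


# ---------------------------------------------------------------------------
# AllelicCountMatrix
# ---------------------------------------------------------------------------


@dataclass
class AllelicCountMatrix:
    """Cells × sites ALT-depth (``ad``) and total-depth (``dp``) counts.

    Parameters
    ----------
    cells
        Ordered cell barcodes (rows).
    sites
        DataFrame with columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``,
        one row per site (columns of ``ad``/``dp``).
    ad, dp
        Sparse cells × sites integer matrices with ``ad <= dp`` elementwise.
    """

    cells: list[str]
    sites: pd.DataFrame
    ad: sp.csr_matrix
    dp: sp.csr_matrix

    def __post_init__(self) -> None:
        self.ad = sp.csr_matrix(self.ad)
        self.dp = sp.csr_matrix(self.dp)
        n_cells, n_sites = len(self.cells), len(self.sites)
        if self.ad.shape != (n_cells, n_sites) or self.dp.shape != (n_cells, n_sites):
            raise ValueError(
                f"shape mismatch: ad {self.ad.shape}, dp {self.dp.shape}, "
                f"registries {(n_cells, n_sites)}"
            )
        excess = (self.ad - self.dp).tocoo()
        bad = excess.data > 0
        if bad.any():
            c, s = excess.row[bad][0], excess.col[bad][0]
            raise ValueError(
                f"ad > dp at cell {self.cells[c]!r}, site index {s} "
                f"({self.sites.iloc[s]['chrom']}:{self.sites.iloc[s]['pos']})"
            )
        if (self.ad.data < 0).any() or (self.dp.data < 0).any():
            raise ValueError("negative counts are not allowed")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def observed_variant_counts(self) -> np.ndarray:
        """Per-cell number of sites with any coverage (dp >= 1)."""
        return np.asarray((self.dp > 0).sum(axis=1)).ravel()

    def restrict_to_x(self) -> "AllelicCountMatrix":
        """Subset to sites on the X chromosome."""
        keep = self.sites["chrom"].isin(X_CHROM_NAMES).to_numpy()
        return self.subset_sites(np.flatnonzero(keep))

    def subset_sites(self, idx: np.ndarray) -> "AllelicCountMatrix":
        idx = np.asarray(idx)
        return AllelicCountMatrix(
            cells=list(self.cells),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            ad=self.ad[:, idx],
            dp=self.dp[:, idx],
        )

    def subset_cells(self, idx: np.ndarray) -> "AllelicCountMatrix":
        idx = np.asarray(idx)
        return AllelicCountMatrix(
            cells=[self.cells[i] for i in idx],
            sites=self.sites.copy(),
            ad=self.ad[idx, :],
            dp=self.dp[idx, :],
        )


_CELLSNP_VCF = "cellSNP.base.vcf"
_CELLSNP_AD = "cellSNP.tag.AD.mtx"
_CELLSNP_DP = "cellSNP.tag.DP.mtx"
_CELLSNP_SAMPLES = "cellSNP.samples.tsv"


def _read_sites_vcf(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        alts = rec.ALT if rec.ALT else ["."]
        for alt in alts:  # multi-allelic records: one site per ALT
            rows.append((rec.CHROM, rec.POS, rec.REF, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def read_cellsnp(directory: str | Path, x_only: bool = False) -> AllelicCountMatrix:
    """Read a cellSNP-lite output directory into an :class:`AllelicCountMatrix`.

    Expects ``cellSNP.base.vcf`` (sites), ``cellSNP.tag.AD.mtx`` /
    ``cellSNP.tag.DP.mtx`` (sites × cells MatrixMarket, transposed on read)
    and ``cellSNP.samples.tsv`` (one barcode per line). Row/column order is
    preserved from the inputs.
    """
    directory = Path(directory)
    paths = {name: directory / name for name in
             (_CELLSNP_VCF, _CELLSNP_AD, _CELLSNP_DP, _CELLSNP_SAMPLES)}
    for name, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing cellSNP file: {p}")
    sites = _read_sites_vcf(paths[_CELLSNP_VCF])
    ad = sp.csr_matrix(mmread(paths[_CELLSNP_AD]).T)
    dp = sp.csr_matrix(mmread(paths[_CELLSNP_DP]).T)
    cells = paths[_CELLSNP_SAMPLES].read_text().split()
    acm = AllelicCountMatrix(cells=cells, sites=sites, ad=ad, dp=dp)
    return acm.restrict_to_x() if x_only else acm


def write_cellsnp(acm: AllelicCountMatrix, directory: str | Path) -> None:
    """Write an :class:`AllelicCountMatrix` in cellSNP-lite layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [
        "##fileformat=VCFv4.2",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for _, r in acm.sites.iterrows():
        lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.")
    (directory / _CELLSNP_VCF).write_text("\n".join(lines) + "\n")
    mmwrite(directory / _CELLSNP_AD, sp.coo_matrix(acm.ad.T))
    mmwrite(directory / _CELLSNP_DP, sp.coo_matrix(acm.dp.T))
    (directory / _CELLSNP_SAMPLES).write_text("\n".join(acm.cells) + "\n")


# ---------------------------------------------------------------------------
# StrandCountTensor
# ---------------------------------------------------------------------------


@dataclass
class StrandCountTensor:
    """Per-position, per-base, per-strand, per-cell mitochondrial read counts.

    ``counts[(base, strand)]`` is a sparse positions × cells matrix; per-cell
    per-position coverage is the sum over all eight (base, strand) layers.
    """

    positions: np.ndarray  # 1-based, sorted
    cells: list[str]
    refbase: np.ndarray  # reference base per position, aligned to positions
    counts: dict[tuple[str, str], sp.csr_matrix] = field(repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.refbase = np.asarray(self.refbase, dtype=object)
        shape = (len(self.positions), len(self.cells))
        full = {}
        for b in BASES:
            for s in STRANDS:
                m = self.counts.get((b, s))
                m = sp.csr_matrix(shape, dtype=np.int64) if m is None else sp.csr_matrix(m)
                if m.shape != shape:
                    raise ValueError(f"layer {(b, s)} has shape {m.shape}, expected {shape}")
                if (m.data < 0).any():
                    raise ValueError("negative counts are not allowed")
                full[(b, s)] = m
        self.counts = full
        self._pos_index = {p: i for i, p in enumerate(self.positions)}

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def coverage(self) -> sp.csr_matrix:
        """Positions × cells total coverage (sum over bases and strands)."""
        total = sp.csr_matrix((len(self.positions), self.n_cells), dtype=np.int64)
        for m in self.counts.values():
            total = total + m
        return total

    def total_reads(self) -> int:
        return int(sum(m.sum() for m in self.counts.values()))

    def ref_of(self, pos: int) -> str:
        return str(self.refbase[self._pos_index[pos]])

    def base_counts(self, pos: int, base: str, strand: str | None = None) -> np.ndarray:
        """Per-cell counts of ``base`` at ``pos`` (one strand or both)."""
        i = self._pos_index[pos]
        strands = STRANDS if strand is None else (strand,)
        out = np.zeros(self.n_cells, dtype=np.int64)
        for s in strands:
            out += np.asarray(self.counts[(base, s)][i].todense()).ravel()
        return out

    def position_coverage(self, pos: int) -> np.ndarray:
        i = self._pos_index[pos]
        out = np.zeros(self.n_cells, dtype=np.int64)
        for m in self.counts.values():
            out += np.asarray(m[i].todense()).ravel()
        return out

    def variants(self, min_total: int = 1) -> list[tuple[int, str, str]]:
        """All (pos, ref, alt) with alt != ref and total alt reads >= min_total."""
        out = []
        for i, pos in enumerate(self.positions):
            ref = str(self.refbase[i])
            for b in BASES:
                if b == ref:
                    continue
                tot = sum(int(self.counts[(b, s)][i].sum()) for s in STRANDS)
                if tot >= min_total:
                    out.append((int(pos), ref, b))
        return out


def read_strand_counts(path: str | Path) -> StrandCountTensor:
    """Read the long-format strand-count TSV dialect.

    Required header columns: ``position`` (1-based), ``cell``, ``base``,
    ``strand``, ``count``, ``ref``. Absent (position, cell, base, strand)
    combinations are zero; duplicated combinations are ambiguous and raise.
    ``ref`` must be constant per position.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "base": str,
                                            "strand": str, "ref": str})
    required = {"position", "cell", "base", "strand", "count", "ref"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    # +2: 1-based lines, header occupies line 1
    bad_strand = ~df["strand"].isin(STRANDS)
    if bad_strand.any():
        line = int(df.index[bad_strand][0]) + 2
        raise ValueError(f"{path}:{line}: strand must be one of {STRANDS}")
    bad_base = ~df["base"].isin(BASES) | ~df["ref"].isin(BASES)
    if bad_base.any():
        line = int(df.index[bad_base][0]) + 2
        raise ValueError(f"{path}:{line}: base must be one of {BASES}")
    dup = df.duplicated(subset=["position", "cell", "base", "strand"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}:{line}: duplicated (position, cell, base, strand) row")
    ref_per_pos = df.groupby("position")["ref"].nunique()
    if (ref_per_pos > 1).any():
        pos = int(ref_per_pos.index[ref_per_pos > 1][0])
        raise ValueError(f"{path}: inconsistent ref base at position {pos}")

    positions = np.sort(df["position"].unique())
    cells = sorted(df["cell"].unique())
    pos_idx = {p: i for i, p in enumerate(positions)}
    cell_idx = {c: i for i, c in enumerate(cells)}
    refbase = df.drop_duplicates("position").set_index("position")["ref"]
    refbase = refbase.reindex(positions).to_numpy()

    shape = (len(positions), len(cells))
    counts: dict[tuple[str, str], sp.csr_matrix] = {}
    for (b, s), sub in df.groupby(["base", "strand"]):
        rows = sub["position"].map(pos_idx).to_numpy()
        cols = sub["cell"].map(cell_idx).to_numpy()
        counts[(b, s)] = sp.csr_matrix(
            (sub["count"].to_numpy(dtype=np.int64), (rows, cols)), shape=shape
        )
    return StrandCountTensor(positions=positions, cells=cells,
                             refbase=refbase, counts=counts)


def write_strand_counts(t: StrandCountTensor, path: str | Path) -> None:
    """Write a :class:`StrandCountTensor` in the long-format TSV dialect."""
    rows = []
    for (b, s), m in sorted(t.counts.items()):
        coo = m.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if v:
                rows.append((int(t.positions[i]), t.cells[j], b, s, int(v),
                             str(t.refbase[i])))
    df = pd.DataFrame(rows, columns=["position", "cell", "base", "strand",
                                     "count", "ref"])
    df = df.sort_values(["position", "cell", "base", "strand"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clone table / cell metadata
# ---------------------------------------------------------------------------

UNKNOWN_LABEL = "(unknown)"


@dataclass
class CloneTable:
    """Mapping cell barcode -> clone id; cells without a clone are absent."""

    assignments: pd.Series  # index: barcode, values: clone id

    def __post_init__(self) -> None:
        self.assignments = self.assignments.dropna()
        if self.assignments.index.duplicated().any():
            dup = self.assignments.index[self.assignments.index.duplicated()][0]
            raise ValueError(f"cell {dup!r} assigned to more than one clone")

    def members(self, clone: str) -> list[str]:
        return list(self.assignments.index[self.assignments == clone])

    @property
    def clone_ids(self) -> list[str]:
        return list(pd.unique(self.assignments))


@dataclass
class CellMetadata:
    """Per-cell labels (cell type, donor); missing labels get a sentinel."""

    table: pd.DataFrame  # index: barcode; columns include cell_type

    def __post_init__(self) -> None:
        if "cell_type" not in self.table.columns:
            raise ValueError("metadata requires a cell_type column")
        self.table = self.table.copy()
        self.table["cell_type"] = self.table["cell_type"].fillna(UNKNOWN_LABEL)

    def cell_type(self, barcode: str) -> str:
        if barcode in self.table.index:
            return str(self.table.loc[barcode, "cell_type"])
        return UNKNOWN_LABEL


def read_clone_table(path: str | Path) -> CloneTable:
    """Read a TSV with columns ``cell`` and ``clone``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell", "clone"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns cell, clone")
    return CloneTable(assignments=df.set_index("cell")["clone"])


def read_cell_metadata(path: str | Path) -> CellMetadata:
    """Read a TSV with a ``cell`` column plus label columns (cell_type, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell" not in df.columns:
        raise ValueError(f"{path}: expected a cell column")
    return CellMetadata(table=df.set_index("cell"))


# ---------------------------------------------------------------------------
# Heterozygous X-linked SNP counting
# ---------------------------------------------------------------------------


def _read_bed(path: str | Path) -> dict[str, object]:
    """BED (0-based half-open) -> per-chromosome interval trees."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                continue
            trees.setdefault(_norm_chrom(chrom), IntervalTree()).addi(start, end)
    return trees


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def count_het_x_variants(vcf_path: str | Path,
                         gene_regions_bed: str | Path) -> pd.Series:
    """Count per-sample heterozygous X-linked SNPs inside genic regions.

    A site contributes once per heterozygous sample (0/1 or 1/0, phased or
    unphased) if its 1-based position falls inside any BED interval (0-based
    half-open; a site exactly at an interval end is outside). Missing
    genotypes are excluded. Returns a Series indexed by sample name.
    """
    from cyvcf2 import VCF

    trees = _read_bed(gene_regions_bed)
    if not trees:
        warnings.warn("empty BED: all heterozygous counts will be 0")
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{vcf_path}: VCF has no samples / GT fields")
    counts = np.zeros(len(samples), dtype=int)
    for rec in vcf:
        if rec.CHROM not in X_CHROM_NAMES:
            continue
        tree = trees.get(_norm_chrom(rec.CHROM))
        if tree is None or not tree.overlaps(rec.POS - 1):
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt; counted once per
        # site regardless of how many gene intervals overlap it
        counts += rec.gt_types == 1
    return pd.Series(counts, index=samples, name="n_het_x")
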