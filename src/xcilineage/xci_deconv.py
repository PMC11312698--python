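"""Assigning each cell an active-X allele from X-linked allelic counts.

In XX cells one X chromosome is stably silenced early in development, and
all descendants inherit the same choice. Allele-specific expression at
X-linked heterozygous SNPs therefore splits cells into two haplotype
classes. This module fits a two-state genotype mixture: cell ``c`` has a
latent active-X state ``z_c`` in {1, 2} with prior mixing weights, and the
ALT-read count at site ``s`` is Binomial(dp[c, s], mu[z_c, s]) with a
state-specific, site-specific ALT-expression probability ``mu``. An EM on
this model recovers the two haplotypes and a posterior state per cell — the
same per-cell genotype-deconvolution idea used for demultiplexing pooled
donors, applied to the two X haplotypes of one donor.

Labels are identifiable only up to the global allele1/allele2 swap; all
comparisons against external truth must allow for it. Cells with too few
observed sites or an equivocal posterior are left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel_io import AllelicCountMatrix

__all__ = ["XCIModel", "XCIAssignment", "fit_xci_model", "assign_xci", "downsample"]

_MU_CLAMP = 1e-6
LABELS = ("allele1", "allele2")
UNASSIGNED = "unassigned"


@dataclass
class XCIModel:
    """Fitted two-state genotype mixture over X-linked sites."""

    mu: np.ndarray                 # (2, n_sites) ALT-expression probability per state
    weights: np.ndarray            # (2,) mixing weights; weights[0] = XCI ratio estimate
    posterior: np.ndarray          # (n_cells, 2), rows sum to 1
    loglik: float
    loglik_trace: np.ndarray = field(repr=False)
    converged: bool = True
    n_iter: int = 0


@dataclass
class XCIAssignment:
    """Per-cell active-X label with quality annotations."""

    cells: list[str]
    labels: np.ndarray             # "allele1" | "allele2" | "unassigned"
    max_posterior: np.ndarray
    n_observed_variants: np.ndarray  # sites with dp >= 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": self.cells,
            "label": self.labels,
            "posterior": self.max_posterior,
            "n_observed_variants": self.n_observed_variants,
        })

    def label_of(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cells, name="label")


def _initial_split(ad: np.ndarray, dp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split cells into two groups by ALT-fraction correlation with a reference cell.

    The cell with the highest total depth anchors one haplotype; every other
    cell joins it or the opposite group according to the sign of the Pearson
    correlation of ALT fractions over co-covered sites. Degenerate cells are
    assigned at random (seeded).
    """
    n_cells = ad.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(dp > 0, ad / np.where(dp > 0, dp, 1), np.nan)
    ref = int(np.argmax(dp.sum(axis=1)))
    group = rng.integers(0, 2, size=n_cells)
    ref_af = af[ref]
    for c in range(n_cells):
        both = np.isfinite(af[c]) & np.isfinite(ref_af)
        if both.sum() < 2:
            continue
        x, y = af[c][both], ref_af[both]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        group[c] = 0 if r >= 0 else 1
    group[ref] = 0
    return group


def fit_xci_model(acm: AllelicCountMatrix, n_states: int = 2, *, seed: int = 0,
                  max_iter: int = 500, tol: float = 1e-6,
                  check_monotone: bool = False) -> XCIModel:
    """Fit the two-state binomial genotype mixture by EM.

    Sites with dp = 0 in a cell contribute nothing to that cell's
    likelihood. The log-likelihood (up to the binomial coefficients, which
    do not depend on the state) is non-decreasing across iterations;
    ``check_monotone=True`` asserts this. Deterministic given ``seed``.
    """
    if n_states != 2:
        raise NotImplementedError("only two active-X states are modelled")
    ad = np.asarray(acm.ad.todense(), dtype=float)
    dp = np.asarray(acm.dp.todense(), dtype=float)
    if ad.shape[0] < 2 or (dp.sum(axis=0) > 0).sum() < 2:
        raise ValueError("no informative sites: need >= 2 cells and >= 2 covered sites")
    if dp.sum() == 0:
        raise ValueError("no informative sites: all depths are zero")

    rng = np.random.default_rng(seed)
    group = _initial_split(ad, dp, rng)
    gamma = np.zeros((ad.shape[0], 2))
    gamma[np.arange(ad.shape[0]), group] = 1.0
    # light smoothing so a one-cell group does not pin mu at the clamp
    gamma = 0.9 * gamma + 0.05

    weights = np.array([0.5, 0.5])
    mu = np.empty((2, ad.shape[1]))
    trace = []
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step (from current responsibilities)
        num = gamma.T @ ad          # (2, sites)
        den = gamma.T @ dp
        pooled = np.divide(ad.sum(axis=0), np.maximum(dp.sum(axis=0), 1.0))
        mu = np.where(den > 0, num / np.maximum(den, 1e-300), pooled[None, :])
        mu = np.clip(mu, _MU_CLAMP, 1.0 - _MU_CLAMP)
        weights = np.clip(gamma.mean(axis=0), _MU_CLAMP, 1.0 - _MU_CLAMP)
        weights = weights / weights.sum()

        # E-step
        log_l = ad @ np.log(mu).T + (dp - ad) @ np.log1p(-mu).T  # (cells, 2)
        log_l = log_l + np.log(weights)[None, :]
        m = log_l.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_l - m).sum(axis=1))
        ll_new = float(lse.sum())
        gamma = np.exp(log_l - lse[:, None])

        if check_monotone and np.isfinite(ll):
            assert ll_new >= ll - 1e-8 * max(abs(ll), 1.0), "EM log-likelihood decreased"
        trace.append(ll_new)
        if np.isfinite(ll) and abs(ll_new - ll) <= tol * max(abs(ll), 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    return XCIModel(mu=mu, weights=weights, posterior=gamma, loglik=ll,
                    loglik_trace=np.asarray(trace), converged=converged, n_iter=it)


def assign_xci(model: XCIModel, acm: AllelicCountMatrix, *,
               posterior_threshold: float = 0.9,
               min_variants: int = 50) -> XCIAssignment:
    """Label cells by their maximum-posterior state, with quality gating.

    A cell is ``unassigned`` iff it has fewer than ``min_variants`` observed
    sites (dp >= 1) or its maximum posterior is below
    ``posterior_threshold`` (the threshold must lie in (0.5, 1]).
    """
    if not 0.5 < posterior_threshold <= 1.0:
        raise ValueError(f"posterior_threshold must be in (0.5, 1], got {posterior_threshold}")
    observed = acm.observed_variant_counts()
    max_post = model.posterior.max(axis=1)
    state = model.posterior.argmax(axis=1)
    labels = np.array([LABELS[z] for z in state], dtype=object)
    labels[(observed < min_variants) | (max_post < posterior_threshold)] = UNASSIGNED
    return XCIAssignment(cells=list(acm.cells), labels=labels,
                         max_posterior=max_post, n_observed_variants=observed)


def downsample(acm: AllelicCountMatrix, *, target_total_reads: int | None = None,
               target_n_sites: int | None = None,
               seed: int = 0) -> AllelicCountMatrix:
    """Downsample reads and/or sites, reproducibly.

    Read downsampling thins each cell independently and without replacement
    (multivariate hypergeometric over that cell's reads, categorised by
    site and ALT/REF allele): each cell keeps ``round(frac * reads_in_cell)``
    reads where ``frac = target_total_reads / total_reads``, so a cell with
    1000 reads thinned to 50% keeps exactly 500. Site downsampling keeps a
    uniform random subset of sites. Targets above what is available raise.
    """
    rng = np.random.default_rng(seed)
    out = acm
    if target_n_sites is not None:
        if target_n_sites > acm.n_sites:
            raise ValueError(f"target_n_sites {target_n_sites} > available {acm.n_sites}")
        keep = np.sort(rng.choice(acm.n_sites, size=target_n_sites, replace=False))
        out = out.subset_sites(keep)
    if target_total_reads is not None:
        total = int(out.dp.sum())
        if target_total_reads > total:
            raise ValueError(f"target_total_reads {target_total_reads} > available {total}")
        if target_total_reads == total:
            return out
        frac = target_total_reads / total if total else 0.0
        ad = np.asarray(out.ad.todense(), dtype=np.int64)
        dp = np.asarray(out.dp.todense(), dtype=np.int64)
        new_ad = np.zeros_like(ad)
        new_dp = np.zeros_like(dp)
        for c in range(out.n_cells):
            t_c = int(dp[c].sum())
            m_c = int(round(frac * t_c))
            if m_c == 0 or t_c == 0:
                continue
            nz = np.flatnonzero(dp[c])
            # colours: ALT then REF reads per covered site
            colors = np.concatenate([ad[c, nz], dp[c, nz] - ad[c, nz]])
            draw = rng.multivariate_hypergeometric(colors, m_c)
            half = len(nz)
            new_ad[c, nz] = draw[:half]
            new_dp[c, nz] = draw[:half] + draw[half:]
        out = AllelicCountMatrix(cells=list(out.cells), sites=out.sites.copy(),
                                 ad=sp.csr_matrix(new_ad), dp=sp.csr_matrix(new_dp))
    return out
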