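"""XCI-directed selection of clonally informative somatic variants.

The core statistic: for one candidate variant, per-cell variant-supporting
read counts ``k`` and site coverages ``n`` are modelled as a two-component
binomial mixture

    P(k | n, Theta) = pi1 * B(k | n, theta1) + pi2 * B(k | n, theta2),

where ``theta1`` is the variant-observation probability in mutated cells
(the clonal heteroplasmy), ``theta2`` the technical-error rate in
non-mutated cells, and ``pi1`` the mutated fraction. The mixture is fitted
by EM separately within each group of cells sharing an active-X allele.
Because a clonal mutation arises after X inactivation, it must be confined
to one active-X background: a variant is selected (PASS) iff exactly one
XCI group shows clonal heteroplasmy above ``0.04`` and the two groups'
heteroplasmies differ by more than ``1.22`` on the logit scale. Mutated
cells are then called from the mixture posterior (> 0.95) combined with a
likelihood-ratio test against a fixed error null (theta = 0.01, chi-square
with 1 df, alpha = 0.05).

A two-component mixture fitted to cells that carry no mutation at all is an
overfit: the second component latches onto the upper tail of the binomial
error distribution. :func:`fit_binomial_mixture` therefore also fits the
single-binomial model and compares the two by BIC; the *effective* clonal
heteroplasmy used by the selection rule is ``theta1`` when two components
are supported and the pooled single-component rate otherwise. The raw
two-component parameters are always reported alongside.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "CLAMP",
    "MixtureFit",
    "SelectionThresholds",
    "SelectionResult",
    "Verdict",
    "logit",
    "fit_binomial_mixture",
    "select_by_xci",
    "lrt_pvalue",
    "call_cells",
    "summarize_selection",
]

#: probability clamp applied before logs / logits
CLAMP = 1e-6


def _clamp(p: float | np.ndarray) -> float | np.ndarray:
    return np.clip(p, CLAMP, 1.0 - CLAMP)


def logit(p: float | np.ndarray) -> float | np.ndarray:
    """ln(p / (1 - p)) after clamping p to [1e-6, 1 - 1e-6]."""
    p = _clamp(np.asarray(p, dtype=float))
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


class Verdict(str, enum.Enum):
    """Per-variant outcome of the XCI-consistency selection rule."""

    PASS = "PASS"
    FAIL_BOTH = "FAIL_BOTH"          # clonal heteroplasmy high in both groups
    FAIL_NEITHER = "FAIL_NEITHER"    # high in neither group
    FAIL_LOGIT = "FAIL_LOGIT"        # one group high but logit gap too small
    INDETERMINATE = "INDETERMINATE"  # fit infeasible or non-convergent


@dataclass
class SelectionThresholds:
    """Selection and calling cutoffs (all comparisons are strict)."""

    heteroplasmy_min: float = 0.04
    logit_diff_min: float = 1.22
    posterior_min: float = 0.95
    h0_theta: float = 0.01
    alpha: float = 0.05
    min_cells_per_group: int = 10

    def __post_init__(self) -> None:
        for name in ("heteroplasmy_min", "posterior_min", "h0_theta", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.logit_diff_min <= 0:
            raise ValueError("logit_diff_min must be positive")


@dataclass
class MixtureFit:
    """Fitted two-component binomial mixture for one variant in one cell group."""

    pi1: float
    theta1: float  # clonal heteroplasmy (theta1 >= theta2 by component swap)
    theta2: float
    loglik: float
    converged: bool
    n_cells: int
    responsibilities: np.ndarray = field(repr=False)
    theta_single: float = float("nan")   # pooled single-binomial MLE
    loglik_single: float = float("nan")
    two_components_supported: bool = True
    n_iter: int = 0

    @property
    def pi2(self) -> float:
        return 1.0 - self.pi1

    @property
    def effective_theta1(self) -> float:
        """Clonal heteroplasmy after the parsimony check.

        ``theta1`` when the two-component model is BIC-supported over the
        single binomial, else the pooled rate (no mutated subpopulation).
        """
        return self.theta1 if self.two_components_supported else self.theta_single

    @property
    def delta_bic(self) -> float:
        """BIC improvement of two components over one (positive = supported)."""
        return 2.0 * (self.loglik - self.loglik_single) - 2.0 * np.log(max(self.n_cells, 1))


def _binom_logpmf(k, n, p):
    p = _clamp(p)
    return (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            + k * np.log(p) + (n - k) * np.log1p(-p))


def fit_binomial_mixture(k, n, *, seed: int | None = None, max_iter: int = 500,
                         tol: float = 1e-6, min_cells: int = 2) -> MixtureFit:
    """Fit the two-component binomial mixture by EM.

    ``k``/``n`` are per-cell variant counts and coverages (cells with n = 0
    should be excluded by the caller). The EM initialisation is
    deterministic — theta1 from the mean allele fraction of the top 5% of
    cells, theta2 = 0.001, pi1 from the fraction of cells above 4% allele
    fraction — so ``seed`` is accepted for interface symmetry but unused.
    Components are ordered so that theta1 >= theta2. The log-likelihood is
    non-decreasing across iterations.
    """
    del seed  # deterministic initialisation; kept for API symmetry
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if k.shape != n.shape or k.ndim != 1:
        raise ValueError("k and n must be 1-D arrays of equal length")
    if np.any(k > n):
        raise ValueError("k > n at some cell")
    S = len(k)
    if S < min_cells:
        raise ValueError(f"insufficient cells: {S} < {min_cells}")

    af = np.divide(k, n, out=np.zeros_like(k), where=n > 0)
    top = max(1, int(np.ceil(0.05 * S)))
    theta1 = max(float(np.sort(af)[::-1][:top].mean()), 0.1)
    theta2 = 0.001
    pi1 = max(float((af > 0.04).mean()), 0.01)

    lchoose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    def component_ll(theta):
        theta = float(_clamp(theta))
        return lchoose + k * np.log(theta) + (n - k) * np.log1p(-theta)

    ll = -np.inf
    gamma = np.full(S, pi1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        l1 = np.log(_clamp(pi1)) + component_ll(theta1)
        l2 = np.log(_clamp(1.0 - pi1)) + component_ll(theta2)
        m = np.maximum(l1, l2)
        denom = np.exp(l1 - m) + np.exp(l2 - m)
        ll_new = float((m + np.log(denom)).sum())
        gamma = np.exp(l1 - m) / denom

        pi1 = float(_clamp(gamma.mean()))
        w1, w2 = (gamma * n).sum(), ((1.0 - gamma) * n).sum()
        theta1 = float((gamma * k).sum() / w1) if w1 > 0 else CLAMP
        theta2 = float(((1.0 - gamma) * k).sum() / w2) if w2 > 0 else CLAMP
        if theta1 < theta2:
            theta1, theta2, pi1, gamma = theta2, theta1, 1.0 - pi1, 1.0 - gamma

        if np.isfinite(ll) and abs(ll_new - ll) <= tol * max(abs(ll), 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    theta1, theta2 = float(_clamp(theta1)), float(_clamp(theta2))
    # parsimony reference: single binomial with pooled rate
    p0 = float(_clamp(k.sum() / n.sum())) if n.sum() > 0 else CLAMP
    ll_single = float(_binom_logpmf(k, n, p0).sum())
    fit = MixtureFit(pi1=pi1, theta1=theta1, theta2=theta2, loglik=ll,
                     converged=converged, n_cells=S, responsibilities=gamma,
                     theta_single=p0, loglik_single=ll_single, n_iter=it)
    fit.two_components_supported = fit.delta_bic > 0
    return fit


def lrt_pvalue(k, n, theta0: float = 0.01, theta1: float = 0.1):
    """Per-cell likelihood-ratio p-value against the fixed error null.

    Log-likelihoods are binomial at ``theta0`` (null, default 0.01) and at
    ``theta1`` (the group's fitted clonal heteroplasmy); the statistic
    ``-2 (ll_H0 - ll_H1)`` is clamped at 0 when the null fits better and
    referred to a chi-square with 1 df (upper tail).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    ll0 = _binom_logpmf(k, n, theta0)
    ll1 = _binom_logpmf(k, n, theta1)
    stat = np.maximum(-2.0 * (ll0 - ll1), 0.0)
    p = chi2.sf(stat, df=1)
    return float(p) if p.ndim == 0 else p


def call_cells(fit: MixtureFit, k, n, thr: SelectionThresholds | None = None):
    """Per-cell mutation calls from a fitted mixture.

    Returns ``(carrier, posterior, pvalue)`` arrays. The posterior of
    harbouring the mutation is ``pi1 B(k|n,theta1) / P(k|n,Theta)``; a cell
    is a carrier iff posterior > 0.95 and the likelihood-ratio p-value
    < 0.05 (strict comparisons). Cells with n = 0 are non-carriers with NaN
    posterior.
    """
    thr = thr or SelectionThresholds()
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    covered = n > 0
    posterior = np.full(k.shape, np.nan)
    if covered.any():
        l1 = np.log(_clamp(fit.pi1)) + _binom_logpmf(k[covered], n[covered], fit.theta1)
        l2 = np.log(_clamp(fit.pi2)) + _binom_logpmf(k[covered], n[covered], fit.theta2)
        m = np.maximum(l1, l2)
        posterior[covered] = np.exp(l1 - m) / (np.exp(l1 - m) + np.exp(l2 - m))
    pvalue = np.where(covered,
                      lrt_pvalue(k, n, thr.h0_theta, fit.effective_theta1), np.nan)
    carrier = covered & (posterior > thr.posterior_min) & (pvalue < thr.alpha)
    return carrier, posterior, pvalue


@dataclass
class SelectionResult:
    """Outcome of :func:`select_by_xci` for a single variant."""

    verdict: Verdict
    passing_allele: str | None            # "allele1"/"allele2" when PASS
    fits: dict[str, MixtureFit | None]    # per-allele fits (None if infeasible)
    logit_diff: float                     # |logit gap| of effective theta1 values
    carrier: np.ndarray | None = None     # aligned to the input cells; PASS only
    posterior: np.ndarray | None = None
    pvalue: np.ndarray | None = None


def select_by_xci(k, n, xci_labels, thr: SelectionThresholds | None = None, *,
                  seed: int | None = None, call_all_cells: bool = False,
                  max_iter: int = 500, tol: float = 1e-6) -> SelectionResult:
    """Apply the XCI-split selection rule to one variant.

    ``xci_labels`` holds "allele1"/"allele2"/"unassigned" per cell, aligned
    with ``k``/``n``. Cells that are unassigned or uncovered are excluded
    from the fits. The mixture is fitted within each allele group; the
    verdict compares each group's effective clonal heteroplasmy against
    ``thr.heteroplasmy_min`` and the absolute logit gap between the two
    groups against ``thr.logit_diff_min`` (strict inequalities):

    * exactly one group above and gap above -> PASS,
    * both above -> FAIL_BOTH, neither -> FAIL_NEITHER,
    * exactly one above but gap below -> FAIL_LOGIT,
    * group too small / zero coverage / EM non-convergence -> INDETERMINATE.

    For PASS variants carrier flags are produced from the passing group's
    fit; by default only cells of the passing allele are called (a clonal
    mutation lives on one active-X background), ``call_all_cells=True``
    calls every covered cell.
    """
    thr = thr or SelectionThresholds()
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    labels = np.asarray(xci_labels, dtype=object)
    if not (k.shape == n.shape == labels.shape):
        raise ValueError("k, n and xci_labels must be aligned 1-D arrays")

    fits: dict[str, MixtureFit | None] = {}
    for allele in ("allele1", "allele2"):
        mask = (labels == allele) & (n > 0)
        if mask.sum() < thr.min_cells_per_group or n[mask].sum() == 0:
            fits[allele] = None
            continue
        fits[allele] = fit_binomial_mixture(k[mask], n[mask], seed=seed,
                                            max_iter=max_iter, tol=tol,
                                            min_cells=thr.min_cells_per_group)

    f1, f2 = fits["allele1"], fits["allele2"]
    if f1 is None or f2 is None or not (f1.converged and f2.converged):
        return SelectionResult(Verdict.INDETERMINATE, None, fits, float("nan"))

    e1, e2 = f1.effective_theta1, f2.effective_theta1
    gap = abs(logit(e1) - logit(e2))
    above1 = e1 > thr.heteroplasmy_min
    above2 = e2 > thr.heteroplasmy_min
    if above1 and above2:
        return SelectionResult(Verdict.FAIL_BOTH, None, fits, gap)
    if not above1 and not above2:
        return SelectionResult(Verdict.FAIL_NEITHER, None, fits, gap)
    if gap <= thr.logit_diff_min:
        return SelectionResult(Verdict.FAIL_LOGIT, None, fits, gap)

    passing = "allele1" if above1 else "allele2"
    fit = fits[passing]
    carrier = np.zeros(len(k), dtype=bool)
    posterior = np.full(len(k), np.nan)
    pvalue = np.full(len(k), np.nan)
    if call_all_cells:
        scope = np.ones(len(k), dtype=bool)
    else:
        scope = labels == passing
    c, po, pv = call_cells(fit, k[scope], n[scope], thr)
    carrier[scope], posterior[scope], pvalue[scope] = c, po, pv
    return SelectionResult(Verdict.PASS, passing, fits, gap,
                           carrier=carrier, posterior=posterior, pvalue=pvalue)


def summarize_selection(results: dict[str, SelectionResult]) -> dict[str, int]:
    """Pipeline bookkeeping over many variants.

    Returns counts keyed by: ``input`` (all variants), ``heteroplasmy_pass``
    (at least one group's effective clonal heteroplasmy above threshold,
    i.e. PASS + FAIL_BOTH + FAIL_LOGIT-with-one-above), ``pass``,
    ``fail_both``, ``fail_neither``, ``fail_logit``, ``indeterminate``.
    """
    counts = {"input": len(results), "pass": 0, "fail_both": 0,
              "fail_neither": 0, "fail_logit": 0, "indeterminate": 0,
              "heteroplasmy_pass": 0}
    for res in results.values():
        counts[res.verdict.value.lower()] += 1
        if res.verdict in (Verdict.PASS, Verdict.FAIL_BOTH, Verdict.FAIL_LOGIT):
            counts["heteroplasmy_pass"] += 1
    return counts
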