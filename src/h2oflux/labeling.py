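"""The heavy-water labeling model and its inversions.

During a ²H₂O labeling window, molecules synthesized de novo incorporate
deuterium at their n exchangeable hydrogen positions, each independently with
probability equal to the body-water ²H mol-fraction excess p.  The excess-label
distribution of the pool is therefore the two-component mixture

    (1 - f) * delta_0  +  f * Binomial(n, p)

where f is the fractional synthesis (fraction of the pool made during the
window).  The instrument observes this convolved with the ion's natural
isotope distribution, truncated at mK.  Natural deuterium background at the
exchangeable positions is carried inside the natural MID (every hydrogen in
the formula sits at natural abundance there), and the excess labeling of new
molecules convolves on top of it independently — so correcting an observed MID
by the full natural MID returns exactly the mixture above.

Inversions provided here: analyte enrichment (the weighted excess-label sum
m1 + 2*m2 + 3*m3), fractional synthesis f = enrichment / (p * n) * 100, and
estimation of n itself from the binomial shape of corrected MIDs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom
from sklearn.base import BaseEstimator

from .formula import ElementalFormula
from .isotopes import DEFAULT_K, MID, natural_mid


class SevereTruncationWarning(UserWarning):
    """Truncated probability mass exceeds the configured bound."""


@dataclass
class LabelingParameters:
    """p: body-water ²H mol-fraction excess; n: exchangeable-H count; f: fractional synthesis (fraction)."""

    p: float
    n: float
    f: float

    def __post_init__(self):
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"p must lie in [0, 1): {self.p}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1: {self.n}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1]: {self.f}")


@dataclass
class LabelingResult:
    """Per sample x analyte outcome of the tracer analysis."""

    sample_id: str
    analyte_id: str
    corrected_mid: MID
    enrichment: float
    p: float
    n: float
    f_percent: float
    flags: tuple = ()

    def __post_init__(self):
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")
        if self.enrichment > self.corrected_mid.K:
            raise ValueError("enrichment cannot exceed K")
        if self.f_percent < 0:
            raise ValueError("fractional synthesis must be >= 0")


def _label_mixture(f: float, n: float, p: float, K: int) -> np.ndarray:
    """(1-f)*delta_0 + f*Binomial(n, p) over shifts 0..K (not renormalized)."""
    b = binom.pmf(np.arange(K + 1), int(round(n)), p)
    mix = f * b
    mix[0] += 1.0 - f
    return mix


def forward_observed_mid(
    params: LabelingParameters,
    formula: ElementalFormula,
    K: int = DEFAULT_K,
    isotopes=None,
    truncation_bound: float = 0.05,
) -> MID:
    """Simulate the MID an instrument would observe before noise.

    Convolves the ion's full natural-abundance MID with the excess-label
    mixture (1-f)*delta_0 + f*Binomial(n, p), truncated at mK.  Warns with
    :class:`SevereTruncationWarning` when the probability mass lost beyond mK
    exceeds ``truncation_bound``.
    """
    if formula.exchangeable_h and formula.exchangeable_h != int(round(params.n)):
        raise ValueError(
            f"formula designates {formula.exchangeable_h} exchangeable H "
            f"but n = {params.n}"
        )
    nat = natural_mid(formula, K, isotopes)
    mix = _label_mixture(params.f, params.n, params.p, K)
    vals = np.convolve(nat.values, mix)[: K + 1]
    trunc = max(0.0, 1.0 - vals.sum())
    if trunc > truncation_bound:
        warnings.warn(
            f"severe truncation: {trunc:.3f} of probability mass beyond m{K}",
            SevereTruncationWarning,
            stacklevel=2,
        )
    return MID(values=vals, truncated_mass=trunc)


def analyte_enrichment(corrected: MID) -> float:
    """Weighted excess-label sum of a corrected MID: m1 + 2*m2 + 3*m3 (+ i*mi for K > 3).

    Units: average ²H label atoms per molecule.
    """
    v = corrected.values
    return float(np.arange(v.size) @ v)


def fractional_synthesis(enrichment: float, p: float, n: float) -> float:
    """Fractional synthesis (%) = enrichment / (p * n) * 100.

    Values slightly above 100 are possible under noise and are returned
    unclipped (callers may flag them).
    """
    if p <= 0:
        raise ValueError("water enrichment unavailable for sample (p = 0)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    return enrichment / (p * n) * 100.0


def truncation_bias_factor(n: float, p: float, K: int = DEFAULT_K) -> float:
    """Expected fraction of a new molecule's label atoms visible at m0..mK.

    The enrichment of a fully labeled pool measured on a K-truncated MID is
    sum_{i<=K} i * Binom(i; n, p) instead of n*p; this factor (<= 1) is their
    ratio.  Dividing an Eq.-1 style f estimate by it removes the K-truncation
    bias.  Equals 1 when p = 0.
    """
    if p <= 0:
        return 1.0
    i = np.arange(K + 1)
    return float((i @ binom.pmf(i, int(round(n)), p)) / (n * p))


def new_pool_amount(f_percent: float, pool_size: float) -> float:
    """Absolute newly synthesized amount: (f/100) * pool concentration (µg/g)."""
    if f_percent < 0:
        raise ValueError("f must be >= 0")
    if pool_size < 0:
        raise ValueError("pool size must be >= 0")
    return f_percent / 100.0 * pool_size


def estimate_f_mixture(corrected: MID, p: float, n: float) -> float:
    """Fractional synthesis (%) by binomial-mixture least squares.

    Fits corrected = alpha*delta_0 + beta*Binom(n, p) (non-negative) and
    returns beta / (alpha + beta) * 100.  Unlike the enrichment-ratio
    formula this estimator is unbiased under mK truncation.
    """
    if p <= 0:
        raise ValueError("water enrichment unavailable for sample (p = 0)")
    K = corrected.K
    A = np.column_stack([np.eye(K + 1)[:, 0], binom.pmf(np.arange(K + 1), int(round(n)), p)])
    coef, _ = nnls(A, corrected.values)
    alpha, beta = coef
    if alpha + beta <= 0:
        raise ValueError("degenerate mixture fit")
    return float(beta / (alpha + beta) * 100.0)


@dataclass
class NEstimationResult:
    """Outcome of exchangeable-hydrogen count estimation."""

    n: int
    candidates: np.ndarray
    residuals: np.ndarray  # pooled sum of squared residuals per candidate
    ratio_estimate: float  # closed-form 1 + 2*(m2/m1)*((1-p)/p) diagnostic
    tie: bool = False
    tied_candidates: tuple = ()


def estimate_n(
    corrected_mids,
    p: float,
    candidates=range(1, 41),
    floor: float = 1e-6,
    tie_tol: float = 1e-9,
    pool: bool = True,
    weighting: str = "relative",
) -> NEstimationResult:
    """Estimate the exchangeable-hydrogen count n from corrected MIDs.

    The study's corrected MIDs are averaged into one pooled MID per analyte
    (``pool=True``; set False for per-sample fitting), then for each
    candidate n the two-parameter non-negative mixture
    alpha*delta_0 + beta*Binom(n, p) is fitted by least squares; the
    candidate minimizing the pooled residual wins.  ``weighting="relative"``
    (default) scales residuals by 1/value, matching the multiplicative error
    of MS peak areas so that the information-rich small isotopologues
    (m2, m3) are not drowned out by m0; ``"none"`` uses plain least squares.
    The closed-form ratio check n = 1 + 2*(m2/m1)*((1-p)/p) is reported as a
    diagnostic.

    Ties (residuals within ``tie_tol`` of the minimum) resolve to the
    smallest n and are reported on the result.
    """
    if p <= 0:
        raise ValueError("p must be > 0 to estimate n")
    if weighting not in ("relative", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rows = [m.values if isinstance(m, MID) else np.asarray(m, dtype=float)
            for m in corrected_mids]
    if not rows:
        raise ValueError("no MIDs supplied")
    M = np.vstack(rows)
    K = M.shape[1] - 1
    excess = M[:, 1:].sum(axis=1)
    if (excess < floor).any():
        raise ValueError("insufficient labeling to determine n")
    cand = np.asarray(list(candidates), dtype=int)
    if cand.size == 0:
        raise ValueError("empty candidate grid")
    fit_rows = M.mean(axis=0, keepdims=True) if pool else M
    e0 = np.eye(K + 1)[:, 0]
    shifts = np.arange(K + 1)
    rss = np.empty(cand.size)
    for ci, c in enumerate(cand):
        A = np.column_stack([e0, binom.pmf(shifts, c, p)])
        total = 0.0
        for row in fit_rows:
            if weighting == "relative":
                w = 1.0 / np.maximum(row, 1e-12)
                _, rnorm = nnls(A * w[:, None], row * w)
            else:
                _, rnorm = nnls(A, row)
            total += rnorm**2
        rss[ci] = total
    best = float(rss.min())
    tied = cand[rss <= best + tie_tol]
    n_hat = int(tied.min())
    # closed-form diagnostic, averaged over MIDs with usable m1
    usable = M[:, 1] > floor
    if K >= 2 and usable.any():
        ratio = M[usable, 2] / M[usable, 1]
        ratio_estimate = float(np.mean(1.0 + 2.0 * ratio * (1.0 - p) / p))
    else:
        ratio_estimate = float("nan")
    return NEstimationResult(
        n=n_hat,
        candidates=cand,
        residuals=rss,
        ratio_estimate=ratio_estimate,
        tie=tied.size > 1,
        tied_candidates=tuple(int(t) for t in tied) if tied.size > 1 else (),
    )


class ExchangeableHydrogenEstimator(BaseEstimator):
    """Estimate an analyte's exchangeable-hydrogen count n from corrected MIDs.

    scikit-learn style: ``fit(X)`` with X of shape (n_samples, K+1) holding
    natural-abundance-corrected MID fractions pools all samples and selects
    the binomial size n that best explains them at water enrichment ``p``.

    Attributes
    ----------
    n_ : int
        Selected exchangeable-hydrogen count.
    residual_profile_ : ndarray
        Pooled squared residual for each candidate.
    ratio_estimate_ : float
        Closed-form m2/m1 diagnostic estimate of n.
    tie_ : bool
    """

    def __init__(self, p: float = 0.04, candidates=range(1, 41),
                 floor: float = 1e-6, tie_tol: float = 1e-9,
                 pool: bool = True, weighting: str = "relative"):
        self.p = p
        self.candidates = candidates
        self.floor = floor
        self.tie_tol = tie_tol
        self.pool = pool
        self.weighting = weighting

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        result = estimate_n(X, self.p, self.candidates, self.floor,
                            self.tie_tol, self.pool, self.weighting)
        self.n_ = result.n
        self.candidates_ = result.candidates
        self.residual_profile_ = result.residuals
        self.ratio_estimate_ = result.ratio_estimate
        self.tie_ = result.tie
        self.tied_candidates_ = result.tied_candidates
        return self
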