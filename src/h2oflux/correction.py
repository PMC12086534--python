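"""Natural-abundance correction of measured isotopologue intensities.

Observed m0-mK intensities are a convolution of the tracer-label distribution
with the ion's natural isotope distribution.  The correction matrix is the
lower-triangular operator of that convolution: column j is the natural MID
shifted down by j rows.  Correction solves the linear system under a
non-negativity constraint (NNLS by default; plain triangular back-substitution
optionally) and renormalizes, yielding the label-only MID whose m0 is the
unlabeled fraction at the exchangeable positions.

The natural MID may come from the ion's elemental formula (theoretical mode)
or from averaged unlabeled baseline samples (empirical mode), mirroring the
field practice of measuring a biological sample collected without tracer.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .formula import ElementalFormula
from .isotopes import DEFAULT_K, MID, natural_mid


class ResidualWarning(UserWarning):
    """Correction solve left a residual above the configured tolerance."""


@dataclass
class CorrectionMatrix:
    """Lower-triangular operator mapping label-only MIDs to observed MIDs."""

    matrix: np.ndarray
    provenance: str = "theoretical"  # or "empirical"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correction matrix must be square")
        if not np.allclose(m, np.tril(m)):
            raise ValueError("correction matrix must be lower-triangular")
        if m.min() < 0 or m.max() > 1 + 1e-12:
            raise ValueError("correction matrix entries must lie in [0, 1]")
        if (m.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("correction matrix columns must sum to <= 1")
        self.matrix = m

    @property
    def K(self) -> int:
        return self.matrix.shape[0] - 1


def build_correction_matrix(natural, provenance: str | None = None) -> CorrectionMatrix:
    """Assemble the correction matrix from a natural-abundance MID.

    ``natural`` may be a theoretical MID (from :func:`natural_mid`) or an
    empirical one measured on unlabeled baseline samples.
    """
    if isinstance(natural, MID):
        nat = natural.values
        if provenance is None:
            provenance = "theoretical"
    else:
        nat = np.asarray(natural, dtype=float)
        if provenance is None:
            provenance = "empirical"
    if nat[0] <= 0:
        raise ValueError("natural MID has m0 = 0; correction matrix would be singular")
    K = nat.size - 1
    m = np.zeros((K + 1, K + 1))
    for j in range(K + 1):
        m[j:, j] = nat[: K + 1 - j]
    return CorrectionMatrix(matrix=m, provenance=provenance)


def correct_mid(
    raw,
    correction: CorrectionMatrix,
    solver: str = "nnls",
    tol: float = 1e-8,
    return_residual: bool = False,
):
    """Correct raw m0..mK intensities for natural isotope abundance.

    The raw vector is normalized to fractions, the correction system is
    solved for the label-only distribution, and the solution is renormalized
    to sum 1.  The result is invariant to positive rescaling of ``raw``.

    Parameters
    ----------
    raw : array-like
        Non-negative peak areas/intensities for m0..mK, at least one positive.
    solver : {"nnls", "triangular"}
        NNLS guards against noise-induced negative isotopologue fractions;
        triangular back-substitution is exact on clean data.
    return_residual : bool
        Also return the solve residual (2-norm in normalized-intensity units).
    """
    raw = np.asarray(raw, dtype=float)
    M = correction.matrix
    if raw.shape != (M.shape[0],):
        raise ValueError(
            f"raw vector length {raw.size} does not match matrix size {M.shape[0]}"
        )
    if raw.min() < 0:
        raise ValueError("raw intensities must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise ValueError("empty spectrum")
    y = raw / total
    if solver == "nnls":
        x, _ = nnls(M, y)
    elif solver == "triangular":
        x = solve_triangular(M, y, lower=True)
        x = np.clip(x, 0.0, None)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    residual = float(np.linalg.norm(M @ x - y))
    s = x.sum()
    if s <= 0:
        raise ValueError("correction produced an all-zero distribution")
    mid = MID(values=x / s, truncated_mass=0.0)
    if residual > tol:
        warnings.warn(
            f"correction residual {residual:.3g} above tolerance {tol:.3g}",
            ResidualWarning,
            stacklevel=2,
        )
    if return_residual:
        return mid, residual
    return mid


class NaturalAbundanceCorrector(TransformerMixin, BaseEstimator):
    """Natural-abundance correction as a fit/transform estimator.

    ``fit`` establishes the natural MID — empirically, by averaging the
    normalized rows of unlabeled baseline intensities passed as ``X``, or
    theoretically from ``formula`` when no baseline is given — and builds the
    correction matrix.  ``transform`` maps rows of raw m0..mK intensities to
    label-only MID fractions.

    Parameters
    ----------
    formula : ElementalFormula, optional
        Monitored-ion composition for theoretical mode.
    K : int, default 3
        Highest monitored mass shift.
    mode : {"auto", "empirical", "theoretical"}
        "auto" uses baseline samples when provided, else the formula.
    solver : {"nnls", "triangular"}
    tol : float
        Residual tolerance above which a warning is recorded.

    Attributes
    ----------
    natural_mid_ : MID
    correction_matrix_ : CorrectionMatrix
    residuals_ : ndarray
        Per-row solve residuals from the last ``correct`` call.
    """

    def __init__(self, formula: ElementalFormula | None = None, K: int = DEFAULT_K,
                 mode: str = "auto", solver: str = "nnls", tol: float = 1e-8,
                 isotopes=None):
        self.formula = formula
        self.K = K
        self.mode = mode
        self.solver = solver
        self.tol = tol
        self.isotopes = isotopes

    def fit(self, X=None, y=None):
        has_baseline = X is not None and len(np.atleast_2d(X)) > 0
        if self.mode == "empirical" and not has_baseline:
            raise ValueError("empirical mode requires baseline samples")
        if self.mode not in ("auto", "empirical", "theoretical"):
            raise ValueError(f"unknown mode {self.mode!r}")
        use_empirical = has_baseline and self.mode in ("auto", "empirical")
        if use_empirical:
            B = np.atleast_2d(np.asarray(X, dtype=float))
            if B.shape[1] != self.K + 1:
                raise ValueError(f"baseline rows must have K+1 = {self.K + 1} entries")
            sums = B.sum(axis=1)
            if (sums <= 0).any():
                raise ValueError("baseline sample with empty spectrum")
            avg = (B / sums[:, None]).mean(axis=0)
            self.natural_mid_ = MID(values=avg / avg.sum(), truncated_mass=0.0)
            prov = "empirical"
        else:
            if self.formula is None:
                raise ValueError("theoretical mode requires a formula")
            self.natural_mid_ = natural_mid(self.formula, self.K, self.isotopes)
            prov = "theoretical"
        self.correction_matrix_ = build_correction_matrix(self.natural_mid_, prov)
        return self

    def correct(self, X):
        """Correct rows of raw intensities; returns (fractions, residuals)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        res = np.empty(X.shape[0])
        for i, row in enumerate(X):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ResidualWarning)
                mid, r = correct_mid(row, self.correction_matrix_, self.solver,
                                     self.tol, return_residual=True)
            out[i] = mid.values
            res[i] = r
        self.residuals_ = res
        return out, res

    def transform(self, X):
        return self.correct(X)[0]
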