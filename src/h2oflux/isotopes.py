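"""Natural-abundance isotope mathematics.

The central currency here is the mass isotopomer distribution (MID): the
fractional abundances of an ion's isotopologues m0, m1, ... mK, where mi
carries i extra nominal mass units.  Instruments in this workflow monitor
m0-m3 only, so every MID is truncated at a configurable K (default 3) and the
probability mass beyond mK is tracked explicitly in ``truncated_mass`` rather
than silently dropped.

``natural_mid`` builds the MID of an elemental formula at natural isotopic
abundance by repeated convolution of per-atom isotope patterns.  Because mass
shifts only add, truncating every intermediate convolution at K+1 entries
leaves the retained entries exact.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .formula import ElementalFormula

DEFAULT_K = 3

_SUM_TOL = 1e-9


class UnknownElementError(KeyError):
    """Raised when a formula uses an element absent from the isotope table."""


@dataclass(frozen=True)
class IsotopePattern:
    """Isotope distribution of a single element.

    ``shifts`` are integer nominal-mass shifts relative to the lightest
    isotope (strictly increasing, starting at 0); ``abundances`` are the
    corresponding mole fractions and must sum to 1.
    """

    element: str
    shifts: tuple
    abundances: tuple

    def __post_init__(self):
        if not self.shifts or self.shifts[0] != 0:
            raise ValueError(f"{self.element}: shifts must start at 0")
        if any(b <= a for a, b in zip(self.shifts, self.shifts[1:])):
            raise ValueError(f"{self.element}: shifts must be strictly increasing")
        if any(not (0.0 <= a <= 1.0) for a in self.abundances):
            raise ValueError(f"{self.element}: abundances must lie in [0, 1]")
        if abs(sum(self.abundances) - 1.0) > 1e-12:
            raise ValueError(f"{self.element}: abundances must sum to 1")

    def vector(self, length: int) -> np.ndarray:
        """Abundances as a dense shift-indexed vector of the given length."""
        v = np.zeros(length)
        for s, a in zip(self.shifts, self.abundances):
            if s < length:
                v[s] = a
        return v


def load_isotope_table(path=None) -> dict:
    """Load per-element isotope patterns from CSV (element, mass_shift, abundance).

    With no path, the packaged table of IUPAC representative abundances is used.
    """
    if path is None:
        source = resources.files("h2oflux.data").joinpath("isotope_abundances.csv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = list(csv.DictReader(text.splitlines()))
    by_el: dict = {}
    for row in rows:
        by_el.setdefault(row["element"], []).append(
            (int(row["mass_shift"]), float(row["abundance"]))
        )
    table = {}
    for el, pairs in by_el.items():
        pairs.sort()
        table[el] = IsotopePattern(
            element=el,
            shifts=tuple(s for s, _ in pairs),
            abundances=tuple(a for _, a in pairs),
        )
    return table


DEFAULT_ISOTOPES = load_isotope_table()


@dataclass
class MID:
    """A truncated mass isotopomer distribution.

    ``values[i]`` is the fraction of molecules at mass shift i for i in
    0..K; ``truncated_mass`` is the fraction beyond mK.  The total is 1.
    """

    values: np.ndarray
    truncated_mass: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).copy()
        if v.ndim != 1 or v.size < 1:
            raise ValueError("MID values must be a 1-D vector")
        # tolerate tiny negative round-off from solvers
        if v.min() < -1e-9:
            raise ValueError(f"MID values must be non-negative (min {v.min():g})")
        v[v < 0] = 0.0
        self.values = v
        self.truncated_mass = float(self.truncated_mass)
        if self.truncated_mass < -1e-9:
            raise ValueError("truncated_mass must be >= 0")
        self.truncated_mass = max(self.truncated_mass, 0.0)
        total = v.sum() + self.truncated_mass
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"MID must total 1 (got {total:.9f})")

    @property
    def K(self) -> int:
        return self.values.size - 1

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, i):
        return self.values[i]

    @classmethod
    def from_values(cls, values, renormalize: bool = False) -> "MID":
        v = np.asarray(values, dtype=float)
        if renormalize:
            s = v.sum()
            if s <= 0:
                raise ValueError("cannot normalize an all-zero vector")
            return cls(values=v / s, truncated_mass=0.0)
        return cls(values=v, truncated_mass=max(0.0, 1.0 - v.sum()))


def _conv_trunc(a: np.ndarray, b: np.ndarray, K: int) -> np.ndarray:
    return np.convolve(a, b)[: K + 1]


def natural_mid(formula: ElementalFormula, K: int = DEFAULT_K, isotopes=None) -> MID:
    """MID of an ion at natural isotopic abundance.

    Computed by convolving per-atom isotope patterns over every atom in the
    formula (binary exponentiation per element), truncated at mK with the
    excess recorded in ``truncated_mass``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if isotopes is None:
        isotopes = DEFAULT_ISOTOPES
    vec = np.zeros(K + 1)
    vec[0] = 1.0
    for el, count in formula.counts.items():
        if el not in isotopes:
            raise UnknownElementError(
                f"no isotope pattern configured for element {el!r}"
            )
        base = isotopes[el].vector(K + 1)
        # base ** count under truncated convolution, by squaring
        acc = None
        power = base
        c = count
        while c:
            if c & 1:
                acc = power if acc is None else _conv_trunc(acc, power, K)
            c >>= 1
            if c:
                power = _conv_trunc(power, power, K)
        vec = _conv_trunc(vec, acc, K)
    return MID(values=vec, truncated_mass=max(0.0, 1.0 - vec.sum()))


def convolve_mids(a: MID, b: MID, K: int | None = None) -> MID:
    """Convolve two MIDs (distribution of summed mass shifts), truncated at K.

    Exact for the retained entries because shifts only add; the truncated
    mass absorbs everything beyond K, including both inputs' own truncation.
    """
    if K is None:
        K = min(a.K, b.K)
    vals = np.convolve(a.values, b.values)[: K + 1]
    return MID(values=vals, truncated_mass=max(0.0, 1.0 - vals.sum()))
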