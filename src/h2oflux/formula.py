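"""Elemental formulas of monitored ions.

A formula records the atom counts of the ion actually measured by the mass
spectrometer (e.g. the palmitate carboxylate ``C16H31O2``, the taurine-conjugate
``[M-H]-`` ions), plus an optional count of hydrogens designated *exchangeable*:
positions that equilibrate with body water during biosynthesis and can
therefore carry the deuterium label.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# canonical element ordering for Hill notation (C, H, then alphabetical)
def _hill_order(symbols):
    rest = sorted(s for s in symbols if s not in ("C", "H"))
    out = [s for s in ("C", "H") if s in symbols]
    return out + rest


@dataclass
class ElementalFormula:
    """Atom counts of a monitored ion.

    Parameters
    ----------
    counts : dict
        Mapping from element symbol to a non-negative atom count.
    exchangeable_h : int, default 0
        Number of hydrogens (a subset of ``counts['H']``) that exchange with
        body water during synthesis; the binomial labeling model acts on
        these positions only.
    """

    counts: dict = field(default_factory=dict)
    exchangeable_h: int = 0

    def __post_init__(self):
        clean = {}
        for el, c in self.counts.items():
            c = int(c)
            if c < 0:
                raise ValueError(f"negative atom count for element {el!r}: {c}")
            if c > 0:
                clean[str(el)] = c
        self.counts = clean
        self.exchangeable_h = int(self.exchangeable_h)
        if self.exchangeable_h < 0:
            raise ValueError("exchangeable_h must be >= 0")
        if self.exchangeable_h > self.counts.get("H", 0):
            raise ValueError(
                f"exchangeable hydrogens ({self.exchangeable_h}) exceed total "
                f"hydrogens ({self.counts.get('H', 0)})"
            )

    @classmethod
    def from_string(cls, s: str, exchangeable_h: int = 0) -> "ElementalFormula":
        """Parse a Hill-notation formula string such as ``"C26H44NO7S"``."""
        s = s.strip()
        counts: dict = {}
        pos = 0
        for m in _TOKEN.finditer(s):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {s!r} at position {pos}")
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(s) or not counts:
            raise ValueError(f"cannot parse formula {s!r}")
        return cls(counts=counts, exchangeable_h=exchangeable_h)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    @property
    def total_h(self) -> int:
        return self.counts.get("H", 0)

    def without_exchangeable(self) -> "ElementalFormula":
        """The formula with its exchangeable hydrogens removed."""
        counts = dict(self.counts)
        if self.exchangeable_h:
            counts["H"] = counts.get("H", 0) - self.exchangeable_h
        return ElementalFormula(counts=counts, exchangeable_h=0)

    def __str__(self) -> str:
        parts = []
        for el in _hill_order(self.counts):
            c = self.counts[el]
            parts.append(el if c == 1 else f"{el}{c}")
        return "".join(parts)
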