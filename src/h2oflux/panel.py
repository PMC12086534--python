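"""Analyte definitions: monitored ions, exchangeable-hydrogen counts, MRM metadata.

The default panel covers the taurine-conjugated bile acids monitored by
LC-MS/MS (common product ion m/z 80, the taurine SO3- anion), the palmitate
carboxylate ion used for de novo lipogenesis, and the partial cholesterol
fragment (m/z 247).  Exchangeable-hydrogen counts are the standard per-analyte
assignments: T-CA 14, T-aMCA 14, T-bMCA 10, T-CDCA 18, T-DCA 10,
palmitate 22, cholesterol fragment 20.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .formula import ElementalFormula


@dataclass
class AnalyteDefinition:
    """A monitored ion: elemental formula, exchangeable-H count n, MRM transition."""

    name: str
    formula: ElementalFormula
    n_exchangeable: int
    precursor_mz: float | None = None
    product_mz: float | None = None

    def __post_init__(self):
        if self.n_exchangeable < 1:
            raise ValueError(f"{self.name}: n must be >= 1")
        if self.n_exchangeable > self.formula.total_h:
            raise ValueError(
                f"{self.name}: n ({self.n_exchangeable}) exceeds total H "
                f"({self.formula.total_h})"
            )
        # keep the formula's exchangeable designation consistent with n
        self.formula.exchangeable_h = self.n_exchangeable


def load_panel(path=None) -> dict:
    """Load analyte definitions from CSV (name, formula, n_exchangeable, m/z).

    With no path, the packaged default panel is used.  Returns a dict keyed
    by analyte name.
    """
    if path is None:
        source = resources.files("h2oflux.data").joinpath("analyte_panel.csv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    panel = {}
    for row in csv.DictReader(text.splitlines()):
        name = row["name"].strip()
        panel[name] = AnalyteDefinition(
            name=name,
            formula=ElementalFormula.from_string(row["formula"]),
            n_exchangeable=int(row["n_exchangeable"]),
            precursor_mz=float(row["precursor_mz"]) if row.get("precursor_mz") else None,
            product_mz=float(row["product_mz"]) if row.get("product_mz") else None,
        )
    return panel


def default_panel() -> dict:
    return load_panel()
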