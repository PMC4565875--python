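"""Chemical formulas, averagine construction, and elemental masses.

A :class:`ChemicalFormula` is an ordered element→count map over the elements
of the active isotope table (C_vH_wN_xO_yS_z and beyond).  The string dialect
is deliberately narrow: ``Element`` or ``ElementCount`` repeated, no
parentheses, charges or isotope labels.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .constants import AVERAGINE
from .errors import DomainError, FormulaError, UnsupportedElementError
from .isotopes import DEFAULT_TABLE, IsotopeTable

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Hill-like canonical ordering: C first, then H, then alphabetical.
def _hill_key(element: str):
    return {"C": (0,), "H": (1,)}.get(element, (2, element))


@dataclass(frozen=True)
class ChemicalFormula:
    """Element→atom-count map with a canonical Hill-like string form."""

    counts: dict[str, int]

    def __post_init__(self):
        clean = {el: int(n) for el, n in self.counts.items() if n}
        if any(n < 0 for n in clean.values()):
            raise DomainError("negative atom count")
        if not clean:
            raise DomainError("empty formula: at least one atom required")
        ordered = {el: clean[el] for el in sorted(clean, key=_hill_key)}
        object.__setattr__(self, "counts", ordered)

    def __str__(self) -> str:
        return "".join(
            f"{el}{n}" if n != 1 else el for el, n in self.counts.items()
        )

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self):
        return iter(self.counts.items())

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def scaled(self, factor: int) -> "ChemicalFormula":
        """Formula with every count multiplied by an integer factor."""
        return ChemicalFormula({el: n * factor for el, n in self.counts.items()})


def parse_formula(text: str, table: IsotopeTable = DEFAULT_TABLE) -> ChemicalFormula:
    """Parse ``"C2934H4615N781O897S39"``-style strings.

    An omitted count means 1.  Raises :class:`FormulaError` at the first
    malformed position and :class:`UnsupportedElementError` for symbols not
    in *table*.
    """
    if not text:
        raise FormulaError("empty formula string", position=0)
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"unexpected character {text[pos]!r}", position=pos)
        el, digits = m.group(1), m.group(2)
        if el not in table:
            raise UnsupportedElementError(
                f"element {el!r} at position {pos} not in isotope table"
            )
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {el!r}", position=pos)
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return ChemicalFormula(counts)


def neutron_denominations(
    formula: ChemicalFormula, table: IsotopeTable = DEFAULT_TABLE
) -> list[tuple[str, int, int]]:
    """Heavy-isotope "coin denominations" available to *formula*.

    Returns ``(element, nominal_nucleon_number, neutron_offset)`` triples in
    formula order then increasing offset, e.g. for a CHNOS molecule the
    offsets (1, 1, 1, 1, 2, 1, 2, 4) of 13C, 2H, 15N, 17O, 18O, 33S, 34S, 36S.
    """
    denoms = []
    for el, _n in formula:
        recs = table[el]
        base_nominal = round(recs[0].mass)
        for r in recs[1:]:
            denoms.append((el, base_nominal + r.neutron_offset, r.neutron_offset))
    return denoms


def averagine_formula(n_units: float) -> ChemicalFormula:
    """Poly-averagine formula for *n_units* averagine units.

    Each element count is ``n_units`` times the averagine stoichiometry,
    rounded half-up independently per element; e.g. 2000 units give
    C9877H15517N2715O2955S83.
    """
    if n_units <= 0:
        raise DomainError("n_units must be positive")
    return ChemicalFormula(
        {el: math.floor(n_units * coef + 0.5) for el, coef in AVERAGINE.items()}
    )


def monoisotopic_mass(
    formula: ChemicalFormula, table: IsotopeTable = DEFAULT_TABLE
) -> float:
    """Mass of the all-light-isotopes variant, Da."""
    return sum(n * table.lightest_mass(el) for el, n in formula)


def average_mass(formula: ChemicalFormula, table: IsotopeTable = DEFAULT_TABLE) -> float:
    """Abundance-weighted mean molecular mass, Da."""
    return sum(n * table.mean_mass(el) for el, n in formula)
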