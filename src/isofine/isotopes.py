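"""Isotope data tables.

An :class:`IsotopeTable` maps each element symbol to its stable isotopes
(mass, abundance, neutron offset relative to the lightest isotope).  The
packaged default table pins the NIST/AME values for C, H, N, O and S; any
element can be overridden or added through :meth:`IsotopeTable.with_element`
or by loading a user file with :func:`load_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import TableError, UnsupportedElementError

_ABUNDANCE_TOL = 1e-9


@dataclass(frozen=True)
class IsotopeRecord:
    """One stable isotope of an element.

    Attributes
    ----------
    mass : float
        Atomic mass in Da.
    abundance : float
        Natural abundance (probability).
    neutron_offset : int
        Nucleon count minus that of the element's lightest isotope.
    """

    mass: float
    abundance: float
    neutron_offset: int


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope records, sorted by neutron offset.

    Validates on construction: each element must have a neutron_offset-0
    (lightest) isotope, strictly increasing offsets, and abundances summing
    to 1 within 1e-9.
    """

    records: dict[str, tuple[IsotopeRecord, ...]]
    provenance: str = "unspecified"

    def __post_init__(self):
        for el, recs in self.records.items():
            if not recs:
                raise TableError(f"element {el!r} has no isotopes")
            offsets = [r.neutron_offset for r in recs]
            if offsets[0] != 0:
                raise TableError(f"element {el!r} lacks a neutron_offset=0 isotope")
            if any(b <= a for a, b in zip(offsets, offsets[1:])):
                raise TableError(f"element {el!r}: offsets not strictly increasing")
            total = sum(r.abundance for r in recs)
            if abs(total - 1.0) > _ABUNDANCE_TOL:
                raise TableError(
                    f"element {el!r}: abundances sum to {total!r}, not 1"
                )

    def __contains__(self, element: str) -> bool:
        return element in self.records

    def __getitem__(self, element: str) -> tuple[IsotopeRecord, ...]:
        try:
            return self.records[element]
        except KeyError:
            raise UnsupportedElementError(
                f"element {element!r} not in isotope table ({self.provenance})"
            ) from None

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.records)

    def lightest_mass(self, element: str) -> float:
        return self[element][0].mass

    def mean_mass(self, element: str) -> float:
        """Abundance-weighted mean isotope mass of one atom, Da."""
        return sum(r.abundance * r.mass for r in self[element])

    def mass_variance(self, element: str) -> float:
        """Variance of one atom's isotope mass, Da^2."""
        m1 = self.mean_mass(element)
        m2 = sum(r.abundance * r.mass**2 for r in self[element])
        return m2 - m1**2

    def mass_per_neutron(self, element: str, neutron_offset: int) -> float:
        """(mass(iso) - mass(lightest)) / offset for a heavy isotope."""
        recs = self[element]
        for r in recs:
            if r.neutron_offset == neutron_offset:
                if neutron_offset == 0:
                    raise TableError("mass-per-neutron undefined for offset 0")
                return (r.mass - recs[0].mass) / neutron_offset
        raise TableError(f"element {element!r} has no isotope at offset {neutron_offset}")

    def with_element(self, element: str, records: list[IsotopeRecord]) -> "IsotopeTable":
        """Return a copy with one element's records replaced (config override)."""
        new = dict(self.records)
        new[element] = tuple(sorted(records, key=lambda r: r.neutron_offset))
        return IsotopeTable(new, provenance=f"{self.provenance}+override:{element}")


def _parse_rows(lines, provenance: str) -> IsotopeTable:
    by_element: dict[str, list[tuple[int, float, float]]] = {}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, nominal, mass, abundance = line.split()
        by_element.setdefault(el, []).append((int(nominal), float(mass), float(abundance)))
    records = {}
    for el, rows in by_element.items():
        rows.sort()
        base = rows[0][0]
        records[el] = tuple(
            IsotopeRecord(mass=m, abundance=a, neutron_offset=n - base)
            for n, m, a in rows
        )
    return IsotopeTable(records, provenance=provenance)


def load_table(path: str | Path) -> IsotopeTable:
    """Load an isotope table from a columnar text file.

    Format: whitespace-separated columns ``element nominal mass_Da abundance``,
    one isotope per row; ``#`` starts a comment.
    """
    path = Path(path)
    return _parse_rows(path.read_text().splitlines(), provenance=str(path))


def default_table() -> IsotopeTable:
    """The packaged NIST/AME table for C, H, N, O, S."""
    text = resources.files("isofine.data").joinpath("isotopes.tsv").read_text()
    return _parse_rows(text.splitlines(), provenance="isofine builtin NIST2005/AME2003")


DEFAULT_TABLE = default_table()
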