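"""Exact-mass chemistry engine.

Formula parsing, monoisotopic masses, ion-form arithmetic,
single-substitution isotopologue patterns and elemental descriptors for
negative-mode PFAS screening.

Conventions
-----------
* The monoisotopic mass of a formula uses the *principal* (most abundant)
  isotope of every element.
* Deprotonation subtracts the proton mass 1.007277 Da; no separate
  electron-mass bookkeeping is applied, so charged masses agree with the
  usual ``accurate mass = m/z + 1.007277`` deconvolution of negative-mode
  direct-infusion data.
* Isotopologue patterns are single substitutions of the most abundant
  heavy isotope of C, S, O, Cl, Br or Si only.  Fine structure (double
  substitutions such as two 37Cl, or combined 13C 18O) is deliberately
  out of scope: single substitutions dominate the detectable signal.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pyteomics import mass as _pyt_mass

__all__ = [
    "FormulaError",
    "MolecularFormula",
    "IsotopeRecord",
    "IsotopeTable",
    "IonForm",
    "Isotopologue",
    "Descriptors",
    "PROTON_MASS",
    "DEPROTONATED",
    "IDENTITY_ION",
    "ISOTOPOLOGUE_ELEMENTS",
    "parse_formula",
    "monoisotopic_mass",
    "charged_mass",
    "isotopologues",
    "descriptors",
    "kendrick",
]

#: Proton mass used for [M-H]- arithmetic, in Da.
PROTON_MASS = 1.007277

#: Elements for which a single-substitution isotopologue is generated.
ISOTOPOLOGUE_ELEMENTS = ("C", "S", "O", "Cl", "Br", "Si")

# Hill order: C first, then H, then everything else alphabetically.
_HILL_HEAD = ("C", "H")

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


@dataclass(frozen=True)
class IsotopeRecord:
    """One isotope: element symbol, mass number, exact mass, abundance."""

    element: str
    mass_number: int
    mass: float
    abundance: float


class IsotopeTable:
    """Isotope masses and natural abundances, indexed by element symbol.

    The default table is built from the NIST/IUPAC values shipped with
    pyteomics; it can be exported to CSV and replaced by a user-supplied
    CSV with columns ``element, mass_number, mass, abundance``.
    """

    def __init__(self, records: Iterable[IsotopeRecord]):
        self._by_element: dict[str, list[IsotopeRecord]] = {}
        for rec in records:
            if rec.mass <= 0:
                raise ValueError(f"non-positive isotope mass: {rec}")
            self._by_element.setdefault(rec.element, []).append(rec)
        for element, recs in self._by_element.items():
            total = sum(r.abundance for r in recs)
            if total > 1.000001:
                raise ValueError(
                    f"abundances for {element} sum to {total:.7f} > 1"
                )
            recs.sort(key=lambda r: r.mass_number)

    _default: "IsotopeTable | None" = None

    @classmethod
    def default(cls) -> "IsotopeTable":
        """The NIST table (cached); only isotopes with abundance > 0."""
        if cls._default is None:
            records = [
                IsotopeRecord(el, mass_number, m, ab)
                for el, isos in _pyt_mass.nist_mass.items()
                for mass_number, (m, ab) in isos.items()
                if mass_number != 0 and ab > 0
            ]
            cls._default = cls(records)
        return cls._default

    def __contains__(self, element: str) -> bool:
        return element in self._by_element

    def elements(self) -> list[str]:
        return sorted(self._by_element)

    def isotopes(self, element: str) -> list[IsotopeRecord]:
        try:
            return list(self._by_element[element])
        except KeyError:
            raise FormulaError(f"unknown element symbol: {element!r}") from None

    def principal(self, element: str) -> IsotopeRecord:
        """The most abundant ("light") isotope of *element*."""
        return max(self.isotopes(element), key=lambda r: r.abundance)

    def heavy(self, element: str) -> IsotopeRecord | None:
        """The most abundant isotope other than the principal one."""
        principal = self.principal(element)
        rest = [r for r in self.isotopes(element) if r is not principal]
        if not rest:
            return None
        return max(rest, key=lambda r: r.abundance)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            (r.element, r.mass_number, r.mass, r.abundance)
            for recs in self._by_element.values()
            for r in recs
        ]
        pd.DataFrame(
            rows, columns=["element", "mass_number", "mass", "abundance"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IsotopeTable":
        df = pd.read_csv(path)
        return cls(
            IsotopeRecord(
                str(row.element), int(row.mass_number), float(row.mass),
                float(row.abundance),
            )
            for row in df.itertuples()
        )


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition: element symbol -> atom count (>= 1)."""

    counts: Mapping[str, int]

    def __post_init__(self):
        table = IsotopeTable.default()
        clean: dict[str, int] = {}
        for element, n in self.counts.items():
            if element not in table:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(
                    f"count for {element} must be a positive integer, got {n!r}"
                )
            clean[element] = n
        if not clean:
            raise FormulaError("empty formula")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for element, n in other.counts.items():
            merged[element] = merged.get(element, 0) + n
        return MolecularFormula(merged)

    @property
    def atom_count(self) -> int:
        return sum(self.counts.values())

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        parts = []
        rest = sorted(set(self.counts) - set(_HILL_HEAD))
        order = [e for e in _HILL_HEAD if e in self.counts] + rest
        if "C" not in self.counts:  # no carbon: plain alphabetical
            order = sorted(self.counts)
        for element in order:
            n = self.counts[element]
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a formula string like ``"C8HF17O3S"`` into a composition.

    Element symbols are one uppercase plus an optional lowercase letter;
    an absent count means 1.  Unknown symbols and malformed strings raise
    :class:`FormulaError` naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    table = IsotopeTable.default()
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r} at position {pos}: {text[pos:]!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in table:
            # A two-letter guess like "Fl" may really be F followed by an
            # unparseable tail; report the symbol as seen.
            raise FormulaError(f"unknown element {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"zero count for {symbol} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(
    f: MolecularFormula, table: IsotopeTable | None = None
) -> float:
    """Monoisotopic mass in Da: principal-isotope mass times count, summed.

    Summation runs in sorted element order so that compositions reached
    by different parse paths (e.g. a salt's re-protonated anion vs. the
    free acid) give bit-identical masses.
    """
    table = table or IsotopeTable.default()
    return sum(
        n * table.principal(el).mass for el, n in sorted(f.counts.items())
    )


@dataclass(frozen=True)
class IonForm:
    """An ion-forming rule: a signed mass delta in Da and a charge."""

    name: str
    mass_delta: float
    charge: int


#: Deprotonation [M-H]-, the default negative-ESI ion form.
DEPROTONATED = IonForm("[M-H]-", -PROTON_MASS, -1)

#: Identity form for species stored already charged.
IDENTITY_ION = IonForm("[M]", 0.0, -1)


def charged_mass(neutral: float, ion: IonForm = DEPROTONATED) -> float:
    """Apply an ion form to a neutral monoisotopic mass.

    For :data:`DEPROTONATED` this is ``neutral - 1.007277``; the identity
    ion leaves already-charged species untouched.
    """
    if neutral <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral}")
    result = neutral + ion.mass_delta
    if result <= 0:
        raise ValueError(
            f"ion form {ion.name} applied to {neutral} Da gives "
            f"non-positive mass {result}"
        )
    return result


@dataclass(frozen=True)
class Isotopologue:
    """One single-substitution heavy-isotope species of a parent formula.

    ``mass_shift`` is relative to the monoisotopic mass (mode-independent,
    so it applies equally to neutral and charged species);
    ``relative_abundance`` is the expected intensity as a fraction of the
    monoisotopic peak.
    """

    label: str
    mass_shift: float
    relative_abundance: float
    parent_id: str = ""


def isotopologues(
    f: MolecularFormula,
    parent_id: str = "",
    table: IsotopeTable | None = None,
) -> list[Isotopologue]:
    """Single-substitution isotopologues for C, S, O, Cl, Br, Si.

    For each of those elements present in *f*, exactly one entry using the
    element's most abundant heavy isotope (13C, 34S, 18O, 37Cl, 81Br,
    29Si).  ``relative_abundance = count * abundance_heavy /
    abundance_light``, the single-substitution binomial ratio.
    """
    table = table or IsotopeTable.default()
    out: list[Isotopologue] = []
    for element in ISOTOPOLOGUE_ELEMENTS:
        n = f[element]
        if n == 0:
            continue
        light = table.principal(element)
        heavy = table.heavy(element)
        if heavy is None:
            continue
        out.append(
            Isotopologue(
                label=f"{heavy.mass_number}{element}",
                mass_shift=heavy.mass - light.mass,
                relative_abundance=n * heavy.abundance / light.abundance,
                parent_id=parent_id,
            )
        )
    return out


@dataclass(frozen=True)
class Descriptors:
    """Elemental-ratio and unsaturation descriptors of one composition.

    Ratios are NaN when the formula contains no carbon.  ``element_count``
    is the total atom count.  ``dbe`` counts Si as tetravalent, N and P as
    trivalent and halogens as monovalent:
    ``DBE = 1 + C + Si - (H+F+Cl+Br+I)/2 + (N+P)/2``.
    The mass defect is signed, relative to the nearest integer.
    """

    f_c: float
    h_c: float
    hf_c: float
    o_c: float
    h_hal_c: float
    hetero_c: float
    element_count: int
    dbe: float
    dbe_o: float
    mass_defect: float

    def as_dict(self) -> dict[str, float]:
        return {
            "F/C": self.f_c,
            "H/C": self.h_c,
            "(H+F)/C": self.hf_c,
            "O/C": self.o_c,
            "(H+Hal)/C": self.h_hal_c,
            "(O+S+P+N)/C": self.hetero_c,
            "element_count": self.element_count,
            "DBE": self.dbe,
            "DBE-O": self.dbe_o,
            "mass_defect": self.mass_defect,
        }


def descriptors(f: MolecularFormula, m: float) -> Descriptors:
    """Descriptor record for formula *f* at mass *m* (Da)."""
    c = f["C"]
    h, o, n, p, s = f["H"], f["O"], f["N"], f["P"], f["S"]
    hal = f["F"] + f["Cl"] + f["Br"] + f["I"]
    dbe = 1 + c + f["Si"] - hal / 2 - h / 2 + (n + p) / 2
    if c > 0:
        f_c = f["F"] / c
        h_c = h / c
        hf_c = (h + f["F"]) / c
        o_c = o / c
        h_hal_c = (h + hal) / c
        hetero_c = (o + s + p + n) / c
    else:
        f_c = h_c = hf_c = o_c = h_hal_c = hetero_c = math.nan
    return Descriptors(
        f_c=f_c,
        h_c=h_c,
        hf_c=hf_c,
        o_c=o_c,
        h_hal_c=h_hal_c,
        hetero_c=hetero_c,
        element_count=f.atom_count,
        dbe=dbe,
        dbe_o=dbe - o,
        mass_defect=m - round(m),
    )


_CF2 = None


def _default_base() -> MolecularFormula:
    global _CF2
    if _CF2 is None:
        _CF2 = parse_formula("CF2")
    return _CF2


def _nominal_mass(f: MolecularFormula, table: IsotopeTable) -> int:
    return sum(n * table.principal(el).mass_number for el, n in f.counts.items())


def kendrick(
    m: float,
    base: MolecularFormula | str | None = None,
    table: IsotopeTable | None = None,
) -> tuple[float, float]:
    """Kendrick mass and Kendrick mass defect for repeat unit *base*.

    ``KM = m * nominal(base) / exact(base)``; ``KMD = round(KM) - KM``.
    The default base is CF2, the standard PFAS homolog unit, so members of
    a CF2 homologous series share a KMD.
    """
    if m <= 0:
        raise ValueError(f"mass must be positive, got {m}")
    table = table or IsotopeTable.default()
    if base is None:
        base = _default_base()
    elif isinstance(base, str):
        base = parse_formula(base)
    exact = monoisotopic_mass(base, table)
    nominal = _nominal_mass(base, table)
    km = m * nominal / exact
    return km, round(km) - km
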