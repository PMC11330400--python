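"""Suspect-list curation.

Builds a machine-readable PFAS suspect list from a raw CSV whose first
column is ``"Molecular formula"`` (CompTox-PFASMASTER-like schema):
masses are always recomputed from the formula, counter-cations are
stripped from salts so that a salt and its free acid share one charged
mass, single-substitution isotopologues and elemental descriptors are
attached, and every entry is classified by its ionizability in negative
ESI (acidic / electropositive / non-ionizable) from the supplied pKa
columns.

The output is a long-format table with one row per monoisotopic mass and
one row per isotopologue, linked by the suspect id — the layout used by
the downstream matching and isotope-scoring stages.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from pfas_screen.chem import (
    DEPROTONATED,
    Descriptors,
    FormulaError,
    IonForm,
    Isotopologue,
    MolecularFormula,
    charged_mass,
    descriptors,
    isotopologues,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "SchemaError",
    "RawSuspectRecord",
    "SuspectEntry",
    "SuspectList",
    "COUNTERION_REGISTRY",
    "load_raw_list",
    "strip_counterion",
    "classify_ionizability",
    "build_suspect_list",
]

#: Recognized monovalent counter-cations, symbol -> composition.
#: Multivalent salts (Ca, Mg, ...) are deliberately absent: stripping half
#: a cation would require fabricating a charge state, so such entries fall
#: back to neutral-parent treatment with a warning.
COUNTERION_REGISTRY: dict[str, dict[str, int]] = {
    "Na": {"Na": 1},
    "K": {"K": 1},
    "Li": {"Li": 1},
    "NH4": {"N": 1, "H": 4},
    "Cs": {"Cs": 1},
    "Ag": {"Ag": 1},
}

_SMILES_CATION_RE = re.compile(r"^\[(Na|K|Li|Cs|Ag|NH4)\+\]$")

ACIDIC = "acidic"
ELECTROPOSITIVE = "electropositive"
NON_IONIZABLE = "non_ionizable"


class SchemaError(ValueError):
    """Raised when the raw CSV does not follow the expected template."""


@dataclass
class RawSuspectRecord:
    """One row of the raw suspect CSV, before any recomputation."""

    id: str
    formula_text: str
    smiles: str | None = None
    inchikey: str | None = None
    iupac_name: str | None = None
    qc_level: int | None = None
    pka_acidic: float | None = None
    pka_basic: float | None = None


@dataclass
class SuspectEntry:
    """One curated suspect: recomputed masses plus screening metadata."""

    id: str
    neutral_formula: MolecularFormula
    neutral_mass: float
    charged_mass: float
    is_salt: bool
    counterion: str | None
    isotopologues: list[Isotopologue]
    descriptors: Descriptors
    qc_level: int | None
    pka_acidic: float | None
    pka_basic: float | None
    ionizability: str


@dataclass
class SuspectList:
    """Curated suspect entries plus the long-format export table."""

    entries: list[SuspectEntry]
    table: pd.DataFrame
    rejects: pd.DataFrame

    def __len__(self) -> int:
        return len(self.entries)

    def by_id(self, suspect_id: str) -> SuspectEntry:
        for e in self.entries:
            if e.id == suspect_id:
                return e
        raise KeyError(suspect_id)

    def to_csv(self, path: str | Path) -> None:
        """Write the long-format table (mono + isotopologue rows)."""
        self.table.to_csv(path, index=False)

    def to_raw_csv(self, path: str | Path) -> None:
        """Write a raw-template CSV that rebuilds this list identically."""
        rows = []
        for e in self.entries:
            formula = e.neutral_formula.hill()
            if e.is_salt and e.counterion:
                # re-attach the counter-ion, minus the acid proton it replaced
                anion = {
                    el: n for el, n in e.neutral_formula.counts.items()
                }
                anion["H"] = anion.get("H", 0) - 1
                anion = {el: n for el, n in anion.items() if n > 0}
                formula = (
                    MolecularFormula(anion).hill() + "." + e.counterion
                )
            rows.append(
                {
                    "Molecular formula": formula,
                    "id": e.id,
                    "qc_level": e.qc_level,
                    "pka_acidic": e.pka_acidic,
                    "pka_basic": e.pka_basic,
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


_OPTIONAL_COLUMNS = {
    "smiles": "smiles",
    "inchikey": "inchikey",
    "inchi key": "inchikey",
    "iupac name": "iupac_name",
    "iupac_name": "iupac_name",
    "qc level": "qc_level",
    "qc_level": "qc_level",
    "pka acidic": "pka_acidic",
    "pka_acidic": "pka_acidic",
    "pka basic": "pka_basic",
    "pka_basic": "pka_basic",
    "id": "id",
    "dtxsid": "id",
}


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def load_raw_list(path: str | Path) -> list[RawSuspectRecord]:
    """Read a raw suspect CSV into records.

    The first column must be named ``"Molecular formula"`` (the template
    contract); optional identifier / QC / pKa columns are picked up by
    name, case-insensitively.  Formula validity is *not* checked here —
    unparseable rows surface in the rejects report of
    :func:`build_suspect_list`, never as a hard failure.
    """
    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.columns[0].strip() != "Molecular formula":
        raise SchemaError(
            'first column must be labeled "Molecular formula", got '
            f"{df.columns[0]!r}" if df.shape[1] else "empty CSV"
        )
    colmap: dict[str, str] = {}
    for col in df.columns[1:]:
        key = col.strip().lower()
        if key in _OPTIONAL_COLUMNS:
            colmap[_OPTIONAL_COLUMNS[key]] = col
    records: list[RawSuspectRecord] = []
    for i, row in df.iterrows():
        def get(field):
            col = colmap.get(field)
            return row[col] if col is not None else None

        rid = _opt_str(get("id")) or f"S{i + 1:05d}"
        qc = get("qc_level")
        qc = int(qc) if qc is not None and not pd.isna(qc) else None
        if qc is not None and not 1 <= qc <= 5:
            raise SchemaError(f"qc_level {qc} outside 1..5 for row {rid}")

        def num(field):
            v = get(field)
            return float(v) if v is not None and not pd.isna(v) else None

        records.append(
            RawSuspectRecord(
                id=rid,
                formula_text=_opt_str(row.iloc[0]) or "",
                smiles=_opt_str(get("smiles")),
                inchikey=_opt_str(get("inchikey")),
                iupac_name=_opt_str(get("iupac_name")),
                qc_level=qc,
                pka_acidic=num("pka_acidic"),
                pka_basic=num("pka_basic"),
            )
        )
    return records


def _formula_from_smiles(smiles: str) -> str | None:
    """Molecular formula of the largest SMILES component, if rdkit exists."""
    try:
        from rdkit import Chem
        from rdkit.Chem.rdMolDescriptors import CalcMolFormula
    except ImportError:  # pragma: no cover - rdkit is an optional extra
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return re.sub(r"[+-]+$", "", CalcMolFormula(mol))


def _salt_components(record: RawSuspectRecord) -> list[str] | None:
    """Dot-separated formula components if the record looks like a salt."""
    if "." in record.formula_text:
        return [c.strip() for c in record.formula_text.split(".") if c.strip()]
    if record.smiles and "." in record.smiles:
        parts = [p.strip() for p in record.smiles.split(".")]
        cations = [p for p in parts if _SMILES_CATION_RE.match(p)]
        if cations:
            # formula column holds the whole salt; name the cation from SMILES
            cation = _SMILES_CATION_RE.match(cations[0]).group(1)
            return [record.formula_text, cation]
    return None


def strip_counterion(
    record: RawSuspectRecord,
) -> tuple[MolecularFormula, str | None]:
    """Remove one recognized counter-cation from a salt record.

    Returns the anion composition (used downstream for the charged mass)
    and the counter-ion name.  Unrecognized counter-ions keep the entry
    with a warning, treated as a neutral parent — conservative, so that
    no compound is silently excluded from the screening.
    """
    components = _salt_components(record)
    if components is None:
        return parse_formula(record.formula_text), None
    cation_names = [c for c in components if c in COUNTERION_REGISTRY]
    if len(cation_names) != 1 or len(components) != 2:
        warnings.warn(
            f"suspect {record.id}: unrecognized or multivalent counter-ion in "
            f"{record.formula_text!r}; treated as neutral parent",
            stacklevel=2,
        )
        merged = None
        for comp in components:
            f = parse_formula(comp)
            merged = f if merged is None else merged + f
        return merged, None
    cation = cation_names[0]
    anion_text = next(c for c in components if c != cation)
    return parse_formula(anion_text), cation


def classify_ionizability(
    pka_acidic: float | None,
    pka_basic: float | None,
    formula: MolecularFormula | None = None,
) -> str:
    """Negative-ESI ionizability class from predicted pKa values.

    A present acidic pKa means the suspect can deprotonate (``acidic``);
    a basic pKa alone means it only ionizes in positive mode
    (``electropositive``); with neither it is ``non_ionizable`` — this
    covers H-free compositions such as perfluorohexane, which lack an
    acidic site entirely.
    """
    if pka_acidic is not None:
        return ACIDIC
    if pka_basic is not None:
        return ELECTROPOSITIVE
    return NON_IONIZABLE


def _curate_one(record: RawSuspectRecord, ion: IonForm) -> SuspectEntry:
    formula_text = record.formula_text
    if not formula_text and record.smiles:
        derived = _formula_from_smiles(record.smiles)
        if derived:
            formula_text = derived
    already_charged = formula_text.endswith("-")
    if already_charged:
        formula_text = formula_text[:-1]
        record = RawSuspectRecord(**{**record.__dict__, "formula_text": formula_text})

    anion_or_neutral, counterion = strip_counterion(record)
    is_salt = counterion is not None
    if is_salt:
        # re-protonate the stripped anion: salt and free acid then share
        # the exact same neutral parent, hence a bit-identical charged mass
        neutral_formula = anion_or_neutral + MolecularFormula({"H": 1})
    else:
        neutral_formula = anion_or_neutral
    neutral_mass = monoisotopic_mass(neutral_formula)
    if already_charged:
        mz = monoisotopic_mass(anion_or_neutral)
    else:
        mz = charged_mass(neutral_mass, ion)
    return SuspectEntry(
        id=record.id,
        neutral_formula=neutral_formula,
        neutral_mass=neutral_mass,
        charged_mass=mz,
        is_salt=is_salt,
        counterion=counterion,
        isotopologues=isotopologues(neutral_formula, parent_id=record.id),
        descriptors=descriptors(neutral_formula, mz),
        qc_level=record.qc_level,
        pka_acidic=record.pka_acidic,
        pka_basic=record.pka_basic,
        ionizability=classify_ionizability(
            record.pka_acidic, record.pka_basic, neutral_formula
        ),
    )


def build_suspect_list(
    records: Sequence[RawSuspectRecord],
    ion: IonForm = DEPROTONATED,
) -> SuspectList:
    """Curate raw records into a suspect list.

    Masses are always recomputed from the formula; any mass column in the
    input is ignored.  The long-format table holds one ``mono`` row per
    accepted suspect plus one row per isotopologue, linked by
    ``parent_id``.  Rows that cannot be curated are collected in
    ``rejects`` with a reason — never silently dropped.
    """
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate suspect id: {rec.id}")
        seen.add(rec.id)

    entries: list[SuspectEntry] = []
    rejects: list[dict] = []
    for rec in records:
        try:
            entries.append(_curate_one(rec, ion))
        except (FormulaError, ValueError) as exc:
            rejects.append(
                {"id": rec.id, "formula": rec.formula_text, "reason": str(exc)}
            )

    rows: list[dict] = []
    for e in entries:
        base = {
            "parent_id": e.id,
            "neutral_mass": e.neutral_mass,
            "qc_level": e.qc_level,
            "pka_acidic": e.pka_acidic,
            "pka_basic": e.pka_basic,
            "ionizability": e.ionizability,
            "is_salt": e.is_salt,
            "counterion": e.counterion,
            "formula": e.neutral_formula.hill(),
        }
        rows.append(
            {
                "id": e.id,
                "label": "mono",
                "charged_mass": e.charged_mass,
                "relative_abundance": 1.0,
                **base,
                **e.descriptors.as_dict(),
            }
        )
        for iso in e.isotopologues:
            rows.append(
                {
                    "id": f"{e.id}__{iso.label}",
                    "label": iso.label,
                    "charged_mass": e.charged_mass + iso.mass_shift,
                    "relative_abundance": iso.relative_abundance,
                    **base,
                }
            )
    table = pd.DataFrame(rows)
    rejects_df = pd.DataFrame(rejects, columns=["id", "formula", "reason"])
    return SuspectList(entries=entries, table=table, rejects=rejects_df)
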