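"""Molecule library I/O, SMILES canonicalization, deduplication and atom statistics.

A *library* is an ordered list of :class:`MoleculeRecord`. Records enter from
CSV/TSV tables (columns ``id,name,smiles`` plus optional ``other_names``,
``biosynthetic_type``) or from SDF, are canonicalized with RDKit, and are
merged so that one record represents each unique structure. Identity is
defined on the canonical SMILES string, which makes deduplication and
known-structure exclusion exact and reproducible.

Canonicalization policy (see :func:`canonicalize`):

* the largest covalent fragment is kept (counter-ions and solvents dropped),
* simple protonation states are neutralized, so carboxylate and
  carboxylic-acid spellings of one compound collapse,
* stereochemistry is retained by default — stereoisomeric siderophores are
  distinct structures — with an ``ignore_stereo`` switch for sensitivity
  analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

BIOSYNTHETIC_TYPES = ("NRPS", "NIS", "NRPS+NIS", "PKS-hybrid", "unknown")
SOURCE_TAGS = ("knownset", "background", "query")

__all__ = [
    "MoleculeRecord",
    "ElementStats",
    "ParseError",
    "canonicalize",
    "mol_from_record",
    "deduplicate",
    "read_library",
    "write_library",
    "element_stats",
]


class ParseError(ValueError):
    """A SMILES string or SDF block could not be parsed.

    Carries ``record_id`` so that batch jobs can name the offending record.
    """

    def __init__(self, message: str, record_id: Optional[str] = None):
        self.record_id = record_id
        if record_id is not None:
            message = f"record {record_id!r}: {message}"
        super().__init__(message)


@dataclass
class MoleculeRecord:
    """One library entry: raw and canonical SMILES plus metadata."""

    record_id: str
    name: str
    smiles_raw: str
    smiles_canonical: str = ""
    other_names: list[str] = field(default_factory=list)
    biosynthetic_type: str = "unknown"
    source_tag: str = "query"

    def __post_init__(self) -> None:
        if self.biosynthetic_type not in BIOSYNTHETIC_TYPES:
            raise ValueError(
                f"record {self.record_id!r}: unknown biosynthetic_type "
                f"{self.biosynthetic_type!r} (expected one of {BIOSYNTHETIC_TYPES})"
            )
        if self.source_tag not in SOURCE_TAGS:
            raise ValueError(
                f"record {self.record_id!r}: unknown source_tag {self.source_tag!r}"
            )
        if not self.smiles_canonical:
            self.smiles_canonical = canonicalize(
                self.smiles_raw, record_id=self.record_id
            )


@dataclass(frozen=True)
class ElementStats:
    """C/N/O atom counts and ratios for one molecule.

    Ratios are ``None`` (undefined), never zero, when the denominator
    element is absent. Implicit hydrogens are not counted.
    """

    n_C: int
    n_N: int
    n_O: int

    @property
    def ratio_CN(self) -> Optional[Fraction]:
        return Fraction(self.n_C, self.n_N) if self.n_N else None

    @property
    def ratio_CO(self) -> Optional[Fraction]:
        return Fraction(self.n_C, self.n_O) if self.n_O else None


_UNCHARGER = rdMolStandardize.Uncharger()


def canonicalize(
    smiles: str,
    *,
    ignore_stereo: bool = False,
    strip_salts: bool = True,
    neutralize: bool = True,
    record_id: Optional[str] = None,
) -> str:
    """Return RDKit's canonical SMILES for ``smiles``.

    The result is idempotent: canonicalizing the output returns the output.
    Two SMILES spellings of the same molecular graph map to the same string.

    Parameters
    ----------
    ignore_stereo:
        Drop stereo descriptors before canonicalizing. Off by default:
        stereoisomers are treated as distinct structures.
    strip_salts:
        Keep only the largest covalent fragment; every dropped fragment is
        logged at INFO level.
    neutralize:
        Neutralize simple protonation states (e.g. carboxylate anions) so
        charge-state spellings collapse to one structure.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES {smiles!r}", record_id)
    if strip_salts:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            frags = sorted(frags, key=lambda m: (m.GetNumAtoms(), Chem.MolToSmiles(m)))
            mol = frags[-1]
            for frag in frags[:-1]:
                logger.info(
                    "stripped fragment %s from %s",
                    Chem.MolToSmiles(frag),
                    record_id or smiles,
                )
    if neutralize:
        mol = _UNCHARGER.uncharge(mol)
    if ignore_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol, isomericSmiles=not ignore_stereo)


def mol_from_record(record: MoleculeRecord) -> Chem.Mol:
    """RDKit molecule for a record's canonical SMILES."""
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:  # canonical SMILES always round-trips; guard anyway
        raise ParseError(
            f"canonical SMILES {record.smiles_canonical!r} failed to re-parse",
            record.record_id,
        )
    return mol


def deduplicate(
    records: Sequence[MoleculeRecord], *, sort_names: bool = False
) -> list[MoleculeRecord]:
    """Merge records that share a canonical SMILES.

    One output record per unique structure, in first-seen order. The
    first-seen record supplies ``record_id`` and the official ``name``;
    the names of merged duplicates are appended to ``other_names``. With
    ``sort_names=True`` the lexicographically first name among the merged
    records becomes official instead, which makes the representative
    independent of input order.

    A duplicate with a known biosynthetic type fills in the representative's
    type when the representative's own is ``unknown``.
    """
    merged: dict[str, MoleculeRecord] = {}
    for rec in records:
        key = rec.smiles_canonical
        if key not in merged:
            merged[key] = replace(rec, other_names=list(rec.other_names))
            continue
        kept = merged[key]
        for name in [rec.name, *rec.other_names]:
            if name and name != kept.name and name not in kept.other_names:
                kept.other_names.append(name)
        if kept.biosynthetic_type == "unknown" and rec.biosynthetic_type != "unknown":
            kept.biosynthetic_type = rec.biosynthetic_type
    out = list(merged.values())
    if sort_names:
        for rec in out:
            names = sorted([rec.name, *rec.other_names])
            rec.name = names[0]
            rec.other_names = names[1:]
    return out


_REQUIRED_COLUMNS = ("id", "name", "smiles")


def _records_from_frame(df: pd.DataFrame, source_tag: str) -> list[MoleculeRecord]:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    ids = df["id"].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate record_id(s): {', '.join(sorted(set(dup)))}")
    records = []
    for _, row in df.iterrows():
        other = row.get("other_names", "")
        other_names = (
            [n for n in str(other).split("|") if n] if pd.notna(other) else []
        )
        btype = row.get("biosynthetic_type", "unknown")
        records.append(
            MoleculeRecord(
                record_id=str(row["id"]),
                name=str(row["name"]),
                smiles_raw=str(row["smiles"]),
                other_names=other_names,
                biosynthetic_type=str(btype) if pd.notna(btype) else "unknown",
                source_tag=source_tag,
            )
        )
    return records


def _infer_format(path: Path) -> str:
    return "sdf" if path.suffix.lower() == ".sdf" else "smiles-table"


def read_library(
    path: str | Path,
    format: Optional[str] = None,
    *,
    source_tag: str = "query",
) -> list[MoleculeRecord]:
    """Read a molecule library from a SMILES table (CSV/TSV) or SDF file.

    Table format requires columns ``id,name,smiles``; ``other_names`` is
    pipe-separated. Format is inferred from the suffix when not given.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "smiles-table":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        return _records_from_frame(df, source_tag)
    if fmt == "sdf":
        records = []
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ParseError(f"malformed SDF molblock at index {i}", str(i))
            rid = mol.GetProp("record_id") if mol.HasProp("record_id") else str(i)
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else rid
            smi = Chem.MolToSmiles(mol)
            records.append(
                MoleculeRecord(record_id=rid, name=name, smiles_raw=smi,
                               source_tag=source_tag)
            )
        ids = [r.record_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record_id(s) in SDF")
        return records
    raise ValueError(f"unknown library format {fmt!r}")


def library_frame(records: Iterable[MoleculeRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the table-file column layout."""
    return pd.DataFrame(
        {
            "id": [r.record_id for r in records],
            "name": [r.name for r in records],
            "smiles": [r.smiles_canonical for r in records],
            "other_names": ["|".join(r.other_names) for r in records],
            "biosynthetic_type": [r.biosynthetic_type for r in records],
        }
    )


def write_library(
    records: Sequence[MoleculeRecord],
    path: str | Path,
    format: Optional[str] = None,
) -> None:
    """Write records to CSV/TSV or SDF (UTF-8). Round-trips id/name/SMILES."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "smiles-table":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        library_frame(records).to_csv(path, sep=sep, index=False)
        return
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for rec in records:
                mol = mol_from_record(rec)
                mol.SetProp("_Name", rec.name)
                mol.SetProp("record_id", rec.record_id)
                writer.write(mol)
        finally:
            writer.close()
        return
    raise ValueError(f"unknown library format {fmt!r}")


def element_stats(record: MoleculeRecord) -> ElementStats:
    """Count C, N and O atoms (heavy atoms only; implicit H ignored)."""
    mol = mol_from_record(record)
    counts = {"C": 0, "N": 0, "O": 0}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
    return ElementStats(n_C=counts["C"], n_N=counts["N"], n_O=counts["O"])
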