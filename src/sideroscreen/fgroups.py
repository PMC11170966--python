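"""Siderophore functional-group registry and substructure matching.

Siderophores chelate ferric iron through a small repertoire of
oxygen/nitrogen donor moieties — hydroxamate, catecholate, phenolate,
citrate-derived carboxylates, and several rarer groups. The default
registry holds one SMARTS query per group in three categories:

``searchable``
    The 15 iron-coordinating groups whose presence flags a molecule as a
    potential siderophore.
``common_excluded``
    Groups that do coordinate iron but are too ubiquitous in ordinary
    metabolites to be informative (free carboxylate, free
    alpha-hydroxycarboxylate). They are profiled and reported, but never
    trigger candidacy.
``modified_veto``
    Eight chemically blocked variants — O-alkylated or O-acylated forms of
    the donor oxygens — that cannot form coordination bonds. Their presence
    vetoes the molecule.

Every searchable SMARTS requires a free ([OX2H1]) donor hydroxyl where the
chemistry demands one, so a veto pattern can never co-count as its intact
parent on the same atom set.

Matching is non-redundant: symmetry-equivalent automorphic hits that cover
the identical atom set are counted once.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem

from .chemio import MoleculeRecord, mol_from_record

CATEGORIES = ("searchable", "common_excluded", "modified_veto")

__all__ = [
    "PatternDef",
    "MatchProfile",
    "load_default_patterns",
    "load_pattern_table",
    "dump_pattern_table",
    "match_groups",
    "match_mol",
    "count_matrix",
    "REGISTRY_VERSION",
]

REGISTRY_VERSION = "1.0"


@dataclass(frozen=True)
class PatternDef:
    """One named substructure pattern.

    ``exemplar`` names a literature siderophore (or blocked analogue) that
    displays the group, so the SMARTS transcription can be audited against
    a published structure.
    """

    group_name: str
    category: str
    smarts: str
    rarity: str = "common"  # 'common' or 'rare' among known siderophores
    exemplar: str = ""

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(
                f"pattern {self.group_name!r}: bad category {self.category!r}"
            )
        if self.query is None:
            raise ValueError(
                f"pattern {self.group_name!r}: SMARTS does not compile: "
                f"{self.smarts!r}"
            )

    @property
    def query(self) -> Optional[Chem.Mol]:
        return Chem.MolFromSmarts(self.smarts)


# The default registry. Donor hydroxyls are written [OX2H1] so that any
# O-substitution (the veto chemistry) breaks the match; aromatic systems use
# RDKit's default aromaticity perception.
_DEFAULTS: list[tuple[str, str, str, str, str]] = [
    # --- searchable: the 15 iron-coordinating groups -----------------------
    ("hydroxamate", "searchable",
     "[CX3](=[OX1])[NX3][OX2H1]",
     "common", "desferrioxamine B"),
    ("catecholate", "searchable",
     "[OX2H1]c1ccccc1[OX2H1]",
     "common", "enterobactin"),
    # ortho-hydroxyphenyl adjacent to a carbonyl or 2-azoline carbon; the
    # catechol case (second ring OH ortho to the first) is carved out so a
    # catecholate site is not double-read as phenolate.
    ("phenolate", "searchable",
     "[OX2H1;$([OX2H1]c1ccccc1[CX3]=[OX1]),"
     "$([OX2H1]c1ccccc1[CX3]2=[NX2][CX4][CX4][S,O]2);"
     "!$([OX2H1]c1c([OX2H1])cccc1);!$([OX2H1]c1ccccc1[OX2H1])]",
     "common", "yersiniabactin (salicyl moiety)"),
    # citrate contexts: a citrate incorporated into a siderophore carries at
    # least one amide arm; free citric acid (no amide) matches neither.
    ("carboxylate-in-citrate", "searchable",
     "[OX2H1,OX1-][CX3](=[OX1])[CH2][CX4]([OX2H1])"
     "([CX3](=[OX1])[OX2H1,OX1-])[CH2][CX3](=[OX1])[NX3]",
     "common", "rhizoferrin"),
    ("alpha-hydroxycarboxylate-in-citrate", "searchable",
     "[OX2H1][CX4]([CX3](=[OX1])[OX2H1,OX1-])"
     "([CH2][CX3](=[OX1])[NX3])[CH2][CX3]=[OX1]",
     "common", "aerobactin"),
    ("alpha-aminocarboxylate", "searchable",
     "[NX3H2,NX4H3+;!$([N]C=[O,N,S])][CX4][CX3](=[OX1])[OX2H1,OX1-]",
     "common", "staphyloferrin A (ornithine arm)"),
    ("hydroxyphenyloxazoline", "searchable",
     "[OX2H1]c1ccccc1[CX3]2=[NX2][CX4][CX4][OX2]2",
     "common", "vibriobactin"),
    ("hydroxyphenylthiazoline", "searchable",
     "[OX2H1]c1ccccc1[CX3]2=[NX2][CX4][CX4][SX2]2",
     "common", "pyochelin"),
    ("hydroxyphenylthiazolidine", "searchable",
     "[OX2H1]c1ccccc1[CX4]2[NX3][CX4][CX4][SX2]2",
     "rare", "reduced pyochelin-type"),
    ("alpha-hydroxyimidazole", "searchable",
     "[OX2H1][CX4]c1c[nX3H,nX2][c][nX3H,nX2]1",
     "rare", "beta-hydroxyhistidine (ornibactin-type)"),
    ("diazeniumdiolate", "searchable",
     "[OX2H1,OX1-][NX3][NX2]=[OX1]",
     "rare", "gramibactin (graminine)"),
    ("2-nitrosophenol", "searchable",
     "[OX2H1]c1ccccc1[NX2]=[OX1]",
     "rare", "ferroverdin-type"),
    ("1-hydroxy-2-pyridinone", "searchable",
     "[OX2H1][#7;X3]1[#6](=[OX1])[#6]~[#6]~[#6]~[#6]1",
     "rare", "cepabactin"),
    ("3-hydroxy-4-pyridinone", "searchable",
     "[OX2H1][#6]1~[#6](~[OX1])~[#6]~[#6]~[#7]~[#6]1",
     "rare", "mimosine-type"),
    ("beta-hydroxyaspartate", "searchable",
     "[NX3][CX4]([CX3](=[OX1])[OX2H1,OX1-,NX3])[CX4]([OX2H1])"
     "[CX3](=[OX1])[OX2H1,OX1-]",
     "rare", "alterobactin-type"),
    # --- common excluded: chelating but ubiquitous -------------------------
    ("alpha-hydroxycarboxylate", "common_excluded",
     "[OX2H1][CX4][CX3](=[OX1])[OX2H1,OX1-]",
     "common", "citric acid"),
    ("carboxylate", "common_excluded",
     "[CX3;!$([CX3][NX3]);!$([CX3][OX2][#6])](=[OX1])[OX2H1,OX1-]",
     "common", "any free acid"),
    # --- modified vetoes: blocked donor oxygens ----------------------------
    ("O-alkyl-hydroxamate", "modified_veto",
     "[CX3](=[OX1])[NX3][OX2][CX4]",
     "common", "O-methylated desferrioxamine"),
    ("O-acyl-hydroxamate", "modified_veto",
     "[CX3](=[OX1])[NX3][OX2][CX3]=[OX1]",
     "common", "O-acetylated hydroxamate"),
    ("O-alkyl-catecholate", "modified_veto",
     "[#6][OX2]c1ccccc1[OX2;H1,$([OX2][#6])]",
     "common", "catechol mono/di-ether (guaiacol motif)"),
    ("O-alkyl-phenolate", "modified_veto",
     "[CX4][OX2]c1ccccc1[CX3]=[OX1]",
     "common", "O-methyl salicylate"),
    ("O-alkyl-hydroxyphenyl-azoline", "modified_veto",
     "[CX4][OX2]c1ccccc1[CX3]2=[NX2][CX4][CX4][S,O]2",
     "common", "O-methylated salicyl-oxazoline/thiazoline"),
    ("citrate-ester", "modified_veto",
     "[#6][OX2][CX3](=[OX1])[CH2][CX4]([OX2H1,OX2&$([OX2][#6])])"
     "([CX3]=[OX1])[CH2][CX3]=[OX1]",
     "common", "citrate arm esterified"),
    ("O-alkyl-alpha-hydroxycarboxylate-in-citrate", "modified_veto",
     "[CX4,CX3&$([CX3]=[OX1])][OX2][CX4]([CX3](=[OX1])[OX2H1,OX1-])"
     "([CH2][CX3](=[OX1])[NX3])[CH2][CX3]=[OX1]",
     "common", "citrate alpha-hydroxyl etherified"),
    ("O-alkyl-2-nitrosophenol", "modified_veto",
     "[#6][OX2]c1ccccc1[NX2]=[OX1]",
     "common", "O-methyl nitrosophenol"),
]

DEFAULT_PATTERNS: tuple[PatternDef, ...] = tuple(
    PatternDef(group_name=name, category=cat, smarts=smarts,
               rarity=rarity, exemplar=exemplar)
    for name, cat, smarts, rarity, exemplar in _DEFAULTS
)

N_SEARCHABLE = 15
N_VETO = 8


def _validate_registry(patterns: Sequence[PatternDef]) -> None:
    names = [p.group_name for p in patterns]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group_name in pattern registry")


def load_default_patterns(
    override_path: Optional[str | Path] = None,
) -> list[PatternDef]:
    """Return the default registry, or one loaded from an override table.

    The override is a TSV with columns ``group_name,category,smarts,rarity``
    (optional ``exemplar``). A non-compiling SMARTS raises a ``ValueError``
    naming the group.
    """
    if override_path is None:
        return list(DEFAULT_PATTERNS)
    return load_pattern_table(override_path)


def load_pattern_table(path: str | Path) -> list[PatternDef]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"group_name", "category", "smarts", "rarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pattern table missing column(s): {sorted(missing)}")
    patterns = [
        PatternDef(
            group_name=row["group_name"],
            category=row["category"],
            smarts=row["smarts"],
            rarity=row["rarity"] or "common",
            exemplar=row.get("exemplar", ""),
        )
        for _, row in df.iterrows()
    ]
    _validate_registry(patterns)
    return patterns


def dump_pattern_table(patterns: Sequence[PatternDef], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["group_name", "category", "smarts", "rarity", "exemplar"])
        for p in patterns:
            writer.writerow([p.group_name, p.category, p.smarts, p.rarity, p.exemplar])


@dataclass
class MatchProfile:
    """Per-molecule non-redundant match counts for every pattern."""

    record_id: str
    counts: dict[str, int] = field(default_factory=dict)
    matched_atoms: dict[str, list[frozenset[int]]] = field(default_factory=dict)

    def groups_with_hits(self, category: str, patterns: Sequence[PatternDef]) -> list[str]:
        by_name = {p.group_name: p for p in patterns}
        return [
            g
            for g, n in self.counts.items()
            if n > 0 and g in by_name and by_name[g].category == category
        ]


def match_mol(mol: Chem.Mol, patterns: Sequence[PatternDef],
              record_id: str = "") -> MatchProfile:
    """Match every pattern against an RDKit molecule.

    Substructure hits covering the identical atom set (automorphic
    symmetry images) are collapsed to one.
    """
    profile = MatchProfile(record_id=record_id)
    for pat in patterns:
        raw = mol.GetSubstructMatches(pat.query, uniquify=True, maxMatches=10000)
        seen: list[frozenset[int]] = []
        for match in raw:
            atoms = frozenset(match)
            if atoms not in seen:
                seen.append(atoms)
        profile.counts[pat.group_name] = len(seen)
        profile.matched_atoms[pat.group_name] = seen
    return profile


def match_groups(
    record: MoleculeRecord, patterns: Optional[Sequence[PatternDef]] = None
) -> MatchProfile:
    """Match a record's canonical structure against the registry."""
    if patterns is None:
        patterns = DEFAULT_PATTERNS
    return match_mol(mol_from_record(record), patterns, record.record_id)


def count_matrix(
    records: Iterable[MoleculeRecord],
    patterns: Optional[Sequence[PatternDef]] = None,
) -> pd.DataFrame:
    """Records x groups table of non-redundant match counts."""
    if patterns is None:
        patterns = DEFAULT_PATTERNS
    rows = {}
    for rec in records:
        rows[rec.record_id] = match_groups(rec, patterns).counts
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    columns = [p.group_name for p in patterns]
    return df.reindex(columns=columns) if len(df) else pd.DataFrame(columns=columns)
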