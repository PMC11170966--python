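"""Download-free test bed: curated siderophores, decoys, veto constructs.

The reference set holds literature-standard structures spanning the four
major siderophore chemistries — catecholate (enterobactin, bacillibactin,
vibriobactin), hydroxamate (desferrioxamines B and E, ferrichrome),
citrate/carboxylate (aerobactin, schizokinen, rhizoferrin, staphyloferrin
A), and phenolate/oxazoline-thiazoline (yersiniabactin, pyochelin), plus
the hydroxypyridinone cepabactin. SMILES are transcribed from the primary
literature / PubChem depictions of the published structures; no stereo
descriptors are carried because the functional-group rules and circular
fingerprints used here are stereo-agnostic.

Each reference record is annotated with hand-derived expected counts for
its diagnostic functional groups, so matcher output can be checked against
an independent reading of the published structure.

``veto_constructs`` are references whose chelating oxygens have been
O-methylated — the modification that abolishes iron coordination — giving
close structural analogues that must be vetoed.

``make_library`` mixes these parts into a seeded, byte-reproducible
library file for end-to-end tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .chemio import MoleculeRecord, write_library

__all__ = [
    "FixtureSpec",
    "reference_set",
    "decoy_set",
    "veto_constructs",
    "make_library",
    "EXPECTED_GROUP_COUNTS",
]

# (id, name, smiles, biosynthetic_type)
_REFERENCES = [
    ("F1", "enterobactin",
     "C1C(C(=O)OCC(C(=O)OCC(C(=O)O1)NC(=O)c1cccc(O)c1O)NC(=O)c1cccc(O)c1O)"
     "NC(=O)c1cccc(O)c1O",
     "NRPS"),
    ("F2", "bacillibactin",
     "CC1OC(=O)C(NC(=O)CNC(=O)c2cccc(O)c2O)C(C)OC(=O)C(NC(=O)CNC(=O)"
     "c2cccc(O)c2O)C(C)OC(=O)C1NC(=O)CNC(=O)c1cccc(O)c1O",
     "NRPS"),
    ("F3", "desferrioxamine B",
     "CC(=O)N(O)CCCCCNC(=O)CCC(=O)N(O)CCCCCNC(=O)CCC(=O)N(O)CCCCCN",
     "NIS"),
    ("F4", "desferrioxamine E",
     "O=C1CCC(=O)N(O)CCCCCNC(=O)CCC(=O)N(O)CCCCCNC(=O)CCC(=O)N(O)CCCCCN1",
     "NIS"),
    ("F5", "ferrichrome",
     "O=C1CNC(=O)CNC(=O)CNC(=O)C(CCCN(O)C(C)=O)NC(=O)C(CCCN(O)C(C)=O)"
     "NC(=O)C(CCCN(O)C(C)=O)N1",
     "NRPS"),
    ("F6", "aerobactin",
     "CC(=O)N(O)CCCCC(C(=O)O)NC(=O)CC(O)(C(=O)O)CC(=O)NC(CCCCN(O)C(C)=O)"
     "C(=O)O",
     "NIS"),
    ("F7", "schizokinen",
     "CC(=O)N(O)CCCNC(=O)CC(O)(C(=O)O)CC(=O)NCCCN(O)C(C)=O",
     "NIS"),
    ("F8", "rhizoferrin",
     "OC(=O)CC(O)(C(=O)O)CC(=O)NCCCCNC(=O)CC(O)(C(=O)O)CC(=O)O",
     "NIS"),
    ("F9", "staphyloferrin A",
     "OC(=O)CC(O)(C(=O)O)CC(=O)NCCCC(NC(=O)CC(O)(C(=O)O)CC(=O)O)C(=O)O",
     "NIS"),
    ("F10", "yersiniabactin",
     "CC(C)(C1CSC(N1)C2CSC(=N2)c3ccccc3O)C(O)C4=NC(CS4)C(=O)O",
     "NRPS"),
    ("F11", "pyochelin",
     "CN1C(C(=O)O)CSC1C1CSC(=N1)c1ccccc1O",
     "NRPS"),
    ("F12", "vibriobactin",
     "CC1OC(=NC1C(=O)NCCCN(CCCNC(=O)c1cccc(O)c1O)C(=O)C1N=C(OC1C)"
     "c1cccc(O)c1O)c1cccc(O)c1O",
     "NRPS"),
    ("F13", "cepabactin",
     "ON1C(=O)C=CC(OC)=C1C",
     "PKS-hybrid"),
]

# Hand-tallied diagnostic counts per reference structure (independent of
# the matcher: derived by reading the published structures).
EXPECTED_GROUP_COUNTS: dict[str, dict[str, int]] = {
    "F1": {"catecholate": 3, "hydroxamate": 0},
    "F2": {"catecholate": 3},
    "F3": {"hydroxamate": 3},
    "F4": {"hydroxamate": 3},
    "F5": {"hydroxamate": 3},
    "F6": {"hydroxamate": 2, "alpha-hydroxycarboxylate-in-citrate": 2},
    "F7": {"hydroxamate": 2, "alpha-hydroxycarboxylate-in-citrate": 2},
    "F8": {"carboxylate-in-citrate": 2, "alpha-hydroxycarboxylate-in-citrate": 2},
    "F9": {"carboxylate-in-citrate": 2, "alpha-aminocarboxylate": 0},
    "F10": {"phenolate": 1, "hydroxyphenylthiazoline": 1},
    "F11": {"phenolate": 1, "hydroxyphenylthiazoline": 1},
    "F12": {"catecholate": 3, "hydroxyphenyloxazoline": 2},
    "F13": {"1-hydroxy-2-pyridinone": 1},
}

# Natural-product-like molecules with no searchable iron-binding group.
_DECOYS = [
    ("D1", "glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("D2", "fructose", "OCC1(O)OCC(O)C(O)C1O"),
    ("D3", "sucrose", "OCC1OC(OC2(CO)OC(CO)C(O)C2O)C(O)C(O)C1O"),
    ("D4", "ribose", "OCC1OC(O)C(O)C1O"),
    ("D5", "caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("D6", "theobromine", "Cn1cnc2c1c(=O)[nH]c(=O)n2C"),
    ("D7", "theophylline", "Cn1c(=O)c2[nH]cnc2n(C)c1=O"),
    ("D8", "limonene", "CC1=CCC(CC1)C(=C)C"),
    ("D9", "alpha-pinene", "CC1=CCC2CC1C2(C)C"),
    ("D10", "menthol", "CC1CCC(C(C)C)C(O)C1"),
    ("D11", "geraniol", "CC(=CCCC(=CCO)C)C"),
    ("D12", "farnesol", "CC(=CCCC(=CCCC(=CCO)C)C)C"),
    ("D13", "cholesterol", "CC(C)CCCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)O)C)C"),
    ("D14", "palmitic acid", "CCCCCCCCCCCCCCCC(=O)O"),
    ("D15", "stearic acid", "CCCCCCCCCCCCCCCCCC(=O)O"),
    ("D16", "citric acid", "OC(=O)CC(O)(C(=O)O)CC(=O)O"),
    ("D17", "lactic acid", "CC(O)C(=O)O"),
    ("D18", "malic acid", "OC(=O)CC(O)C(=O)O"),
    ("D19", "indole", "c1ccc2[nH]ccc2c1"),
    ("D20", "cinnamaldehyde", "O=CC=Cc1ccccc1"),
]

# References with every chelating hydroxyl O-methylated (the modification
# of the veto rules); each stays structurally close to its parent.
_VETO_CONSTRUCTS = [
    ("V1", "tri-O-methyl desferrioxamine B", "F3",
     "CC(=O)N(OC)CCCCCNC(=O)CCC(=O)N(OC)CCCCCNC(=O)CCC(=O)N(OC)CCCCCN"),
    ("V2", "tri-O-methyl enterobactin", "F1",
     "C1C(C(=O)OCC(C(=O)OCC(C(=O)O1)NC(=O)c1cccc(O)c1OC)"
     "NC(=O)c1cccc(O)c1OC)NC(=O)c1cccc(O)c1OC"),
    ("V3", "di-O-methyl schizokinen", "F7",
     "CC(=O)N(OC)CCCNC(=O)CC(O)(C(=O)O)CC(=O)NCCCN(OC)C(C)=O"),
    ("V4", "O-methyl pyochelin", "F11",
     "CN1C(C(=O)O)CSC1C1CSC(=N1)c1ccccc1OC"),
]

VETO_PARENT: dict[str, str] = {vid: parent for vid, _, parent, _ in _VETO_CONSTRUCTS}


def reference_set() -> list[MoleculeRecord]:
    """Curated known siderophores spanning the four major chemistries."""
    return [
        MoleculeRecord(record_id=rid, name=name, smiles_raw=smi,
                       biosynthetic_type=btype, source_tag="knownset")
        for rid, name, smi, btype in _REFERENCES
    ]


def decoy_set() -> list[MoleculeRecord]:
    """Natural-product-like negatives: no searchable iron-binding group."""
    return [
        MoleculeRecord(record_id=rid, name=name, smiles_raw=smi,
                       source_tag="background")
        for rid, name, smi in _DECOYS
    ]


def veto_constructs() -> list[MoleculeRecord]:
    """Reference siderophores with chelating oxygens O-methylated."""
    return [
        MoleculeRecord(record_id=rid, name=name, smiles_raw=smi,
                       source_tag="query")
        for rid, name, _parent, smi in _VETO_CONSTRUCTS
    ]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a seeded synthetic screening library."""

    n_positives: int
    n_decoys: int
    n_veto_constructs: int
    seed: int
    positive_template_ids: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return self.n_positives + self.n_decoys + self.n_veto_constructs


def _sample(pool: list[MoleculeRecord], n: int, rng: random.Random,
            prefix: str) -> list[MoleculeRecord]:
    """Draw n records, cycling the pool with fresh suffixed ids as needed."""
    out: list[MoleculeRecord] = []
    while len(out) < n:
        take = rng.sample(pool, min(len(pool), n - len(out)))
        for rec in take:
            copy_idx = len(out)
            out.append(
                MoleculeRecord(
                    record_id=f"{prefix}{copy_idx + 1}_{rec.record_id}",
                    name=rec.name,
                    smiles_raw=rec.smiles_raw,
                    smiles_canonical=rec.smiles_canonical,
                    biosynthetic_type=rec.biosynthetic_type,
                    source_tag="query",
                )
            )
    return out


def make_library(spec: FixtureSpec, path: str | Path) -> list[MoleculeRecord]:
    """Write a seeded mixed library (CSV/TSV) and return its records.

    Positive ids carry prefix ``pos``, decoys ``neg``, veto constructs
    ``mod``, so tests can verify recovery by id. Same spec, same bytes.
    """
    rng = random.Random(spec.seed)
    refs = reference_set()
    if spec.positive_template_ids:
        wanted = set(spec.positive_template_ids)
        refs = [r for r in refs if r.record_id in wanted]
        if not refs:
            raise ValueError("positive_template_ids matched no reference")
    library = (
        _sample(refs, spec.n_positives, rng, "pos")
        + _sample(decoy_set(), spec.n_decoys, rng, "neg")
        + _sample(veto_constructs(), spec.n_veto_constructs, rng, "mod")
    )
    rng.shuffle(library)
    write_library(library, path)
    return library
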