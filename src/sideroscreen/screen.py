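"""Candidate screening: the functional-group rule with vetoes.

A molecule is a potential siderophore when it

1. contains at least one of the 15 searchable iron-coordinating groups,
2. contains none of the 8 modified (blocked) groups, and
3. is not itself a known siderophore structure.

The veto is global: a blocked group anywhere in the molecule rejects it,
even if intact groups are present elsewhere. A per-site alternative —
reject only when no intact searchable group remains — is available via
``veto_mode='per-site'`` but is off by default.

Known-structure exclusion is by exact canonical-SMILES identity, the only
reproducible reading of "known"; similarity-based novelty is a separate
question handled by :mod:`sideroscreen.simnet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .chemio import MoleculeRecord
from .fgroups import DEFAULT_PATTERNS, MatchProfile, PatternDef, match_groups

__all__ = ["ScreenDecision", "ScreenSummary", "decide", "screen_library",
           "iter_decisions"]


@dataclass(frozen=True)
class ScreenDecision:
    """Auditable verdict for one record."""

    record_id: str
    is_candidate: bool
    triggering_groups: tuple[str, ...]
    vetoing_groups: tuple[str, ...]
    excluded_known: bool


@dataclass
class ScreenSummary:
    """Stage counts for one screening run."""

    n_records: int = 0
    n_candidates: int = 0
    n_vetoed: int = 0
    n_known_excluded: int = 0
    n_no_trigger: int = 0

    def update(self, decision: ScreenDecision) -> None:
        self.n_records += 1
        if decision.is_candidate:
            self.n_candidates += 1
        if decision.vetoing_groups:
            self.n_vetoed += 1
        if decision.excluded_known:
            self.n_known_excluded += 1
        if not decision.triggering_groups:
            self.n_no_trigger += 1

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def decide(
    profile: MatchProfile,
    known_set: frozenset[str] | set[str],
    smiles_canonical: Optional[str] = None,
    patterns: Optional[Sequence[PatternDef]] = None,
    *,
    veto_mode: str = "global",
) -> ScreenDecision:
    """Apply the candidate rule to one match profile.

    ``known_set`` holds canonical SMILES of known siderophores;
    ``smiles_canonical`` is the molecule's own canonical SMILES (omit to
    skip the known-structure check). Only ``searchable`` groups can
    trigger; ``common_excluded`` groups (free carboxylate and free
    alpha-hydroxycarboxylate) never do.
    """
    if patterns is None:
        patterns = DEFAULT_PATTERNS
    if veto_mode not in ("global", "per-site"):
        raise ValueError(f"unknown veto_mode {veto_mode!r}")
    triggering = tuple(profile.groups_with_hits("searchable", patterns))
    vetoing = tuple(profile.groups_with_hits("modified_veto", patterns))
    excluded_known = (
        smiles_canonical is not None and smiles_canonical in known_set
    )
    if veto_mode == "global":
        vetoed = bool(vetoing)
    else:  # per-site: veto only when no intact searchable group remains
        vetoed = bool(vetoing) and not triggering
    is_candidate = bool(triggering) and not vetoed and not excluded_known
    return ScreenDecision(
        record_id=profile.record_id,
        is_candidate=is_candidate,
        triggering_groups=triggering,
        vetoing_groups=vetoing,
        excluded_known=excluded_known,
    )


def iter_decisions(
    records: Iterable[MoleculeRecord],
    known_set: frozenset[str] | set[str] = frozenset(),
    patterns: Optional[Sequence[PatternDef]] = None,
    *,
    veto_mode: str = "global",
) -> Iterator[ScreenDecision]:
    """Stream one decision per record; memory stays bounded by one profile."""
    if patterns is None:
        patterns = DEFAULT_PATTERNS
    for rec in records:
        profile = match_groups(rec, patterns)
        yield decide(profile, known_set, rec.smiles_canonical, patterns,
                     veto_mode=veto_mode)


def screen_library(
    records: Iterable[MoleculeRecord],
    known_set: frozenset[str] | set[str] = frozenset(),
    patterns: Optional[Sequence[PatternDef]] = None,
    *,
    veto_mode: str = "global",
) -> tuple[list[ScreenDecision], ScreenSummary]:
    """Screen a deduplicated library; return decisions plus stage counts."""
    summary = ScreenSummary()
    decisions = []
    for decision in iter_decisions(records, known_set, patterns,
                                   veto_mode=veto_mode):
        summary.update(decision)
        decisions.append(decision)
    return decisions, summary
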