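"""Name-pattern retrieval of compounds and their linked gene families.

Bridges the metabolome to the functional layers: significant metabolite
names become case-insensitive regular expressions (unanchored, Python
``re`` dialect), matched against the compound names of the reaction
universe; every KO with a reaction touching a matched compound on either
side is retrieved.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .tables import ReactionUniverse

__all__ = ["MatchLog", "find_compounds", "kos_for_compounds", "glutamate_ko_set"]


@dataclass
class MatchLog:
    """(pattern, compound, matched name) triples recorded during retrieval."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, pattern: str, compound: str, name: str) -> None:
        self.records.append((pattern, compound, name))


def find_compounds(
    u: ReactionUniverse, patterns: list[str], log: MatchLog | None = None
) -> set[str]:
    """Compound ids with at least one name matching at least one pattern.

    Patterns are case-insensitive regular expressions searched anywhere
    in the name (use anchors for exact matches). A pattern matching
    nothing produces a warning, not an error.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    compiled = [(p, re.compile(p, re.IGNORECASE)) for p in patterns]
    hits: set[str] = set()
    matched_patterns: set[str] = set()
    for cid in sorted(u.compound_names):
        for name in u.compound_names[cid]:
            for raw, rx in compiled:
                if rx.search(name):
                    hits.add(cid)
                    matched_patterns.add(raw)
                    if log is not None:
                        log.add(raw, cid, name)
    for raw, _ in compiled:
        if raw not in matched_patterns:
            warnings.warn(f"pattern {raw!r} matched no compound", stacklevel=2)
    return hits


def kos_for_compounds(u: ReactionUniverse, compounds: set[str]) -> set[str]:
    """All KOs having >= 1 reaction whose reactant or product set
    intersects the compound set (both reaction sides count)."""
    out: set[str] = set()
    for ko, rxns in u.ko_reactions.items():
        for rxn in rxns:
            lhs, rhs = u.reaction_sides[rxn]
            if (lhs | rhs) & compounds:
                out.add(ko)
                break
    return out


def glutamate_ko_set(u: ReactionUniverse, log: MatchLog | None = None) -> set[str]:
    """KOs linked to any glutamate enantiomer (L-, D-, beta-).

    The beta form typically has a single reaction entry, so the whole
    glutamate family is retrieved instead of the beta compound alone.
    """
    patterns = ["L-glutamate", "D-glutamate", "beta-glutamate"]
    compounds: set[str] = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in patterns:
            try:
                compounds |= find_compounds(u, [p], log=log)
            except ValueError:
                pass
    if not compounds:
        warnings.warn("no glutamate-named compounds in universe", stacklevel=2)
        return set()
    return kos_for_compounds(u, compounds)
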