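"""Candidate enzymes for a predicted reaction.

Candidates come from the annotation of the rule's source (reference)
reaction, plus — by inference from the transformation rule — from every
other database reaction performing the same center chemistry (identical
center signature in any permitted direction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .db import ReactionDB
from .rules import CandidateReaction, TransformationRule, reaction_signatures

__all__ = ["Evidence", "EnzymeCandidate", "candidate_enzymes"]


class Evidence(str, enum.Enum):
    REFERENCE_REACTION = "reference_reaction"
    RULE_INFERENCE = "rule_inference"


@dataclass(frozen=True)
class EnzymeCandidate:
    ec: str
    name: str
    source_reaction: str
    evidence: Evidence

    def __post_init__(self) -> None:
        if not self.ec and not self.name:
            raise ValueError("enzyme candidate needs an EC number or a name")


def _reaction_enzymes(rxn, evidence: Evidence) -> list[EnzymeCandidate]:
    out = []
    ecs, names = rxn.ec_numbers, rxn.enzyme_names
    paired = max(len(ecs), len(names))
    for i in range(paired):
        ec = ecs[i] if i < len(ecs) else ""
        name = names[i] if i < len(names) else ""
        if ec or name:
            out.append(
                EnzymeCandidate(ec=ec, name=name, source_reaction=rxn.id, evidence=evidence)
            )
    return out


def candidate_enzymes(
    selected: CandidateReaction,
    rule: TransformationRule,
    db: ReactionDB,
) -> list[EnzymeCandidate]:
    """Enzymes that might catalyze a selected candidate reaction.

    The source reaction's own annotation carries ``reference_reaction``
    evidence; annotations of other signature-sharing reactions carry
    ``rule_inference`` evidence.  Deduplicated by (ec, name) keeping the
    stronger evidence; a purely chemical reference with no annotation
    yields an empty list.
    """
    if rule.source_reaction not in db:
        raise KeyError(f"rule source reaction {rule.source_reaction!r} not in database")
    results: dict[tuple[str, str], EnzymeCandidate] = {}
    source = db[rule.source_reaction]
    for cand in _reaction_enzymes(source, Evidence.REFERENCE_REACTION):
        results[(cand.ec, cand.name)] = cand
    signature = selected.signature
    for rxn in db:
        if rxn.id == source.id:
            continue
        if signature in reaction_signatures(rxn).values():
            for cand in _reaction_enzymes(rxn, Evidence.RULE_INFERENCE):
                results.setdefault((cand.ec, cand.name), cand)
    return list(results.values())
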