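"""Reaction database: TSV I/O, validation, deduplication and queries.

The on-disk dialect is a UTF-8 tab-delimited file with the header
``id  reaction_smiles  reversibility  ec  enzyme_name  source`` and one
reaction per row (``ec``/``enzyme_name`` semicolon-separated).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .chem import (
    Reaction,
    ReactionValidationError,
    Reversibility,
    canonical_reaction_key,
    check_balance,
    parse_reaction_smiles,
    reaction_smiles,
)

log = logging.getLogger(__name__)

COLUMNS = ["id", "reaction_smiles", "reversibility", "ec", "enzyme_name", "source"]

__all__ = [
    "ReactionDB",
    "load_db",
    "write_db",
    "deduplicate",
    "rule_directions",
    "find_exact",
    "COLUMNS",
]


@dataclass
class ReactionDB:
    """In-memory reaction collection with canonical-key and compound indices."""

    reactions: dict[str, Reaction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rebuild_indices()

    def _rebuild_indices(self) -> None:
        self.key_index: dict[str, str] = {}
        self.compound_index: set[str] = set()
        for rxn in self.reactions.values():
            self._index_reaction(rxn)

    def _index_reaction(self, rxn: Reaction) -> None:
        self.key_index.setdefault(canonical_reaction_key(rxn), rxn.id)
        if rxn.reversibility is Reversibility.REVERSIBLE:
            self.key_index.setdefault(canonical_reaction_key(rxn, "reversed"), rxn.id)
        for mol in rxn.reactants + rxn.products:
            self.compound_index.add(mol.canonical_smiles)

    def add(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ReactionValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn
        self._index_reaction(rxn)

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions.values())

    def __contains__(self, rxn_id: str) -> bool:
        return rxn_id in self.reactions

    def __getitem__(self, rxn_id: str) -> Reaction:
        return self.reactions[rxn_id]


def load_db(path: str | Path, h_slack: int = 0) -> ReactionDB:
    """Load and validate a reaction TSV; logs a balance verdict per row.

    Raises :class:`ReactionValidationError` on unknown reversibility tokens,
    duplicate ids, or malformed reaction SMILES (the error names the row).
    """
    path = Path(path)
    db = ReactionDB()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != COLUMNS:
            raise ReactionValidationError(
                f"{path}: expected header {COLUMNS}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            rxn_id = (row.get("id") or "").strip()
            if not rxn_id:
                raise ReactionValidationError(f"{path}:{lineno}: missing reaction id")
            try:
                rxn = parse_reaction_smiles(
                    rxn_id,
                    row["reaction_smiles"].strip(),
                    Reversibility.parse(row["reversibility"]),
                    ec_numbers=_split_multi(row.get("ec", "")),
                    enzyme_names=_split_multi(row.get("enzyme_name", "")),
                    source=(row.get("source") or "").strip(),
                )
            except ReactionValidationError as exc:
                raise ReactionValidationError(f"{path}:{lineno}: {exc}") from exc
            verdict = check_balance(rxn, h_slack=h_slack)
            if verdict.balanced:
                log.debug("row %d (%s): balanced", lineno, rxn_id)
            else:
                log.warning(
                    "row %d (%s): unbalanced, diff=%s charge_diff=%+d",
                    lineno, rxn_id, verdict.diff_dict(), verdict.charge_diff,
                )
            if rxn_id in db:
                raise ReactionValidationError(
                    f"{path}:{lineno}: duplicate reaction id {rxn_id!r}"
                )
            db.add(rxn)
    return db


def _split_multi(raw: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in (raw or "").split(";") if s.strip())


def write_db(db: ReactionDB, path: str | Path) -> None:
    """Write the TSV dialect; column order is fixed by :data:`COLUMNS`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COLUMNS)
        for rxn in db:
            writer.writerow(
                [
                    rxn.id,
                    reaction_smiles(rxn),
                    rxn.reversibility.value,
                    ";".join(rxn.ec_numbers),
                    ";".join(rxn.enzyme_names),
                    rxn.source,
                ]
            )


def deduplicate(db: ReactionDB) -> ReactionDB:
    """Drop direction-equivalent duplicate reactions, keeping first occurrence.

    A reaction is redundant when its as-written key was already seen, or —
    for reversible chemistry — when its key matches an earlier reversible
    reaction read in the opposite direction.  Enzyme annotations of dropped
    duplicates are merged into the surviving record.
    """
    kept: dict[str, Reaction] = {}
    seen: dict[str, str] = {}  # canonical key -> surviving id
    removed = 0
    for rxn in db:
        key = canonical_reaction_key(rxn)
        rkey = canonical_reaction_key(rxn, "reversed")
        match_id = seen.get(key)
        if match_id is None and rxn.reversibility is Reversibility.REVERSIBLE:
            cand = seen.get(rkey)
            if cand is not None and kept[cand].reversibility is Reversibility.REVERSIBLE:
                match_id = cand
        if match_id is not None:
            survivor = kept[match_id]
            kept[match_id] = _merge_annotations(survivor, rxn)
            removed += 1
            continue
        kept[rxn.id] = rxn
        seen[key] = rxn.id
        if rxn.reversibility is Reversibility.REVERSIBLE:
            seen.setdefault(rkey, rxn.id)
    if removed:
        log.info("deduplicate: removed %d redundant reaction(s)", removed)
    return ReactionDB(reactions=kept)


def _merge_annotations(survivor: Reaction, dup: Reaction) -> Reaction:
    ecs = survivor.ec_numbers + tuple(
        e for e in dup.ec_numbers if e not in survivor.ec_numbers
    )
    names = survivor.enzyme_names + tuple(
        n for n in dup.enzyme_names if n not in survivor.enzyme_names
    )
    from dataclasses import replace

    return replace(survivor, ec_numbers=ecs, enzyme_names=names)


def rule_directions(rxn: Reaction) -> list[str]:
    """Directions in which transformation rules are generated for a reaction.

    Reversible chemistry yields a rule per direction; irreversible or
    unknown reversibility yields the as-written rule only.
    """
    if rxn.reversibility is Reversibility.REVERSIBLE:
        return ["as_written", "reversed"]
    return ["as_written"]


def find_exact(rxn_candidate: Reaction, db: ReactionDB) -> list[str]:
    """Ids of database reactions direction-equivalent to the candidate.

    An empty result marks the candidate as a novel reaction.  Reversible
    database entries match candidates written in either direction.
    """
    key = canonical_reaction_key(rxn_candidate)
    hits = []
    hit = db.key_index.get(key)
    if hit is not None:
        hits.append(hit)
    return hits
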