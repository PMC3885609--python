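"""Iterative retrosynthesis: ranked candidate expansion to known precursors.

Applies every transformation rule to the current target, ranks the
candidate precursor reactions (presence of reactants in the database,
presence of the predicted reaction itself, structural simplicity, cofactor
frequency as a tie layer), expands the top-``beam`` candidates breadth-wise
and recurses on each proposed main precursor until a known metabolic
precursor is reached, a depth limit hits, or no rule applies.  Complete
precursor-to-target routes are then enumerated from the search tree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .chem import Molecule, canonical_reaction_key, reaction_smiles
from .db import ReactionDB, find_exact, rule_directions
from .rules import CandidateReaction, TransformationRule, apply_retro, center_signature

log = logging.getLogger(__name__)

__all__ = [
    "RankWeights",
    "RankScore",
    "RetroNode",
    "CandidateEntry",
    "Route",
    "RouteIntegrityError",
    "SignatureIndex",
    "rank_candidates",
    "cofactor_preference",
    "build_tree",
    "extract_routes",
    "replay_forward",
    "tree_to_dict",
    "tree_to_graphml",
]


@dataclass(frozen=True)
class RankWeights:
    reaction_in_db: float = 4.0
    reactant_in_db: float = 2.0
    simplicity: float = 1.0
    cofactor: float = 0.01  # final tie-layer

    def as_dict(self) -> dict:
        return {
            "reaction_in_db": self.reaction_in_db,
            "reactant_in_db": self.reactant_in_db,
            "simplicity": self.simplicity,
            "cofactor": self.cofactor,
        }


@dataclass(frozen=True)
class RankScore:
    reactant_in_db: float  # fraction of proposed reactants known to the DB
    reaction_in_db: int  # 1 when the full reaction is an exact DB match
    simplicity: float  # in [0,1], larger = smaller main precursor
    cofactor_freq: int  # signature-sharing DB reactions with this cofactor set
    total: float


class SignatureIndex:
    """Center-signature index over database reactions (built once per run)."""

    def __init__(self, db: ReactionDB):
        self.db = db
        self.by_signature: dict[str, list[str]] = {}
        for rxn in db:
            seen = set()
            for direction in rule_directions(rxn):
                try:
                    sig = center_signature(rxn, direction)
                except Exception:
                    continue
                if sig not in seen:
                    seen.add(sig)
                    self.by_signature.setdefault(sig, []).append(rxn.id)

    def cofactor_frequency(self, cand: CandidateReaction) -> int:
        """How often the candidate's cofactor set occurs among DB reactions
        performing the same center chemistry."""
        cofactors = set(cand.cofactor_reactants) | set(cand.cofactor_products)
        count = 0
        for rxn_id in self.by_signature.get(cand.signature, ()):
            rxn = self.db[rxn_id]
            pool = {m.canonical_smiles for m in rxn.reactants + rxn.products}
            if cofactors <= pool:
                count += 1
        return count


def rank_candidates(
    cands: list[CandidateReaction],
    db: ReactionDB,
    weights: RankWeights = RankWeights(),
    sig_index: SignatureIndex | None = None,
) -> list[tuple[CandidateReaction, RankScore]]:
    """Deterministically rank candidate reactions for one target.

    Descending by weighted total; exact ties broken by the candidate's
    canonical reaction key.
    """
    if not cands:
        return []
    if sig_index is None:
        sig_index = SignatureIndex(db)
    sizes = [c.main_precursor.heavy_atom_count for c in cands]
    lo, hi = min(sizes), max(sizes)
    freqs = [sig_index.cofactor_frequency(c) for c in cands]
    max_freq = max(freqs) if freqs else 0
    scored = []
    for cand, size, freq in zip(cands, sizes, freqs):
        mols = cand.reaction.reactants
        frac = sum(1 for m in mols if m.canonical_smiles in db.compound_index) / len(mols)
        in_db = 1 if find_exact(cand.reaction, db) else 0
        simplicity = 1.0 if hi == lo else (hi - size) / (hi - lo)
        total = (
            weights.reaction_in_db * in_db
            + weights.reactant_in_db * frac
            + weights.simplicity * simplicity
            + weights.cofactor * (freq / max_freq if max_freq else 0.0)
        )
        scored.append(
            (
                cand,
                RankScore(
                    reactant_in_db=frac,
                    reaction_in_db=in_db,
                    simplicity=simplicity,
                    cofactor_freq=freq,
                    total=total,
                ),
            )
        )
    scored.sort(key=lambda cs: (-cs[1].total, cs[0].key))
    return scored


def cofactor_preference(
    cands: list[CandidateReaction],
    db: ReactionDB,
    sig_index: SignatureIndex | None = None,
) -> list[CandidateReaction]:
    """Order cofactor variants by descending frequency of their co-reactant
    set among signature-sharing database reactions (deterministic)."""
    if sig_index is None:
        sig_index = SignatureIndex(db)
    return sorted(
        cands,
        key=lambda c: (-sig_index.cofactor_frequency(c), c.key),
    )


# --------------------------------------------------------------------------
# search tree


@dataclass
class CandidateEntry:
    candidate: CandidateReaction
    score: RankScore
    exact_matches: tuple[str, ...]  # DB reaction ids; empty = novel
    rule_ids: tuple[str, ...]
    children: list["RetroNode"] = field(default_factory=list)

    @property
    def novel(self) -> bool:
        return not self.exact_matches


@dataclass
class RetroNode:
    compound: Molecule
    status: str  # precursor | expanded | dead_end | depth_limited
    depth: int
    candidates: list[CandidateEntry] = field(default_factory=list)


def build_tree(
    target: Molecule,
    rules: list[TransformationRule],
    db: ReactionDB,
    precursors: set[str],
    max_depth: int = 6,
    beam: int = 5,
    weights: RankWeights = RankWeights(),
    expand_unknown: bool = False,
) -> RetroNode:
    """Breadth-limited retrosynthesis tree rooted at ``target``.

    ``precursors`` is a set of canonical SMILES at which search terminates.
    At every node the top-``beam`` ranked candidates are expanded; a
    candidate one of whose precursor components is a known precursor always
    gets that terminal child node.  A compound already on the current root
    path is never re-expanded (per-path cycle prevention); nodes at
    ``max_depth`` are marked ``depth_limited``.

    By default recursion is restricted to proposed precursors that occur in
    the reaction database (novel candidate reactions are still listed and
    flagged at every node, but search does not iterate through compounds
    the reference chemistry has never seen); ``expand_unknown=True`` lifts
    the restriction.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if beam < 1:
        raise ValueError("beam must be >= 1")
    sig_index = SignatureIndex(db)
    precursors = {Molecule.from_smiles(s).canonical_smiles for s in precursors}
    # candidate generation and ranking depend only on the compound, not on
    # the path; cache them (the same cofactor reappears on many branches)
    cand_cache: dict[str, list[tuple[CandidateReaction, RankScore, tuple[str, ...]]]] = {}

    def candidates_for(compound: Molecule):
        key = compound.canonical_smiles
        if key in cand_cache:
            return cand_cache[key]
        merged: dict[str, tuple[CandidateReaction, list[str]]] = {}
        for rule in rules:
            for cand in apply_retro(rule, compound):
                if cand.key in merged:
                    ids = merged[cand.key][1]
                    if rule.rule_id not in ids:
                        ids.append(rule.rule_id)
                else:
                    merged[cand.key] = (cand, [rule.rule_id])
        ranked = rank_candidates(
            [cand for cand, _ in merged.values()], db, weights, sig_index
        )
        out = [
            (cand, score, tuple(merged[cand.key][1])) for cand, score in ranked
        ]
        cand_cache[key] = out
        return out

    def expand(compound: Molecule, depth: int, path: frozenset) -> RetroNode:
        if compound.canonical_smiles in precursors:
            return RetroNode(compound=compound, status="precursor", depth=depth)
        if depth >= max_depth:
            return RetroNode(compound=compound, status="depth_limited", depth=depth)
        ranked = candidates_for(compound)
        if not ranked:
            return RetroNode(compound=compound, status="dead_end", depth=depth)
        node = RetroNode(compound=compound, status="expanded", depth=depth)
        for pos, (cand, score, rule_ids) in enumerate(ranked):
            entry = CandidateEntry(
                candidate=cand,
                score=score,
                exact_matches=tuple(find_exact(cand.reaction, db)),
                rule_ids=rule_ids,
            )
            hits_precursor = any(
                c.canonical_smiles in precursors for c in cand.precursor_components
            )
            if hits_precursor or pos < beam:
                for comp in cand.precursor_components:
                    smi = comp.canonical_smiles
                    if smi in precursors:
                        entry.children.append(
                            RetroNode(compound=comp, status="precursor", depth=depth + 1)
                        )
                    elif smi in path:  # per-root-path cycle prevention
                        entry.children.append(
                            RetroNode(compound=comp, status="dead_end", depth=depth + 1)
                        )
                    elif expand_unknown or smi in db.compound_index:
                        entry.children.append(expand(comp, depth + 1, path | {smi}))
            node.candidates.append(entry)
        return node

    return expand(target, 0, frozenset({target.canonical_smiles}))


# --------------------------------------------------------------------------
# routes


class RouteIntegrityError(ValueError):
    """Raised when a route's steps do not chain precursor -> target."""


@dataclass(frozen=True)
class RouteStep:
    """One forward step of a route: ``via`` (+ cofactors) -> ``product``."""

    candidate: CandidateReaction
    via: Molecule  # the chained precursor component of this step
    product: Molecule  # the compound this step synthesizes (the retro target)

    @property
    def key(self) -> str:
        return self.candidate.key


@dataclass(frozen=True)
class Route:
    """Linear synthesis route, steps ordered precursor -> target."""

    steps: tuple[RouteStep, ...]
    aggregate_rank: float

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def key_sequence(self) -> tuple[str, ...]:
        return tuple(s.key for s in self.steps)

    @property
    def compounds(self) -> tuple[str, ...]:
        """Canonical SMILES chain precursor -> target along the chained line."""
        if not self.steps:
            return ()
        chain = [self.steps[0].via.canonical_smiles]
        chain.extend(s.product.canonical_smiles for s in self.steps)
        return tuple(chain)


def extract_routes(tree: RetroNode) -> list[Route]:
    """All distinct precursor-terminated root paths of the tree.

    Deduplicated by the ordered sequence of canonical reaction keys; sorted
    by (length, descending aggregate rank score, key sequence).
    """
    found: dict[tuple, Route] = {}

    def walk(node: RetroNode, trail: list[tuple[RouteStep, float]]):
        if node.status == "precursor" and trail:
            steps = tuple(step for step, _ in reversed(trail))
            agg = sum(score for _, score in trail)
            route = Route(steps=steps, aggregate_rank=agg)
            found.setdefault(route.key_sequence, route)
            return
        for entry in node.candidates:
            for child in entry.children:
                step = RouteStep(
                    candidate=entry.candidate,
                    via=child.compound,
                    product=node.compound,
                )
                walk(child, trail + [(step, entry.score.total)])

    walk(tree, [])
    routes = list(found.values())
    routes.sort(key=lambda r: (r.length, -r.aggregate_rank, r.key_sequence))
    return routes


def replay_forward(route: Route) -> Molecule:
    """Replay a route forward from its precursor; returns the final target.

    Raises :class:`RouteIntegrityError` on an empty route or whenever a
    step's product does not feed the next step as a reactant.
    """
    if not route.steps:
        raise RouteIntegrityError("empty route cannot be replayed")
    current = route.steps[0].via
    for i, step in enumerate(route.steps):
        if step.via.canonical_smiles != current.canonical_smiles:
            raise RouteIntegrityError(
                f"step {i}: chained reactant {step.via.canonical_smiles} "
                f"!= previous product {current.canonical_smiles}"
            )
        reactant_pool = {m.canonical_smiles for m in step.candidate.reaction.reactants}
        if current.canonical_smiles not in reactant_pool:
            raise RouteIntegrityError(
                f"step {i}: chained compound missing from step reactants"
            )
        product_pool = {m.canonical_smiles for m in step.candidate.reaction.products}
        if step.product.canonical_smiles not in product_pool:
            raise RouteIntegrityError(
                f"step {i}: declared product missing from step products"
            )
        current = step.product
    return current


# --------------------------------------------------------------------------
# serialization


def _entry_to_dict(entry: CandidateEntry) -> dict:
    return {
        "reaction": reaction_smiles(entry.candidate.reaction, mapped=False),
        "key": entry.candidate.key,
        "main_precursor": entry.candidate.main_precursor.canonical_smiles,
        "main_product": entry.candidate.main_product.canonical_smiles,
        "rule_ids": list(entry.rule_ids),
        "source_reaction": entry.candidate.source_reaction,
        "novel": entry.novel,
        "exact_matches": list(entry.exact_matches),
        "score": {
            "reactant_in_db": entry.score.reactant_in_db,
            "reaction_in_db": entry.score.reaction_in_db,
            "simplicity": entry.score.simplicity,
            "cofactor_freq": entry.score.cofactor_freq,
            "total": entry.score.total,
        },
        "children": [tree_to_dict(c) for c in entry.children],
    }


def tree_to_dict(node: RetroNode) -> dict:
    return {
        "compound": node.compound.canonical_smiles,
        "status": node.status,
        "depth": node.depth,
        "candidates": [_entry_to_dict(e) for e in node.candidates],
    }


def routes_to_dict(routes: list[Route]) -> list[dict]:
    return [
        {
            "length": r.length,
            "aggregate_rank": r.aggregate_rank,
            "compounds": list(r.compounds),
            "steps": [
                {
                    "reaction": reaction_smiles(s.candidate.reaction, mapped=False),
                    "key": s.key,
                    "via": s.via.canonical_smiles,
                    "product": s.product.canonical_smiles,
                    "source_reaction": s.candidate.source_reaction,
                    "rule_id": s.candidate.rule_id,
                }
                for s in r.steps
            ],
        }
        for r in routes
    ]


def tree_to_graphml(tree: RetroNode, path: str | Path) -> None:
    import networkx as nx

    g = nx.DiGraph()
    counter = [0]

    def add(node: RetroNode) -> int:
        nid = counter[0]
        counter[0] += 1
        g.add_node(nid, compound=node.compound.canonical_smiles, status=node.status, depth=node.depth)
        for entry in node.candidates:
            for child in entry.children:
                cid = add(child)
                g.add_edge(
                    nid,
                    cid,
                    reaction=entry.candidate.key,
                    total=entry.score.total,
                    novel=entry.novel,
                )
        return nid

    add(tree)
    nx.write_graphml(g, str(path))
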