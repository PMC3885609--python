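"""Transformation-rule extraction and retro application.

A rule is a directed subgraph rewrite derived from a fully atom-mapped
reference reaction: the reaction center (bonds broken/formed/order-changed
plus atoms with changed hydrogen count or charge) padded by a configurable
bond-radius environment.  Retro application matches the rule's product-side
pattern in a target molecule and rebuilds the complete precursor reaction —
grafting the atoms that leave as co-products, restoring reactant-side bond
orders and hydrogen counts, and copying spectator co-substrates verbatim.

Match semantics: element, aromaticity flag and ring membership must agree
for every pattern atom; hydrogen count and formal charge are additionally
constrained on center atoms only.  Embeddings are reduced to one
representative per pattern-automorphism orbit.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from rdkit import Chem

from .chem import (
    Molecule,
    Reaction,
    Reversibility,
    canonical_reaction_key,
    parse_molecule,
)

log = logging.getLogger(__name__)

__all__ = [
    "ReactionCenter",
    "TransformationRule",
    "CandidateReaction",
    "MappingError",
    "reaction_center",
    "extract_rule",
    "extract_rules_for_db",
    "apply_retro",
    "apply_forward",
    "center_signature",
    "reaction_signatures",
    "self_consistent",
    "write_rules",
    "read_rules",
]

DEFAULT_RADIUS = 1


class MappingError(ValueError):
    """Raised when rule extraction meets an incompletely mapped reaction."""


# --------------------------------------------------------------------------
# map-keyed side tables


@dataclass(frozen=True)
class _AtomInfo:
    symbol: str
    charge: int
    n_h: int
    aromatic: bool
    in_ring: bool
    mol_idx: int
    atom_idx: int


def _side_tables(mols: tuple[Molecule, ...], side_name: str, rxn_id: str):
    """Map-keyed atom and bond tables for one side of a mapped reaction."""
    atoms: dict[int, _AtomInfo] = {}
    bonds: dict[frozenset, float] = {}
    for mi, mol in enumerate(mols):
        idx_to_map = {}
        for ai, a in enumerate(mol.atoms):
            if a.symbol == "H":
                continue  # proton/H2 species tracked via hydrogen counts
            if a.map_num == 0:
                raise MappingError(
                    f"reaction {rxn_id!r}: unmapped atoms present "
                    f"({side_name} molecule {mi}, atom {ai} {a.symbol})"
                )
            if a.map_num in atoms:
                raise MappingError(
                    f"reaction {rxn_id!r}: duplicate atom map {a.map_num} on {side_name} side"
                )
            atoms[a.map_num] = _AtomInfo(
                a.symbol, a.charge, a.n_h, a.aromatic, a.in_ring, mi, ai
            )
            idx_to_map[ai] = a.map_num
        for b in mol.bonds:
            if b.i in idx_to_map and b.j in idx_to_map:
                bonds[frozenset((idx_to_map[b.i], idx_to_map[b.j]))] = b.order
    return atoms, bonds


# --------------------------------------------------------------------------
# reaction center


@dataclass(frozen=True)
class ReactionCenter:
    """Changed bonds/atoms of a mapped reaction, oriented reactants->products."""

    changed_bonds: tuple[tuple[tuple[int, int], str], ...]  # ((m1,m2), kind)
    changed_atoms: tuple[int, ...]

    @property
    def empty(self) -> bool:
        return not self.changed_bonds and not self.changed_atoms

    def bond_kinds(self) -> dict[frozenset, str]:
        return {frozenset(pair): kind for pair, kind in self.changed_bonds}


def reaction_center(rxn: Reaction) -> ReactionCenter:
    """Detect the reaction center of a fully atom-mapped reaction.

    The center is the symmetric difference of the mapped bond sets
    (classified broken / formed / order-changed relative to the as-written
    direction) plus every atom with a changed hydrogen count, charge or
    aromaticity.
    """
    r_atoms, r_bonds = _side_tables(rxn.reactants, "reactant", rxn.id)
    p_atoms, p_bonds = _side_tables(rxn.products, "product", rxn.id)
    if set(r_atoms) != set(p_atoms):
        raise MappingError(
            f"reaction {rxn.id!r}: atom-map sets differ between sides"
        )
    changed_bonds = []
    for pair in sorted(set(r_bonds) | set(p_bonds), key=sorted):
        ro, po = r_bonds.get(pair), p_bonds.get(pair)
        if ro == po:
            continue
        kind = "broken" if po is None else "formed" if ro is None else "order-changed"
        changed_bonds.append((tuple(sorted(pair)), kind))
    changed = set()
    for pair, _ in changed_bonds:
        changed.update(pair)
    for m in r_atoms:
        ra, pa = r_atoms[m], p_atoms[m]
        if (ra.n_h, ra.charge, ra.aromatic) != (pa.n_h, pa.charge, pa.aromatic):
            changed.add(m)
    return ReactionCenter(
        changed_bonds=tuple(changed_bonds),
        changed_atoms=tuple(sorted(changed)),
    )


def center_signature(rxn: Reaction, direction: str = "as_written") -> str:
    """Canonical string of changed-bond types and atom deltas for a direction.

    Reactions performing the same chemistry (e.g. all transaminations)
    share the signature regardless of substrate; used for cofactor
    frequency counting and rule-inference enzyme evidence.
    """
    oriented = rxn if direction == "as_written" else rxn.reversed()
    r_atoms, r_bonds = _side_tables(oriented.reactants, "reactant", rxn.id)
    p_atoms, p_bonds = _side_tables(oriented.products, "product", rxn.id)
    center = reaction_center(oriented)
    parts = []
    for pair, kind in center.changed_bonds:
        elems = "".join(sorted(r_atoms[m].symbol for m in pair))
        ro = r_bonds.get(frozenset(pair))
        po = p_bonds.get(frozenset(pair))
        parts.append(f"bond:{kind}:{elems}:{ro}->{po}")
    for m in center.changed_atoms:
        ra, pa = r_atoms[m], p_atoms[m]
        if ra.n_h != pa.n_h:
            parts.append(f"dH:{ra.symbol}:{pa.n_h - ra.n_h:+d}")
        if ra.charge != pa.charge:
            parts.append(f"dq:{ra.symbol}:{pa.charge - ra.charge:+d}")
    return "|".join(sorted(parts))


def reaction_signatures(rxn: Reaction) -> dict[str, str]:
    """Signature per permitted rule direction of a database reaction."""
    from .db import rule_directions

    return {d: center_signature(rxn, d) for d in rule_directions(rxn)}


# --------------------------------------------------------------------------
# rules


@dataclass(frozen=True)
class TransformationRule:
    """Directed rewrite extracted from a reference reaction.

    ``reactants``/``products`` are the mapped molecules of the rule
    direction (for ``direction='reversed'`` the original sides swapped).
    ``co_reactants``/``co_products`` are the spectator molecules carrying no
    center atoms; they are copied verbatim into candidate reactions.
    """

    rule_id: str
    source_reaction: str
    direction: str
    radius: int
    reactants: tuple[Molecule, ...]
    products: tuple[Molecule, ...]
    center: ReactionCenter
    ec_numbers: tuple[str, ...] = ()
    enzyme_names: tuple[str, ...] = ()
    source: str = ""

    @property
    def co_reactants(self) -> tuple[Molecule, ...]:
        cs = set(self.center.changed_atoms)
        return tuple(m for m in self.reactants if not (set(m.map_numbers) & cs))

    @property
    def co_products(self) -> tuple[Molecule, ...]:
        cs = set(self.center.changed_atoms)
        return tuple(m for m in self.products if not (set(m.map_numbers) & cs))

    @property
    def signature(self) -> str:
        rxn = Reaction(
            id=self.source_reaction,
            reactants=self.reactants,
            products=self.products,
            reversibility=Reversibility.UNKNOWN,
        )
        return center_signature(rxn, "as_written")

    def principal_products(self) -> list[int]:
        """Indices of product molecules carrying center atoms (matchable)."""
        cs = set(self.center.changed_atoms)
        return [
            i for i, m in enumerate(self.products) if set(m.map_numbers) & cs
        ]

    def pattern_maps(self, product_idx: int) -> set[int]:
        """Atom maps of the match pattern for one principal product:
        center atoms plus everything within ``radius`` bonds of them."""
        mol = self.products[product_idx]
        adj: dict[int, set[int]] = {}
        idx_to_map = {}
        for ai, a in enumerate(mol.atoms):
            if a.symbol != "H" and a.map_num:
                idx_to_map[ai] = a.map_num
        for b in mol.bonds:
            if b.i in idx_to_map and b.j in idx_to_map:
                adj.setdefault(idx_to_map[b.i], set()).add(idx_to_map[b.j])
                adj.setdefault(idx_to_map[b.j], set()).add(idx_to_map[b.i])
        frontier = set(self.center.changed_atoms) & set(idx_to_map.values())
        seen = set(frontier)
        for _ in range(self.radius):
            frontier = {n for m in frontier for n in adj.get(m, ()) if n not in seen}
            seen |= frontier
        return seen

    def pattern_smarts(self, product_idx: int) -> str:
        """Human-readable rendering of one pattern (not used for matching)."""
        mol = self.products[product_idx].to_rdkit()
        maps = self.pattern_maps(product_idx)
        idxs = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() in maps]
        if not idxs:
            return ""
        return Chem.MolFragmentToSmiles(mol, atomsToUse=idxs, canonical=True)


def extract_rule(
    rxn: Reaction, direction: str = "as_written", radius: int = DEFAULT_RADIUS
) -> TransformationRule:
    """Extract the transformation rule of ``rxn`` in one direction.

    Raises :class:`MappingError` for partially mapped reactions.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if direction not in ("as_written", "reversed"):
        raise ValueError(f"bad direction {direction!r}")
    oriented = rxn if direction == "as_written" else rxn.reversed()
    center = reaction_center(oriented)
    return TransformationRule(
        rule_id=f"{rxn.id}:{direction}:r{radius}",
        source_reaction=rxn.id,
        direction=direction,
        radius=radius,
        reactants=oriented.reactants,
        products=oriented.products,
        center=center,
        ec_numbers=rxn.ec_numbers,
        enzyme_names=rxn.enzyme_names,
        source=rxn.source,
    )


def extract_rules_for_db(db, radius: int = DEFAULT_RADIUS, exclude_ids=()) -> list[TransformationRule]:
    """One rule per permitted direction per database reaction."""
    from .db import rule_directions

    rules = []
    for rxn in db:
        if rxn.id in exclude_ids:
            continue
        for direction in rule_directions(rxn):
            rules.append(extract_rule(rxn, direction, radius))
    log.info("extracted %d rule(s) from %d reaction(s)", len(rules), len(db))
    return rules


# --------------------------------------------------------------------------
# candidate reactions


@dataclass(frozen=True)
class CandidateReaction:
    """A complete proposed reaction: precursor(s) + co-reactants >> target + co-products."""

    reaction: Reaction
    rule_id: str
    source_reaction: str
    main_precursor: Molecule  # largest rewrite component (by target overlap)
    main_product: Molecule
    precursor_components: tuple[Molecule, ...]  # rewrite components, recursion points
    cofactor_reactants: tuple[str, ...]  # canonical SMILES, reactants minus main precursor
    cofactor_products: tuple[str, ...]
    signature: str

    @property
    def key(self) -> str:
        return canonical_reaction_key(self.reaction)


# --------------------------------------------------------------------------
# mutable graph used during rewriting


class _MolGraph:
    def __init__(self) -> None:
        self.atoms: dict[object, dict] = {}
        self.bonds: dict[frozenset, float] = {}

    @classmethod
    def from_molecule(cls, mol: Molecule) -> "_MolGraph":
        g = cls()
        for ai, a in enumerate(mol.atoms):
            g.atoms[ai] = dict(
                symbol=a.symbol, charge=a.charge, n_h=a.n_h, aromatic=a.aromatic
            )
        for b in mol.bonds:
            g.bonds[frozenset((b.i, b.j))] = b.order
        return g

    def neighbors(self, node):
        for pair in self.bonds:
            if node in pair:
                (other,) = pair - {node}
                yield other

    def components(self) -> list[set]:
        remaining = set(self.atoms)
        comps = []
        for seed in sorted(self.atoms, key=str):  # deterministic order
            if seed not in remaining:
                continue
            remaining.discard(seed)
            comp = {seed}
            stack = [seed]
            while stack:
                for nb in list(self.neighbors(stack.pop())):
                    if nb in remaining:
                        remaining.discard(nb)
                        comp.add(nb)
                        stack.append(nb)
            comps.append(comp)
        return comps

    def to_molecule(self, nodes: set) -> Molecule:
        order_map = {
            1.0: Chem.BondType.SINGLE,
            2.0: Chem.BondType.DOUBLE,
            3.0: Chem.BondType.TRIPLE,
            1.5: Chem.BondType.AROMATIC,
        }
        rw = Chem.RWMol()
        idx = {}
        for node in sorted(nodes, key=str):
            data = self.atoms[node]
            atom = Chem.Atom(data["symbol"])
            atom.SetFormalCharge(data["charge"])
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(max(0, data["n_h"]))
            atom.SetIsAromatic(data["aromatic"])
            idx[node] = rw.AddAtom(atom)
        for pair, order in self.bonds.items():
            a, b = tuple(pair)
            if a in nodes and b in nodes:
                rw.AddBond(idx[a], idx[b], order_map[order])
                if order == 1.5:
                    rw.GetBondBetweenAtoms(idx[a], idx[b]).SetIsAromatic(True)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return Molecule.from_rdkit(mol)


# --------------------------------------------------------------------------
# matching


def _target_graph(target: Molecule) -> nx.Graph:
    g = nx.Graph()
    for ai, a in enumerate(target.atoms):
        g.add_node(
            ai,
            symbol=a.symbol,
            aromatic=a.aromatic,
            in_ring=a.in_ring,
            n_h=a.n_h,
            charge=a.charge,
            center=False,
        )
    for b in target.bonds:
        g.add_edge(b.i, b.j, order=b.order)
    return g


def _pattern_graph(rule: TransformationRule, product_idx: int) -> nx.Graph | None:
    mol = rule.products[product_idx]
    maps = rule.pattern_maps(product_idx)
    if not maps:
        return None
    center = set(rule.center.changed_atoms)
    g = nx.Graph()
    idx_to_map = {}
    for ai, a in enumerate(mol.atoms):
        if a.map_num in maps:
            idx_to_map[ai] = a.map_num
            g.add_node(
                a.map_num,
                symbol=a.symbol,
                aromatic=a.aromatic,
                in_ring=a.in_ring,
                n_h=a.n_h,
                charge=a.charge,
                center=a.map_num in center,
            )
    for b in mol.bonds:
        if b.i in idx_to_map and b.j in idx_to_map:
            g.add_edge(idx_to_map[b.i], idx_to_map[b.j], order=b.order)
    return g


def _node_match(target_attrs: dict, pattern_attrs: dict) -> bool:
    if target_attrs["symbol"] != pattern_attrs["symbol"]:
        return False
    if target_attrs["aromatic"] != pattern_attrs["aromatic"]:
        return False
    if target_attrs["in_ring"] != pattern_attrs["in_ring"]:
        return False
    if pattern_attrs["center"]:
        if target_attrs["n_h"] != pattern_attrs["n_h"]:
            return False
        if target_attrs["charge"] != pattern_attrs["charge"]:
            return False
    return True


def _edge_match(t_attrs: dict, p_attrs: dict) -> bool:
    return t_attrs["order"] == p_attrs["order"]


def _embeddings(pattern: nx.Graph, target_g: nx.Graph) -> list[dict]:
    """Automorphism-distinct monomorphisms pattern->target."""
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        target_g, pattern, node_match=_node_match, edge_match=_edge_match
    )
    raw = []
    for m in matcher.subgraph_monomorphisms_iter():
        raw.append({p: t for t, p in m.items()})
    if not raw:
        return []
    auto_matcher = nx.algorithms.isomorphism.GraphMatcher(
        pattern,
        pattern,
        node_match=lambda a, b: _node_match(a, b) and _node_match(b, a),
        edge_match=_edge_match,
    )
    autos = list(auto_matcher.isomorphisms_iter())
    nodes = sorted(pattern.nodes)
    kept: dict[tuple, dict] = {}
    for emb in raw:
        orbit_key = min(tuple(emb[a[p]] for p in nodes) for a in autos)
        kept.setdefault(orbit_key, emb)
    return [kept[k] for k in sorted(kept)]


# --------------------------------------------------------------------------
# retro application


def apply_retro(rule: TransformationRule, target: Molecule) -> list[CandidateReaction]:
    """Apply a rule in the retro direction to a target molecule.

    Returns one complete candidate reaction per automorphism-distinct
    embedding of the rule's product-side pattern in the target (over every
    matchable principal product); an empty list when nothing matches.
    """
    results: list[CandidateReaction] = []
    target_g = _target_graph(target)
    r_atoms, r_bonds = _side_tables(rule.reactants, "reactant", rule.rule_id)
    signature = rule.signature
    for prod_idx in rule.principal_products():
        pattern = _pattern_graph(rule, prod_idx)
        if pattern is None:
            continue
        p_atoms, p_bonds = _side_tables(
            (rule.products[prod_idx],), "product", rule.rule_id
        )
        maps_P = set(rule.products[prod_idx].map_numbers)
        for k, emb in enumerate(_embeddings(pattern, target_g)):
            cand = _rewrite(
                rule, target, emb, prod_idx, maps_P, r_atoms, r_bonds, p_atoms,
                p_bonds, signature, k,
            )
            if cand is not None:
                results.append(cand)
    return results


def _rewrite(
    rule: TransformationRule,
    target: Molecule,
    emb: dict,
    prod_idx: int,
    maps_P: set,
    r_atoms: dict,
    r_bonds: dict,
    p_atoms: dict,
    p_bonds: dict,
    signature: str,
    emb_idx: int,
) -> CandidateReaction | None:
    g = _MolGraph.from_molecule(target)
    matched: dict[int, object] = dict(emb)  # map number -> target node
    # principal reactant molecules: those sharing atoms with the match
    principal_r = [
        rm for rm in rule.reactants if set(rm.map_numbers) & set(matched)
    ]
    principal_maps = set().union(*(set(rm.map_numbers) for rm in principal_r)) if principal_r else set()
    # graft reactant-side atoms that leave the principal product (-> co-products)
    node_of: dict[int, object] = dict(matched)
    for m in sorted(principal_maps):
        if m in maps_P:
            continue
        info = r_atoms[m]
        node = ("graft", m)
        g.atoms[node] = dict(
            symbol=info.symbol, charge=info.charge, n_h=info.n_h,
            aromatic=info.aromatic,
        )
        node_of[m] = node
    # bond edits: reconcile template bonds over available atoms
    pairs = set()
    for pair in r_bonds:
        if all(m in node_of for m in pair):
            pairs.add(pair)
    for pair in p_bonds:
        if all(m in node_of for m in pair):
            pairs.add(pair)
    for pair in pairs:
        ro = r_bonds.get(pair)
        po = p_bonds.get(pair) if all(m in matched for m in pair) else None
        if all(m in matched for m in pair):
            if ro == po:
                continue
        gpair = frozenset(node_of[m] for m in pair)
        if ro is None:
            g.bonds.pop(gpair, None)
        else:
            g.bonds[gpair] = ro
    # hydrogen / charge / aromaticity deltas on matched atoms
    for m, node in matched.items():
        ra, pa = r_atoms[m], p_atoms[m]
        data = g.atoms[node]
        data["n_h"] += ra.n_h - pa.n_h
        data["charge"] += ra.charge - pa.charge
        if ra.aromatic != pa.aromatic:
            data["aromatic"] = ra.aromatic
        if data["n_h"] < 0:
            return None
    # assemble precursor molecules
    comp_nodes = g.components()
    try:
        comps = [g.to_molecule(nodes) for nodes in comp_nodes]
    except Exception as exc:  # sanitize failure = chemically invalid embedding
        log.debug("rule %s: discarded embedding (%s)", rule.rule_id, exc)
        return None
    target_nodes = set(range(len(target.atoms)))
    overlap = [len(nodes & target_nodes) for nodes in comp_nodes]
    main_i = max(
        range(len(comps)),
        key=lambda i: (overlap[i], comps[i].heavy_atom_count, comps[i].canonical_smiles),
    )
    verbatim_reactants = [
        rm.without_maps() for rm in rule.reactants if rm not in principal_r
    ]
    co_products = [
        pm.without_maps() for i, pm in enumerate(rule.products) if i != prod_idx
    ]
    clean_target = target if not any(a.map_num for a in target.atoms) else target.without_maps()
    reactants = tuple(comps) + tuple(verbatim_reactants)
    products = (clean_target,) + tuple(co_products)
    reaction = Reaction(
        id=f"cand:{rule.rule_id}:{prod_idx}:{emb_idx}",
        reactants=reactants,
        products=products,
        reversibility=Reversibility.UNKNOWN,
        ec_numbers=rule.ec_numbers,
        enzyme_names=rule.enzyme_names,
        source=f"predicted:{rule.rule_id}",
    )
    main = comps[main_i]
    cof_r = sorted(m.canonical_smiles for i, m in enumerate(reactants) if i != main_i)
    cof_p = sorted(m.canonical_smiles for m in co_products)
    return CandidateReaction(
        reaction=reaction,
        rule_id=rule.rule_id,
        source_reaction=rule.source_reaction,
        main_precursor=main,
        main_product=clean_target,
        precursor_components=tuple(comps),
        cofactor_reactants=tuple(cof_r),
        cofactor_products=tuple(cof_p),
        signature=signature,
    )


def apply_forward(rule: TransformationRule, precursor: Molecule) -> list[CandidateReaction]:
    """Apply a rule in its forward direction (retro application of the
    direction-flipped rule); used for route replay and self-consistency."""
    flipped = TransformationRule(
        rule_id=rule.rule_id + ":flip",
        source_reaction=rule.source_reaction,
        direction="reversed" if rule.direction == "as_written" else "as_written",
        radius=rule.radius,
        reactants=rule.products,
        products=rule.reactants,
        center=rule.center,
        ec_numbers=rule.ec_numbers,
        enzyme_names=rule.enzyme_names,
        source=rule.source,
    )
    return apply_retro(flipped, precursor)


def self_consistent(rule: TransformationRule) -> bool:
    """A rule applied to its own source product side must regenerate the
    source reactant side (canonical-form equality) for every principal
    product pattern."""
    want_r = sorted(m.canonical_smiles for m in rule.reactants)
    want_p = sorted(m.canonical_smiles for m in rule.products)
    for prod_idx in rule.principal_products():
        target = rule.products[prod_idx].without_maps()
        ok = False
        for cand in apply_retro(rule, target):
            got_r = sorted(m.canonical_smiles for m in cand.reaction.reactants)
            got_p = sorted(m.canonical_smiles for m in cand.reaction.products)
            if got_r == want_r and got_p == want_p:
                ok = True
                break
        if not ok:
            return False
    return True


# --------------------------------------------------------------------------
# serialization


def write_rules(rules: list[TransformationRule], path: str | Path, config: dict | None = None) -> None:
    doc = {
        "format": "rpe-rules/1",
        "config": config or {},
        "rules": [
            {
                "rule_id": r.rule_id,
                "source_reaction": r.source_reaction,
                "direction": r.direction,
                "radius": r.radius,
                "reactants": [m.smiles for m in r.reactants],
                "products": [m.smiles for m in r.products],
                "pattern_smarts": [r.pattern_smarts(i) for i in r.principal_products()],
                "co_reactants": [m.canonical_smiles for m in r.co_reactants],
                "co_products": [m.canonical_smiles for m in r.co_products],
                "signature": r.signature,
                "ec": list(r.ec_numbers),
                "enzyme_name": list(r.enzyme_names),
                "source": r.source,
            }
            for r in rules
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_rules(path: str | Path) -> list[TransformationRule]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    rules = []
    for entry in doc["rules"]:
        reactants = tuple(parse_molecule(s) for s in entry["reactants"])
        products = tuple(parse_molecule(s) for s in entry["products"])
        rxn = Reaction(
            id=entry["source_reaction"],
            reactants=reactants,
            products=products,
            reversibility=Reversibility.UNKNOWN,
        )
        center = reaction_center(rxn)
        rules.append(
            TransformationRule(
                rule_id=entry["rule_id"],
                source_reaction=entry["source_reaction"],
                direction=entry["direction"],
                radius=entry["radius"],
                reactants=reactants,
                products=products,
                center=center,
                ec_numbers=tuple(entry.get("ec", ())),
                enzyme_names=tuple(entry.get("enzyme_name", ())),
                source=entry.get("source", ""),
            )
        )
    return rules
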