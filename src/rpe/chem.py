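"""Molecule and reaction representation on top of RDKit.

Molecules are held as lightweight element/bond records plus a canonical
SMILES (stereo and atom maps stripped).  Atom-map integers are preserved on
the records so that downstream rule extraction can diff mapped reaction
sides.  Hydrogens are resolved to explicit per-atom counts; hydrogen-only
species (``[H+]``, ``[H][H]``) are legal molecules and are exempt from the
atom-mapping bookkeeping that applies to heavy atoms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomRecord",
    "BondRecord",
    "Molecule",
    "ElementalComposition",
    "Reversibility",
    "Reaction",
    "BalanceVerdict",
    "MoleculeParseError",
    "ReactionValidationError",
    "parse_molecule",
    "parse_reaction_smiles",
    "elemental_formula",
    "composition_of",
    "check_balance",
    "canonical_reaction_key",
    "reaction_smiles",
]


class MoleculeParseError(ValueError):
    """Raised for SMILES that RDKit cannot parse or sanitize."""


class ReactionValidationError(ValueError):
    """Raised for structurally invalid reaction records."""


@dataclass(frozen=True)
class AtomRecord:
    symbol: str
    charge: int
    map_num: int  # 0 = unmapped
    n_h: int  # resolved total hydrogen count
    aromatic: bool
    in_ring: bool


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    order: float  # 1.0/2.0/3.0, 1.5 for aromatic
    aromatic: bool


@dataclass(frozen=True)
class Molecule:
    """Parsed structure with explicit hydrogen counts and a canonical form.

    ``canonical_smiles`` is invariant under atom reordering, atom-map
    renumbering and stereo annotation.  ``smiles`` keeps the atom maps as
    written (maps renumbered only by the caller).
    """

    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...]
    canonical_smiles: str
    smiles: str

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        if not smiles or not smiles.strip():
            raise MoleculeParseError("empty SMILES string")
        mol = Chem.MolFromSmiles(smiles, sanitize=True)
        if mol is None:
            problems = describe_smiles_problems(smiles)
            raise MoleculeParseError(
                f"unparsable SMILES {smiles!r}: {problems}"
            )
        return cls.from_rdkit(mol, source_smiles=smiles)

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, source_smiles: str | None = None) -> "Molecule":
        Chem.RemoveStereochemistry(mol)
        atoms = tuple(
            AtomRecord(
                symbol=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                map_num=a.GetAtomMapNum(),
                n_h=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
                in_ring=a.IsInRing(),
            )
            for a in mol.GetAtoms()
        )
        bonds = tuple(
            BondRecord(
                i=b.GetBeginAtomIdx(),
                j=b.GetEndAtomIdx(),
                order=b.GetBondTypeAsDouble(),
                aromatic=b.GetIsAromatic(),
            )
            for b in mol.GetBonds()
        )
        stripped = Chem.Mol(mol)
        for a in stripped.GetAtoms():
            a.SetAtomMapNum(0)
        canonical = Chem.MolToSmiles(stripped)
        mapped = Chem.MolToSmiles(mol)
        if source_smiles is None:
            source_smiles = mapped
        return cls(atoms=atoms, bonds=bonds, canonical_smiles=canonical, smiles=mapped)

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - round-trip of our own output
            raise MoleculeParseError(f"internal SMILES no longer parses: {self.smiles!r}")
        return mol

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.symbol != "H")

    @property
    def map_numbers(self) -> tuple[int, ...]:
        """Sorted multiset of atom-map numbers on heavy atoms (0s excluded)."""
        return tuple(sorted(a.map_num for a in self.atoms if a.symbol != "H" and a.map_num))

    @property
    def fully_mapped(self) -> bool:
        """True when every heavy atom carries an atom map.

        Hydrogen-only molecules (protons, molecular hydrogen) count as
        trivially mapped; their bookkeeping happens through hydrogen counts.
        """
        heavy = [a for a in self.atoms if a.symbol != "H"]
        return all(a.map_num > 0 for a in heavy)

    def without_maps(self) -> "Molecule":
        return Molecule.from_smiles(self.canonical_smiles)


def describe_smiles_problems(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        # Tokenizer-level failure; point at the likely offender.
        depth = 0
        for pos, ch in enumerate(smiles):
            depth += {"(": 1, ")": -1}.get(ch, 0)
            if depth < 0:
                return f"unbalanced ')' at position {pos}"
        if depth != 0:
            return f"unclosed '(' ({depth} open) in {smiles!r}"
        return "token stream rejected by SMILES parser"
    problems = Chem.DetectChemistryProblems(mol)
    if problems:
        return "; ".join(p.Message() for p in problems)
    return "sanitization failed"


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Atom maps (``:n``) are preserved; implicit hydrogens are resolved.
    Raises :class:`MoleculeParseError` on malformed input.
    """
    return Molecule.from_smiles(smiles)


@dataclass(frozen=True)
class ElementalComposition:
    """Per-element atom counts (hydrogen explicit) plus net formal charge."""

    counts: tuple[tuple[str, int], ...]
    net_charge: int

    @classmethod
    def from_dict(cls, counts: dict[str, int], net_charge: int) -> "ElementalComposition":
        clean = {el: n for el, n in counts.items() if n}
        return cls(counts=tuple(sorted(clean.items())), net_charge=net_charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition.from_dict(merged, self.net_charge + other.net_charge)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
        return ElementalComposition(
            counts=tuple(sorted((el, n) for el, n in merged.items() if n)),
            net_charge=self.net_charge - other.net_charge,
        )


def elemental_formula(mol: Molecule) -> ElementalComposition:
    """Elemental composition with explicit hydrogens and net charge."""
    counts: dict[str, int] = {}
    charge = 0
    for atom in mol.atoms:
        counts[atom.symbol] = counts.get(atom.symbol, 0) + 1
        if atom.n_h:
            counts["H"] = counts.get("H", 0) + atom.n_h
        charge += atom.charge
    return ElementalComposition.from_dict(counts, charge)


def composition_of(mols: list[Molecule] | tuple[Molecule, ...]) -> ElementalComposition:
    total = ElementalComposition(counts=(), net_charge=0)
    for m in mols:
        total = total + elemental_formula(m)
    return total


class Reversibility(str, enum.Enum):
    REVERSIBLE = "reversible"
    IRREVERSIBLE = "irreversible"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str) -> "Reversibility":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ReactionValidationError(
                f"unknown reversibility token {token!r}; "
                f"expected one of {[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[Molecule, ...]
    products: tuple[Molecule, ...]
    reversibility: Reversibility
    ec_numbers: tuple[str, ...] = ()
    enzyme_names: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ReactionValidationError(
                f"reaction {self.id!r}: reactant and product lists must be nonempty"
            )

    @property
    def fully_mapped(self) -> bool:
        return all(m.fully_mapped for m in self.reactants + self.products)

    def map_multisets_match(self) -> bool:
        """For mapped reactions: heavy-atom map multisets agree across sides."""
        left: list[int] = []
        right: list[int] = []
        for m in self.reactants:
            left.extend(m.map_numbers)
        for m in self.products:
            right.extend(m.map_numbers)
        return sorted(left) == sorted(right)

    def reversed(self) -> "Reaction":
        return replace(self, reactants=self.products, products=self.reactants)


def parse_reaction_smiles(
    rxn_id: str,
    smiles: str,
    reversibility: Reversibility | str = Reversibility.UNKNOWN,
    ec_numbers: tuple[str, ...] = (),
    enzyme_names: tuple[str, ...] = (),
    source: str = "",
) -> Reaction:
    """Parse ``A.B>>C.D`` reaction SMILES (atom maps allowed) into a Reaction."""
    if isinstance(reversibility, str):
        reversibility = Reversibility.parse(reversibility)
    parts = smiles.split(">>")
    if len(parts) != 2:
        raise ReactionValidationError(
            f"reaction {rxn_id!r}: expected exactly one '>>' in {smiles!r}"
        )
    left, right = parts
    try:
        reactants = tuple(parse_molecule(s) for s in left.split(".") if s)
        products = tuple(parse_molecule(s) for s in right.split(".") if s)
    except MoleculeParseError as exc:
        raise ReactionValidationError(f"reaction {rxn_id!r}: {exc}") from exc
    rxn = Reaction(
        id=rxn_id,
        reactants=reactants,
        products=products,
        reversibility=reversibility,
        ec_numbers=tuple(ec_numbers),
        enzyme_names=tuple(enzyme_names),
        source=source,
    )
    if rxn.fully_mapped and not rxn.map_multisets_match():
        raise ReactionValidationError(
            f"reaction {rxn_id!r}: reactant/product atom-map multisets differ"
        )
    return rxn


def reaction_smiles(rxn: Reaction, mapped: bool = True) -> str:
    """Serialize a reaction back to ``A.B>>C.D`` form."""
    if mapped:
        left = ".".join(m.smiles for m in rxn.reactants)
        right = ".".join(m.smiles for m in rxn.products)
    else:
        left = ".".join(m.canonical_smiles for m in rxn.reactants)
        right = ".".join(m.canonical_smiles for m in rxn.products)
    return f"{left}>>{right}"


@dataclass(frozen=True)
class BalanceVerdict:
    balanced: bool
    diff: tuple[tuple[str, int], ...]  # element -> product minus reactant
    charge_diff: int = 0

    def diff_dict(self) -> dict[str, int]:
        return dict(self.diff)


def check_balance(rxn: Reaction, h_slack: int = 0) -> BalanceVerdict:
    """Stoichiometric balance check.

    Balanced iff per-element sums agree on both sides.  A hydrogen
    discrepancy of at most ``h_slack`` is tolerated provided the charge
    difference accounts for it (proton-level slack for databases that omit
    explicit protons); with the default ``h_slack=0`` the check is exact.
    """
    if h_slack < 0:
        raise ValueError("h_slack must be >= 0")
    delta = composition_of(list(rxn.products)) - composition_of(list(rxn.reactants))
    diffs = {el: n for el, n in delta.counts if n}
    dq = delta.net_charge
    dh = diffs.pop("H", 0)
    non_h_ok = not diffs
    if dh == 0 and dq == 0:
        h_ok = True
    else:
        h_ok = abs(dh) <= h_slack and dh == dq
    balanced = non_h_ok and h_ok
    full = dict(diffs)
    if dh:
        full["H"] = dh
    return BalanceVerdict(
        balanced=balanced,
        diff=tuple(sorted(full.items())),
        charge_diff=dq,
    )


def canonical_reaction_key(rxn: Reaction, direction: str = "as_written") -> str:
    """Direction-sensitive reaction identity key.

    Invariant under reactant/product ordering and atom-map renumbering
    (keys are built from map-stripped canonical SMILES multisets).
    """
    if direction not in ("as_written", "reversed"):
        raise ValueError(f"direction must be as_written|reversed, got {direction!r}")
    left = sorted(m.canonical_smiles for m in rxn.reactants)
    right = sorted(m.canonical_smiles for m in rxn.products)
    if direction == "reversed":
        left, right = right, left
    return ".".join(left) + ">>" + ".".join(right)
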