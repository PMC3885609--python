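"""Deterministic in-repo test data.

Two generators:

* :func:`build_flavor_network` — a fully atom-mapped, stoichiometrically
  balanced reaction set covering branched-chain amino-acid catabolism
  (transaminations, decarboxylations, dehydrogenations, the CoA/phosphate
  branch, the hydroxy-acid branch), the sulfur pathway (C-S lyase,
  S-methylation, the KMBA->MTAC chemical oxidation) and supporting
  reference chemistry.  Regeneration is byte-stable.

* :func:`simulate_protein_family` — gap-free protein alignments evolved on
  a known gene tree with per-branch substitution probability, plus the
  species map and true duplication clades, for exercising the phylogenetic
  ortholog machinery.

Compound structures are embedded as SMILES literals (neutral protonated
forms so that every reaction balances exactly, protons written explicitly
where transferred).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import Reaction, parse_reaction_smiles
from .db import ReactionDB, write_db
from .phylo import TreeNode, label_events, parse_newick

__all__ = [
    "COMPOUNDS",
    "FixtureManifest",
    "ProteinFamily",
    "build_flavor_network",
    "flavor_network_db",
    "simulate_protein_family",
    "write_family_fasta",
    "write_species_map",
    "DEFAULT_FAMILY_TREE",
]

# --------------------------------------------------------------------------
# shared cofactor fragments (atom maps aligned across both redox states so
# that every reaction using them is fully and consistently mapped)

_NAD_TAIL = (
    "[CH:110]2[O:111][CH:112]([CH2:113][O:114][P:115](=[O:116])([OH:117])"
    "[O:118][P:119](=[O:120])([OH:121])[O:122][CH2:123][CH:124]3[O:125]"
    "[CH:126]([n:127]4[cH:128][n:129][c:130]5[c:131]([NH2:132])[n:133]"
    "[cH:134][n:135][c:136]45)[CH:137]([OH:138])[CH:139]3[OH:140])"
    "[CH:141]([OH:142])[CH:143]2[OH:144]"
)
NAD_OX = (
    "[NH2:101][C:102](=[O:103])[c:104]1[cH:105][cH:106][cH:107][n+:108]([cH:109]1)"
    + _NAD_TAIL
)
NAD_RED = (
    "[NH2:101][C:102](=[O:103])[C:104]1=[CH:109][N:108]([CH:107]=[CH:106][CH2:105]1)"
    + _NAD_TAIL
)

_COA_REST = (
    "[CH2:202][CH2:203][NH:204][C:205](=[O:206])[CH2:207][CH2:208][NH:209]"
    "[C:210](=[O:211])[CH:212]([OH:213])[C:214]([CH3:215])([CH3:216])"
    "[CH2:217][O:218][P:219](=[O:220])([OH:221])[O:222][P:223](=[O:224])"
    "([OH:225])[O:226][CH2:227][CH:228]1[O:229][CH:230]([n:231]2[cH:232]"
    "[n:233][c:234]3[c:235]([NH2:236])[n:237][cH:238][n:239][c:240]23)"
    "[CH:241]([OH:242])[CH:243]1[O:244][P:245](=[O:246])([OH:247])[OH:248]"
)
COA_SH = "[SH:201]" + _COA_REST
COA_THIO = "[S:201]" + _COA_REST  # continuation after an acyl carbonyl

_ADP_CORE = (
    "[P:62](=[O:63])([OH:64])[O:65][P:66](=[O:67])([OH:68])[O:69][CH2:70]"
    "[CH:71]1[O:72][CH:73]([n:74]2[cH:75][n:76][c:77]3[c:78]([NH2:79])"
    "[n:80][cH:81][n:82][c:83]23)[CH:84]([OH:85])[CH:86]1[OH:87]"
)
ADP = "[OH:61]" + _ADP_CORE
ATP = "[P:51](=[O:52])([OH:53])([OH:54])[O:61]" + _ADP_CORE

_ADOSYL = (
    "[CH2:20][CH:21]1[O:22][CH:23]([n:24]2[cH:25][n:26][c:27]3[c:28]"
    "([NH2:29])[n:30][cH:31][n:32][c:33]23)[CH:34]([OH:35])[CH:36]1[OH:37]"
)
_HCY_ARM = "[CH2:11][CH2:12][CH:13]([NH2:14])[C:15](=[O:16])[OH:17]"
ADOMET = "[CH3:9][S+:10](" + _ADOSYL + ")" + _HCY_ARM
ADOHCY = "[S:10](" + _ADOSYL + ")" + _HCY_ARM

# unmapped canonical structures for tests / precursor files
COMPOUNDS: dict[str, str] = {
    "leucine": "CC(C)CC(N)C(=O)O",
    "valine": "CC(C)C(N)C(=O)O",
    "isoleucine": "CCC(C)C(N)C(=O)O",
    "alanine": "CC(N)C(=O)O",
    "glutamate": "NC(CCC(=O)O)C(=O)O",
    "oxoglutarate": "O=C(O)CCC(=O)C(=O)O",
    "pyruvate": "CC(=O)C(=O)O",
    "KICA": "CC(C)CC(=O)C(=O)O",
    "KIVA": "CC(C)C(=O)C(=O)O",
    "KMVA": "CCC(C)C(=O)C(=O)O",
    "HICA": "CC(C)CC(O)C(=O)O",
    "3-methylbutanal": "CC(C)CC=O",
    "3-methylbutanol": "CC(C)CCO",
    "3-methylbutanoic acid": "CC(C)CC(=O)O",
    "2-methylpropanal": "CC(C)C=O",
    "lactate": "CC(O)C(=O)O",
    "acetate": "CC(=O)O",
    "oxalic acid": "O=C(O)C(=O)O",
    "KMBA": "CSCCC(=O)C(=O)O",
    "MTAC": "CSCC=O",
    "methionine": "CSCCC(N)C(=O)O",
    "homocysteine": "SCCC(N)C(=O)O",
    "methanethiol": "CS",
    "DMS": "CSC",
    "DMSO": "CS(=O)C",
    "ethanethiol": "CCS",
    "2-oxobutanoate": "CCC(=O)C(=O)O",
    "ethanol": "CCO",
    "water": "O",
    "O2": "O=O",
    "CO2": "O=C=O",
    "ammonia": "N",
    "proton": "[H+]",
    "phosphate": "OP(=O)(O)O",
    "S-AdoMet": "C[S+](CCC(N)C(=O)O)CC1OC(n2cnc3c(N)ncnc32)C(O)C1O",
    "S-AdoHcy": "NC(CCSCC1OC(n2cnc3c(N)ncnc32)C(O)C1O)C(=O)O",
}

# leucine / keto-acid skeletons used repeatedly below
_LEU = "[CH3:1][CH:2]([CH3:3])[CH2:4][CH:5]([NH2:6])[C:7](=[O:8])[OH:9]"
_KICA = "[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:6])[C:7](=[O:8])[OH:9]"
_OXOGLU = "[OH:10][C:11](=[O:12])[CH2:13][CH2:14][C:15](=[O:16])[C:17](=[O:18])[OH:19]"


def _glutamate(n_map: int) -> str:
    return (
        f"[OH:10][C:11](=[O:12])[CH2:13][CH2:14][CH:15]([NH2:{n_map}])"
        "[C:17](=[O:18])[OH:19]"
    )


@dataclass(frozen=True)
class _Row:
    id: str
    smiles: str
    reversibility: str
    ec: tuple[str, ...] = ()
    names: tuple[str, ...] = ()
    source: str = "fixture:flavor-network"
    in_default_profile: bool = True


_ROWS: tuple[_Row, ...] = (
    # --- transaminations (three oxoglutarate acceptors, one pyruvate) ---
    _Row(
        "R001",
        f"{_LEU}.{_OXOGLU}"
        ">>[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:16])[C:7](=[O:8])[OH:9]"
        f".{_glutamate(6)}",
        "reversible",
        ("2.6.1.42",),
        ("BcAT",),
    ),
    _Row(
        "R002",
        f"[CH3:1][CH:2]([CH3:3])[CH:5]([NH2:6])[C:7](=[O:8])[OH:9].{_OXOGLU}"
        ">>[CH3:1][CH:2]([CH3:3])[C:5](=[O:16])[C:7](=[O:8])[OH:9]"
        f".{_glutamate(6)}",
        "reversible",
        ("2.6.1.42",),
        ("BcAT",),
    ),
    _Row(
        "R003",
        f"[CH3:1][CH2:2][CH:3]([CH3:4])[CH:5]([NH2:6])[C:7](=[O:8])[OH:9].{_OXOGLU}"
        ">>[CH3:1][CH2:2][CH:3]([CH3:4])[C:5](=[O:16])[C:7](=[O:8])[OH:9]"
        f".{_glutamate(6)}",
        "reversible",
        ("2.6.1.42",),
        ("BcAT",),
    ),
    _Row(
        "R004",
        f"{_LEU}.[CH3:10][C:11](=[O:12])[C:13](=[O:14])[OH:15]"
        ">>[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:12])[C:7](=[O:8])[OH:9]"
        ".[CH3:10][CH:11]([NH2:6])[C:13](=[O:14])[OH:15]",
        "irreversible",
        ("2.6.1.66",),
        ("alanine aminotransferase",),
    ),
    # --- keto-acid decarboxylations ---
    _Row(
        "R005",
        f"{_KICA}"
        ">>[CH3:1][CH:2]([CH3:3])[CH2:4][CH:5]=[O:6].[O:8]=[C:7]=[O:9]",
        "irreversible",
        ("4.1.1.72",),
        ("KdcA",),
    ),
    _Row(
        "R006",
        "[CH3:1][CH:2]([CH3:3])[C:4](=[O:5])[C:6](=[O:7])[OH:8]"
        ">>[CH3:1][CH:2]([CH3:3])[CH:4]=[O:5].[O:7]=[C:6]=[O:8]",
        "irreversible",
        ("4.1.1.72",),
        ("KdcA",),
    ),
    # --- aldehyde reduction / oxidation ---
    _Row(
        "R007",
        f"[CH3:1][CH:2]([CH3:3])[CH2:4][CH:5]=[O:6].{NAD_RED}.[H+]"
        f">>[CH3:1][CH:2]([CH3:3])[CH2:4][CH2:5][OH:6].{NAD_OX}",
        "reversible",
        ("1.1.1.1",),
        ("AlcDH",),
    ),
    _Row(
        "R008",
        f"[CH3:1][CH:2]([CH3:3])[CH2:4][CH:5]=[O:6].{NAD_OX}.[OH2:7]"
        f">>[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:6])[OH:7].{NAD_RED}.[H+]",
        "irreversible",
        ("1.2.1.3",),
        ("AldDH",),
    ),
    # --- oxidative decarboxylation branch: CoA / phosphate / kinase ---
    _Row(
        "R009",
        f"{_KICA}.{COA_SH}.{NAD_OX}"
        f">>[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:6]){COA_THIO}"
        f".[O:8]=[C:7]=[O:9].{NAD_RED}.[H+]",
        "irreversible",
        ("1.2.4.4",),
        ("KaDH",),
    ),
    _Row(
        "R010",
        f"[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:6]){COA_THIO}"
        ".[OH:50][P:51](=[O:52])([OH:53])[OH:54]"
        ">>[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:6])[O:50][P:51](=[O:52])([OH:53])[OH:54]"
        f".{COA_SH}",
        "reversible",
        ("2.3.1.8",),
        ("PTA",),
    ),
    _Row(
        "R011",
        "[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:6])[O:50][P:51](=[O:52])([OH:53])[OH:54]"
        f".{ADP}"
        f">>[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:6])[OH:50].{ATP}",
        "irreversible",
        ("2.7.2.1",),
        ("ACK",),
    ),
    # --- hydroxy-acid branch ---
    _Row(
        "R012",
        f"{_KICA}.{NAD_RED}.[H+]"
        f">>[CH3:1][CH:2]([CH3:3])[CH2:4][CH:5]([OH:6])[C:7](=[O:8])[OH:9].{NAD_OX}",
        "reversible",
        ("1.1.1.345",),
        ("HycDH",),
    ),
    _Row(
        "R013",
        "[CH3:1][CH:2]([OH:3])[C:4](=[O:5])[OH:6].[O:7]=[O:8]"
        ">>[CH3:1][C:2](=[O:7])[OH:3].[O:5]=[C:4]=[O:6].[OH2:8]",
        "irreversible",
        ("1.13.12.4",),
        ("lactate 2-monooxygenase",),
    ),
    # --- chemical oxidation (sulfur pathway reference, no enzyme) ---
    _Row(
        "R014",
        "[CH3:1][S:2][CH2:3][CH2:4][C:5](=[O:6])[C:7](=[O:8])[OH:9].[O:10]=[O:11]"
        ">>[CH3:1][S:2][CH2:3][CH:4]=[O:10]"
        ".[O:8]=[C:7]([OH:9])[C:5](=[O:6])[OH:11]",
        "irreversible",
        (),
        (),
        source="fixture:chemical",
    ),
    # --- methionine catabolism ---
    _Row(
        "R015",
        "[CH3:1][S:2][CH2:3][CH2:4][CH:5]([NH2:6])[C:7](=[O:8])[OH:9].[OH2:10]"
        ">>[CH3:1][SH:2].[CH3:3][CH2:4][C:5](=[O:10])[C:7](=[O:8])[OH:9].[NH3:6]",
        "irreversible",
        ("4.4.1.11",),
        ("C-S lyase",),
    ),
    _Row(
        "R016",
        f"[SH:1][CH2:2][CH2:3][CH:4]([NH2:5])[C:6](=[O:7])[OH:8].{ADOMET}"
        f">>[CH3:9][S:1][CH2:2][CH2:3][CH:4]([NH2:5])[C:6](=[O:7])[OH:8].{ADOHCY}.[H+]",
        "irreversible",
        ("2.1.1.10", "2.1.1.13"),
        ("homocysteine S-methyltransferase", "methionine synthase"),
    ),
    _Row(
        "R017",
        f"[CH3:1][CH2:2][SH:3].{ADOMET}"
        f">>[CH3:1][CH2:2][S:3][CH3:9].{ADOHCY}.[H+]",
        "irreversible",
        ("2.1.1.9",),
        ("thiol S-methyltransferase",),
    ),
    # --- esterase (manifest-documented, excluded from default retro profile) ---
    _Row(
        "R018",
        "[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:6])[OH:7].[OH:10][CH2:11][CH3:12]"
        ">>[CH3:1][CH:2]([CH3:3])[CH2:4][C:5](=[O:6])[O:10][CH2:11][CH3:12].[OH2:7]",
        "irreversible",
        ("3.1.1.1",),
        ("EstA",),
        in_default_profile=False,
    ),
    # --- DMS reference chemistry ---
    _Row(
        "R019",
        f"[CH3:1][S:2](=[O:3])[CH3:4].{NAD_RED}.[H+]"
        f">>[CH3:1][S:2][CH3:4].{NAD_OX}.[OH2:3]",
        "unknown",
        ("1.8.5.3",),
        ("DMSO reductase",),
    ),
)


@dataclass(frozen=True)
class FixtureManifest:
    """What the generated network contains; regeneration is byte-stable."""

    name: str
    reaction_count: int
    compounds: tuple[tuple[str, str], ...]  # (name, canonical SMILES)
    enzymes: tuple[str, ...]
    reversibility: tuple[tuple[str, str], ...]  # (reaction id, flag)
    default_profile_excluded: tuple[str, ...]

    def compound_smiles(self, name: str) -> str:
        return dict(self.compounds)[name]


def flavor_network_db() -> tuple[ReactionDB, FixtureManifest]:
    """Build the in-memory flavor-network reaction database + manifest."""
    db = ReactionDB()
    for row in _ROWS:
        rxn = parse_reaction_smiles(
            row.id,
            row.smiles,
            row.reversibility,
            ec_numbers=row.ec,
            enzyme_names=row.names,
            source=row.source,
        )
        db.add(rxn)
    from .chem import parse_molecule

    compounds = tuple(
        (name, parse_molecule(smi).canonical_smiles) for name, smi in COMPOUNDS.items()
    )
    manifest = FixtureManifest(
        name="flavor-network",
        reaction_count=len(db),
        compounds=compounds,
        enzymes=tuple(sorted({n for r in _ROWS for n in r.names})),
        reversibility=tuple((r.id, r.reversibility) for r in _ROWS),
        default_profile_excluded=tuple(
            r.id for r in _ROWS if not r.in_default_profile
        ),
    )
    return db, manifest


def build_flavor_network(path: str | Path) -> FixtureManifest:
    """Write the flavor-network reaction TSV; returns the manifest."""
    db, manifest = flavor_network_db()
    write_db(db, path)
    return manifest


# --------------------------------------------------------------------------
# simulated protein families

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_FAMILY_TREE = (
    "(((lox1_lpl:1,lox1_lla:1):1,lox1_sth:1):1,"
    "((lox2_lpl:1,lox2_lla:1):1,lox2_sth:1):1);"
)


@dataclass(frozen=True)
class ProteinFamily:
    aligned: tuple[tuple[str, str], ...]  # (leaf name, sequence), gap-free
    species_map: tuple[tuple[str, str], ...]
    true_tree: TreeNode
    true_duplication_clades: tuple[frozenset, ...]

    def species_dict(self) -> dict[str, str]:
        return dict(self.species_map)


def simulate_protein_family(
    true_tree: str | TreeNode,
    seq_length: int = 500,
    sub_rate: float = 0.05,
    seed: int = 0,
) -> ProteinFamily:
    """Evolve a gap-free protein family along a known gene tree.

    The root sequence is uniform over the 20 amino acids; along every
    branch each site independently substitutes with probability
    ``sub_rate`` to a uniformly chosen different residue.  No indels, so
    the leaf sequences are trivially aligned.  Species are taken from the
    leaf-name suffix after the last underscore.  Deterministic per seed.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not (0 <= sub_rate < 1):
        raise ValueError("sub_rate must be in [0, 1)")
    tree = parse_newick(true_tree) if isinstance(true_tree, str) else true_tree.copy()
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    root_seq = rng.integers(0, len(alphabet), size=seq_length)

    leaves: list[tuple[str, str]] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            mutated = seq.copy()
            hit = rng.random(seq_length) < sub_rate
            if hit.any():
                shifts = rng.integers(1, len(alphabet), size=int(hit.sum()))
                mutated[hit] = (mutated[hit] + shifts) % len(alphabet)
            if child.is_leaf:
                leaves.append(
                    (child.name, b"".join(alphabet[mutated]).decode())
                )
            else:
                descend(child, mutated)

    descend(tree, root_seq)
    species_map = {name: name.rsplit("_", 1)[-1] for name, _ in leaves}
    labeled = label_events(tree, species_map, root=False)
    dup_clades = tuple(
        sorted(
            (
                node.leaf_names()
                for node in labeled.walk()
                if node.event == "duplication"
            ),
            key=sorted,
        )
    )
    return ProteinFamily(
        aligned=tuple(leaves),
        species_map=tuple(sorted(species_map.items())),
        true_tree=labeled,
        true_duplication_clades=dup_clades,
    )


def write_family_fasta(family: ProteinFamily, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, seq in family.aligned:
            fh.write(f">{name}\n{seq}\n")


def write_species_map(family: ProteinFamily, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("seq_id\tspecies_id\n")
        for name, species in family.species_map:
            fh.write(f"{name}\t{species}\n")
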