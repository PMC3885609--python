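"""Gene-tree construction and ortholog inference.

Pipeline: aligned protein sequences -> p-distances -> neighbor-joining tree
(deterministic tie-break) -> bootstrap supports from column resampling ->
midpoint rooting -> duplication/speciation labeling by the species-overlap
rule -> ortholog verdict for a seed gene in a target species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TreeNode",
    "DistanceMatrix",
    "PhyloError",
    "parse_newick",
    "to_newick",
    "p_distances",
    "nj_tree",
    "midpoint_root",
    "bootstrap_supports",
    "label_events",
    "ortholog_verdict",
    "OrthologVerdict",
    "bipartitions",
    "pairwise_align",
    "tree_length",
]

GAP_CHARS = frozenset("-.")


class PhyloError(ValueError):
    pass


# --------------------------------------------------------------------------
# tree structure and Newick I/O


@dataclass
class TreeNode:
    """Gene-tree node.  Leaves carry ``name`` (and later ``species``);
    internal nodes may carry bootstrap ``support`` (percent) and an
    ``event`` label ('speciation' | 'duplication')."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None
    event: str | None = None
    species: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def copy(self) -> "TreeNode":
        return TreeNode(
            name=self.name,
            length=self.length,
            children=[c.copy() for c in self.children],
            support=self.support,
            event=self.event,
            species=self.species,
        )


_TOKEN = re.compile(r"\(|\)|,|;|:[-+0-9.eE]+|\[&&NHX[^\]]*\]|[^(),:;\[\]]+")


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (branch lengths, internal labels, NHX event tags)."""
    tokens = _TOKEN.findall(text.strip())
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(tokens) and tokens[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(tokens):
                    raise PhyloError("unbalanced parentheses in newick")
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
                raise PhyloError(f"unexpected token {tokens[pos]!r}")
        while pos < len(tokens) and tokens[pos] not in "(),;":
            tok = tokens[pos]
            if tok.startswith(":"):
                node.length = float(tok[1:])
            elif tok.startswith("[&&NHX"):
                m = re.search(r"Ev=([DS])", tok)
                if m:
                    node.event = "duplication" if m.group(1) == "D" else "speciation"
            else:
                if node.is_leaf:
                    node.name = tok
                else:
                    try:  # internal label = bootstrap support
                        node.support = float(tok)
                    except ValueError:
                        node.name = tok
            pos += 1
        return node

    root = parse_node()
    return root


def to_newick(node: TreeNode, supports: bool = True, nhx_events: bool = True) -> str:
    """Serialize to Newick; bootstrap supports as internal labels and event
    labels as NHX tags (``[&&NHX:Ev=D]`` / ``Ev=S``)."""

    def fmt(n: TreeNode, top: bool = False) -> str:
        if n.is_leaf:
            body = n.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if supports and n.support is not None:
                body += f"{n.support:g}"
        if not top:
            body += f":{n.length:g}"
        if nhx_events and n.event is not None:
            body += f"[&&NHX:Ev={'D' if n.event == 'duplication' else 'S'}]"
        return body

    return fmt(node, top=True) + ";"


# --------------------------------------------------------------------------
# distances


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise PhyloError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise PhyloError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise PhyloError("distances must be nonnegative")


def _as_pairs(aligned) -> list[tuple[str, str]]:
    if isinstance(aligned, dict):
        return list(aligned.items())
    return list(aligned)


def p_distances(aligned) -> DistanceMatrix:
    """Pairwise p-distances: mismatches / shared non-gap columns.

    ``aligned`` is a dict or list of (id, sequence) with equal lengths.
    Raises on ragged input or on a pair sharing no ungapped columns.
    """
    pairs = _as_pairs(aligned)
    if len(pairs) < 2:
        raise PhyloError("need at least 2 sequences")
    length = len(pairs[0][1])
    for name, seq in pairs:
        if len(seq) != length:
            raise PhyloError(f"ragged alignment: {name!r} has length {len(seq)} != {length}")
    labels = tuple(name for name, _ in pairs)
    arr = np.array([list(seq) for _, seq in pairs])
    gap = np.isin(arr, list(GAP_CHARS))
    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            total = int(shared.sum())
            if total == 0:
                raise PhyloError(
                    f"sequences {labels[i]!r} and {labels[j]!r} share no ungapped columns"
                )
            mism = int((arr[i][shared] != arr[j][shared]).sum())
            d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(labels=labels, matrix=d)


# --------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining, deterministic.

    Ties on the Q criterion are broken by the smallest (i, j) pair in the
    current node ordering; negative branch lengths are clamped to zero.
    The result is an unrooted tree rendered with a trifurcating root
    (a single edge for two taxa).
    """
    n = len(dm.labels)
    if n < 2:
        raise PhyloError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    d = dm.matrix.astype(float).copy()
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def D(i, j):
        return dist[(min(i, j), max(i, j))] if i != j else 0.0

    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = D(i, j) - li
        parent = TreeNode()
        ci, cj = node_of[i], node_of[j]
        ci.length = max(0.0, li)
        cj.length = max(0.0, lj)
        parent.children = [ci, cj]
        node_of[next_id] = parent
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D(i, k) + D(j, k) - D(i, j))
            dist[(min(next_id, k), max(next_id, k))] = max(0.0, dk)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    root = TreeNode()
    if len(active) == 2:
        i, j = active
        a, b = node_of[i], node_of[j]
        a.length = D(i, j) / 2
        b.length = D(i, j) / 2
        root.children = [a, b]
    else:
        i, j, k = active
        a, b, c = node_of[i], node_of[j], node_of[k]
        a.length = max(0.0, 0.5 * (D(i, j) + D(i, k) - D(j, k)))
        b.length = max(0.0, 0.5 * (D(i, j) + D(j, k) - D(i, k)))
        c.length = max(0.0, 0.5 * (D(i, k) + D(j, k) - D(i, j)))
        root.children = [a, b, c]
    return root


def tree_length(tree: TreeNode) -> float:
    return sum(n.length for n in tree.walk() if n is not tree)


# --------------------------------------------------------------------------
# bipartitions and bootstrap


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of an (un)rooted tree, each represented by the
    side not containing the lexicographically smallest taxon."""
    all_taxa = tree.leaf_names()
    anchor = min(all_taxa)
    splits = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_taxa - side
        if len(side) >= 2 and len(all_taxa - side) >= 2:
            splits.add(side)
    return splits


def bootstrap_supports(aligned, n: int, seed: int) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports.

    ``n`` column-resampled replicates (with replacement); the support of
    each internal bipartition of the full-data tree is the percentage of
    replicate trees containing it.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise PhyloError("bootstrap replicate count must be >= 1")
    pairs = _as_pairs(aligned)
    full = nj_tree(p_distances(pairs))
    counts: dict[frozenset, int] = {s: 0 for s in bipartitions(full)}
    rng = np.random.default_rng(seed)
    ncol = len(pairs[0][1])
    names = [name for name, _ in pairs]
    seqs = np.array([list(seq) for _, seq in pairs])
    for _ in range(n):
        cols = rng.integers(0, ncol, size=ncol)
        rep = [(name, "".join(seqs[i][cols])) for i, name in enumerate(names)]
        rep_splits = bipartitions(nj_tree(p_distances(rep)))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    all_taxa = full.leaf_names()
    anchor = min(all_taxa)
    for node in full.walk():
        if node is full or node.is_leaf:
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_taxa - side
        if side in counts:
            node.support = 100.0 * counts[side] / n
    return full


# --------------------------------------------------------------------------
# rooting


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    # collect undirected edges
    edges: list[tuple[int, int, float, TreeNode]] = []
    ids: dict[int, TreeNode] = {}

    def index(node: TreeNode, parent_id: int | None):
        nid = id(node)
        ids[nid] = node
        if parent_id is not None:
            edges.append((parent_id, nid, node.length, node))
        for c in node.children:
            index(c, nid)

    index(tree, None)
    adj: dict[int, list[tuple[int, float]]] = {}
    for a, b, w, _ in edges:
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    leaves = [id(l) for l in tree.leaves()]

    def paths_from(src):
        dist = {src: 0.0}
        prev: dict[int, int] = {}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    best = (-1.0, None, None, None)
    for src in leaves:
        dist, prev = paths_from(src)
        far = max(leaves, key=lambda l: (dist[l], ids[l].name or ""))
        if dist[far] > best[0]:
            best = (dist[far], src, far, prev)
    total, src, far, prev = best
    # walk back from far to src accumulating distance; find midpoint edge
    path = [far]
    while path[-1] != src:
        path.append(prev[path[-1]])
    half = total / 2.0
    acc = 0.0
    w_lookup = {frozenset((a, b)): w for a, b, w, _ in edges}
    for k in range(len(path) - 1):
        w = w_lookup[frozenset((path[k], path[k + 1]))]
        if acc + w >= half - 1e-12:
            offset = half - acc  # distance from path[k] into this edge
            return _reroot_on_edge(tree, ids[path[k]], ids[path[k + 1]], offset, w)
        acc += w
    return tree.copy()  # degenerate (zero-length tree)


def _reroot_on_edge(
    tree: TreeNode, end_a: TreeNode, end_b: TreeNode, offset_from_a: float, edge_len: float
) -> TreeNode:
    """Build a rooted copy with the root inserted on edge (end_a, end_b)."""
    parent_map: dict[int, TreeNode | None] = {id(tree): None}
    for node in tree.walk():
        for c in node.children:
            parent_map[id(c)] = node
    # the edge belongs to whichever endpoint is the child
    child = end_b if parent_map.get(id(end_b)) is end_a else end_a
    other = end_a if child is end_b else end_b
    dist_child = offset_from_a if child is end_a else edge_len - offset_from_a

    def hang(node: TreeNode, came_from: TreeNode | None) -> TreeNode:
        """Copy of the tree as seen from ``node`` walking away from ``came_from``."""
        new = TreeNode(
            name=node.name, support=node.support, event=node.event, species=node.species
        )
        neigh: list[tuple[TreeNode, float]] = []
        for c in node.children:
            if c is not came_from:
                neigh.append((c, c.length))
        p = parent_map.get(id(node))
        if p is not None and p is not came_from:
            neigh.append((p, node.length))
        for nb, ln in neigh:
            sub = hang(nb, node)
            sub.length = ln
            new.children.append(sub)
        return new

    root = TreeNode()
    side_child = hang(child, other)
    side_child.length = max(0.0, dist_child)
    side_other = hang(other, child)
    side_other.length = max(0.0, edge_len - dist_child)
    # edge support travels with the split
    side_child.support = child.support if not child.is_leaf else None
    root.children = [side_child, side_other]
    return root


# --------------------------------------------------------------------------
# event labeling and orthology


def label_events(tree: TreeNode, species_map: dict[str, str], root: bool = True) -> TreeNode:
    """Label internal nodes duplication/speciation by species overlap.

    The tree is midpoint-rooted first unless ``root=False`` (already
    rooted/binary).  An internal node is a duplication iff the species sets
    of its child clades intersect, else a speciation.  Raises on leaves
    missing from ``species_map``.
    """
    labeled = midpoint_root(tree) if root else tree.copy()
    for leaf in labeled.leaves():
        if leaf.name not in species_map:
            raise PhyloError(f"no species mapping for leaf {leaf.name!r}")
        leaf.species = species_map[leaf.name]

    def species_of(node: TreeNode) -> set:
        if node.is_leaf:
            return {node.species}
        sets = [species_of(c) for c in node.children]
        overlap = any(
            sets[i] & sets[j] for i in range(len(sets)) for j in range(i + 1, len(sets))
        )
        node.event = "duplication" if overlap else "speciation"
        return set().union(*sets)

    species_of(labeled)
    return labeled


@dataclass(frozen=True)
class OrthologVerdict:
    found: bool
    leaf_ids: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.found


def ortholog_verdict(
    tree: TreeNode,
    seed_leaf: str,
    target_species: str,
    min_support: float | None = None,
) -> OrthologVerdict:
    """Orthologs of ``seed_leaf`` by the species-overlap rule: a leaf is an
    ortholog of the seed iff their last common ancestor is labeled a
    speciation (the event at the divergence point decides the relation, as
    in standard species-overlap orthology); the verdict reports the
    orthologs belonging to ``target_species``.  ``none_found`` downgrades
    the associated reaction's confidence.

    With ``min_support`` set, a speciation ancestor whose bootstrap support
    falls below the threshold does not transmit orthology.
    """
    by_name = {l.name: l for l in tree.leaves()}
    if seed_leaf not in by_name:
        raise PhyloError(f"seed leaf {seed_leaf!r} not in tree")
    parent: dict[int, TreeNode | None] = {id(tree): None}
    for node in tree.walk():
        for c in node.children:
            parent[id(c)] = node

    def path_to_root(node: TreeNode) -> list[TreeNode]:
        out = []
        cur: TreeNode | None = node
        while cur is not None:
            out.append(cur)
            cur = parent[id(cur)]
        return out

    seed_path = path_to_root(by_name[seed_leaf])
    seed_index = {id(n): k for k, n in enumerate(seed_path)}

    def speciation_ok(node: TreeNode) -> bool:
        if node.event != "speciation":
            return False
        if min_support is not None and node.support is not None:
            return node.support >= min_support
        return True

    hits = []
    for leaf in tree.leaves():
        if leaf.name == seed_leaf:
            continue
        lca = next(anc for anc in path_to_root(leaf) if id(anc) in seed_index)
        if speciation_ok(lca) and (leaf.species or "") == target_species:
            hits.append(leaf.name)
    hits.sort()
    return OrthologVerdict(found=bool(hits), leaf_ids=tuple(hits))


# --------------------------------------------------------------------------
# pairwise alignment convenience (distance estimation for unaligned input)


def pairwise_align(a: str, b: str, match: int = 1, mismatch: int = 0, gap: int = -1):
    """Needleman–Wunsch global alignment (linear gap penalty).

    Returns (aligned_a, aligned_b, score).  Convenience only — a full
    progressive MSA is out of scope; pre-aligned input is preferred.
    """
    la, lb = len(a), len(b)
    score = np.zeros((la + 1, lb + 1))
    score[:, 0] = np.arange(la + 1) * gap
    score[0, :] = np.arange(lb + 1) * gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i, j] = max(diag, score[i - 1, j] + gap, score[i, j - 1] + gap)
    out_a, out_b = [], []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[la, lb])
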