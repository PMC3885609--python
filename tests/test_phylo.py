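import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpe.phylo import (
    DistanceMatrix,
    OrthologVerdict,
    PhyloError,
    TreeNode,
    bipartitions,
    bootstrap_supports,
    label_events,
    midpoint_root,
    nj_tree,
    ortholog_verdict,
    p_distances,
    pairwise_align,
    parse_newick,
    to_newick,
)

# --------------------------------------------------------------------------
# independent oracles


def _random_tree_matrix(rng, n):
    """Random binary unrooted tree on n labeled taxa with positive edge
    lengths; returns (split set, additive distance matrix)."""
    labels = [f"t{i}" for i in range(n)]
    # edge-list representation: start from a 3-star, insert leaves on edges
    next_node = n
    center = next_node
    next_node += 1
    edges = {(0, center), (1, center), (2, center)}
    for leaf in range(3, n):
        edge = sorted(edges)[rng.integers(0, len(edges))]
        edges.discard(edge)
        mid = next_node
        next_node += 1
        a, b = edge
        edges |= {(a, mid), (b, mid), (leaf, mid)}
    lengths = {tuple(sorted(e)): float(rng.uniform(0.5, 2.0)) for e in edges}
    adj = {}
    for (a, b), w in lengths.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    d = np.zeros((n, n))
    for i in range(n):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j in range(n):
            d[i, j] = dist[j]
    splits = _splits_of_edges(edges, labels, n)
    return labels, splits, d


def _splits_of_edges(edges, labels, n):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    splits = set()
    for a, b in edges:
        # leaves on the 'a' side when edge (a,b) removed
        seen = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v != b and v not in seen and not (u == a and v == b):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
        side = frozenset(labels[x] for x in seen if x < n)
        if 2 <= len(side) <= n - 2:
            if labels[0] in side:
                side = frozenset(labels) - side
            splits.add(side)
    return splits


def _enumerate_topologies(n):
    """All unrooted binary topologies on taxa 0..n-1 as edge sets
    (internal node ids start at n)."""
    assert n >= 3
    base = [({(0, n), (1, n), (2, n)}, n + 1)]
    for leaf in range(3, n):
        nxt = []
        for edges, next_node in base:
            for edge in sorted(edges):
                mid = next_node
                a, b = edge
                new_edges = set(edges)
                new_edges.discard(edge)
                new_edges |= {(a, mid), (b, mid), (leaf, mid)}
                nxt.append((new_edges, next_node + 1))
        base = nxt
    return [e for e, _ in base]


def _lsq_fit_rss(edges, n, d):
    """Least-squares branch-length fit of a topology to a distance matrix."""
    adj = {}
    edge_list = sorted(tuple(sorted(e)) for e in edges)
    index = {e: k for k, e in enumerate(edge_list)}
    for a, b in edge_list:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    rows, rhs = [], []
    for i, j in itertools.combinations(range(n), 2):
        # path i -> j
        prev = {i: None}
        stack = [i]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in prev:
                    prev[v] = u
                    stack.append(v)
        row = np.zeros(len(edge_list))
        u = j
        while prev[u] is not None:
            row[index[tuple(sorted((u, prev[u])))] ] = 1.0
            u = prev[u]
        rows.append(row)
        rhs.append(d[i, j])
    A = np.array(rows)
    b = np.array(rhs)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    rss = float(np.sum((A @ x - b) ** 2))
    return rss


def _best_topology_splits(n, d, labels):
    best = None
    for edges in _enumerate_topologies(n):
        rss = _lsq_fit_rss(edges, n, d)
        if best is None or rss < best[0] - 1e-9:
            best = (rss, edges)
    return _splits_of_edges(best[1], labels, n)


# --------------------------------------------------------------------------


class TestPDistances:
    def test_identical_sequences_zero(self):
        dm = p_distances([("a", "ACDEFG"), ("b", "ACDEFG")])
        assert dm.matrix[0, 1] == 0.0

    def test_single_mismatch(self):
        dm = p_distances([("a", "ACDEFG"), ("b", "ACDEFY")])
        assert dm.matrix[0, 1] == pytest.approx(1 / 6)

    def test_gaps_excluded_from_denominator(self):
        dm = p_distances([("a", "AC-EFG"), ("b", "ACD-FG")])
        assert dm.matrix[0, 1] == 0.0  # 4 shared columns, all identical

    def test_no_shared_columns_raises(self):
        with pytest.raises(PhyloError, match="no ungapped"):
            p_distances([("a", "AC--"), ("b", "--DE")])

    def test_ragged_alignment_raises(self):
        with pytest.raises(PhyloError, match="ragged"):
            p_distances([("a", "ACDE"), ("b", "ACD")])


class TestNJTree:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree = nj_tree(dm)
        assert tree.leaf_names() == frozenset({"a", "b"})
        assert sum(c.length for c in tree.children) == pytest.approx(0.4)

    def test_close_pair_joined_first_on_three_taxa(self):
        # Q-matrix computation by hand: (a,b) closest, joined first
        d = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        # unrooted 3-star; exact edge lengths from the three-point formulas
        lengths = {c.name: c.length for c in tree.children}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.1)
        assert lengths["c"] == pytest.approx(0.7)

    def test_four_taxon_additive_recovery_vs_enumeration(self):
        rng = np.random.default_rng(7)
        labels, true_splits, d = _random_tree_matrix(rng, 4)
        tree = nj_tree(DistanceMatrix(tuple(labels), d))
        assert bipartitions(tree) == true_splits
        assert true_splits == _best_topology_splits(4, d, labels)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(PhyloError, match="symmetric"):
            DistanceMatrix(("a", "b"), m)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_recovery_matches_brute_force(self, n):
        rng = np.random.default_rng(100 + n)
        labels, true_splits, d = _random_tree_matrix(rng, n)
        tree = nj_tree(DistanceMatrix(tuple(labels), d))
        assert bipartitions(tree) == true_splits
        if n <= 6:  # full enumeration oracle (105 topologies at n=6)
            assert true_splits == _best_topology_splits(n, d, labels)
        else:  # exact-additivity oracle: NJ tree must reproduce the matrix
            assert _tree_distances_match(tree, labels, d)


def _tree_distances_match(tree, labels, d):
    # path lengths in the NJ tree vs the input matrix
    adj = {}

    def index(node, parent):
        if parent is not None:
            adj.setdefault(id(parent), []).append((id(node), node.length))
            adj.setdefault(id(node), []).append((id(parent), node.length))
        for c in node.children:
            index(c, node)

    index(tree, None)
    leaf_ids = {l.name: id(l) for l in tree.leaves()}
    for i, a in enumerate(labels):
        dist = {leaf_ids[a]: 0.0}
        stack = [leaf_ids[a]]
        while stack:
            u = stack.pop()
            for v, w in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, b in enumerate(labels):
            if i < j and abs(dist[leaf_ids[b]] - d[i, j]) > 1e-6:
                return False
    return True


class TestBootstrap:
    def _family(self, seed=0):
        from rpe.fixtures import simulate_protein_family

        fam = simulate_protein_family(
            "((a_s1:1,b_s1:1):1,(c_s2:1,d_s2:1):1);", seq_length=300,
            sub_rate=0.08, seed=seed,
        )
        return list(fam.aligned)

    def test_unanimous_split_gets_full_support(self):
        aligned = self._family()
        tree = bootstrap_supports(aligned, n=50, seed=1)
        supports = [n.support for n in tree.walk() if n.support is not None]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_support_is_binary(self):
        aligned = self._family()
        tree = bootstrap_supports(aligned, n=1, seed=3)
        for node in tree.walk():
            if node.support is not None:
                assert node.support in (0.0, 100.0)

    def test_same_seed_reproducible(self):
        aligned = self._family()
        t1 = bootstrap_supports(aligned, n=25, seed=42)
        t2 = bootstrap_supports(aligned, n=25, seed=42)
        assert to_newick(t1) == to_newick(t2)

    def test_sequence_order_invariance(self):
        aligned = self._family()
        t1 = bootstrap_supports(aligned, n=25, seed=5)
        t2 = bootstrap_supports(list(reversed(aligned)), n=25, seed=5)

        def support_map(t):
            taxa = t.leaf_names()
            anchor = min(taxa)
            out = {}
            for node in t.walk():
                if node.support is not None:
                    side = node.leaf_names()
                    if anchor in side:
                        side = taxa - side
                    out[side] = node.support
            return out

        assert support_map(t1) == support_map(t2)


class TestLabelEvents:
    def test_two_copy_family_root_duplication(self):
        tree = parse_newick("((a_s1:1,a_s2:1):1,(b_s1:1,b_s2:1):1);")
        species = {"a_s1": "s1", "a_s2": "s2", "b_s1": "s1", "b_s2": "s2"}
        labeled = label_events(tree, species)
        assert labeled.event == "duplication"
        assert all(c.event == "speciation" for c in labeled.children)

    def test_single_copy_tree_all_speciation(self):
        tree = parse_newick("((x_s1:1,x_s2:1):1,x_s3:2);")
        labeled = label_events(
            tree, {"x_s1": "s1", "x_s2": "s2", "x_s3": "s3"}, root=False
        )
        events = [n.event for n in labeled.walk() if not n.is_leaf]
        assert events and all(e == "speciation" for e in events)

    def test_partial_overlap_hand_case(self):
        tree = parse_newick("((a_s1:1,b_s1:1):1,c_s2:2);")
        labeled = label_events(
            tree, {"a_s1": "s1", "b_s1": "s1", "c_s2": "s2"}, root=False
        )
        inner = next(
            n for n in labeled.walk() if not n.is_leaf and len(n.leaves()) == 2
        )
        assert inner.event == "duplication"  # both leaves from s1
        assert labeled.event == "speciation"

    def test_unmapped_leaf_raises(self):
        tree = parse_newick("(a_s1:1,b_s1:1);")
        with pytest.raises(PhyloError, match="species"):
            label_events(tree, {"a_s1": "s1"}, root=False)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_duplication_count_pigeonhole(self, seed):
        """#duplications >= max per-species copy number - 1 on random trees."""
        from rpe.fixtures import simulate_protein_family

        rng = np.random.default_rng(seed)
        n_species = int(rng.integers(2, 4))
        n_copies = int(rng.integers(1, 4))
        leaves = [
            f"g{c}_s{s}" for c in range(n_copies) for s in range(n_species)
        ]
        rng.shuffle(leaves)

        def random_tree(names):
            if len(names) == 1:
                return names[0]
            k = int(rng.integers(1, len(names)))
            return f"({random_tree(names[:k])}:1,{random_tree(names[k:])}:1)"

        newick = random_tree(leaves) + ";"
        tree = parse_newick(newick)
        species = {l: l.rsplit("_", 1)[-1] for l in leaves}
        labeled = label_events(tree, species, root=False)
        dups = sum(1 for n in labeled.walk() if n.event == "duplication")
        assert dups >= n_copies - 1


class TestOrthologVerdict:
    def _labeled(self):
        tree = parse_newick("((a_s1:1,a_s2:1):1,(b_s1:1,b_s2:1):1);")
        species = {"a_s1": "s1", "a_s2": "s2", "b_s1": "s1", "b_s2": "s2"}
        return label_events(tree, species, root=False)

    def test_clean_clade_ortholog_found(self):
        verdict = ortholog_verdict(self._labeled(), "a_s1", "s2")
        assert verdict.found
        assert verdict.leaf_ids == ("a_s2",)

    def test_copy_across_duplication_not_ortholog(self):
        # the only s1 gene reachable from b_s2 without passing the root
        # duplication is b_s1; a_s1 must not be reported
        verdict = ortholog_verdict(self._labeled(), "b_s2", "s1")
        assert verdict.leaf_ids == ("b_s1",)

    def test_target_species_only_behind_duplication_none_found(self):
        tree = parse_newick("((a_s1:1,b_s1:1):1,c_s2:2);")
        labeled = label_events(
            tree, {"a_s1": "s1", "b_s1": "s1", "c_s2": "s2"}, root=False
        )
        # a_s1..b_s1 sit under a duplication; from a_s1 the only route to s2
        # passes the root (speciation) -> found; but from a_s1 to s1 copies
        # passes the duplication -> none
        assert ortholog_verdict(labeled, "a_s1", "s2").found
        assert not ortholog_verdict(labeled, "a_s1", "s1").found

    def test_single_species_tree_none_found(self):
        tree = parse_newick("(a_s1:1,b_s1:1);")
        labeled = label_events(tree, {"a_s1": "s1", "b_s1": "s1"}, root=False)
        assert not ortholog_verdict(labeled, "a_s1", "s9").found

    def test_missing_seed_raises(self):
        with pytest.raises(PhyloError, match="seed"):
            ortholog_verdict(self._labeled(), "zzz", "s1")


class TestNewick:
    def test_roundtrip_with_events_and_supports(self):
        tree = parse_newick("((a_s1:1,a_s2:1):1,(b_s1:1,b_s2:1):1);")
        species = {"a_s1": "s1", "a_s2": "s2", "b_s1": "s1", "b_s2": "s2"}
        labeled = label_events(tree, species, root=False)
        for n in labeled.walk():
            if not n.is_leaf and n is not labeled:
                n.support = 87.0
        text = to_newick(labeled)
        back = parse_newick(text)
        assert back.leaf_names() == labeled.leaf_names()
        assert "[&&NHX:Ev=D]" in text or "[&&NHX:Ev=S]" in text
        events = {n.event for n in back.walk() if n.event}
        assert events == {n.event for n in labeled.walk() if n.event}


class TestMidpointRoot:
    def test_midpoint_on_balanced_tree(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        rooted = midpoint_root(tree)
        sides = sorted(len(c.leaves()) for c in rooted.children)
        assert sides == [2, 2]

    def test_midpoint_pulls_long_branch(self):
        tree = parse_newick("((a:0.1,b:0.1):0.1,(c:0.1,d:10):0.1);")
        rooted = midpoint_root(tree)
        # d hangs alone on one side of the root
        singleton = min(rooted.children, key=lambda c: len(c.leaves()))
        assert singleton.leaf_names() == frozenset({"d"})


class TestPairwiseAlign:
    def test_identical(self):
        a, b, score = pairwise_align("ACDE", "ACDE")
        assert a == b == "ACDE"
        assert score == 4

    def test_gap_insertion(self):
        a, b, _ = pairwise_align("ACDE", "ACE")
        assert b.count("-") == 1
        assert a == "ACDE"
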