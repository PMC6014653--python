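"""NeighborNet ordering, circular split systems and NNLS weights."""

import numpy as np
import pytest

from harimau import InsufficientDataError, ValidationError
from harimau.craniometrics import CranioDistanceMatrix
from harimau.neighbornet import (CircularOrdering, Split, candidate_splits,
                                 estimate_weights, neighbor_net, nnet_ordering,
                                 read_splits_nexus, write_splits_nexus)


def dm(labels, d):
    return CranioDistanceMatrix(groups=list(labels), d=np.asarray(d, float))


def circular_metric(labels, order, weights_by_arc):
    """Distances from an explicit circular split system (generator oracle)."""
    n = len(labels)
    d = np.zeros((n, n))
    pos = {lab: i for i, lab in enumerate(order)}
    for (i, j), w in weights_by_arc.items():
        side = set(order[i:j + 1])
        for a in labels:
            for b in labels:
                if (a in side) != (b in side):
                    d[labels.index(a), labels.index(b)] += w
    return d


def split_weights(system):
    """Weight lookup robust to which side of each bipartition is stored."""
    out = {}
    for s, w in system.splits:
        out[s.side] = w
        out[s.other_side] = w
    return out


def tree_metric_4():
    """Additive quartet: pendant edges 1,1,1,1 and internal edge 0.5 for
    {A,B} | {C,D}."""
    labels = ["A", "B", "C", "D"]
    d = np.array([
        [0, 2, 2.5, 2.5],
        [2, 0, 2.5, 2.5],
        [2.5, 2.5, 0, 2],
        [2.5, 2.5, 2, 0],
    ], dtype=float)
    return dm(labels, d)


class TestOrdering:
    def test_three_taxa_any_ordering(self):
        o = nnet_ordering(dm("ABC", [[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0]]))
        assert sorted(o.labels) == ["A", "B", "C"]

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(InsufficientDataError):
            nnet_ordering(dm("AB", [[0, 1], [1, 0]]))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.1, 0, 1], [2, 1, 0]])
        with pytest.raises(ValidationError):
            nnet_ordering(dm("ABC", d))

    def test_quartet_neighbors_adjacent(self):
        # four-point condition: A,B and C,D must be cyclic neighbours
        o = nnet_ordering(tree_metric_4()).labels
        idx = {x: i for i, x in enumerate(o)}
        assert abs(idx["A"] - idx["B"]) in (1, 3)
        assert abs(idx["C"] - idx["D"]) in (1, 3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_generating_circular_ordering(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(5)]
        order = list(rng.permutation(labels))
        arcs = {(i, j): rng.uniform(0.2, 1.0)
                for i in range(1, 5) for j in range(i, 5)}
        d = circular_metric(labels, order, arcs)
        got = nnet_ordering(dm(labels, d))
        assert got.labels == CircularOrdering(tuple(order)).canonical().labels


class TestCandidateSplits:
    @pytest.mark.parametrize("n,count", [(3, 3), (5, 10), (8, 28)])
    def test_count_is_n_choose_2(self, n, count):
        o = CircularOrdering(tuple(f"t{i}" for i in range(n)))
        splits = candidate_splits(o)
        assert len(splits) == count
        assert len(set(s.side for s in splits)) == count
        assert all(s.is_circular(o) for s in splits)


class TestWeights:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.7, 1.1], [0.7, 0, 0.8], [1.1, 0.8, 0]])
        system = neighbor_net(dm("ABC", d))
        w = split_weights(system)
        # w_A = (d_AB + d_AC - d_BC)/2 etc.
        assert w[frozenset("A")] == pytest.approx((0.7 + 1.1 - 0.8) / 2, abs=1e-10)
        assert w[frozenset("B")] == pytest.approx((0.7 + 0.8 - 1.1) / 2, abs=1e-10)
        assert w[frozenset("C")] == pytest.approx((1.1 + 0.8 - 0.7) / 2, abs=1e-10)

    def test_additive_quartet_recovers_branch_lengths(self):
        system = neighbor_net(tree_metric_4())
        w = split_weights(system)
        for taxon in "ABCD":
            assert w[frozenset(taxon)] == pytest.approx(1.0, abs=1e-8)
        assert w[frozenset("AB")] == pytest.approx(0.5, abs=1e-8)
        # no other non-trivial split carries weight
        assert all(s.is_trivial() or
                   s.side in (frozenset("AB"), frozenset("CD"))
                   for s, _ in system.splits)

    def test_random_circular_system_roundtrip(self, rng):
        labels = [f"t{i}" for i in range(7)]
        o = CircularOrdering(tuple(labels))
        splits = candidate_splits(o)
        true_w = rng.uniform(0.05, 1.0, len(splits))
        d = np.zeros((7, 7))
        for s, w in zip(splits, true_w):
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if s.separates(a, b):
                        d[i, j] += w
        system = estimate_weights(dm(labels, d), splits)
        got = {s.side: w for s, w in system.splits}
        for s, w in zip(splits, true_w):
            assert got.get(s.side, 0.0) == pytest.approx(w, abs=1e-8)

    def test_dimension_mismatch_rejected(self):
        o = CircularOrdering(("A", "B", "C"))
        splits = candidate_splits(o)
        with pytest.raises(ValidationError):
            estimate_weights(dm("ABCD", np.zeros((4, 4))), splits)


class TestNeighborNetEndToEnd:
    def test_reconstruction_consistency_on_circular_metrics(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            order = list(rng.permutation(labels))
            arcs = {(i, j): rng.uniform(0.1, 1.0)
                    for i in range(1, n) for j in range(i, n)}
            d = circular_metric(labels, order, arcs)
            system = neighbor_net(dm(labels, d))
            rec = system.reconstructed_distance().to_frame()
            src = dm(labels, d).to_frame()
            err = max(abs(rec.loc[a, b] - src.loc[a, b])
                      for a in labels for b in labels)
            assert err <= 1e-8

    def test_weight_perturbation_never_improves_residual(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            labels = [f"t{i}" for i in range(n)]
            d = rng.uniform(0.1, 1.0, (n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            system = neighbor_net(dm(labels, d))
            splits = [s for s, _ in system.splits]
            w = np.array([wt for _, wt in system.splits])
            A = np.array([[1.0 if s.separates(labels[i], labels[j]) else 0.0
                           for s in splits]
                          for i in range(n) for j in range(i + 1, n)])
            dvec = np.array([d[i, j] for i in range(n) for j in range(i + 1, n)])
            base = np.sum((A @ w - dvec) ** 2)
            for k in range(len(w)):
                for delta in (1e-4, -1e-4):
                    w2 = w.copy()
                    w2[k] = max(0.0, w2[k] + delta)
                    assert np.sum((A @ w2 - dvec) ** 2) >= base - 1e-12

    def test_permutation_equivariance(self, rng):
        n = 6
        labels = [f"t{i}" for i in range(n)]
        d = rng.uniform(0.2, 1.5, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        sys1 = neighbor_net(dm(labels, d))
        perm = rng.permutation(n)
        sys2 = neighbor_net(dm([labels[i] for i in perm], d[np.ix_(perm, perm)]))
        w1 = {s.side: round(w, 9) for s, w in sys1.splits}
        w2 = {s.side: round(w, 9) for s, w in sys2.splits}
        assert set(w1) == set(w2)
        for k in w1:
            assert w1[k] == pytest.approx(w2[k], abs=1e-7)

    def test_additive_metrics_agree_with_neighbor_joining(self):
        """On tree-like distances the nonzero splits equal the NJ tree's
        bipartitions (scikit-bio NJ as the independent oracle)."""
        from io import StringIO

        import skbio

        rng = np.random.default_rng(3)
        for trial in range(4):
            n = int(rng.integers(5, 9))
            labels = [f"t{i}" for i in range(n)]
            # random additive metric: random topology via random ordering splits
            tree = skbio.TreeNode.read(StringIO(_random_newick(labels, rng)))
            d = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        d[i, j] = d[j, i] = tree.find(a).distance(tree.find(b))
            system = neighbor_net(dm(labels, d))
            got = {s.side for s, w in system.splits if not s.is_trivial()
                   and w > 1e-8}
            want = set()
            for node in tree.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    if "t0" in side:
                        side = frozenset(labels) - side
                    want.add(side)
            assert got == want
            for s, w in system.splits:
                assert w >= 0


def _random_newick(labels, rng):
    """Random binary tree over labels with positive branch lengths."""
    nodes = [f"{x}:{rng.uniform(0.2, 1.0):.4f}" for x in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.2, 1.0):.4f}")
    return f"({nodes[0]},{nodes[1]});"


class TestNexusIO:
    def test_roundtrip_and_determinism(self, tmp_path, rng):
        labels = [f"t{i}" for i in range(5)]
        d = rng.uniform(0.2, 1.5, (5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        system = neighbor_net(dm(labels, d))
        p1, p2 = tmp_path / "a.nex", tmp_path / "b.nex"
        write_splits_nexus(system, p1)
        write_splits_nexus(system, p2)
        assert p1.read_bytes() == p2.read_bytes()
        text = p1.read_text()
        assert "BEGIN Splits" in text and "CYCLE" in text
        back = read_splits_nexus(p1)
        assert back.ordering.labels == system.ordering.labels
        w1 = {s.side: w for s, w in system.splits}
        w2 = {s.side: w for s, w in back.splits}
        assert w1 == w2

    def test_three_taxon_file_has_three_splits(self, tmp_path):
        d = np.array([[0, 1.0, 1.0], [1.0, 0, 1.0], [1.0, 1.0, 0]])
        system = neighbor_net(dm("ABC", d))
        p = tmp_path / "t.nex"
        write_splits_nexus(system, p)
        assert sum(1 for line in p.read_text().splitlines()
                   if line.startswith("[") and "," in line and "size=" in line) == 3
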