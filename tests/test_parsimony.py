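"""Dollo and constrained-Fitch reconstruction against exhaustive oracles."""

import itertools

import pytest

from intronarch import (
    IntronSiteMatrix,
    SpeciesTree,
    ancestral_intron_count,
    dollo_reconstruct,
    fitch_reconstruct,
)
from intronarch.parsimony import GAIN, LOSS, low_confidence_sites
from intronarch.simulate import SimConfig, simulate_family


def _matrix(tree, carriers, site="s"):
    leaves = tree.leaf_labels
    return IntronSiteMatrix.from_dict(
        {t: ({site} if t in carriers else set()) for t in leaves}, site_order=[site]
    )


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle (independent of the implementation)
# ---------------------------------------------------------------------------

def _enumerate_min_events(tree, carriers, dollo):
    """Minimum event count over all internal labelings.

    The absent ancestral state acts through a virtual edge above the root:
    a present root costs one gain. Under the Dollo constraint only labelings
    with at most one gain (virtual edge included) are admissible.
    """
    internal = [l for l in tree.postorder_labels() if not tree.is_leaf(l)]
    root = tree.root_label
    leaves = set(tree.leaf_labels)
    best = None
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = dict(zip(internal, assign))
        for leaf in leaves:
            states[leaf] = 1 if leaf in carriers else 0
        gains = states[root]  # change on the virtual edge above the root
        losses = 0
        for node in tree.preorder_labels():
            if node == root:
                continue
            parent = states[tree.parent_label(node)]
            if states[node] != parent:
                if states[node] == 1:
                    gains += 1
                else:
                    losses += 1
        if dollo and gains > 1:
            continue
        total = gains + losses
        if best is None or total < best:
            best = total
    return best


def _all_tree_shapes(n):
    """All rooted binary tree shapes with n leaves, canonical newick strings."""
    def shapes(k):
        if k == 1:
            return {"L"}
        out = set()
        for i in range(1, k // 2 + 1):
            for left in shapes(i):
                for right in shapes(k - i):
                    out.add("(%s,%s)" % tuple(sorted([left, right])))
        return out

    labeled = []
    for shape in sorted(shapes(n)):
        counter = itertools.count(1)
        newick = ""
        for ch in shape:
            newick += f"T{next(counter)}" if ch == "L" else ch
        labeled.append(newick + ";")
    return labeled


class TestSpecExamples:
    def test_single_clade_site(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        h = dollo_reconstruct(_matrix(tree, {"A", "B"}), tree)
        assert [(e.node, e.kind) for e in h.events] == [(tree.mrca_label(["A", "B"]), GAIN)]

    def test_gain_at_root_with_one_loss(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        h = dollo_reconstruct(_matrix(tree, {"A", "B", "C"}), tree)
        kinds = sorted((e.kind, e.node) for e in h.events)
        assert kinds == [(GAIN, tree.root_label), (LOSS, "D")]

    def test_all_present_site(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        h = dollo_reconstruct(_matrix(tree, {"A", "B", "C", "D"}), tree)
        assert [(e.node, e.kind) for e in h.events] == [(tree.root_label, GAIN)]

    def test_fitch_agrees_on_clean_clade(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        m = _matrix(tree, {"A", "B"})
        d = dollo_reconstruct(m, tree)
        f = fitch_reconstruct(m, tree)
        assert {(e.node, e.kind) for e in f.events} == {(e.node, e.kind) for e in d.events}

    def test_scattered_presence_ties_in_count(self):
        # presence on A, C, E of ((A,(B,C)),(D,E)): both methods need 3 events
        tree = SpeciesTree.from_newick("((A,(B,C)),(D,E));")
        m = _matrix(tree, {"A", "C", "E"})
        d = dollo_reconstruct(m, tree)
        f = fitch_reconstruct(m, tree)
        assert len(d.events) == len(f.events) == 3
        assert d.method != f.method  # both histories carry their method tag
        assert _enumerate_min_events(tree, {"A", "C", "E"}, dollo=False) == 3

    def test_empty_site_dropped(self, caplog):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        with caplog.at_level("WARNING", logger="intronarch"):
            h = dollo_reconstruct(_matrix(tree, set()), tree)
        assert h.events == []
        assert "dropped" in caplog.text


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_all_patterns_all_shapes(self, n):
        for newick in _all_tree_shapes(n):
            tree = SpeciesTree.from_newick(newick)
            leaves = tree.leaf_labels
            for bits in range(1, 2 ** n):
                carriers = {leaves[i] for i in range(n) if bits >> i & 1}
                m = _matrix(tree, carriers)
                d = dollo_reconstruct(m, tree)
                assert len(d.events) == _enumerate_min_events(tree, carriers, dollo=True)
                for tiebreak in ("ACCTRAN", "DELTRAN"):
                    f = fitch_reconstruct(m, tree, tiebreak=tiebreak)
                    assert len(f.events) == _enumerate_min_events(
                        tree, carriers, dollo=False
                    ), (newick, sorted(carriers), tiebreak)


class TestDolloProperties:
    def test_never_gains_twice(self, small_family):
        _, _, truth = small_family
        tree = SpeciesTree.from_newick(truth.tree_newick)
        h = dollo_reconstruct(truth.matrix(), tree)
        for site in {e.site for e in h.events}:
            assert sum(1 for e in h.events if e.site == site and e.kind == GAIN) == 1

    def test_leaf_states_match_matrix(self, small_family):
        _, _, truth = small_family
        tree = SpeciesTree.from_newick(truth.tree_newick)
        m = truth.matrix()
        h = dollo_reconstruct(m, tree)
        for site in m.sites:
            for taxon in m.taxa:
                assert h.states[site][taxon] == m.presence.loc[taxon, site]

    def test_missing_taxa_excluded_per_site(self):
        tree = SpeciesTree.from_newick("((A,B),(C,D));")
        m = IntronSiteMatrix.from_dict(
            {"A": {"s"}, "B": {"s"}, "C": set(), "D": set()},
            site_order=["s"],
            missing_taxa={"D"},
        )
        h = dollo_reconstruct(m, tree)
        # D carries no evidence: no loss may be charged to it
        assert all(e.node != "D" for e in h.events)
        assert h.states["s"]["D"] is None

    def test_loss_only_simulation_recovered_exactly(self):
        cfg = SimConfig(seed=5, n_leaves=8, gain_rate=0.0, loss_rate=0.3, subst_rate=0.0)
        _, truth = simulate_family(cfg)
        tree = SpeciesTree.from_newick(truth.tree_newick)
        h = dollo_reconstruct(truth.matrix(), tree)
        surviving = {s for sites in truth.leaf_sites.values() for s in sites}
        truth_events = {
            (e["site"], e["branch"], e["kind"])
            for e in truth.events
            if e["site"] in surviving
        }
        got = {(e.site, e.node, e.kind) for e in h.events}
        assert got == truth_events


class TestAncestralCounts:
    def test_unknown_node_errors(self, seed_plant_case):
        tree, matrix = seed_plant_case
        h = dollo_reconstruct(matrix, tree)
        with pytest.raises(KeyError):
            ancestral_intron_count(h, "no_such_node")

    def test_counts_at_named_clades(self, seed_plant_case):
        tree, matrix = seed_plant_case
        h = dollo_reconstruct(matrix, tree)
        assert ancestral_intron_count(h, "seed_plants") == 22
        assert ancestral_intron_count(h, "mesangiospermae") == 21
        assert ancestral_intron_count(h, tree.mrca_label(["Gnetum", "Welwitschia"])) == 23


def test_low_confidence_flags_method_disagreement():
    tree = SpeciesTree.from_newick("((A,(B,C)),(D,E));")
    m = IntronSiteMatrix.from_dict(
        {"A": {"x", "y"}, "B": {"y"}, "C": {"x", "y"}, "D": {"y"}, "E": {"x", "y"}},
        site_order=["x", "y"],
    )
    flagged = low_confidence_sites(m, tree)
    assert "y" not in flagged  # all-present: both methods gain it at the root
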