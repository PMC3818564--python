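"""Tree model, Newick I/O, surgery, covariance, rate smoothing, parsimony."""

import numpy as np
import pytest

from phylotraits import (
    NewickError,
    attach_sibling_halfway,
    count_origins_fitch,
    graft_rescaled,
    is_ultrametric,
    parse_newick,
    prune_to,
    resolve_polytomies,
    set_equal_branch_lengths,
    ultrametricize_pl,
    vcv,
    write_newick,
    yule_tree,
)
from phylotraits.phylo import _pl_pack

from conftest import random_tree
from oracles import bipartitions, brute_force_vcv, exhaustive_fitch


class TestNewick:
    def test_two_tip(self):
        t = parse_newick("(A:1,B:1);")
        assert t.n_tips == 2
        assert t.depths() == {"A": 1.0, "B": 1.0}

    def test_depths(self, three_tip):
        d = three_tip.depths()
        assert d["A"] == 2.0 and d["C"] == 2.0

    def test_topology_only_has_no_lengths(self):
        t = parse_newick("((A,B),(C,D));")
        assert t.n_tips == 4
        assert all(n.length is None for n in t.preorder() if n.parent is not None)
        assert ":" not in write_newick(t)

    @pytest.mark.parametrize(
        "bad", ["", "   ", "((A:1,B:1;", "(A:1,A:2);", "(A:1,(B:1,A:1):1);"]
    )
    def test_parse_errors(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_quoted_labels_and_comments(self):
        t = parse_newick("('Genus species':1[a comment],B:2);")
        assert "Genus species" in t.tip_labels

    def test_round_trip_small(self):
        s = write_newick(parse_newick("(A:1,B:1);"))
        t = parse_newick(s)
        assert sorted(t.tip_labels) == ["A", "B"]
        assert t.depths()["A"] == 1.0

    def test_round_trip_preserves_topology_and_lengths(self):
        tree = random_tree(100, seed=7, clock=False, rate_sd=0.5)
        back = parse_newick(write_newick(tree))
        assert bipartitions(back) == bipartitions(tree)
        d1, d2 = tree.depths(), back.depths()
        for label in d1:
            assert d2[label] == pytest.approx(d1[label], rel=1e-9)


class TestPrune:
    def test_hand_case(self, three_tip):
        p = prune_to(three_tip, {"A", "C"})
        assert sorted(p.tip_labels) == ["A", "C"]
        assert p.depths() == {"A": 2.0, "C": 2.0}

    def test_identity(self, three_tip):
        p = prune_to(three_tip, set(three_tip.tip_labels))
        assert bipartitions(p) == bipartitions(three_tip)
        assert p.depths() == three_tip.depths()

    def test_depths_preserved_random(self):
        tree = random_tree(64, seed=3, clock=False, rate_sd=0.4)
        rng = np.random.default_rng(0)
        keep = set(rng.choice(tree.tip_labels, size=10, replace=False))
        orig = tree.depths()
        pruned = prune_to(tree, keep)
        assert set(pruned.tip_labels) == keep
        for label in keep:
            assert pruned.depths()[label] == pytest.approx(orig[label], abs=1e-9)

    def test_unknown_label_listed(self, three_tip):
        with pytest.raises(KeyError, match="ZZZ"):
            prune_to(three_tip, {"A", "ZZZ"})


class TestAttachSibling:
    def test_halfway_split(self):
        t = attach_sibling_halfway(parse_newick("(A:4,C:4);"), "A", "B")
        d = t.depths()
        assert d == {"A": 4.0, "B": 4.0, "C": 4.0}
        a = t.find_tip("A")
        assert a.length == 2.0 and a.parent.length == 2.0

    def test_unit_branch_split_point(self):
        t = attach_sibling_halfway(parse_newick("(A:1,C:1);"), "A", "B")
        assert t.find_tip("A").length == 0.5

    def test_preserves_ultrametric_and_tip_count(self, tree10):
        label = tree10.tip_labels[4]
        out = attach_sibling_halfway(tree10, label, "new_sp")
        assert out.n_tips == tree10.n_tips + 1
        assert is_ultrametric(out, 1e-9)

    def test_duplicate_and_missing_length_errors(self, tree10):
        with pytest.raises(ValueError):
            attach_sibling_halfway(tree10, tree10.tip_labels[0], tree10.tip_labels[1])
        topo = parse_newick("((A,B),C);")
        with pytest.raises(ValueError):
            attach_sibling_halfway(topo, "A", "X")


class TestGraft:
    def test_scale_factor(self):
        backbone = parse_newick("((ref:6,B:6):2,C:8);")
        sub = parse_newick("((ref:2,X:2):1,Y:3);")  # root-to-ref = 3
        out = graft_rescaled(backbone, sub, "ref")
        d = out.depths()
        # attachment node depth 2; every subtree edge scaled by 6/3 = 2
        assert d["ref"] == pytest.approx(8.0)
        assert d["X"] == pytest.approx(8.0)
        assert d["Y"] == pytest.approx(2 + 3 * 2)

    def test_single_tip_subtree_identity(self):
        backbone = parse_newick("((ref:6,B:6):2,C:8);")
        sub = parse_newick("(ref:1);")
        out = graft_rescaled(backbone, sub, "ref")
        assert bipartitions(out) == bipartitions(backbone)
        assert out.depths() == backbone.depths()

    def test_depth_oracle_on_simulated_genus(self):
        backbone = random_tree(20, seed=9, clock=False, rate_sd=0.3)
        ref = backbone.tip_labels[5]
        genus = yule_tree(5, seed=4)
        for i, tip in enumerate(genus.tips()):
            tip.label = f"g{i}"
        genus.find_tip("g0").label = ref
        d_back = backbone.find_tip(ref).length
        attach_depth = backbone.depths()[ref] - d_back
        scale = d_back / genus.depths()[ref]
        out = graft_rescaled(backbone, genus, ref)
        assert out.depths()[ref] == pytest.approx(backbone.depths()[ref])
        for label, depth in genus.depths().items():
            assert out.depths()[label] == pytest.approx(attach_depth + scale * depth)

    def test_label_collision_error(self):
        backbone = parse_newick("((ref:6,B:6):2,C:8);")
        sub = parse_newick("(ref:1,B:1);")
        with pytest.raises(ValueError, match="collision"):
            graft_rescaled(backbone, sub, "ref")


class TestEqualBranchLengths:
    def test_all_edges_set(self):
        t = set_equal_branch_lengths(parse_newick("((A,B),(C,D));"), 1.0)
        lengths = [n.length for n in t.preorder() if n.parent is not None]
        assert lengths == [1.0] * 6

    def test_idempotent(self, tree10):
        once = set_equal_branch_lengths(tree10, 1.0)
        twice = set_equal_branch_lengths(once, 1.0)
        assert write_newick(once) == write_newick(twice)

    def test_caterpillar_depth_pattern(self):
        t = set_equal_branch_lengths(parse_newick("(((A,B),C),D);"), 1.0)
        assert sorted(t.depths().values()) == [1.0, 2.0, 3.0, 3.0]

    def test_rejects_nonpositive(self, tree10):
        with pytest.raises(ValueError):
            set_equal_branch_lengths(tree10, 0.0)


class TestVCV:
    def test_hand_case(self, three_tip):
        V = vcv(three_tip)
        assert V.labels == ("A", "B", "C")
        np.testing.assert_allclose(V.matrix, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_is_identity(self, star5):
        np.testing.assert_allclose(vcv(star5).matrix, np.eye(5))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_mrca_paths(self, seed):
        n = int(np.random.default_rng(seed).integers(5, 51))
        tree = random_tree(n, seed=seed, clock=False, rate_sd=0.4)
        labels, M = brute_force_vcv(tree)
        V = vcv(tree)
        assert list(V.labels) == labels
        np.testing.assert_allclose(V.matrix, M, atol=1e-12)

    def test_psd_and_symmetry(self, tree10):
        M = vcv(tree10).matrix
        np.testing.assert_allclose(M, M.T)
        assert np.linalg.eigvalsh(M).min() > -1e-12

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError):
            vcv(parse_newick("((A,B),C);"))


class TestUltrametricCheck:
    def test_true_and_false(self, three_tip):
        assert is_ultrametric(three_tip)
        assert not is_ultrametric(parse_newick("(A:1,B:2);"))


class TestResolvePolytomies:
    def test_binary_and_depth_preserving(self, star5):
        r = resolve_polytomies(star5)
        assert r.is_binary
        assert r.depths() == star5.depths()
        assert sorted(r.tip_labels) == sorted(star5.tip_labels)


class TestPenalizedLikelihood:
    def test_two_tip_forced(self):
        ch = ultrametricize_pl(parse_newick("(A:1,B:3);"), smoothing=10.0)
        assert is_ultrametric(ch.tree, 1e-9)
        assert ch.tree.depths() == pytest.approx({"A": 1.0, "B": 1.0})

    def test_clock_input_recovers_true_ages(self):
        true = yule_tree(30, seed=2)
        depths = true.node_depths()
        H = true.max_depth()
        clock = true.copy()
        for n in clock.preorder():
            if n.parent is not None:
                n.length *= 3.0  # constant rate
        ch = ultrametricize_pl(clock, smoothing=10.0, seed=0)
        true_ages = np.array([1.0 - depths[id(n)] / H for n in true.preorder()])
        internal = np.array([not n.is_tip for n in ch.tree.preorder()])
        np.testing.assert_allclose(ch.ages[internal], true_ages[internal], atol=1e-3)

    def test_rate_perturbed_age_correlation(self):
        true = yule_tree(40, seed=11)
        depths = true.node_depths()
        H = true.max_depth()
        work = true.copy()
        rng = np.random.default_rng(3)
        for n in work.preorder():
            if n.parent is not None:
                n.length *= rng.lognormal(0.0, 0.3)
        ch = ultrametricize_pl(work, smoothing=10.0, seed=2)
        true_ages = np.array([1.0 - depths[id(n)] / H for n in true.preorder()])
        internal = np.array([not n.is_tip for n in ch.tree.preorder()])
        r = np.corrcoef(true_ages[internal], ch.ages[internal])[0, 1]
        assert r >= 0.9

    def test_output_always_ultrametric_and_rates_positive(self):
        for seed in range(5):
            tree = random_tree(15, seed=seed, clock=False, rate_sd=0.6)
            ch = ultrametricize_pl(tree, smoothing=10.0, seed=seed)
            assert is_ultrametric(ch.tree, 1e-6)
            rates = ch.rates[~np.isnan(ch.rates)]
            assert (rates > 0).all()
            ages = ch.ages
            parent = _pl_pack(ch.tree)[1]
            for i in range(1, len(ages)):
                assert ages[parent[i]] > ages[i]

    def test_analytic_gradient_matches_finite_differences(self):
        # check the optimizer's gradient on a small perturbed tree
        from phylotraits import phylo as P

        tree = random_tree(8, seed=5, clock=False, rate_sd=0.5)
        work = tree.copy()
        nodes, parent, is_tip, x = P._pl_pack(work)
        captured = {}

        orig_min = P.minimize

        def spy(fun, x0, **kw):
            captured["fun"] = fun
            captured["x0"] = x0
            return orig_min(fun, x0, **kw)

        P.minimize = spy
        try:
            ultrametricize_pl(tree, smoothing=5.0, n_restarts=1)
        finally:
            P.minimize = orig_min
        fun, x0 = captured["fun"], captured["x0"]
        f0, g0 = fun(x0)
        num = np.empty_like(x0)
        h = 1e-6
        for i in range(x0.size):
            xp = x0.copy()
            xp[i] += h
            xm = x0.copy()
            xm[i] -= h
            num[i] = (fun(xp)[0] - fun(xm)[0]) / (2 * h)
        np.testing.assert_allclose(g0, num, rtol=1e-4, atol=1e-6)


class TestFitch:
    def test_single_clade_one_origin(self):
        t = parse_newick("((A,B),(C,D));")
        assert count_origins_fitch(t, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1

    def test_alternating_two_changes(self):
        t = parse_newick("((A,B),(C,D));")
        assert count_origins_fitch(t, {"A": 1, "B": 0, "C": 1, "D": 0}) == 2

    def test_constant_trait_zero(self, tree10):
        states = {l: 1 for l in tree10.tip_labels}
        assert count_origins_fitch(tree10, states) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_minimization(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        tree = yule_tree(n, seed=seed)
        states = {l: int(s) for l, s in zip(tree.tip_labels, rng.integers(0, 2, n))}
        assert count_origins_fitch(tree, states) == exhaustive_fitch(tree, states)

    def test_missing_states_rejected(self, tree10):
        with pytest.raises(KeyError):
            count_origins_fitch(tree10, {tree10.tip_labels[0]: 1})
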