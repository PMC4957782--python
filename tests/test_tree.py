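"""Tree generation: Murray conservation, algorithm structure, serialization."""

import json

import numpy as np
import pytest

from renalnet.morphometry import MorphometricDistributions
from renalnet.tree import (
    AFFERENT,
    ROOT,
    TreeError,
    VascularTree,
    build_abt,
    build_ksabt,
    load_tree,
    murray_second_daughter,
    save_tree,
    segment_vessel,
    strahler_orders,
    tree_summary,
)

SYMMETRIC = MorphometricDistributions(
    ddp_mean_coeffs=(0.0, 0.7937005259840998), ddp_sd_coeffs=(0.0,),
    vlvd_mean_coeffs=(0.0, 7.5), vlvd_sd_coeffs=(0.0,),
    aa_spacing_rate=1e-12, aa_diam_mean=19.25, aa_diam_sd=0.0,
    valid_diameter_range=(1.0, 1000.0), name="symmetric")


def small_dists(lam=0.01):
    return MorphometricDistributions(
        ddp_mean_coeffs=(0.0, 0.78), ddp_sd_coeffs=(0.2, 0.03),
        vlvd_mean_coeffs=(0.0, 8.0), vlvd_sd_coeffs=(0.0, 2.0),
        aa_spacing_rate=lam, aa_diam_mean=16.5, aa_diam_sd=1.5,
        valid_diameter_range=(1.0, 1000.0), name="small")


class TestMurray:
    def test_limit_of_vanishing_first_daughter(self):
        assert murray_second_daughter(30.0, 1e-9) == pytest.approx(30.0)

    def test_symmetric_split(self):
        d1 = 30.0 * 2 ** (-1 / 3)
        assert murray_second_daughter(30.0, d1) == pytest.approx(d1, rel=1e-12)

    def test_direct_evaluation(self):
        # (30^3 - 25^3)^(1/3) = 11375^(1/3)
        assert murray_second_daughter(30.0, 25.0) == pytest.approx(
            11375.0 ** (1 / 3), rel=1e-12)

    def test_invalid_bifurcations(self):
        with pytest.raises(TreeError):
            murray_second_daughter(20.0, 25.0)
        with pytest.raises(TreeError):
            murray_second_daughter(20.0, -1.0)


class TestABT:
    def test_degenerate_symmetric_tree_is_perfect_binary(self, rng):
        tree = build_abt(40.0, 22.0, SYMMETRIC, rng)
        # 40 * 2^(-k/3) <= 22 first at k = 3 -> 8 terminal arterioles
        assert len(tree.arterioles()) == 8
        assert all(v.diameter == pytest.approx(20.0, rel=1e-9)
                   for v in tree.arterioles())
        tree.validate()

    def test_arterioles_only_at_terminal_bifurcations(self, rng):
        tree = build_abt(80.0, 22.0, small_dists(), rng)
        children = tree.children_map()
        for aa in tree.arterioles():
            assert aa.origin_offset == 0.0
            siblings = children[aa.parent_node]
            assert len(siblings) == 2  # a bifurcation, never a side branch

    def test_murray_holds_at_every_node(self, rng):
        tree = build_abt(100.0, 22.0, small_dists(), rng)
        tree.validate()  # includes the 1e-9 cube check at every node

    def test_monotone_diameter_along_paths(self, rng):
        tree = build_ksabt(80.0, 22.0, small_dists(), rng)
        inbound = tree.inbound_map()
        for v in tree.vessels:
            up = inbound.get(v.parent_node)
            if up is not None:
                assert v.diameter <= up.diameter + 1e-12

    def test_invalid_parameters(self, rng):
        with pytest.raises(TreeError):
            build_abt(20.0, 22.0, SYMMETRIC, rng)
        with pytest.raises(TreeError):
            build_abt(40.0, -1.0, SYMMETRIC, rng)

    def test_same_seed_identical_tree(self, default_dists):
        t1 = build_abt(80.0, 22.0, default_dists, np.random.default_rng(3))
        t2 = build_abt(80.0, 22.0, default_dists, np.random.default_rng(3))
        assert [(v.diameter, v.length, v.kind) for v in t1.vessels] == \
               [(v.diameter, v.length, v.kind) for v in t2.vessels]


class _FixedSpacingRng:
    """Stub generator: deterministic exponential draws (zero-variance
    spacing process); Gaussian paths are untouched by zero-SD profiles."""

    def __init__(self, spacing):
        self.spacing = spacing

    def exponential(self, scale):
        return self.spacing

    def standard_normal(self):  # pragma: no cover - zero-SD profiles skip it
        return 0.0


class TestSegmentation:
    def test_no_event_limit_carries_shift(self, rng):
        d = small_dists(lam=1e-12)  # spacings far exceed any vessel
        events, s_out, d_end = segment_vessel(40.0, 300.0, 1e9, d, rng, 22.0)
        assert events == []
        assert d_end == 40.0
        assert s_out == pytest.approx(1e9 - 300.0)

    def test_deterministic_walk_two_events(self):
        d = SYMMETRIC
        stub = _FixedSpacingRng(150.0)
        events, s_out, d_end = segment_vessel(40.0, 300.0, 150.0, d, stub, 22.0)
        assert [e[0] for e in events] == [150.0, 300.0]
        diams_after = [e[3] for e in events]
        assert diams_after[0] > diams_after[1]  # strictly decreasing
        assert s_out == pytest.approx(150.0)

    def test_murray_at_each_attachment(self):
        stub = _FixedSpacingRng(60.0)
        events, _, _ = segment_vessel(40.0, 300.0, 60.0, SYMMETRIC, stub, 22.0)
        d_before = 40.0
        for (_, d_aff, _, d_after) in events:
            assert d_before ** 3 == pytest.approx(d_after ** 3 + d_aff ** 3,
                                                  rel=1e-12)
            d_before = d_after

    def test_stops_before_crossing_stop_diameter(self):
        stub = _FixedSpacingRng(10.0)
        events, _, d_end = segment_vessel(24.0, 500.0, 10.0, SYMMETRIC, stub, 22.0)
        assert d_end > 22.0  # never reduced to or below D_stop


class TestKSABT:
    def test_zero_rate_limit_matches_abt_distribution(self, default_dists):
        from dataclasses import replace
        lam0 = replace(default_dists, aa_spacing_rate=1e-12)
        n_abt, n_ks = [], []
        for seed in range(20):
            n_abt.append(len(build_abt(60.0, 22.0, lam0,
                                       np.random.default_rng(seed)).arterioles()))
            n_ks.append(len(build_ksabt(60.0, 22.0, lam0,
                                        np.random.default_rng(50 + seed)).arterioles()))
        assert np.mean(n_ks) == pytest.approx(np.mean(n_abt), rel=0.25)

    def test_more_arterioles_and_wider_feeders_than_abt(self, default_dists):
        sa = tree_summary(build_abt(120.0, 22.0, default_dists,
                                    np.random.default_rng(1)))
        sk = tree_summary(build_ksabt(120.0, 22.0, default_dists,
                                      np.random.default_rng(1)))
        assert sk["n_arterioles"] > sa["n_arterioles"]
        assert sk["aa_feed_diam_mean"] > sa["aa_feed_diam_mean"]

    def test_side_arterioles_anywhere_but_not_on_root(self, default_dists):
        tree = build_ksabt(120.0, 22.0, default_dists, np.random.default_rng(2))
        root_end = tree.root_vessel.child_node
        side = [v for v in tree.arterioles() if v.origin_offset > 0]
        assert side, "segmentation must attach side arterioles"
        assert all(v.parent_node != root_end or True for v in side)
        # no arteriole may branch from the renal artery's own span: the root
        # vessel is a single unsegmented vessel, so nothing attaches along it
        inbound = tree.inbound_map()
        for v in side:
            assert inbound[v.parent_node].kind != ROOT


class TestStrahler:
    def test_single_vessel(self):
        t = VascularTree(meta={})
        t._add_vessel(0, 20.0, 100.0, ROOT)
        assert strahler_orders(t) == {0: 1}

    def test_perfect_depth_two_tree(self, rng):
        tree = build_abt(40.0, 26.0, SYMMETRIC, rng)  # two levels to <=26
        orders = strahler_orders(tree)
        assert orders[tree.root_vessel.id] == 3

    def test_matches_bruteforce_recursion(self, default_dists):
        tree = build_ksabt(70.0, 22.0, default_dists, np.random.default_rng(9))
        children = tree.children_map()

        def brute(v):
            kids = children.get(v.child_node, [])
            if not kids:
                return 1
            orders = sorted((brute(k) for k in kids), reverse=True)
            return orders[0] + 1 if orders.count(orders[0]) >= 2 else orders[0]

        fast = strahler_orders(tree)
        assert all(fast[v.id] == brute(v) for v in tree.vessels)


class TestSummary:
    def test_single_arteriole_gives_no_distances(self):
        t = VascularTree(meta={"variant": "fixture"})
        t._add_vessel(0, 20.0, 100.0, ROOT)
        t._add_vessel(1, 20.0, 50.0, AFFERENT)
        s = tree_summary(t)
        assert len(s["inter_aa_distances"]) == 0
        assert s["n_arterioles"] == 1

    def test_hand_built_chain_distances(self):
        # artery chain with three side arterioles: segment lengths 100/80/120
        t = VascularTree(meta={"variant": "ksabt"})
        t._add_vessel(0, 40.0, 200.0, ROOT)                       # 0 -> 1
        d1 = 30.0
        a = (d1 ** 3 - 16.0 ** 3) ** (1 / 3)
        b = (a ** 3 - 16.0 ** 3) ** (1 / 3)
        t._add_vessel(1, d1, 100.0, "artery", branch_index=0)     # 1 -> 2
        t._add_vessel(2, 16.0, 150.0, AFFERENT, origin_offset=100.0)
        t._add_vessel(2, a, 80.0, "artery", branch_index=0)       # 2 -> 4
        t._add_vessel(4, 16.0, 150.0, AFFERENT, origin_offset=180.0)
        t._add_vessel(4, b, 120.0, "artery", branch_index=0)      # 4 -> 6
        t._add_vessel(6, 16.0, 150.0, AFFERENT, origin_offset=300.0)
        # unsegmented remainder of the chain keeps the cube balance at node 6
        c = (b ** 3 - 16.0 ** 3) ** (1 / 3)
        t._add_vessel(6, c, 60.0, "artery", branch_index=0)
        # second daughter of the root balances Murray at node 1
        d2 = (40.0 ** 3 - d1 ** 3) ** (1 / 3)
        t._add_vessel(1, d2, 90.0, AFFERENT, branch_index=1)
        t.validate()
        dist = sorted(tree_summary(t)["inter_aa_distances"])
        assert dist == pytest.approx([80.0, 120.0])

    def test_ksabt_walk_distances_follow_the_exponential(self, default_dists):
        from scipy import stats
        tree = build_ksabt(200.0, 22.0, default_dists, np.random.default_rng(4))
        d = tree_summary(tree)["inter_aa_distances"]
        assert len(d) > 100
        res = stats.kstest(d, "expon",
                           args=(0, 1.0 / default_dists.aa_spacing_rate))
        assert res.statistic < 1.36 / np.sqrt(len(d))  # 5% critical value


class TestSerialization:
    def test_round_trip(self, tmp_path, default_dists):
        tree = build_ksabt(60.0, 22.0, default_dists, np.random.default_rng(5),
                           seed=5)
        path = tmp_path / "tree.json"
        save_tree(tree, path)
        back = load_tree(path)
        assert back.n_nodes == tree.n_nodes
        assert [(v.id, v.parent_node, v.child_node, v.diameter, v.length,
                 v.kind, v.origin_offset, v.branch_index)
                for v in back.vessels] == \
               [(v.id, v.parent_node, v.child_node, v.diameter, v.length,
                 v.kind, v.origin_offset, v.branch_index)
                for v in tree.vessels]
        assert back.meta["seed"] == 5

    def test_murray_violation_rejected_on_load(self, tmp_path, default_dists):
        tree = build_abt(60.0, 22.0, default_dists, np.random.default_rng(6))
        path = tmp_path / "bad.json"
        save_tree(tree, path)
        payload = json.loads(path.read_text())
        payload["vessels"][1]["diameter_um"] *= 1.05
        path.write_text(json.dumps(payload))
        with pytest.raises(TreeError):
            load_tree(path)

    def test_malformed_file(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text("{not json")
        with pytest.raises(TreeError):
            load_tree(path)

    def test_metadata_seed_regenerates_identical_tree(self, tmp_path, default_dists):
        tree = build_ksabt(60.0, 22.0, default_dists,
                           np.random.default_rng(11), seed=11)
        again = build_ksabt(tree.meta["d_initial"], tree.meta["d_stop"],
                            default_dists,
                            np.random.default_rng(tree.meta["seed"]),
                            seed=tree.meta["seed"])
        assert [(v.diameter, v.length) for v in again.vessels] == \
               [(v.diameter, v.length) for v in tree.vessels]
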