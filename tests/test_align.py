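import pytest

from motifprofiler import (
    align_profiles,
    build_compatibility_graph,
    build_profile,
    enumerate_orientations,
    extend_alignment,
    find_best_clique,
    merge_profiles,
    motif_to_profile,
    order_interactions,
    relation_group,
    rotate_profile,
)
from motifprofiler.align import CompatibilityGraph, Vertex
from motifprofiler.profile import Profile
from motifprofiler.synth import KINK_TURN_LIKE, random_profile, sample_family

from _oracles import best_clique_exhaustive, random_graph, random_small_profile


def _profile(columns, bp=None, stk=None, break_points=None, mc=1):
    return Profile(
        columns=columns,
        bp=bp or {},
        stk=stk or {},
        break_points=break_points or [len(columns)],
        mc=mc,
    )


def _uniform(seq, mc=1):
    return [{nt: mc} for nt in seq]


class TestOrderInteractions:
    def test_five_prime_ordering(self):
        p = _profile(
            _uniform("AAAAAAAAAAAA"),
            bp={(2, 9): {("cis-W/W", "A-A"): 1}, (1, 7): {("cis-W/W", "A-A"): 1}, (1, 12): {("cis-W/W", "A-A"): 1}},
        )
        assert order_interactions(p) == [(1, 7), (1, 12), (2, 9)]

    def test_random_cells_match_sort_oracle(self, rng):
        cells = {
            (int(i), int(j)): {("cis-W/W", "A-A"): 1}
            for i, j in ((rng.integers(1, 11), rng.integers(11, 21)) for _ in range(10))
        }
        p = _profile(_uniform("A" * 20), bp=cells)
        assert order_interactions(p) == sorted(cells)


class TestRelationGroup:
    @pytest.mark.parametrize(
        "a,b,group",
        [
            ((1, 4), (5, 9), "juxtaposing"),
            ((1, 4), (4, 9), "juxtaposing_shared"),
            ((1, 6), (3, 9), "crossing"),
            ((1, 9), (3, 6), "enclosing"),
            ((2, 6), (2, 10), "enclosing_shared_left"),
            ((2, 10), (6, 10), "enclosing_shared_right"),
        ],
    )
    def test_named_configurations(self, a, b, group):
        assert relation_group(a, b) == group

    def test_exhaustive_partition_small_indices(self):
        # every ordered pair of distinct cells with indices <= 5 falls in
        # exactly one group, and the group matches declarative predicates
        cells = [(i, j) for i in range(1, 6) for j in range(i + 1, 6)]
        for a in cells:
            for b in cells:
                if not (a < b):
                    continue
                g = relation_group(a, b)
                (i, j), (k, l) = a, b
                shared = {i, j} & {k, l}
                if g == "juxtaposing":
                    assert j < k and not shared
                elif g == "juxtaposing_shared":
                    assert j == k
                elif g == "crossing":
                    assert i < k < j < l and not shared
                elif g == "enclosing":
                    assert i < k < l < j and not shared
                elif g == "enclosing_shared_left":
                    assert i == k and j < l
                elif g == "enclosing_shared_right":
                    assert j == l and i < k
                else:
                    pytest.fail(f"unknown group {g}")

    def test_identical_cells_rejected(self):
        with pytest.raises(ValueError):
            relation_group((1, 4), (1, 4))


class TestOrientations:
    def test_worked_internal_loop_reindexing(self):
        # 7+5 internal loop with a pair at (2,10): the flipped orientation
        # has strand lengths 5 then 7 and the pair at (3,7), edges reversed
        p = _profile(
            _uniform("A" * 12),
            bp={(2, 10): {("trans-H/S", "A-A"): 1}},
            break_points=[7, 12],
        )
        q = rotate_profile(p, 1)
        assert q.break_points == [5, 12]
        assert q.bp == {(3, 7): {("trans-S/H", "A-A"): 1}}

    def test_full_rotation_is_identity(self, rng):
        for _ in range(100):
            p = random_profile(rng)
            q = p
            for _ in range(p.n_segments):
                q = rotate_profile(q, 1)
            assert q.structurally_equal(p)

    def test_hairpin_has_single_orientation(self, rng):
        p = random_small_profile(rng, 1)
        assert len(enumerate_orientations(p)) == 1

    def test_three_way_orientations_preserve_entries(self, rng):
        from motifprofiler.motifs import BasePairType

        for _ in range(20):
            p = random_small_profile(rng, 3)
            oris = enumerate_orientations(p)
            assert len(oris) == 3

            def canon(profile):
                out = []
                for cell in profile.bp.values():
                    for (lw, pair), c in cell.items():
                        rev = str(BasePairType.from_string(lw).reverse())
                        rpair = "-".join(reversed(pair.split("-")))
                        out.append((min((lw, pair), (rev, rpair)), c))
                return sorted(out)

            for q in oris:
                assert canon(q) == canon(p)
                assert sum(len(c) for c in q.bp.values()) == sum(len(c) for c in p.bp.values())


class TestCompatibilityGraph:
    def test_single_cell_each_gives_one_vertex_no_edges(self, matrices, cfg):
        x = _profile(_uniform("GAAA"), bp={(1, 4): {("cis-W/W", "G-A"): 1}})
        y = _profile(_uniform("GAAA"), bp={(1, 4): {("cis-W/W", "G-A"): 1}})
        g = build_compatibility_graph(x, y, matrices, cfg)
        assert g.n == 1 and g.adj == [set()]

    def test_two_juxtaposing_cells_each(self, matrices, cfg):
        bp = {(1, 4): {("cis-W/W", "A-A"): 1}, (5, 9): {("trans-H/S", "A-A"): 1}}
        x = _profile(_uniform("A" * 9), bp=bp)
        y = _profile(_uniform("A" * 9), bp=dict(bp))
        g = build_compatibility_graph(x, y, matrices, cfg)
        assert g.n == 4
        # of the 4*3/2 candidate edges, only the order-preserving matching
        # pair (x1->y1 with x2->y2) is consistent: sharing an x or y cell is
        # a double use, and the crossed pair (x1->y2 with x2->y1) would be a
        # non-monotone alignment
        edges = {(u, v) for u in range(4) for v in g.adj[u] if u < v}
        consistent = {
            (u, v)
            for (u, v) in edges
            for vu, vv in [(g.vertices[u], g.vertices[v])]
            if vu.x_cell < vv.x_cell and vu.y_cell < vv.y_cell
        }
        assert edges == consistent and len(edges) == 1

    def test_stacking_vertices_follow_flag(self, matrices, cfg):
        from motifprofiler.align import AlignConfig

        x = _profile(_uniform("GAAA"), stk={(1, 2): {"upward": 1}})
        y = _profile(_uniform("GAAA"), stk={(1, 2): {"upward": 1}})
        assert build_compatibility_graph(x, y, matrices, cfg).n == 0
        g = build_compatibility_graph(x, y, matrices, AlignConfig(include_stackings=True))
        assert g.n == 1 and g.vertices[0].kind == "stacking"

    def test_cross_segment_matchings_excluded(self, matrices, cfg):
        x = _profile(_uniform("A" * 8), bp={(2, 3): {("cis-W/W", "A-A"): 1}}, break_points=[4, 8])
        y = _profile(_uniform("A" * 8), bp={(6, 7): {("cis-W/W", "A-A"): 1}}, break_points=[4, 8])
        assert build_compatibility_graph(x, y, matrices, cfg).n == 0


class TestFindBestClique:
    def test_single_vertex(self):
        g = CompatibilityGraph(vertices=[Vertex("basepair", (1, 2), (1, 2), 4.0)], adj=[set()])
        idxs, score = find_best_clique(g)
        assert idxs == [0] and score == 4.0

    def test_isolated_heavy_vertex_beats_light_triangle(self):
        verts = [Vertex("basepair", (1, 2), (1, 2), w) for w in (1.0, 1.0, 1.0, 10.0)]
        adj = [{1, 2}, {0, 2}, {0, 1}, set()]
        g = CompatibilityGraph(vertices=verts, adj=adj)
        idxs, score = find_best_clique(g)
        assert idxs == [3] and score == 10.0

    def test_empty_graph_returns_empty_clique(self):
        idxs, score = find_best_clique(CompatibilityGraph(vertices=[], adj=[]))
        assert idxs == [] and score == 0.0

    def test_negative_weights_prefer_empty_clique(self):
        verts = [Vertex("basepair", (1, 2), (1, 2), -1.0)]
        g = CompatibilityGraph(vertices=verts, adj=[set()])
        assert find_best_clique(g) == ([], 0.0)

    def test_matches_subset_enumeration(self, rng):
        for _ in range(40):
            g = random_graph(rng, n_max=8)
            got_idxs, got_score = find_best_clique(g)
            want_idxs, want_score = best_clique_exhaustive(g)
            assert got_score == pytest.approx(want_score)
            assert got_idxs == want_idxs


class TestExtendAlignment:
    def test_empty_clique_identical_profiles_identity_mapping(self, matrices, cfg):
        p = _profile(_uniform("GCAU"))
        res = extend_alignment(p, p, [], matrices, cfg)
        assert res.mapping == [(1, 1), (2, 2), (3, 3), (4, 4)]
        from motifprofiler.scoring import score_nt_column

        want = sum(score_nt_column(c, c, matrices, cfg.normalize_counts, 1) for c in p.columns)
        assert res.score == pytest.approx(want)

    def test_anchored_self_alignment_is_identity(self, matrices, cfg):
        p = _profile(
            _uniform("A" * 12),
            bp={(2, 10): {("trans-H/S", "A-A"): 1}},
            break_points=[7, 12],
        )
        g = build_compatibility_graph(p, p, matrices, cfg)
        res = extend_alignment(p, p, g.vertices, matrices, cfg)
        assert res.mapping == [(i, i) for i in range(1, 13)]

    def test_segment_mismatch_rejected(self, matrices, cfg):
        hairpin = _profile(_uniform("GAAA"))
        internal = _profile(_uniform("GAAA"), break_points=[2, 4])
        with pytest.raises(ValueError, match="segment"):
            extend_alignment(hairpin, internal, [], matrices, cfg)

    def test_gaps_never_bridge_break_points(self, matrices, cfg):
        x = _profile(_uniform("GCAUG"), break_points=[3, 5])
        y = _profile(_uniform("GCG"), break_points=[2, 3])
        res = extend_alignment(x, y, [], matrices, cfg)
        # segment 1 of x (cols 1-3) must align within segment 1 of y (cols 1-2)
        for xi, yj in res.mapping:
            if xi is not None and yj is not None:
                assert x.segment_of(xi) == y.segment_of(yj)


class TestAlignProfiles:
    def test_self_alignment_matches_every_bp_cell(self, matrices, cfg, kink_family):
        p = build_profile(kink_family, matrices, cfg)
        res = align_profiles(p, p, matrices, cfg)
        assert res.orientation == 0
        assert res.mapping == [(i, i) for i in range(1, p.length + 1)]
        assert {v.x_cell for v in res.clique} == set(p.bp)
        assert all(v.x_cell == v.y_cell for v in res.clique)

    def test_junction_type_mismatch_raises(self, matrices, cfg):
        hairpin = _profile(_uniform("GAAA"))
        internal = _profile(_uniform("GAAA"), break_points=[2, 4])
        with pytest.raises(ValueError, match="segments"):
            align_profiles(hairpin, internal, matrices, cfg)

    def test_shared_bps_anchor_clique(self, matrices, cfg):
        a, b = sample_family(KINK_TURN_LIKE, 2, seed=7)
        pa, pb = motif_to_profile(a), motif_to_profile(b)
        shared = set(pa.bp) & set(pb.bp)
        res = align_profiles(pa, pb, matrices, cfg)
        assert len([v for v in res.clique if v.kind == "basepair"]) >= min(len(shared), 3)

    def test_score_invariant_under_common_rotation(self, matrices, cfg, rng):
        for _ in range(8):
            x = random_small_profile(rng, 2)
            y = random_small_profile(rng, 2)
            s0 = align_profiles(x, y, matrices, cfg).score
            s1 = align_profiles(rotate_profile(x, 1), rotate_profile(y, 1), matrices, cfg).score
            assert s0 == pytest.approx(s1)


class TestMergeProfiles:
    def test_self_merge_doubles_every_count(self, matrices, cfg, kink_family):
        p = build_profile(kink_family, matrices, cfg)
        res = align_profiles(p, p, matrices, cfg)
        m = merge_profiles(p, p, res)
        assert m.mc == 2 * p.mc
        for col, col0 in zip(m.columns, p.columns):
            assert col == {k: 2 * v for k, v in col0.items()}
        for cell, cell0 in zip(m.bp.values(), p.bp.values()):
            assert cell == {k: 2 * v for k, v in cell0.items()}

    def test_extra_five_prime_column_gains_gap(self, matrices, cfg):
        x = _profile(_uniform("GGAAA"), bp={(2, 5): {("cis-W/W", "G-A"): 1}})
        y = _profile(_uniform("GAAA"), bp={(1, 4): {("cis-W/W", "G-A"): 1}})
        res = align_profiles(x, y, matrices, cfg)
        m = merge_profiles(x, y, res)
        assert m.mc == 2
        assert m.columns[0] == {"G": 1, "-": 1}
        # the shared bp cell carries both counts
        assert any(sum(cell.values()) == 2 for cell in m.bp.values())

    def test_merge_conserves_interaction_totals(self, matrices, cfg, rng):
        for _ in range(10):
            x = random_small_profile(rng, 2)
            y = random_small_profile(rng, 2)
            res = align_profiles(x, y, matrices, cfg)
            m = merge_profiles(x, y, res)
            assert m.mc == x.mc + y.mc
            for col in m.columns:
                assert sum(col.values()) == m.mc

            def total(cells):
                return sum(c for cell in cells.values() for c in cell.values())

            assert total(m.bp) == total(x.bp) + total(y.bp)
            assert total(m.stk) == total(x.stk) + total(y.stk)
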